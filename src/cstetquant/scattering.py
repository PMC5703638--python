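"""Predicted bright-field scattering signals of reference materials.

In BF STEM, electrons scattered beyond the detector's outer cutoff angle are
lost from the recorded signal, so the local decrement of BF intensity is
proportional (in the thin-sample, single-scattering regime) to

    S = sum_e  n_e * sigma_e   [nm^-1]

where n_e is the number density of element e (atoms/nm^3) and sigma_e the
partial elastic cross-section for scattering beyond the cutoff (nm^2). A
packaged per-element cross-section table for 200 keV and a 5 mrad BF cutoff
is the default pathway; a screened-atom (Lenz) model is available for
sensitivity analysis.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Mapping

import pandas as pd
from scipy import constants

from cstetquant.composition import NumberDensityProfile
from cstetquant.elements import ATOMIC_NUMBERS

logger = logging.getLogger(__name__)

Provenance = Literal["packaged_table", "lenz_model", "user"]


@dataclass(frozen=True)
class BeamConfig:
    """Electron beam energy (keV) and BF detector outer cutoff (mrad)."""

    energy_kev: float = 200.0
    bf_cutoff_mrad: float = 5.0

    def __post_init__(self) -> None:
        if self.energy_kev <= 0:
            raise ValueError("beam energy must be positive")
        if not 0 < self.bf_cutoff_mrad < math.pi * 1000:
            raise ValueError("BF cutoff must be in (0, pi) rad")


@dataclass(frozen=True)
class CrossSectionTable:
    """Per-element partial cross-sections (nm^2) beyond the BF cutoff."""

    beam: BeamConfig
    sigma: Mapping[str, float]
    provenance: Provenance = "user"

    def __post_init__(self) -> None:
        for el, s in self.sigma.items():
            if s < 0:
                raise ValueError(f"negative cross-section for {el!r}")


@dataclass(frozen=True)
class ScatteringSignal:
    """Expected scattered signal per nm^3 of a material, nm^-1."""

    label: str
    signal: float

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("scattering signal must be non-negative")


def load_cross_sections(path=None) -> CrossSectionTable:
    """Load a cross-section table; default is the packaged 200 keV / 5 mrad one.

    File format: '#'-prefixed header lines recording ``energy_keV`` and
    ``cutoff_mrad``, then CSV columns ``element,sigma_nm2``.
    """
    if path is None:
        ref = resources.files("cstetquant") / "reference_data" / "cross_sections_200kV_5mrad.csv"
        text = ref.read_text()
        provenance: Provenance = "packaged_table"
    else:
        with open(path) as fh:
            text = fh.read()
        provenance = "user"
    meta = {}
    body = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = float(val)
        elif line.strip():
            body.append(line)
    sigma = {
        row["element"]: float(row["sigma_nm2"])
        for row in csv.DictReader(io.StringIO("\n".join(body)))
    }
    beam = BeamConfig(meta.get("energy_keV", 200.0), meta.get("cutoff_mrad", 5.0))
    return CrossSectionTable(beam, sigma, provenance)


def write_cross_sections(table: CrossSectionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# energy_keV: {table.beam.energy_kev}\n")
        fh.write(f"# cutoff_mrad: {table.beam.bf_cutoff_mrad}\n")
        fh.write("element,sigma_nm2\n")
        for el, s in table.sigma.items():
            fh.write(f"{el},{s}\n")


def signal_per_volume(
    profile: NumberDensityProfile, xsec: CrossSectionTable
) -> ScatteringSignal:
    """Scattering signal per nm^3: sum of density_e * sigma_e over elements.

    Hydrogen may be absent from the table (it does not scatter beyond the
    cutoff); any other element with nonzero density must be present.
    """
    total = 0.0
    for el, dens in profile.densities.items():
        if el not in xsec.sigma:
            if el == "H" or dens == 0.0:
                continue
            raise KeyError(
                f"element {el!r} (density {dens}/nm^3) missing from cross-section table"
            )
        total += dens * xsec.sigma[el]
    return ScatteringSignal(profile.label, total)


def predicted_ratio(
    numerator: ScatteringSignal, denominator: ScatteringSignal
) -> float:
    """Predicted BF intensity-decrement ratio between two materials."""
    if denominator.signal <= 0:
        raise ZeroDivisionError("denominator signal must be positive")
    return numerator.signal / denominator.signal


def reference_signal_report(
    profiles: Mapping[str, NumberDensityProfile] | None = None,
    xsec: CrossSectionTable | None = None,
    signal_decimals: int = 3,
    ratio_decimals: int = 2,
) -> dict[str, pd.DataFrame]:
    """Predicted signals and material/water ratios, at report precision.

    Returns ``{"signals": ..., "ratios": ...}`` DataFrames. Signals are
    quoted to ``signal_decimals``; ratios are quotients of the quoted
    signals, rounded to ``ratio_decimals`` — i.e. ratios between quantities
    each stated at table precision, which is how downstream calibration
    consumes them. Unrounded signals are included as a separate column.
    """
    from cstetquant.composition import reference_profiles

    if profiles is None:
        profiles = reference_profiles()
    if xsec is None:
        xsec = load_cross_sections()
    signals = {
        name: signal_per_volume(p, xsec).signal for name, p in profiles.items()
    }
    sig_df = pd.DataFrame(
        {
            "material": list(signals),
            "signal_nm_inv": [signals[m] for m in signals],
            "signal_quoted": [round(signals[m], signal_decimals) for m in signals],
        }
    ).set_index("material")
    if "water" not in signals:
        raise KeyError("profiles must include a 'water' reference")
    water_q = round(signals["water"], signal_decimals)
    ratios = {}
    for name in signals:
        if name == "water":
            continue
        q = round(signals[name], signal_decimals)
        ratios[f"{name}/water"] = {
            "ratio": round(q / water_q, ratio_decimals),
            "ratio_unrounded": signals[name] / signals["water"],
        }
    ratio_df = pd.DataFrame(ratios).T
    return {"signals": sig_df, "ratios": ratio_df}


# ---------------------------------------------------------------------------
# screened-atom (Lenz) elastic model


def electron_wavelength_nm(energy_kev: float) -> float:
    """Relativistically corrected electron de Broglie wavelength, nm."""
    ev = energy_kev * 1e3 * constants.e
    mc2 = constants.m_e * constants.c**2
    p = math.sqrt(ev * (ev + 2 * mc2)) / constants.c
    return constants.h / p * 1e9


def _lenz_parameters(Z: int, beam: BeamConfig) -> tuple[float, float, float]:
    """Return (prefactor nm^2, theta0 rad, k nm^-1) of the Lenz model."""
    a0 = constants.physical_constants["Bohr radius"][0] * 1e9  # nm
    lam = electron_wavelength_nm(beam.energy_kev)
    k = 2 * math.pi / lam
    mc2_kev = constants.m_e * constants.c**2 / constants.e / 1e3
    gamma = 1.0 + beam.energy_kev / mc2_kev
    r_screen = a0 * Z ** (-1.0 / 3.0)
    theta0 = 1.0 / (k * r_screen)
    prefactor = 4.0 * gamma**2 * Z**2 / (a0**2 * k**4)
    return prefactor, theta0, k


def lenz_differential_cross_section(
    Z: int, beam: BeamConfig, theta_rad: float
) -> float:
    """d(sigma)/d(Omega) (nm^2/sr) of the screened-Rutherford (Lenz) model.

    Elastic scattering from a Wentzel screened atomic potential with
    screening radius a0 * Z^(-1/3), in the small-angle momentum-transfer
    approximation q ~ k*theta, relativistically corrected.
    """
    if Z < 1:
        raise ValueError("Z must be >= 1")
    pre, theta0, _ = _lenz_parameters(Z, beam)
    return pre / (theta_rad**2 + theta0**2) ** 2


def lenz_partial_cross_section(
    Z: int, beam: BeamConfig, theta_min_mrad: float | None = None
) -> float:
    """Partial elastic cross-section (nm^2) for scattering beyond theta_min.

    Closed-form solid-angle integral of the Lenz differential model from
    ``theta_min`` (default: the beam's BF cutoff) up to pi:

        sigma(>t) = pi * P * [1/(t^2 + theta0^2) - 1/(pi^2 + theta0^2)]

    with P the model prefactor. Not expected to match the packaged table
    (whose underlying model is unidentified); intended for sensitivity
    analysis only.
    """
    if Z < 1:
        raise ValueError("Z must be >= 1")
    theta_min = (
        beam.bf_cutoff_mrad if theta_min_mrad is None else theta_min_mrad
    ) * 1e-3
    if not 0 <= theta_min < math.pi:
        raise ValueError("theta_min must be in [0, pi) rad")
    pre, theta0, _ = _lenz_parameters(Z, beam)
    sigma = math.pi * pre * (
        1.0 / (theta_min**2 + theta0**2) - 1.0 / (math.pi**2 + theta0**2)
    )
    return sigma


def log_lenz_vs_table(xsec: CrossSectionTable | None = None) -> dict[str, float]:
    """Log the ratio of Lenz-model to tabulated cross-sections per element."""
    if xsec is None:
        xsec = load_cross_sections()
    ratios = {}
    for el, s in xsec.sigma.items():
        if s == 0:
            continue
        model = lenz_partial_cross_section(ATOMIC_NUMBERS[el], xsec.beam)
        ratios[el] = model / s
        logger.debug("Lenz/table cross-section ratio for %s: %.3g", el, model / s)
    return ratios
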