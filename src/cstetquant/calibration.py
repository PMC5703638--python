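"""Intensity-to-density calibration of BF tomograms.

BF polarity: stronger scattering means *lower* recorded intensity. Measured
intensities additionally carry an additive offset ``x`` from unscattered
illumination, so the scattering-proportional part of a voxel value I is
(x - I). The calibration pins down x by imposing the predicted
intensity-decrement ratio between an internal standard (ribosomes or their
RNA) and cytosolic water:

    (I_ref - x) / (I_water - x) = predicted ratio   =>   x solved exactly.

The intensity a solid block of crystalline tricalcium phosphate (TCP) would
produce is then extrapolated with the predicted TCP/water ratio, fixing a
linear scale from x (density 0) to I_TCP (density = crystalline TCP). Any
intensity maps to a fraction of TCP density, a mass density, and an
equivalent molar concentration of Ca3(PO4)2 formula units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import pandas as pd

from cstetquant.composition import TCP_DENSITY, TCP_FORMULA, parse_formula
from cstetquant.elements import molecular_weight
from cstetquant.units import CM3_PER_L

Reference = Literal["rna_peak", "ribosome_inclusive"]


def tcp_formula_weight() -> float:
    """Formula weight of Ca3(PO4)2 from the packaged atomic weights, g/mol."""
    return molecular_weight(
        {el: float(n) for el, n in parse_formula(TCP_FORMULA).items()}
    )


@dataclass(frozen=True)
class ThresholdSet:
    """Five measured intensity levels from a BF tomogram.

    ``peak`` levels select the most strongly scattering voxels of an object
    class; ``inclusive`` levels just capture the whole object. BF polarity:
    peak < inclusive < water.
    """

    granule_peak: float
    granule_inclusive: float
    ribosome_peak: float
    ribosome_inclusive: float
    water: float

    def __post_init__(self) -> None:
        if not self.ribosome_peak < self.ribosome_inclusive < self.water:
            raise ValueError(
                "expected ribosome_peak < ribosome_inclusive < water "
                f"(got {self.ribosome_peak}, {self.ribosome_inclusive}, {self.water})"
            )
        if not self.granule_peak < self.granule_inclusive < self.water:
            raise ValueError(
                "expected granule_peak < granule_inclusive < water "
                f"(got {self.granule_peak}, {self.granule_inclusive}, {self.water})"
            )


@dataclass(frozen=True)
class IntensityCalibration:
    """Linear intensity scale from background (density 0) to TCP (density 1)."""

    background_x: float
    water_intensity: float
    tcp_intensity: float
    tcp_water_ratio: float
    reference_used: Reference | str = "rna_peak"
    tcp_mass_density: float = TCP_DENSITY

    def __post_init__(self) -> None:
        if not self.background_x > self.water_intensity:
            raise ValueError("background must exceed water intensity (BF polarity)")
        if not self.tcp_intensity < self.water_intensity:
            raise ValueError("TCP intensity must lie below water intensity")

    @classmethod
    def from_reference(
        cls,
        reference_intensity: float,
        water_intensity: float,
        predicted_ratio: float,
        tcp_water_ratio: float,
        reference_used: str = "rna_peak",
        tcp_mass_density: float = TCP_DENSITY,
    ) -> "IntensityCalibration":
        x = estimate_background(reference_intensity, water_intensity, predicted_ratio)
        tcp = extrapolate_tcp_intensity(x, water_intensity, tcp_water_ratio)
        return cls(x, water_intensity, tcp, tcp_water_ratio, reference_used,
                   tcp_mass_density)

    @classmethod
    def from_thresholds(
        cls,
        thresholds: ThresholdSet,
        predicted_ratio: float,
        tcp_water_ratio: float,
        reference: Reference = "rna_peak",
        tcp_mass_density: float = TCP_DENSITY,
    ) -> "IntensityCalibration":
        """Build a calibration from a ThresholdSet.

        ``rna_peak`` pairs the peak-ribosome level with the predicted
        rRNA/water ratio (the RNA dominates the densest part of the
        ribosome); ``ribosome_inclusive`` pairs the inclusive-ribosome level
        with the whole-ribosome/water ratio.
        """
        if reference == "rna_peak":
            ref_intensity = thresholds.ribosome_peak
        elif reference == "ribosome_inclusive":
            ref_intensity = thresholds.ribosome_inclusive
        else:
            raise ValueError(f"unknown reference {reference!r}")
        return cls.from_reference(
            ref_intensity, thresholds.water, predicted_ratio, tcp_water_ratio,
            reference, tcp_mass_density,
        )


@dataclass(frozen=True)
class DensityEstimate:
    """Density of a voxel class on the background-to-TCP scale."""

    fraction_of_tcp: float
    ratio_to_water: float
    mass_density: float  # g/cm^3
    formula_molar_density: float  # mol Ca3(PO4)2 per cm^3


def estimate_background(
    reference_intensity: float, water_intensity: float, predicted_ratio: float
) -> float:
    """Solve (reference - x)/(water - x) = ratio for the additive background.

    Exact solution x = (ratio * water - reference) / (ratio - 1); with
    reference < water and ratio > 1 the solution always lies above water,
    as BF polarity requires.
    """
    if predicted_ratio <= 1:
        raise ValueError(
            f"predicted ratio must exceed 1 for a BF-consistent solution, "
            f"got {predicted_ratio}"
        )
    if reference_intensity >= water_intensity:
        raise ValueError("reference intensity must lie below water intensity")
    return (predicted_ratio * water_intensity - reference_intensity) / (
        predicted_ratio - 1.0
    )


def extrapolate_tcp_intensity(
    x: float, water_intensity: float, tcp_water_ratio: float
) -> float:
    """Intensity a solid TCP region would have: x - ratio * (x - water)."""
    if x <= water_intensity:
        raise ValueError("background must exceed water intensity (BF polarity)")
    if tcp_water_ratio < 1:
        raise ValueError("TCP/water ratio must be >= 1")
    return x - tcp_water_ratio * (x - water_intensity)


def density_fraction(
    intensity: float, calib: IntensityCalibration
) -> DensityEstimate:
    """Map a BF intensity to densities on the calibrated scale.

    fraction_of_tcp = (x - I)/(x - I_TCP); ratio_to_water = (x - I)/(x - I_w).
    Intensities above the background imply a negative density and are
    rejected rather than clipped.
    """
    x = calib.background_x
    if intensity > x:
        raise ValueError(
            f"intensity {intensity} exceeds the calibrated background {x}; "
            "this would imply a negative density"
        )
    fraction = (x - intensity) / (x - calib.tcp_intensity)
    ratio_to_water = (x - intensity) / (x - calib.water_intensity)
    mass_density = fraction * calib.tcp_mass_density
    formula_molar = mass_density / tcp_formula_weight()
    return DensityEstimate(fraction, ratio_to_water, mass_density, formula_molar)


def equivalent_concentration(
    estimate: DensityEstimate, volume_fraction: float
) -> dict[str, float]:
    """Molar concentrations if granule material were dissolved in the ROI.

    A region in which granules occupy ``volume_fraction`` of the volume at
    the estimated intra-granule density holds, per litre of region,
    ``formula_molar_density * volume_fraction * 1000`` moles of Ca3(PO4)2
    formula units; each unit carries 3 Ca and 2 PO4.
    """
    if not 0.0 <= volume_fraction <= 1.0:
        raise ValueError(f"volume_fraction must be in [0, 1], got {volume_fraction}")
    formula_molar = estimate.formula_molar_density * volume_fraction * CM3_PER_L
    return {
        "formula_molar": formula_molar,
        "calcium_molar": 3.0 * formula_molar,
        "phosphate_molar": 2.0 * formula_molar,
    }


# ---------------------------------------------------------------------------
# full report


def _round_sig(value: float, sig: int = 3) -> float:
    return float(f"{value:.{sig}g}")


def run_table3(
    thresholds: ThresholdSet,
    ratios: Mapping[str, float] | None = None,
) -> dict:
    """Full granule-density evaluation from five measured thresholds.

    Builds the primary calibration (peak-ribosome level paired with the
    rRNA/water ratio) and the parenthetical one (inclusive-ribosome level
    with the whole-ribosome/water ratio), extrapolates the TCP intensity for
    each, and evaluates ratio-to-water and fraction-of-TCP for all five
    levels under both.

    ``ratios`` maps ``{"rrna_water", "ribosome_water", "tcp_water"}`` to
    predicted intensity ratios; the default takes them from the packaged
    reference tables at report precision (two decimals), the precision at
    which such ratios are quoted.

    Returns a dict with keys ``calibrations`` (per column), ``grid`` (a
    DataFrame of unrounded values) and ``formatted`` (a DataFrame of strings
    at report precision: two-decimal ratios, three-significant-figure
    background, one-decimal TCP intensity chained from the quoted
    background).
    """
    if ratios is None:
        from cstetquant.scattering import reference_signal_report

        rep = reference_signal_report()["ratios"]
        ratios = {
            "rrna_water": rep.loc["rrna/water", "ratio"],
            "ribosome_water": rep.loc["ribosome/water", "ratio"],
            "tcp_water": rep.loc["tcp/water", "ratio"],
        }

    columns = {
        "primary": IntensityCalibration.from_thresholds(
            thresholds, ratios["rrna_water"], ratios["tcp_water"], "rna_peak"
        ),
        "parenthetical": IntensityCalibration.from_thresholds(
            thresholds,
            ratios["ribosome_water"],
            ratios["tcp_water"],
            "ribosome_inclusive",
        ),
    }

    levels = {
        "granule_peak": thresholds.granule_peak,
        "granule_inclusive": thresholds.granule_inclusive,
        "ribosome_peak": thresholds.ribosome_peak,
        "ribosome_inclusive": thresholds.ribosome_inclusive,
        "water": thresholds.water,
    }

    rows = []
    for name, level in levels.items():
        row: dict[str, float] = {"threshold": level}
        for col, calib in columns.items():
            est = density_fraction(level, calib)
            row[f"ratio_to_water_{col}"] = est.ratio_to_water
            row[f"ratio_to_tcp_{col}"] = est.fraction_of_tcp
        rows.append(pd.Series(row, name=name))
    grid = pd.DataFrame(rows)

    fmt_rows = {}
    for name in levels:
        fmt_rows[name] = {
            "threshold": f"{levels[name]:g}",
            **{
                f"ratio_to_water_{col}": f"{grid.loc[name, f'ratio_to_water_{col}']:.2f}"
                for col in columns
            },
            **{
                f"ratio_to_tcp_{col}": f"{grid.loc[name, f'ratio_to_tcp_{col}']:.2f}"
                for col in columns
            },
        }
    for col, calib in columns.items():
        x_q = _round_sig(calib.background_x, 3)
        tcp_q = x_q - calib.tcp_water_ratio * (x_q - thresholds.water)
        fmt_rows.setdefault("background", {})[f"threshold_{col}"] = f"{x_q:g}"
        fmt_rows.setdefault("tcp", {})[f"threshold_{col}"] = f"{tcp_q:.1f}"
    formatted = pd.DataFrame(fmt_rows).T

    return {"calibrations": columns, "grid": grid, "formatted": formatted,
            "ratios": dict(ratios)}
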