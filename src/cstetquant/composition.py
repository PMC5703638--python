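"""Elemental number-density profiles of reference materials.

The density calibration rests on knowing, per nm^3 of a reference material,
how many atoms of each element are present. Profiles can be built four ways:

* from explicit atom counts inside a known envelope volume (a ribosome whose
  atomic model fits a 7000 nm^3 isosurface),
* from atom counts plus a partial specific volume (ribosomal RNA at
  0.569 cm^3/g),
* from a chemical formula plus a bulk mass density (crystalline tricalcium
  phosphate at 3.14 g/cm^3, vitreous ice at 0.93 g/cm^3),
* by adding bulk solvent into the envelope of a solvated macromolecule.

A packaged reference table ships the published number densities for the
ribosome, ribosomal RNA and TCP; `reference_profiles` exposes both those
table values and fully recomputed profiles.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Mapping

from cstetquant.elements import atomic_weight, molecular_weight
from cstetquant.units import AVOGADRO, NM3_PER_CM3

Source = Literal["counts_and_volume", "formula_and_density", "psv", "mixture", "table"]

#: Default mass density of low-density amorphous (vitreous) ice, g/cm^3.
VITREOUS_ICE_DENSITY = 0.93

#: Default mass density of crystalline tricalcium phosphate, g/cm^3.
TCP_DENSITY = 3.14

#: Chemical formula of tricalcium phosphate.
TCP_FORMULA = "Ca3(PO4)2"

#: Envelope volume enclosing one ribosome, nm^3.
RIBOSOME_VOLUME = 7000.0

#: Solvent fraction of the ribosome envelope treated as bulk vitreous ice.
RIBOSOME_SOLVENT_FRACTION = 0.42

#: Partial specific volume of RNA, cm^3/g.
RNA_PSV = 0.569


@dataclass(frozen=True)
class ElementCounts:
    """Atom counts per formula unit or per particle.

    ``counts`` maps element symbols to non-negative atom counts. At least
    one element must be present.
    """

    counts: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("ElementCounts requires at least one element")
        for el, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for element {el!r}: {n}")
            atomic_weight(el)  # raises UnknownElementError for bad symbols

    def molecular_weight(self) -> float:
        """Total weight of the counted atoms, g/mol."""
        return molecular_weight(dict(self.counts))

    def items(self):
        return self.counts.items()


@dataclass(frozen=True)
class NumberDensityProfile:
    """Per-element atom number densities of a named material.

    ``densities`` is atoms/nm^3 per element; ``mass_density`` in g/cm^3 is
    either derived from the densities or supplied with them.
    """

    label: str
    densities: Mapping[str, float]
    mass_density: float
    source: Source = "table"

    def __post_init__(self) -> None:
        for el, d in self.densities.items():
            if d < 0:
                raise ValueError(f"negative density for element {el!r}: {d}")
            atomic_weight(el)
        if self.mass_density < 0:
            raise ValueError(f"mass_density must not be negative, got {self.mass_density}")

    def recomputed_mass_density(self) -> float:
        """Mass density (g/cm^3) implied by the stored number densities."""
        g_per_nm3 = sum(
            d * atomic_weight(el) for el, d in self.densities.items()
        ) / AVOGADRO
        return g_per_nm3 * NM3_PER_CM3

    def scaled(self, factor: float) -> "NumberDensityProfile":
        return NumberDensityProfile(
            label=self.label,
            densities={el: d * factor for el, d in self.densities.items()},
            mass_density=self.mass_density * factor,
            source=self.source,
        )


def _coerce(counts: ElementCounts | Mapping[str, float]) -> ElementCounts:
    if isinstance(counts, ElementCounts):
        return counts
    return ElementCounts(dict(counts))


def densities_from_counts(
    counts: ElementCounts | Mapping[str, float],
    volume: float,
    label: str = "",
) -> NumberDensityProfile:
    """Number densities of ``counts`` atoms spread over ``volume`` nm^3.

    Parameters
    ----------
    counts : element -> atom count
    volume : envelope volume in nm^3; must be positive.
    """
    counts = _coerce(counts)
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    densities = {el: n / volume for el, n in counts.items()}
    mass_density = counts.molecular_weight() / AVOGADRO / volume * NM3_PER_CM3
    return NumberDensityProfile(label, densities, mass_density, "counts_and_volume")


def densities_from_psv(
    counts: ElementCounts | Mapping[str, float],
    partial_specific_volume: float,
    label: str = "",
) -> NumberDensityProfile:
    """Number densities from atom counts and a partial specific volume.

    The particle mass follows from the counts and atomic weights; the
    occupied volume is mass times ``partial_specific_volume`` (cm^3/g).
    """
    counts = _coerce(counts)
    if partial_specific_volume <= 0:
        raise ValueError(
            f"partial specific volume must be positive, got {partial_specific_volume}"
        )
    mass_g = counts.molecular_weight() / AVOGADRO
    volume_nm3 = mass_g * partial_specific_volume * NM3_PER_CM3
    profile = densities_from_counts(counts, volume_nm3, label)
    return NumberDensityProfile(label, profile.densities, profile.mass_density, "psv")


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a chemical formula with integer subscripts and parentheses.

    Supports nested parenthesized groups with integer multipliers, e.g.
    ``Ca3(PO4)2``. Element symbols are case-sensitive.
    """
    stack: list[dict[str, int]] = [{}]
    pos = 0
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if m is None or m.start() != pos or m.group(0) == "":
            raise ValueError(f"unparsable formula {formula!r} at position {pos}")
        if m.group(1):  # element
            n = int(m.group(2)) if m.group(2) else 1
            atomic_weight(m.group(1))
            top = stack[-1]
            top[m.group(1)] = top.get(m.group(1), 0) + n
        elif m.group(3):  # open paren
            stack.append({})
        else:  # close paren with optional multiplier
            if len(stack) == 1:
                raise ValueError(f"unbalanced ')' in formula {formula!r}")
            mult = int(m.group(5)) if m.group(5) else 1
            group = stack.pop()
            top = stack[-1]
            for el, n in group.items():
                top[el] = top.get(el, 0) + n * mult
        pos = m.end()
    if len(stack) != 1:
        raise ValueError(f"unbalanced '(' in formula {formula!r}")
    if not stack[0]:
        raise ValueError(f"empty formula {formula!r}")
    return stack[0]


def densities_from_formula(
    formula: str,
    mass_density: float,
    label: str = "",
) -> NumberDensityProfile:
    """Number densities of a bulk material given formula and mass density.

    Formula units per nm^3 = mass_density * N_A / formula weight, with the
    cm^3 -> nm^3 conversion; per-element densities scale by stoichiometry.
    """
    if mass_density <= 0:
        raise ValueError(f"mass_density must be positive, got {mass_density}")
    stoich = parse_formula(formula)
    fw = molecular_weight({el: float(n) for el, n in stoich.items()})
    units_per_nm3 = mass_density * AVOGADRO / fw / NM3_PER_CM3
    densities = {el: n * units_per_nm3 for el, n in stoich.items()}
    return NumberDensityProfile(
        label or formula, densities, mass_density, "formula_and_density"
    )


def solvated_composition(
    macromolecule: NumberDensityProfile,
    solvent: NumberDensityProfile,
    solvent_fraction: float,
    label: str = "",
) -> NumberDensityProfile:
    """Add bulk solvent into the envelope of a macromolecule profile.

    ``macromolecule`` must already be expressed over the full envelope
    volume (dry atoms / envelope volume); the solvent contributes
    ``solvent_fraction`` of its bulk density on top.
    """
    if not 0.0 <= solvent_fraction <= 1.0:
        raise ValueError(f"solvent_fraction must be in [0, 1], got {solvent_fraction}")
    elements = set(macromolecule.densities) | set(solvent.densities)
    densities = {
        el: macromolecule.densities.get(el, 0.0)
        + solvent_fraction * solvent.densities.get(el, 0.0)
        for el in elements
    }
    mass_density = (
        macromolecule.mass_density + solvent_fraction * solvent.mass_density
    )
    return NumberDensityProfile(
        label or f"{macromolecule.label}+solvent", densities, mass_density, "mixture"
    )


# ---------------------------------------------------------------------------
# packaged reference table


def _read_packaged(name: str) -> Iterable[dict[str, str]]:
    ref = resources.files("cstetquant") / "reference_data" / name
    with ref.open("r") as fh:
        rows = [row for row in csv.DictReader(fh) if not row["material"].startswith("#")]
    return rows


def reference_atom_counts() -> dict[str, ElementCounts]:
    """Packaged atom counts for the ribosome (solvated envelope) and rRNA."""
    by_material: dict[str, dict[str, float]] = {}
    for row in _read_packaged("atom_counts.csv"):
        by_material.setdefault(row["material"], {})[row["element"]] = float(row["count"])
    return {mat: ElementCounts(c) for mat, c in by_material.items()}


def reference_profiles(computed: bool = False) -> dict[str, NumberDensityProfile]:
    """Reference number-density profiles for ribosome, rRNA, TCP and water.

    With ``computed=False`` (default) the ribosome/rRNA/TCP densities are the
    packaged table values, as used for the published signal predictions;
    water is always computed from vitreous-ice density. With
    ``computed=True`` every profile is recomputed from counts + envelope
    volume (ribosome), counts + psv (rRNA) or formula + density (TCP).
    """
    counts = reference_atom_counts()
    water = densities_from_formula("H2O", VITREOUS_ICE_DENSITY, "water")
    if computed:
        profiles = {
            "ribosome": densities_from_counts(
                counts["ribosome"], RIBOSOME_VOLUME, "ribosome"
            ),
            "rrna": densities_from_psv(counts["rrna"], RNA_PSV, "rrna"),
            "tcp": densities_from_formula(TCP_FORMULA, TCP_DENSITY, "tcp"),
        }
    else:
        by_material: dict[str, dict[str, float]] = {}
        for row in _read_packaged("number_densities.csv"):
            by_material.setdefault(row["material"], {})[row["element"]] = float(
                row["atoms_per_nm3"]
            )
        profiles = {}
        for mat, dens in by_material.items():
            mass = NumberDensityProfile(mat, dens, 1.0, "table").recomputed_mass_density()
            profiles[mat] = NumberDensityProfile(mat, dens, mass, "table")
    profiles["water"] = water
    return profiles


def load_profiles_csv(path) -> dict[str, NumberDensityProfile]:
    """Load user-supplied number-density profiles from a CSV file.

    Expected columns: material, element, atoms_per_nm3 (same layout as the
    packaged reference table).
    """
    by_material: dict[str, dict[str, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            by_material.setdefault(row["material"], {})[row["element"]] = float(
                row["atoms_per_nm3"]
            )
    out = {}
    for mat, dens in by_material.items():
        mass = NumberDensityProfile(mat, dens, 1.0, "table").recomputed_mass_density()
        out[mat] = NumberDensityProfile(mat, dens, mass, "table")
    return out
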