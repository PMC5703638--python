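"""Unit conventions and conversions.

Internal conventions: lengths in nm, number densities in atoms/nm^3, mass
densities in g/cm^3, cross-sections in nm^2, molar quantities in mol/cm^3
unless a function says otherwise. Every cm^3 <-> nm^3 conversion goes
through this module so the factor appears exactly once.
"""

AVOGADRO = 6.02214076e23  # mol^-1 (exact, SI 2019)

NM3_PER_CM3 = 1.0e21
CM3_PER_L = 1000.0


def atoms_per_nm3(moles_per_cm3: float) -> float:
    """Convert a molar density in mol/cm^3 to particles per nm^3."""
    return moles_per_cm3 * AVOGADRO / NM3_PER_CM3


def grams_per_cm3(mass_g_per_nm3: float) -> float:
    """Convert a mass density in g/nm^3 to g/cm^3."""
    return mass_g_per_nm3 * NM3_PER_CM3
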