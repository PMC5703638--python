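"""Standard atomic weights and atomic numbers.

A static table of IUPAC 2021 conventional atomic weights covering the
elements that occur in biological specimens and common mineral inclusions.
Kept as plain dicts so the composition arithmetic has no runtime
dependency beyond the standard library.
"""

from __future__ import annotations

# g/mol, IUPAC 2021 conventional values
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Mn": 54.938,
    "Fe": 55.845,
    "Zn": 65.38,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1,
    "C": 6,
    "N": 7,
    "O": 8,
    "Na": 11,
    "Mg": 12,
    "P": 15,
    "S": 16,
    "Cl": 17,
    "K": 19,
    "Ca": 20,
    "Mn": 25,
    "Fe": 26,
    "Zn": 30,
}


class UnknownElementError(KeyError):
    """Raised when an element symbol is not in the packaged weight table."""


def atomic_weight(symbol: str) -> float:
    """Return the standard atomic weight (g/mol) of ``symbol``.

    Raises
    ------
    UnknownElementError
        If the symbol is not in the packaged table.
    """
    try:
        return ATOMIC_WEIGHTS[symbol]
    except KeyError:
        raise UnknownElementError(
            f"element {symbol!r} is not in the packaged atomic-weight table"
        ) from None


def molecular_weight(counts: dict[str, float]) -> float:
    """Formula/molecular weight (g/mol) of an element-count map."""
    return sum(n * atomic_weight(el) for el, n in counts.items())
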