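"""Molecular formulas and the nominal oxidation state of carbon (NOSC).

NOSC summarizes how oxidized, on average, the carbon atoms of a compound
are.  It is computed from elemental composition alone:

    NOSC = 4 - (-Z + 4*C + H - 3*N - 2*O + 5*P - 2*S) / C

where the letters are element counts and ``Z`` is the net charge.  Fully
reduced carbon (methane) scores -4; carbohydrates score 0; more positive
values mean more oxidized, lower-energy substrates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["MolecularFormula", "nosc", "HALOGENS"]

HALOGENS = frozenset({"F", "Cl", "Br", "I"})

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts plus net charge.

    ``elements`` maps element symbols to nonnegative integer counts; any
    element may be present (halogens are needed for artifact screening),
    but only C, H, N, O, P, S and the charge enter the NOSC computation.
    """

    elements: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        for sym, n in self.elements.items():
            if n < 0:
                raise ValueError(f"negative count for element {sym!r}")

    @classmethod
    def parse(cls, text: str, charge: int = 0) -> "MolecularFormula":
        """Parse a Hill-style formula string such as ``"C6H12O6"``.

        Counts of 1 may be omitted (``CH4``) or explicit (``C1H4``).
        """
        text = text.strip()
        if not text:
            raise ValueError("empty formula")
        pos = 0
        counts: dict[str, int] = {}
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if not m or not m.group(1):
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
            pos = m.end()
        return cls(counts, charge)

    def count(self, symbol: str) -> int:
        return self.elements.get(symbol, 0)

    @property
    def contains_halogen(self) -> bool:
        return any(self.elements.get(h, 0) >= 1 for h in HALOGENS)

    def __str__(self) -> str:
        parts = []
        for sym in sorted(self.elements, key=lambda s: (s != "C", s != "H", s)):
            n = self.elements[sym]
            if n:
                parts.append(f"{sym}{n if n != 1 else ''}")
        return "".join(parts)


def nosc(formula: MolecularFormula | str, charge: int | None = None) -> float:
    """Nominal oxidation state of carbon for a molecular formula.

    Accepts a :class:`MolecularFormula` or a formula string; ``charge``
    overrides the formula's net charge when given.  Requires at least one
    carbon atom.

    >>> nosc("CH4")
    -4.0
    >>> nosc("C6H12O6")
    0.0
    """
    if isinstance(formula, str):
        formula = MolecularFormula.parse(formula, charge or 0)
    z = formula.charge if charge is None else charge
    c = formula.count("C")
    if c < 1:
        raise ValueError("NOSC requires at least one carbon atom")
    h = formula.count("H")
    n = formula.count("N")
    o = formula.count("O")
    p = formula.count("P")
    s = formula.count("S")
    return 4.0 - (-z + 4 * c + h - 3 * n - 2 * o + 5 * p - 2 * s) / c
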