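"""Molecular-formula arithmetic for deprotonated (negative-mode) ions.

Masses are monoisotopic. Formulas written for an anion denote the atom
composition of the charged species itself, i.e. already missing one H
relative to the neutral molecule; the electron gained on deprotonation is
added explicitly so that calculated m/z values agree with high-resolution
instrument software to the fifth decimal.
"""

from __future__ import annotations

import re
import warnings
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "MolecularFormula",
    "parse_formula",
    "anion_mz",
    "neutral_mass",
    "ppm_error",
    "within_tolerance",
]

# CODATA/IUPAC monoisotopic atomic masses, full precision. C/H/O suffice for
# flavonol glycosides; N and S included for reuse.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
    "N": 14.0030740048,
    "S": 31.97207100,
}

ELECTRON_MASS = 0.00054857990907

_HILL_ORDER = ("C", "H", "N", "O", "S")
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown elements."""


class MolecularFormula(dict):
    """Element → count mapping with Hill-order rendering and arithmetic.

    Counts are non-negative integers; zero-count entries are dropped.
    """

    def __init__(self, counts: dict[str, int] | None = None):
        counts = counts or {}
        clean: dict[str, int] = {}
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer, got {n!r}")
            if n:
                clean[el] = n
        super().__init__(clean)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return MolecularFormula(out)

    def __bool__(self) -> bool:
        return any(self.values())

    def hill(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical)."""
        parts = []
        for el in _HILL_ORDER:
            n = self.get(el, 0)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MolecularFormula({self.hill()!r})"


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string like ``"C27H29O17"``.

    An empty string yields an empty formula (mass 0). Element symbols may
    repeat; counts accumulate.
    """
    text = text.strip()
    if not text:
        return MolecularFormula()
    pos = 0
    counts: dict[str, int] = {}
    for m in _TOKEN.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return MolecularFormula(counts)


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def neutral_mass(f: MolecularFormula) -> float:
    """Unrounded monoisotopic mass of a neutral composition in Da."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.items())


def anion_mz(f: MolecularFormula) -> float:
    """Theoretical m/z of a singly charged anion with atom composition *f*.

    The electron mass is added (the anion carries one extra electron), and
    the result is rounded half-up to 5 decimals, the precision at which
    high-resolution instruments report calculated masses.
    """
    if not f:
        warnings.warn("anion_mz of an empty formula is the electron mass only", stacklevel=2)
    return _round_half_up(neutral_mass(f) + ELECTRON_MASS, 5)


def ppm_error(calculated: float, measured: float) -> float:
    """Relative mass error (measured − calculated)/calculated in ppm.

    Rounded half-up to 2 decimals. ``calculated`` must be positive.
    """
    if calculated <= 0:
        raise ValueError("calculated mass must be positive")
    return _round_half_up((measured - calculated) / calculated * 1e6, 2)


def within_tolerance(mz_a: float, mz_b: float, tol_ppm: float) -> bool:
    """True iff the ppm error between the two masses is within ``tol_ppm``."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    return abs((mz_b - mz_a) / mz_a * 1e6) <= tol_ppm
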