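"""Elemental-formula arithmetic for CHNOSP molecular formulae.

Monoisotopic mass, elemental ratios, double-bond equivalents, the modified
aromaticity index (AI-mod), and stoichiometric compound-class assignment as
used to categorize DOM formulae on van Krevelen diagrams.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from pyteomics import mass as _pmass

__all__ = [
    "MolecularFormula",
    "CompoundClass",
    "FormulaAnnotation",
    "monoisotopic_mass",
    "ai_mod",
    "dbe",
    "classify",
    "annotate",
    "parse_formula",
    "format_formula",
    "PROTON_MASS",
]

# Monoisotopic masses of the principal isotopes (12C, 1H, 14N, 16O, 32S, 31P),
# taken from the NIST table shipped with pyteomics.
MONOISOTOPIC = {
    "C": _pmass.nist_mass["C"][12][0],
    "H": _pmass.nist_mass["H"][1][0],
    "N": _pmass.nist_mass["N"][14][0],
    "O": _pmass.nist_mass["O"][16][0],
    "S": _pmass.nist_mass["S"][32][0],
    "P": _pmass.nist_mass["P"][31][0],
}

#: Mass removed when a neutral molecule loses a proton to form [M-H]-.
PROTON_MASS = 1.00727646688


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Immutable CHNOSP element-count vector; requires c >= 1, counts >= 0."""

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError(f"carbon count must be >= 1, got {self.c}")
        for el in ("h", "n", "o", "s", "p"):
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el.upper()} count")

    @property
    def heteroatoms(self) -> int:
        return self.n + self.s + self.p

    def __str__(self) -> str:
        return format_formula(self)


class CompoundClass(str, Enum):
    """Stoichiometric compound classes used to summarize DOM composition."""

    BLACK_CARBON = "black_carbon"
    POLYPHENOL = "polyphenol"
    HIGHLY_UNSATURATED = "highly_unsaturated"
    UNSATURATED_ALIPHATIC = "unsaturated_aliphatic"
    SATURATED_FATTY_ACID = "saturated_fatty_acid"
    SUGAR = "sugar"
    PEPTIDE = "peptide"
    OTHER = "other"


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da."""
    return (
        f.c * MONOISOTOPIC["C"]
        + f.h * MONOISOTOPIC["H"]
        + f.n * MONOISOTOPIC["N"]
        + f.o * MONOISOTOPIC["O"]
        + f.s * MONOISOTOPIC["S"]
        + f.p * MONOISOTOPIC["P"]
    )


def ai_mod(f: MolecularFormula) -> float:
    """Modified aromaticity index (Koch-Dittmar 2006 form).

    AI-mod = (1 + C - 0.5 O - S - 0.5 H) / (C - 0.5 O - N - S - P).
    Clamped to 0 when the numerator is negative or the denominator is
    non-positive (saturated / heteroatom-rich formulae where aromaticity
    is undefined).
    """
    num = 1.0 + f.c - 0.5 * f.o - f.s - 0.5 * f.h
    den = f.c - 0.5 * f.o - f.n - f.s - f.p
    if num < 0 or den <= 0:
        return 0.0
    return num / den


def dbe(f: MolecularFormula) -> float:
    """Ring-plus-double-bond equivalents: 1 + C - H/2 + N/2 + P/2."""
    return 1.0 + f.c - f.h / 2.0 + f.n / 2.0 + f.p / 2.0


def classify(f: MolecularFormula) -> CompoundClass:
    """Assign exactly one compound class from elemental stoichiometry.

    Precedence: sugars (O/C >= 0.9) first, then the aromaticity tiers
    (black carbon AI-mod >= 0.67, polyphenols 0.5 <= AI-mod < 0.67), then
    the aliphatic tiers on H/C, then highly unsaturated; anything left is
    OTHER.
    """
    oc = f.o / f.c
    hc = f.h / f.c
    ai = ai_mod(f)
    if oc >= 0.9:
        return CompoundClass.SUGAR
    if ai >= 0.67:
        return CompoundClass.BLACK_CARBON
    if 0.5 <= ai < 0.67:
        return CompoundClass.POLYPHENOL
    if hc >= 2.0:
        return CompoundClass.SATURATED_FATTY_ACID
    if 1.5 <= hc < 2.0:
        if f.n > 0:
            return CompoundClass.PEPTIDE
        return CompoundClass.UNSATURATED_ALIPHATIC
    if ai < 0.5 and hc < 1.5:
        return CompoundClass.HIGHLY_UNSATURATED
    return CompoundClass.OTHER


@dataclass(frozen=True)
class FormulaAnnotation:
    """A formula with its derived descriptors, as written to annotation CSVs."""

    formula: MolecularFormula
    neutral_mass: float
    oc_ratio: float
    hc_ratio: float
    ai_mod: float
    dbe: float
    compound_class: CompoundClass


def annotate(f: MolecularFormula) -> FormulaAnnotation:
    return FormulaAnnotation(
        formula=f,
        neutral_mass=monoisotopic_mass(f),
        oc_ratio=f.o / f.c,
        hc_ratio=f.h / f.c,
        ai_mod=ai_mod(f),
        dbe=dbe(f),
        compound_class=classify(f),
    )


_FORMULA_RE = re.compile(r"([CHNOSP])(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-like formula string such as ``C10H12N2O3S1`` or ``C6H6``.

    Zero counts may be omitted; a bare element symbol means count 1.
    Inverse of :func:`format_formula`.
    """
    text = text.strip()
    counts = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0, "P": 0}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"unparseable formula string: {text!r}")
        counts[m.group(1)] += int(m.group(2)) if m.group(2) else 1
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"unparseable formula string: {text!r}")
    return MolecularFormula(
        c=counts["C"], h=counts["H"], n=counts["N"],
        o=counts["O"], s=counts["S"], p=counts["P"],
    )


def format_formula(f: MolecularFormula) -> str:
    """Write ``CcHhNnOoSsPp`` omitting zero counts (C first, then H, N, O, S, P)."""
    parts = []
    for sym, count in (("C", f.c), ("H", f.h), ("N", f.n),
                       ("O", f.o), ("S", f.s), ("P", f.p)):
        if count > 0:
            parts.append(f"{sym}{count}")
    return "".join(parts)
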