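"""Molecular-formula arithmetic and small thermodynamic helpers.

Covers the mass bookkeeping a screening campaign leans on: parsing
Hill-style molecular formulas, monoisotopic m/z for ESI adduct ions,
average molecular weight, heavy-atom counts, ligand efficiency from a
dissociation constant, and the thermochemical kcal/kJ conversion.

Masses come from a bundled read-only table of IUPAC values: the
monoisotopic mass of the most abundant isotope per element (carbon
exactly 12 by definition of the unified scale) and the standard average
atomic weight.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "MolecularFormula",
    "AtomicMassTable",
    "LigandEfficiencyInput",
    "ELECTRON_MASS_DA",
    "GAS_CONSTANT_KCAL",
    "KCAL_TO_KJ",
    "load_mass_table",
    "parse_formula",
    "format_formula",
    "monoisotopic_mz",
    "average_mw",
    "heavy_atom_count",
    "ligand_efficiency",
    "kcal_to_kj",
    "kj_to_kcal",
]

#: CODATA electron mass in Da; subtracted once per positive elementary charge.
ELECTRON_MASS_DA = 5.48579909065e-4

#: Molar gas constant in kcal mol^-1 K^-1 (thermochemical calorie).
GAS_CONSTANT_KCAL = 1.98720425864083e-3

#: Exact thermochemical conversion factor.
KCAL_TO_KJ = 4.184

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formulas or elements missing from the mass table."""


@dataclass(frozen=True)
class AtomicMassTable:
    """Read-only per-element monoisotopic and average masses (Da)."""

    monoisotopic: Mapping[str, float]
    average: Mapping[str, float]
    electron_mass: float = ELECTRON_MASS_DA

    def __contains__(self, element: str) -> bool:
        return element in self.monoisotopic


def load_mass_table() -> AtomicMassTable:
    """Load the bundled atomic mass table."""
    mono: dict[str, float] = {}
    avg: dict[str, float] = {}
    text = resources.files("cryptic_triage.data").joinpath("atomic_masses.csv").read_text()
    for line in text.strip().splitlines()[1:]:
        element, m, a = line.split(",")
        mono[element] = float(m)
        avg[element] = float(a)
    return AtomicMassTable(monoisotopic=mono, average=avg)


_DEFAULT_TABLE = load_mass_table()

# Hill order: C first, then H, then the rest alphabetically; if no carbon,
# everything alphabetical.
def _hill_key(symbols: list[str], has_carbon: bool) -> list[str]:
    if has_carbon:
        rest = sorted(s for s in symbols if s not in ("C", "H"))
        ordered = [s for s in ("C", "H") if s in symbols] + rest
        return ordered
    return sorted(symbols)


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition with an optional net charge.

    Counts are strictly positive for every element present; the charge is
    a signed number of elementary charges (positive for cations).
    """

    element_counts: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise FormulaError("formula has no elements")
        for element, count in self.element_counts.items():
            if count < 1:
                raise FormulaError(f"count for {element} must be >= 1, got {count}")
            if element not in _DEFAULT_TABLE:
                raise FormulaError(f"unknown element symbol: {element!r}")

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.element_counts)
        for element, count in other.element_counts.items():
            merged[element] = merged.get(element, 0) + count
        return MolecularFormula(merged, self.charge + other.charge)

    def hill_formula(self) -> str:
        return format_formula(self)


@dataclass(frozen=True)
class LigandEfficiencyInput:
    """Inputs for the free-energy-per-heavy-atom ligand efficiency."""

    kd: float
    heavy_atoms: int
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError(f"kd must be positive, got {self.kd}")
        if self.heavy_atoms < 1:
            raise ValueError(f"heavy_atoms must be >= 1, got {self.heavy_atoms}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")


def parse_formula(text: str, charge: int = 0) -> MolecularFormula:
    """Parse ``"C14H17N4OS"``-style element+count strings.

    Each token is a one- or two-letter element symbol followed by an
    optional positive integer (implicit 1). Parentheses, hydrates and
    isotope labels are not part of the grammar.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula at {text[pos:]!r}")
        element, digits = m.group(1), m.group(2)
        if element not in _DEFAULT_TABLE:
            raise FormulaError(f"unknown element symbol: {element!r}")
        count = int(digits) if digits else 1
        if count < 1:
            raise FormulaError(f"count for {element} must be >= 1, got {count}")
        counts[element] = counts.get(element, 0) + count
        pos = m.end()
    return MolecularFormula(counts, charge)


def format_formula(formula: MolecularFormula) -> str:
    """Render in Hill order (C, H, then alphabetical)."""
    symbols = list(formula.element_counts)
    ordered = _hill_key(symbols, "C" in formula.element_counts)
    parts = []
    for s in ordered:
        n = formula.element_counts[s]
        parts.append(s if n == 1 else f"{s}{n}")
    return "".join(parts)


def monoisotopic_mz(
    formula: MolecularFormula, table: AtomicMassTable | None = None
) -> float:
    """Monoisotopic m/z in Da per elementary charge.

    For a charged species the mass of ``charge`` electrons is subtracted
    (added, for anions) before dividing by ``|charge|``; a neutral
    formula returns the plain monoisotopic mass.
    """
    table = table or _DEFAULT_TABLE
    mass = 0.0
    for element, count in formula.element_counts.items():
        try:
            mass += count * table.monoisotopic[element]
        except KeyError:
            raise FormulaError(f"element {element!r} missing from mass table") from None
    mass -= formula.charge * table.electron_mass
    return mass / max(abs(formula.charge), 1)


def average_mw(formula: MolecularFormula, table: AtomicMassTable | None = None) -> float:
    """Average molecular weight in Da from standard atomic weights."""
    table = table or _DEFAULT_TABLE
    mass = 0.0
    for element, count in formula.element_counts.items():
        try:
            mass += count * table.average[element]
        except KeyError:
            raise FormulaError(f"element {element!r} missing from mass table") from None
    return mass


def heavy_atom_count(formula: MolecularFormula) -> int:
    """Number of non-hydrogen atoms."""
    return sum(n for el, n in formula.element_counts.items() if el != "H")


def ligand_efficiency(inp: LigandEfficiencyInput) -> float:
    """Ligand efficiency in kcal mol^-1 per heavy atom.

    LE = -RT ln(K_D) / HA with K_D in molar; positive for sub-molar
    binders. The conventional reference temperature is 298.15 K.
    """
    return (-GAS_CONSTANT_KCAL * inp.temperature * math.log(inp.kd)) / inp.heavy_atoms


def kcal_to_kj(x: float) -> float:
    """Thermochemical kcal/mol -> kJ/mol (exact factor 4.184)."""
    return x * KCAL_TO_KJ


def kj_to_kcal(x: float) -> float:
    """Inverse of :func:`kcal_to_kj`."""
    return x / KCAL_TO_KJ
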