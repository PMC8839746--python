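"""Structure reading and binding-pocket geometry.

A docking campaign against a cryptic pocket needs three geometric
primitives: resolve a single named atom (the pocket anchor, e.g. the
thiazole nitrogen of a bound fragment), measure atom–atom distances
(e.g. the unbinding reaction coordinate between a ligand carbon and an
aspartate beta-carbon), and enumerate the residues lining a spherical
pocket of given centre and radius. Files are read with gemmi (PDB and
mmCIF dialects both accepted); coordinates stay in the deposited frame.

Multi-model files use model 1. Altloc'd atoms keep the highest-occupancy
conformer, ties broken by altloc identifier order, so selections are
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gemmi

__all__ = [
    "Atom",
    "Structure",
    "AtomSelector",
    "PocketDefinition",
    "SelectorError",
    "read_structure",
    "atom_coord",
    "atom_distance",
    "residues_within",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class SelectorError(ValueError):
    """An atom selector resolved to zero or more than one atom."""


@dataclass(frozen=True)
class Atom:
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    x: float
    y: float
    z: float
    het: bool

    @property
    def pos(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    @property
    def is_water(self) -> bool:
        return self.residue_name in _WATER_NAMES


@dataclass(frozen=True)
class Structure:
    atoms: tuple[Atom, ...]
    model_id: str = "1"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("structure contains no atoms")
        for a in self.atoms:
            if not all(math.isfinite(v) for v in a.pos):
                raise ValueError(f"non-finite coordinates on atom {a}")


@dataclass(frozen=True)
class AtomSelector:
    """Selects exactly one atom by residue and atom name.

    Any of ``chain_id``, ``residue_name`` and ``residue_number`` may be
    omitted; ``het_only`` restricts the match to HETATM records (handy
    for picking ligand atoms by name without knowing the residue code).
    """

    atom_name: str
    chain_id: str | None = None
    residue_name: str | None = None
    residue_number: int | None = None
    het_only: bool = False

    def matches(self, atom: Atom) -> bool:
        if atom.atom_name != self.atom_name:
            return False
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_name is not None and atom.residue_name != self.residue_name:
            return False
        if self.residue_number is not None and atom.residue_number != self.residue_number:
            return False
        if self.het_only and not atom.het:
            return False
        return True


@dataclass(frozen=True)
class PocketDefinition:
    """Spherical pocket: centre in deposited Å coordinates plus radius."""

    center: tuple[float, float, float]
    radius: float = 10.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"pocket radius must be positive, got {self.radius}")


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc identifier order
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def read_structure(path: str | Path) -> Structure:
    """Read a PDB or mmCIF file into a flat atom list (model 1 only)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            by_name: dict[str, list[gemmi.Atom]] = {}
            for a in residue:
                by_name.setdefault(a.name, []).append(a)
            for name, group in by_name.items():
                a = _pick_altloc(group) if len(group) > 1 else group[0]
                atoms.append(
                    Atom(
                        atom_name=name,
                        element=a.element.name,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        x=a.pos.x,
                        y=a.pos.y,
                        z=a.pos.z,
                        het=het,
                    )
                )
    if not atoms:
        raise ValueError(f"no atoms in {path}")
    model_id = getattr(model, "num", getattr(model, "name", 1))
    return Structure(atoms=tuple(atoms), model_id=str(model_id))


def _resolve(structure: Structure, selector: AtomSelector) -> Atom:
    hits = [a for a in structure.atoms if selector.matches(a)]
    if not hits:
        raise SelectorError(f"selector matched no atom: {selector}")
    if len(hits) > 1:
        raise SelectorError(
            f"selector matched {len(hits)} atoms (must be unique): {selector}"
        )
    return hits[0]


def atom_coord(structure: Structure, selector: AtomSelector) -> tuple[float, float, float]:
    """Deposited Å coordinates of the uniquely selected atom."""
    return _resolve(structure, selector).pos


def atom_distance(
    structure: Structure,
    selector_a: AtomSelector,
    selector_b: AtomSelector,
    unit: str = "angstrom",
) -> float:
    """Euclidean distance between two uniquely selected atoms.

    ``unit`` is ``"angstrom"`` (default) or ``"nm"`` (10 Å = 1 nm).
    """
    if unit not in ("angstrom", "nm"):
        raise ValueError(f"unit must be 'angstrom' or 'nm', got {unit!r}")
    a = _resolve(structure, selector_a)
    b = _resolve(structure, selector_b)
    d = math.dist(a.pos, b.pos)
    return d / 10.0 if unit == "nm" else d


def residues_within(
    structure: Structure,
    pocket: PocketDefinition,
    include_waters: bool = False,
) -> list[tuple[str, int, str, float]]:
    """Residues with at least one atom inside the pocket sphere.

    Returns ``(chain_id, residue_number, residue_name, min_distance)``
    tuples sorted by minimum atom distance ascending, ties by chain then
    residue number. Membership is any-atom-within-radius, matching the
    convention of docking cavity definitions.
    """
    cx, cy, cz = pocket.center
    best: dict[tuple[str, int, str], float] = {}
    for a in structure.atoms:
        if not include_waters and a.is_water:
            continue
        d = math.dist((cx, cy, cz), a.pos)
        key = (a.chain_id, a.residue_number, a.residue_name)
        if d <= pocket.radius and d < best.get(key, math.inf):
            best[key] = d
    out = [(c, n, r, d) for (c, n, r), d in best.items()]
    out.sort(key=lambda t: (t[3], t[0], t[1]))
    return out
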