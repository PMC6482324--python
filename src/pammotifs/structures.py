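"""Parsing and selection of protein crystal structures.

Structures are read through gemmi (PDB and mmCIF dialects) into a flat,
typed atom list plus ordered per-chain residue views.  Selection follows
the data-curation rules used throughout the package: high-resolution
X-ray structures with deposited hydrogens, atoms restricted by element
and occupancy, water and other small molecules excluded.

Only the first model of a multi-model file is used; symmetry mates are
never generated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: residue names treated as water for the small-molecule exclusion
WATER_RESIDUES = frozenset({"HOH", "DOD", "WAT"})

ResidueKey = tuple[str, int, str]  # (chain id, author residue number, insertion code)


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record with the metadata the filters need."""

    element: str
    name: str
    position: np.ndarray  # (3,) in Angstrom
    occupancy: float
    altloc: str
    residue_key: ResidueKey
    residue_name: str
    is_hetero: bool

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]"
            )


@dataclass
class ResidueView:
    """Atoms of one residue, in file order."""

    key: ResidueKey
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        """First atom with the given name, or None."""
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ProteinStructure:
    """A parsed structure: id, resolution metadata and the atom list."""

    structure_id: str
    resolution: float | None
    atoms: list[AtomRecord]

    def chains(self) -> dict[str, list[ResidueView]]:
        """Ordered residue lists per chain.

        Residues appear in file order; within each chain they are sorted
        by (sequence number, insertion code), which for deposited
        structures is the author ordering.
        """
        by_chain: dict[str, dict[ResidueKey, ResidueView]] = {}
        for atom in self.atoms:
            chain_id = atom.residue_key[0]
            residues = by_chain.setdefault(chain_id, {})
            view = residues.get(atom.residue_key)
            if view is None:
                view = ResidueView(key=atom.residue_key, name=atom.residue_name)
                residues[atom.residue_key] = view
            view.atoms.append(atom)
        return {
            cid: sorted(res.values(), key=lambda r: (r.key[1], r.key[2]))
            for cid, res in by_chain.items()
        }

    def count_element(self, element: str) -> int:
        return sum(1 for a in self.atoms if a.element == element)


@dataclass(frozen=True)
class SelectionCriteria:
    """Structure- and atom-level selection rules.

    ``max_resolution`` keeps structures diffracting *better* than the
    threshold (strictly smaller number).  ``min_occupancy`` keeps atoms
    whose occupancy is at or above the threshold, which in practice
    removes split conformers.  Elements outside ``elements`` are dropped
    when the set is non-empty.
    """

    max_resolution: float = 1.2
    min_occupancy: float = 0.95
    require_hydrogens: bool = True
    exclude_water_and_small_molecules: bool = True
    elements: frozenset[str] = frozenset({"N", "O", "H"})
    water_residues: frozenset[str] = WATER_RESIDUES

    def __post_init__(self) -> None:
        if self.max_resolution <= 0:
            raise ValueError("max_resolution must be positive")
        if not 0.0 <= self.min_occupancy <= 1.0:
            raise ValueError("min_occupancy must be in [0, 1]")


def parse_structure(path: str | Path, dialect: str | None = None) -> ProteinStructure:
    """Read a PDB or mmCIF file into a :class:`ProteinStructure`.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"pdb"``, ``"mmcif"`` or None to detect from the extension.

    All ATOM and HETATM records of the first model are returned; nothing
    is silently dropped.  A missing resolution record yields
    ``resolution=None`` (structure-level filters then reject it).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        None: gemmi.CoorFormat.Unknown,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc

    atoms: list[AtomRecord] = []
    if len(st) > 0:
        model = st[0]
        for chain in model:
            for residue in chain:
                key = (chain.name, residue.seqid.num, residue.seqid.icode.strip())
                het = residue.het_flag == "H"
                for a in residue:
                    altloc = a.altloc if a.altloc != "\x00" else ""
                    atoms.append(
                        AtomRecord(
                            element=a.element.name,
                            name=a.name,
                            position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                            occupancy=min(max(float(a.occ), 0.0), 1.0),
                            altloc=altloc,
                            residue_key=key,
                            residue_name=residue.name,
                            is_hetero=het,
                        )
                    )
    resolution = float(st.resolution) if st.resolution > 0 else None
    sid = st.name if st.name else path.stem
    return ProteinStructure(structure_id=sid, resolution=resolution, atoms=atoms)


def select_atoms(
    structure: ProteinStructure, criteria: SelectionCriteria
) -> list[AtomRecord]:
    """Atoms passing the element, occupancy and small-molecule rules.

    Returns atoms in file order; an empty result is valid.
    """
    out = []
    for atom in structure.atoms:
        if criteria.elements and atom.element not in criteria.elements:
            continue
        if atom.occupancy < criteria.min_occupancy:
            continue
        if criteria.exclude_water_and_small_molecules and (
            atom.is_hetero or atom.residue_name in criteria.water_residues
        ):
            continue
        out.append(atom)
    return out


def filter_structures(
    structures: Iterable[ProteinStructure], criteria: SelectionCriteria
) -> list[ProteinStructure]:
    """Keep structures whose resolution is strictly better than the cutoff.

    "Better than X" means numerically smaller than X.  Structures with
    no recorded resolution are rejected and logged, as are structures
    with no hydrogen atoms when ``require_hydrogens`` is set.
    """
    kept = []
    for st in structures:
        if st.resolution is None:
            logger.info("rejecting %s: no resolution record", st.structure_id)
            continue
        if not st.resolution < criteria.max_resolution:
            logger.info(
                "rejecting %s: resolution %.2f not better than %.2f",
                st.structure_id,
                st.resolution,
                criteria.max_resolution,
            )
            continue
        if criteria.require_hydrogens and st.count_element("H") == 0:
            logger.info("rejecting %s: no hydrogen atoms", st.structure_id)
            continue
        kept.append(st)
    return kept
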