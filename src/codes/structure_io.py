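"""PDB ingestion into a two-body complex representation.

A :class:`ComplexModel` is an ordered list of atoms plus an explicit
receptor/ligand chain partition.  When no partition is declared the chains
are split so that the body with more residues becomes the receptor.  Only
standard polymer atoms are kept: HETATM records (including waters) are
dropped, alternate locations are collapsed to the highest-occupancy
conformer, and hydrogens are retained in the model but flagged so that the
geometry layer can exclude them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from codes.exceptions import EmptySelectionError, PartitionError, PDBFormatError

logger = logging.getLogger(__name__)

#: Residue identity key: (chain id, author residue number, insertion code).
ResidueKey = Tuple[str, int, str]

#: Backbone atom names used for all RMSD selections.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class Atom:
    """A single heavy or hydrogen atom of a polymer residue."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    coords: np.ndarray
    is_hydrogen: bool

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial} has invalid coordinates {coords!r}")
        object.__setattr__(self, "coords", coords)
        expected = self.element.upper() in _HYDROGEN_ELEMENTS
        if self.is_hydrogen != expected:
            raise ValueError(
                f"atom {self.serial}: is_hydrogen={self.is_hydrogen} inconsistent "
                f"with element {self.element!r}"
            )

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_seq, self.insertion_code)


@dataclass
class ComplexModel:
    """Atoms of a two-body complex with a receptor/ligand chain partition."""

    model_id: str
    target_id: str
    atoms: Sequence[Atom]
    receptor_chains: frozenset
    ligand_chains: frozenset

    def __post_init__(self) -> None:
        self.receptor_chains = frozenset(self.receptor_chains)
        self.ligand_chains = frozenset(self.ligand_chains)
        if self.receptor_chains & self.ligand_chains:
            raise PartitionError(
                f"{self.model_id}: receptor and ligand chain sets overlap: "
                f"{sorted(self.receptor_chains & self.ligand_chains)}"
            )
        declared = self.receptor_chains | self.ligand_chains
        present = {a.chain_id for a in self.atoms}
        stray = present - declared
        if stray:
            raise PartitionError(
                f"{self.model_id}: chains {sorted(stray)} belong to neither body"
            )

    def body_of(self, chain_id: str) -> str:
        if chain_id in self.receptor_chains:
            return "receptor"
        if chain_id in self.ligand_chains:
            return "ligand"
        raise PartitionError(f"chain {chain_id!r} is not in the partition")

    def body_atoms(self, body: str, heavy_only: bool = True) -> list:
        chains = self.receptor_chains if body == "receptor" else self.ligand_chains
        return [
            a
            for a in self.atoms
            if a.chain_id in chains and not (heavy_only and a.is_hydrogen)
        ]

    def residues(self, body: Optional[str] = None) -> "dict[ResidueKey, list]":
        """Ordered mapping residue key -> atoms, optionally restricted to a body."""
        chains: Optional[frozenset] = None
        if body == "receptor":
            chains = self.receptor_chains
        elif body == "ligand":
            chains = self.ligand_chains
        out: dict = {}
        for atom in self.atoms:
            if chains is not None and atom.chain_id not in chains:
                continue
            out.setdefault(atom.residue_key, []).append(atom)
        return out

    def with_atoms(self, atoms: Sequence[Atom], model_id: Optional[str] = None) -> "ComplexModel":
        return replace(self, atoms=list(atoms), model_id=model_id or self.model_id)


def _partition_chains(
    chain_residue_counts: Mapping[str, int],
    receptor_chains: Optional[Iterable[str]],
    ligand_chains: Optional[Iterable[str]],
) -> Tuple[frozenset, frozenset]:
    chains = list(chain_residue_counts)
    if receptor_chains is not None and ligand_chains is not None:
        return frozenset(receptor_chains), frozenset(ligand_chains)
    if receptor_chains is not None:
        rec = frozenset(receptor_chains)
        return rec, frozenset(c for c in chains if c not in rec)
    if ligand_chains is not None:
        lig = frozenset(ligand_chains)
        return frozenset(c for c in chains if c not in lig), lig
    if len(chains) < 2:
        raise PartitionError(
            "cannot auto-partition a file with fewer than two chains; "
            "declare receptor/ligand chains explicitly"
        )
    # Auto partition: larger-by-residue-count chain is the receptor; remaining
    # chains join the smaller body.  Deterministic: sort by (count, chain id).
    ordered = sorted(chains, key=lambda c: (-chain_residue_counts[c], c))
    rec = {ordered[0]}
    lig = set(ordered[1:])
    # Greedily move chains to keep the receptor at least as large as the ligand.
    while sum(chain_residue_counts[c] for c in rec) < sum(
        chain_residue_counts[c] for c in lig
    ):
        mover = max(lig, key=lambda c: (chain_residue_counts[c], c))
        if len(lig) == 1:
            break
        lig.remove(mover)
        rec.add(mover)
    return frozenset(rec), frozenset(lig)


def read_pdb(
    path,
    receptor_chains: Optional[Iterable[str]] = None,
    ligand_chains: Optional[Iterable[str]] = None,
    model_id: Optional[str] = None,
    target_id: str = "",
) -> ComplexModel:
    """Parse a PDB file into a :class:`ComplexModel`.

    HETATM records and waters are excluded; for disordered atoms the
    highest-occupancy altloc is kept.  If no partition is given the chains
    are split so the larger body (by residue count) is the receptor.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises bare ValueError on bad input
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise PDBFormatError(f"{path} contains no coordinate model")

    atoms: list = []
    chain_residue_counts: dict = {}
    serial = 0
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag.strip():  # HETATM or water
                continue
            chain_residue_counts[chain.id] = chain_residue_counts.get(chain.id, 0) + 1
            for bio_atom in residue:
                if bio_atom.is_disordered():
                    bio_atom = bio_atom.selected_child  # highest occupancy
                element = (bio_atom.element or "").strip().upper()
                serial += 1
                atoms.append(
                    Atom(
                        serial=bio_atom.serial_number or serial,
                        name=bio_atom.get_name(),
                        element=element,
                        residue_name=residue.get_resname().strip(),
                        chain_id=chain.id,
                        residue_seq=resseq,
                        insertion_code=icode.strip() or "",
                        coords=np.asarray(bio_atom.coord, dtype=float),
                        is_hydrogen=element in _HYDROGEN_ELEMENTS,
                    )
                )
    if not atoms:
        raise PDBFormatError(f"{path} contains no polymer atoms")

    rec, lig = _partition_chains(chain_residue_counts, receptor_chains, ligand_chains)
    return ComplexModel(
        model_id=model_id or path.stem,
        target_id=target_id,
        atoms=atoms,
        receptor_chains=rec,
        ligand_chains=lig,
    )


def write_pdb(model: ComplexModel, path) -> None:
    """Write a model back out as a minimal ATOM-record PDB file."""
    lines = []
    for i, atom in enumerate(model.atoms, start=1):
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        x, y, z = atom.coords
        lines.append(
            f"ATOM  {i:5d} {name}{'':1s}{atom.residue_name:>3s} "
            f"{atom.chain_id:1s}{atom.residue_seq:4d}{atom.insertion_code or ' ':1s}"
            f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def backbone_coords(
    model: ComplexModel,
    residue_subset: Optional[Iterable[ResidueKey]] = None,
    body: Optional[str] = None,
) -> np.ndarray:
    """Coordinates of backbone atoms (N, CA, C, O) in stable residue order.

    Residues missing part of their backbone contribute the atoms they have;
    a warning is logged once per call.  Raises
    :class:`~codes.exceptions.EmptySelectionError` when nothing matches
    (including an explicitly empty ``residue_subset``).
    """
    if residue_subset is not None:
        residue_subset = set(residue_subset)
        if not residue_subset:
            raise EmptySelectionError("empty residue subset")
    coords = []
    n_partial = 0
    for key, res_atoms in model.residues(body=body).items():
        if residue_subset is not None and key not in residue_subset:
            continue
        by_name = {a.name: a for a in res_atoms}
        present = [by_name[n] for n in BACKBONE_ATOMS if n in by_name]
        if len(present) < len(BACKBONE_ATOMS):
            n_partial += 1
        coords.extend(a.coords for a in present)
    if n_partial:
        logger.warning(
            "%s: %d residue(s) with incomplete backbone", model.model_id, n_partial
        )
    if not coords:
        raise EmptySelectionError(f"{model.model_id}: no backbone atoms selected")
    return np.asarray(coords, dtype=float)


def backbone_atom_map(
    model: ComplexModel,
    residue_subset: Optional[Iterable[ResidueKey]] = None,
    body: Optional[str] = None,
) -> "dict[tuple, np.ndarray]":
    """Mapping (residue key, atom name) -> coords for backbone atoms.

    Used to put two models in atom-wise correspondence by shared keys.
    """
    if residue_subset is not None:
        residue_subset = set(residue_subset)
    out: dict = {}
    for key, res_atoms in model.residues(body=body).items():
        if residue_subset is not None and key not in residue_subset:
            continue
        for a in res_atoms:
            if a.name in BACKBONE_ATOMS:
                out[(key, a.name)] = a.coords
    return out
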