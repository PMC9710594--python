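"""Geometric kernel: contacts, interface residues, clashes, superposition.

Distance queries use a KD-tree but are exact: every operator is defined as
the brute-force all-pairs result at the stated cutoff.  Cutoff comparisons
are strict (``<``) so ties at exactly the cutoff are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from codes.exceptions import CorrespondenceError
from codes.structure_io import ComplexModel, ResidueKey

CONTACT_CUTOFF = 5.0
INTERFACE_CUTOFF = 10.0
CLASH_CUTOFF = 3.0


@dataclass(frozen=True)
class ContactMap:
    """Set of (receptor residue, ligand residue) contact pairs for one model."""

    target_id: str
    model_id: str
    contacts: frozenset
    cutoff: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "contacts", frozenset(self.contacts))

    def __len__(self) -> int:
        return len(self.contacts)

    def __contains__(self, pair: Tuple[ResidueKey, ResidueKey]) -> bool:
        return pair in self.contacts


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid superposition: ``mobile @ rotation.T + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _body_arrays(model: ComplexModel):
    rec = model.body_atoms("receptor", heavy_only=True)
    lig = model.body_atoms("ligand", heavy_only=True)
    rec_xyz = np.asarray([a.coords for a in rec], dtype=float).reshape(-1, 3)
    lig_xyz = np.asarray([a.coords for a in lig], dtype=float).reshape(-1, 3)
    return rec, rec_xyz, lig, lig_xyz


def _cross_pairs(rec_xyz: np.ndarray, lig_xyz: np.ndarray, cutoff: float):
    """Indices (i, j) of receptor/ligand atom pairs with distance < cutoff."""
    if len(rec_xyz) == 0 or len(lig_xyz) == 0:
        return []
    tree = cKDTree(lig_xyz)
    pairs = []
    for i, neighbors in enumerate(tree.query_ball_point(rec_xyz, cutoff)):
        for j in neighbors:
            # query_ball_point uses <=; enforce the strict inequality
            if np.linalg.norm(rec_xyz[i] - lig_xyz[j]) < cutoff:
                pairs.append((i, j))
    return pairs


def residue_contacts(model: ComplexModel, cutoff: float = CONTACT_CUTOFF) -> ContactMap:
    """Residue pairs with any heavy-atom pair closer than ``cutoff``."""
    rec, rec_xyz, lig, lig_xyz = _body_arrays(model)
    contacts = {
        (rec[i].residue_key, lig[j].residue_key)
        for i, j in _cross_pairs(rec_xyz, lig_xyz, cutoff)
    }
    return ContactMap(
        target_id=model.target_id,
        model_id=model.model_id,
        contacts=frozenset(contacts),
        cutoff=cutoff,
    )


def interface_residues(
    model: ComplexModel, cutoff: float = INTERFACE_CUTOFF
) -> Set[ResidueKey]:
    """Residues of either body with a heavy atom within ``cutoff`` of the partner."""
    rec, rec_xyz, lig, lig_xyz = _body_arrays(model)
    out: Set[ResidueKey] = set()
    for i, j in _cross_pairs(rec_xyz, lig_xyz, cutoff):
        out.add(rec[i].residue_key)
        out.add(lig[j].residue_key)
    return out


def count_clashes(model: ComplexModel, cutoff: float = CLASH_CUTOFF) -> int:
    """Number of inter-body heavy-atom pairs closer than ``cutoff``."""
    _, rec_xyz, _, lig_xyz = _body_arrays(model)
    return len(_cross_pairs(rec_xyz, lig_xyz, cutoff))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between matched coordinate arrays, no fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or len(a) < 1:
        raise CorrespondenceError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Kabsch least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (det = +1; smallest singular vector reflected
    when needed) and translation minimizing the RMSD, plus the post-fit RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise CorrespondenceError(
            f"shape mismatch: {mobile.shape} vs {reference.shape}"
        )
    if len(mobile) < 3:
        raise CorrespondenceError("superposition needs at least 3 points")
    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    p = mobile - mob_center
    q = reference - ref_center
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_center - rotation @ mob_center
    fitted = p @ rotation.T + ref_center
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        rmsd=rmsd(fitted, reference),
    )


def apply_rigid(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation


def transform_model(
    model: ComplexModel,
    rotation: np.ndarray,
    translation: np.ndarray,
    chains: Iterable[str] | None = None,
    model_id: str | None = None,
) -> ComplexModel:
    """Apply a rigid transform to (a subset of the chains of) a model."""
    chain_set = None if chains is None else set(chains)
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    new_atoms = []
    for atom in model.atoms:
        if chain_set is None or atom.chain_id in chain_set:
            from dataclasses import replace

            atom = replace(atom, coords=rotation @ atom.coords + translation)
        new_atoms.append(atom)
    return model.with_atoms(new_atoms, model_id=model_id)
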