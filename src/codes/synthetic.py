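"""Seeded synthetic data: toy two-chain complexes, rigid-body-perturbed decoy
ensembles with planted quality tiers, and feature tables with stated
class-conditional distributions.

The native is a pair of idealized helical backbones in contact (no side
chains; residue names assigned round-robin over the 20 amino acids so
class-count features are non-trivial).  Decoys perturb the ligand rigidly
with tier-dependent magnitudes; a configurable fraction is interpenetrated
to create clash outliers.  Perturbations for the non-incorrect tiers are
biased parallel to the interface so that planted tiers match assessed tiers
distributionally (individual boundary spillover is expected and tolerated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from codes.exceptions import CodesError
from codes.features import FeatureTable
from codes.structure_io import Atom, ComplexModel

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

QUALITY_TIERS = ("incorrect", "acceptable", "medium", "high")


@dataclass(frozen=True)
class FeatureSpec:
    """Class-conditional Gaussian spec for one synthetic feature."""

    name: str
    mu_incorrect: float
    mu_correct: float
    sd: float = 1.0
    missing_rate: float = 0.0

    @property
    def informative(self) -> bool:
        return self.mu_incorrect != self.mu_correct


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic data generator.  ``seed`` is mandatory."""

    seed: int
    n_targets: int = 8
    n_receptor_residues: int = 40
    n_ligand_residues: int = 25
    decoys_per_tier: Dict[str, int] = field(
        default_factory=lambda: {
            "incorrect": 30, "acceptable": 8, "medium": 6, "high": 6,
        }
    )
    # (translation Å, rotation °) per tier; must strictly increase
    # from high to incorrect.
    tier_magnitudes: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "high": (0.25, 1.5),
            "medium": (2.8, 10.0),
            "acceptable": (4.5, 14.0),
            "incorrect": (30.0, 90.0),
        }
    )
    clash_outlier_fraction: float = 0.0
    features: Tuple[FeatureSpec, ...] = (
        FeatureSpec("inf_1", mu_incorrect=0.0, mu_correct=2.0, sd=1.0),
        FeatureSpec("noise_1", mu_incorrect=0.0, mu_correct=0.0, sd=1.0),
        FeatureSpec("noise_2", mu_incorrect=1.0, mu_correct=1.0, sd=2.0),
    )

    def __post_init__(self) -> None:
        if self.n_receptor_residues < self.n_ligand_residues:
            raise CodesError("receptor must have at least as many residues as ligand")
        order = ("high", "medium", "acceptable", "incorrect")
        mags = [self.tier_magnitudes[t][0] for t in order]
        if any(a >= b for a, b in zip(mags, mags[1:])):
            raise CodesError("tier translation magnitudes must increase high -> incorrect")
        if any(n < 0 for n in self.decoys_per_tier.values()):
            raise CodesError("decoy counts must be nonnegative")


def _helix_backbone(
    n_residues: int,
    chain_id: str,
    residue_offset: int,
    origin: np.ndarray,
    rng: np.random.Generator,
    name_offset: int = 0,
    jitter: float = 0.03,
) -> List[Atom]:
    """Idealized helical backbone: CA on a helix, N/C/O at small offsets."""
    radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    atoms: List[Atom] = []
    serial = residue_offset * 10
    for i in range(n_residues):
        angle = twist * i
        ca = origin + np.array(
            [radius * np.cos(angle), radius * np.sin(angle), rise * i]
        )
        tangent = np.array([-np.sin(angle), np.cos(angle), 0.0])
        axial = np.array([0.0, 0.0, 1.0])
        offsets = {
            "N": -0.6 * tangent - 0.2 * axial,
            "CA": np.zeros(3),
            "C": 0.6 * tangent + 0.2 * axial,
            "O": 0.6 * tangent + 0.8 * axial,
        }
        res_name = AMINO_ACIDS[(i + name_offset) % len(AMINO_ACIDS)]
        for atom_name, off in offsets.items():
            serial += 1
            coords = ca + off + rng.normal(0.0, jitter, 3)
            atoms.append(
                Atom(
                    serial=serial,
                    name=atom_name,
                    element=atom_name[0],
                    residue_name=res_name,
                    chain_id=chain_id,
                    residue_seq=i + 1,
                    insertion_code="",
                    coords=coords,
                    is_hydrogen=False,
                )
            )
    return atoms


def make_native(spec: SyntheticSpec, target_index: int) -> ComplexModel:
    """Deterministic toy native complex for (seed, target index).

    The two helices run parallel with axes ~9 Å apart, which yields an
    interface with at least 5 residue contacts at 5 Å and no clashes.
    """
    rng = np.random.default_rng([spec.seed, target_index, 0])
    receptor = _helix_backbone(
        spec.n_receptor_residues, "A", 0, np.zeros(3), rng, name_offset=target_index
    )
    lig_origin = np.array([8.0, 0.0, 2.0])
    ligand = _helix_backbone(
        spec.n_ligand_residues,
        "B",
        spec.n_receptor_residues,
        lig_origin,
        rng,
        name_offset=target_index + 7,
    )
    return ComplexModel(
        model_id="native",
        target_id=f"T{target_index:03d}",
        atoms=receptor + ligand,
        receptor_chains=frozenset({"A"}),
        ligand_chains=frozenset({"B"}),
    )


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _perturb_ligand(
    native: ComplexModel,
    translation: np.ndarray,
    rotation: np.ndarray,
    model_id: str,
) -> ComplexModel:
    lig_atoms = [a for a in native.atoms if a.chain_id in native.ligand_chains]
    centroid = np.mean([a.coords for a in lig_atoms], axis=0)
    from dataclasses import replace

    new_atoms = []
    for atom in native.atoms:
        if atom.chain_id in native.ligand_chains:
            coords = rotation @ (atom.coords - centroid) + centroid + translation
            atom = replace(atom, coords=coords)
        new_atoms.append(atom)
    return native.with_atoms(new_atoms, model_id=model_id)


def make_decoys(
    native: ComplexModel, spec: SyntheticSpec
) -> Tuple[List[ComplexModel], List[str]]:
    """Rigid-body-perturbed decoys with planted quality tiers.

    Returns (decoys, planted tier per decoy).  A ``clash_outlier_fraction``
    of the decoys is additionally driven into the receptor to plant
    clash-count outliers (taken from the incorrect tier).
    """
    target_index = int(native.target_id.lstrip("T") or 0)
    rng = np.random.default_rng([spec.seed, target_index, 1])
    decoys: List[ComplexModel] = []
    tiers: List[str] = []
    counter = 0
    for tier in ("high", "medium", "acceptable", "incorrect"):
        n = spec.decoys_per_tier.get(tier, 0)
        trans_mag, rot_deg = spec.tier_magnitudes[tier]
        for _ in range(n):
            counter += 1
            direction = rng.normal(size=3)
            if tier != "incorrect":
                # bias parallel to the interface plane (x is the interface
                # normal of the generated native) to keep fnat in-tier
                direction[0] *= 0.15
            direction /= np.linalg.norm(direction)
            translation = direction * trans_mag * rng.uniform(0.85, 1.15)
            axis = rng.normal(size=3)
            angle = np.deg2rad(rot_deg * rng.uniform(0.8, 1.2))
            decoys.append(
                _perturb_ligand(
                    native,
                    translation,
                    _rotation_matrix(axis, angle),
                    model_id=f"d{counter:05d}",
                )
            )
            tiers.append(tier)
    n_outliers = int(round(spec.clash_outlier_fraction * len(decoys)))
    if n_outliers:
        incorrect_idx = [i for i, t in enumerate(tiers) if t == "incorrect"]
        chosen = incorrect_idx[:n_outliers] if incorrect_idx else list(range(n_outliers))
        for i in chosen:
            # drive the ligand into the receptor along -x to plant clashes
            decoys[i] = _perturb_ligand(
                native,
                np.array([-5.0, 0.0, 0.0]) + rng.normal(0.0, 0.3, 3),
                np.eye(3),
                model_id=decoys[i].model_id,
            )
    return decoys, tiers


def make_feature_table(
    labels: Sequence[int],
    spec: SyntheticSpec,
    keys: Optional[Sequence[Tuple[str, str]]] = None,
    salt: int = 2,
) -> FeatureTable:
    """Feature table with stated class-conditional Gaussians and missingness.

    ``labels`` is the binary label vector (0 incorrect / 1 correct); ``keys``
    optionally supplies the (target_id, model_id) index.
    """
    informative = [f for f in spec.features if f.informative]
    noise = [f for f in spec.features if not f.informative]
    if not informative or not noise:
        raise CodesError("feature spec needs >= 1 informative and >= 1 noise feature")
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    rng = np.random.default_rng([spec.seed, salt])
    if keys is None:
        keys = [("T000", f"d{i:05d}") for i in range(n)]
    columns = {}
    for fs in spec.features:
        mu = np.where(labels == 1, fs.mu_correct, fs.mu_incorrect)
        values = rng.normal(mu, fs.sd)
        if fs.missing_rate > 0:
            mask = rng.uniform(size=n) < fs.missing_rate
            values = np.where(mask, np.nan, values)
        columns[fs.name] = values
    df = pd.DataFrame(columns, index=pd.MultiIndex.from_tuples(keys, names=["target_id", "model_id"]))
    return FeatureTable(df, {c: "internal" for c in df.columns})


def make_labeled_features(
    spec: SyntheticSpec, labels_by_target: Dict[str, Sequence[int]]
) -> FeatureTable:
    """Multi-target feature table: one block per target, shared feature spec."""
    keys = []
    flat_labels: List[int] = []
    for target in sorted(labels_by_target):
        for i, lab in enumerate(labels_by_target[target]):
            keys.append((target, f"d{i:05d}"))
            flat_labels.append(int(lab))
    return make_feature_table(flat_labels, spec, keys=keys)
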