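"""Per-decoy features: consensus contact score, contact-class counts, buried
surface area, non-interacting surface, plus ingestion/cleaning/normalization
of external feature tables.

The internal registry covers the consensus score (mean ensemble frequency of
a decoy's inter-residue contacts at 5 Å), 21 contact-class counts over the
five residue classes (apolar, polar, aliphatic, aromatic, charged — classes
overlap on purpose), total/polar/apolar buried surface area, and the
polar/apolar composition of the solvent-exposed non-interface surface.
Externally computed potentials (CCharPPI/CIPS-style exports) are merged in
as CSV/TSV tables keyed by (target_id, model_id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from codes.exceptions import CodesError, KeyCollisionError
from codes.geometry import (
    CONTACT_CUTOFF,
    INTERFACE_CUTOFF,
    ContactMap,
    interface_residues,
    residue_contacts,
)
from codes.structure_io import ComplexModel

logger = logging.getLogger(__name__)

# Residue classes (3-letter codes); membership intentionally overlaps.
RESIDUE_CLASSES: Dict[str, frozenset] = {
    "apolar": frozenset(
        {"ALA", "VAL", "LEU", "ILE", "MET", "PRO", "GLY", "PHE", "TRP"}
    ),
    "polar": frozenset({"SER", "THR", "ASN", "GLN", "CYS", "TYR", "HIS"}),
    "aliphatic": frozenset({"ALA", "VAL", "LEU", "ILE"}),
    "aromatic": frozenset({"PHE", "TRP", "TYR", "HIS"}),
    "charged": frozenset({"ASP", "GLU", "LYS", "ARG", "HIS"}),
}
CLASS_NAMES = tuple(RESIDUE_CLASSES)

#: Theoretical maximum accessible surface areas (Tien et al. 2013), Å².
MAX_ASA: Dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Polar side of the binary polar/apolar partition used by the NIS terms.
NIS_POLAR = RESIDUE_CLASSES["polar"] | RESIDUE_CLASSES["charged"]

MISSING = np.nan


def internal_registry() -> List[str]:
    """Ordered names of the internally computed features."""
    names = ["CONSRANK_score"]
    for a, b in combinations_with_replacement(CLASS_NAMES, 2):
        names.append(f"NC_{a}_{b}")
    names.extend(f"NC_{c}" for c in CLASS_NAMES)
    names.append("NC_total")
    names.extend(["BSA_total", "BSA_polar", "BSA_apolar", "NIS_polar", "NIS_apolar"])
    return names


# ---------------------------------------------------------------------------
# consensus contact scoring


def contact_frequencies(ensemble: Sequence[ContactMap]) -> Dict[tuple, float]:
    """Frequency of each inter-residue contact across a decoy ensemble."""
    if not ensemble:
        raise CodesError("contact_frequencies: empty ensemble")
    counts: Dict[tuple, int] = {}
    for cmap in ensemble:
        for contact in cmap.contacts:
            counts[contact] = counts.get(contact, 0) + 1
    m = len(ensemble)
    return {c: n / m for c, n in counts.items()}


def consrank_score(
    model_contacts: ContactMap,
    frequencies: Mapping[tuple, float],
    normalize: bool = True,
) -> float:
    """Mean (or, with ``normalize=False``, summed) ensemble frequency of the
    model's contacts; 0 for a contactless model."""
    if len(model_contacts) == 0:
        return 0.0
    total = sum(frequencies.get(c, 0.0) for c in model_contacts.contacts)
    return total / len(model_contacts) if normalize else total


# ---------------------------------------------------------------------------
# contact-class counts


def residue_classes_of(residue_name: str) -> Tuple[str, ...]:
    classes = tuple(c for c in CLASS_NAMES if residue_name in RESIDUE_CLASSES[c])
    if not classes:
        logger.warning("residue %s matches no class", residue_name)
    return classes


def contact_class_counts(
    model: ComplexModel, cutoff: float = CONTACT_CUTOFF
) -> Dict[str, int]:
    """Counts of 5 Å residue contacts per residue-class pair.

    Returns 15 unordered class-pair counts, 5 per-class totals (contacts with
    at least one member in the class) and the overall contact total.
    Overlapping class membership makes one contact count in every applicable
    pair.
    """
    counts = {f"NC_{a}_{b}": 0 for a, b in combinations_with_replacement(CLASS_NAMES, 2)}
    counts.update({f"NC_{c}": 0 for c in CLASS_NAMES})
    counts["NC_total"] = 0
    res_names = {a.residue_key: a.residue_name for a in model.atoms}
    for rec_key, lig_key in residue_contacts(model, cutoff=cutoff).contacts:
        counts["NC_total"] += 1
        rec_classes = residue_classes_of(res_names[rec_key])
        lig_classes = residue_classes_of(res_names[lig_key])
        for c in set(rec_classes) | set(lig_classes):
            counts[f"NC_{c}"] += 1
        seen_pairs = set()
        for cr in rec_classes:
            for cl in lig_classes:
                a, b = sorted((cr, cl), key=CLASS_NAMES.index)
                seen_pairs.add(f"NC_{a}_{b}")
        for pair in seen_pairs:
            counts[pair] += 1
    return counts


# ---------------------------------------------------------------------------
# surface areas


def _sasa_per_atom(atoms, point_number: int = 960, probe_radius: float = 1.4) -> np.ndarray:
    """Shrake-Rupley SASA per heavy atom (element-based radii)."""
    import biotite.structure as struc

    n = len(atoms)
    array = struc.AtomArray(n)
    array.coord = np.asarray([a.coords for a in atoms], dtype=np.float32)
    array.chain_id = np.asarray([a.chain_id for a in atoms])
    array.res_id = np.asarray([a.residue_seq for a in atoms])
    array.ins_code = np.asarray([a.insertion_code for a in atoms])
    array.res_name = np.asarray([a.residue_name for a in atoms])
    array.atom_name = np.asarray([a.name for a in atoms])
    array.element = np.asarray([a.element for a in atoms])
    array.hetero = np.zeros(n, dtype=bool)
    values = struc.sasa(
        array,
        probe_radius=probe_radius,
        point_number=point_number,
        vdw_radii="Single",
    )
    return np.nan_to_num(np.asarray(values, dtype=float))


def buried_surface_area(
    model: ComplexModel, point_number: int = 960, probe_radius: float = 1.4
) -> Tuple[float, float, float]:
    """Buried surface area (total, polar, apolar) in Å².

    BSA = SASA(receptor alone) + SASA(ligand alone) − SASA(complex), split
    into a polar part (N/O atoms) and an apolar part (all other heavy atoms,
    i.e. C/S); total = polar + apolar by construction.
    """
    rec = model.body_atoms("receptor", heavy_only=True)
    lig = model.body_atoms("ligand", heavy_only=True)
    all_atoms = rec + lig
    sasa_complex = _sasa_per_atom(all_atoms, point_number, probe_radius)
    sasa_rec = _sasa_per_atom(rec, point_number, probe_radius)
    sasa_lig = _sasa_per_atom(lig, point_number, probe_radius)
    free = np.concatenate([sasa_rec, sasa_lig])
    buried = free - sasa_complex
    polar_mask = np.asarray([a.element in ("N", "O") for a in all_atoms])
    polar = float(buried[polar_mask].sum())
    apolar = float(buried[~polar_mask].sum())
    return polar + apolar, polar, apolar


def nis(
    model: ComplexModel,
    exposure_threshold: float = 0.05,
    interface_cutoff: float = INTERFACE_CUTOFF,
    point_number: int = 960,
    probe_radius: float = 1.4,
) -> Tuple[float, float]:
    """Polar / apolar percentages of the exposed non-interacting surface.

    Among residues that are solvent exposed in the complex (relative SASA
    above ``exposure_threshold`` of the residue's theoretical maximum) and
    NOT within the 10 Å interface, returns the percentage classified polar
    (polar or charged class) and apolar.  Returns (nan, nan) when no residue
    qualifies.
    """
    atoms = model.body_atoms("receptor", True) + model.body_atoms("ligand", True)
    sasa_atoms = _sasa_per_atom(atoms, point_number, probe_radius)
    per_residue: Dict[tuple, float] = {}
    res_names: Dict[tuple, str] = {}
    for atom, area in zip(atoms, sasa_atoms):
        per_residue[atom.residue_key] = per_residue.get(atom.residue_key, 0.0) + area
        res_names[atom.residue_key] = atom.residue_name
    iface = interface_residues(model, cutoff=interface_cutoff)
    n_polar = n_apolar = 0
    for key, area in per_residue.items():
        if key in iface:
            continue
        max_asa = MAX_ASA.get(res_names[key], 200.0)
        if area / max_asa <= exposure_threshold:
            continue
        if res_names[key] in NIS_POLAR:
            n_polar += 1
        else:
            n_apolar += 1
    total = n_polar + n_apolar
    if total == 0:
        return (MISSING, MISSING)
    return (100.0 * n_polar / total, 100.0 * n_apolar / total)


# ---------------------------------------------------------------------------
# feature tables


@dataclass
class FeatureTable:
    """Per-decoy feature vectors over a named registry.

    ``data`` is indexed by (target_id, model_id); missing values are NaN.
    ``provenance`` tags each feature as internally computed or externally
    ingested.
    """

    data: pd.DataFrame
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.MultiIndex):
            raise CodesError("FeatureTable index must be (target_id, model_id)")
        self.data.index = self.data.index.set_names(["target_id", "model_id"])
        for name in self.data.columns:
            self.provenance.setdefault(name, "external")

    @property
    def registry(self) -> List[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def rows_for_targets(self, targets: Iterable[str]) -> "FeatureTable":
        targets = set(targets)
        mask = self.data.index.get_level_values("target_id").isin(targets)
        return FeatureTable(self.data.loc[mask].copy(), dict(self.provenance))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, provenance: str = "external") -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={0: str, 1: str})
        df = df.set_index(["target_id", "model_id"])
        return cls(df, {c: provenance for c in df.columns})


def compute_internal_features(
    decoys: Sequence[ComplexModel],
    target_id: str,
    contact_cutoff: float = CONTACT_CUTOFF,
    with_surface: bool = True,
    sasa_points: int = 960,
) -> FeatureTable:
    """Compute the internal feature block for one target's decoy ensemble.

    The consensus score uses contact frequencies over exactly the given
    ensemble.  Surface features (BSA, NIS) can be switched off for speed.
    """
    maps = [residue_contacts(d, cutoff=contact_cutoff) for d in decoys]
    freqs = contact_frequencies(maps)
    rows = {}
    for decoy, cmap in zip(decoys, maps):
        row: Dict[str, float] = {"CONSRANK_score": consrank_score(cmap, freqs)}
        row.update(contact_class_counts(decoy, cutoff=contact_cutoff))
        if with_surface:
            try:
                total, polar, apolar = buried_surface_area(decoy, point_number=sasa_points)
                row["BSA_total"], row["BSA_polar"], row["BSA_apolar"] = total, polar, apolar
            except Exception as exc:
                logger.warning("BSA failed for %s: %s", decoy.model_id, exc)
                row["BSA_total"] = row["BSA_polar"] = row["BSA_apolar"] = MISSING
            row["NIS_polar"], row["NIS_apolar"] = nis(decoy, point_number=sasa_points)
        else:
            for name in ("BSA_total", "BSA_polar", "BSA_apolar", "NIS_polar", "NIS_apolar"):
                row[name] = MISSING
        rows[(target_id, decoy.model_id)] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=internal_registry())
    df.index = pd.MultiIndex.from_tuples(df.index, names=["target_id", "model_id"])
    return FeatureTable(df, {c: "internal" for c in df.columns})


def load_external_features(
    paths: Sequence, registry: Optional[Sequence[str]] = None
) -> FeatureTable:
    """Merge CSV/TSV feature exports keyed by (target_id, model_id).

    Columns outside ``registry`` (when given) are ignored with a warning;
    duplicate keys with conflicting values raise
    :class:`~codes.exceptions.KeyCollisionError`.
    """
    frames = []
    for path in paths:
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, na_values=["NA"], dtype={"target_id": str, "model_id": str})
        if "target_id" not in df.columns or "model_id" not in df.columns:
            raise CodesError(f"{path}: missing target_id/model_id key columns")
        df = df.set_index(["target_id", "model_id"])
        if registry is not None:
            unknown = [c for c in df.columns if c not in registry]
            if unknown:
                logger.warning("%s: ignoring unknown columns %s", path, unknown)
                df = df.drop(columns=unknown)
        frames.append(df)
    merged: Optional[pd.DataFrame] = None
    for df in frames:
        if merged is None:
            merged = df
            continue
        overlap_cols = merged.columns.intersection(df.columns)
        if len(overlap_cols):
            shared = merged.index.intersection(df.index)
            if len(shared):
                a = merged.loc[shared, overlap_cols]
                b = df.loc[shared, overlap_cols]
                conflict = ~((a.values == b.values) | (pd.isna(a.values) & pd.isna(b.values)))
                if conflict.any():
                    raise KeyCollisionError(
                        "conflicting values for duplicated (target, model) keys"
                    )
        merged = merged.combine_first(df)
    assert merged is not None
    return FeatureTable(merged, {c: "external" for c in merged.columns})


def merge_tables(*tables: FeatureTable) -> FeatureTable:
    """Column-wise merge of feature tables sharing the (target, model) keying."""
    data = tables[0].data
    provenance = dict(tables[0].provenance)
    for t in tables[1:]:
        dup = data.columns.intersection(t.data.columns)
        if len(dup):
            raise KeyCollisionError(f"duplicate feature columns: {list(dup)}")
        data = data.join(t.data, how="outer")
        provenance.update(t.provenance)
    return FeatureTable(data, provenance)


def clean_and_impute(
    table: FeatureTable, max_missing_frac: float = 0.3
) -> FeatureTable:
    """Drop features missing for more than ``max_missing_frac`` of all rows,
    then impute remaining gaps with the per-target feature mean (global mean
    when a target has no observed value).  Idempotent."""
    if len(table) == 0:
        raise CodesError("clean_and_impute: empty table")
    df = table.data.copy()
    missing_frac = df.isna().mean(axis=0)
    dropped = [c for c in df.columns if missing_frac[c] > max_missing_frac]
    if dropped:
        logger.warning(
            "dropping %d feature(s) missing in >%.0f%% of rows: %s",
            len(dropped),
            100 * max_missing_frac,
            dropped,
        )
        df = df.drop(columns=dropped)
    target_means = df.groupby(level="target_id").transform("mean")
    df = df.fillna(target_means)
    df = df.fillna(df.mean(axis=0))  # global-mean fallback
    still_empty = [c for c in df.columns if df[c].isna().any()]
    if still_empty:
        logger.warning("dropping feature(s) with no observations: %s", still_empty)
        df = df.drop(columns=still_empty)
    prov = {c: table.provenance.get(c, "external") for c in df.columns}
    return FeatureTable(df, prov)


@dataclass
class NormalizationStats:
    """Per-feature mean/sd fit on training rows only (z-score parameters)."""

    mu: pd.Series
    sigma: pd.Series

    @classmethod
    def fit(cls, table: FeatureTable, ddof: int = 0) -> "NormalizationStats":
        mu = table.data.mean(axis=0)
        sigma = table.data.std(axis=0, ddof=ddof)
        return cls(mu=mu, sigma=sigma)

    def to_dict(self) -> dict:
        return {"mu": self.mu.to_dict(), "sigma": self.sigma.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(mu=pd.Series(d["mu"]), sigma=pd.Series(d["sigma"]))


def zscore(table: FeatureTable, stats: NormalizationStats) -> FeatureTable:
    """Replace every cell x by (x − μ)/σ; constant features (σ = 0) are
    dropped with a warning."""
    constant = [c for c in table.data.columns if not stats.sigma.get(c, 0) > 0]
    if constant:
        logger.warning("dropping constant feature(s): %s", constant)
    keep = [c for c in table.data.columns if c not in constant]
    df = (table.data[keep] - stats.mu[keep]) / stats.sigma[keep]
    return FeatureTable(df, {c: table.provenance.get(c, "external") for c in keep})
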