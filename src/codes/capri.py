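"""CAPRI-style quality assessment of docking decoys against a native complex.

For each decoy three parameters are computed — fnat (fraction of native
5 Å residue contacts reproduced), L-rms (ligand backbone RMSD after
superposing the receptors) and I-rms (backbone RMSD over the native 10 Å
interface residues after superposing them) — and combined into the
four-level quality label.  Per-target clash screening discards decoys with
more clashes than the target mean plus two standard deviations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from codes.exceptions import (
    CorrespondenceError,
    DegenerateStatisticsError,
    UndefinedNativeError,
)
from codes.geometry import (
    CLASH_CUTOFF,
    CONTACT_CUTOFF,
    INTERFACE_CUTOFF,
    ContactMap,
    count_clashes,
    interface_residues,
    residue_contacts,
    rmsd,
    superpose,
)
from codes.structure_io import ComplexModel, backbone_atom_map

logger = logging.getLogger(__name__)

QUALITY_ORDER = ("incorrect", "acceptable", "medium", "high")
CORRECT_QUALITIES = frozenset({"acceptable", "medium", "high"})


def quality_rank(label: str) -> int:
    return QUALITY_ORDER.index(label)


@dataclass(frozen=True)
class QualityCriteria:
    """Thresholds of the ranked quality classification.

    Defaults follow the published CAPRI assessment criteria:

    * incorrect: fnat < 0.1, or L-rms > 10 and I-rms > 4
    * high: fnat >= 0.5 and (L-rms <= 1 or I-rms <= 1)
    * medium: fnat >= 0.3 and (L-rms <= 5 or I-rms <= 2), not high
    * acceptable: everything else not incorrect
    """

    fnat_incorrect: float = 0.1
    lrms_incorrect: float = 10.0
    irms_incorrect: float = 4.0
    fnat_medium: float = 0.3
    lrms_medium: float = 5.0
    irms_medium: float = 2.0
    fnat_high: float = 0.5
    lrms_high: float = 1.0
    irms_high: float = 1.0

    @classmethod
    def from_json(cls, path) -> "QualityCriteria":
        with open(path) as fh:
            data = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown criteria keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class CapriMetrics:
    """Assessment of one decoy: the three parameters, label and clash count."""

    model_id: str
    fnat: float
    lrms: float
    irms: float
    quality: str
    clashes: int
    error: Optional[str] = None

    @property
    def is_correct(self) -> bool:
        return self.quality in CORRECT_QUALITIES


@dataclass(frozen=True)
class ClashScreen:
    """Per-target mean + 2*sd clash filter outcome."""

    target_id: str
    mean_clashes: float
    sd_clashes: float
    threshold: float
    kept_ids: Tuple[str, ...]
    discarded_ids: Tuple[str, ...]


def fnat(native_contacts: ContactMap, model_contacts: ContactMap) -> float:
    """Fraction of native contacts reproduced by the model (extras ignored)."""
    if len(native_contacts) == 0:
        raise UndefinedNativeError(
            f"{native_contacts.target_id}: native contact map is empty"
        )
    shared = native_contacts.contacts & model_contacts.contacts
    return len(shared) / len(native_contacts)


def _matched_backbone(
    native: ComplexModel,
    decoy: ComplexModel,
    body: Optional[str] = None,
    residue_subset=None,
    min_atoms: int = 3,
) -> Tuple[np.ndarray, np.ndarray]:
    """Backbone coordinate arrays matched by (residue key, atom name)."""
    nat = backbone_atom_map(native, residue_subset=residue_subset, body=body)
    dec = backbone_atom_map(decoy, residue_subset=residue_subset, body=body)
    common = [k for k in nat if k in dec]  # native order
    dropped = len(nat) - len(common)
    if dropped:
        logger.info(
            "%s vs %s: %d native backbone atom(s) unmatched in decoy",
            native.model_id,
            decoy.model_id,
            dropped,
        )
    if len(common) < min_atoms:
        raise CorrespondenceError(
            f"only {len(common)} matched backbone atoms (need >= {min_atoms})"
        )
    nat_xyz = np.asarray([nat[k] for k in common])
    dec_xyz = np.asarray([dec[k] for k in common])
    return nat_xyz, dec_xyz


def ligand_rmsd(native: ComplexModel, decoy: ComplexModel) -> float:
    """Ligand backbone RMSD after optimally superposing the receptors."""
    nat_rec, dec_rec = _matched_backbone(native, decoy, body="receptor")
    fit = superpose(dec_rec, nat_rec)
    nat_lig, dec_lig = _matched_backbone(native, decoy, body="ligand", min_atoms=1)
    return rmsd(fit.apply(dec_lig), nat_lig)


def interface_rmsd(
    native: ComplexModel,
    decoy: ComplexModel,
    cutoff: float = INTERFACE_CUTOFF,
) -> float:
    """Backbone RMSD over the native interface residues after superposing them.

    The interface is defined on the native only, at the 10 Å heavy-atom
    criterion.
    """
    iface = interface_residues(native, cutoff=cutoff)
    nat_xyz, dec_xyz = _matched_backbone(native, decoy, residue_subset=iface)
    return superpose(dec_xyz, nat_xyz).rmsd


def classify_quality(
    fnat_value: float,
    lrms: float,
    irms: float,
    criteria: QualityCriteria = QualityCriteria(),
) -> str:
    """Ranked CAPRI classification of (fnat, L-rms, I-rms)."""
    c = criteria
    if fnat_value < c.fnat_incorrect or (
        lrms > c.lrms_incorrect and irms > c.irms_incorrect
    ):
        return "incorrect"
    if fnat_value >= c.fnat_high and (lrms <= c.lrms_high or irms <= c.irms_high):
        return "high"
    if fnat_value >= c.fnat_medium and (lrms <= c.lrms_medium or irms <= c.irms_medium):
        return "medium"
    return "acceptable"


def screen_clashes(
    models: Sequence[Tuple[str, int]],
    n_sd: float = 2.0,
    ddof: int = 1,
) -> ClashScreen:
    """Discard models with clashes strictly above mean + ``n_sd`` * sd.

    The standard deviation uses the sample (n-1) denominator by default.
    """
    if len(models) < 2:
        raise DegenerateStatisticsError(
            f"clash screening needs >= 2 models, got {len(models)}"
        )
    counts = np.asarray([c for _, c in models], dtype=float)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=ddof))
    threshold = mean + n_sd * sd
    kept = tuple(mid for (mid, c) in models if c <= threshold)
    discarded = tuple(mid for (mid, c) in models if c > threshold)
    return ClashScreen(
        target_id="",
        mean_clashes=mean,
        sd_clashes=sd,
        threshold=threshold,
        kept_ids=kept,
        discarded_ids=discarded,
    )


def assess_decoy(
    native: ComplexModel,
    decoy: ComplexModel,
    native_contacts: Optional[ContactMap] = None,
    criteria: QualityCriteria = QualityCriteria(),
    contact_cutoff: float = CONTACT_CUTOFF,
    clash_cutoff: float = CLASH_CUTOFF,
) -> CapriMetrics:
    """Assess a single decoy; failures become flagged records, not exceptions."""
    if native_contacts is None:
        native_contacts = residue_contacts(native, cutoff=contact_cutoff)
    try:
        decoy_contacts = residue_contacts(decoy, cutoff=contact_cutoff)
        f = fnat(native_contacts, decoy_contacts)
        l = ligand_rmsd(native, decoy)
        i = interface_rmsd(native, decoy)
        q = classify_quality(f, l, i, criteria=criteria)
        clashes = count_clashes(decoy, cutoff=clash_cutoff)
        return CapriMetrics(
            model_id=decoy.model_id, fnat=f, lrms=l, irms=i, quality=q, clashes=clashes
        )
    except Exception as exc:
        logger.warning("assessment failed for %s: %s", decoy.model_id, exc)
        return CapriMetrics(
            model_id=decoy.model_id,
            fnat=float("nan"),
            lrms=float("nan"),
            irms=float("nan"),
            quality="incorrect",
            clashes=-1,
            error=str(exc),
        )


def assess_target(
    native: ComplexModel,
    decoys: Iterable[ComplexModel],
    criteria: QualityCriteria = QualityCriteria(),
    contact_cutoff: float = CONTACT_CUTOFF,
    clash_cutoff: float = CLASH_CUTOFF,
) -> List[CapriMetrics]:
    """Assess every decoy of a target; order-preserving, per-decoy independent."""
    native_contacts = residue_contacts(native, cutoff=contact_cutoff)
    return [
        assess_decoy(
            native,
            decoy,
            native_contacts=native_contacts,
            criteria=criteria,
            contact_cutoff=contact_cutoff,
            clash_cutoff=clash_cutoff,
        )
        for decoy in decoys
    ]


def metrics_to_tsv(records: Sequence[CapriMetrics], path) -> None:
    """Write assessment records as a TSV report."""
    header = "model_id\tfnat\tlrms\tirms\tclashes\tquality"
    lines = [header]
    for r in records:
        lines.append(
            f"{r.model_id}\t{r.fnat:.4f}\t{r.lrms:.4f}\t{r.irms:.4f}\t"
            f"{r.clashes}\t{r.quality}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
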