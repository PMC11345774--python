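"""Property-matched, topology-dissimilar decoy selection, and curation of
the active set used for query validation.

Decoys are drawn per active from a candidate universe: a candidate must sit
inside every physicochemical window around its active (MW, logP, rotatable
bonds, HBD, HBA, exact net charge) yet be topologically dissimilar
(circular-fingerprint Tanimoto below a cap, default 0.35). Each active draws
``k`` candidates without replacement under a fixed seed; decoys claimed by an
earlier active are not reassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chem import BasicityVerdict, MoleculeRecord, compute_descriptors, nonbasic_filter

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = {
    "MW": 25.0,  # Da
    "logP_estimate": 1.0,
    "rotatable_bonds": 2,
    "hbd": 1,
    "hba": 1,
}


@dataclass
class DecoySpec:
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    max_fingerprint_similarity: float = 0.35
    decoys_per_active: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.windows.values()):
            raise ValueError("property windows must be non-negative")
        if not 0 < self.max_fingerprint_similarity < 1:
            raise ValueError("max_fingerprint_similarity must be in (0, 1)")
        if self.decoys_per_active < 1:
            raise ValueError("decoys_per_active must be >= 1")


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def fingerprint(rec: MoleculeRecord):
    return _FP_GEN.GetFingerprint(rec.mol)


def _within_windows(d_active: dict, d_cand: dict, windows: dict) -> bool:
    for prop, width in windows.items():
        if abs(d_cand[prop] - d_active[prop]) > width:
            return False
    return d_cand["net_formal_charge"] == d_active["net_formal_charge"]


def generate_decoys(
    actives: list[MoleculeRecord],
    universe: list[MoleculeRecord],
    spec: DecoySpec,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Select property-matched decoys from ``universe`` for each active.

    Returns the decoy set and a provenance table (decoy id -> active id plus
    the matched property values). Shortfalls — actives with fewer than ``k``
    eligible candidates left — are logged and recorded in the table.
    """
    if not universe:
        raise ValueError("empty decoy universe")
    active_keys = {rec.inchikey for rec in actives}
    pool = [rec for rec in universe if rec.inchikey not in active_keys]
    for rec in pool + list(actives):
        if not rec.descriptors:
            rec.descriptors = compute_descriptors(rec)
    pool_fps = [fingerprint(rec) for rec in pool]

    rng = np.random.default_rng(spec.seed)
    taken: set[int] = set()
    decoys: list[MoleculeRecord] = []
    rows = []
    for active in actives:
        fp_a = fingerprint(active)
        candidates = [
            i
            for i in range(len(pool))
            if i not in taken
            and _within_windows(active.descriptors, pool[i].descriptors, spec.windows)
            and DataStructs.TanimotoSimilarity(fp_a, pool_fps[i]) < spec.max_fingerprint_similarity
        ]
        k = spec.decoys_per_active
        if len(candidates) < k:
            logger.warning(
                "shortfall for active %s: %d candidates < k=%d", active.id, len(candidates), k
            )
            chosen = candidates
        else:
            chosen = list(rng.choice(len(candidates), size=k, replace=False))
            chosen = [candidates[j] for j in sorted(chosen)]
        for i in chosen:
            taken.add(i)
            decoys.append(pool[i])
            rows.append(
                {
                    "decoy_id": pool[i].id,
                    "active_id": active.id,
                    "tanimoto": DataStructs.TanimotoSimilarity(fp_a, pool_fps[i]),
                    "shortfall": len(candidates) < k,
                    **{f"decoy_{p}": pool[i].descriptors[p] for p in spec.windows},
                }
            )
    provenance = pd.DataFrame(rows)
    return decoys, provenance


def curate_actives(raw: list[MoleculeRecord], annotations: pd.DataFrame) -> tuple[list[MoleculeRecord], dict]:
    """Apply the active-set curation rules and report per-stage counts.

    ``annotations`` columns: id, ec50_nM (numeric or inexact strings like
    ">1000"), assay, units. Kept: exact EC50 in nM, MW 300-500 Da, a
    [35S]GTPgammaS functional assay, uncharged/nonbasic structures; then
    de-duplicated by canonical identity (InChIKey).
    """
    ann = annotations.set_index("id")
    counts = {"input": len(raw)}

    def exact_ec50(mol_id: str) -> bool:
        if mol_id not in ann.index:
            return False
        row = ann.loc[mol_id]
        if str(row.get("units", "")).strip().lower() != "nm":
            return False
        try:
            val = float(row["ec50_nM"])
        except (TypeError, ValueError):
            return False
        return np.isfinite(val) and val > 0

    stage = [rec for rec in raw if exact_ec50(rec.id)]
    counts["exact_ec50_nM"] = len(stage)
    stage = [
        rec
        for rec in stage
        if str(ann.loc[rec.id].get("assay", "")).strip().lower() in {"gtpgammas", "[35s]gtpgammas"}
    ]
    counts["gtpgammas_assay"] = len(stage)
    stage = [rec for rec in stage if 300.0 <= (rec.descriptors or compute_descriptors(rec))["MW"] <= 500.0]
    counts["mw_300_500"] = len(stage)
    stage = [rec for rec in stage if nonbasic_filter(rec) is BasicityVerdict.PASS]
    counts["uncharged"] = len(stage)
    seen: set[str] = set()
    curated = []
    for rec in stage:
        key = rec.inchikey
        if key not in seen:
            seen.add(key)
            curated.append(rec)
    counts["deduplicated"] = len(curated)
    return curated, counts


def verify_decoys(
    actives: list[MoleculeRecord],
    decoys: list[MoleculeRecord],
    provenance: pd.DataFrame,
    spec: DecoySpec,
) -> bool:
    """Independent recheck: recompute every decoy's descriptors from its
    structure and confirm it sits inside all windows of its assigned active
    and below the similarity cap."""
    by_id = {rec.id: rec for rec in actives}
    dec_by_id = {rec.id: rec for rec in decoys}
    for _, row in provenance.iterrows():
        active = by_id[row["active_id"]]
        decoy = dec_by_id[row["decoy_id"]]
        d_a = compute_descriptors(active)
        d_d = compute_descriptors(decoy)
        if not _within_windows(d_a, d_d, spec.windows):
            return False
        sim = DataStructs.TanimotoSimilarity(fingerprint(active), fingerprint(decoy))
        if sim >= spec.max_fingerprint_similarity:
            return False
    return True
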