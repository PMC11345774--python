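"""Hit triage and end-to-end pipeline orchestration.

The screening campaign this package models runs two parallel screens
(pharmacophore match and Gaussian shape), merges their hit lists by
canonical structure, removes charged/basic molecules and physicochemical
outliers, re-scores externally generated docking poses against the query in
a fixed receptor frame, and annotates poses with contacts to the binding-
site residues known to matter for the salvinorin scaffold (Q115, V118,
Y139, Y312, Y313). Manual pose inspection is deliberately not automated:
the pipeline ends in a ranked report with every selection criterion as a
sortable column.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from . import chem
from .chem import BasicityVerdict, MoleculeRecord, compute_descriptors, nonbasic_filter
from .pharmacophore import PharmacophoreQuery, match
from .ranking import RankedScreen

logger = logging.getLogger(__name__)

HBOND_DISTANCE_MAX = 3.5  # Angstrom, heavy-atom donor-acceptor
HYDROPHOBIC_DISTANCE_MAX = 4.5  # Angstrom, apolar C...C
KEY_RESIDUES = ("Q115", "V118", "Y139", "Y312", "Y313")

_ONE_LETTER = {"GLN": "Q", "VAL": "V", "TYR": "Y", "GLU": "E", "LEU": "L",
               "ILE": "I", "ALA": "A", "GLY": "G", "SER": "S", "THR": "T",
               "PHE": "F", "TRP": "W", "MET": "M", "CYS": "C", "HIS": "H",
               "LYS": "K", "ARG": "R", "ASP": "D", "ASN": "N", "PRO": "P"}


@dataclass
class Contact:
    residue: str  # e.g. "Y312"
    kind: str  # "hbond" | "hydrophobic"
    distance: float
    ligand_atom: int
    receptor_atom: str


@dataclass
class TriageRecord:
    id: str
    origin: str  # pharm_screen | shape_screen | both
    pharm_score: float | None = None
    shape_combo: float | None = None
    filter_flags: dict = field(default_factory=dict)
    pose_score: float | None = None
    c2_analog_matched: bool | None = None
    contacts: list[Contact] = field(default_factory=list)
    record: MoleculeRecord | None = None

    @property
    def survives_filters(self) -> bool:
        return not any(self.filter_flags.values())


def merge_hits(
    screens: dict[str, RankedScreen],
    records_by_id: dict[str, MoleculeRecord],
) -> list[TriageRecord]:
    """Union of hit lists by canonical-structure identity (InChIKey).

    Duplicates collapse into one record keeping the best score from each
    method; origin is 'both' when a structure appears in both screens.
    """
    if not screens:
        raise ValueError("need at least one screen to merge")
    by_key: dict[str, TriageRecord] = {}
    for origin, screen_res in screens.items():
        for e in screen_res:
            rec = records_by_id[e.id]
            key = rec.inchikey
            tr = by_key.get(key)
            if tr is None:
                tr = TriageRecord(id=e.id, origin=origin, record=rec)
                by_key[key] = tr
            elif tr.origin != origin:
                tr.origin = "both"
            if origin == "pharm_screen":
                tr.pharm_score = max(tr.pharm_score or 0.0, e.score)
            elif origin == "shape_screen":
                tr.shape_combo = max(tr.shape_combo or 0.0, e.score)
    return list(by_key.values())


def apply_filters(
    records: list[TriageRecord], mw_max: float = 500.0, rotb_max: int = 10
) -> tuple[list[TriageRecord], dict]:
    """Charge/basicity and physicochemical filters; boundary values pass.

    Every record gets its flags; survivors have all flags False. Returns
    (survivors, per-flag counts). The filters commute — each flag is an
    independent predicate of the structure.
    """
    counts = {"input": len(records), "charged": 0, "basic": 0, "mw_gt_max": 0, "rotb_gt_max": 0}
    survivors = []
    for tr in records:
        rec = tr.record
        d = rec.descriptors or compute_descriptors(rec)
        verdict = nonbasic_filter(rec)
        tr.filter_flags = {
            "charged": verdict is BasicityVerdict.FAIL_CHARGED,
            "basic": verdict is BasicityVerdict.FAIL_BASIC,
            "mw_gt_max": d["MW"] > mw_max,
            "rotb_gt_max": d["rotatable_bonds"] > rotb_max,
        }
        for k in ("charged", "basic", "mw_gt_max", "rotb_gt_max"):
            counts[k] += int(tr.filter_flags[k])
        if tr.survives_filters:
            survivors.append(tr)
    counts["survivors"] = len(survivors)
    return survivors, counts


def rescore_poses(
    poses: list[MoleculeRecord],
    query: PharmacophoreQuery,
    c2_label: str = "C2-HBA",
    score_threshold: float = 0.0,
) -> list[TriageRecord]:
    """Fixed-frame pharmacophore re-scoring of docking poses.

    Poses and query must share one coordinate frame: features are matched
    without realignment and poses are kept only when the partial-match score
    exceeds the threshold (default: greater than zero). When the query
    carries the feature analogous to the C2-acetoxy carbonyl acceptor,
    each kept pose records whether that feature was fulfilled.
    """
    q_centers = np.array([f.center for f in query.features])
    kept: list[TriageRecord] = []
    for rec in poses:
        coords = rec.conformer_coords(0)
        min_d = np.min(
            np.linalg.norm(coords[:, None, :] - q_centers[None, :, :], axis=2)
        )
        if min_d > 20.0:
            logger.warning(
                "pose %s lies %.1f A from every query feature - frame mismatch?",
                rec.id, min_d,
            )
        res = match(query, rec, mode="partial", fixed_frame=True)
        score = res.score if res is not None and not res.clash else 0.0
        if score <= score_threshold:
            continue
        c2 = None
        if c2_label in query.labels:
            c2 = bool(res is not None and c2_label in res.assignment)
        kept.append(
            TriageRecord(
                id=rec.id,
                origin="pose",
                pose_score=score,
                c2_analog_matched=c2,
                record=rec,
            )
        )
    return kept


def _parse_receptor(receptor: str | Path):
    """Accept a PDB file path or raw PDB text."""
    parser = PDBParser(QUIET=True)
    if isinstance(receptor, Path) or (isinstance(receptor, str) and "\n" not in receptor):
        path = Path(receptor)
        if not path.exists():
            raise IOError(f"receptor PDB not found: {receptor}")
        structure = parser.get_structure("receptor", str(path))
    else:
        structure = parser.get_structure("receptor", io.StringIO(receptor))
    atoms = []
    for model in structure:
        for chain_obj in model:
            for res in chain_obj:
                resname = res.get_resname().strip()
                label = f"{_ONE_LETTER.get(resname, 'X')}{res.get_id()[1]}"
                for atom in res:
                    atoms.append((label, atom.get_name(), atom.element, np.array(atom.get_coord(), dtype=float)))
        break
    if not atoms:
        raise IOError("no atoms parsed from receptor PDB")
    return atoms


def annotate_contacts(
    pose: MoleculeRecord,
    receptor: str | Path,
    residue_whitelist: tuple[str, ...] | None = KEY_RESIDUES,
    hbond_max: float = HBOND_DISTANCE_MAX,
    hydrophobic_max: float = HYDROPHOBIC_DISTANCE_MAX,
) -> list[Contact]:
    """Distance-based protein-ligand contact detection in a shared frame.

    Hydrogen bond: a ligand acceptor (donor) heavy atom within ``hbond_max``
    of a receptor N/O atom (distance-only; no explicit hydrogens in either
    partner). Hydrophobic: an apolar ligand carbon within ``hydrophobic_max``
    of a receptor carbon. ``residue_whitelist=None`` reports all residues.
    """
    atoms = _parse_receptor(receptor)
    if residue_whitelist is not None:
        atoms = [a for a in atoms if a[0] in residue_whitelist]
    coords = pose.conformer_coords(0)
    acceptors = chem._hba_atoms(pose.mol)
    donors = chem._hbd_atoms(pose.mol)
    apolar = chem._apolar_atoms(pose.mol)
    carbons = {i for i in apolar if pose.mol.GetAtomWithIdx(i).GetAtomicNum() == 6}
    contacts: list[Contact] = []
    for label, name, element, xyz in atoms:
        el = (element or name[0]).strip().upper()
        d = np.linalg.norm(coords - xyz, axis=1)
        if el in {"N", "O"}:
            for i in sorted(acceptors | donors):
                if d[i] <= hbond_max:
                    contacts.append(Contact(label, "hbond", float(d[i]), i, name))
        elif el == "C":
            for i in sorted(carbons):
                if d[i] <= hydrophobic_max:
                    contacts.append(Contact(label, "hydrophobic", float(d[i]), i, name))
    return contacts


# --- end-to-end pipeline ----------------------------------------------------

_REQUIRED_CONFIG = ("seed", "n_actives", "decoys_per_active")


def run_pipeline(config: dict) -> dict:
    """Fixture-driven end-to-end run mirroring the campaign workflow:
    build inputs, screen, merge, filter, optionally re-score poses and
    annotate contacts, and report per-stage counts.

    Config keys: ``seed``, ``n_actives``, ``decoys_per_active`` (required);
    ``mode`` (pharmacophore screen mode, default "full"), ``screen_decoys``
    (how many universe decoys to screen, default all generated),
    ``shape_top_n`` (default 500; 0 disables the shape screen),
    ``shape_library_cap`` (molecules entering the shape screen, default 25),
    ``mw_max`` (500), ``rotb_max`` (10), ``rescore`` (bool, default True).
    Deterministic under a fixed config.
    """
    for key in _REQUIRED_CONFIG:
        if key not in config:
            raise ValueError(f"missing pipeline config key: {key!r}")
    from . import decoys as decoy_mod
    from . import fixtures
    from .pharmacophore import screen as pharm_screen
    from .shape import align_and_score, shape_screen

    seed = int(config["seed"])
    mode = config.get("mode", "full")
    shape_top_n = int(config.get("shape_top_n", 500))
    if shape_top_n < 1:
        raise ValueError("shape_top_n must be >= 1 (skip the shape stage with shape_library_cap = 0)")

    spec = fixtures.FixtureSpec(
        seed=seed,
        n_actives=int(config["n_actives"]),
        decoys_per_active=int(config["decoys_per_active"]),
        universe_depth=int(config.get("universe_depth", 3)),
    )
    actives, universe = fixtures.make_compound_fixture(spec)
    query = fixtures.reference_query(spec)
    report: dict = {"config": dict(config), "stages": {}}
    report["stages"]["actives"] = len(actives)
    report["stages"]["universe"] = len(universe)

    dec, prov = decoy_mod.generate_decoys(
        actives, universe, decoy_mod.DecoySpec(decoys_per_active=spec.decoys_per_active, seed=seed)
    )
    report["stages"]["decoys"] = len(dec)

    n_screen_dec = int(config.get("screen_decoys", len(dec)))
    screened_decoys = dec[:n_screen_dec]
    for rec in screened_decoys:
        if rec.n_conformers == 0:
            chem.embed_conformers(rec, spec.conformers_per_molecule, fixtures._mol_seed(seed, rec.id))
    library = actives + screened_decoys
    labels = {r.id: "active" for r in actives}
    labels.update({r.id: "decoy" for r in screened_decoys})
    report["stages"]["screened_library"] = len(library)

    pharm = pharm_screen(query, library, mode=mode, label_by_id=labels)
    report["stages"]["pharm_hits"] = len(pharm)
    screens = {"pharm_screen": pharm}

    cap = int(config.get("shape_library_cap", 25))
    if shape_top_n and cap:
        template = fixtures.template_active(spec)
        shape_lib = library[:cap]
        shp = shape_screen(template, shape_lib, top_n=shape_top_n, label_by_id=labels)
        screens["shape_screen"] = shp
        report["stages"]["shape_hits"] = len(shp)

    records_by_id = {r.id: r for r in library}
    merged = merge_hits(screens, records_by_id)
    report["stages"]["merged_hits"] = len(merged)

    survivors, fcounts = apply_filters(
        merged, mw_max=float(config.get("mw_max", 500.0)), rotb_max=int(config.get("rotb_max", 10))
    )
    report["stages"]["filter_counts"] = fcounts
    report["stages"]["filtered_hits"] = len(survivors)

    if config.get("rescore", True):
        # fixture poses: place each surviving hit into the query frame with
        # its own match transform (docking is external in real campaigns)
        poses = []
        for tr in survivors:
            res = match(query, tr.record, mode="partial")
            if res is None:
                continue
            posed = MoleculeRecord(tr.id, _transformed_mol(tr.record, res.rotation, res.translation),
                                   dict(tr.record.descriptors), dict(tr.record.flags))
            poses.append(posed)
        rescored = rescore_poses(poses, query)
        report["stages"]["poses_kept"] = len(rescored)
        pdb_text, _ = fixtures.make_pocket_fixture(spec)
        for tr in rescored:
            tr.contacts = annotate_contacts(tr.record, pdb_text)
        by_id = {tr.id: tr for tr in rescored}
        for tr in survivors:
            src = by_id.get(tr.id)
            if src is not None:
                tr.pose_score = src.pose_score
                tr.c2_analog_matched = src.c2_analog_matched
                tr.contacts = src.contacts

    report["candidates"] = triage_table(survivors).to_dict(orient="records")
    report["stages"]["retrieved_actives"] = sum(
        1 for tr in survivors if labels.get(tr.id) == "active"
    )
    return report


def _transformed_mol(rec: MoleculeRecord, R: np.ndarray, t: np.ndarray):
    from rdkit import Chem as _Chem

    mol = _Chem.Mol(rec.mol)
    conf = mol.GetConformer(0)
    coords = rec.conformer_coords(0) @ np.asarray(R).T + np.asarray(t)
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, xyz.tolist())
    return mol


def triage_table(records: list[TriageRecord]) -> pd.DataFrame:
    rows = []
    for tr in records:
        d = tr.record.descriptors if tr.record is not None else {}
        rows.append(
            {
                "id": tr.id,
                "origin": tr.origin,
                "pharm_score": tr.pharm_score,
                "shape_combo": tr.shape_combo,
                "pose_score": tr.pose_score,
                "c2_analog_matched": tr.c2_analog_matched,
                "n_hbond_contacts": sum(1 for c in tr.contacts if c.kind == "hbond"),
                "n_hydrophobic_contacts": sum(1 for c in tr.contacts if c.kind == "hydrophobic"),
                "key_residues_contacted": ";".join(sorted({c.residue for c in tr.contacts})),
                "MW": d.get("MW"),
                "rotatable_bonds": d.get("rotatable_bonds"),
                **{f"flag_{k}": v for k, v in tr.filter_flags.items()},
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            by=["pose_score", "pharm_score", "shape_combo", "id"],
            ascending=[False, False, False, True],
            na_position="last",
        ).reset_index(drop=True)
    return df


def save_report(report: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=1, default=default))
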