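"""Hit merging, filters, pose re-scoring, contacts, end-to-end pipeline."""

import itertools
import json

import numpy as np
import pytest

from korscreen import chem, fixtures, triage
from korscreen.pharmacophore import match
from korscreen.ranking import RankedScreen, ScreenEntry
from korscreen.triage import (
    TriageRecord,
    annotate_contacts,
    apply_filters,
    merge_hits,
    rescore_poses,
    run_pipeline,
)

from conftest import rotate_record


def screens_from_ids(pharm_ids, shape_ids, records):
    return {
        "pharm_screen": RankedScreen([ScreenEntry(i, 10.0) for i in pharm_ids]),
        "shape_screen": RankedScreen([ScreenEntry(i, 1.0) for i in shape_ids]),
    }, {r.id: r for r in records}


class TestMergeHits:
    def test_union_identity(self, small_fixture):
        actives, _ = small_fixture
        a_ids = [r.id for r in actives[:4]]
        b_ids = [r.id for r in actives[2:6]]
        screens, by_id = screens_from_ids(a_ids, b_ids, actives)
        merged = merge_hits(screens, by_id)
        assert len(merged) == len(set(a_ids) | set(b_ids))
        both = [t for t in merged if t.origin == "both"]
        assert {t.id for t in both} == set(a_ids) & set(b_ids)

    def test_identical_lists_collapse(self, small_fixture):
        actives, _ = small_fixture
        ids = [r.id for r in actives[:3]]
        screens, by_id = screens_from_ids(ids, ids, actives)
        assert len(merge_hits(screens, by_id)) == 3

    def test_disjoint_lists_sum(self, small_fixture):
        actives, _ = small_fixture
        screens, by_id = screens_from_ids(
            [actives[0].id, actives[1].id], [actives[2].id, actives[3].id], actives
        )
        assert len(merge_hits(screens, by_id)) == 4

    def test_best_scores_kept(self, small_fixture):
        actives, _ = small_fixture
        rec = actives[0]
        screens = {
            "pharm_screen": RankedScreen([ScreenEntry(rec.id, 42.0)]),
            "shape_screen": RankedScreen([ScreenEntry(rec.id, 1.7)]),
        }
        merged = merge_hits(screens, {rec.id: rec})
        assert merged[0].pharm_score == 42.0
        assert merged[0].shape_combo == 1.7
        assert merged[0].origin == "both"


class TestApplyFilters:
    def make_tr(self, smiles, mol_id="m"):
        return TriageRecord(id=mol_id, origin="pharm_screen", record=chem.from_smiles(mol_id, smiles))

    def test_boundary_values_pass(self):
        # MW exactly at the cap and RotB exactly 10 must survive
        tr = self.make_tr("O=C1c2ccccc2C(=O)c2cc(O)ccc12")
        survivors, counts = apply_filters([tr], mw_max=tr.record.descriptors["MW"], rotb_max=0)
        assert survivors == [tr]
        assert counts["survivors"] == 1

    def test_mw_above_cap_dropped(self):
        tr = self.make_tr("O=C1c2cc(I)c(I)cc2C(=O)c2cc(O)c(I)cc12")  # > 500 Da
        survivors, counts = apply_filters([tr], mw_max=500.0)
        assert survivors == []
        assert counts["mw_gt_max"] == 1

    def test_charged_and_basic_flagged(self):
        charged = self.make_tr("C[N+](C)(C)C", "q")
        basic = self.make_tr("CCN(CC)CC", "b")
        survivors, counts = apply_filters([charged, basic])
        assert survivors == []
        assert counts["charged"] == 1 and counts["basic"] == 1

    def test_counts_conserved(self, small_fixture):
        actives, universe = small_fixture
        records = [
            TriageRecord(id=r.id, origin="pharm_screen", record=r)
            for r in actives + universe[:10]
        ]
        survivors, counts = apply_filters(records)
        flagged = sum(1 for tr in records if not tr.survives_filters)
        assert counts["input"] == len(survivors) + flagged

    def test_filters_commute(self):
        """Each flag is an independent structural predicate, so any filter
        order yields the same survivor set."""
        mols = [
            self.make_tr("O=C1c2ccccc2C(=O)c2cc(O)ccc12", "ok"),
            self.make_tr("C[N+](C)(C)C", "charged"),
            self.make_tr("CCN(CC)CC", "basic"),
            self.make_tr("O=C1c2cc(I)c(I)cc2C(=O)c2cc(O)c(I)cc12", "heavy"),
            self.make_tr("C" * 30, "floppy"),
        ]
        flags = ["charged", "basic", "mw_gt_max", "rotb_gt_max"]
        apply_filters(mols)  # populate flags once

        def survivors_in_order(order):
            alive = list(mols)
            for f in order:
                alive = [t for t in alive if not t.filter_flags[f]]
            return {t.id for t in alive}

        reference = survivors_in_order(flags)
        for perm in itertools.permutations(flags):
            assert survivors_in_order(perm) == reference


class TestRescorePoses:
    def make_pose(self, rec, query):
        res = match(query, rec, mode="partial")
        assert res is not None
        return chem.MoleculeRecord(
            rec.id,
            triage._transformed_mol(rec, res.rotation, res.translation),
            dict(rec.descriptors),
            dict(rec.flags),
        )

    def test_aligned_pose_kept(self, small_fixture, reduced_query):
        actives, _ = small_fixture
        poses = [self.make_pose(actives[0], reduced_query)]
        kept = rescore_poses(poses, reduced_query)
        assert len(kept) == 1
        assert kept[0].pose_score > 0

    def test_distant_pose_dropped(self, small_fixture, reduced_query):
        actives, _ = small_fixture
        pose = self.make_pose(actives[0], reduced_query)
        far = rotate_record(pose, np.eye(3), np.array([15.0, 0.0, 0.0]))
        assert rescore_poses([far], reduced_query) == []

    def test_c2_analog_flag_tracks_residual(self, small_fixture, full_query):
        actives, _ = small_fixture
        pose = self.make_pose(actives[0], full_query)
        kept = rescore_poses([pose], full_query, c2_label="C2-HBA")
        assert len(kept) == 1
        res = match(full_query, pose, mode="partial", fixed_frame=True)
        assert kept[0].c2_analog_matched == ("C2-HBA" in res.assignment)

    def test_c2_flag_none_when_label_absent(self, small_fixture, reduced_query):
        actives, _ = small_fixture
        pose = self.make_pose(actives[0], reduced_query)
        kept = rescore_poses([pose], reduced_query, c2_label="C2-HBA")
        assert kept[0].c2_analog_matched is None


class TestContacts:
    def test_reported_distance_is_atom_pair_distance(self):
        pdb_text, lig = fixtures.make_pocket_fixture()
        coords = lig.conformer_coords(0)
        atoms = triage._parse_receptor(pdb_text)
        by_res = {}
        for label, name, element, xyz in atoms:
            by_res.setdefault(label, {})[name] = xyz
        for c in annotate_contacts(lig, pdb_text):
            recomputed = float(np.linalg.norm(coords[c.ligand_atom] - by_res[c.residue][c.receptor_atom]))
            assert c.distance == pytest.approx(recomputed, abs=1e-9)

    def test_whitelist_restricts_residues(self):
        pdb_text, lig = fixtures.make_pocket_fixture()
        only_y312 = annotate_contacts(lig, pdb_text, residue_whitelist=("Y312",))
        assert {c.residue for c in only_y312} <= {"Y312"}

    def test_bad_pdb_raises(self, tmp_path):
        _, lig = fixtures.make_pocket_fixture()
        with pytest.raises(IOError):
            annotate_contacts(lig, tmp_path / "missing.pdb")


PIPELINE_CONFIG = {
    "seed": 11,
    "n_actives": 5,
    "decoys_per_active": 4,
    "screen_decoys": 8,
    "shape_library_cap": 6,
    "universe_depth": 2,
}


@pytest.fixture(scope="module")
def report():
    return run_pipeline(dict(PIPELINE_CONFIG))


class TestRunPipeline:
    CONFIG = PIPELINE_CONFIG

    def test_stage_counts_match_construction(self, report):
        st = report["stages"]
        assert st["actives"] == 5
        assert st["decoys"] == 20
        assert st["screened_library"] == 5 + 8
        assert st["retrieved_actives"] == 5  # fixtures built to match the query

    def test_counts_conserved_through_filters(self, report):
        fc = report["stages"]["filter_counts"]
        assert fc["input"] == fc["survivors"] + fc["charged"] + fc["basic"] + fc[
            "mw_gt_max"
        ] + fc["rotb_gt_max"]

    def test_rerun_is_deterministic(self, report):
        again = run_pipeline(dict(self.CONFIG))
        assert json.dumps(report, sort_keys=True, default=str) == json.dumps(
            again, sort_keys=True, default=str
        )

    def test_missing_config_key_named(self):
        with pytest.raises(ValueError, match="decoys_per_active"):
            run_pipeline({"seed": 1, "n_actives": 3})

    def test_zero_shape_top_n_rejected(self):
        bad = dict(self.CONFIG, shape_top_n=0)
        with pytest.raises(ValueError):
            run_pipeline(bad)
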