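"""Pharmacophore query editing, matching, scoring and screening."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from korscreen import chem, fixtures, pharmacophore as ph
from korscreen.pharmacophore import (
    ExclusionVolume,
    PharmacophoreQuery,
    QueryFeature,
    kabsch,
    match,
    query_from_features,
    screen,
)

from conftest import rotate_record


def self_query(rec, max_features=None, radius=1.5):
    """Query built from a molecule's own perceived features."""
    feats = chem.perceive_features(rec, 0)
    if max_features:
        feats = feats[:max_features]
    return query_from_features(
        feats, [(i, f"f{i}") for i in range(len(feats))], radius=radius
    )


def brute_force_best_score(query, rec, mode="partial"):
    """Exhaustive assignment search using scipy's independent superposition.

    Enumerates every subset of query features and every injective, kind-
    compatible assignment; superposes with Rotation.align_vectors; applies
    the same acceptance rule (all residuals inside tolerance, no exclusion
    clash) and returns the best score, or None.
    """
    feats = chem.perceive_features(rec, 0)
    coords = rec.conformer_coords(0)
    n = len(query.features)
    required = set(query.required_labels) if query.required_labels else (
        set(query.labels) if mode == "full" else set()
    )
    best = None
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            labels = {query.features[i].label for i in subset}
            if not required <= labels:
                continue
            pools = [
                [j for j, lf in enumerate(feats) if lf.kind == query.features[i].kind]
                for i in subset
            ]
            for lig in itertools.product(*pools):
                if len(set(lig)) != len(lig):
                    continue
                q = np.array([query.features[i].center for i in subset])
                p = np.array([feats[j].center for j in lig])
                if size >= 3:
                    rot, _ = Rotation.align_vectors(q - q.mean(0), p - p.mean(0))
                    R = rot.as_matrix()
                    t = q.mean(0) - R @ p.mean(0)
                elif size == 2:
                    R, t = ph._two_point_transform(p, q)
                else:
                    R, t = np.eye(3), q[0] - p[0]
                placed = p @ R.T + t
                d = np.linalg.norm(placed - q, axis=1)
                radii = np.array([query.features[i].radius for i in subset])
                if np.any(d > radii):
                    continue
                moved = coords @ R.T + t
                if any(
                    np.any(np.linalg.norm(moved - np.asarray(x.center), axis=1) < x.radius)
                    for x in query.exclusion_volumes
                ):
                    continue
                s = 9.0 * size + float(np.sum(1 - d / radii))
                if best is None or s > best:
                    best = s
    return best


class TestQueryEditing:
    def test_drop_feature(self, full_query):
        assert len(full_query.features) == 6
        reduced = full_query.drop_feature("C2-HBA")
        assert len(reduced.features) == 5
        assert "C2-HBA" not in reduced.labels
        assert len(reduced.exclusion_volumes) == len(full_query.exclusion_volumes)

    def test_drop_then_re_add_restores_feature_set(self, full_query):
        feat = full_query.feature("C2-HBA")
        again = full_query.drop_feature("C2-HBA").add_feature(feat)
        assert set(again.features) == set(full_query.features)

    def test_drop_required_label_unrequires_it(self):
        q = PharmacophoreQuery(
            [QueryFeature("HBA", (0, 0, 0), label="a"), QueryFeature("HY", (3, 0, 0), label="b")],
            required_labels={"a", "b"},
        )
        assert "a" not in q.drop_feature("a").required_labels

    def test_unknown_label_raises(self, full_query):
        with pytest.raises(KeyError):
            full_query.drop_feature("nope")

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            PharmacophoreQuery([])

    def test_round_trip_json_yaml(self, full_query, tmp_path):
        for suffix in (".json", ".yaml"):
            path = tmp_path / f"q{suffix}"
            full_query.save(path)
            back = PharmacophoreQuery.load(path)
            assert back.to_dict() == full_query.to_dict()


class TestMatch:
    def test_self_match_identity(self, template):
        q = self_query(template)
        res = match(q, template, mode="full")
        n = len(q.features)
        assert res is not None and not res.clash
        assert res.n_matched == n
        assert all(d == pytest.approx(0.0, abs=1e-6) for d in res.residuals.values())
        assert res.score == pytest.approx(10.0 * n, abs=1e-6)

    def test_rigid_motion_invariance(self, template):
        q = self_query(template)
        base = match(q, template, mode="full").score
        R = Rotation.from_euler("xyz", [1.2, -0.3, 2.5]).as_matrix()
        moved = rotate_record(template, R, np.array([8.0, -4.0, 3.0]))
        res = match(q, moved, mode="full")
        assert res.score == pytest.approx(base, abs=1e-6)

    def test_exclusion_sphere_on_ligand_atom_causes_clash(self, template):
        q = self_query(template)
        atom0 = tuple(template.conformer_coords(0)[0])
        q_clash = PharmacophoreQuery(
            q.features, [ExclusionVolume(atom0, 1.0)], name="clash"
        )
        res = match(q_clash, template, mode="full")
        assert res is not None and res.clash
        ranked = screen(q_clash, [template], mode="full")
        assert len(ranked) == 0  # clashing matches are rejected in screening

    def test_no_features_returns_none(self):
        rec = chem.from_smiles("methane", "C")
        chem.embed_conformers(rec, 1, 3)
        q = PharmacophoreQuery([QueryFeature("HBA", (0, 0, 0), label="a")])
        assert match(q, rec, mode="partial") is None

    def test_partial_mode_prefers_more_features(self, template):
        # displace one feature so only a subset can be satisfied
        q = self_query(template)
        feats = list(q.features)
        broken = feats[0]
        feats[0] = QueryFeature(broken.kind, (100.0, 0.0, 0.0), broken.radius, broken.label)
        q2 = PharmacophoreQuery(feats, name="broken")
        res = match(q2, template, mode="partial")
        assert res is not None
        assert res.n_matched == len(feats) - 1
        assert broken.label not in res.assignment

    @pytest.mark.parametrize("smiles", ["CC(C)=O", "c1ccc(O)cc1", "CCOC(C)=O"])
    def test_agrees_with_brute_force_small_queries(self, mol_3d, template, smiles):
        """Pruned search equals exhaustive enumeration on <=4-feature queries."""
        probe = mol_3d(smiles)
        q = self_query(template, max_features=4, radius=2.0)
        expected = brute_force_best_score(q, probe, mode="partial")
        res = match(q, probe, mode="partial")
        if expected is None:
            assert res is None
        else:
            assert res is not None
            assert res.score == pytest.approx(expected, abs=1e-6)

    def test_brute_force_agreement_on_self(self, template):
        q = self_query(template, max_features=4)
        res = match(q, template, mode="partial")
        expected = brute_force_best_score(q, template, mode="partial")
        assert res.score == pytest.approx(expected, abs=1e-6)


class TestKabsch:
    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(6, 3))
        R_true = Rotation.from_euler("zyx", [0.4, 1.1, -0.8]).as_matrix()
        t_true = np.array([1.0, -2.0, 0.5])
        R, t = kabsch(P, P @ R_true.T + t_true)
        np.testing.assert_allclose(R, R_true, atol=1e-9)
        np.testing.assert_allclose(t, t_true, atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_rejects_reflection(self):
        rng = np.random.default_rng(6)
        P = rng.normal(size=(5, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirrored target
        R, _ = kabsch(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0)


class TestScreen:
    def test_full_mode_retrieves_constructed_actives(self, small_fixture, reduced_query):
        actives, _ = small_fixture
        ranked = screen(reduced_query, actives, mode="full")
        assert len(ranked) == len(actives)

    def test_partial_mode_score_threshold(self, small_fixture, reduced_query):
        actives, universe = small_fixture
        lib = actives + [u for u in universe[:4]]
        for rec in lib:
            if rec.n_conformers == 0:
                chem.embed_conformers(rec, 1, 99)
        ranked = screen(reduced_query, lib, mode="partial")
        positive = [e for e in ranked if e.score > 0]
        for e in positive:
            assert e.extras["n_matched"] >= 1
        for e in ranked:
            if e.score == 0:
                assert e.extras["n_matched"] == 0

    def test_ordering_and_tie_break(self):
        from korscreen.ranking import RankedScreen, ScreenEntry

        ranked = RankedScreen(
            [ScreenEntry("b", 1.0), ScreenEntry("a", 1.0), ScreenEntry("c", 2.0)]
        )
        assert [e.id for e in ranked] == ["c", "a", "b"]

    def test_empty_library_rejected(self, reduced_query):
        with pytest.raises(ValueError):
            screen(reduced_query, [], mode="full")


class TestMonotonicity:
    def test_exclusion_volume_never_increases_hits(self, small_fixture, reduced_query):
        actives, _ = small_fixture
        baseline = len(screen(reduced_query, actives, mode="full"))
        centroid = actives[0].conformer_coords(0).mean(axis=0)
        stricter = PharmacophoreQuery(
            reduced_query.features,
            [*reduced_query.exclusion_volumes, ExclusionVolume(tuple(centroid), 1.5)],
            reduced_query.required_labels,
            name="stricter",
        )
        assert len(screen(stricter, actives, mode="full")) <= baseline

    def test_dropping_feature_never_decreases_hits(self, small_fixture, full_query):
        actives, _ = small_fixture
        n_full = len(screen(full_query, actives, mode="full"))
        reduced = full_query.drop_feature("C2-HBA")
        assert len(screen(reduced, actives, mode="full")) >= n_full
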