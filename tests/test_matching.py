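"""Partial-match fitting: superposition, enumeration, screening."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pharmscreen.features import FeatureSet, PerceivedFeature
from pharmscreen.matching import (
    MatchParams,
    PharmacophoreScreener,
    best_match,
    enumerate_correspondences,
    screen_library,
    superpose,
)
from pharmscreen.model import expr_satisfied
from pharmscreen.synthetic import GeneratorParams, synth_active


def exact_feature_set(model, drop=(), kinds_for=None):
    """Feature set placed exactly at the model centers."""
    kinds_for = kinds_for or {
        "F1": {"Aro"}, "F2": {"Hyd"}, "F3": {"Aro"},
        "F4": {"Acc"}, "F5": {"ML", "Don"},
    }
    feats = [
        PerceivedFeature(frozenset(kinds_for[f.id]), f.center.copy())
        for f in model.features if f.id not in drop
    ]
    return FeatureSet("exact", features=feats)


def brute_force_correspondences(fs, model, params):
    """Independent oracle: exhaustive enumeration over injective maps."""
    min_match = params.min_match if params.min_match is not None else model.min_match
    n = model.n_features
    ess = {i for i, f in enumerate(model.features) if f.essential}
    centers = model.centers()
    radii = [f.radius for f in model.features]
    pts = fs.positions()
    results = []
    for size in range(min_match, n + 1):
        for model_subset in itertools.combinations(range(n), size):
            if not ess <= set(model_subset):
                continue
            for perm in itertools.permutations(range(len(fs)), size):
                ok = True
                for (mi, pi), (mj, pj) in itertools.combinations(zip(model_subset, perm), 2):
                    dm = np.linalg.norm(centers[mi] - centers[mj])
                    dp = np.linalg.norm(pts[pi] - pts[pj])
                    if abs(dp - dm) > params.radius_scale * (radii[mi] + radii[mj]) + params.pair_slack:
                        ok = False
                        break
                if ok and all(
                    expr_satisfied(model.features[mi].expr, fs.features[pi].kinds)
                    for mi, pi in zip(model_subset, perm)
                ):
                    ids = [model.features[mi].id for mi in model_subset]
                    results.append(dict(zip(ids, perm)))
    return results


class TestSuperpose:
    def test_coincident_points_identity(self, model):
        pts = model.centers()
        rot, t, residuals, rmsd = superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0, atol=1e-9)
        assert rmsd == pytest.approx(0, abs=1e-10)

    def test_recovers_exact_rigid_motion(self, model):
        pts = model.centers()
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([1.0, 2.0, 3.0])
        rot, t, residuals, rmsd = superpose(pts, moved)
        assert rmsd == pytest.approx(0, abs=1e-8)
        np.testing.assert_allclose(moved @ rot.T + t, pts, atol=1e-8)

    def test_rotation_is_always_proper(self):
        # a mirrored point set must not be fixed by an improper rotation
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(5, 3))
        mirrored = pts * np.array([-1, 1, 1])
        rot, _, _, rmsd = superpose(pts, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.01

    @pytest.mark.parametrize("n_pairs", [4, 6])
    def test_noisy_rmsd_matches_numeric_minimization_oracle(self, n_pairs):
        """Closed-form result vs direct minimization over rotation vectors."""
        rng = np.random.default_rng(7)
        m = rng.normal(size=(n_pairs, 3)) * 3
        p = m + rng.normal(scale=0.3, size=(n_pairs, 3))
        _, _, _, rmsd = superpose(m, p)

        def cost(x):
            rot = Rotation.from_rotvec(x[:3]).as_matrix()
            aligned = p @ rot.T + x[3:]
            return np.sum((aligned - m) ** 2)

        best = min(
            minimize(cost, np.concatenate([rv, tv]), method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000}).fun
            for rv in [np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 2.0, 1.0])]
            for tv in [np.zeros(3), m.mean(0) - p.mean(0)]
        )
        assert rmsd == pytest.approx(np.sqrt(best / n_pairs), abs=1e-6)

    def test_single_pair_translation_only(self):
        rot, t, residuals, rmsd = superpose([[1, 2, 3]], [[4, 4, 4]])
        np.testing.assert_allclose(rot, np.eye(3))
        assert rmsd == pytest.approx(0, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((0, 3)), np.zeros((0, 3)))


class TestEnumeration:
    def test_exact_set_has_one_maximal_correspondence(self, model):
        fs = exact_feature_set(model)
        corrs = enumerate_correspondences(fs, model, MatchParams())
        assert corrs[0] == {"F1": 0, "F2": 1, "F3": 2, "F4": 3, "F5": 4}
        assert len(corrs[0]) == 5  # maximal first

    def test_empty_set_yields_nothing(self, model):
        assert enumerate_correspondences(FeatureSet("empty"), model) == []

    def test_missing_essential_compatible_feature_yields_nothing(self, model):
        # no perceived feature can satisfy F5 (no ML anywhere)
        fs = exact_feature_set(model, kinds_for={
            "F1": {"Aro"}, "F2": {"Hyd"}, "F3": {"Aro"}, "F4": {"Acc"}, "F5": {"Acc"},
        })
        assert enumerate_correspondences(fs, model) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_on_random_instances(self, model, seed):
        """Oracle equivalence on instances with up to 8 perceived features."""
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 9)
        kinds_pool = [{"Aro"}, {"Hyd"}, {"Acc"}, {"Don"}, {"ML", "Acc"}, {"Aro", "Hyd"}]
        feats = [
            PerceivedFeature(
                frozenset(kinds_pool[rng.integers(len(kinds_pool))]),
                rng.uniform(-5, 5, 3),
            )
            for _ in range(n)
        ]
        fs = FeatureSet(f"rand{seed}", features=feats)
        params = MatchParams()
        got = enumerate_correspondences(fs, model, params)
        expected = brute_force_correspondences(fs, model, params)
        key = lambda c: sorted(c.items())
        assert sorted(map(key, got)) == sorted(map(key, expected))


class TestBestMatch:
    def test_exact_set_scores_five_of_five(self, model):
        res = best_match(exact_feature_set(model), model)
        assert res.fitting == "5/5"
        assert res.rmsd == pytest.approx(0, abs=1e-8)

    def test_dropping_nonessential_scores_four_of_five(self, model):
        res = best_match(exact_feature_set(model, drop={"F4"}), model)
        assert res.fitting == "4/5"

    @pytest.mark.parametrize("essential", ["F1", "F2", "F3", "F5"])
    def test_dropping_any_essential_never_matches(self, model, essential):
        assert best_match(exact_feature_set(model, drop={essential}), model) is None

    def test_invariant_under_rigid_motion(self, model):
        rng = np.random.default_rng(3)
        params = GeneratorParams(jitter_sd=0.15, dropout_prob=0.0, seed=3)
        for _ in range(10):
            fs = synth_active(model, params, rng)
            res = best_match(fs, model)
            rot = Rotation.random(random_state=rng).as_matrix()
            moved = fs.transformed(rot, rng.uniform(-20, 20, 3))
            res2 = best_match(moved, model)
            assert (res is None) == (res2 is None)
            if res is not None:
                assert res.n_matched == res2.n_matched
                assert res.rmsd == pytest.approx(res2.rmsd, abs=1e-6)

    def test_shrinking_radii_never_creates_a_match(self, model):
        rng = np.random.default_rng(9)
        params = GeneratorParams(jitter_sd=0.4, dropout_prob=0.2, seed=9)
        scales = [1.0, 0.8, 0.6, 0.4]
        for _ in range(20):
            fs = synth_active(model, params, rng)
            matched = [
                best_match(fs, model, MatchParams(radius_scale=s)) is not None
                for s in scales
            ]
            # once lost at some scale, never regained at a smaller one
            assert matched == sorted(matched, reverse=True)

    def test_accepted_residuals_within_scaled_radii(self, model):
        rng = np.random.default_rng(21)
        params = GeneratorParams(jitter_sd=0.25, dropout_prob=0.3, seed=21)
        for _ in range(20):
            fs = synth_active(model, params, rng)
            res = best_match(fs, model)
            if res is None:
                continue
            radii = np.array([model.feature(fid).radius for fid in res.correspondence])
            assert np.all(res.residuals <= radii + 1e-9)

    def test_best_conformer_wins(self, model):
        bad = FeatureSet("m", conformer=0, features=[
            PerceivedFeature(f.kinds, f.position + 10) for f in exact_feature_set(model).features
        ])
        good = exact_feature_set(model)
        good.conformer = 1
        res = best_match([bad, good], model)
        assert res.conformer == 1 and res.fitting == "5/5"


class TestScreenLibrary:
    def test_actives_hit_and_decoys_miss(self, model):
        from pharmscreen.synthetic import synth_decoy

        rng = np.random.default_rng(4)
        params = GeneratorParams(jitter_sd=0.0, dropout_prob=0.0, seed=4)
        lib = [synth_active(model, params, rng, f"a{i}") for i in range(3)]
        lib += [synth_decoy(model, params, rng, f"d{i}", mode="type_scramble") for i in range(2)]
        table = screen_library(lib, model)
        assert (table["hit"] == 1).sum() == 3
        assert (table["hit"] == 0).sum() == 2
        # hits sorted first
        assert list(table["hit"])[:3] == [1, 1, 1]

    def test_empty_library(self, model):
        table = screen_library([], model)
        assert len(table) == 0

    def test_unreadable_record_flagged_and_screening_continues(self, model):
        lib = [exact_feature_set(model), None]
        table = screen_library(lib, model)
        assert len(table) == 2
        assert (table["hit"] == "error").sum() == 1
        assert (table["hit"] == 1).sum() == 1

    def test_fixture_drugs_screen_is_recorded(self, model, drugs):
        table = screen_library(drugs, model)
        assert len(table) == 10
        assert set(table["molecule_id"]) == {d.GetProp("_Name") for d in drugs}
        # fitting scores recorded for every non-error row
        assert all(f.endswith("/5") for f in table.loc[table["hit"] != "error", "fitting"])


class TestScreenerEstimator:
    def test_sklearn_contract(self, model):
        from sklearn.base import clone

        s = PharmacophoreScreener(radius_scale=1.0)
        params = s.get_params()
        assert "radius_scale" in params and "pair_slack" in params
        clone(s)  # must be clonable from constructor params

    def test_predict_labels_hits(self, model):
        from pharmscreen.synthetic import make_benchmark

        bench = make_benchmark(model, GeneratorParams(n_actives=10, n_decoys=10, seed=2))
        y = np.array([1 if bench.labels[fs.molecule_id] == "active" else 0
                      for fs in bench.feature_sets])
        s = PharmacophoreScreener().fit()
        acc = s.score(bench.feature_sets, y)
        assert acc >= 0.9
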