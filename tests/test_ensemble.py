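import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agrosdm import (EnsembleCalibration, Learner, WeightReport, assign_folds,
                     binarize, compute_auc, compute_weights, crossvalidate_learners,
                     find_threshold_maxss, fit_ensemble, predict_consensus)
from agrosdm.ensemble import EnsembleCalibration as _EC


def brute_force_auc(pres, absc):
    wins = sum(1.0 if p > a else 0.5 if p == a else 0.0 for p in pres for a in absc)
    return wins / (len(pres) * len(absc))


def brute_force_maxss(pres, absc):
    cand = sorted(set(pres) | set(absc))
    best_t, best_ss = None, -1.0
    for t in cand:
        sens = sum(p >= t for p in pres) / len(pres)
        spec = sum(a < t for a in absc) / len(absc)
        if sens + spec > best_ss + 1e-12:
            best_ss, best_t = sens + spec, t
    return best_t


scores = st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=1, max_size=20)


class TestFoldAssignment:
    def test_balanced_stratified_folds(self):
        y = np.array([1] * 8 + [0] * 8)
        folds = assign_folds(y, k=4, seed=1)
        for f in range(4):
            assert np.sum((folds == f) & (y == 1)) == 2
            assert np.sum((folds == f) & (y == 0)) == 2

    def test_seeded_determinism(self):
        y = np.array([1] * 10 + [0] * 15)
        assert np.array_equal(assign_folds(y, 4, seed=3), assign_folds(y, 4, seed=3))

    def test_pigeonhole_sizes_with_nine_presences(self):
        y = np.array([1] * 9 + [0] * 8)
        folds = assign_folds(y, k=4, seed=2)
        sizes = sorted(np.sum((folds == f) & (y == 1)) for f in range(4))
        assert sizes == [2, 2, 2, 3]

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(np.array([1, 1, 1, 0, 0, 0, 0, 0]), k=4, seed=1)


class TestAuc:
    @pytest.mark.parametrize("pres,absc,expected", [
        ([0.9, 0.8], [0.2, 0.1], 1.0),       # perfect separation
        ([0.5, 0.5], [0.5, 0.5], 0.5),       # all tied
        ([0.8, 0.4], [0.6, 0.2], 0.75),      # 3 wins out of 4 pairs
    ])
    def test_known_values(self, pres, absc, expected):
        assert compute_auc(pres, absc) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(scores, scores)
    def test_matches_pairwise_counting(self, pres, absc):
        assert abs(compute_auc(pres, absc) - brute_force_auc(pres, absc)) < 1e-12

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 15))
            a = rng.uniform(size=rng.integers(2, 15))
            y = np.concatenate([np.ones(len(p)), np.zeros(len(a))])
            sk = roc_auc_score(y, np.concatenate([p, a]))
            assert compute_auc(p, a) == pytest.approx(sk, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([], [0.1])


def constant_learner(value):
    class Const:
        classes_ = np.array([0, 1])
        def fit(self, X, y):
            return self
        def predict_proba(self, X):
            return np.column_stack([np.full(len(X), 1 - value),
                                    np.full(len(X), value)])
    return Learner(f"const{value}", lambda seed: Const())


def failing_learner():
    class Boom:
        def fit(self, X, y):
            raise RuntimeError("synthetic failure")
    return Learner("boom", lambda seed: Boom())


class TestCrossValidation:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.X = rng.standard_normal((40, 3))
        self.y = np.array([1] * 20 + [0] * 20)
        self.folds = assign_folds(self.y, k=4, seed=0)

    def test_constant_learner_has_no_discrimination(self):
        _, mean, _ = crossvalidate_learners(
            [constant_learner(0.5), constant_learner(0.7)], self.X, self.y, self.folds)
        assert mean["const0.5"] == pytest.approx(0.5)
        assert mean["const0.7"] == pytest.approx(0.5)

    def test_identical_learners_identical_auc_vectors(self):
        from agrosdm.learners import NicheCentroidScorer
        a = Learner("centroid_a", lambda seed: NicheCentroidScorer())
        b = Learner("centroid_b", lambda seed: NicheCentroidScorer())
        auc, _, _ = crossvalidate_learners([a, b], self.X, self.y, self.folds, seed=9)
        np.testing.assert_allclose(auc.loc["centroid_a"].to_numpy(),
                                   auc.loc["centroid_b"].to_numpy())

    def test_failing_learner_scored_half_and_logged(self):
        _, mean, failures = crossvalidate_learners(
            [failing_learner(), constant_learner(0.5)], self.X, self.y, self.folds)
        assert mean["boom"] == 0.5
        assert failures and failures[0]["learner"] == "boom"

    def test_oracle_learner_recovers_separable_signal(self, stack):
        """A learner scoring by the true niche response reaches high CV AUC."""
        from agrosdm import make_virtual_species

        class NicheOracle:
            classes_ = np.array([0, 1])
            def __init__(self, niche):
                self.niche = niche
            def fit(self, X, y):
                return self
            def predict_proba(self, X):
                p = np.ones(len(X))
                for j, (mu, sigma) in enumerate(self.niche):
                    p *= np.exp(-0.5 * ((X[:, j] - mu) / sigma) ** 2)
                return np.column_stack([1 - p, p])

        from agrosdm import true_suitability
        aucs = []
        for seed in range(10):
            sp = make_virtual_species(stack, ["bio08", "bio13"], seed=seed,
                                      prevalence_target=0.1)
            # separable dataset: presences from well-inside the niche,
            # absences from well outside it
            s = true_suitability(sp, stack)
            rng = np.random.default_rng(seed)
            hi = np.flatnonzero((s >= 0.6) & stack.mask)
            lo = np.flatnonzero((s <= 0.3) & stack.mask)
            cells = np.concatenate([
                rng.choice(hi, size=min(80, len(hi)), replace=False),
                rng.choice(lo, size=min(160, len(lo)), replace=False)])
            y = np.concatenate([np.ones(min(80, len(hi)), dtype=int),
                                np.zeros(min(160, len(lo)), dtype=int)])
            r, c = np.unravel_index(cells, stack.grid.shape)
            X = stack.values_at(r, c, ["bio08", "bio13"])
            niche = [sp.niche["bio08"], sp.niche["bio13"]]
            folds = assign_folds(y, 4, seed=seed)
            _, mean, _ = crossvalidate_learners(
                [Learner("oracle", lambda s: NicheOracle(niche)),
                 constant_learner(0.5)], X, y, folds)
            aucs.append(mean["oracle"])
        assert np.median(aucs) > 0.9


class TestWeights:
    def test_hand_worked_three_learner_case(self):
        w = compute_weights({"a": 0.9, "b": 0.8, "c": 0.7})
        assert w.raw["a"] == pytest.approx(0.9 / 2.4)
        assert w.raw["b"] == pytest.approx(0.8 / 2.4)
        assert w.raw["c"] == pytest.approx(0.7 / 2.4)
        assert set(w.selected) == {"a", "b", "c"}
        for k in w.final:
            assert w.final[k] == pytest.approx(w.raw[k])

    def test_weak_learner_dropped_and_weights_renormalised(self):
        aucs = {f"good{i}": 0.95 for i in range(10)}
        aucs["weak"] = 0.40
        w = compute_weights(aucs, weight_cutoff=0.05)
        assert "weak" not in w.selected
        assert len(w.selected) == 10
        for k in w.selected:
            assert w.final[k] == pytest.approx(0.1)

    def test_single_learner_gets_unit_weight(self):
        w = compute_weights({"only": 0.8}, weight_cutoff=0.05)
        assert w.final == {"only": 1.0}

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.3, 1.0), min_size=1, max_size=12))
    def test_weight_sums_are_one(self, aucs):
        w = compute_weights({f"l{i}": a for i, a in enumerate(aucs)})
        assert sum(w.raw.values()) == pytest.approx(1.0)
        assert sum(w.final.values()) == pytest.approx(1.0)

    def test_empty_selection_is_error(self):
        with pytest.raises(ValueError, match="cutoff"):
            compute_weights({f"l{i}": 0.5 for i in range(30)}, weight_cutoff=0.05)


class TestThreshold:
    @pytest.mark.parametrize("pres,absc,expected", [
        ([0.9, 0.8], [0.2, 0.1], 0.8),
        ([0.8, 0.4], [0.6, 0.2], 0.4),   # tie between 0.4 and 0.8 -> smallest
    ])
    def test_known_values(self, pres, absc, expected):
        assert find_threshold_maxss(pres, absc) == expected

    def test_separated_data_reaches_perfect_sum(self):
        t = find_threshold_maxss([0.7, 0.9], [0.1, 0.3])
        sens = np.mean(np.array([0.7, 0.9]) >= t)
        spec = np.mean(np.array([0.1, 0.3]) < t)
        assert sens + spec == 2.0

    @settings(max_examples=200, deadline=None)
    @given(scores, scores)
    def test_matches_exhaustive_search(self, pres, absc):
        assert find_threshold_maxss(pres, absc) == brute_force_maxss(pres, absc)


class TestConsensus:
    def make_calib(self, weights, values):
        models = {name: _stub(v) for (name, v) in values.items()}
        return _EC(predictor_names=["a"],
                   auc_table=pd.DataFrame(), mean_auc=pd.Series(dtype=float),
                   weights=WeightReport(raw=weights, selected=tuple(weights),
                                        final=weights),
                   threshold=0.5, models=models)

    def test_weighted_average_arithmetic(self):
        calib = self.make_calib({"hot": 0.6, "cold": 0.4}, {"hot": 1.0, "cold": 0.0})
        assert calib.predict_rows(np.zeros((3, 1))) == pytest.approx([0.6] * 3)

    def test_single_learner_identity_and_convexity(self):
        calib = self.make_calib({"only": 1.0}, {"only": 0.37})
        assert calib.predict_rows(np.zeros((2, 1))) == pytest.approx([0.37, 0.37])
        calib = self.make_calib({"a": 0.5, "b": 0.5}, {"a": 0.2, "b": 0.9})
        out = calib.predict_rows(np.zeros((5, 1)))
        assert np.all(out >= 0.2) and np.all(out <= 0.9)

    def test_masked_cells_stay_masked(self, training_set, stack):
        calib = fit_ensemble(training_set, stack, ["bio02", "bio08", "bio13"],
                             learners=None, seed=17)
        suit = predict_consensus(calib, stack)
        assert np.all(np.isnan(suit[~stack.mask]))
        assert np.nanmin(suit) >= 0 and np.nanmax(suit) <= 1
        assert 0 < calib.threshold < 1


def _stub(value):
    class Stub:
        classes_ = np.array([0, 1])
        def predict_proba(self, X):
            return np.column_stack([np.full(len(X), 1 - value),
                                    np.full(len(X), value)])
    return Stub()


class TestBinarize:
    def test_boundary_is_presence(self):
        out = binarize(np.array([[0.5, 0.49, np.nan]]), 0.5)
        assert out[0, 0] == 1.0 and out[0, 1] == 0.0 and np.isnan(out[0, 2])

    def test_count_matches_direct_scan(self, training_set, stack):
        calib = fit_ensemble(training_set, stack, ["bio02", "bio08"],
                             learners=None, seed=18)
        suit = predict_consensus(calib, stack)
        binary = binarize(suit, calib.threshold)
        assert np.nansum(binary) == np.sum(suit[stack.mask] >= calib.threshold)
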