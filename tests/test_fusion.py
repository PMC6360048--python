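import numpy as np
import pandas as pd
import pytest

from motifeeg.benchmark_features import benchmark_feature_names
from motifeeg.extraction import FeatureTable, feature_group_tags
from motifeeg.fusion import (GroupPrediction, feature_fusion, oaf_fuse,
                             score_fusion, search_weights, simplex_grid)
from motifeeg.graph_features import motif_feature_names
from sklearn.metrics import balanced_accuracy_score


def random_table(names, group, n, rng):
    tags = {c: (group, "x") for c in names}
    return FeatureTable(
        data=pd.DataFrame(rng.standard_normal((n, len(names))),
                          columns=names),
        labels=pd.DataFrame({"valence": np.arange(n) % 2,
                             "arousal": np.arange(n) % 2}),
        groups=tags)


def random_pred(rng, n, group="g", f1=0.8):
    p1 = rng.uniform(0.01, 0.99, size=n)
    return GroupPrediction(group, np.column_stack([1 - p1, p1]), f1)


class TestFeatureFusion:
    def test_benchmark_plus_motif_is_166_columns(self, montage, rng):
        bnames = benchmark_feature_names(montage)
        mnames = motif_feature_names(montage)
        fused = feature_fusion([
            random_table(bnames, "benchmark", 6, rng),
            random_table(mnames, "motif", 6, rng)])
        assert len(fused.feature_names) == 166
        tags = feature_group_tags(montage)
        assert all(n in tags for n in fused.feature_names)

    def test_duplicate_names_rejected(self, rng):
        t = random_table(["a", "b"], "benchmark", 4, rng)
        with pytest.raises(ValueError, match="duplicate"):
            feature_fusion([t, t])

    def test_empty_table_is_identity(self, rng):
        t = random_table(["a", "b"], "benchmark", 4, rng)
        empty = FeatureTable(data=t.data[[]], labels=t.labels, groups={})
        fused = feature_fusion([t, empty])
        pd.testing.assert_frame_equal(fused.data, t.data)

    def test_trial_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            feature_fusion([random_table(["a"], "benchmark", 4, rng),
                            random_table(["b"], "motif", 5, rng)])


class TestScoreFusion:
    def test_equal_weights_equal_f1_reduce_to_mean(self, rng):
        a, b = random_pred(rng, 10, "a"), random_pred(rng, 10, "b")
        fused, _ = score_fusion([a, b], np.array([0.5, 0.5]))
        np.testing.assert_allclose(fused, (a.proba + b.proba) / 2)

    def test_degenerate_weight_selects_single_group(self, rng):
        a = random_pred(rng, 12, "a", f1=0.9)
        b = random_pred(rng, 12, "b", f1=0.2)
        fused, _ = score_fusion([a, b], np.array([1.0, 0.0]))
        np.testing.assert_allclose(fused, a.proba)

    def test_fused_probabilities_sum_to_one(self, rng):
        # algebraic self-normalization for arbitrary valid weights and F1
        for _ in range(25):
            n_groups = rng.integers(2, 5)
            preds = [random_pred(rng, 7, f"g{i}",
                                 f1=float(rng.uniform(0.1, 1.0)))
                     for i in range(n_groups)]
            alphas = rng.dirichlet(np.ones(n_groups))
            fused, dec = score_fusion(preds, alphas)
            np.testing.assert_allclose(fused.sum(axis=1), 1.0)
            assert set(dec) <= {0, 1}

    def test_single_group_identity_regardless_of_f1(self, rng):
        a = random_pred(rng, 9, "a", f1=0.123)
        fused, _ = score_fusion([a], np.array([1.0]))
        np.testing.assert_allclose(fused, a.proba)

    def test_zero_f1_rejected(self, rng):
        a = random_pred(rng, 5, "a", f1=0.0)
        with pytest.raises(ValueError, match="zero"):
            score_fusion([a], np.array([1.0]))


class TestSearchWeights:
    def test_grid_size(self):
        assert len(list(simplex_grid(2, 0.5))) == 3
        grid = list(simplex_grid(3, 0.5))
        assert len(grid) == 6  # compositions of 2 into 3 parts

    def test_predictive_group_gets_full_weight(self, rng):
        y = np.arange(40) % 2
        # moderately confident but always correct vs confidently random:
        # blending in the noise group flips decisions, so (almost) all
        # weight must land on the predictive group
        p_good = np.where(y == 1, 0.7, 0.3)
        good = GroupPrediction(
            "good", np.column_stack([1 - p_good, p_good]), 0.8)
        p_noise = rng.choice([0.01, 0.99], size=40)
        noise = GroupPrediction(
            "noise", np.column_stack([1 - p_noise, p_noise]), 0.8)
        w = search_weights([good, noise], y, step=0.1)
        assert w[0] >= 0.8

    def test_identical_groups_tie_break_uniform(self, rng):
        y = np.arange(20) % 2
        p = random_pred(rng, 20, "a", f1=0.7)
        q = GroupPrediction("b", p.proba.copy(), 0.7)
        w = search_weights([p, q], y, step=0.1)
        np.testing.assert_allclose(w, [0.5, 0.5])


class TestOaf:
    def _stage1(self, y, informative, rng, noise=0.05):
        """Stage-1 probabilities: informative tracks y, else pure noise."""
        if informative:
            p1 = np.clip(y + noise * rng.standard_normal(len(y)), 0.01, 0.99)
        else:
            p1 = rng.uniform(0.01, 0.99, len(y))
        return [GroupPrediction("g", np.column_stack([1 - p1, p1]), 0.8)]

    def test_perfect_stage1_is_preserved(self, rng):
        y = np.arange(60) % 2
        tr, te = np.arange(0, 40), np.arange(40, 60)
        preds = {
            "valence": self._stage1(y, True, rng),
            "arousal": self._stage1(y, True, rng),
        }
        split = lambda ps, idx: {d: [GroupPrediction(p.group_id,
                                                     p.proba[idx],
                                                     p.f1_train)
                                     for p in v] for d, v in ps.items()}
        out = oaf_fuse(split(preds, tr), split(preds, te),
                       {"valence": y[tr], "arousal": y[tr]})
        assert balanced_accuracy_score(y[te], out["valence"]) >= 0.95

    def test_noise_stage1_is_chance(self, rng):
        y = np.arange(100) % 2
        tr, te = np.arange(0, 70), np.arange(70, 100)
        mk = lambda: {
            "valence": self._stage1(y, False, rng),
            "arousal": self._stage1(y, False, rng)}
        split = lambda ps, idx: {d: [GroupPrediction(p.group_id,
                                                     p.proba[idx],
                                                     p.f1_train)
                                     for p in v] for d, v in ps.items()}
        preds = mk()
        out = oaf_fuse(split(preds, tr), split(preds, te),
                       {"valence": y[tr], "arousal": y[tr]})
        assert abs(balanced_accuracy_score(y[te], out["valence"]) - 0.5) \
            < 0.25

    def test_cross_dimension_information_flows(self, rng):
        # correlated labels, arousal-only informative stage-1 inputs:
        # the stage-2 valence model can exploit the arousal probabilities
        y = rng.permutation(np.arange(120) % 2)
        tr, te = np.arange(0, 90), np.arange(90, 120)
        preds = {
            "valence": self._stage1(y, False, rng),
            "arousal": self._stage1(y, True, rng),
        }
        split = lambda ps, idx: {d: [GroupPrediction(p.group_id,
                                                     p.proba[idx],
                                                     p.f1_train)
                                     for p in v] for d, v in ps.items()}
        out = oaf_fuse(split(preds, tr), split(preds, te),
                       {"valence": y[tr], "arousal": y[tr]})
        stage1_val = (preds["valence"][0].proba[te, 1] > 0.5).astype(int)
        oaf_bacc = balanced_accuracy_score(y[te], out["valence"])
        s1_bacc = balanced_accuracy_score(y[te], stage1_val)
        assert oaf_bacc > s1_bacc
        assert oaf_bacc >= 0.9

    def test_missing_dimension_rejected(self, rng):
        y = np.arange(20) % 2
        preds = {"valence": self._stage1(y, True, rng)}
        with pytest.raises(ValueError, match="missing"):
            oaf_fuse(preds, preds, {"valence": y})
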