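"""auROC, permutation inference, and the time-point GLM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fscvda as f
from fscvda.stats import build_design, label_shuffle_test, sign_flip_test

from conftest import make_aligned


def brute_force_auroc(a, b):
    """Exhaustive pairwise oracle: P(b > a) + 0.5 P(b == a)."""
    wins = sum(1.0 if y > x else (0.5 if y == x else 0.0)
               for x in a for y in b)
    return wins / (len(a) * len(b))


class TestAuroc:
    def test_identical_samples_give_half(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert f.auroc(x, x) == pytest.approx(0.5)

    def test_fully_separated_groups_give_one(self):
        assert f.auroc([1, 2, 3], [10, 11, 12]) == 1.0
        assert f.auroc([10, 11, 12], [1, 2, 3]) == 0.0

    def test_tie_handling_small_example(self):
        # pairwise oracle on {1,2,3} vs {2,3,4}: 6 wins + 2 ties of 9 pairs
        assert brute_force_auroc([1, 2, 3], [2, 3, 4]) == pytest.approx(7 / 9)
        assert f.auroc([1, 2, 3], [2, 3, 4]) == pytest.approx(7 / 9)

    @given(a=st.lists(st.integers(0, 5), min_size=1, max_size=12),
           b=st.lists(st.integers(0, 5), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_rank_implementation_equals_brute_force(self, a, b):
        assert f.auroc(a, b) == pytest.approx(brute_force_auroc(a, b),
                                              abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            f.auroc([], [1.0])

    def test_series_and_window_index(self):
        al = make_aligned(n_trials=20, seed=1)
        mask_b = np.arange(20) < 8
        al.data[mask_b] += 10.0          # fully separated everywhere
        roc = f.auroc_series(al, ~mask_b, mask_b)
        np.testing.assert_allclose(roc.auroc, 1.0)
        assert roc.window_index == 1.0
        assert not roc.low_n

    def test_low_n_flagged_but_computed(self):
        al = make_aligned(n_trials=10, seed=2)
        mask_b = np.arange(10) < 1
        roc = f.auroc_series(al, ~mask_b, mask_b)
        assert roc.low_n
        assert np.isfinite(roc.window_index)

    def test_discrimination_index_devaluation_exceeds_baseline(self):
        """SWITCH-vs-expected discriminability rises when satiation plants a
        value difference between the reinforcers."""
        base_idx, dev_idx = [], []
        for seed in range(12):
            cfg = f.ExperimentConfig()
            for kind, sink in (("baseline_A", base_idx),
                               ("devalue_sucrose", dev_idx)):
                sd = f.run_session(cfg, f.ValueState(), kind, seed=seed + 50)
                al = sd.aligned("reward")
                sw = ((al.labels.is_switch == 1)
                      & (al.labels.outcome_identity == "food")).to_numpy()
                ex = ((al.labels.outcome_class == "standard")
                      & (al.labels.outcome_identity == "sucrose")).to_numpy()
                if sw.sum() >= 2 and ex.sum() >= 2:
                    sink.append(f.discrimination_index(al, ex, sw))
        assert np.mean(dev_idx) > np.mean(base_idx)
        assert np.mean(dev_idx) > 0.75


class TestPermutation:
    def test_all_zero_data_nothing_significant(self):
        res = sign_flip_test(np.zeros((8, 40)))
        assert res.flags.sum() == 0

    def test_exhaustive_enumeration_for_small_groups(self):
        series = np.random.default_rng(0).standard_normal((8, 30))
        res = sign_flip_test(series)
        assert res.exhaustive and res.n_perm == 256
        assert res.min_p == pytest.approx(2 / 256)

    def test_exhaustive_pvalue_matches_direct_count(self):
        """p equals the enumerated fraction of flip means at least as large."""
        series = np.array([[1.0], [2.0], [0.5], [1.5]])
        res = sign_flip_test(series)
        import itertools
        obs = abs(series.mean())
        count = sum(abs(np.dot(s, series[:, 0]) / 4) >= obs - 1e-12
                    for s in itertools.product((1, -1), repeat=4))
        assert res.p[0] == pytest.approx(count / 16)

    def test_strong_consistent_effect_hits_resolution_floor(self):
        series = 5.0 + 0.1 * np.random.default_rng(1).standard_normal((8, 10))
        res = sign_flip_test(series, corrected_alpha=0.01)
        np.testing.assert_allclose(res.p, 2 / 256)
        assert res.flags.all()

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            sign_flip_test(np.ones((1, 5)))

    def test_strict_guard_enforces_nperm(self):
        data = np.random.default_rng(2).standard_normal((20, 5))
        labels = np.arange(20) % 2
        with pytest.raises(ValueError, match="n_perm"):
            label_shuffle_test(data, labels, n_perm=500,
                               corrected_alpha=0.001)

    def test_resolve_guard_allows_reduced_nperm(self):
        data = np.random.default_rng(2).standard_normal((20, 5))
        labels = np.arange(20) % 2
        res = label_shuffle_test(data, labels, n_perm=2000,
                                 corrected_alpha=0.001, guard="resolve",
                                 seed=0)
        assert res.min_p == pytest.approx(1 / 2001)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="10 trials"):
            label_shuffle_test(np.ones((6, 3)), np.arange(6) % 2, n_perm=100,
                               corrected_alpha=0.05, guard="resolve")

    def test_rank_statistic_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((24, 8))
        labels = rng.permutation(np.arange(24) % 2)
        p1 = label_shuffle_test(data, labels, stat="auroc", n_perm=300,
                                corrected_alpha=0.05, guard="resolve",
                                seed=11).p
        p2 = label_shuffle_test(np.exp(data), labels, stat="auroc",
                                n_perm=300, corrected_alpha=0.05,
                                guard="resolve", seed=11).p
        np.testing.assert_allclose(p1, p2)

    def test_planted_effect_detected(self):
        """A 3-sigma effect over a third of the window is flagged there."""
        rng = np.random.default_rng(4)
        data = rng.standard_normal((40, 30))
        labels = np.arange(40) % 2
        data[labels == 1, 10:20] += 3.0
        res = label_shuffle_test(data, labels, n_perm=2000,
                                 corrected_alpha=0.001, guard="resolve",
                                 seed=5)
        assert res.flags[10:20].all()
        assert not res.flags[:10].any() and not res.flags[20:].any()


class TestTimepointGLM:
    def test_constant_only_design_recovers_mean_trace(self):
        al = make_aligned(n_trials=25, seed=6)
        res = f.fit_glm_timepoint(al, [])
        np.testing.assert_allclose(res.beta("const"), al.data.mean(axis=0),
                                   atol=1e-10)

    def test_betas_match_statsmodels_ols(self):
        import statsmodels.api as sm
        al = make_aligned(n_trials=30, seed=7)
        res = f.fit_glm_timepoint(al, ["is_more", "is_food"])
        X, names = build_design(al.labels, ["is_more", "is_food"])
        for t_idx in (0, 17, 49):
            fit = sm.OLS(al.data[:, t_idx], X).fit()
            np.testing.assert_allclose(res.animal_params[0, :, t_idx],
                                       fit.params, atol=1e-10)
            np.testing.assert_allclose(res.animal_bse[0, :, t_idx],
                                       fit.bse, atol=1e-10)

    def test_planted_additive_effect_recovered(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(50):
            labels = pd.DataFrame({
                "animal": "r00",
                "is_more": rng.permutation(np.arange(40) < 8).astype(float),
            })
            data = rng.standard_normal((40, 20))
            data[labels.is_more.to_numpy(bool), 5:15] += 2.0
            al = make_aligned(n_trials=40, labels=labels, data=data)
            res = f.fit_glm_timepoint(al, ["is_more"])
            ci = res.conf_int(0.05)[0, res.names.index("is_more"), 10]
            hits += ci[0] <= 2.0 <= ci[1]
        assert hits >= 45  # nominal 95% coverage

    def test_rank_deficient_animal_reported(self):
        labels = pd.DataFrame({"animal": ["a"] * 10 + ["b"] * 10,
                               "is_more": [0.0] * 10 + [0.5] * 5 + [0.0] * 5})
        data = np.random.default_rng(9).standard_normal((20, 6))
        al = make_aligned(n_trials=20, labels=labels, data=data)
        res = f.fit_glm_timepoint(al, ["is_more"])
        assert [s["animal"] for s in res.skipped] == ["a"]
        assert res.animals == ["b"]

    def test_all_animals_rank_deficient_raises(self):
        labels = pd.DataFrame({"animal": "a", "is_more": np.zeros(10)})
        al = make_aligned(n_trials=10, labels=labels)
        with pytest.raises(ValueError, match="full-rank"):
            f.fit_glm_timepoint(al, ["is_more"])

    def test_unknown_regressor_column_rejected(self):
        al = make_aligned(n_trials=10, seed=10)
        with pytest.raises(KeyError):
            f.fit_glm_timepoint(al, ["is_switch"])

    def test_interaction_term_is_product(self):
        labels = pd.DataFrame({"animal": "r00",
                               "is_more": [0, 1, 0, 1, 0, 1, 0, 1, 1, 0],
                               "is_food": [0, 0, 1, 1, 0, 0, 1, 1, 0, 1]})
        X, names = build_design(labels, f.REWARD_DESIGN)
        j = names.index("is_more:is_food")
        np.testing.assert_allclose(
            X[:, j], labels.is_more.to_numpy() * labels.is_food.to_numpy())

    def test_group_significance_on_consistent_effect(self):
        rng = np.random.default_rng(12)
        als = []
        for i in range(8):
            labels = pd.DataFrame({
                "animal": f"r{i:02d}",
                "is_more": rng.permutation(np.arange(30) < 6).astype(float),
            })
            data = rng.standard_normal((30, 20))
            data[labels.is_more.to_numpy(bool), 8:12] += 5.0
            als.append(make_aligned(n_trials=30, labels=labels, data=data))
        al = f.AlignedTraces(
            data=np.vstack([a.data for a in als]), time=als[0].time,
            labels=pd.concat([a.labels for a in als], ignore_index=True),
            event="reward")
        res = f.fit_glm_timepoint(al, ["is_more"])
        perm = res.permutation_pvalues(corrected_alpha=0.01)
        assert perm["is_more"].flags[8:12].all()
        assert perm["is_more"].p[:5].min() > 0.05

    def test_summary_and_tidy_frame(self):
        al = make_aligned(n_trials=20, seed=13)
        res = f.fit_glm_timepoint(al, ["is_more"])
        assert "is_more" in res.summary()
        df = res.to_frame()
        assert set(df.regressor) == {"const", "is_more"}
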