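import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spinecomp.stats import (
    SpineTrajectoryDataset,
    bootstrap_exp_decay,
    fit_exp_decay,
    kruskal_dunn_fdr,
    nmse,
    normalise,
    r2w,
    studentised_bootstrap_ci,
    welch_fdr,
)


def make_raw(values_by_spine, pre=(-6.0, -4.0, -2.0), post=(2.0, 4.0)):
    rows = []
    for sid, (pre_vals, post_vals) in values_by_spine.items():
        for t, v in zip(pre, pre_vals):
            rows.append(("e1", sid, 0.0, 1, "single", t, v))
        for t, v in zip(post, post_vals):
            rows.append(("e1", sid, 0.0, 1, "single", t, v))
    return SpineTrajectoryDataset(pd.DataFrame(
        rows, columns=["experiment_id", "spine_id", "position_um",
                       "stimulated", "paradigm", "time_min", "fluorescence"]))


class TestNormalise:
    def test_divides_by_prestim_mean(self):
        ds = normalise(make_raw({0: ((2.0, 2.0, 2.0), (3.0, 2.0))}))
        post = ds.df[ds.df.time_min > 0].sort_values("time_min")
        assert post["size_norm"].tolist() == [1.5, 1.0]

    def test_constant_trace_maps_to_one(self):
        ds = normalise(make_raw({0: ((5.0, 5.0, 5.0), (5.0, 5.0))}))
        assert np.allclose(ds.df["size_norm"], 1.0)

    def test_uneven_baseline(self):
        ds = normalise(make_raw({0: ((1.0, 2.0, 3.0), (4.0, 2.0))}))
        post = ds.df[ds.df.time_min > 0].sort_values("time_min")
        assert post["size_norm"].tolist() == [2.0, 1.0]

    def test_prestim_mean_exactly_one(self):
        rng = np.random.default_rng(0)
        ds = normalise(make_raw({i: (rng.uniform(1, 9, 3), rng.uniform(1, 9, 2))
                                 for i in range(8)}))
        pre = ds.df[ds.df.time_min < 0].groupby("spine_id")["size_norm"].mean()
        assert np.abs(pre - 1.0).max() < 1e-12

    def test_nonpositive_baseline_names_spine(self):
        with pytest.raises(ValueError, match="non-positive"):
            normalise(make_raw({3: ((0.0, 0.0, 0.0), (1.0, 1.0))}))

    def test_wrong_prestim_count_rejected(self):
        ds = make_raw({0: ((2.0, 2.0, 2.0), (3.0, 2.0))})
        with pytest.raises(ValueError, match="pre-stimulation"):
            normalise(ds, n_pre=4)


class TestGoodnessOfFit:
    def test_mean_predictor_attains_exact_minimum(self):
        rng = np.random.default_rng(7)
        obs = [rng.normal(1.2, 0.1, 9) for _ in range(6)]
        pred = np.array([o.mean() for o in obs])
        assert nmse(pred, obs) == 1.0

    def test_nmse_hand_values(self):
        obs = [np.array([0.0, 2.0])]
        assert nmse(np.array([1.0]), obs) == pytest.approx(1.0)
        assert nmse(np.array([0.0]), obs) == pytest.approx(2.0)

    def test_r2w_perfect_and_null_predictors(self):
        obs = [np.array([0.9, 1.1]), np.array([1.8, 2.2]), np.array([1.4, 1.6])]
        means = np.array([o.mean() for o in obs])
        assert r2w(means, obs) == pytest.approx(1.0)
        pooled = np.concatenate(obs).mean()
        assert r2w(np.full(3, pooled), obs) == pytest.approx(0.0)

    def test_r2w_hand_value(self):
        # snapshot means (1, 2), equal variances, swapped prediction -> -3
        obs = [np.array([0.5, 1.5]), np.array([1.5, 2.5])]
        assert r2w(np.array([2.0, 1.0]), obs) == pytest.approx(-3.0)

    def test_degenerate_snapshot_excluded_with_warning(self):
        obs = [np.array([1.0, 1.0]), np.array([0.0, 2.0])]
        with pytest.warns(UserWarning, match="zero-variance"):
            val = nmse(np.array([1.0, 1.0]), obs)
        assert val == pytest.approx(1.0)

    def test_all_degenerate_rejected(self):
        obs = [np.array([1.0, 1.0])]
        with pytest.raises(ValueError, match="zero variance"):
            with pytest.warns(UserWarning):
                nmse(np.array([1.0]), obs)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_to_within_snapshot_reordering(self, seed):
        rng = np.random.default_rng(seed)
        obs = [rng.normal(1.0, 0.2, 5) for _ in range(4)]
        pred = rng.normal(1.0, 0.1, 4)
        shuffled = [rng.permutation(o) for o in obs]
        assert nmse(pred, obs) == pytest.approx(nmse(pred, shuffled))
        assert r2w(pred, obs) == pytest.approx(r2w(pred, shuffled))

    def test_invariant_to_snapshot_reordering(self):
        rng = np.random.default_rng(1)
        obs = [rng.normal(1.0, 0.2, 5) for _ in range(4)]
        pred = rng.normal(1.0, 0.1, 4)
        order = [2, 0, 3, 1]
        assert nmse(pred[order], [obs[k] for k in order]) == pytest.approx(
            nmse(pred, obs))


class TestWelchFdr:
    def test_identical_groups(self):
        table = welch_fdr({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert table.loc[0, "t"] == 0.0 and table.loc[0, "p_adj"] == 1.0

    def test_single_comparison_is_identity_adjustment(self):
        rng = np.random.default_rng(2)
        g = {"a": rng.normal(0, 1, 10), "b": rng.normal(1, 1, 10)}
        table = welch_fdr(g, comparisons=[("a", "b")])
        assert table.loc[0, "p_adj"] == pytest.approx(table.loc[0, "p_raw"])

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(mu, 1, 12)
                  for k, mu in zip("abcd", [0, 0.2, 1.0, 3.0])}
        table = welch_fdr(groups)
        assert np.all(table["p_adj"] >= table["p_raw"] - 1e-15)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            welch_fdr({"a": [1.0], "b": [1.0, 2.0]})


class TestStudentisedBootstrap:
    def test_constant_sample_zero_width(self):
        with pytest.warns(UserWarning, match="constant"):
            out = studentised_bootstrap_ci([2.0, 2.0, 2.0], seed=0)
        assert out["sem"] == 0.0 and out["ci"][0] == out["ci"][1] == 2.0

    def test_seed_determinism(self):
        x = np.random.default_rng(5).normal(0, 1, 50)
        a = studentised_bootstrap_ci(x, n_boot=500, seed=9)
        b = studentised_bootstrap_ci(x, n_boot=500, seed=9)
        assert a == b

    def test_matches_normal_theory_at_large_n(self):
        x = np.random.default_rng(11).normal(0.0, 1.0, 10_000)
        out = studentised_bootstrap_ci(x, n_boot=2000, seed=1)
        half = (out["ci"][1] - out["ci"][0]) / 2
        assert half == pytest.approx(1.96 / 100, rel=0.10)


class TestExpDecay:
    def test_noiseless_recovery(self):
        t = np.array([2.0, 10.0, 20.0, 30.0, 40.0])
        y = 0.5 * np.exp(-0.1 * t) + 1.2
        f = fit_exp_decay(t, y)
        assert (f.a, f.b, f.c) == pytest.approx((0.5, 0.1, 1.2), abs=1e-4)
        assert f.identifiable

    def test_constant_data_flagged(self):
        f = fit_exp_decay([2.0, 10.0, 20.0], [1.2, 1.2, 1.2])
        assert not f.identifiable and f.c == pytest.approx(1.2)

    def test_b_zero_confound_flagged(self):
        t = np.linspace(2, 40, 8)
        f = fit_exp_decay(t, np.full(8, 1.6) + 1e-9 * t)
        assert f.a + f.c == pytest.approx(1.6, abs=1e-3)
        assert not f.identifiable

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_exp_decay([2.0, 4.0], [1.0, 1.1])


class TestBootstrapExpDecay:
    @staticmethod
    def cohort(n_exp=6, noise=0.0, seed=0):
        t = np.arange(2.0, 41.0, 2.0)
        rng = np.random.default_rng(seed)
        rows = {}
        for k in range(n_exp):
            y = 0.4 * np.exp(-0.05 * t) + 1.15
            rows[f"e{k}"] = y * np.exp(rng.normal(0, noise, t.size))
        return pd.DataFrame(rows, index=t).T

    def test_identical_experiments_zero_iqr(self):
        fit = bootstrap_exp_decay(self.cohort(), n_boot=50, seed=0)
        s = fit.summary().set_index("parameter")
        assert np.allclose(s["iqr_high"] - s["iqr_low"], 0.0, atol=1e-10)
        assert fit.n_failed == 0

    def test_seed_determinism(self):
        a = bootstrap_exp_decay(self.cohort(noise=0.05, seed=3), n_boot=100, seed=4)
        b = bootstrap_exp_decay(self.cohort(noise=0.05, seed=3), n_boot=100, seed=4)
        assert np.array_equal(a.samples, b.samples)

    def test_needs_two_experiments(self):
        with pytest.raises(ValueError, match=">= 2 experiments"):
            bootstrap_exp_decay(self.cohort(n_exp=1), n_boot=10, seed=0)


class TestKruskalDunn:
    def test_identical_groups_omnibus_one(self):
        out = kruskal_dunn_fdr({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert out["omnibus_p"] == pytest.approx(1.0)

    def test_fully_tied_skips_pairwise(self):
        out = kruskal_dunn_fdr({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert out["omnibus_p"] == 1.0 and out["pairwise"] is None

    def test_separated_groups_all_significant(self):
        groups = {"a": np.arange(1, 101), "b": np.arange(101, 201),
                  "c": np.arange(201, 301)}
        out = kruskal_dunn_fdr(groups)
        assert out["omnibus_p"] < 1e-3
        assert out["pairwise"]["significant"].all()
        assert np.all(out["pairwise"]["p_adj"] >= out["pairwise"]["p_raw"] - 1e-15)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 groups"):
            kruskal_dunn_fdr({"a": [1.0, 2.0]})
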