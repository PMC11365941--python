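import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinecomp.layout import (
    SpineLayout,
    classify_edge_middle,
    compute_competition,
    compute_d,
    count_nhat,
    frame_to_layouts,
    layouts_to_frame,
)


def stim_layout(positions, paradigm="three"):
    pos = np.asarray(positions, dtype=float)
    return SpineLayout(pos, np.ones(pos.size, bool), paradigm=paradigm)


class TestSpineLayout:
    def test_rejects_non_finite_positions(self):
        with pytest.raises(ValueError, match="finite"):
            SpineLayout(np.array([0.0, np.inf]), np.array([True, False]),
                        paradigm="single")

    def test_non_sham_requires_stimulated_spine(self):
        with pytest.raises(ValueError, match="stimulated"):
            SpineLayout(np.array([0.0]), np.array([False]), paradigm="three")

    def test_sham_may_have_zero_stimulated(self):
        lay = SpineLayout(np.array([0.0, 1.0]), np.array([False, False]),
                          paradigm="sham")
        assert lay.n_stim == 0

    def test_cluster_span_non_negative(self):
        assert stim_layout([5.0, 2.0, 9.0]).cluster_span == 7.0
        assert stim_layout([3.0], "single").cluster_span == 0.0


class TestProximitySum:
    def test_single_spine_empty_sum(self, single_layout):
        assert compute_d(single_layout, lam=1.0, i=0) == 0.0

    def test_two_spines_unit_distance(self):
        lay = stim_layout([0.0, 1.0])
        assert compute_d(lay, lam=1.0, i=0) == pytest.approx(0.5)

    @pytest.mark.parametrize("lam", [0.5, 1.0, 3.0])
    def test_colocated_spines_give_zero(self, lam):
        lay = stim_layout([2.0, 2.0, 2.0])
        for i in range(3):
            assert compute_d(lay, lam=lam, i=i) == 0.0

    def test_bounded_by_n_minus_one(self):
        lay = stim_layout(np.linspace(0, 500, 8), paradigm="seven")
        for i in range(8):
            assert 0.0 <= compute_d(lay, lam=1.0, i=i) < 7.0

    def test_unstimulated_index_rejected(self):
        lay = SpineLayout(np.array([0.0, 1.0]), np.array([True, False]),
                          paradigm="single")
        with pytest.raises(ValueError, match="not a stimulated"):
            compute_d(lay, lam=1.0, i=1)

    def test_nonpositive_lambda_rejected(self, single_layout):
        with pytest.raises(ValueError, match="lam"):
            compute_d(single_layout, lam=0.0, i=0)


class TestNhatCount:
    def test_needs_two_nearby_sites(self):
        # unstimulated spine 1 um from both stimulation sites -> counted
        lay = SpineLayout(np.array([0.0, 1.0, 2.0]),
                          np.array([True, False, True]), paradigm="three")
        assert count_nhat(lay, radius=2.0) == 1

    def test_single_nearby_site_not_counted(self):
        lay = SpineLayout(np.array([0.0, 1.0, 30.0]),
                          np.array([True, False, True]), paradigm="three")
        assert count_nhat(lay, radius=2.0) == 0

    def test_no_unstimulated_spines(self, three_layout):
        assert count_nhat(three_layout) == 0


class TestCompetitionFactors:
    def test_isolated_spine_gets_everything(self, single_layout):
        comp = compute_competition(single_layout, lam=1.0)
        assert comp.D[0] == 1.0 and comp.n_stim == 1 and comp.n_hat == 0

    def test_colocated_cluster_shares_equally(self):
        comp = compute_competition(stim_layout([0.0, 0.0, 0.0]), lam=2.0)
        assert np.allclose(comp.D, 1.0 / 3.0)

    def test_two_distant_spines(self):
        comp = compute_competition(stim_layout([0.0, 100.0], "three"), lam=1.0)
        assert comp.d == pytest.approx([100 / 101] * 2)
        assert comp.D == pytest.approx([1.990099 / 2] * 2)

    def test_nhat_enters_denominator(self):
        lay = SpineLayout(np.array([0.0, 1.0, 2.0]),
                          np.array([True, False, True]), paradigm="three")
        comp = compute_competition(lay, lam=40.0)
        assert comp.n_hat == 1
        assert np.all(comp.D <= 2.0 / 3.0 + 1e-12)

    def test_nhat_override(self, three_layout):
        comp = compute_competition(three_layout, lam=1.0, n_hat=7)
        assert comp.n_hat == 7
        assert np.all(comp.D <= 3.0 / 10.0 + np.max(comp.d) / 10.0)

    def test_bounds_invariant(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(2, 10)
            lay = stim_layout(np.sort(rng.uniform(0, 50, n)), "seven")
            comp = compute_competition(lay, lam=float(rng.uniform(0.3, 50)))
            assert np.all(comp.D >= 1.0 / n - 1e-12)
            assert np.all(comp.D <= 1.0 - 1e-12) or n == 1

    def test_colocated_share_decreases_with_n(self):
        prev = np.inf
        for n in (2, 3, 5, 9):
            comp = compute_competition(stim_layout([0.0] * n, "seven"), lam=1.0)
            assert comp.D[0] < prev
            prev = comp.D[0]

    def test_distance_decoupling_monotone(self):
        d10 = compute_competition(stim_layout([0.0, 10.0], "three"), lam=1.0).D[0]
        d100 = compute_competition(stim_layout([0.0, 100.0], "three"), lam=1.0).D[0]
        assert d10 < d100 < 1.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.permutations(list(range(5))),
           st.floats(min_value=0.5, max_value=10.0))
    def test_permutation_invariance(self, perm, lam):
        pos = np.array([0.0, 1.3, 2.9, 7.0, 11.5])
        base = compute_competition(stim_layout(pos, "seven"), lam=lam)
        shuf = compute_competition(stim_layout(pos[perm], "seven"), lam=lam)
        assert np.allclose(np.sort(base.D), np.sort(shuf.D))

    def test_no_stimulated_spines_rejected(self):
        lay = SpineLayout(np.array([0.0]), np.array([False]), paradigm="sham")
        with pytest.raises(ValueError, match="no stimulated"):
            compute_competition(lay, lam=1.0)


class TestEdgeMiddle:
    @pytest.mark.parametrize("n,paradigm,expected", [
        (3, "three", ["edge", "middle", "edge"]),
        (7, "seven", ["edge"] * 2 + ["middle"] * 3 + ["edge"] * 2),
        (15, "fifteen", ["edge"] * 4 + ["middle"] * 7 + ["edge"] * 4),
    ])
    def test_published_splits(self, n, paradigm, expected):
        lay = stim_layout(np.arange(n, dtype=float), paradigm)
        assert classify_edge_middle(lay).tolist() == expected

    def test_labels_follow_layout_order(self):
        lay = stim_layout([2.0, 0.0, 1.0], "three")   # unsorted positions
        assert classify_edge_middle(lay).tolist() == ["edge", "edge", "middle"]

    def test_unknown_split_needs_explicit_count(self):
        lay = stim_layout(np.arange(7.0), "seven_distributed")
        with pytest.raises(ValueError, match="edge_per_side"):
            classify_edge_middle(lay)
        assert (classify_edge_middle(lay, edge_per_side=2) == "edge").sum() == 4

    def test_duplicate_positions_tiebreak_deterministic(self):
        pos = np.array([0.0, 0.0, 1.0])
        ref = SpineLayout(pos, np.ones(3, bool), spine_id=np.array([0, 1, 2]),
                          paradigm="three")
        labels = classify_edge_middle(ref)
        assert labels.tolist() == ["edge", "middle", "edge"]


class TestCsvRoundTrip:
    def test_roundtrip_exact(self, tmp_path, three_layout):
        path = tmp_path / "layout.csv"
        layouts = {"e1": three_layout}
        layouts_to_frame(layouts).to_csv(path, index=False)
        import pandas as pd
        back = frame_to_layouts(pd.read_csv(path))["e1"]
        assert np.array_equal(back.position, three_layout.position)
        assert np.array_equal(back.stimulated, three_layout.stimulated)
        assert back.paradigm == three_layout.paradigm

    def test_missing_column_reported(self):
        import pandas as pd
        df = pd.DataFrame({"experiment_id": ["a"], "spine_id": [0],
                           "stimulated": [1], "paradigm": ["single"]})
        with pytest.raises(ValueError, match="position_um"):
            frame_to_layouts(df)
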