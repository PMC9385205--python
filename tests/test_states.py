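"""Seeded non-negative tensor factorization and state statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dynfc as d


def _two_seeds(n_rois, patterns=None):
    if patterns is None:
        membership = np.zeros((2, n_rois))
        membership[0, : n_rois // 2] = 1.0
        membership[1, n_rois // 2:] = 1.0
    else:
        membership = (np.asarray(patterns) > 0).astype(float)
    return d.SeedNetworks(["net1", "net2"], membership)


class TestConcatenate:
    def _tensor(self, n_frames, subject, seed=0):
        rng = np.random.default_rng(seed)
        phases = rng.uniform(-np.pi, np.pi, (4, n_frames))
        ph = d.PhaseSeries(phases, 2.0, list("abcd"), subject_id=subject)
        return d.phase_connectivity_tensor(ph)

    def test_lengths_and_boundaries(self):
        merged, bounds, sids = d.concatenate_tensors(
            [self._tensor(5, "s1", 1), self._tensor(7, "s2", 2)])
        assert merged.n_frames == 12
        assert bounds == [5, 12]
        assert sids == ["s1", "s2"]

    def test_single_tensor_identity(self):
        t1 = self._tensor(6, "solo")
        merged, bounds, _ = d.concatenate_tensors([t1])
        assert np.array_equal(merged.frames, t1.frames)
        assert bounds == [6]

    def test_order_swap_permutes_frames(self):
        a, b = self._tensor(5, "s1", 1), self._tensor(7, "s2", 2)
        m1, _, _ = d.concatenate_tensors([a, b])
        m2, _, _ = d.concatenate_tensors([b, a])
        assert np.array_equal(m2.frames[:, :, :7], m1.frames[:, :, 5:])

    def test_label_mismatch_names_region(self):
        a = self._tensor(5, "s1", 1)
        rng = np.random.default_rng(3)
        ph = d.PhaseSeries(rng.uniform(-3, 3, (4, 5)), 2.0, ["a", "b", "XX", "d"],
                           subject_id="s2")
        with pytest.raises(ValueError, match="XX"):
            d.concatenate_tensors([a, d.phase_connectivity_tensor(ph)])


class TestNNTF:
    def test_planted_rank2_recovery(self):
        truth = d.make_planted_truth(24, 2, 60)
        tensor = d.generate_planted_tensor(truth)
        comps = d.nntf_decompose(tensor, _two_seeds(24, truth.patterns), seed=0)
        assert comps.n_components == 3
        assert comps.diagnostics["final_relative_error"] <= 1e-3
        iu = np.triu_indices(24, 1)
        for l in range(2):
            fitted = d.spatial_pattern(comps, l)[iu]
            best = max(np.corrcoef(fitted, _planted_pattern(truth, m)[iu])[0, 1]
                       for m in range(2))
            assert best >= 0.99

    def test_error_history_non_increasing(self):
        truth = d.make_planted_truth(20, 2, 40, noise_sd=0.1)
        tensor = d.generate_planted_tensor(truth, seed=3)
        comps = d.nntf_decompose(tensor, _two_seeds(20), seed=1)
        errs = np.array(comps.diagnostics["error_history"])
        assert np.all(np.diff(errs) <= 1e-9)

    def test_factors_non_negative(self):
        truth = d.make_planted_truth(20, 2, 40, noise_sd=0.1)
        tensor = d.generate_planted_tensor(truth, seed=5)
        comps = d.nntf_decompose(tensor, _two_seeds(20), seed=2)
        assert comps.spatial_a.min() >= 0
        assert comps.spatial_b.min() >= 0
        assert comps.temporal.min() >= 0

    def test_all_zero_tensor(self):
        tensor = d.ConnectivityTensor(np.zeros((6, 6, 10)), 2.0,
                                      [f"r{i}" for i in range(6)])
        comps = d.nntf_decompose(tensor, _two_seeds(6), seed=0)
        assert np.allclose(comps.temporal, 0)
        assert comps.diagnostics["final_relative_error"] == 0

    def test_determinism(self):
        truth = d.make_planted_truth(16, 2, 30, noise_sd=0.05)
        tensor = d.generate_planted_tensor(truth, seed=9)
        c1 = d.nntf_decompose(tensor, _two_seeds(16), seed=4)
        c2 = d.nntf_decompose(tensor, _two_seeds(16), seed=4)
        assert np.array_equal(c1.temporal, c2.temporal)
        assert np.array_equal(c1.spatial_a, c2.spatial_a)

    def test_negative_tensor_rejected(self):
        truth = d.make_planted_truth(8, 2, 10)
        tensor = d.generate_planted_tensor(truth)
        tensor.frames[0, 1, 0] = -0.5  # sabotage after validation
        with pytest.raises(ValueError, match="non-negative"):
            d.nntf_decompose(tensor, _two_seeds(8), seed=0)


def _planted_pattern(truth, m):
    outer = np.outer(truth.patterns[m], truth.patterns[m])
    np.fill_diagonal(outer, 0.0)
    return outer


class TestSpatialPattern:
    def test_support_and_symmetry(self):
        a = np.zeros((5, 1))
        a[[1, 2], 0] = 1.0
        comps = d.TensorComponents(a, a.copy(), np.ones((3, 1)), ["x"], 0, [3], ["s"], 2.0)
        pattern = d.spatial_pattern(comps, 0)
        assert pattern[1, 2] == 1.0 and pattern[2, 1] == 1.0
        assert np.allclose(pattern, pattern.T)
        assert pattern.sum() == 2.0  # support exactly on the (1,2) pair


class TestSplitLoadings:
    def test_round_trip(self):
        temporal = np.arange(24, dtype=float).reshape(12, 2)
        comps = d.TensorComponents(np.ones((4, 2)), np.ones((4, 2)), temporal,
                                   ["x", "y"], 1, [5, 12], ["s1", "s2"], 2.0)
        per_subject = d.split_loadings(comps)
        assert np.array_equal(np.vstack([per_subject["s1"], per_subject["s2"]]), temporal)
        assert per_subject["s1"].shape == (5, 2)

    def test_boundary_every_point(self):
        temporal = np.ones((3, 1))
        comps = d.TensorComponents(np.ones((2, 1)), np.ones((2, 1)), temporal,
                                   ["x"], 0, [1, 2, 3], ["a", "b", "c"], 2.0)
        out = d.split_loadings(comps)
        assert all(v.shape == (1, 1) for v in out.values())


class TestTimelineAndDwell:
    def test_argmax_winners(self):
        tl = d.state_timeline(np.array([[3.0, 1.0], [1.0, 3.0]]))
        assert list(tl.winners) == [0, 1]

    def test_tie_goes_to_lowest_index(self):
        tl = d.state_timeline(np.ones((4, 3)))
        assert list(tl.winners) == [0, 0, 0, 0]

    def test_planted_block_loadings_recovered(self):
        truth = d.make_planted_truth(12, 3, 30)
        tl = d.state_timeline(truth.loadings.T)
        assert np.array_equal(tl.winners, truth.winner_timeline)

    def test_dwell_run_lengths(self):
        loadings = np.zeros((6, 2))
        winners = [0, 0, 1, 1, 1, 0]
        loadings[np.arange(6), winners] = 1.0
        tl = d.state_timeline(loadings, names=["A", "B"], dt=2.0)
        dwell = d.dwell_times(tl)
        assert dwell["A"]["runs_seconds"] == [4.0, 2.0]
        assert dwell["B"]["runs_seconds"] == [6.0]

    def test_single_state_and_never_winning(self):
        tl = d.state_timeline(np.tile([1.0, 0.0], (7, 1)), names=["A", "B"], dt=2.0)
        dwell = d.dwell_times(tl)
        assert dwell["A"]["runs_seconds"] == [14.0]
        assert dwell["B"]["mean_seconds"] == 0.0
        assert dwell["B"]["never_wins"]

    @given(st.integers(0, 2**31 - 1), st.integers(2, 5), st.integers(3, 40))
    @settings(max_examples=40, deadline=None)
    def test_run_lengths_sum_to_samples(self, seed, n_comp, t):
        rng = np.random.default_rng(seed)
        tl = d.state_timeline(rng.uniform(0, 1, (t, n_comp)))
        assert sum(sum(v) for v in tl.runs.values()) == t


class TestExcursions:
    def test_constant_series_zero(self):
        assert d.excursions_from_median(np.ones(10)).statistic == 0.0

    def test_hand_enumerated_case(self):
        stat = d.excursions_from_median([0.0, 1.0, 0.0, -1.0, 0.0])
        assert np.isclose(stat.statistic, 0.4)
        assert len(stat.excursions) == 2
        sides = {e[0] for e in stat.excursions}
        assert sides == {"above", "below"}

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    @settings(max_examples=40, deadline=None)
    def test_shift_invariance_and_scaling(self, seed, k):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(30)
        base = d.excursions_from_median(x).statistic
        shifted = d.excursions_from_median(x + 5.0).statistic
        scaled = d.excursions_from_median(k * x).statistic
        assert np.isclose(shifted, base, rtol=1e-9, atol=1e-12)
        assert np.isclose(scaled, k * base, rtol=1e-9, atol=1e-12)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            d.excursions_from_median([1.0, 2.0])
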