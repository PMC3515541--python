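"""Connectivity-matrix construction and sparsity thresholding."""

import numpy as np
import pytest

from cortexnets.networks import (
    ConnectivityMatrix,
    bandpass_filter,
    edge_count_at_sparsity,
    functional_matrix,
    largest_component_curve,
    regress_nuisance,
    structural_matrix,
    threshold_at_sparsity,
)


def _sinusoid(freq_hz, tr=2.0, n_t=400):
    t = np.arange(n_t) * tr
    return np.sin(2 * np.pi * freq_hz * t)


class TestBandpass:
    def test_passband_center_retained(self):
        x = _sinusoid(0.05)
        y = bandpass_filter(x, 0.01, 0.1, 2.0)[0]
        mid = slice(50, 350)  # avoid filter edge transients
        ratio = np.abs(y[mid]).max() / np.abs(x[mid]).max()
        assert 0.9 <= ratio <= 1.1

    def test_stopband_attenuated(self):
        x = _sinusoid(0.2)
        y = bandpass_filter(x, 0.01, 0.1, 2.0)[0]
        assert np.abs(y[50:350]).max() <= 0.1 * np.abs(x).max()

    def test_constant_series_removed(self):
        y = bandpass_filter(np.full(300, 7.0), 0.01, 0.1, 2.0)[0]
        assert np.abs(y).max() < 1e-6

    def test_zero_phase(self):
        # a passband sinusoid keeps its peak positions (forward-backward IIR)
        x = _sinusoid(0.05)
        y = bandpass_filter(x, 0.01, 0.1, 2.0)[0]
        mid = slice(100, 300)
        assert abs(np.argmax(x[mid]) - np.argmax(y[mid])) <= 1

    def test_rejects_cutoff_at_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(np.zeros((2, 100)), 0.01, 0.25, 2.0)

    def test_rejects_short_series(self):
        with pytest.raises(ValueError, match="timepoints"):
            bandpass_filter(np.zeros(10), 0.01, 0.1, 2.0)


class TestNuisanceRegression:
    def test_perfect_fit_gives_zero_residual(self):
        rng = np.random.default_rng(0)
        nuis = rng.standard_normal((3, 120))
        resid = regress_nuisance(nuis[1][None, :], nuis)
        assert np.abs(resid).max() < 1e-10

    def test_orthogonal_series_unchanged_up_to_mean(self):
        rng = np.random.default_rng(1)
        nuis = rng.standard_normal((2, 200))
        x = rng.standard_normal(200)
        # orthogonalize x against nuisance and intercept first
        design = np.column_stack([np.ones(200),
                                  (nuis - nuis.mean(1, keepdims=True)).T])
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        x_orth = x - design @ beta
        resid = regress_nuisance(x_orth[None, :], nuis)
        np.testing.assert_allclose(resid[0], x_orth, atol=1e-10)

    def test_residual_orthogonal_to_motion(self):
        rng = np.random.default_rng(2)
        motion = rng.standard_normal((6, 150))
        signal = rng.standard_normal((4, 150))
        series = signal + 0.5 * motion[0]
        resid = regress_nuisance(series, motion)
        for row in resid:
            for m in motion:
                mc = m - m.mean()
                assert abs(np.corrcoef(row, mc)[0, 1]) < 1e-10

    def test_rank_deficient_names_row(self):
        nuis = np.ones((3, 50))
        nuis[0] = np.arange(50)
        nuis[1] = 2 * np.arange(50) + 5  # dependent on row 0 after de-meaning
        with pytest.raises(ValueError, match="row 1"):
            regress_nuisance(np.zeros((1, 50)), nuis)


class TestFunctionalMatrix:
    def test_identical_and_negated_rows(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(50)
        series = np.vstack([base, base, -base])
        m = functional_matrix(series)
        assert m.values[0, 1] == pytest.approx(1.0)
        assert m.values[0, 2] == pytest.approx(-1.0)
        assert np.all(np.diag(m.values) == 0)

    def test_matches_hand_computed_fixture(self):
        # frozen from explicit sum-formula arithmetic on this 3x5 table
        series = np.array([
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [2.0, 1.0, 4.0, 3.0, 6.0],
            [5.0, 3.0, 4.0, 1.0, 2.0],
        ])
        m = functional_matrix(series).values
        assert m[0, 1] == pytest.approx(0.8219949365267863, abs=1e-12)
        assert m[0, 2] == pytest.approx(-0.8, abs=1e-12)
        assert m[1, 2] == pytest.approx(-0.3287979746107145, abs=1e-12)

    def test_rejects_zero_variance_region(self):
        series = np.vstack([np.arange(10.0), np.full(10, 3.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            functional_matrix(series)

    def test_rejects_too_few_timepoints(self):
        with pytest.raises(ValueError):
            functional_matrix(np.random.default_rng(0).standard_normal((3, 2)))


class TestStructuralMatrix:
    def test_proportional_regions_perfectly_correlated(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(20) + 5
        gm = np.column_stack([v, 2 * v, rng.standard_normal(20)])
        m = structural_matrix(gm)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_independent_volumes_nearly_uncorrelated(self):
        rng = np.random.default_rng(5)
        gm = rng.standard_normal((2000, 15))
        m = structural_matrix(gm)
        off = m.values[np.triu_indices(15, k=1)]
        assert np.abs(off).max() < 0.1

    def test_correlation_is_across_subjects_not_time(self):
        # 3 subjects exactly: the minimal group; one more subject changes r
        gm = np.array([[1.0, 2.0], [2.0, 4.5], [3.0, 5.0]])
        m = structural_matrix(gm)
        expected = np.corrcoef(gm[:, 0], gm[:, 1])[0, 1]
        assert m.values[0, 1] == pytest.approx(expected)
        with pytest.raises(ValueError, match="3 subjects"):
            structural_matrix(gm[:2])


class TestThresholding:
    def test_edge_count_formula(self):
        assert edge_count_at_sparsity(90, 0.17) == 681
        assert edge_count_at_sparsity(90, 1.0) == 4005

    def _random_matrix(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-1, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        return ConnectivityMatrix(values=a, kind="functional")

    def test_complete_graph_at_full_sparsity(self):
        net = threshold_at_sparsity(self._random_matrix(12, 0), 1.0)
        assert net.edge_count == 12 * 11 // 2

    def test_topk_matches_bruteforce_sort(self):
        m = self._random_matrix(15, 1)
        k = edge_count_at_sparsity(15, 0.3)
        net = threshold_at_sparsity(m, 0.3, ranking="absolute")
        iu, ju = np.triu_indices(15, k=1)
        order = np.argsort(-np.abs(m.values[iu, ju]), kind="stable")
        expected = {(iu[o], ju[o]) for o in order[:k]}
        got = {(i, j) for i, j in zip(*np.nonzero(np.triu(net.adjacency, 1)))}
        assert got == expected

    def test_signed_ranking_differs_from_absolute(self):
        m = self._random_matrix(15, 2)
        net_abs = threshold_at_sparsity(m, 0.2, ranking="absolute")
        net_pos = threshold_at_sparsity(m, 0.2, ranking="positive")
        assert net_abs.edge_count == net_pos.edge_count
        assert not np.array_equal(net_abs.adjacency, net_pos.adjacency)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nested_edge_sets_across_grid(self, seed):
        m = self._random_matrix(30, seed)
        grid = [round(0.15 + 0.01 * i, 2) for i in range(16)]
        prev = None
        for s in grid:
            adj = threshold_at_sparsity(m, s).adjacency
            if prev is not None:
                assert np.all(adj[prev])  # every earlier edge still present
            prev = adj

    def test_nestedness_with_ties(self):
        # heavy ties exercise the deterministic lexicographic tie-break
        vals = np.zeros((10, 10))
        vals[np.triu_indices(10, 1)] = np.repeat([0.5, 0.3, 0.1], 15)
        vals = vals + vals.T
        m = ConnectivityMatrix(values=vals, kind="functional")
        prev = None
        for s in (0.2, 0.4, 0.6, 0.8, 1.0):
            adj = threshold_at_sparsity(m, s).adjacency
            if prev is not None:
                assert np.all(adj[prev])
            prev = adj

    def test_rejects_bad_sparsity(self):
        m = self._random_matrix(10, 3)
        with pytest.raises(ValueError):
            threshold_at_sparsity(m, 0.0)
        with pytest.raises(ValueError):
            threshold_at_sparsity(m, 1.5)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           n=st.integers(6, 25),
           s1=st.floats(0.05, 0.95),
           s2=st.floats(0.05, 0.95))
    def test_threshold_invariants_property(seed, n, s1, s2):
        """Exact edge count at any sparsity; nested edge sets for s1 <= s2."""
        rng = np.random.default_rng(seed)
        a = rng.uniform(-1, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        m = ConnectivityMatrix(values=a, kind="functional")
        lo, hi = sorted((s1, s2))
        if edge_count_at_sparsity(n, lo) < 1:
            return
        net_lo = threshold_at_sparsity(m, lo)
        net_hi = threshold_at_sparsity(m, hi)
        assert net_lo.edge_count == edge_count_at_sparsity(n, lo)
        assert net_hi.edge_count == edge_count_at_sparsity(n, hi)
        assert np.all(net_hi.adjacency[net_lo.adjacency])
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


class TestLargestComponentCurve:
    def test_block_diagonal_spans_late(self):
        # two 5-node blocks, zero between-block correlation: the network
        # cannot span all nodes until between-block (zero) edges enter
        vals = np.zeros((10, 10))
        for blk in (range(5), range(5, 10)):
            for i in blk:
                for j in blk:
                    if i < j:
                        vals[i, j] = vals[j, i] = 0.8
        m = ConnectivityMatrix(values=vals, kind="structural")
        res = largest_component_curve(m, [0.1, 0.2, 0.4, 0.9, 1.0])
        sizes = dict(res["curve"])
        assert sizes[0.4] == 5  # 18 edges: still only within-block
        assert res["min_connected_sparsity"] == pytest.approx(0.9)

    def test_curve_monotone_on_random_matrices(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(-1, 1, (20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        m = ConnectivityMatrix(values=a, kind="functional")
        res = largest_component_curve(m, np.linspace(0.05, 1.0, 20))
        sizes = [s for _, s in res["curve"]]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))
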