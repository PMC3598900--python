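"""Nonlinear cascade model: prediction, fitting, model comparison, selection."""

import numpy as np
import pytest
from scipy.optimize import minimize

from subunitscope import (
    Filter,
    GNM,
    GNMModel,
    NeuronSpec,
    compute_sta,
    select_filters_sparse,
    xval_ll_improvement,
)
from subunitscope.neurons import SpikeCounts, simulate, softplus


class TestPrediction:
    def test_reduces_to_ln(self, small_design, small_gabor):
        m = GNMModel(filters=[small_gabor], nonlinearities=["identity"],
                     h=[[1.0]], theta=0.0)
        r = m.predict(small_design)
        g = small_design.X[small_design.valid] @ small_gabor.flat()
        assert np.allclose(r[small_design.valid], softplus(g), atol=1e-12)
        assert np.all(r[small_design.padded] == 0)

    def test_zero_nonlinearities_constant_rate(self, small_design, small_gabor):
        m = GNMModel(filters=[small_gabor], nonlinearities=[lambda u: 0.0 * u],
                     h=[[1.0]], theta=-1.2)
        r = m.predict(small_design)[small_design.valid]
        assert np.allclose(r, softplus(1.2), atol=1e-12)

    def test_energy_ground_truth_equivalence(self, small_design, quadrature_pair_small):
        k1, k2 = quadrature_pair_small
        spec = NeuronSpec(kind="energy_complex", filters=[k1, k2],
                          spiking_gain=0.5, spiking_offset=-2.0, seed=0)
        rate, _ = simulate(spec, small_design, seed=0)
        m = GNMModel(filters=[k1, k2], nonlinearities=["square", "square"],
                     h=[[0.5], [0.5]], theta=2.0)
        assert np.max(np.abs(m.predict(small_design) - rate)) < 1e-10

    def test_rates_positive_and_finite(self, small_design, quadrature_pair_small):
        k1, k2 = quadrature_pair_small
        m = GNMModel(filters=[k1, k2], nonlinearities=["halfwave", "square"],
                     h=[[2.0], [-1.0]], theta=5.0)
        r = m.predict(small_design)[small_design.valid]
        assert np.all(np.isfinite(r)) and np.all(r > 0)


class TestFitting:
    def test_softplus_glm_identity(self, small_design, small_gabor, ln_cell_data):
        # with 2 knots the tent nonlinearity is affine over the data range, so
        # the GNM collapses to a softplus GLM; an independent direct
        # optimization of the 2-parameter likelihood must agree
        _, _, spikes = ln_cell_data
        est = GNM(filters=[small_gabor], n_knots=2, lambda_f=0.0).fit(
            small_design, spikes)
        nl = est.model_.nonlinearities[0]
        slope = (nl.values[-1] - nl.values[0]) / (nl.knots[-1] - nl.knots[0])
        intercept = nl(0.0) - est.model_.theta
        g = small_design.X[small_design.valid] @ small_gabor.flat()
        y = spikes.counts[small_design.valid].astype(float)

        def nll(p):
            r = softplus(p[0] * g + p[1]) + 1e-12
            return np.sum(r - y * np.log(r))

        ref = minimize(nll, np.array([0.1, -1.0]), method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-10, maxiter=5000)).x
        assert abs(slope - ref[0]) / abs(ref[0]) < 1e-4
        assert abs(intercept - ref[1]) / abs(ref[1]) < 1e-4

    def test_heavy_smoothing_flattens_curvature(self, small_design, energy_cell_data):
        _, _, spikes = energy_cell_data
        k = energy_cell_data[0].filters[0]
        est = GNM(filters=[k], n_knots=15, lambda_f=1e8).fit(small_design, spikes)
        vals = est.model_.nonlinearities[0].values
        assert np.linalg.norm(np.diff(vals, 2)) < 1e-3

    def test_objective_monotone_over_blocks(self, small_design, energy_cell_data):
        spec, _, spikes = energy_cell_data
        est = GNM(filters=list(spec.filters), n_knots=12, h_len=3,
                  max_outer=5).fit(small_design, spikes)
        path = est.objective_path_
        assert np.all(np.diff(path) <= 1e-6 * np.abs(path[:-1]))

    def test_temporal_kernel_unit_norm(self, small_design, energy_cell_data):
        spec, _, spikes = energy_cell_data
        est = GNM(filters=list(spec.filters), n_knots=10, h_len=3,
                  max_outer=3).fit(small_design, spikes)
        for h in est.model_.h:
            assert abs(np.linalg.norm(h) - 1.0) < 1e-9

    def test_zero_spikes_rejected(self, small_design, small_gabor):
        counts = SpikeCounts(np.zeros(small_design.n_frames, dtype=int))
        with pytest.raises(ValueError, match="zero spikes"):
            GNM(filters=[small_gabor]).fit(small_design, counts)

    def test_degenerate_filter_rejected(self, small_design):
        zero_out = Filter(np.zeros((12, 8)))
        counts = SpikeCounts(np.ones(small_design.n_frames, dtype=int))
        with pytest.raises(ValueError, match="degenerate"):
            GNM(filters=[zero_out]).fit(small_design, counts)


class TestCrossValidation:
    def test_stimulus_independent_spikes_no_improvement(self, small_design, small_gabor):
        rng = np.random.default_rng(17)
        counts = SpikeCounts(rng.poisson(0.3, size=small_design.n_frames))
        imp = xval_ll_improvement(GNM(filters=[small_gabor], n_knots=10),
                                  small_design, counts, folds=10)
        half = 2.262 * imp.std(ddof=1) / np.sqrt(imp.size)
        assert abs(imp.mean()) <= max(half, 0.003)

    def test_true_model_beats_flat_sta_model(self, small_design, energy_cell_data):
        spec, _, spikes = energy_cell_data
        imp_true = xval_ll_improvement(GNM(filters=list(spec.filters), n_knots=10),
                                       small_design, spikes, folds=5)
        sta = compute_sta(small_design, spikes)
        imp_sta = xval_ll_improvement(GNM(filters=[sta], n_knots=10),
                                      small_design, spikes, folds=5)
        assert np.all(imp_true > imp_sta)

    def test_folds_validated(self, small_design, small_gabor, energy_cell_data):
        with pytest.raises(ValueError, match="folds"):
            xval_ll_improvement(GNM(filters=[small_gabor]), small_design,
                                energy_cell_data[2], folds=1)


class TestSparseSelection:
    def test_recovers_true_filter_among_noise(self, small_design, small_gabor,
                                              ln_cell_data):
        _, _, spikes = ln_cell_data
        rng = np.random.default_rng(23)
        noise = [Filter(w / np.linalg.norm(w)) for w in
                 rng.standard_normal((30, 12, 8))]
        sel = select_filters_sparse([small_gabor] + noise, small_design,
                                    spikes, folds=5)
        assert sel.indices.size <= 10
        best = max(abs(np.dot(k.flat(), small_gabor.flat())) for k in sel.filters)
        assert best >= 0.8

    def test_infinite_penalty_empty_selection(self, small_design, small_gabor,
                                              ln_cell_data):
        _, _, spikes = ln_cell_data
        with pytest.warns(UserWarning, match="no filters"):
            sel = select_filters_sparse([small_gabor], small_design, spikes,
                                        lambda_grid=[1e9], folds=3)
        assert sel.indices.size == 0

    def test_duplicates_do_not_enlarge_selected_span(self, small_design,
                                                     small_gabor, ln_cell_data):
        _, _, spikes = ln_cell_data
        rng = np.random.default_rng(29)
        noise = [Filter(w / np.linalg.norm(w)) for w in
                 rng.standard_normal((5, 12, 8))]
        base = [small_gabor] + noise
        sel_a = select_filters_sparse(base, small_design, spikes, folds=3)
        sel_b = select_filters_sparse(base + [small_gabor], small_design,
                                      spikes, folds=3)

        def span_rank(filters):
            if not filters:
                return 0
            A = np.stack([k.flat() for k in filters])
            return np.linalg.matrix_rank(A, tol=1e-8)

        assert span_rank(sel_b.filters) == span_rank(sel_a.filters)
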