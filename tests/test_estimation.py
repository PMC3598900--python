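"""Spike-triggered average/covariance and PCA whitening."""

import numpy as np
import pytest

from subunitscope import (
    NeuronSpec,
    PCAWhitener,
    SpikeCounts,
    SpikeTriggeredAnalysis,
    StimulusMovie,
    compute_sta,
    compute_stc,
    embed_stimulus,
    generate_pink_noise_movie,
    select_significant,
)
from subunitscope.neurons import poisson_spikes, simulate


class TestSTA:
    def test_uniform_firing_gives_zero_sta(self, small_design):
        counts = SpikeCounts(np.ones(small_design.n_frames, dtype=int))
        est = SpikeTriggeredAnalysis().fit(small_design, counts)
        assert np.linalg.norm(est.sta_raw_) < 1e-10

    def test_zero_spikes_rejected(self, small_design):
        counts = SpikeCounts(np.zeros(small_design.n_frames, dtype=int))
        with pytest.raises(ValueError, match="spike"):
            compute_sta(small_design, counts)

    def test_ln_cell_recovery(self, small_design, small_gabor, ln_cell_data):
        _, _, spikes = ln_cell_data
        sta = compute_sta(small_design, spikes)
        assert abs(np.dot(sta.flat(), small_gabor.flat())) > 0.9

    def test_length_mismatch_rejected(self, small_design):
        with pytest.raises(ValueError, match="length"):
            compute_sta(small_design, SpikeCounts(np.ones(10, dtype=int)))


class TestSTC:
    def test_eigenvalue_sum_equals_trace(self, small_design, energy_cell_data):
        _, _, spikes = energy_cell_data
        res = compute_stc(small_design, spikes)
        # conservation: the eigenvalues are exactly the spectrum of dC
        assert np.isclose(res.eigenvalues.sum(),
                          np.trace(_delta_cov(small_design, spikes)), rtol=1e-10)

    def test_eigenvectors_orthonormal_sorted(self, small_design, energy_cell_data):
        _, _, spikes = energy_cell_data
        res = compute_stc(small_design, spikes)
        V = res.eigenvectors
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_symmetric_onoff_cell_has_flat_sta_but_strong_stc(
            self, small_design, energy_cell_data):
        # a cell driven by g**2 responds identically to s and -s: the STA
        # carries no structure while the top STC eigenvalue is far above null
        _, _, spikes = energy_cell_data
        res = select_significant(small_design, spikes, method="shuffle",
                                 n_shuffles=50, random_state=0)
        assert np.linalg.norm(res.sta_raw) < 0.25
        assert res.excitatory.size >= 1
        assert res.eigenvalues[0] > 0.3

    def test_stimulus_independent_spikes_inside_null(self, small_design):
        rng = np.random.default_rng(7)
        counts = SpikeCounts(rng.poisson(0.3, size=small_design.n_frames))
        res = select_significant(small_design, counts, method="shuffle",
                                 n_shuffles=50, alpha=0.01, random_state=1)
        assert res.excitatory.size == 0
        assert res.suppressive.size == 0

    def test_fixed_selection_counts(self, small_design, energy_cell_data):
        _, _, spikes = energy_cell_data
        res = select_significant(small_design, spikes, method="fixed",
                                 n_pos=2, n_neg=0)
        assert res.excitatory.size == 2 and res.suppressive.size == 0
        with pytest.raises(ValueError, match="exceeds"):
            select_significant(small_design, spikes, method="fixed",
                               n_pos=90, n_neg=10)

    def test_duplicating_stimulus_with_zero_spikes_is_invariant(
            self, small_design, energy_cell_data):
        # appending an exact copy of the valid ensemble with zero spikes
        # leaves all moments, hence STA and STC, exactly unchanged
        _, _, spikes = energy_cell_data
        X = small_design.X[small_design.valid]
        y = spikes.counts[small_design.valid]
        res1 = compute_stc(X, y)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, np.zeros_like(y)])
        res2 = compute_stc(X2, y2)
        assert np.allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-10)
        assert np.allclose(res1.sta_raw, res2.sta_raw, atol=1e-12)

    def test_separable_simple_is_rank_two(self, small_design, quadrature_pair_small):
        k1, k2 = quadrature_pair_small
        spec = NeuronSpec(kind="separable_simple", filters=[k1, k2],
                          subunit_nonlinearity="halfwave", spiking_gain=2.0,
                          spiking_offset=-2.0, seed=0)
        _, spikes = simulate(spec, small_design, seed=11)
        res = select_significant(small_design, spikes, method="shuffle",
                                 n_shuffles=50, alpha=0.01, random_state=2)
        # rank-2 truth: at most the two subunit directions are detected and the
        # third-largest eigenvalue stays inside the shuffle null
        assert 1 <= res.excitatory.size <= 2
        assert 2 not in res.excitatory
        assert res.suppressive.size == 0

    def test_too_few_spikes_rejected(self, small_design):
        counts = np.zeros(small_design.n_frames, dtype=int)
        counts[5000] = 3
        with pytest.raises(ValueError, match="need at least"):
            compute_stc(small_design, SpikeCounts(counts))


def _delta_cov(design, spikes):
    X = design.X[design.valid]
    w = spikes.counts[design.valid].astype(float)
    mu = X.mean(0)
    c_all = (X.T @ X) / X.shape[0] - np.outer(mu, mu)
    idx = w > 0
    mu_s = (w[idx] @ X[idx]) / w.sum()
    c_sp = ((X[idx] * w[idx, None]).T @ X[idx]) / w.sum() - np.outer(mu_s, mu_s)
    return c_sp - c_all


class TestWhitening:
    def test_white_design_already_white(self, small_design):
        wh = PCAWhitener(M=small_design.X.shape[1]).fit(small_design)
        Z = wh.transform(small_design)
        C = np.cov(Z, rowvar=False)
        assert np.linalg.norm(C - np.eye(C.shape[0]), 2) < 0.05

    def test_default_retained_dimension(self):
        assert PCAWhitener().M == 600

    def test_pink_design_condition_number(self):
        movie = generate_pink_noise_movie(12, 12, 8000, exponent=1.0, seed=2)
        design = embed_stimulus(movie, 3)
        wh = PCAWhitener(M=100).fit(design)
        Z = wh.transform(design)
        ev = np.linalg.eigvalsh(np.cov(Z, rowvar=False))
        assert ev[-1] / ev[0] < 1.5

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(3)
        low = rng.standard_normal((500, 4)) @ rng.standard_normal((4, 20))
        with pytest.raises(ValueError, match="smaller M"):
            PCAWhitener(M=10).fit(low)

    def test_dewhiten_basis_vector(self, small_design):
        wh = PCAWhitener(M=30).fit(small_design)
        e3 = np.zeros(30)
        e3[3] = 1.0
        out = wh.dewhiten(e3)  # normalized sqrt(D_3) * V_3 == +-V_3
        assert abs(abs(np.dot(out, wh.basis_.V[:, 3])) - 1.0) < 1e-10

    def test_dewhiten_zero_rejected(self, small_design):
        wh = PCAWhitener(M=5).fit(small_design)
        with pytest.raises(ValueError, match="zero"):
            wh.dewhiten(np.zeros(5))

    def test_roundtrip_matches_direct_stc_on_white_noise(
            self, small_design, energy_cell_data):
        _, _, spikes = energy_cell_data
        direct = compute_stc(small_design, spikes)
        wh = PCAWhitener(M=96).fit(small_design)
        res_w = compute_stc(wh.transform(small_design),
                            spikes.counts[small_design.valid])
        b = wh.dewhiten(res_w.eigenvectors[:, 0])
        assert abs(np.dot(b, direct.eigenvectors[:, 0])) >= 0.99

    def test_m_too_large_rejected(self, small_design):
        with pytest.raises(ValueError, match="M cannot"):
            PCAWhitener(M=1000).fit(small_design)
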