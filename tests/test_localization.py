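"""Localized-filter search within an STC subspace."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subunitscope import (
    Filter,
    align_and_pca,
    find_localized_filter,
    find_localized_set,
    localization_cost,
    make_gabor_strf,
    next_localized_at,
    temporal_power,
)
from subunitscope.localization import LocalizedSet, _CostCache, power_centroid


def _bump(n_x, n_lags, x0, phase=0.0):
    """Localized oscillating filter centered at x0."""
    x = np.arange(n_x)[:, None]
    l = np.arange(n_lags)[None, :]
    w = np.cos(1.3 * l + phase) * np.exp(-((x - x0) ** 2) / 2.0)
    return Filter(w / np.linalg.norm(w))


class TestTemporalPower:
    def test_constant_across_lags_is_zero(self):
        w = np.tile(np.random.default_rng(0).standard_normal((6, 1)), (1, 5))
        assert np.allclose(temporal_power(Filter(w)), 0.0)

    def test_support_confined_to_one_position(self):
        w = np.zeros((8, 5))
        w[3] = np.random.default_rng(1).standard_normal(5)
        R = temporal_power(Filter(w))
        assert R[3] > 0
        assert np.all(R[np.arange(8) != 3] == 0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_total_power_bounded_by_mean_square(self, seed):
        # per-position variance across lags can never exceed the mean square,
        # so sum_x R(x) <= ||f||^2 / T for unit-norm filters
        w = np.random.default_rng(seed).standard_normal((7, 6))
        w /= np.linalg.norm(w)
        assert temporal_power(Filter(w)).sum() <= 1.0 / 6 + 1e-12


class TestLocalizationCost:
    def test_power_at_target_gives_zero(self):
        b = _bump(16, 6, 8.0)
        centroid = power_centroid(b)[0]
        assert localization_cost(centroid, np.array([1.0]), [b]) < \
            localization_cost(centroid + 4, np.array([1.0]), [b])

    def test_split_power_arithmetic(self):
        # power R at c-d and c+d only: cost = R_total * d**2
        w = np.zeros((9, 4))
        w[2, :] = [1.0, -1.0, 1.0, -1.0]
        w[6, :] = [1.0, -1.0, 1.0, -1.0]
        f = Filter(w)
        R = temporal_power(f)
        cost = localization_cost(4.0, np.array([1.0]), [f])
        assert np.isclose(cost, R.sum() * 4.0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_sign_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        basis = [Filter(rng.standard_normal((8, 5))) for _ in range(3)]
        beta = rng.standard_normal(3)
        c = rng.uniform(0, 7)
        assert np.isclose(localization_cost(c, beta, basis),
                          localization_cost(c, -beta, basis))


class TestFindLocalizedFilter:
    def test_single_basis_returns_it(self):
        b = _bump(16, 6, 5.0)
        lf = find_localized_filter([b], 5.0, seed=0)
        assert np.allclose(np.abs(lf.beta), [1.0], atol=1e-8)
        assert np.allclose(np.abs(lf.filter.weights), np.abs(b.weights), atol=1e-6)

    def test_disjoint_bumps_select_the_near_one(self):
        basis = [_bump(16, 6, 3.0), _bump(16, 6, 12.0)]
        lf = find_localized_filter(basis, 3.0, seed=0)
        assert abs(lf.beta[0]) >= 0.99

    def test_no_worse_than_any_basis_filter(self):
        rng = np.random.default_rng(4)
        basis = [Filter(rng.standard_normal((10, 6))) for _ in range(4)]
        c = 4.5
        lf = find_localized_filter(basis, c, seed=1)
        for i, b in enumerate(basis):
            e = np.zeros(4)
            e[i] = 1.0
            assert lf.cost <= localization_cost(c, e, basis) + 1e-9

    def test_matches_rayleigh_eigen_oracle(self):
        # closed form: the optimum is the smallest eigenvector of Q(c)
        rng = np.random.default_rng(5)
        basis = [Filter(rng.standard_normal((10, 6))) for _ in range(5)]
        c = 6.0
        lf = find_localized_filter(basis, c, n_restarts=20, seed=2)
        cache = _CostCache(basis)
        evals = np.linalg.eigvalsh(cache.Q(c))
        assert np.isclose(lf.cost, evals[0], rtol=1e-8, atol=1e-10)

    def test_brute_force_circle_oracle_for_two_filters(self):
        # exhaustive scan of the unit circle in beta-space
        basis = [_bump(16, 6, 3.0), _bump(16, 6, 12.0)]
        c = 12.0
        thetas = np.linspace(0, np.pi, 20001)
        costs = [localization_cost(c, np.array([np.cos(t), np.sin(t)]), basis)
                 for t in thetas]
        lf = find_localized_filter(basis, c, seed=3)
        assert lf.cost <= min(costs) + 1e-9

    def test_beta_unit_norm(self):
        rng = np.random.default_rng(6)
        basis = [Filter(rng.standard_normal((8, 5))) for _ in range(3)]
        lf = find_localized_filter(basis, 2.0, seed=4)
        assert abs(np.linalg.norm(lf.beta) - 1.0) < 1e-8

    def test_superset_basis_never_costs_more(self):
        rng = np.random.default_rng(7)
        basis = [Filter(rng.standard_normal((10, 5))) for _ in range(4)]
        for c in (1.0, 4.5, 8.0):
            small = find_localized_filter(basis[:2], c, seed=5).cost
            large = find_localized_filter(basis, c, seed=5).cost
            assert large <= small + 1e-9


class TestNextLocalizedAt:
    def test_two_dim_basis_second_is_orthogonal_complement(self):
        basis = [_bump(16, 6, 4.0), _bump(16, 6, 10.0)]
        first = find_localized_filter(basis, 4.0, seed=0)
        second = next_localized_at(basis, 4.0, first, seed=0)
        assert abs(np.dot(first.beta, second.beta)) < 1e-6
        # in 2-D the complement is unique up to sign
        comp = np.array([-first.beta[1], first.beta[0]])
        assert np.isclose(abs(np.dot(second.beta, comp)), 1.0, atol=1e-8)

    def test_subspace_exhaustion(self):
        basis = [_bump(16, 6, 4.0), _bump(16, 6, 10.0)]
        first = find_localized_filter(basis, 4.0, seed=0)
        second = next_localized_at(basis, 4.0, first, seed=0)
        with pytest.raises(ValueError, match="exhausted"):
            next_localized_at(basis, 4.0, [first, second], seed=0)

    def test_quadrature_basis_yields_phase_shifted_pair(self):
        k1 = make_gabor_strf(16, 8, 3.0, 0.0, 2.0, 2.5, phase=0.0)
        k2 = make_gabor_strf(16, 8, 3.0, 0.0, 2.0, 2.5, phase=np.pi / 2)
        first = find_localized_filter([k1, k2], 7.5, seed=1)
        second = next_localized_at([k1, k2], 7.5, first, seed=1)
        # orthogonal unit combinations of a quadrature pair stay ~90 deg apart
        assert abs(np.dot(first.filter.flat(), second.filter.flat())) < 0.05


class TestFindLocalizedSet:
    def test_centers_cover_domain_with_endpoints(self):
        rng = np.random.default_rng(8)
        basis = [Filter(rng.standard_normal((16, 5))) for _ in range(3)]
        s = find_localized_set(basis, n_centers=40, n_restarts=5, seed=0)
        assert len(s.filters) == 40
        assert s.centers[0] == 0.0 and s.centers[-1] == 15.0
        assert np.allclose(np.diff(s.centers), s.centers[1] - s.centers[0])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        basis = [Filter(rng.standard_normal((12, 5))) for _ in range(3)]
        a = find_localized_set(basis, n_centers=8, n_restarts=5, seed=3)
        b = find_localized_set(basis, n_centers=8, n_restarts=5, seed=3)
        for fa, fb in zip(a.filters, b.filters):
            assert np.array_equal(fa.beta, fb.beta)


class TestAlignAndPCA:
    def test_identical_shifted_copies_single_component(self):
        base = _bump(16, 6, 8.0)
        copies = [_bump(16, 6, float(x)) for x in (4, 6, 8, 10, 12)]
        s = LocalizedSet(filters=[
            _as_localized(f, float(x)) for f, x in zip(copies, (4, 6, 8, 10, 12))])
        _, explained = align_and_pca(s)
        assert explained[0] > 0.999

    def test_quadrature_family_two_components(self):
        rng = np.random.default_rng(10)
        fs = []
        for x in (4, 5, 6, 8, 10, 11, 12):
            phi = rng.uniform(0, 2 * np.pi)
            fs.append(_as_localized(_mix(x, phi), float(x)))
        _, explained = align_and_pca(LocalizedSet(filters=fs))
        assert explained[:2].sum() > 0.99

    def test_needs_three_filters(self):
        s = LocalizedSet(filters=[_as_localized(_bump(16, 6, 5.0), 5.0)] * 2)
        with pytest.raises(ValueError, match="at least 3"):
            align_and_pca(s)


def _mix(x0, phi):
    a = _bump(16, 6, x0, phase=0.0).weights
    b = _bump(16, 6, x0, phase=np.pi / 2).weights
    w = np.cos(phi) * a + np.sin(phi) * b
    return Filter(w / np.linalg.norm(w))


def _as_localized(f, c):
    from subunitscope.localization import LocalizedFilter

    return LocalizedFilter(beta=np.array([1.0]), filter=f, center_target=c,
                           cost=0.0, power_profile=temporal_power(f))
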