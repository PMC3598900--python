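"""Spatially localized filters within an STC subspace.

The STC eigenvectors form one orthonormal coordinate system for the stimulus
subspace a neuron is sensitive to, but individual eigenvectors are typically
multi-lobed and spatially extensive -- unlike the localized receptive fields of
the simple cells thought to provide a cortical neuron's input. Since any unit
vector ``k_beta = sum_i beta_i b_i`` (with ``sum beta_i^2 = 1``) lies in the
same subspace, we can search the subspace for *localized* alternatives.

The spatial profile of a candidate filter is summarized by its temporal power

    R_beta(x) = 1/T * sum_t [ <k_beta(x, .)>_t - k_beta(x, t) ]^2,

the variance of its weights across lags at each spatial position. A filter
localized at target position c minimizes the spread cost

    L(c, beta) = sum_x R_beta(x) * (c - x)^2   subject to  sum_i beta_i^2 = 1.

Because R is quadratic in the filter, the cost is a Rayleigh quotient
``beta' Q(c) beta / beta' beta``; we nevertheless minimize it with the
multi-restart quasi-Newton scheme (20 random initializations per target
location, 40 locations tiling the stimulus), parameterizing beta
unconstrained and normalizing inside the cost. Additional filters at the same
location are found by projecting out previous solutions and searching the
orthogonal complement. A set of localized filters is summarized by aligning
each filter's power centroid to the grid center and running (uncentered) PCA:
for a homogeneous population of shifted quadrature-pair subunits, two
components capture nearly all variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .neurons import Filter

__all__ = [
    "LocalizedFilter",
    "LocalizedSet",
    "SubunitLocalizer",
    "temporal_power",
    "localization_cost",
    "find_localized_filter",
    "find_localized_set",
    "next_localized_at",
    "align_and_pca",
]


@dataclass
class LocalizedFilter:
    """A unit-norm linear combination of basis filters localized at ``center_target``."""

    beta: np.ndarray
    filter: Filter
    center_target: float | tuple[float, ...]
    cost: float
    power_profile: np.ndarray


@dataclass
class LocalizedSet:
    """Localized filters over a grid of target centers, for one subspace."""

    filters: list[LocalizedFilter]
    subspace_tag: str = "excitatory"
    pca_basis: np.ndarray | None = None
    pca_explained: np.ndarray | None = None
    centers: np.ndarray = field(default_factory=lambda: np.array([]))


def _basis_array(basis) -> tuple[np.ndarray, tuple[int, ...]]:
    """Stack basis filters into (M, *spatial, T); returns array and filter shape."""
    if isinstance(basis, np.ndarray):
        arr = basis
        if arr.ndim < 3:
            raise ValueError("basis array must be (M, *spatial, n_lags)")
    else:
        filters = list(basis)
        if not filters:
            raise ValueError("basis must be non-empty")
        arr = np.stack([f.weights for f in filters])
    return arr, arr.shape[1:]


def temporal_power(filt: Filter | np.ndarray) -> np.ndarray:
    """Per-position variance of a filter across lags (population convention, divisor T)."""
    w = filt.weights if isinstance(filt, Filter) else np.asarray(filt)
    if w.shape[-1] < 2:
        raise ValueError("temporal power needs at least 2 lags")
    return ((w.mean(axis=-1, keepdims=True) - w) ** 2).mean(axis=-1)


def _distance_sq(c, spatial_shape: tuple[int, ...]) -> np.ndarray:
    """Squared distance (index units) from target c to every grid position."""
    if len(spatial_shape) == 1:
        x = np.arange(spatial_shape[0], dtype=np.float64)
        return (x - float(np.asarray(c).reshape(())) ) ** 2
    cx, cy = np.asarray(c, dtype=np.float64)
    gx = np.arange(spatial_shape[0])[:, None]
    gy = np.arange(spatial_shape[1])[None, :]
    return (gx - cx) ** 2 + (gy - cy) ** 2


def localization_cost(c, beta: np.ndarray, basis) -> float:
    """Power-weighted spatial spread L(c, beta) of the combined filter.

    ``beta`` is normalized internally if it is not unit-norm.
    """
    B, shape = _basis_array(basis)
    beta = np.asarray(beta, dtype=np.float64)
    nrm = np.linalg.norm(beta)
    if nrm == 0:
        raise ValueError("beta must be nonzero")
    k = np.tensordot(beta / nrm, B, axes=1)
    R = temporal_power(k)
    return float(np.sum(R * _distance_sq(c, shape[:-1])))


def _quadratic_form(B: np.ndarray) -> np.ndarray:
    """Per-position quadratic forms M_x[i,j] = (1/T) <centered b_i(x,.), centered b_j(x,.)>.

    Returns an array of shape (n_space_flat, M, M) so that
    L(c, beta) = beta' (sum_x w_x(c) M_x) beta for unit beta.
    """
    M = B.shape[0]
    T = B.shape[-1]
    flat = B.reshape(M, -1, T)
    centered = flat - flat.mean(axis=-1, keepdims=True)
    return np.einsum("ixt,jxt->xij", centered, centered) / T


class _CostCache:
    """Precomputed quadratic structure of the localization cost for one basis."""

    def __init__(self, basis):
        self.B, self.shape = _basis_array(basis)
        self.spatial_shape = self.shape[:-1]
        self.Mx = _quadratic_form(self.B)

    def Q(self, c) -> np.ndarray:
        w = _distance_sq(c, self.spatial_shape).reshape(-1)
        return np.tensordot(w, self.Mx, axes=1)


def _rayleigh_min(Q: np.ndarray, n_restarts: int, rng: np.random.Generator):
    """Multi-restart quasi-Newton minimization of beta'Q beta / beta'beta on the sphere."""
    M = Q.shape[0]

    def fun(b):
        ss = b @ b
        Qb = Q @ b
        f = (b @ Qb) / ss
        grad = 2 * (Qb - f * b) / ss
        return f, grad

    best_f, best_b = np.inf, None
    n_fail = 0
    for _ in range(n_restarts):
        b0 = rng.standard_normal(M)
        b0 /= np.linalg.norm(b0)
        res = minimize(fun, b0, jac=True, method="L-BFGS-B")
        if not np.isfinite(res.fun):
            n_fail += 1
            continue
        # strict improvement beyond tie tolerance keeps the first-restart winner
        if res.fun < best_f - 1e-10:
            best_f, best_b = res.fun, res.x
    if best_b is None:
        raise RuntimeError(
            f"localization optimizer failed on all {n_restarts} restarts "
            f"({n_fail} non-finite results)"
        )
    beta = best_b / np.linalg.norm(best_b)
    return best_f, beta


def _make_localized(cache: _CostCache, beta: np.ndarray, c, cost: float) -> LocalizedFilter:
    k = np.tensordot(beta, cache.B, axes=1)
    # deterministic sign: largest-magnitude filter weight positive
    i = np.unravel_index(np.argmax(np.abs(k)), k.shape)
    if k[i] < 0:
        k = -k
        beta = -beta
    return LocalizedFilter(
        beta=beta,
        filter=Filter(k, center=c),
        center_target=c,
        cost=float(cost),
        power_profile=temporal_power(k),
    )


def find_localized_filter(
    basis, c, n_restarts: int = 20, seed: int = 0
) -> LocalizedFilter:
    """Most spatially localized unit-norm combination of the basis at target c."""
    cache = basis if isinstance(basis, _CostCache) else _CostCache(basis)
    rng = np.random.default_rng(seed)
    cost, beta = _rayleigh_min(cache.Q(c), n_restarts, rng)
    return _make_localized(cache, beta, c, cost)


def next_localized_at(
    basis, c, existing, n_restarts: int = 20, seed: int = 0
) -> LocalizedFilter:
    """Next most localized filter at c, orthogonal to previously found solutions.

    ``existing`` is a LocalizedFilter or list thereof; the search runs in the
    orthogonal complement of their beta coefficients within the basis span.
    """
    cache = basis if isinstance(basis, _CostCache) else _CostCache(basis)
    prev = existing if isinstance(existing, (list, tuple)) else [existing]
    P = np.stack([p.beta for p in prev])
    M = cache.B.shape[0]
    # orthonormal complement of span(P) in R^M
    _, s, Vt = np.linalg.svd(P, full_matrices=True)
    rank = int(np.sum(s > 1e-10))
    U = Vt[rank:].T  # (M, M - rank)
    if U.shape[1] == 0:
        raise ValueError("subspace exhausted: no orthogonal directions remain")
    Qc = U.T @ cache.Q(c) @ U
    rng = np.random.default_rng(seed)
    cost, gamma = _rayleigh_min(Qc, n_restarts, rng)
    beta = U @ gamma
    beta /= np.linalg.norm(beta)
    return _make_localized(cache, beta, c, cost)


def _center_grid(spatial_shape: tuple[int, ...], n_centers: int) -> list:
    if len(spatial_shape) == 1:
        return list(np.linspace(0, spatial_shape[0] - 1, n_centers))
    # 2-D: roughly square grid with about n_centers points, endpoints included
    per_axis = max(2, int(np.ceil(np.sqrt(n_centers))))
    gx = np.linspace(0, spatial_shape[0] - 1, per_axis)
    gy = np.linspace(0, spatial_shape[1] - 1, per_axis)
    return [(float(a), float(b)) for a in gx for b in gy]


def find_localized_set(
    basis,
    n_centers: int = 40,
    n_restarts: int = 20,
    seed: int = 0,
    subspace_tag: str = "excitatory",
) -> LocalizedSet:
    """Localized filters at evenly spaced target centers covering the stimulus."""
    cache = _CostCache(basis)
    centers = _center_grid(cache.spatial_shape, n_centers)
    rng = np.random.default_rng(seed)
    out = []
    for c in centers:
        cost, beta = _rayleigh_min(cache.Q(c), n_restarts, rng)
        out.append(_make_localized(cache, beta, c, cost))
    return LocalizedSet(
        filters=out,
        subspace_tag=subspace_tag,
        centers=np.asarray(centers, dtype=np.float64),
    )


def power_centroid(filt: Filter | np.ndarray) -> np.ndarray:
    """Center of mass of the temporal-power profile (index units)."""
    R = temporal_power(filt)
    total = R.sum()
    if total == 0:
        raise ValueError("filter has zero temporal power")
    if R.ndim == 1:
        return np.array([np.sum(np.arange(R.size) * R) / total])
    gx = np.arange(R.shape[0])[:, None]
    gy = np.arange(R.shape[1])[None, :]
    return np.array([np.sum(gx * R) / total, np.sum(gy * R) / total])


def _integer_shift(w: np.ndarray, shift: tuple[int, ...]) -> np.ndarray:
    """Shift spatial axes by integers with zero fill (no wrap)."""
    out = w
    for axis, s in enumerate(shift):
        shifted = np.zeros_like(out)
        n = out.shape[axis]
        if s >= 0:
            sl_to = [slice(None)] * out.ndim
            sl_from = [slice(None)] * out.ndim
            sl_to[axis] = slice(s, n)
            sl_from[axis] = slice(0, n - s)
        else:
            sl_to = [slice(None)] * out.ndim
            sl_from = [slice(None)] * out.ndim
            sl_to[axis] = slice(0, n + s)
            sl_from[axis] = slice(-s, n)
        shifted[tuple(sl_to)] = out[tuple(sl_from)]
        out = shifted
    return out


def align_and_pca(localized: LocalizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Align filters by their power centroid and summarize with uncentered PCA.

    Each filter is shifted by the nearest-integer offset that moves its power
    centroid to the spatial grid center (no interpolation), the aligned filters
    are stacked as rows, and the principal components / explained-variance
    fractions of the uncentered stack are returned (and stored on the set).
    Uncentered PCA keeps the result meaningful for sign-ambiguous filters.
    """
    if len(localized.filters) < 3:
        raise ValueError("aligned PCA needs at least 3 filters")
    shapes = {lf.filter.weights.shape for lf in localized.filters}
    if len(shapes) != 1:
        raise ValueError("all filters must share a shape")
    shape = shapes.pop()
    spatial_shape = shape[:-1]
    # integer center so equal spacings round to identical aligned positions
    target = np.array([n // 2 for n in spatial_shape], dtype=np.float64)
    rows = []
    for lf in localized.filters:
        centroid = power_centroid(lf.filter)
        shift = tuple(int(np.rint(t - c)) for t, c in zip(target, centroid))
        rows.append(_integer_shift(lf.filter.weights, shift).reshape(-1))
    A = np.stack(rows)
    _, s, Vt = np.linalg.svd(A, full_matrices=False)
    explained = s**2 / np.sum(s**2)
    basis = Vt.reshape(-1, *shape)
    localized.pca_basis = basis
    localized.pca_explained = explained
    return basis, explained


class SubunitLocalizer(BaseEstimator):
    """Estimator wrapper around the localization search.

    ``fit(basis)`` takes a list of Filters (or an (M, *spatial, n_lags) array)
    spanning one STC subspace and produces:

    - ``set_`` : the :class:`LocalizedSet` over the target-center grid
    - ``filters_``, ``centers_``, ``costs_`` : convenience views
    - ``pca_basis_``, ``pca_explained_`` : aligned-PCA summary (if >= 3 filters)
    """

    def __init__(
        self,
        n_centers: int = 40,
        n_restarts: int = 20,
        seed: int = 0,
        subspace_tag: str = "excitatory",
        run_pca: bool = True,
    ):
        self.n_centers = n_centers
        self.n_restarts = n_restarts
        self.seed = seed
        self.subspace_tag = subspace_tag
        self.run_pca = run_pca

    def fit(self, basis, y=None):
        self.set_ = find_localized_set(
            basis,
            n_centers=self.n_centers,
            n_restarts=self.n_restarts,
            seed=self.seed,
            subspace_tag=self.subspace_tag,
        )
        self.filters_ = [lf.filter for lf in self.set_.filters]
        self.centers_ = self.set_.centers
        self.costs_ = np.array([lf.cost for lf in self.set_.filters])
        if self.run_pca and len(self.set_.filters) >= 3:
            self.pca_basis_, self.pca_explained_ = align_and_pca(self.set_)
        return self
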