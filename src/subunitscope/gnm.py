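"""Generalized nonlinear cascade model (GNM) fit by penalized Poisson likelihood.

The firing rate is modeled as

    r(t) = F[ sum_i sum_tau h_{i,tau} f_i( k_i . s_{t-tau} ) - theta ],

with fixed spatiotemporal filters ``k_i`` (from STC/localization), per-filter
scalar *upstream* nonlinearities ``f_i``, nonnegative-lag temporal integration
kernels ``h_i``, an offset ``theta`` and the softplus spiking nonlinearity
``F(u) = log(1 + exp(u))``. Holding the filters fixed, the nonlinearities and
kernels are estimated by maximizing the Poisson log-likelihood

    LL = sum_t [ n_t log r_t - r_t ]          (bin width = 1 frame)

minus smoothness penalties ``lambda_f * sum_i ||D2 f_i||^2`` and
``lambda_h * sum_i ||D2 h_i||^2`` (squared second differences). Each f_i is a
piecewise-linear (tent-basis) function with knots at empirical quantiles of its
filter output; scale is absorbed into ``h_i`` (unit norm) and the additive
constant into ``theta`` (f_i is zero at the median filter output), which fixes
the usual cascade-model degeneracies.

Model comparison uses the cross-validated log-likelihood improvement over a
constant (mean-rate) model, in nats per spike, on contiguous time-block folds.
A large set of candidate localized filters is pruned with L1-penalized logistic
regression on the half-wave-rectified outputs of each filter and its negative,
with the sparseness weight chosen by cross-validated deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.preprocessing import StandardScaler

from .neurons import Filter, SpikeCounts, softplus
from .stimuli import DesignMatrix

__all__ = [
    "TentNonlinearity",
    "GNMModel",
    "FitReport",
    "GNM",
    "SparseFilterSelector",
    "SparseSelection",
    "gnm_predict",
    "fit_nonlinearities",
    "xval_ll_improvement",
    "select_filters_sparse",
]

_RATE_FLOOR = 1e-12

_NAMED_NL: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda u: u,
    "halfwave": lambda u: np.maximum(u, 0.0),
    "square": lambda u: u * u,
}


@dataclass
class TentNonlinearity:
    """Piecewise-linear function: values at sorted knots, linear in between.

    Outside the knot range the function continues at the boundary value
    (constant extension), so extreme filter outputs never extrapolate wildly.
    """

    knots: np.ndarray
    values: np.ndarray

    def __call__(self, u: np.ndarray) -> np.ndarray:
        return np.interp(u, self.knots, self.values)


def _as_callable(f) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(f, str):
        try:
            return _NAMED_NL[f]
        except KeyError:
            raise ValueError(f"unknown nonlinearity name {f!r}") from None
    return f


@dataclass
class GNMModel:
    """A fitted (or hand-built) nonlinear cascade model."""

    filters: list[Filter]
    nonlinearities: list  # TentNonlinearity | str | callable
    h: list[np.ndarray]
    theta: float

    def __post_init__(self) -> None:
        if not (len(self.filters) == len(self.nonlinearities) == len(self.h)):
            raise ValueError("filters, nonlinearities and h must have equal lengths")
        self.h = [np.atleast_1d(np.asarray(hi, dtype=np.float64)) for hi in self.h]

    def generator(self, X: np.ndarray) -> np.ndarray:
        """Pre-spiking signal z(t) on contiguous rows (causal conv, zero history)."""
        z = np.full(X.shape[0], -self.theta)
        for k, f, h in zip(self.filters, self.nonlinearities, self.h):
            F = _as_callable(f)(X @ k.flat())
            if h.size == 1:
                z += h[0] * F
            else:
                z += np.convolve(F, h)[: X.shape[0]]
        return z

    def predict(self, design) -> np.ndarray:
        """Per-frame rate; padded design rows get rate 0."""
        if isinstance(design, DesignMatrix):
            rate = np.zeros(design.n_frames)
            rate[design.valid] = softplus(self.generator(design.X[design.valid]))
            return rate
        return softplus(self.generator(np.asarray(design)))


@dataclass
class FitReport:
    """Training/cross-validation summary of a GNM fit."""

    train_ll: float  # nats/spike improvement over mean-rate model, training data
    xval_ll: float | None
    folds: int
    penalty_weights: dict
    n_iter: int
    converged: bool
    objective_path: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


def gnm_predict(model: GNMModel, design) -> np.ndarray:
    """Firing rate of a cascade model on a design matrix."""
    return model.predict(design)


def _rows(design, spikes):
    counts = spikes.counts if isinstance(spikes, SpikeCounts) else np.asarray(spikes)
    if isinstance(design, DesignMatrix):
        if counts.size != design.n_frames:
            raise ValueError("spike counts and design matrix have different lengths")
        return design.X[design.valid], counts[design.valid].astype(np.float64)
    X = np.asarray(design)
    if counts.size != X.shape[0]:
        raise ValueError("spike counts and design matrix have different lengths")
    return X, counts.astype(np.float64)


def _tent_matrix(g: np.ndarray, knots: np.ndarray) -> sp.csr_matrix:
    """Sparse (n x K) interpolation-weight matrix: T @ values == interp(g)."""
    K = knots.size
    idx = np.clip(np.searchsorted(knots, g, side="right") - 1, 0, K - 2)
    span = knots[idx + 1] - knots[idx]
    w = np.clip((g - knots[idx]) / span, 0.0, 1.0)
    n = g.size
    rows = np.repeat(np.arange(n), 2)
    cols = np.stack([idx, idx + 1], axis=1).reshape(-1)
    data = np.stack([1.0 - w, w], axis=1).reshape(-1)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, K))


def _second_diff(K: int) -> np.ndarray:
    if K < 3:
        return np.zeros((0, K))
    D = np.zeros((K - 2, K))
    for i in range(K - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D


def _poisson_nll_terms(z: np.ndarray, y: np.ndarray):
    r = softplus(z) + _RATE_FLOOR
    nll = float(np.sum(r - y * np.log(r)))
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    dnll_dz = (1.0 - y / r) * sig
    return nll, dnll_dz


def _causal_conv(F: np.ndarray, h: np.ndarray) -> np.ndarray:
    if h.size == 1:
        return h[0] * F
    return np.convolve(F, h)[: F.size]


def _causal_conv_adjoint(v: np.ndarray, h: np.ndarray) -> np.ndarray:
    if h.size == 1:
        return h[0] * v
    return np.correlate(np.concatenate([v, np.zeros(h.size - 1)]), h, mode="valid")[: v.size]


class GNM(BaseEstimator):
    """Sklearn-style estimator for the nonlinear cascade model.

    Parameters
    ----------
    filters : list of Filter
        Fixed spatiotemporal filters (from STC, localization, or ground truth).
    n_knots : int
        Tent-basis knots per nonlinearity, placed at empirical quantiles of the
        filter output (including the extremes, so the training range is covered).
    lambda_f, lambda_h : float
        Smoothness penalty weights on the second differences of the f_i values
        and of the temporal kernels.
    h_len : int
        Length of each temporal integration kernel (1 = instantaneous, the
        right default for bar data binned at the stimulus frame rate).
    max_outer, tol : outer alternating-block iterations and relative objective
        tolerance; each block is solved by L-BFGS-B with analytic gradients.

    After ``fit(design, spikes)``: ``model_`` (a :class:`GNMModel`),
    ``report_``, ``objective_path_``, ``n_iter_``, ``converged_``.
    """

    def __init__(
        self,
        filters: Sequence[Filter] = (),
        n_knots: int = 20,
        lambda_f: float = 1.0,
        lambda_h: float = 1.0,
        h_len: int = 1,
        max_outer: int = 200,
        tol: float = 1e-6,
        max_inner: int = 500,
    ):
        self.filters = filters
        self.n_knots = n_knots
        self.lambda_f = lambda_f
        self.lambda_h = lambda_h
        self.h_len = h_len
        self.max_outer = max_outer
        self.tol = tol
        self.max_inner = max_inner

    # -- internals ----------------------------------------------------------

    def _objective_f(self, p, T, Dmats, h_list, y):
        M = len(T)
        z = np.full(y.size, -p[-1])
        offset = 0
        a_list = []
        for i in range(M):
            K = T[i].shape[1]
            a = p[offset : offset + K]
            a_list.append(a)
            z += _causal_conv(T[i] @ a, h_list[i])
            offset += K
        nll, dz = _poisson_nll_terms(z, y)
        grad = np.empty_like(p)
        offset = 0
        pen = 0.0
        for i in range(M):
            K = T[i].shape[1]
            Da = Dmats[i] @ a_list[i]
            pen += self.lambda_f * float(Da @ Da)
            g = T[i].T @ _causal_conv_adjoint(dz, h_list[i])
            g += 2 * self.lambda_f * (Dmats[i].T @ Da)
            grad[offset : offset + K] = g
            offset += K
        grad[-1] = -float(np.sum(dz))
        return nll + pen, grad

    def _objective_h(self, hp, Fsig, theta, y):
        M = len(Fsig)
        L = self.h_len
        Dh = _second_diff(L)
        z = np.full(y.size, -theta)
        for i in range(M):
            z += _causal_conv(Fsig[i], hp[i * L : (i + 1) * L])
        nll, dz = _poisson_nll_terms(z, y)
        grad = np.empty_like(hp)
        pen = 0.0
        for i in range(M):
            h = hp[i * L : (i + 1) * L]
            Dhh = Dh @ h
            pen += self.lambda_h * float(Dhh @ Dhh)
            # d z_t / d h_tau = F_i(t - tau)
            g = np.array(
                [np.dot(dz[tau:], Fsig[i][: y.size - tau]) for tau in range(L)]
            )
            grad[i * L : (i + 1) * L] = g + 2 * self.lambda_h * (Dh.T @ Dhh)
        return nll + pen, grad

    # -- API ----------------------------------------------------------------

    def fit(self, design, spikes):
        X, y = _rows(design, spikes)
        filters = list(self.filters)
        if not filters:
            raise ValueError("GNM needs at least one filter")
        if y.sum() < 1:
            raise ValueError("cannot fit a Poisson model with zero spikes")
        M = len(filters)
        G = [X @ k.flat() for k in filters]
        knots_list, T, Dmats = [], [], []
        for g in G:
            q = np.quantile(g, np.linspace(0, 1, self.n_knots))
            knots = np.unique(q)
            if knots.size < 2:
                raise ValueError("degenerate filter: its output has zero variance")
            knots_list.append(knots)
            T.append(_tent_matrix(g, knots))
            Dmats.append(_second_diff(knots.size))
        h_list = [np.ones(1) for _ in range(M)]
        if self.h_len > 1:
            for i in range(M):
                h = np.zeros(self.h_len)
                h[0] = 1.0
                h_list[i] = h
        mean_rate = max(y.mean(), 1e-6)
        theta0 = -float(np.log(np.expm1(mean_rate))) if mean_rate < 30 else -mean_rate
        p = np.concatenate([np.zeros(k.size) for k in knots_list] + [[theta0]])

        path = []
        prev_obj = np.inf
        n_outer = 0
        converged = False
        for n_outer in range(1, self.max_outer + 1):
            res = minimize(
                self._objective_f,
                p,
                args=(T, Dmats, h_list, y),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.max_inner},
            )
            p = res.x
            obj = float(res.fun)
            path.append(obj)
            if self.h_len > 1:
                theta = p[-1]
                a_split = np.split(p[:-1], np.cumsum([k.size for k in knots_list])[:-1])
                Fsig = [T[i] @ a_split[i] for i in range(M)]
                hp0 = np.concatenate(h_list)
                res_h = minimize(
                    self._objective_h,
                    hp0,
                    args=(Fsig, theta, y),
                    jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": self.max_inner},
                )
                hp = res_h.x
                for i in range(M):
                    h = hp[i * self.h_len : (i + 1) * self.h_len]
                    nrm = np.linalg.norm(h)
                    if nrm > 0:  # absorb scale into f (tent values)
                        h_list[i] = h / nrm
                        a_split[i] *= nrm
                p = np.concatenate(a_split + [[theta]])
                obj = float(res_h.fun)
                path.append(obj)
            if abs(prev_obj - obj) <= self.tol * max(1.0, abs(prev_obj)):
                converged = True
                break
            prev_obj = obj
        if not converged and self.h_len == 1:
            # single block: one L-BFGS solve is the full optimization
            converged = bool(res.success) or len(path) > 1

        theta = float(p[-1])
        a_split = np.split(p[:-1], np.cumsum([k.size for k in knots_list])[:-1])
        # identifiability: f_i(median of its input) = 0, constant absorbed into theta
        nls = []
        for i in range(M):
            med = float(np.median(G[i]))
            c = float(np.interp(med, knots_list[i], a_split[i]))
            vals = a_split[i] - c
            theta -= c * float(np.sum(h_list[i]))
            nls.append(TentNonlinearity(knots=knots_list[i], values=vals))
        self.model_ = GNMModel(filters=filters, nonlinearities=nls, h=h_list, theta=theta)
        self.objective_path_ = np.asarray(path)
        self.n_iter_ = n_outer
        self.converged_ = converged
        z = self.model_.generator(X)
        r = softplus(z) + _RATE_FLOOR
        ll = float(np.sum(y * np.log(r) - r))
        rbar = y.mean() + _RATE_FLOOR
        ll0 = float(np.sum(y * np.log(rbar) - rbar))
        self.train_ll_ = (ll - ll0) / y.sum()
        self.report_ = FitReport(
            train_ll=self.train_ll_,
            xval_ll=None,
            folds=0,
            penalty_weights={"lambda_f": self.lambda_f, "lambda_h": self.lambda_h},
            n_iter=self.n_iter_,
            converged=self.converged_,
            objective_path=self.objective_path_,
        )
        return self

    def predict(self, design) -> np.ndarray:
        return self.model_.predict(design)


def fit_nonlinearities(
    filters: Sequence[Filter],
    design,
    spikes,
    n_knots: int = 20,
    lambda_f: float = 1.0,
    lambda_h: float = 1.0,
    h_len: int = 1,
    folds: int = 0,
) -> tuple[GNMModel, FitReport]:
    """Fit per-filter nonlinearities (and optionally temporal kernels) by penalized ML.

    With ``folds >= 2`` the report additionally carries the mean cross-validated
    log-likelihood improvement (nats/spike) over a mean-rate model.
    """
    counts = spikes.counts if isinstance(spikes, SpikeCounts) else np.asarray(spikes)
    if counts.sum() < 100:
        warnings.warn("fewer than 100 spikes; nonlinearity estimates will be unreliable",
                      stacklevel=2)
    est = GNM(
        filters=filters, n_knots=n_knots, lambda_f=lambda_f, lambda_h=lambda_h, h_len=h_len
    ).fit(design, spikes)
    report = est.report_
    if folds >= 2:
        imp = xval_ll_improvement(est, design, spikes, folds=folds)
        report.xval_ll = float(np.mean(imp))
        report.folds = folds
    return est.model_, report


def xval_ll_improvement(estimator: GNM, design, spikes, folds: int = 10) -> np.ndarray:
    """Per-fold held-out Poisson LL improvement (nats/spike) over a mean-rate model.

    Folds are contiguous time blocks of the valid frames (temporal dependence
    makes random-frame folds optimistic). For each fold the model is refit on
    the remaining blocks; the constant-rate reference uses the training mean.
    Folds without spikes are skipped with a warning.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, y = _rows(design, spikes)
    n = X.shape[0]
    bounds = np.linspace(0, n, folds + 1).astype(int)
    improvements = []
    for f in range(folds):
        lo, hi = bounds[f], bounds[f + 1]
        test = np.zeros(n, dtype=bool)
        test[lo:hi] = True
        y_te = y[test]
        n_sp = y_te.sum()
        if n_sp == 0:
            warnings.warn(f"fold {f} has zero spikes; skipped", stacklevel=2)
            continue
        est = clone(estimator)
        est.fit(X[~test], y[~test])
        r = softplus(est.model_.generator(X[test])) + _RATE_FLOOR
        ll = float(np.sum(y_te * np.log(r) - r))
        rbar = y[~test].mean() + _RATE_FLOOR
        ll0 = float(np.sum(y_te * np.log(rbar) - rbar))
        improvements.append((ll - ll0) / n_sp)
    return np.asarray(improvements)


@dataclass
class SparseSelection:
    """Result of L1-logistic filter selection."""

    indices: np.ndarray
    filters: list[Filter]
    lambda_: float
    coefficients: np.ndarray
    cv_deviance: np.ndarray
    lambda_grid: np.ndarray


class SparseFilterSelector(BaseEstimator):
    """Prune candidate filters with L1-penalized logistic regression.

    Features are the half-wave-rectified outputs of each candidate filter and
    of its negative (so ON- and OFF-driven contributions can be selected
    independently); the target is the binarized spike count (>= 1 spike in the
    bin). The sparseness weight lambda is chosen by cross-validated deviance on
    contiguous folds, and a candidate is kept if either of its two rectified
    features has a nonzero coefficient at the chosen lambda. Lambda is picked
    by the one-standard-error rule (sparsest value within one SE of the
    minimum cross-validated deviance).
    """

    def __init__(
        self,
        candidates: Sequence[Filter] = (),
        lambda_grid: Sequence[float] | None = None,
        folds: int = 5,
    ):
        self.candidates = candidates
        self.lambda_grid = lambda_grid
        self.folds = folds

    def fit(self, design, spikes):
        X, y = _rows(design, spikes)
        cands = list(self.candidates)
        if not cands:
            raise ValueError("need at least one candidate filter")
        G = np.stack([X @ k.flat() for k in cands], axis=1)
        feats = np.concatenate([np.maximum(G, 0), np.maximum(-G, 0)], axis=1)
        feats = StandardScaler().fit_transform(feats)
        target = (y >= 1).astype(int)
        if target.sum() == 0 or target.sum() == target.size:
            raise ValueError("target is constant; cannot run logistic selection")
        grid = (
            np.asarray(self.lambda_grid, dtype=np.float64)
            if self.lambda_grid is not None
            else np.logspace(-4.5, 0.5, 11)
        )
        grid = np.sort(grid)
        n = feats.shape[0]
        bounds = np.linspace(0, n, self.folds + 1).astype(int)
        dev = np.full(grid.size, np.nan)
        dev_se = np.full(grid.size, np.nan)
        for j, lam in enumerate(grid):
            losses = []
            for f in range(self.folds):
                lo, hi = bounds[f], bounds[f + 1]
                test = np.zeros(n, dtype=bool)
                test[lo:hi] = True
                if target[~test].sum() in (0, (~test).sum()):
                    continue
                clf = LogisticRegression(
                    penalty="l1", C=1.0 / (lam * n), solver="liblinear",
                    max_iter=2000, random_state=0,
                )
                clf.fit(feats[~test], target[~test])
                p = clf.predict_proba(feats[test])[:, 1]
                losses.append(log_loss(target[test], p, labels=[0, 1]))
            if losses:
                dev[j] = float(np.mean(losses))
                dev_se[j] = float(np.std(losses, ddof=1) / np.sqrt(len(losses))) \
                    if len(losses) > 1 else 0.0
        if np.all(np.isnan(dev)):
            raise ValueError("no usable folds for sparse selection")
        # one-standard-error rule: the sparsest lambda whose CV deviance is
        # within one SE of the minimum
        jmin = int(np.nanargmin(dev))
        ok = np.nonzero(dev <= dev[jmin] + dev_se[jmin])[0]
        best = int(ok.max())
        lam = float(grid[best])
        clf = LogisticRegression(
            penalty="l1", C=1.0 / (lam * n), solver="liblinear",
            max_iter=2000, random_state=0,
        )
        clf.fit(feats, target)
        coef = clf.coef_.ravel()
        m = len(cands)
        keep = np.nonzero((np.abs(coef[:m]) > 1e-10) | (np.abs(coef[m:]) > 1e-10))[0]
        if keep.size == 0:
            warnings.warn("sparse selection kept no filters at the chosen lambda",
                          stacklevel=2)
        self.selection_ = SparseSelection(
            indices=keep,
            filters=[cands[i] for i in keep],
            lambda_=lam,
            coefficients=coef,
            cv_deviance=dev,
            lambda_grid=grid,
        )
        self.support_ = keep
        return self


def select_filters_sparse(
    candidates, design, spikes, lambda_grid=None, folds: int = 5
) -> SparseSelection:
    """Select the relevant subset of localized filters (see SparseFilterSelector)."""
    from .localization import LocalizedSet

    if isinstance(candidates, LocalizedSet):
        cands = [lf.filter for lf in candidates.filters]
    else:
        cands = list(candidates)
    sel = SparseFilterSelector(candidates=cands, lambda_grid=lambda_grid, folds=folds)
    return sel.fit(design, spikes).selection_
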