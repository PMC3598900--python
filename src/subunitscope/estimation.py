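"""Spike-triggered characterization: STA, STC, and PCA whitening.

The spike-triggered average (STA) is the spike-weighted mean stimulus minus the
ensemble mean: the first-order (linear) receptive-field estimate. Spike-triggered
covariance (STC) diagonalizes the difference between the spike-conditioned and
ensemble stimulus covariances, ``dC = C_spike - C_all``; eigenvectors with
significantly positive eigenvalues mark stimulus directions along which spiking
*increases* variance ("excitatory" filters) and significantly negative ones mark
variance-decreasing ("suppressive") directions. The STA is not projected out of
the STC filters.

For correlated ensembles (pink noise, naturalistic movies) the design matrix is
first whitened on a reduced PCA basis, ``Z = (S - mean) V D^{-1/2}``; filters
estimated in the whitened space are mapped back with ``b = V D^{1/2} b_w``,
which de-emphasizes poorly sampled stimulus directions and effectively smooths
the estimate.

Frames with count k contribute with weight k, consistent with the Poisson
likelihood used downstream; padded initial rows are always excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .neurons import Filter, SpikeCounts
from .stimuli import DesignMatrix

__all__ = [
    "STCResult",
    "WhiteningBasis",
    "SpikeTriggeredAnalysis",
    "PCAWhitener",
    "compute_sta",
    "compute_stc",
    "select_significant",
    "whiten_design",
    "dewhiten_filter",
]


@dataclass
class STCResult:
    """Output of spike-triggered covariance analysis.

    ``eigenvectors`` is (n_dims, n_dims) with unit-norm columns sorted by
    descending eigenvalue; ``excitatory`` / ``suppressive`` hold the indices of
    the selected significant columns (positive / negative eigenvalues).
    """

    sta: np.ndarray
    sta_raw: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_spikes_used: int
    filter_shape: tuple[int, ...] | None = None
    excitatory: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    suppressive: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def filters(self, indices: np.ndarray | list[int]) -> list[Filter]:
        if self.filter_shape is None:
            raise ValueError("no filter shape attached (whitened-space result)")
        return [Filter(self.eigenvectors[:, i].reshape(self.filter_shape)) for i in indices]

    def excitatory_filters(self) -> list[Filter]:
        return self.filters(self.excitatory)

    def suppressive_filters(self) -> list[Filter]:
        return self.filters(self.suppressive)

    def sta_filter(self) -> Filter:
        if self.filter_shape is None:
            raise ValueError("no filter shape attached (whitened-space result)")
        return Filter(self.sta.reshape(self.filter_shape))


@dataclass
class WhiteningBasis:
    """Retained PCA basis of the stimulus ensemble: V (n_dims x M), eigenvalues D."""

    V: np.ndarray
    D: np.ndarray
    mean: np.ndarray

    @property
    def M(self) -> int:
        return self.V.shape[1]


def _design_arrays(design, spikes) -> tuple[np.ndarray, np.ndarray, tuple[int, ...] | None]:
    """Valid rows, per-row counts and the filter shape (None for plain arrays)."""
    counts = spikes.counts if isinstance(spikes, SpikeCounts) else np.asarray(spikes)
    if isinstance(design, DesignMatrix):
        if counts.size != design.n_frames:
            raise ValueError("spike counts and design matrix have different lengths")
        return design.X[design.valid], counts[design.valid], design.filter_shape()
    X = np.asarray(design)
    if counts.size != X.shape[0]:
        raise ValueError("spike counts and design matrix have different lengths")
    return X, counts, None


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    """Deterministic sign: the largest-magnitude entry is made positive."""
    i = int(np.argmax(np.abs(vec)))
    return -vec if vec[i] < 0 else vec


def _sta_stc_moments(X: np.ndarray, w: np.ndarray, need_cov: bool):
    n_sp = w.sum()
    if n_sp == 0:
        raise ValueError("at least one spike is required in unpadded frames")
    mu_all = X.mean(axis=0)
    idx = np.nonzero(w > 0)[0]
    Xs = X[idx]
    ws = w[idx].astype(np.float64)
    mu_sp = (ws @ Xs) / n_sp
    sta_raw = mu_sp - mu_all
    if not need_cov:
        return sta_raw, None, int(n_sp)
    c_all = (X.T @ X) / X.shape[0] - np.outer(mu_all, mu_all)
    c_sp = ((Xs * ws[:, None]).T @ Xs) / n_sp - np.outer(mu_sp, mu_sp)
    return sta_raw, c_sp - c_all, int(n_sp)


class SpikeTriggeredAnalysis(BaseEstimator):
    """STA/STC estimator with excitatory/suppressive filter selection.

    Parameters
    ----------
    selection : {"fixed", "shuffle", None}
        How significant STC filters are chosen. ``"fixed"`` keeps the ``n_pos``
        largest and ``n_neg`` smallest eigenvalues. ``"shuffle"`` keeps
        eigenvalues outside the [alpha/2, 1-alpha/2] envelope of the extreme
        eigenvalues obtained from circularly time-shifted spike trains (a null
        that preserves both stimulus statistics and spike autostructure).
    n_pos, n_neg : int
        Counts for fixed selection (in practice N_pos = 2-8 for simple cells,
        4-10 for complex cells).
    n_shuffles, alpha, random_state
        Shuffle-null settings.

    Attributes (after ``fit(design, spikes)``)
    ----------
    sta_, sta_raw_ : unit-norm / raw spike-triggered average (flat vectors)
    eigenvalues_, eigenvectors_ : STC eigendecomposition, descending
    excitatory_, suppressive_ : indices of selected significant filters
    result_ : the full :class:`STCResult`
    """

    def __init__(
        self,
        selection: str | None = None,
        n_pos: int = 2,
        n_neg: int = 0,
        n_shuffles: int = 100,
        alpha: float = 0.01,
        random_state: int | None = None,
    ):
        self.selection = selection
        self.n_pos = n_pos
        self.n_neg = n_neg
        self.n_shuffles = n_shuffles
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, design, spikes):
        X, w, shape = _design_arrays(design, spikes)
        d = X.shape[1]
        sta_raw, dC, n_sp = _sta_stc_moments(X, w, need_cov=True)
        if n_sp < d:
            raise ValueError(f"need at least {d} spikes for a {d}-dim STC, got {n_sp}")
        if n_sp < 10 * d:
            warnings.warn(
                f"only {n_sp} spikes for {d} dimensions (<10x); STC filters may be noisy",
                stacklevel=2,
            )
        evals, evecs = np.linalg.eigh(dC)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        evecs = evecs[:, order]
        for j in range(evecs.shape[1]):
            evecs[:, j] = _fix_sign(evecs[:, j])
        sta_norm = np.linalg.norm(sta_raw)
        self.sta_raw_ = sta_raw
        self.sta_ = sta_raw / sta_norm if sta_norm > 0 else sta_raw
        self.eigenvalues_ = evals
        self.eigenvectors_ = evecs
        self.n_spikes_ = n_sp
        self.result_ = STCResult(
            sta=self.sta_,
            sta_raw=sta_raw,
            eigenvalues=evals,
            eigenvectors=evecs,
            n_spikes_used=n_sp,
            filter_shape=shape,
        )
        if self.selection == "fixed":
            self._select_fixed()
        elif self.selection == "shuffle":
            self._select_shuffle(X, w)
        self.result_.excitatory = getattr(self, "excitatory_", np.array([], dtype=int))
        self.result_.suppressive = getattr(self, "suppressive_", np.array([], dtype=int))
        return self

    def _select_fixed(self) -> None:
        d = self.eigenvalues_.size
        if self.n_pos + self.n_neg > d:
            raise ValueError("n_pos + n_neg exceeds the stimulus dimension")
        self.excitatory_ = np.arange(self.n_pos)
        self.suppressive_ = np.arange(d - self.n_neg, d)

    def _select_shuffle(self, X: np.ndarray, w: np.ndarray) -> None:
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        lo = max(1, min(getattr(self, "_min_shift", 20), n - 1))
        max_null = np.empty(self.n_shuffles)
        min_null = np.empty(self.n_shuffles)
        for i in range(self.n_shuffles):
            shift = int(rng.integers(lo, n - lo + 1))
            w_shift = np.roll(w, shift)
            _, dC, _ = _sta_stc_moments(X, w_shift, need_cov=True)
            ev = np.linalg.eigvalsh(dC)
            max_null[i] = ev[-1]
            min_null[i] = ev[0]
        hi_thr = np.quantile(max_null, 1 - self.alpha / 2)
        lo_thr = np.quantile(min_null, self.alpha / 2)
        self.null_max_ = max_null
        self.null_min_ = min_null
        self.excitatory_ = np.nonzero(self.eigenvalues_ > max(hi_thr, 0.0))[0]
        self.suppressive_ = np.nonzero(self.eigenvalues_ < min(lo_thr, 0.0))[0]


class PCAWhitener(BaseEstimator, TransformerMixin):
    """Whiten a design matrix on its leading M principal components.

    ``transform`` maps rows to ``Z = (X - mean) V D^{-1/2}`` so the retained
    subspace has identity covariance; ``dewhiten`` maps a whitened-space filter
    back to stimulus coordinates via ``V D^{1/2} b_w`` (unit-normalized). The
    default M = 600 balances estimate reliability against filter resolution for
    movie stimuli.
    """

    def __init__(self, M: int = 600):
        self.M = M

    def fit(self, design, y=None):
        X = design.X[design.valid] if isinstance(design, DesignMatrix) else np.asarray(design)
        n, d = X.shape
        if self.M > min(n, d):
            raise ValueError("M cannot exceed min(n_rows, n_dims)")
        mean = X.mean(axis=0)
        cov = (X.T @ X) / n - np.outer(mean, mean)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][: self.M]
        D = evals[order]
        if D[-1] <= 1e-10 * max(D[0], 1.0):
            raise ValueError(
                "near-zero eigenvalue in the retained set; use a smaller M"
            )
        self.basis_ = WhiteningBasis(V=evecs[:, order], D=D, mean=mean)
        return self

    def transform(self, design):
        X = design.X[design.valid] if isinstance(design, DesignMatrix) else np.asarray(design)
        b = self.basis_
        return (X - b.mean) @ b.V / np.sqrt(b.D)

    def dewhiten(
        self,
        b_w: np.ndarray,
        shape: tuple[int, ...] | None = None,
        smoothing: bool = True,
    ):
        """Map a whitened-space filter back to stimulus coordinates.

        With ``smoothing=True`` (default) the map is ``V D^{1/2} b_w``, which
        accentuates well-sampled stimulus dimensions: the result is the
        correlation-weighted spike-triggered *pattern* (robust and smooth, the
        method's display convention). With ``smoothing=False`` the exact
        inverse of the whitening map, ``V D^{-1/2} b_w``, is used: it undoes
        the stimulus correlations and is the right choice when the recovered
        filter is to be compared against a known ground-truth filter, at the
        price of amplifying noise in poorly sampled dimensions.
        """
        b_w = np.asarray(b_w, dtype=np.float64)
        if b_w.size != self.basis_.M:
            raise ValueError("whitened filter dimension does not match M")
        scale = np.sqrt(self.basis_.D) if smoothing else 1.0 / np.sqrt(self.basis_.D)
        vec = self.basis_.V @ (scale * b_w)
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise ValueError("cannot dewhiten an all-zero filter")
        vec = vec / norm
        return Filter(vec.reshape(shape)) if shape is not None else vec


# ---------------------------------------------------------------------------
# thin functional wrappers


def compute_sta(design, spikes) -> Filter:
    """Spike-triggered average as a unit-norm Filter (raw magnitude in .center-free attr).

    Returns the unit-norm STA; the raw (unnormalized) STA is available from
    :class:`SpikeTriggeredAnalysis` as ``sta_raw_``.
    """
    X, w, shape = _design_arrays(design, spikes)
    sta_raw, _, _ = _sta_stc_moments(X, w, need_cov=False)
    norm = np.linalg.norm(sta_raw)
    vec = sta_raw / norm if norm > 0 else sta_raw
    return Filter(vec.reshape(shape)) if shape is not None else Filter(vec[:, None])


def compute_sta_raw(design, spikes) -> np.ndarray:
    X, w, _ = _design_arrays(design, spikes)
    sta_raw, _, _ = _sta_stc_moments(X, w, need_cov=False)
    return sta_raw


def compute_stc(design, spikes) -> STCResult:
    """Full STC eigendecomposition (no significance selection)."""
    return SpikeTriggeredAnalysis(selection=None).fit(design, spikes).result_


def select_significant(
    design,
    spikes,
    method: str = "fixed",
    n_pos: int = 2,
    n_neg: int = 0,
    n_shuffles: int = 100,
    alpha: float = 0.01,
    random_state: int | None = None,
) -> STCResult:
    """STC with excitatory/suppressive filter selection (fixed count or shuffle null)."""
    est = SpikeTriggeredAnalysis(
        selection=method,
        n_pos=n_pos,
        n_neg=n_neg,
        n_shuffles=n_shuffles,
        alpha=alpha,
        random_state=random_state,
    )
    return est.fit(design, spikes).result_


def whiten_design(design, M: int = 600) -> tuple[np.ndarray, WhiteningBasis, PCAWhitener]:
    """Whitened design rows (valid frames only), the retained basis and the fitted whitener."""
    wh = PCAWhitener(M=M).fit(design)
    return wh.transform(design), wh.basis_, wh


def dewhiten_filter(b_w: np.ndarray, basis: WhiteningBasis, shape=None, smoothing: bool = True):
    """Map a whitened-space filter back to stimulus coordinates, unit-normalized.

    See :meth:`PCAWhitener.dewhiten` for the smoothing vs exact-inverse choice.
    """
    wh = PCAWhitener(M=basis.M)
    wh.basis_ = basis
    return wh.dewhiten(b_w, shape=shape, smoothing=smoothing)
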