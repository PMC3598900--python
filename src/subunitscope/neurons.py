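"""Generative model neurons with known subunit structure.

These cells provide ground truth for the estimation pipeline:

* ``ln_simple`` -- a single linear filter followed by the spiking nonlinearity;
* ``separable_simple`` -- a direction-selective simple cell built *de novo* from
  two space-time-separable (hence individually non-DS) filters, each half-wave
  rectified before summation;
* ``energy_complex`` -- the classical motion-energy complex cell: the squared
  outputs of a quadrature pair of DS filters are summed, yielding phase-invariant
  direction selectivity;
* ``pooled_complex`` -- a second-order complex cell that pools spatially shifted
  copies of a multi-filter prototype simple cell under a Gaussian envelope.

Firing rates go through a softplus spiking nonlinearity (the same form used in
model fitting) and spikes are drawn from an inhomogeneous Poisson process, one
count per stimulus frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stimuli import DesignMatrix

__all__ = [
    "Filter",
    "SpikeCounts",
    "NeuronSpec",
    "make_gabor_strf",
    "shift_filter",
    "neuron_rate",
    "poisson_spikes",
    "softplus",
]


def softplus(x: np.ndarray) -> np.ndarray:
    """Numerically stable log(1 + exp(x))."""
    x = np.asarray(x, dtype=np.float64)
    return np.where(x > 30, x, np.log1p(np.exp(np.minimum(x, 30))))


_SUBUNIT_NL = {
    "linear": lambda u: u,
    "halfwave": lambda u: np.maximum(u, 0.0),
    "square": lambda u: u * u,
}


@dataclass
class Filter:
    """A spatiotemporal filter on a space(xspace) x lag grid.

    ``weights`` has shape ``(n_x[, n_y], n_lags)``; C-order flattening matches
    the (space-major, lag-minor) design-matrix column layout.
    """

    weights: np.ndarray
    center: float | tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("filter weights must be finite")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.weights))

    @property
    def n_lags(self) -> int:
        return self.weights.shape[-1]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.weights.shape[:-1]

    def flat(self) -> np.ndarray:
        return self.weights.reshape(-1)

    def normalized(self) -> "Filter":
        n = self.norm
        if n == 0:
            raise ValueError("cannot normalize an all-zero filter")
        return Filter(self.weights / n, center=self.center)


@dataclass
class SpikeCounts:
    """Per-frame spike counts aligned with a design matrix."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(np.int64)
            if np.any(counts < 0):
                raise ValueError("spike counts must be nonnegative integers")
        self.counts = counts.astype(np.int64)

    @property
    def total_spikes(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.counts.size


@dataclass
class NeuronSpec:
    """Specification of a generative model neuron.

    ``spiking_gain`` and ``spiking_offset`` parameterize the output stage
    ``rate = F(gain * drive + offset)`` with F softplus by default
    (``spiking="relu"`` substitutes half-wave rectification, useful for cells
    whose response modulation should be exactly that of a rectified sinusoid).

    For ``pooled_complex``, ``filters`` holds the prototype subunit filters;
    ``shifts`` lists integer bar shifts of the prototype and ``envelope_sd``
    sets the Gaussian pooling weight of each shifted copy (centered at
    ``envelope_center``, in bar units relative to the unshifted prototype).
    """

    kind: str
    filters: Sequence[Filter]
    subunit_nonlinearity: str = "halfwave"
    spiking_gain: float = 1.0
    spiking_offset: float = 0.0
    spiking: str = "softplus"
    shifts: Sequence[int] = field(default_factory=lambda: (0,))
    envelope_sd: float = 3.0
    envelope_center: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        kinds = {"ln_simple", "separable_simple", "energy_complex", "pooled_complex"}
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {sorted(kinds)}")
        n = len(self.filters)
        expected = {"ln_simple": 1, "separable_simple": 2, "energy_complex": 2}
        if self.kind in expected and n != expected[self.kind]:
            raise ValueError(f"{self.kind} requires {expected[self.kind]} filters, got {n}")
        if self.kind == "pooled_complex" and n < 1:
            raise ValueError("pooled_complex requires at least one prototype filter")
        if self.subunit_nonlinearity not in _SUBUNIT_NL:
            raise ValueError(f"unknown subunit nonlinearity {self.subunit_nonlinearity!r}")
        if self.spiking not in ("softplus", "relu"):
            raise ValueError("spiking must be 'softplus' or 'relu'")

    def pooling_weights(self) -> np.ndarray:
        shifts = np.asarray(self.shifts, dtype=np.float64)
        w = np.exp(-((shifts - self.envelope_center) ** 2) / (2 * self.envelope_sd**2))
        return w


def make_gabor_strf(
    n_x: int,
    n_lags: int,
    spatial_freq: float = 2.0,
    tilt_phase_per_lag: float = 0.0,
    sigma_x: float | None = None,
    sigma_t: float | None = None,
    phase: float = 0.0,
    center_x: float | None = None,
    center_t: float | None = None,
) -> Filter:
    """Gabor-like x-t filter, the parametric stand-in for a V1 simple-cell STRF.

    ``weights(x, l) = cos(2 pi spatial_freq x / n_x + tilt_phase_per_lag * l + phase)
    * exp(-(x - cx)^2 / 2 sx^2) * exp(-(l - ct)^2 / 2 st^2)``, unit-normalized.
    A nonzero ``tilt_phase_per_lag`` tilts the x-t envelope, making the filter
    direction selective; zero tilt gives an exactly separable (rank-1) filter.
    """
    if n_x < 4 or n_lags < 4:
        raise ValueError("n_x and n_lags must be at least 4")
    sigma_x = n_x / 5 if sigma_x is None else sigma_x
    sigma_t = n_lags / 4 if sigma_t is None else sigma_t
    if sigma_x <= 0 or sigma_t <= 0:
        raise ValueError("envelope sds must be positive")
    cx = (n_x - 1) / 2 if center_x is None else center_x
    ct = (n_lags - 1) / 2 if center_t is None else center_t
    x = np.arange(n_x)[:, None]
    lag = np.arange(n_lags)[None, :]
    carrier = np.cos(2 * np.pi * spatial_freq * x / n_x + tilt_phase_per_lag * lag + phase)
    envelope = np.exp(-((x - cx) ** 2) / (2 * sigma_x**2)) * np.exp(
        -((lag - ct) ** 2) / (2 * sigma_t**2)
    )
    return Filter(carrier * envelope, center=float(cx)).normalized()


def shift_filter(filt: Filter, shift: int) -> Filter:
    """Shift a filter spatially by an integer number of bars, truncating at edges.

    Weights shifted past the stimulus border are dropped (no wrap-around) and the
    result is *not* renormalized, mimicking a finite receptive-field envelope.
    """
    w = filt.weights
    if w.ndim != 2:
        raise ValueError("shift_filter supports 1-D-space (x, lag) filters")
    out = np.zeros_like(w)
    n_x = w.shape[0]
    if shift >= 0:
        out[shift:, :] = w[: n_x - shift, :]
    else:
        out[: n_x + shift, :] = w[-shift:, :]
    center = None if filt.center is None else float(filt.center) + shift
    return Filter(out, center=center)


def _drive(spec: NeuronSpec, X: np.ndarray) -> np.ndarray:
    """Pre-spiking generator signal for valid design rows."""
    if spec.kind == "ln_simple":
        return X @ spec.filters[0].flat()
    if spec.kind == "separable_simple":
        f = _SUBUNIT_NL[spec.subunit_nonlinearity]
        return sum(f(X @ k.flat()) for k in spec.filters)
    if spec.kind == "energy_complex":
        g1 = X @ spec.filters[0].flat()
        g2 = X @ spec.filters[1].flat()
        return g1 * g1 + g2 * g2
    # pooled_complex
    f = _SUBUNIT_NL[spec.subunit_nonlinearity]
    weights = spec.pooling_weights()
    drive = np.zeros(X.shape[0])
    for w_s, s in zip(weights, spec.shifts):
        for k in spec.filters:
            drive += w_s * f(X @ shift_filter(k, int(s)).flat())
    return drive


def neuron_rate(spec: NeuronSpec, design: DesignMatrix) -> np.ndarray:
    """Per-frame firing rate (spikes/bin) of a model neuron; padded rows get 0."""
    d = int(np.prod(design.filter_shape()))
    for k in spec.filters:
        if k.flat().size != d:
            raise ValueError(
                f"filter has {k.flat().size} weights but design rows have {d} columns"
            )
    rate = np.zeros(design.n_frames)
    valid = design.valid
    z = spec.spiking_gain * _drive(spec, design.X[valid]) + spec.spiking_offset
    rate[valid] = softplus(z) if spec.spiking == "softplus" else np.maximum(z, 0.0)
    return rate


def poisson_spikes(rate: np.ndarray, seed: int) -> SpikeCounts:
    """Independent Poisson counts per frame with the given per-bin means."""
    rate = np.asarray(rate, dtype=np.float64)
    if np.any(rate < 0) or not np.all(np.isfinite(rate)):
        raise ValueError("rates must be nonnegative and finite")
    rng = np.random.default_rng(seed)
    return SpikeCounts(rng.poisson(rate))


def simulate(spec: NeuronSpec, design: DesignMatrix, seed: int) -> tuple[np.ndarray, SpikeCounts]:
    """Convenience: rate and Poisson spikes for a neuron on a design matrix."""
    rate = neuron_rate(spec, design)
    return rate, poisson_spikes(rate, seed)
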