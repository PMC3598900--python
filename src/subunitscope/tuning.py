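"""Classical tuning indices and separability analysis.

* :func:`grating_tuning` drives a model neuron (generative spec or fitted GNM)
  with drifting sinusoidal gratings over a spatial/temporal-frequency grid and
  measures the direction selectivity index DSI = (Rp - Rnp)/(Rp + Rnp) and the
  modulation index MI = F1/DC at the preferred grating (MI > 1: phase-modulated
  "simple" response; MI < 1: phase-invariant "complex" response).
* :func:`dsi_from_rf` predicts direction selectivity directly from a filter:
  DSI_RF = (Q1 - Q2)/(Q1 + Q2) with Q1, Q2 the summed power of the two upper
  quadrants of the filter's 2-D Fourier transform. Any space-time-separable
  filter has DSI_RF = 0 exactly.
* :func:`svd_separable` decomposes a direction-selective x-t filter into
  space-time-separable (rank-1, hence non-DS) components via SVD; a tilted
  cosine filter is exactly rank 2 (the cosine addition identity).
* :func:`project_preferred_axis` reduces a 3-D (x, y, lag) filter to an x-t plot
  by rotating the preferred-motion axis horizontal and summing over the
  orthogonal spatial coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .gnm import GNMModel
from .neurons import Filter, NeuronSpec, neuron_rate
from .stimuli import embed_stimulus, generate_grating

__all__ = [
    "TuningMetrics",
    "SeparableDecomposition",
    "grating_tuning",
    "dsi_from_rf",
    "svd_separable",
    "project_preferred_axis",
    "estimate_orientation",
]


@dataclass
class TuningMetrics:
    """Grating-response tuning summary."""

    dsi: float
    mi: float
    preferred: dict
    rates: dict | None = None


@dataclass
class SeparableDecomposition:
    """Truncated SVD of an x-t filter into separable components."""

    spatial_kernels: np.ndarray  # (n_x, rank), unit-norm columns
    temporal_kernels: np.ndarray  # (n_lags, rank), unit-norm columns
    singular_values: np.ndarray  # descending
    rank_kept: int
    reconstruction: np.ndarray
    rel_error: float

    def component(self, r: int) -> Filter:
        return Filter(
            self.singular_values[r]
            * np.outer(self.spatial_kernels[:, r], self.temporal_kernels[:, r])
        )


def _model_rate(model, design) -> np.ndarray:
    if isinstance(model, NeuronSpec):
        return neuron_rate(model, design)
    if isinstance(model, GNMModel):
        return model.predict(design)
    raise TypeError("model must be a NeuronSpec or GNMModel")


def _model_shape(model) -> tuple[int, int]:
    filt = model.filters[0]
    w = filt.weights if isinstance(filt, Filter) else np.asarray(filt)
    if w.ndim != 2:
        raise ValueError("grating tuning requires 1-D-space (x, lag) filters")
    return w.shape


def grating_tuning(
    model,
    sf_grid,
    tf_grid,
    n_cycles: int = 6,
    frame_rate_hz: float = 100.0,
) -> TuningMetrics:
    """Measure DSI and MI from simulated responses to drifting gratings.

    Gratings at every (spatial frequency, temporal frequency, direction)
    combination are presented; one transient cycle is discarded and the mean
    rate is computed over an integer number of steady-state cycles. The
    preferred grating maximizes the mean rate; Rp/Rnp are the mean rates in the
    two directions at the preferred parameters, F1 is the response amplitude at
    the grating temporal frequency and DC the mean rate, both at the preferred
    grating.
    """
    sf_grid = np.atleast_1d(np.asarray(sf_grid, dtype=np.float64))
    tf_grid = np.atleast_1d(np.asarray(tf_grid, dtype=np.float64))
    if sf_grid.size == 0 or tf_grid.size == 0:
        raise ValueError("frequency grids must be non-empty")
    if n_cycles < 4:
        raise ValueError("need at least 4 steady-state cycles")
    n_x, n_lags = _model_shape(model)
    mean_rates: dict[tuple, float] = {}
    traces: dict[tuple, tuple[np.ndarray, int]] = {}
    for sf in sf_grid:
        for tf in tf_grid:
            frames_per_cycle = frame_rate_hz / tf
            window = int(round(n_cycles * frames_per_cycle))
            skip = n_lags - 1 + int(np.ceil(frames_per_cycle))  # padding + 1 cycle
            n_frames = skip + window
            for direction in (1, -1):
                movie = generate_grating(
                    n_x, n_frames, sf, tf, direction=direction, frame_rate_hz=frame_rate_hz
                )
                design = embed_stimulus(movie, n_lags)
                rate = _model_rate(model, design)[skip:]
                key = (float(sf), float(tf), direction)
                mean_rates[key] = float(rate.mean())
                traces[key] = (rate, window)
    pref_key = max(mean_rates, key=mean_rates.get)
    sf, tf, direction = pref_key
    rp = mean_rates[pref_key]
    rnp = mean_rates[(sf, tf, -direction)]
    dsi = (rp - rnp) / (rp + rnp) if rp + rnp > 0 else 0.0
    rate, window = traces[pref_key]
    dc = rate.mean()
    if dc <= 0:
        raise ValueError("zero mean rate at the preferred grating; MI undefined")
    t = np.arange(window)
    f1 = 2 * np.abs(np.sum(rate * np.exp(-2j * np.pi * tf * t / frame_rate_hz))) / window
    return TuningMetrics(
        dsi=float(dsi),
        mi=float(f1 / dc),
        preferred={"spatial_freq": sf, "temporal_freq": tf, "direction": direction},
        rates=mean_rates,
    )


def dsi_from_rf(filt: Filter | np.ndarray) -> float:
    """Direction-selectivity index of an x-t filter from its 2-D Fourier power.

    DSI_RF = (Q1 - Q2)/(Q1 + Q2), where Q1 and Q2 are the total power in the
    two upper quadrants of the centered 2-D DFT. The zero-frequency row/column
    (shared by both quadrants) and, for even dimensions, the unpaired Nyquist
    frequency are excluded, so that any real separable filter gives exactly 0.
    The quadrant orientation is chosen so the sign agrees with the rate-based
    DSI of the same filter in an LN cascade (positive for a filter preferring
    motion toward +x).
    """
    w = filt.weights if isinstance(filt, Filter) else np.asarray(filt)
    if w.ndim != 2:
        raise ValueError("dsi_from_rf requires a 2-D x-t filter")
    if not np.any(w):
        raise ValueError("all-zero filter")
    P = np.abs(np.fft.fftshift(np.fft.fft2(w))) ** 2
    fx = np.fft.fftshift(np.fft.fftfreq(w.shape[0]))
    ft = np.fft.fftshift(np.fft.fftfreq(w.shape[1]))
    # exclude the Nyquist bin (present only at -0.5 for even sizes): it has no
    # positive-frequency partner and would bias the quadrant comparison
    q1 = P[np.ix_(fx > 0, ft > 0)].sum()
    q2 = P[np.ix_((fx < 0) & (fx > -0.5), ft > 0)].sum()
    return float((q1 - q2) / (q1 + q2))


def svd_separable(filt: Filter | np.ndarray, rank: int) -> SeparableDecomposition:
    """Decompose an x-t filter into space-time-separable components by SVD."""
    w = filt.weights if isinstance(filt, Filter) else np.asarray(filt)
    if w.ndim != 2:
        raise ValueError("svd_separable requires a 2-D x-t filter")
    if rank > min(w.shape):
        raise ValueError("rank cannot exceed min(n_x, n_lags)")
    U, s, Vt = np.linalg.svd(w, full_matrices=False)
    recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
    denom = np.linalg.norm(w)
    rel = float(np.linalg.norm(w - recon) / denom) if denom > 0 else 0.0
    return SeparableDecomposition(
        spatial_kernels=U[:, :rank],
        temporal_kernels=Vt[:rank].T,
        singular_values=s,
        rank_kept=rank,
        reconstruction=recon,
        rel_error=rel,
    )


def estimate_orientation(filter3d: np.ndarray) -> float:
    """Preferred-motion axis of an (x, y, lag) filter, in radians.

    Estimated as the dominant orientation of the spatial power spectrum at the
    lag with maximal spatial power. Raises for near-isotropic filters whose
    orientation is undefined.
    """
    w = np.asarray(filter3d)
    if w.ndim != 3:
        raise ValueError("expected an (x, y, lag) filter")
    power_per_lag = w.var(axis=(0, 1))
    plane = w[:, :, int(np.argmax(power_per_lag))]
    P = np.abs(np.fft.fftshift(np.fft.fft2(plane))) ** 2
    fx = np.fft.fftshift(np.fft.fftfreq(plane.shape[0]))[:, None]
    fy = np.fft.fftshift(np.fft.fftfreq(plane.shape[1]))[None, :]
    P = P.copy()
    P[(fx == 0) & (fy == 0)] = 0.0
    if P.max() <= 0:
        raise ValueError("orientation undefined for an all-zero plane")
    # second-moment (structure-tensor) orientation of the power distribution
    sxx = float(np.sum(P * fx * fx))
    syy = float(np.sum(P * fy * fy))
    sxy = float(np.sum(P * fx * fy))
    anisotropy = np.hypot(sxx - syy, 2 * sxy) / max(sxx + syy, 1e-300)
    if anisotropy < 0.1:
        raise ValueError(
            "filter spatial spectrum is nearly isotropic; supply an orientation"
        )
    return float(0.5 * np.arctan2(2 * sxy, sxx - syy))


def project_preferred_axis(
    filter3d: np.ndarray | Filter, orientation: float | None = None
) -> Filter:
    """Project an (x, y, lag) filter onto its preferred-motion axis.

    The spatial frame is rotated so the preferred axis is horizontal, then
    summed over the orthogonal spatial coordinate, producing an x-t filter
    directly comparable with bar-stimulus receptive fields.
    """
    w = filter3d.weights if isinstance(filter3d, Filter) else np.asarray(filter3d)
    if w.ndim != 3:
        raise ValueError("expected an (x, y, lag) filter")
    if orientation is None:
        orientation = estimate_orientation(w)
    deg = -np.degrees(orientation)
    out = np.empty((w.shape[0], w.shape[2]))
    for lag in range(w.shape[2]):
        plane = w[:, :, lag]
        if deg % 360 != 0:
            plane = ndimage.rotate(plane, deg, reshape=False, order=1, mode="constant")
        out[:, lag] = plane.sum(axis=1)
    return Filter(out)
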