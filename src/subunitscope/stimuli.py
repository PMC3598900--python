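"""Stimulus ensembles for receptive-field mapping and their time-embedded design matrices.

Three stimulus classes are provided, mirroring the ensembles in common use for
system identification of visual cortex:

* **random bars** -- black/white bars whose contrasts follow a binary maximal-length
  shift-register (m-)sequence, presented at the monitor frame rate (typically 100 Hz);
* **drifting sinusoidal gratings** -- the classical stimulus for measuring direction
  selectivity and response modulation;
* **spatiotemporal pink noise** -- Gaussian noise with a 1/f amplitude spectrum over
  radial spatiotemporal frequency, a stand-in for naturalistic movies.

A movie is turned into an estimation-ready :class:`DesignMatrix` by temporal
embedding: row *t* concatenates the stimulus frames at lags 0..n_lags-1, so that
spike-triggered and likelihood-based estimators see the full spatiotemporal
stimulus history that can drive the response in bin *t*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusMovie",
    "DesignMatrix",
    "generate_bar_stimulus",
    "generate_grating",
    "generate_pink_noise_movie",
    "embed_stimulus",
    "mseq",
]

# Feedback taps of primitive polynomials over GF(2), one per register length
# (Fibonacci LFSR convention). Each yields a maximal-length sequence of period
# 2**order - 1. Fixed table so bar movies are bit-reproducible.
_PRIMITIVE_TAPS: dict[int, tuple[int, ...]] = {
    2: (2, 1),
    3: (3, 2),
    4: (4, 3),
    5: (5, 3),
    6: (6, 5),
    7: (7, 6),
    8: (8, 6, 5, 4),
    9: (9, 5),
    10: (10, 7),
    11: (11, 9),
    12: (12, 6, 4, 1),
    13: (13, 4, 3, 1),
    14: (14, 5, 3, 1),
    15: (15, 14),
    16: (16, 15, 13, 4),
}


@dataclass
class StimulusMovie:
    """A zero-mean contrast movie on a 1-D bar grid or 2-D pixel grid.

    Parameters
    ----------
    values
        Contrast array of shape ``(n_x, n_frames)`` or ``(n_x, n_y, n_frames)``.
    frame_rate_hz
        Presentation rate in frames per second.
    kind
        Tag in ``{"bars", "grating", "pink_noise", "custom"}``.
    """

    values: np.ndarray
    frame_rate_hz: float
    kind: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ValueError("movie must be (n_x, n_frames) or (n_x, n_y, n_frames)")
        if self.n_frames < 1:
            raise ValueError("movie needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.values.shape[-1]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.values.shape[:-1]

    @property
    def n_space(self) -> int:
        return int(np.prod(self.spatial_shape))

    def flat(self) -> np.ndarray:
        """Values reshaped to (n_space, n_frames), C-order over space."""
        return self.values.reshape(self.n_space, self.n_frames)


@dataclass
class DesignMatrix:
    """Time-embedded stimulus: one row per frame, columns (space-major, lag-minor).

    Column ``s * n_lags + l`` of row ``t`` holds the stimulus at flattened spatial
    position ``s`` and frame ``t - l`` (lag 0 is the frame in the same bin as the
    response). Rows with ``t < n_lags - 1`` contain zero padding for the missing
    history and are flagged in :attr:`padded`; estimators exclude them.
    """

    X: np.ndarray
    n_lags: int
    spatial_shape: tuple[int, ...]
    frame_rate_hz: float
    padded: np.ndarray = field(repr=False)

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_space(self) -> int:
        return int(np.prod(self.spatial_shape))

    @property
    def valid(self) -> np.ndarray:
        return ~self.padded

    def filter_shape(self) -> tuple[int, ...]:
        return (*self.spatial_shape, self.n_lags)


def mseq(order: int) -> np.ndarray:
    """One period of the binary maximal-length sequence of the given register order.

    Returns an array of 0/1 bits with length ``2**order - 1``. The feedback taps
    come from a fixed table of primitive polynomials (orders 2-16), so the output
    is fully deterministic.
    """
    if order not in _PRIMITIVE_TAPS:
        raise ValueError(
            f"no primitive polynomial stored for order {order}; supported orders: "
            f"{sorted(_PRIMITIVE_TAPS)}"
        )
    taps = _PRIMITIVE_TAPS[order]
    period = 2**order - 1
    reg = np.ones(order, dtype=np.uint8)
    bits = np.empty(period, dtype=np.uint8)
    for i in range(period):
        bits[i] = reg[-1]
        fb = 0
        for t in taps:
            fb ^= reg[t - 1]
        reg[1:] = reg[:-1]
        reg[0] = fb
    return bits


def generate_bar_stimulus(
    n_bars: int, n_frames: int, mseq_order: int = 15, frame_rate_hz: float = 100.0
) -> StimulusMovie:
    """Random-bar movie: +/-1 bar contrasts read off a binary m-sequence.

    Each frame takes the next window of ``n_bars`` consecutive bits from the
    m-sequence (cycling through its period), mapped {0 -> +1, 1 -> -1}.
    Deterministic for fixed order: no RNG is involved.
    """
    if mseq_order < 2:
        raise ValueError("mseq_order must be >= 2")
    if 2**mseq_order - 1 < n_bars:
        raise ValueError("m-sequence period must be at least n_bars")
    if n_bars < 1 or n_frames < 1:
        raise ValueError("n_bars and n_frames must be positive")
    bits = mseq(mseq_order)
    idx = np.arange(n_bars * n_frames) % bits.size
    vals = 1.0 - 2.0 * bits[idx].astype(np.float64)
    return StimulusMovie(
        values=vals.reshape(n_frames, n_bars).T,
        frame_rate_hz=frame_rate_hz,
        kind="bars",
    )


def generate_grating(
    n_bars: int,
    n_frames: int,
    spatial_freq: float,
    temporal_freq: float,
    direction: int = 1,
    frame_rate_hz: float = 100.0,
) -> StimulusMovie:
    """Drifting sinusoidal grating sampled on a bar grid.

    ``value(x, t) = cos(2 pi (spatial_freq * x / n_bars - direction * temporal_freq
    * t / frame_rate_hz))`` with unit contrast amplitude. ``spatial_freq`` is in
    cycles per stimulus width, ``temporal_freq`` in Hz; ``direction`` is +1 or -1.
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    if abs(temporal_freq) >= frame_rate_hz / 2:
        raise ValueError("temporal_freq must be below the Nyquist rate frame_rate_hz/2")
    x = np.arange(n_bars)[:, None]
    t = np.arange(n_frames)[None, :]
    phase = 2 * np.pi * (
        spatial_freq * x / n_bars - direction * temporal_freq * t / frame_rate_hz
    )
    return StimulusMovie(values=np.cos(phase), frame_rate_hz=frame_rate_hz, kind="grating")


def generate_pink_noise_movie(
    n_x: int,
    n_y: int,
    n_frames: int,
    exponent: float = 1.0,
    seed: int | None = None,
    frame_rate_hz: float = 50.0,
) -> StimulusMovie:
    """Spatiotemporal 1/f noise by Fourier-domain amplitude shaping.

    Seeded Gaussian white noise is transformed to the 3-D Fourier domain and its
    amplitude scaled by ``1 / f**exponent`` of the radial spatiotemporal frequency
    (axes in cycles/sample); the DC term is zeroed. The result is standardized to
    zero mean and unit variance. ``exponent=0`` reduces to white noise.
    """
    if n_x < 2 or n_y < 2 or n_frames < 2:
        raise ValueError("each dimension must be at least 2")
    if seed is None:
        raise ValueError("seed is required for reproducible pink noise")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_x, n_y, n_frames))
    spec = np.fft.fftn(white)
    fx = np.fft.fftfreq(n_x)[:, None, None]
    fy = np.fft.fftfreq(n_y)[None, :, None]
    ft = np.fft.fftfreq(n_frames)[None, None, :]
    radial = np.sqrt(fx**2 + fy**2 + ft**2)
    with np.errstate(divide="ignore"):
        amp = np.where(radial > 0, radial ** (-exponent), 0.0)
    vals = np.fft.ifftn(spec * amp).real
    vals -= vals.mean()
    vals /= vals.std()
    return StimulusMovie(values=vals, frame_rate_hz=frame_rate_hz, kind="pink_noise")


def embed_stimulus(movie: StimulusMovie, n_lags: int) -> DesignMatrix:
    """Temporally embed a movie: row t holds frames t, t-1, ..., t-(n_lags-1).

    Columns are ordered space-major, lag-minor, matching the C-order flattening
    of a ``(spatial..., n_lags)`` filter grid. The first ``n_lags - 1`` rows are
    zero-padded and flagged.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if n_lags > movie.n_frames:
        raise ValueError("n_lags cannot exceed the number of frames")
    vals = movie.flat()  # (n_space, n_frames)
    n_space, n_frames = vals.shape
    emb = np.zeros((n_frames, n_space, n_lags), dtype=np.float64)
    for lag in range(n_lags):
        emb[lag:, :, lag] = vals[:, : n_frames - lag].T
    padded = np.zeros(n_frames, dtype=bool)
    padded[: n_lags - 1] = True
    return DesignMatrix(
        X=emb.reshape(n_frames, n_space * n_lags),
        n_lags=n_lags,
        spatial_shape=movie.spatial_shape,
        frame_rate_hz=movie.frame_rate_hz,
        padded=padded,
    )
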