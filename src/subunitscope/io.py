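"""HDF5 dataset container and plain-text spike-time ingestion.

Layout of the container::

    /stimulus          contrast array, (n_x, n_frames) or (n_x, n_y, n_frames)
    /frame_rate_hz     scalar
    /kind              stimulus tag (bars | grating | pink_noise | custom)
    /spikes            per-frame spike counts (optional)
    /ground_truth/filters   (n_filters, *spatial, n_lags) array (optional)

Spike trains may alternatively be given as a text file with one spike time per
line (seconds); they are binned at the stimulus frame rate, counting times in
[t, t + dt).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .neurons import Filter, SpikeCounts
from .stimuli import StimulusMovie

__all__ = ["write_dataset", "read_dataset", "bin_spike_times", "read_spike_times"]


def write_dataset(
    path,
    movie: StimulusMovie,
    spikes: SpikeCounts | None = None,
    ground_truth: list[Filter] | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("stimulus", data=movie.values)
        f.create_dataset("frame_rate_hz", data=float(movie.frame_rate_hz))
        f.create_dataset("kind", data=movie.kind)
        if spikes is not None:
            if len(spikes) != movie.n_frames:
                raise ValueError("spike counts and movie have different lengths")
            f.create_dataset("spikes", data=spikes.counts)
        if ground_truth:
            f.create_dataset(
                "ground_truth/filters", data=np.stack([k.weights for k in ground_truth])
            )


def read_dataset(path):
    """Read (movie, spikes-or-None, ground-truth filters-or-None) from a container."""
    with h5py.File(path, "r") as f:
        if "stimulus" not in f:
            raise ValueError(f"{path}: missing required dataset /stimulus")
        vals = f["stimulus"][()]
        rate = float(f["frame_rate_hz"][()]) if "frame_rate_hz" in f else 100.0
        kind = f["kind"][()] if "kind" in f else "custom"
        if isinstance(kind, bytes):
            kind = kind.decode()
        movie = StimulusMovie(values=vals, frame_rate_hz=rate, kind=str(kind))
        spikes = None
        if "spikes" in f:
            counts = f["spikes"][()]
            if not np.issubdtype(counts.dtype, np.integer):
                if not np.allclose(counts, np.rint(counts)):
                    raise ValueError(f"{path}: /spikes must hold integer counts")
                counts = np.rint(counts).astype(np.int64)
            if counts.size != movie.n_frames:
                raise ValueError(
                    f"{path}: spike counts ({counts.size}) and movie frames "
                    f"({movie.n_frames}) are misaligned"
                )
            spikes = SpikeCounts(counts)
        truth = None
        if "ground_truth/filters" in f:
            truth = [Filter(w) for w in f["ground_truth/filters"][()]]
    return movie, spikes, truth


def bin_spike_times(times, frame_rate_hz: float, n_frames: int) -> SpikeCounts:
    """Bin spike times (seconds) into per-frame counts over [0, n_frames/rate)."""
    times = np.asarray(times, dtype=np.float64)
    dt = 1.0 / frame_rate_hz
    edges = np.arange(n_frames + 1) * dt
    counts, _ = np.histogram(times, bins=edges)
    return SpikeCounts(counts)


def read_spike_times(path, frame_rate_hz: float, n_frames: int) -> SpikeCounts:
    """Read one-spike-time-per-line text (seconds) and bin at the frame rate."""
    times = [float(line) for line in Path(path).read_text().split()]
    return bin_spike_times(times, frame_rate_hz, n_frames)
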