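"""Core data types shared by simulators and estimators.

Stimulus-response data is represented by three small containers:

* :class:`StimulusEnsemble` — a ``T × D`` design matrix whose row ``t`` holds
  the lagged stimulus history preceding (and including) time bin ``t``,
  flattened lag-major (oldest lag first, channels contiguous within a lag).
* :class:`BinaryResponse` — per-bin spike labels in ``{-1, +1}`` together with
  the raw spike counts they were derived from.
* :class:`LinearFilter` — an estimated or ground-truth receptive field:
  weight vector ``k`` of length ``D = n_lags * n_channels`` plus a spiking
  threshold ``theta`` (the negated bias of the separating hyperplane).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusEnsemble",
    "BinaryResponse",
    "LinearFilter",
    "build_lagged_design",
    "binarize_counts",
    "center_design",
    "save_container",
    "load_container",
]


@dataclass
class StimulusEnsemble:
    """Time-indexed ensemble of lagged stimulus vectors.

    Parameters
    ----------
    X : ndarray, shape (T, D)
        One row per time bin; ``D = n_lags * n_channels``.  Units are
        z-scored stimulus amplitude or log-compressed spectral energy.
    n_lags : int
        Number of time lags per row.
    n_channels : int
        Number of stimulus channels (frequency bands, pixels, ...).
    dt : float, optional
        Bin width in seconds.
    channel_freqs : ndarray, optional
        Center frequencies of the channels in Hz.
    """

    X: np.ndarray
    n_lags: int
    n_channels: int
    dt: float | None = None
    channel_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D array (T rows, D columns)")
        if self.n_lags < 1 or self.n_channels < 1:
            raise ValueError("n_lags and n_channels must be positive")
        if self.X.shape[1] != self.n_lags * self.n_channels:
            raise ValueError(
                f"D={self.X.shape[1]} does not equal "
                f"n_lags*n_channels={self.n_lags * self.n_channels}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("stimulus matrix contains non-finite entries")
        if self.X.shape[0] < self.X.shape[1]:
            warnings.warn(
                "fewer time bins than stimulus dimensions (T < D); "
                "estimates will be strongly regularization-dependent",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_dim(self) -> int:
        return self.X.shape[1]


@dataclass
class BinaryResponse:
    """Per-bin spike labels in {-1, +1} plus the raw counts."""

    labels: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.counts = np.asarray(self.counts)
        if self.labels.shape != self.counts.shape:
            raise ValueError("labels and counts must have the same shape")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must take values in {-1, +1}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.array_equal(self.labels == 1, self.counts >= 1):
            raise ValueError("labels[t] must be +1 exactly where counts[t] >= 1")

    @property
    def n_spikes(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def spike_fraction(self) -> float:
        return self.n_spikes / self.labels.size


@dataclass
class LinearFilter:
    """Receptive-field estimate: weights ``k`` and spiking threshold ``theta``.

    ``theta`` is the negated bias of the separating hyperplane: the model
    predicts a spike when ``k . x > theta``.
    """

    k: np.ndarray
    theta: float
    n_lags: int
    n_channels: int

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float).ravel()
        if self.k.size != self.n_lags * self.n_channels:
            raise ValueError("filter length must equal n_lags * n_channels")
        if not (np.all(np.isfinite(self.k)) and np.isfinite(self.theta)):
            raise ValueError("filter entries and theta must be finite")

    def as_matrix(self) -> np.ndarray:
        """Reshape to (n_lags, n_channels); row 0 is the oldest lag."""
        return self.k.reshape(self.n_lags, self.n_channels)

    def project(self, ens: StimulusEnsemble) -> np.ndarray:
        """Projections ``k . x_t`` of an ensemble onto the filter."""
        if ens.n_dim != self.k.size:
            raise ValueError("ensemble dimensionality does not match filter")
        return ens.X @ self.k

    def normalized(self) -> "LinearFilter":
        nrm = float(np.linalg.norm(self.k))
        if nrm == 0:
            raise ValueError("cannot normalize an all-zero filter")
        return LinearFilter(self.k / nrm, self.theta / nrm, self.n_lags, self.n_channels)


def build_lagged_design(series: np.ndarray, n_lags: int, *, dt: float | None = None,
                        channel_freqs: np.ndarray | None = None) -> StimulusEnsemble:
    """Recast a multichannel time series into lagged stimulus vectors.

    Row ``t`` of the output concatenates the series rows
    ``t - n_lags + 1 ... t`` (oldest first, channels contiguous within a
    lag), so each row holds the stimulus history that could causally drive a
    response in bin ``t``.  Bins before the start of the recording are
    zero-padded, keeping the number of rows equal to the series length.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    if series.ndim != 2:
        raise ValueError("series must be 1-D or 2-D")
    T, n_channels = series.shape
    if T < 1:
        raise ValueError("series must contain at least one time bin")
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if n_lags > T:
        raise ValueError(f"n_lags={n_lags} exceeds series length T={T}")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")

    padded = np.vstack([np.zeros((n_lags - 1, n_channels)), series])
    windows = np.lib.stride_tricks.sliding_window_view(padded, n_lags, axis=0)
    # windows: (T, n_channels, n_lags) with last axis ordered oldest->newest
    X = np.ascontiguousarray(windows.transpose(0, 2, 1)).reshape(T, n_lags * n_channels)
    return StimulusEnsemble(X, n_lags=n_lags, n_channels=n_channels, dt=dt,
                            channel_freqs=channel_freqs)


def binarize_counts(counts: np.ndarray) -> BinaryResponse:
    """Collapse spike counts to ±1 labels (multi-spike bins map to +1)."""
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integer-valued")
        counts = np.round(counts).astype(np.int64)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    labels = np.where(counts >= 1, 1, -1)
    return BinaryResponse(labels=labels, counts=counts)


def center_design(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove per-column means; returns (centered matrix, column means)."""
    mu = X.mean(axis=0)
    return X - mu, mu


def save_container(path, ens: StimulusEnsemble, counts: np.ndarray | None = None,
                   **extra_datasets) -> None:
    """Write an ensemble (and optional counts) to an HDF5 container.

    Layout: datasets ``/stimulus`` and ``/counts``; attributes ``dt``,
    ``n_lags``, ``n_channels`` and, if present, ``channel_freqs``.
    """
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("stimulus", data=ens.X)
        d.attrs["n_lags"] = ens.n_lags
        d.attrs["n_channels"] = ens.n_channels
        if ens.dt is not None:
            d.attrs["dt"] = ens.dt
        if ens.channel_freqs is not None:
            d.attrs["channel_freqs"] = np.asarray(ens.channel_freqs, dtype=float)
        if counts is not None:
            f.create_dataset("counts", data=np.asarray(counts, dtype=np.int64))
        for name, arr in extra_datasets.items():
            f.create_dataset(name, data=np.asarray(arr))


def load_container(path) -> tuple[StimulusEnsemble, np.ndarray | None]:
    """Read an ensemble (and counts, if stored) back from an HDF5 container."""
    import h5py

    with h5py.File(path, "r") as f:
        d = f["stimulus"]
        ens = StimulusEnsemble(
            d[()],
            n_lags=int(d.attrs["n_lags"]),
            n_channels=int(d.attrs["n_channels"]),
            dt=float(d.attrs["dt"]) if "dt" in d.attrs else None,
            channel_freqs=np.asarray(d.attrs["channel_freqs"])
            if "channel_freqs" in d.attrs else None,
        )
        counts = f["counts"][()] if "counts" in f else None
    return ens, counts
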