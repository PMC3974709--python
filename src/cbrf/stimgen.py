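"""Synthetic stimulus ensembles and ground-truth receptive fields.

The generators reproduce the stimulus regimes used to probe RF estimators:

* skewed (asymmetric) white noise — i.i.d. but non-Gaussian marginals;
* whitened sinusoid-grating image patches — spherically symmetric second
  order, but with higher-order dependencies between pixels;
* frequency-modulated (FM) tone complexes — naturalistic auditory stimuli
  with strong higher-order spectro-temporal correlations, rendered as
  waveforms and passed through a log-compressed band-pass filterbank
  front-end (a gammatone-like cochlear approximation);
* correlated spectrograms — Gaussian noise shaped to a 1/f^alpha temporal
  spectrum with smooth cross-channel correlation and optional skewing, a
  synthetic stand-in for speech/vocalization spectrograms.

Ground-truth filters (temporal onset detector, 2-D Gabor, separable
spectro-temporal onset) are unit-norm :class:`~cbrf.datamodel.LinearFilter`
instances used to drive the response simulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .datamodel import LinearFilter

__all__ = [
    "FMComplexSpec",
    "GroundTruthFilter",
    "WhiteningTransform",
    "gen_skewed_white_noise",
    "gen_gratings",
    "whiten_ensemble",
    "gen_fm_complex",
    "save_waveform_wav",
    "spectrogram_frontend",
    "gen_correlated_spectrogram",
    "make_ground_truth",
]


# ---------------------------------------------------------------------------
# skewed white noise


def gen_skewed_white_noise(n: int, skew_exponent: float = 2.0,
                           seed: int | np.random.Generator | None = None) -> np.ndarray:
    """I.i.d. positively skewed white noise.

    Gaussian draws are passed through the asymmetric power transform
    ``x -> |x|**skew_exponent`` for positive and ``x -> -|x|**(1/skew_exponent)``
    for negative amplitudes (expansion of positive, compression of negative
    values), then re-centered to zero mean.  The transform acts pointwise, so
    the auto-covariance stays diagonal while the marginal acquires a long
    positive tail.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if skew_exponent <= 1:
        raise ValueError("skew_exponent must exceed 1 (1 leaves the Gaussian unchanged)")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n)
    x = np.where(g > 0, np.abs(g) ** skew_exponent, -np.abs(g) ** (1.0 / skew_exponent))
    return x - x.mean()


# ---------------------------------------------------------------------------
# gratings and whitening


def gen_gratings(n_patches: int, size: int,
                 seed: int | np.random.Generator | None = None,
                 freq_band: tuple[float, float] = (1.0, 6.0),
                 orientation: float | None = None,
                 frequency: float | None = None,
                 phase: float | None = None) -> np.ndarray:
    """Random sinusoid gratings, flattened row-major to (n_patches, size**2).

    Orientation ~ U[0, pi), spatial frequency ~ U[freq_band] in cycles per
    patch, phase ~ U[0, 2*pi); each may be pinned to a fixed value instead.
    Amplitude is unit, so values lie in [-1, 1].
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    rng = np.random.default_rng(seed)
    theta = np.full(n_patches, orientation) if orientation is not None \
        else rng.uniform(0, np.pi, n_patches)
    freq = np.full(n_patches, frequency) if frequency is not None \
        else rng.uniform(*freq_band, n_patches)
    phase = np.full(n_patches, phase) if phase is not None \
        else rng.uniform(0, 2 * np.pi, n_patches)

    coords = np.arange(size) / size  # patch coordinates in [0, 1)
    ii, jj = np.meshgrid(coords, coords, indexing="ij")
    # phase plane per patch: f * (i cos t + j sin t)
    arg = (freq[:, None, None]
           * (ii[None] * np.cos(theta)[:, None, None]
              + jj[None] * np.sin(theta)[:, None, None]))
    patches = np.sin(2 * np.pi * arg + phase[:, None, None])
    return patches.reshape(n_patches, size * size)


@dataclass
class WhiteningTransform:
    """ZCA whitening transform ``x_w = W (x - mean)`` with its inverse.

    A filter ``k_w`` fitted in whitened coordinates corresponds to
    ``W @ k_w`` in original stimulus coordinates (W is symmetric).
    """

    W: np.ndarray
    W_inv: np.ndarray
    mean: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) @ self.W.T

    def filter_to_original(self, k_w: np.ndarray) -> np.ndarray:
        """Map a filter from whitened back to original stimulus space."""
        return self.W @ k_w

    def filter_to_whitened(self, k: np.ndarray) -> np.ndarray:
        return self.W_inv @ k


def whiten_ensemble(X: np.ndarray, eig_floor: float = 1e-10
                    ) -> tuple[np.ndarray, WhiteningTransform]:
    """Remove second-order correlations by ZCA whitening.

    Eigenvalues of the sample covariance below ``eig_floor`` times the
    largest are floored (with a warning) so rank-deficient ensembles still
    yield a usable transform.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than columns to estimate covariance")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    floor = eig_floor * evals.max()
    if np.any(evals < floor):
        warnings.warn("rank-deficient covariance: eigenvalue floor applied",
                      stacklevel=2)
        evals = np.maximum(evals, floor)
    W = evecs @ np.diag(evals ** -0.5) @ evecs.T
    W_inv = evecs @ np.diag(evals ** 0.5) @ evecs.T
    tf = WhiteningTransform(W=W, W_inv=W_inv, mean=mean)
    return Xc @ W.T, tf


# ---------------------------------------------------------------------------
# FM tone complexes


@dataclass
class FMComplexSpec:
    """Parameters of a frequency-modulated tone-complex stimulus.

    ``block`` mode tiles the stimulus with contiguous blocks of length
    ``block_len`` seconds, each containing ``sweeps_per_block`` simultaneous
    linear FM sweeps with start/end frequencies drawn uniformly from
    ``[f_lo, f_hi]``.  ``continuous`` mode draws sweep onsets as a
    homogeneous point process whose rate is tuned so the time-averaged
    number of concurrent sweeps falls inside ``target_density``.
    """

    mode: str = "block"
    f_lo: float = 500.0
    f_hi: float = 16000.0
    block_len: float = 0.1
    sweeps_per_block: int = 4
    target_density: tuple[float, float] = (3.0, 4.0)
    ramp_len: float = 0.005
    duration: float = 1.0
    sample_rate: float = 44100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("block", "continuous"):
            raise ValueError("mode must be 'block' or 'continuous'")
        if not (0 < self.f_lo < self.f_hi < self.sample_rate / 2):
            raise ValueError("require 0 < f_lo < f_hi < sample_rate/2")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if 2 * self.ramp_len >= self.block_len:
            raise ValueError("ramps must fit inside a sweep")


def _sweep(f0: float, f1: float, n: int, fs: float, n_ramp: int) -> np.ndarray:
    """Unit-amplitude linear FM sweep with half-cosine on/off ramps."""
    t = np.arange(n) / fs
    T = n / fs
    phase = 2 * np.pi * (f0 * t + (f1 - f0) * t ** 2 / (2 * T))
    w = np.sin(phase)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        w[:n_ramp] *= ramp
        w[-n_ramp:] *= ramp[::-1]
    return w


def gen_fm_complex(spec: FMComplexSpec) -> np.ndarray:
    """Render an FM sweep complex waveform according to ``spec``."""
    fs = spec.sample_rate
    rng = np.random.default_rng(spec.seed)
    n_total = int(round(spec.duration * fs))
    n_sweep = int(round(spec.block_len * fs))
    n_ramp = int(round(spec.ramp_len * fs))
    wave = np.zeros(n_total)

    def add_sweep(start: int) -> None:
        f0, f1 = rng.uniform(spec.f_lo, spec.f_hi, 2)
        n = min(n_sweep, n_total - start)
        if n <= 2 * n_ramp:
            return
        wave[start:start + n] += _sweep(f0, f1, n, fs, n_ramp)

    if spec.mode == "block":
        n_blocks = n_total // n_sweep
        for b in range(n_blocks):
            for _ in range(spec.sweeps_per_block):
                add_sweep(b * n_sweep)
    else:
        lo, hi = spec.target_density
        target = 0.5 * (lo + hi)
        # mean concurrent sweeps = onset rate * sweep length; bisect the rate
        # against the empirically realized density of the drawn onset times
        rate_lo, rate_hi = 0.5 * lo / spec.block_len, 2.0 * hi / spec.block_len
        for _ in range(30):
            rate = 0.5 * (rate_lo + rate_hi)
            n_onsets = rng.poisson(rate * spec.duration)
            onsets = np.sort(rng.uniform(0, spec.duration, n_onsets))
            density = n_onsets * spec.block_len / spec.duration
            if lo <= density <= hi:
                break
            if density < target:
                rate_lo = rate
            else:
                rate_hi = rate
        for t0 in onsets:
            add_sweep(int(t0 * fs))
    return wave


def save_waveform_wav(path, waveform: np.ndarray, sample_rate: float) -> None:
    """Write a waveform as 16-bit single-channel WAV (peak-normalized)."""
    from scipy.io import wavfile

    w = np.asarray(waveform, dtype=float)
    peak = np.abs(w).max()
    if peak > 0:
        w = w / peak * 0.99
    wavfile.write(path, int(round(sample_rate)), (w * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# spectrogram front-end


def spectrogram_frontend(waveform: np.ndarray, sample_rate: float,
                         f_lo: float = 500.0, f_hi: float = 8000.0,
                         n_channels: int = 45, dt: float = 0.002,
                         dynamic_range_db: float = 25.0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Log-compressed band-pass filterbank spectrogram (cochlear front-end).

    A bank of 4th-order band-pass filters with log-spaced center frequencies
    between ``f_lo`` and ``f_hi`` approximates a gammatone filterbank.  The
    Hilbert envelope of each band is log-compressed (floor at
    ``dynamic_range_db`` below the ensemble maximum) and frame-averaged to
    bins of width ``dt``.

    Returns
    -------
    S : ndarray, shape (T, n_channels)
        Spectrogram in dB relative to the floor.
    centers : ndarray
        Channel center frequencies in Hz.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if f_hi >= sample_rate / 2:
        raise ValueError("f_hi must be below the Nyquist frequency")
    waveform = np.asarray(waveform, dtype=float)
    centers = np.geomspace(f_lo, f_hi, n_channels)
    # band edges at geometric means of neighboring centers
    edges = np.sqrt(centers[:-1] * centers[1:])
    lo_edges = np.concatenate([[centers[0] / (edges[0] / centers[0])], edges])
    hi_edges = np.concatenate([edges, [centers[-1] * (centers[-1] / edges[-1])]])
    hi_edges = np.minimum(hi_edges, 0.999 * sample_rate / 2)

    envs = np.empty((waveform.size, n_channels))
    for c in range(n_channels):
        sos = signal.butter(2, [lo_edges[c], hi_edges[c]], btype="bandpass",
                            fs=sample_rate, output="sos")  # 4th-order bandpass
        band = signal.sosfilt(sos, waveform)
        envs[:, c] = np.abs(signal.hilbert(band))

    env_max = envs.max()
    if env_max == 0:
        env_max = 1.0
    floor = env_max * 10 ** (-dynamic_range_db / 20)
    S = 20 * np.log10(envs + floor) - 20 * np.log10(floor)

    n_per_bin = max(1, int(round(dt * sample_rate)))
    T = S.shape[0] // n_per_bin
    S = S[: T * n_per_bin].reshape(T, n_per_bin, n_channels).mean(axis=1)
    return S, centers


# ---------------------------------------------------------------------------
# correlated spectrogram (synthetic natural-stimulus stand-in)


def gen_correlated_spectrogram(duration: float, n_channels: int, dt: float,
                               spectral_exponent: float = 1.0,
                               channel_corr_width: float = 2.0,
                               skew_exponent: float | None = 1.5,
                               seed: int | np.random.Generator | None = None,
                               ) -> tuple[np.ndarray, dict]:
    """Gaussian noise shaped to a 1/f^alpha temporal spectrum per channel,
    with smooth cross-channel correlation and optional pointwise skewing.

    This is a fully synthetic spectrogram-like ensemble emulating two
    statistical signatures of natural sounds — temporal 1/f correlations and
    a skewed marginal amplitude distribution — without any recorded audio.

    Returns the ``(T, n_channels)`` matrix and a dict of realized statistics
    (per-channel skewness and lag-1 autocorrelation).
    """
    if spectral_exponent < 0:
        raise ValueError("spectral_exponent must be >= 0")
    T = int(round(duration / dt))
    if T < 8:
        raise ValueError("duration too short for the requested bin width")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((T, n_channels))

    # temporal 1/f^alpha shaping via rFFT amplitude envelope
    freqs = np.fft.rfftfreq(T, d=dt)
    amp = np.ones_like(freqs)
    amp[1:] = freqs[1:] ** (-spectral_exponent / 2)
    spec = np.fft.rfft(noise, axis=0) * amp[:, None]
    shaped = np.fft.irfft(spec, n=T, axis=0)

    # smooth cross-channel mixing with a Gaussian kernel
    if channel_corr_width > 0 and n_channels > 1:
        idx = np.arange(n_channels)
        K = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / channel_corr_width) ** 2)
        K /= np.linalg.norm(K, axis=1, keepdims=True)
        shaped = shaped @ K.T

    shaped /= shaped.std(axis=0, keepdims=True)
    if skew_exponent is not None:
        if skew_exponent <= 1:
            raise ValueError("skew_exponent must exceed 1 (or be None)")
        shaped = np.where(shaped > 0, np.abs(shaped) ** skew_exponent,
                          -np.abs(shaped) ** (1.0 / skew_exponent))
        shaped -= shaped.mean(axis=0, keepdims=True)

    c = shaped - shaped.mean(axis=0, keepdims=True)
    sd = c.std(axis=0)
    stats = {
        "skewness": ((c ** 3).mean(axis=0) / sd ** 3),
        "lag1_autocorr": (c[1:] * c[:-1]).mean(axis=0) / sd ** 2,
    }
    return shaped, stats


# ---------------------------------------------------------------------------
# ground-truth filters


@dataclass
class GroundTruthFilter:
    """A parametric ground-truth RF together with its realized filter."""

    kind: str
    parameters: dict
    filter: LinearFilter


def _temporal_onset(n_lags: int, pos_center: float, lobe_sep: float,
                    width: float) -> np.ndarray:
    """Biphasic onset kernel on the lag axis (index n_lags-1 = most recent).

    Difference of two Gaussians with equal amplitudes: a positive lobe near
    the response bin preceded by a negative lobe, an onset detector.
    """
    lag = np.arange(n_lags)
    t_pos = (n_lags - 1) - pos_center      # positions counted back from "now"
    t_neg = t_pos - lobe_sep
    k = (np.exp(-0.5 * ((lag - t_pos) / width) ** 2)
         - np.exp(-0.5 * ((lag - t_neg) / width) ** 2))
    return k


def make_ground_truth(kind: str, n_lags: int, n_channels: int,
                      parameters: dict | None = None,
                      seed: int | np.random.Generator | None = None,
                      ) -> GroundTruthFilter:
    """Construct a unit-norm ground-truth receptive field.

    Kinds
    -----
    ``temporal_onset``
        Biphasic difference-of-Gaussians in time (n_channels must be 1 unless
        combined separably); parameters: ``pos_center`` (lags back from the
        response bin, default n_lags/8), ``lobe_sep`` (default n_lags/5),
        ``width`` (default n_lags/12).
    ``gabor_2d``
        Oriented Gabor over the (lag, channel) grid; parameters:
        ``orientation`` (rad), ``frequency`` (cycles per patch, default 3),
        ``phase``, ``center`` ((lag, channel) in [0,1] units), ``env_width``.
    ``strf_onset``
        Separable (spectral Gaussian) x (temporal biphasic) spectro-temporal
        onset pattern; parameters: ``center_channel`` (default middle),
        ``channel_width`` (default n_channels/8) plus the temporal_onset
        parameters.
    """
    p = dict(parameters or {})
    rng = np.random.default_rng(seed)

    if kind == "temporal_onset":
        if n_channels != 1:
            raise ValueError("temporal_onset requires n_channels == 1")
        k = _temporal_onset(
            n_lags,
            p.setdefault("pos_center", n_lags / 8),
            p.setdefault("lobe_sep", n_lags / 5),
            p.setdefault("width", n_lags / 12),
        )
    elif kind == "gabor_2d":
        ori = p.setdefault("orientation", rng.uniform(0, np.pi))
        freq = p.setdefault("frequency", 3.0)
        phase = p.setdefault("phase", 0.0)
        cy, cx = p.setdefault("center", (0.5, 0.5))
        w = p.setdefault("env_width", 0.15)
        yy = np.arange(n_lags) / max(n_lags - 1, 1) - cy
        xx = np.arange(n_channels) / max(n_channels - 1, 1) - cx
        Y, X = np.meshgrid(yy, xx, indexing="ij")
        u = Y * np.cos(ori) + X * np.sin(ori)
        env = np.exp(-(Y ** 2 + X ** 2) / (2 * w ** 2))
        k = (env * np.cos(2 * np.pi * freq * u + phase)).ravel()
    elif kind == "strf_onset":
        cc = p.setdefault("center_channel", (n_channels - 1) / 2)
        cw = p.setdefault("channel_width", max(n_channels / 8, 0.75))
        temporal = _temporal_onset(
            n_lags,
            p.setdefault("pos_center", n_lags / 8),
            p.setdefault("lobe_sep", n_lags / 4),
            p.setdefault("width", n_lags / 10),
        )
        spectral = np.exp(-0.5 * ((np.arange(n_channels) - cc) / cw) ** 2)
        k = np.outer(temporal, spectral).ravel()
    else:
        raise ValueError(f"unsupported ground-truth kind: {kind!r}")

    k = k / np.linalg.norm(k)
    filt = LinearFilter(k, theta=0.0, n_lags=n_lags, n_channels=n_channels)
    return GroundTruthFilter(kind=kind, parameters=p, filter=filt)
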