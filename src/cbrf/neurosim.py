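"""Spike-response simulators.

Two generative models produce responses from a ground-truth linear filter:

* the linear-nonlinear-Poisson (LNP) cascade — a static nonlinearity maps
  the stimulus projection to a spike rate and an inhomogeneous Poisson
  process draws counts per bin;
* the binary noisy-threshold model — the response is the sign of the
  projection plus Gaussian threshold noise minus the spiking threshold.
  Its implied static nonlinearity is the Gaussian CDF of the noise.

The nonlinearity zoo ranges from half-wave linear to step-like, the regimes
under which estimator robustness is probed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import BinaryResponse, LinearFilter, StimulusEnsemble
from .stimgen import GroundTruthFilter, make_ground_truth

__all__ = [
    "Nonlinearity",
    "lnp_simulate",
    "calibrate_rate",
    "binary_threshold_simulate",
    "make_model_cell_population",
]

NL_KINDS = ("halfwave_linear", "power", "compressive", "sigmoid", "hard_threshold")


@dataclass
class Nonlinearity:
    """Monotone static nonlinearity mapping projection -> spike rate per bin.

    Kinds and parameters
    --------------------
    halfwave_linear : ``rate_scale * max(z, 0)``
    power           : ``rate_scale * max(z, 0)**p`` with exponent ``p >= 1``
    compressive     : same form with ``p < 1``
    sigmoid         : ``rate_scale / (1 + exp(-slope*(z - midpoint)))``
    hard_threshold  : ``rate_scale * 1[z >= threshold]``

    ``slope_per_sd``, ``midpoint_quantile`` and ``threshold_quantile``
    parameters express placement relative to the projection distribution and
    are resolved into concrete ``slope`` / ``midpoint`` / ``threshold``
    values by :meth:`resolve` (called by :func:`calibrate_rate`).
    """

    kind: str
    params: dict = field(default_factory=dict)
    rate_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in NL_KINDS:
            raise ValueError(f"unknown nonlinearity kind {self.kind!r}")
        if self.rate_scale < 0:
            raise ValueError("rate_scale must be >= 0")

    def resolve(self, z: np.ndarray) -> "Nonlinearity":
        """Resolve quantile/SD-relative parameters against a projection sample."""
        p = dict(self.params)
        sd = float(np.std(z))
        if "slope_per_sd" in p and "slope" not in p:
            p["slope"] = p["slope_per_sd"] / max(sd, 1e-12)
        if "midpoint_quantile" in p and "midpoint" not in p:
            p["midpoint"] = float(np.quantile(z, p["midpoint_quantile"]))
        if "threshold_quantile" in p and "threshold" not in p:
            p["threshold"] = float(np.quantile(z, p["threshold_quantile"]))
        return replace(self, params=p)

    def rate(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        p = self.params
        if self.kind == "halfwave_linear":
            base = np.maximum(z - p.get("threshold", 0.0), 0.0)
        elif self.kind in ("power", "compressive"):
            expo = p.get("exponent", 2.0 if self.kind == "power" else 0.5)
            if self.kind == "power" and expo < 1:
                raise ValueError("power kind requires exponent >= 1")
            if self.kind == "compressive" and not 0 < expo < 1:
                raise ValueError("compressive kind requires 0 < exponent < 1")
            base = np.maximum(z - p.get("threshold", 0.0), 0.0) ** expo
        elif self.kind == "sigmoid":
            slope = p.get("slope", 1.0)
            mid = p.get("midpoint", 0.0)
            base = 1.0 / (1.0 + np.exp(-slope * (z - mid)))
        else:  # hard_threshold
            base = (z >= p.get("threshold", 0.0)).astype(float)
        out = self.rate_scale * base
        assert np.all(out >= 0)
        return out


def lnp_simulate(ens: StimulusEnsemble, k: LinearFilter, nl: Nonlinearity,
                 seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Draw Poisson spike counts from the LNP cascade ``Poisson(nl(k.x_t))``."""
    rng = np.random.default_rng(seed)
    rate = nl.rate(k.project(ens))
    return rng.poisson(rate)


def calibrate_rate(ens: StimulusEnsemble, k: LinearFilter, nl: Nonlinearity,
                   target_rate: float,
                   seed: int | np.random.Generator | None = None,
                   rtol: float = 0.1) -> Nonlinearity:
    """Scale a nonlinearity so the expected spike count per bin hits a target.

    ``rate_scale`` is adjusted by bisection (on a log grid) until the
    expected spikes/sample, evaluated on the given ensemble, is within
    ``rtol`` of ``target_rate``.  Quantile-relative parameters (sigmoid
    midpoint, hard threshold location) are resolved against the projection
    distribution first, which places thresholds at the requested percentile.
    """
    if not 0 < target_rate < 0.5:
        raise ValueError("target_rate must lie in (0, 0.5)")
    z = k.project(ens)
    nl = nl.resolve(z)
    base = replace(nl, rate_scale=1.0).rate(z).mean()
    if base <= 0:
        raise ValueError("stimulus never drives the nonlinearity; "
                         "target rate unattainable")
    lo, hi = target_rate / base * 1e-3, target_rate / base * 1e3
    for _ in range(100):
        mid = np.sqrt(lo * hi)
        realized = mid * base
        if abs(realized - target_rate) <= rtol * target_rate / 2:
            break
        if realized < target_rate:
            lo = mid
        else:
            hi = mid
    return replace(nl, rate_scale=float(mid))


def binary_threshold_simulate(ens: StimulusEnsemble, k: LinearFilter,
                              noise_sd: float,
                              seed: int | np.random.Generator | None = None,
                              ) -> BinaryResponse:
    """Binary noisy-threshold response: ``sign(k.x_t + eta_t - theta)``.

    ``eta_t ~ N(0, noise_sd**2)``; the boundary case sign(0) is fixed to +1.
    The implied P(spike | z) is the Gaussian CDF ``Phi((z - theta)/noise_sd)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    z = k.project(ens)
    eta = rng.normal(0.0, noise_sd, z.shape) if noise_sd > 0 else 0.0
    labels = np.where(z + eta - k.theta >= 0, 1, -1)
    counts = (labels == 1).astype(np.int64)
    return BinaryResponse(labels=labels, counts=counts)


def make_model_cell_population(n_cells: int, filter_kinds: list[str],
                               nl_kinds: list[str], n_lags: int,
                               n_channels: int,
                               seed: int | np.random.Generator | None = None,
                               ) -> list[tuple[GroundTruthFilter, Nonlinearity]]:
    """Reproducible population of (ground-truth filter, nonlinearity) cells.

    Nonlinearity kinds are assigned by stratified cycling so every requested
    kind appears; parameters are drawn from documented ranges: compressive
    exponent U[0.3, 0.8], power exponent in {2, 3}, sigmoid slope U[2, 10]
    per projection SD, thresholds/midpoints at the 90th-98th percentile of
    projections.  Filters get randomized placements (center frequency shifts
    for spectro-temporal onsets, orientations for Gabors).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not filter_kinds or not nl_kinds:
        raise ValueError("filter_kinds and nl_kinds must be non-empty")
    rng = np.random.default_rng(seed)
    cells = []
    for i in range(n_cells):
        fk = filter_kinds[i % len(filter_kinds)]
        params: dict = {}
        if fk == "strf_onset":
            params["center_channel"] = rng.uniform(0.25, 0.75) * (n_channels - 1)
        elif fk == "gabor_2d":
            params["orientation"] = rng.uniform(0, np.pi)
            params["phase"] = rng.uniform(0, 2 * np.pi)
        gt = make_ground_truth(fk, n_lags, n_channels, params,
                               seed=rng.integers(2 ** 31))

        nk = nl_kinds[i % len(nl_kinds)]
        np_: dict = {}
        if nk == "power":
            np_["exponent"] = float(rng.choice([2, 3]))
        elif nk == "compressive":
            np_["exponent"] = rng.uniform(0.3, 0.8)
        elif nk == "sigmoid":
            np_["slope_per_sd"] = rng.uniform(2, 10)
            np_["midpoint_quantile"] = rng.uniform(0.90, 0.98)
        elif nk == "hard_threshold":
            np_["threshold_quantile"] = rng.uniform(0.90, 0.98)
        cells.append((gt, Nonlinearity(kind=nk, params=np_)))
    return cells
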