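"""Baseline receptive-field estimators: STA, ridge, NRC, Poisson GLM, MID.

All estimators consume the same lagged design matrix and report a
:class:`~cbrf.estimator.FitReport`.  Hyperparameters (ridge penalty, NRC
rank, GLM penalty) are selected by cross-validated projection mutual
information with 11 histogram bins; MID maximizes the histogram MI
directly by gradient ascent with annealed restarts and early stopping.

Conventions: STA, ridge and NRC regress on labels recoded {0, 1} (an affine
recoding that changes the filter only by positive scaling); the Poisson GLM
consumes raw spike counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.model_selection import StratifiedKFold

from .datamodel import BinaryResponse, LinearFilter, StimulusEnsemble, center_design
from .estimator import FitReport
from .evalbench import projection_mi

__all__ = [
    "BaselineConfig",
    "MidConfig",
    "fit_sta",
    "fit_ridge",
    "fit_nrc",
    "fit_glm_poisson",
    "fit_mid",
]


@dataclass
class BaselineConfig:
    """Shared cross-validation controls for the closed-form/GLM baselines."""

    n_folds: int = 5
    n_bins: int = 11
    seed: int = 0
    max_iter: int = 200
    grad_tol: float = 1e-6


def _labels(response) -> np.ndarray:
    if isinstance(response, BinaryResponse):
        return response.labels
    return np.asarray(response)


def _counts(response) -> np.ndarray:
    if isinstance(response, BinaryResponse):
        return response.counts
    return np.asarray(response)


# ---------------------------------------------------------------------------
# STA


def fit_sta(ens: StimulusEnsemble, response) -> LinearFilter:
    """Spike-triggered average on the centered design.

    Unbiased in direction only for spherically symmetric stimulus ensembles;
    used here both as a baseline and to demonstrate its bias under skewed
    or higher-order-correlated stimuli.  The threshold is a diagnostic: the
    projection value at which the empirical spike probability first exceeds
    its overall mean.
    """
    y = _labels(response)
    spikes = y == 1
    if not spikes.any():
        raise ValueError("STA requires at least one spike")
    Xc, mu = center_design(ens.X)
    # classical STA: every spike contributes, so multi-spike bins are
    # weighted by their count (falls back to labels if counts are absent)
    w = _counts(response).astype(float) if isinstance(response, BinaryResponse) \
        else spikes.astype(float)
    k = (Xc * w[:, None]).sum(axis=0) / w.sum()

    z = Xc @ k
    p_global = spikes.mean()
    edges = np.quantile(z, np.linspace(0, 1, 21))
    theta = float(np.median(z))
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (z >= lo) & (z <= hi)
        if in_bin.any() and spikes[in_bin].mean() >= p_global:
            theta = float(0.5 * (lo + hi))
            break
    return LinearFilter(k, theta=theta + float(k @ mu),
                        n_lags=ens.n_lags, n_channels=ens.n_channels)


# ---------------------------------------------------------------------------
# ridge and NRC (closed-form least squares on {0,1} labels)


def _cv_mi_select(Xc: np.ndarray, y: np.ndarray, grid: np.ndarray,
                  solve, config: BaselineConfig) -> tuple[int, pd.DataFrame]:
    """Pick the grid index maximizing mean held-out projection MI.

    ``solve(X_train, y01_train) -> list of filters`` (one per grid value).
    Ties break toward the last (most regularized) grid entry.
    """
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    mis = np.zeros((grid.size, config.n_folds))
    y01 = (y == 1).astype(float)
    for f, (tr, va) in enumerate(skf.split(Xc, y)):
        ks = solve(Xc[tr], y01[tr])
        for i, k in enumerate(ks):
            mis[i, f] = projection_mi(Xc[va] @ k, y[va], n_bins=config.n_bins)
    mean = mis.mean(axis=1)
    best = int(np.flatnonzero(mean >= mean.max() - 1e-12)[-1])
    curve = pd.DataFrame({"value": grid, "mean": mean, "sd": mis.std(axis=1)})
    return best, curve


def _ridge_path(X: np.ndarray, y01: np.ndarray, lambdas: np.ndarray,
                warn_singular: bool = False) -> list[np.ndarray]:
    yc = y01 - y01.mean()
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    uy = U.T @ yc
    ks = []
    for lam in lambdas:
        if lam == 0:
            tol = s.max() * max(X.shape) * np.finfo(float).eps
            if warn_singular and np.any(s <= tol):
                warnings.warn("singular system at lambda=0: pseudo-inverse "
                              "solution returned", stacklevel=3)
            shrink = np.where(s > tol, 1.0 / np.maximum(s, tol), 0.0)
        else:
            shrink = s / (s ** 2 + lam)
        ks.append(Vt.T @ (shrink * uy))
    return ks


def fit_ridge(ens: StimulusEnsemble, response, lambda_grid=None,
              config: BaselineConfig | None = None) -> FitReport:
    """Closed-form ridge regression ``(X'X + lam I)^-1 X' y`` on centered data,
    with the penalty chosen by cross-validated projection MI."""
    config = config or BaselineConfig()
    y = _labels(response)
    grid = np.sort(np.atleast_1d(lambda_grid if lambda_grid is not None
                                 else np.logspace(-1, 5, 7)).astype(float))
    Xc, _ = center_design(ens.X)
    best, curve = (0, None)
    if grid.size > 1:
        best, curve = _cv_mi_select(
            Xc, y, grid, lambda X, t: _ridge_path(X, t, grid), config)
    k = _ridge_path(Xc, (y == 1).astype(float), grid[[best]],
                    warn_singular=True)[0]
    if curve is None:
        curve = pd.DataFrame({"value": grid, "mean": [np.nan], "sd": [np.nan]})
    filt = LinearFilter(k, theta=0.0, n_lags=ens.n_lags, n_channels=ens.n_channels)
    return FitReport(filter=filt, method="ridge",
                     selected_hyperparam=float(grid[best]),
                     hyperparam_name="lambda", cv_curve=curve, seed=config.seed)


def _nrc_path(X: np.ndarray, y01: np.ndarray, ranks: np.ndarray) -> list[np.ndarray]:
    yc = y01 - y01.mean()
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    uy_over_s = np.where(s > tol, (U.T @ yc) / np.maximum(s, tol), 0.0)
    ks = []
    for r in ranks:
        r_eff = min(int(r), rank)
        if r_eff < r:
            warnings.warn(f"NRC rank {r} exceeds matrix rank {rank}; clipped",
                          stacklevel=3)
        ks.append(Vt[:r_eff].T @ uy_over_s[:r_eff])
    return ks


def fit_nrc(ens: StimulusEnsemble, response, rank_grid=None,
            config: BaselineConfig | None = None) -> FitReport:
    """Normalized reverse correlation: least squares restricted to the top-r
    eigenvectors of the stimulus covariance, r chosen by cross-validated MI."""
    config = config or BaselineConfig()
    y = _labels(response)
    D = ens.n_dim
    if rank_grid is None:
        rank_grid = np.unique(np.geomspace(1, D, 7).round().astype(int))
    grid = np.sort(np.atleast_1d(rank_grid).astype(int))
    Xc, _ = center_design(ens.X)
    best, curve = (0, None)
    if grid.size > 1:
        best, curve = _cv_mi_select(
            Xc, y, grid.astype(float), lambda X, t: _nrc_path(X, t, grid), config)
    k = _nrc_path(Xc, (y == 1).astype(float), grid[[best]])[0]
    if curve is None:
        curve = pd.DataFrame({"value": grid.astype(float),
                              "mean": [np.nan], "sd": [np.nan]})
    filt = LinearFilter(k, theta=0.0, n_lags=ens.n_lags, n_channels=ens.n_channels)
    return FitReport(filter=filt, method="nrc",
                     selected_hyperparam=float(grid[best]),
                     hyperparam_name="rank", cv_curve=curve, seed=config.seed)


# ---------------------------------------------------------------------------
# Poisson GLM


_ETA_CLIP = 30.0  # exp() divergence guard on the linear predictor


def glm_objective_and_gradient(k: np.ndarray, b: float, X: np.ndarray,
                               counts: np.ndarray, lam: float,
                               ) -> tuple[float, np.ndarray]:
    """Penalized negative Poisson log-likelihood (per sample) and gradient.

    ``J = (1/T) sum_t [exp(eta_t) - c_t eta_t] + (lam/2) ||k||^2`` with
    ``eta = X k + b``; the intercept is not penalized.  The linear predictor
    is clipped at +-30 as a divergence guard.
    """
    T = X.shape[0]
    eta = np.clip(X @ k + b, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    J = float((mu - counts * eta).mean() + 0.5 * lam * k @ k)
    resid = (mu - counts) / T
    g = np.empty(k.size + 1)
    g[:-1] = X.T @ resid + lam * k
    g[-1] = resid.sum()
    return J, g


def _glm_fit_one(X: np.ndarray, counts: np.ndarray, lam: float,
                 x0: np.ndarray | None, config: BaselineConfig) -> np.ndarray:
    T = X.shape[0]
    if x0 is None:
        x0 = np.zeros(X.shape[1] + 1)
        x0[-1] = np.log(max(counts.mean(), 1e-8))

    def fun(p):
        return glm_objective_and_gradient(p[:-1], p[-1], X, counts, lam)

    def hessp(p, v):
        eta = np.clip(X @ p[:-1] + p[-1], -_ETA_CLIP, _ETA_CLIP)
        w = np.exp(eta) / T
        s = X @ v[:-1] + v[-1]
        out = np.empty_like(v)
        out[:-1] = X.T @ (w * s) + lam * v[:-1]
        out[-1] = np.sum(w * s)
        return out

    res = optimize.minimize(fun, x0, jac=True, hessp=hessp, method="trust-ncg",
                            options={"maxiter": config.max_iter,
                                     "gtol": config.grad_tol})
    return res.x


def fit_glm_poisson(ens: StimulusEnsemble, response, lambda_grid=None,
                    config: BaselineConfig | None = None) -> FitReport:
    """Poisson GLM with exponential inverse link and L2 penalty on the filter.

    Maximizes the Poisson log-likelihood by trust-region Newton-CG; the
    penalty is selected by cross-validated projection MI.  Unbiased when the
    neuron's true nonlinearity matches the exponential link, biased
    otherwise — the regime contrast probed by the simulation benchmarks.
    """
    config = config or BaselineConfig()
    counts = _counts(response)
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    y = np.where(counts >= 1, 1, -1)
    grid = np.sort(np.atleast_1d(lambda_grid if lambda_grid is not None
                                 else np.logspace(-6, 0, 7)).astype(float))
    Xc, _ = center_design(ens.X)

    def solve(X, _y01_unused, counts_tr):
        ks, x0 = [], None
        for lam in grid[::-1]:
            x0 = _glm_fit_one(X, counts_tr, lam, x0, config)
            ks.append(x0[:-1].copy())
        return ks[::-1]

    best = 0
    curve = None
    if grid.size > 1:
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                              random_state=config.seed)
        mis = np.zeros((grid.size, config.n_folds))
        for f, (tr, va) in enumerate(skf.split(Xc, y)):
            ks = solve(Xc[tr], None, counts[tr])
            for i, k in enumerate(ks):
                mis[i, f] = projection_mi(Xc[va] @ k, y[va], n_bins=config.n_bins)
        mean = mis.mean(axis=1)
        best = int(np.flatnonzero(mean >= mean.max() - 1e-12)[-1])
        curve = pd.DataFrame({"value": grid, "mean": mean, "sd": mis.std(axis=1)})
    sol = _glm_fit_one(Xc, counts, grid[best], None, config)
    if curve is None:
        curve = pd.DataFrame({"value": grid, "mean": [np.nan], "sd": [np.nan]})
    filt = LinearFilter(sol[:-1], theta=-float(sol[-1]),
                        n_lags=ens.n_lags, n_channels=ens.n_channels)
    return FitReport(filter=filt, method="glm",
                     selected_hyperparam=float(grid[best]),
                     hyperparam_name="lambda", cv_curve=curve, seed=config.seed)


# ---------------------------------------------------------------------------
# MID


@dataclass
class MidConfig:
    """Controls for maximally-informative-dimensions estimation."""

    n_bins: int = 15
    n_restarts: int = 5
    max_steps: int = 120
    patience: int = 15
    lr: float = 1.0
    temperature: float = 0.5      # initial annealing perturbation scale
    temp_decay: float = 0.5       # geometric decay across restarts
    val_fraction: float = 0.2
    seed: int = 0


def _mid_bins(z: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(z, np.linspace(0, 1, n_bins + 1)))
    return edges


def _mid_mi_and_grad(v: np.ndarray, X: np.ndarray, spikes: np.ndarray,
                     n_bins: int, want_grad: bool = True):
    """Plug-in histogram MI of the projection and its gradient w.r.t. v.

    The gradient follows from differentiating the histogram MI: bins carry
    weight P(b|spike) * d/dz log[P(z|spike)/P(z)] * (<x|b,spike> - <x|b>).
    """
    z = X @ v
    edges = _mid_bins(z, n_bins)
    idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, len(edges) - 2)
    nb = len(edges) - 1
    n_all = np.bincount(idx, minlength=nb).astype(float)
    n_spk = np.bincount(idx[spikes], minlength=nb).astype(float)
    P = n_all / n_all.sum()
    Ps = n_spk / max(n_spk.sum(), 1.0)
    ok = (Ps > 0) & (P > 0)
    mi = float(np.sum(Ps[ok] * np.log2(Ps[ok] / P[ok])))
    if not want_grad:
        return mi, None

    # bin centers and conditional means over occupied bins
    centers = np.full(nb, np.nan)
    mean_all = np.zeros((nb, X.shape[1]))
    mean_spk = np.zeros((nb, X.shape[1]))
    for b in range(nb):
        m = idx == b
        if n_all[b] > 0:
            centers[b] = z[m].mean()
            mean_all[b] = X[m].mean(axis=0)
        ms = m & spikes
        if n_spk[b] > 0:
            mean_spk[b] = X[ms].mean(axis=0)

    logr = np.zeros(nb)
    logr[ok] = np.log(Ps[ok] / P[ok])
    occ = np.flatnonzero(ok)
    if occ.size < 2:
        return mi, np.zeros_like(v)
    dlogr = np.zeros(nb)
    c = centers[occ]
    lr_ = logr[occ]
    dlogr[occ] = np.gradient(lr_, c)
    grad = np.zeros_like(v)
    for b in occ:
        grad += Ps[b] * (mean_spk[b] - mean_all[b]) * dlogr[b]
    return mi, grad / np.log(2)


def fit_mid(ens: StimulusEnsemble, response,
            config: MidConfig | None = None) -> FitReport:
    """Maximally informative dimensions: maximize the histogram MI between
    projection and spike label by gradient ascent.

    Simulated-annealing restarts perturb the best solution so far with a
    geometrically decaying temperature (the first restart starts at the STA,
    a standard initialization); early stopping monitors MI on a held-out
    20% validation split.  The filter is renormalized to unit length after
    every step — histogram MI is invariant to the filter's scale.
    """
    config = config or MidConfig()
    y = _labels(response)
    spikes = y == 1
    if not spikes.any() or spikes.all():
        raise ValueError("both classes must be present")
    Xc, _ = center_design(ens.X)
    rng = np.random.default_rng(config.seed)

    # stratified holdout for early stopping
    n = Xc.shape[0]
    order_spk = rng.permutation(np.flatnonzero(spikes))
    order_non = rng.permutation(np.flatnonzero(~spikes))
    n_val = (max(1, int(config.val_fraction * order_spk.size)),
             max(1, int(config.val_fraction * order_non.size)))
    val_idx = np.concatenate([order_spk[:n_val[0]], order_non[:n_val[1]]])
    tr_idx = np.concatenate([order_spk[n_val[0]:], order_non[n_val[1]:]])
    Xtr, str_ = Xc[tr_idx], spikes[tr_idx]
    Xva, sva = Xc[val_idx], spikes[val_idx]

    n_bins = config.n_bins
    while n_bins > 3 and np.sum(str_) < 2 * n_bins:
        n_bins = max(3, n_bins // 2)
    if n_bins != config.n_bins:
        warnings.warn("few spikes: MID histogram bins reduced to "
                      f"{n_bins}", stacklevel=2)

    def val_mi(v):
        return _mid_mi_and_grad(v, Xva, sva, n_bins, want_grad=False)[0]

    sta = Xtr[str_].mean(axis=0)
    sta_norm = np.linalg.norm(sta)
    v_init = sta / sta_norm if sta_norm > 0 else rng.standard_normal(Xc.shape[1])

    best_v, best_val = v_init, val_mi(v_init)
    curve_rows = []
    temp = config.temperature
    for restart in range(config.n_restarts):
        if restart == 0:
            v = v_init.copy()
        else:
            v = best_v + temp * rng.standard_normal(best_v.size)
            v /= np.linalg.norm(v)
            temp *= config.temp_decay
        mi, grad = _mid_mi_and_grad(v, Xtr, str_, n_bins)
        stale, best_val_r, best_v_r = 0, val_mi(v), v.copy()
        for _ in range(config.max_steps):
            grad = grad - (grad @ v) * v   # tangent step on the unit sphere
            gn = np.linalg.norm(grad)
            if gn < 1e-12:
                break
            step = config.lr
            improved = False
            for _ in range(12):
                v_new = v + step * grad / gn
                v_new /= np.linalg.norm(v_new)
                mi_new, grad_new = _mid_mi_and_grad(v_new, Xtr, str_, n_bins)
                if mi_new > mi:
                    v, mi, grad = v_new, mi_new, grad_new
                    improved = True
                    break
                step *= 0.5
            if not improved:
                break
            vm = val_mi(v)
            if vm > best_val_r:
                best_val_r, best_v_r, stale = vm, v.copy(), 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
        curve_rows.append((restart, best_val_r))
        if best_val_r > best_val:
            best_val, best_v = best_val_r, best_v_r

    curve = pd.DataFrame(curve_rows, columns=["value", "mean"])
    curve["sd"] = 0.0
    filt = LinearFilter(best_v, theta=0.0, n_lags=ens.n_lags,
                        n_channels=ens.n_channels)
    return FitReport(filter=filt, method="mid",
                     selected_hyperparam=float(best_val),
                     hyperparam_name="val_mi", cv_curve=curve,
                     seed=config.seed, extras={"n_bins": n_bins})
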