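"""Classification-based receptive field (CbRF) estimation.

The receptive field is estimated by discriminating spike-eliciting from
non-spike-eliciting stimulus vectors with a linear large-margin classifier.
With labels ``y_t in {-1, +1}`` and margins ``m_t = y_t (k . x_t - theta)``,
the convex objective is

    J(k, theta) = 1/2 ||k||^2 + C * sum_t w_{y_t} * max(0, 1 - m_t)^2,

i.e. an L2-regularized squared hinge loss whose per-example weights
``w_{+1} = 1/(2 p+)`` and ``w_{-1} = 1/(2 p-)`` are the inverse empirical
class priors (balanced classes give unit weights).  ``C = 1/(2 lambda T)``
so the regularization parameter ``lambda`` is comparable across sample
sizes; ``theta`` (the spiking threshold / negated bias) is not regularized.

The optimum is found with a trust-region Newton conjugate-gradient method
using the generalized Hessian of the piecewise-quadratic loss; gradient and
curvature only involve the margin-violating examples.  ``lambda`` is chosen
by maximizing the mean held-out ROC-AUC of the projections in stratified
cross-validation, with ties broken toward stronger regularization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datamodel import LinearFilter, StimulusEnsemble, center_design

__all__ = [
    "CbrfConfig",
    "FitReport",
    "class_prior_weights",
    "objective_and_gradient",
    "fit_cbrf_at_lambda",
    "select_lambda_by_auc",
    "fit_cbrf",
]


def _default_grid() -> np.ndarray:
    return np.logspace(-3, 3, 7)


@dataclass
class CbrfConfig:
    """Hyperparameters of the CbRF fit."""

    lambda_grid: np.ndarray = field(default_factory=_default_grid)
    n_folds: int = 5
    max_iter: int = 200
    grad_tol: float = 1e-6
    class_weighting: str = "inverse_prior"
    seed: int = 0

    def __post_init__(self) -> None:
        self.lambda_grid = np.sort(np.atleast_1d(np.asarray(self.lambda_grid, float)))
        if self.lambda_grid.size == 0 or np.any(self.lambda_grid <= 0):
            raise ValueError("lambda_grid must be non-empty and positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.class_weighting not in ("inverse_prior", "uniform"):
            raise ValueError("class_weighting must be 'inverse_prior' or 'uniform'")


@dataclass
class FitReport:
    """Bundle returned by every cross-validated estimator.

    ``cv_curve`` tabulates the selection criterion (AUC for CbRF, projection
    MI for the baselines) per hyperparameter candidate: columns
    ``value``, ``mean``, ``sd``.
    """

    filter: LinearFilter
    method: str
    selected_hyperparam: float
    hyperparam_name: str
    cv_curve: pd.DataFrame
    train_auc: float | None = None
    n_iter: int = 0
    converged: bool = True
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def selected_lambda(self) -> float:
        return self.selected_hyperparam


def class_prior_weights(y: np.ndarray) -> tuple[float, float]:
    """Inverse-class-prior loss weights ``w_y = 1/(2 P(y))``.

    Normalized so that balanced classes give ``(1, 1)``; e.g. a spike
    probability of 0.02 gives ``w_plus = 25`` and ``w_minus ~ 0.51``.
    """
    y = np.asarray(y)
    p_plus = float(np.mean(y == 1))
    if p_plus in (0.0, 1.0):
        raise ValueError(
            "both spike (+1) and non-spike (-1) examples are required to "
            "estimate class priors; check the response binarization"
        )
    return 1.0 / (2.0 * p_plus), 1.0 / (2.0 * (1.0 - p_plus))


def _weight_vector(y: np.ndarray, weights: tuple[float, float]) -> np.ndarray:
    w_plus, w_minus = weights
    return np.where(y == 1, w_plus, w_minus)


def objective_and_gradient(k: np.ndarray, theta: float, X: np.ndarray,
                           y: np.ndarray, lam: float,
                           weights: tuple[float, float] = (1.0, 1.0),
                           ) -> tuple[float, np.ndarray]:
    """Weighted squared-hinge objective and its gradient over (k, theta).

    Returns ``(J, g)`` with ``g[:-1] = dJ/dk`` and ``g[-1] = dJ/dtheta``.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    T = X.shape[0]
    C = 1.0 / (2.0 * lam * T)
    w = _weight_vector(y, weights)
    m = y * (X @ k - theta)
    r = np.maximum(0.0, 1.0 - m)
    J = 0.5 * k @ k + C * np.sum(w * r * r)
    coef = -2.0 * C * w * r * y          # nonzero only on violating examples
    g = np.empty(k.size + 1)
    g[:-1] = k + X.T @ coef
    g[-1] = -np.sum(coef)
    return float(J), g


def _make_problem(X: np.ndarray, y: np.ndarray, lam: float,
                  weights: tuple[float, float]):
    """fun/jac and Hessian-vector product closures for the solver."""
    T = X.shape[0]
    C = 1.0 / (2.0 * lam * T)
    w = _weight_vector(y, weights)
    yf = y.astype(float)

    def fun(p):
        J, g = objective_and_gradient(p[:-1], p[-1], X, y, lam, weights)
        return J, g

    def hessp(p, v):
        # generalized Hessian: identity on k plus 2C * sum over active
        # examples of w * [x, -1][x, -1]^T
        m = yf * (X @ p[:-1] - p[-1])
        active = m < 1.0
        Xa = X[active]
        wa = w[active]
        s = Xa @ v[:-1] - v[-1]
        out = np.empty_like(v)
        out[:-1] = v[:-1] + 2.0 * C * (Xa.T @ (wa * s))
        out[-1] = -2.0 * C * np.sum(wa * s)
        return out

    return fun, hessp


def fit_cbrf_at_lambda(X: np.ndarray, y: np.ndarray, lam: float,
                       weights: tuple[float, float] = (1.0, 1.0),
                       x0: np.ndarray | None = None, max_iter: int = 200,
                       grad_tol: float = 1e-6,
                       ) -> tuple[np.ndarray, float, int, bool]:
    """Minimize the convex CbRF objective at fixed ``lambda``.

    Returns ``(k, theta, n_iter, converged)``.  ``x0`` allows warm starts
    along the regularization path; convexity guarantees a unique optimum.
    """
    if np.all(y == y[0]):
        raise ValueError("both classes must be present")
    D = X.shape[1]
    if x0 is None:
        x0 = np.zeros(D + 1)
    fun, hessp = _make_problem(X, y, lam, weights)
    res = optimize.minimize(fun, x0, jac=True, hessp=hessp, method="trust-ncg",
                            options={"maxiter": max_iter, "gtol": grad_tol})
    converged = bool(np.max(np.abs(res.jac)) <= max(grad_tol * 10, 1e-4))
    if not converged:
        warnings.warn(f"CbRF solver did not reach tolerance at lambda={lam:g} "
                      f"(|grad|_inf={np.max(np.abs(res.jac)):.2e})", stacklevel=2)
    return res.x[:-1], float(res.x[-1]), int(res.nit), converged


def select_lambda_by_auc(X: np.ndarray, y: np.ndarray, config: CbrfConfig,
                         weights: tuple[float, float],
                         ) -> tuple[float, pd.DataFrame]:
    """Stratified K-fold selection of ``lambda`` by mean held-out AUC.

    Ties (within 1e-12) are broken toward larger ``lambda`` (stronger
    regularization, smoother filter).
    """
    grid = config.lambda_grid
    n_spikes = int(np.sum(y == 1))
    n_nospike = int(np.sum(y == -1))
    if min(n_spikes, n_nospike) < config.n_folds:
        raise ValueError(
            f"too few examples of one class ({n_spikes} spikes, "
            f"{n_nospike} non-spikes) for {config.n_folds}-fold stratified CV"
        )
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    aucs = np.zeros((grid.size, config.n_folds))
    for f, (tr, va) in enumerate(skf.split(X, y)):
        x0 = None
        for i, lam in enumerate(grid[::-1]):  # strong-to-weak warm starts
            k, theta, _, _ = fit_cbrf_at_lambda(
                X[tr], y[tr], lam, weights, x0=x0,
                max_iter=config.max_iter, grad_tol=config.grad_tol)
            x0 = np.concatenate([k, [theta]])
            aucs[grid.size - 1 - i, f] = roc_auc_score(y[va] == 1, X[va] @ k)
    mean = aucs.mean(axis=1)
    best = np.flatnonzero(mean >= mean.max() - 1e-12)[-1]
    curve = pd.DataFrame({"value": grid, "mean": mean, "sd": aucs.std(axis=1)})
    return float(grid[best]), curve


def fit_cbrf(ens: StimulusEnsemble, y: np.ndarray,
             config: CbrfConfig | None = None) -> FitReport:
    """Full CbRF pipeline: class weights -> CV lambda selection -> final fit.

    The design matrix is centered internally; the returned filter is
    expressed in original stimulus units (the threshold absorbs the shift:
    ``theta = theta_centered + k . mean``).
    """
    config = config or CbrfConfig()
    y = np.asarray(y)
    Xc, mu = center_design(ens.X)
    if config.class_weighting == "inverse_prior":
        weights = class_prior_weights(y)
    else:
        class_prior_weights(y)  # validates both classes are present
        weights = (1.0, 1.0)
    if config.lambda_grid.size > 1:
        lam, curve = select_lambda_by_auc(Xc, y, config, weights)
    else:
        lam = float(config.lambda_grid[0])
        curve = pd.DataFrame({"value": [lam], "mean": [np.nan], "sd": [np.nan]})
    k, theta_c, n_iter, converged = fit_cbrf_at_lambda(
        Xc, y, lam, weights, max_iter=config.max_iter, grad_tol=config.grad_tol)
    filt = LinearFilter(k, theta=theta_c + float(k @ mu),
                        n_lags=ens.n_lags, n_channels=ens.n_channels)
    train_auc = roc_auc_score(y == 1, Xc @ k)
    return FitReport(filter=filt, method="cbrf", selected_hyperparam=lam,
                     hyperparam_name="lambda", cv_curve=curve,
                     train_auc=float(train_auc), n_iter=n_iter,
                     converged=converged, seed=config.seed,
                     extras={"weights": weights,
                             "class_weighting": config.class_weighting})
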