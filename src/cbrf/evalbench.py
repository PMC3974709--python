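"""Evaluation metrics and protocols for receptive-field estimates.

Metrics
-------
* ROC-AUC of the projections — rank-based separability of spike vs
  non-spike stimulus examples (the CbRF model-selection criterion).
* Projection mutual information — histogram MI in bits between the filtered
  stimulus and spike occurrence, the model-independent predictive-power
  measure used for cross-method comparison (scale-invariant, so estimators
  with arbitrarily scaled filters are comparable).
* Filter correlation — absolute Pearson correlation between mean-removed
  flattened filters (sign-aligned, since filter polarity is identifiable
  only jointly with the nonlinearity).
* Nonlinearity reconstruction — the histogram ratio P(z|spike)/P(z).

Protocols
---------
* :func:`population_protocol` — 80/20 stratified 5-fold evaluation of
  held-out projection MI per method.
* :func:`convergence_protocol` — temporal-prefix subsets (10%...100% of the
  recording) correlated against the full-data estimate per method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datamodel import BinaryResponse, LinearFilter, StimulusEnsemble

__all__ = [
    "roc_auc",
    "projection_mi",
    "filter_correlation",
    "estimate_nonlinearity",
    "population_protocol",
    "convergence_protocol",
    "subset_ensemble",
]


def roc_auc(z: np.ndarray, y: np.ndarray) -> float:
    """Probability that a random spike projection exceeds a random non-spike
    projection (ties count 1/2); equals the area under the ROC curve."""
    y = np.asarray(y)
    if np.all(y == y[0]):
        raise ValueError("both classes are required to compute AUC")
    return float(roc_auc_score(y == 1, np.asarray(z, float)))


def _shared_edges(z: np.ndarray, n_bins: int, binning: str) -> np.ndarray:
    if binning == "equal_width":
        lo, hi = z.min(), z.max()
        if lo == hi:
            hi = lo + 1.0
        return np.linspace(lo, hi, n_bins + 1)
    if binning == "quantile":
        edges = np.quantile(z, np.linspace(0, 1, n_bins + 1))
        return np.unique(edges)
    raise ValueError("binning must be 'equal_width' or 'quantile'")


def projection_mi(z: np.ndarray, y: np.ndarray, n_bins: int = 11,
                  binning: str = "equal_width") -> float:
    """Histogram mutual information (bits) between projection and spike label.

    ``I = sum_b P(b|spike) log2[P(b|spike) / P(b)]`` over shared bin edges
    spanning the pooled projection range; bins with zero probability are
    excluded from the sum.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    z = np.asarray(z, float)
    y = np.asarray(y)
    if np.all(y == y[0]):
        raise ValueError("both classes are required to compute projection MI")
    edges = _shared_edges(z, n_bins, binning)
    p_all, _ = np.histogram(z, edges)
    p_spk, _ = np.histogram(z[y == 1], edges)
    P = p_all / p_all.sum()
    Ps = p_spk / p_spk.sum()
    ok = (Ps > 0) & (P > 0)
    return float(np.sum(Ps[ok] * np.log2(Ps[ok] / P[ok])))


def filter_correlation(k1, k2) -> float:
    """Absolute Pearson correlation between two flattened filters."""
    a = np.asarray(k1.k if isinstance(k1, LinearFilter) else k1, float).ravel()
    b = np.asarray(k2.k if isinstance(k2, LinearFilter) else k2, float).ravel()
    if a.size != b.size:
        raise ValueError("filters must have equal length")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance filter has no defined correlation")
    return float(abs(a @ b / (na * nb)))


def estimate_nonlinearity(ens: StimulusEnsemble, y: np.ndarray,
                          filt: LinearFilter, n_bins: int = 11,
                          binning: str = "equal_width",
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct the static nonlinearity as the ratio P(z|spike)/P(z).

    Returns bin centers and ratio values over the occupied marginal bins.
    Up to the overall spike probability and the bin width, the ratio is
    proportional to the spike rate as a function of the projection.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = np.asarray(y)
    if np.all(y == y[0]):
        raise ValueError("both classes are required")
    z = ens.X @ filt.k
    edges = _shared_edges(z, n_bins, binning)
    p_all, _ = np.histogram(z, edges)
    p_spk, _ = np.histogram(z[y == 1], edges)
    occupied = p_all > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    P = p_all / p_all.sum()
    Ps = p_spk / p_spk.sum()
    ratio = Ps[occupied] / P[occupied]
    return centers[occupied], ratio


def subset_ensemble(ens: StimulusEnsemble, idx) -> StimulusEnsemble:
    """Row-subset of an ensemble, keeping the lag/channel metadata."""
    return StimulusEnsemble(ens.X[idx], n_lags=ens.n_lags,
                            n_channels=ens.n_channels, dt=ens.dt,
                            channel_freqs=ens.channel_freqs)


def _extract_filter(fit_result) -> LinearFilter:
    return fit_result.filter if hasattr(fit_result, "filter") else fit_result


def population_protocol(ens: StimulusEnsemble, response: BinaryResponse,
                        methods: dict, n_folds: int = 5, n_bins: int = 11,
                        seed: int = 0) -> pd.DataFrame:
    """Cross-validated predictive power (held-out projection MI) per method.

    The data is split into 80% training / 20% evaluation in a stratified
    ``n_folds``-fold scheme.  Each method is a callable
    ``(ens_train, response_train) -> LinearFilter | FitReport`` performing
    its own hyperparameter selection on the training part only.

    Returns a DataFrame indexed by method with per-fold MI values and their
    mean and SD.
    """
    if not methods:
        raise ValueError("at least one method is required")
    y = response.labels
    if int(np.sum(y == 1)) < n_folds:
        raise ValueError("too few spikes for stratified outer folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = {}
    for name, fit in methods.items():
        fold_mi = []
        for tr, te in skf.split(ens.X, y):
            filt = _extract_filter(fit(
                subset_ensemble(ens, tr),
                BinaryResponse(labels=y[tr], counts=response.counts[tr])))
            fold_mi.append(projection_mi(ens.X[te] @ filt.k, y[te],
                                         n_bins=n_bins))
        rows[name] = fold_mi
    df = pd.DataFrame(rows).T
    df.columns = [f"fold{i}" for i in range(n_folds)]
    df["mean"] = df.iloc[:, :n_folds].mean(axis=1)
    df["sd"] = df.iloc[:, :n_folds].std(axis=1)
    return df


def convergence_protocol(ens: StimulusEnsemble, response: BinaryResponse,
                         methods: dict,
                         fractions=(0.10, 0.25, 0.50, 0.75, 1.0),
                         ) -> pd.DataFrame:
    """Relative convergence: prefix-data estimates vs the full-data estimate.

    For each fraction f the first ``f * T`` time bins are used (temporal
    prefixes mimic a recording stopped early, not random subsamples) and the
    resulting filter is correlated with the same method's 100% estimate.
    Fractions whose prefix contains no spikes yield NaN.

    Returns a DataFrame indexed by fraction with one column per method.
    """
    fractions = list(fractions)
    if not fractions == sorted(fractions) or not all(0 < f <= 1 for f in fractions):
        raise ValueError("fractions must be sorted and lie in (0, 1]")
    T = ens.n_samples
    y = response.labels
    out = {}
    for name, fit in methods.items():
        full = _extract_filter(fit(ens, response))
        col = []
        for f in fractions:
            n = int(round(f * T))
            if np.all(y[:n] == -1) or np.all(y[:n] == 1):
                col.append(np.nan)
                continue
            part = _extract_filter(fit(
                subset_ensemble(ens, slice(0, n)),
                BinaryResponse(labels=y[:n], counts=response.counts[:n])))
            col.append(filter_correlation(part, full))
        out[name] = col
    return pd.DataFrame(out, index=pd.Index(fractions, name="fraction"))
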