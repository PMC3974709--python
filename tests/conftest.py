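import numpy as np
import pytest

from cbrf import neurosim, stimgen
from cbrf.datamodel import build_lagged_design, binarize_counts


@pytest.fixture(scope="session")
def gaussian_lnp_data():
    """Gaussian white-noise LNP simulation (the regime where every estimator
    is consistent): 20k samples, 32-lag temporal onset filter, half-wave
    linear nonlinearity at ~0.05 spikes/sample."""
    rng = np.random.default_rng(1234)
    series = rng.standard_normal(20000)
    ens = build_lagged_design(series, 32)
    gt = stimgen.make_ground_truth("temporal_onset", 32, 1)
    nl = neurosim.calibrate_rate(ens, gt.filter,
                                 neurosim.Nonlinearity("halfwave_linear"), 0.05)
    counts = neurosim.lnp_simulate(ens, gt.filter, nl, 99)
    return ens, gt, binarize_counts(counts)


@pytest.fixture(scope="session")
def threshold_model_data():
    """Noisy-threshold binary responses from a known 8-dim filter."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((30000, 8))
    from cbrf.datamodel import LinearFilter, StimulusEnsemble

    k = rng.standard_normal(8)
    k /= np.linalg.norm(k)
    filt = LinearFilter(k, theta=1.0, n_lags=1, n_channels=8)
    ens = StimulusEnsemble(X, n_lags=1, n_channels=8)
    resp = neurosim.binary_threshold_simulate(ens, filt, noise_sd=0.5, seed=11)
    return ens, filt, resp
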