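"""How quickly do RF estimates stabilize as a recording grows?

Refits the receptive field on temporal prefixes (10%...100%) of a simulated
recording and correlates each partial estimate with the full-data estimate
of the same method.  Values near 1 at small fractions mean the method would
have delivered the same answer from a much shorter recording.
"""

import numpy as np

from cbrf import baselines, neurosim
from cbrf.datamodel import binarize_counts, build_lagged_design
from cbrf.estimator import CbrfConfig, fit_cbrf
from cbrf.evalbench import convergence_protocol
from cbrf.stimgen import gen_correlated_spectrogram, make_ground_truth

S, _ = gen_correlated_spectrogram(duration=20.0, n_channels=8, dt=0.0025,
                                  spectral_exponent=1.0, seed=3)
ens = build_lagged_design(S, n_lags=6, dt=0.0025)
truth = make_ground_truth("strf_onset", 6, 8)
nl = neurosim.calibrate_rate(ens, truth.filter,
                             neurosim.Nonlinearity("power"), 0.05)
resp = binarize_counts(neurosim.lnp_simulate(ens, truth.filter, nl, seed=4))

methods = {
    "cbrf": lambda e, r: fit_cbrf(e, r.labels, CbrfConfig(
        lambda_grid=np.logspace(-2, 2, 3), n_folds=3)),
    "mid": lambda e, r: baselines.fit_mid(
        e, r, baselines.MidConfig(seed=0, n_restarts=2)),
}
table = convergence_protocol(ens, resp, methods,
                             fractions=(0.10, 0.25, 0.50, 0.75, 1.0))
print("correlation of prefix estimates with the full-data estimate:")
print(table.round(3))
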