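"""Effect of a concentrated rotation prior on MMSE estimation accuracy.

Rotations are drawn from an isotropic Gaussian on SO(3) with eta = 0.1
(strongly preferred orientations).  The MMSE estimator is run once with a
candidate grid sampled from the true prior and once with a Haar-uniform
grid; MLE is the prior-free baseline.  Trials are paired.
"""

import bayespose as bp

V = bp.make_phantom_volume("blob-asym", N=24, seed=0)
df = bp.run_prior_comparison(
    V, eta_true=0.1, snr_values=[1e-2, 1e-1], L=1024, trials=300, seed=0,
    assumed_etas=(None, 0.1),
)
print(df[["snr", "estimator", "mean_geodesic_error", "stderr"]].to_string(index=False))
# Matching the assumed prior to the true concentrated rotation distribution
# shrinks the mean geodesic error, most visibly at low SNR where the
# likelihood alone cannot pin the orientation down.
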