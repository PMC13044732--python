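"""Grid-size scaling of the orientation-estimation error.

At high SNR the error of grid-search estimators is limited by the grid
resolution.  SO(3) has three rotational degrees of freedom, so the
per-axis resolution of an L-node grid grows like L^(1/3) and the geodesic
error decays with the same exponent.
"""

import bayespose as bp

V = bp.make_phantom_volume("blob-asym", N=24, seed=0)
grid_sizes = [192, 648, 1536, 3000]
df = bp.run_scaling_study(V, grid_sizes, snr=10.0, trials=100, seed=0)
print(df[["L_actual", "method", "mean_geodesic_error", "stderr"]].to_string(index=False))
for method in ("mle", "mmse"):
    sub = df[df["method"] == method].sort_values("L_actual")
    expo = bp.fit_scaling_exponent(sub["L_actual"], sub["mean_geodesic_error"])
    print(f"{method}: fitted |slope| of log error vs log L = {expo:.3f}  (theory: 1/3)")
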