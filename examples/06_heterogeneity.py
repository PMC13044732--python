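"""Pose accuracy and recovery of continuous conformational variability.

A one-dimensional conformational transition (a sub-blob moving along a
curved path, K equally spaced states) is observed through noisy randomly
rotated subtomograms.  The conformational subspace is estimated by
align-average-debias covariance analysis under three pose sources: ground
truth, Bayesian MMSE estimates and hard MLE estimates against a consensus
reference.
"""

import bayespose as bp

traj = bp.make_trajectory(N=32, K=10, seed=0)
sigma = bp.sigma_for_snr(traj.mean_volume.grid, snr=1e-2)
grid = bp.build_so3_quadrature(300)
df = bp.compare_pose_sources(traj, M=400, sigma=sigma, grid=grid, seeds=[0], rank=8)

pivot = df.pivot_table(index="k", columns="pose_source", values="variance_captured")
print("percentage of total conformational variance captured:")
print(pivot.round(1).to_string())
# Better poses mean sharper alignment before covariance estimation, so the
# recovered principal subspace explains more of the true conformational
# variance: ground truth >= MMSE >= MLE, with the gap widening at high
# noise where the rotation posterior is spread.
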