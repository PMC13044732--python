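"""2D polar image recovery: soft (EM/MMSE) versus hard (MLE) assignment.

M noisy, randomly rotated copies of an unknown image are observed on a
polar grid where rotation is an exact cyclic shift.  Starting from a
different template image, the iterative reconstruction either weights all
rotations by their posterior (soft) or commits to the best one (hard).
"""

import numpy as np

import bayespose as bp
from bayespose.reconstruction import ObservationSet

D_R, L_THETA, M, SNR = 64, 30, 1000, 4e-3
truth = bp.make_polar_phantom(D_R, L_THETA, seed=1)
template = bp.make_polar_phantom(D_R, L_THETA, seed=2)
grid = bp.build_cyclic_grid(L_THETA)

rng = np.random.default_rng(0)
sigma = bp.sigma_for_snr(truth.grid, SNR)
shifts = rng.integers(0, L_THETA, size=M)
data = np.stack([np.roll(truth.grid, k, axis=1) for k in shifts])
data += rng.normal(0, sigma, size=data.shape)
obs = ObservationSet(data, sigma, "polar-2d", true_shifts=shifts)

soft = bp.em_reconstruct(obs, template, grid)
hard = bp.hard_assign_reconstruct(obs, template, grid)
for name, state in [("soft (EM/MMSE)", soft), ("hard (MLE)", hard)]:
    cc = bp.pearson_cc(bp.align_global(state.estimate, truth, grid), truth)
    print(f"{name:15s}: {state.iteration:3d} iterations, PCC with truth = {cc:.4f}")
# At this noise level the posterior over rotations is genuinely spread, so
# averaging over it (soft assignment) recovers the image markedly better
# than committing to the single most likely rotation.
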