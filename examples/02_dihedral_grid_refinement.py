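"""Refine a dipeptide-like dihedral-grid ensemble with known ground truth.

A 36x36 phi/psi grid (1296 conformers) with Boltzmann prior weights is
refined against 12 synthetic observables (two Karplus couplings, ten
shift-like surfaces) whose "experimental" values were generated from a
known reweighting of the prior plus 0.2-sigma noise.  Because the truth
is known, we can measure how much closer the refined ensemble averages
are to the generating targets.
"""

import numpy as np

from ure import make_grid_system, make_recovery_fixture, optimize_k

grid = make_grid_system(seed=1)
fix = make_recovery_fixture(grid, k_true=2.0, noise_sd=0.2, seed=1)

result = optimize_k(theta=0.05, prior=fix.prior, obs=fix.obs)

means_prior = fix.obs.calc_matrix.T @ fix.prior.weights
means_opt = fix.obs.calc_matrix.T @ result.weights_opt.weights
err_prior = np.abs(means_prior - fix.target_means) / fix.obs.sigma
err_opt = np.abs(means_opt - fix.target_means) / fix.obs.sigma

print(f"conformers           : {fix.prior.n_conformers}")
print(f"observables          : {fix.obs.n_observables}")
print(f"chi2: {result.chi2_init:.3f} -> {result.chi2_opt:.3f}")
print(f"ensemble preservation: {result.ensemble_preservation:.1f} %")
print(f"mean |<O> - truth| / sigma: prior {err_prior.mean():.2f} "
      f"-> refined {err_opt.mean():.2f}")
print(f"observables moved closer to truth: {(err_opt < err_prior).sum()}/12")

# chi2 measures agreement with the noisy experimental values; the last
# two lines measure agreement with the noiseless generating targets —
# the refinement recovers them because the truth lies inside the model
# family.
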