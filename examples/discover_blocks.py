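"""Discover the block structure from the data itself.

When no grouping annotation exists, blocks can be found by thresholding
the sample correlation matrix (graph connected components at |r| >= t), or,
with no prior information at all, by letting AIC pick the threshold.
"""

import numpy as np

from ebcov import SampleSummary, draw, estimate, make_truth

scenario = make_truth(p=20, block_sizes=(6, 6, 8), rho_within=0.7, seed=10)
X = draw(scenario, n=20, seed=11).X

est_thr = estimate(X, "threshold", threshold=0.5)
print("threshold 0.5 recovered blocks:",
      [len(b) for b in est_thr.prior.structure.blocks],
      f"(truth: {list(scenario.structure.sizes)})")

est_aic = estimate(X, "aic")
scan = est_aic.threshold_scan
print(f"AIC-chosen threshold: {scan.chosen:.2f}")
print("AIC recovered blocks:", [len(b) for b in est_aic.prior.structure.blocks])
best = scan.chosen_index
print(f"AIC at chosen threshold: {scan.aic_values[best]:.1f} "
      f"({scan.n_parameters[best]} free parameters)")
# Each candidate threshold induces a partition; its AIC is 2k - 2 lnL with k
# the free entries of the block covariance and lnL the Gaussian likelihood
# of the observed scatter under the averaged-correlation block model.  The
# minimizing threshold balances block richness against overfitting.
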