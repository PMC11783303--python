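"""Expression covariates: TMM-FPKM and tissue specificity (tau).

Simulates a ten-tissue count matrix whose genes span the full range of
tissue specificity, normalizes it with TMM, and compares the estimated
tau against the generator's targets.
"""

import numpy as np

import immusel as im
from immusel.expression import summarize_expression, tmm_factors

n_genes = 100
rng = np.random.default_rng(3)
targets = rng.uniform(0, 1, n_genes)

matrix = im.simulate_expression(
    n_genes=n_genes, n_tissues=10, tau_target_per_gene=targets,
    library_sizes=[2e6] * 40, seed=4,
)

factors = tmm_factors(matrix.counts)
print("TMM factors (first 5 samples):",
      np.round(factors.values[:5], 3))

summary = summarize_expression(matrix, factors)
err = np.abs(summary["tau"].values - targets)
print(f"tau: median abs error vs targets = {np.nanmedian(err):.3f} "
      f"over {n_genes} genes")
print(f"mean expression spans {summary['mean_expression'].min():.2f} to "
      f"{summary['mean_expression'].max():.1f} TMM-FPKM")
print("\nfive example genes:")
print(summary[["mean_expression", "tau"]].head().round(3))
# tau = 0 means uniform expression across the ten tissues, tau = 1 means
# single-tissue expression; the estimator tracks the generator's targets
# to within a few hundredths despite negative-binomial counting noise.
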