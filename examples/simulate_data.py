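"""Simulate a two-class scRNA-seq dataset and look at its basic properties.

The simulator draws gamma-distributed baseline gene means, gives a chosen
fraction of genes a log-normal fold change in class 2, and generates
gamma-Poisson (negative binomial) counts under log-normal library sizes —
the over-dispersed, sparse regime typical of real droplet data.
"""

import numpy as np

from scfsnn import SimParams, simulate_counts

truth = simulate_counts(SimParams(n_cells=400, n_genes=1000, de_prop=0.1, seed=7))
counts = truth.counts.values

print(f"cells x genes:      {counts.shape[0]} x {counts.shape[1]}")
print(f"class sizes:        {np.bincount(truth.labels.y).tolist()}")
print(f"truly DE genes:     {int(truth.de_mask.sum())}")
print(f"zero fraction:      {np.mean(counts == 0):.3f}")
print(f"median library:     {int(np.median(counts.sum(axis=1)))}")
mu = counts.mean(axis=0)
var = counts.var(axis=0)
big = mu > 5
print(f"var/mean (mu>5):    median {np.median(var[big] / mu[big]):.2f}  (overdispersed if > 1)")
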