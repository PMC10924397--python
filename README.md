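# scfsnn

Backward feature selection inside a deep neural network, with false
discovery rate (FDR) control, for single-cell RNA-seq classification.

## The problem

A cells × genes count matrix typically holds thousands of genes of which
only a small subset carries class information (cell type, condition,
disease status). Penalized models and filter statistics struggle with the
over-dispersion, sparsity and non-linearity of scRNA-seq counts. This
package selects the informative gene subset *during* the training of a
neural-network classifier and tells you how trustworthy that subset is: the
expected fraction of false positives among the selected genes is estimated
at every step and the selection stops at a user-chosen FDR target.

## The method

Counts are normalized, log-transformed and standardized per gene,

&nbsp;&nbsp;&nbsp;&nbsp; x<sub>ij</sub> = (log(x′<sub>ij</sub> d₀/dᵢ + 1) − m<sub>j</sub>) / s<sub>j</sub>.

q = ⌊p/2⌋ **surrogate null features** — entries sampled without replacement
from the processed matrix, hence label-independent by construction — are
appended, and an MLP (256/128 hidden units, batch norm, dropout 0.5, Adam)
is trained on all p + q features, with convex-pseudodata augmentation
x* = (1−α)xᵢ + αx<sub>j</sub>, α ~ U(0, 0.2), of the training set. Features
are scored by the mean absolute gradient of the per-sample loss with respect
to each input on the validation set,

&nbsp;&nbsp;&nbsp;&nbsp; S<sub>j</sub> = (1/n) Σᵢ |∂L(yᵢ, Oᵢ)/∂x<sub>ij</sub>| ,

and the worst-scoring features are deleted in adaptive batches of
⌈ε(1 − η*/η̂) r₀⌉. With r features surviving, r₀ of them surrogates, the
FDR of the surviving originals is estimated as

&nbsp;&nbsp;&nbsp;&nbsp; η̂ = (r₀/q) · p̂₀ / (r − r₀),
&nbsp;&nbsp;&nbsp;&nbsp; p̂₀ = min(2 · #{S<sub>j</sub> < S<sub>m</sub>}, p),

where S<sub>m</sub> is the median surrogate score. Elimination stops when
η̂ ≤ η* (default 0.1); a fresh network is then trained on the selected
genes and evaluated once on a held-out test split (outer split 64/16/20).
A Splatter-style two-class count simulator with ground-truth DE masks is
bundled, so FDR control and power are verifiable end to end without any
external data. See `docs/methods.md` for the full model description and
design choices.

## Worked example

```python
from scfsnn import (RunConfig, SimParams, empirical_fdr, empirical_power,
                    run_scfsnn, simulate_counts)

truth = simulate_counts(SimParams(n_cells=300, n_genes=500, de_prop=0.1, seed=42))
result = run_scfsnn(truth.counts, truth.labels, RunConfig(seed=0))
```

Running `python examples/select_features.py` (the same computation, with
commentary) prints:

```
input genes:        491
elimination steps:  134
selected genes:     21
estimated FDR at stop: 0.0832
empirical FDR:      0.1905
empirical power:    0.3400
test accuracy:      1.0000
```

491 of 1000 simulated genes survive the zero-count filter; after 134
elimination steps the estimated FDR falls below the 0.1 target and 21 genes
remain. Against the simulator's ground truth, 4 of the 21 are false
discoveries (single-run FDR 0.19 — individual runs fluctuate around the
estimate; the replicate mean is controlled, see below), the selected set
covers the strongly shifted DE genes, and a classifier using only those 21
genes classifies held-out cells perfectly.

The same run is available from the shell:

```bash
scfsnn simulate --n-cells 300 --n-genes 500 --de-prop 0.1 --seed 42 --out sim/
scfsnn select --counts sim/ --labels sim/labels.tsv --seed 0 --out run/
scfsnn benchmark --grid grid.yaml --reps 20 --out bench.tsv
```

`run/` then contains `selected_genes.tsv` (gene, final score),
`trajectory.tsv` (per-step r, r₀, p̂₀, η̂, deletions) and `result.json`.

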