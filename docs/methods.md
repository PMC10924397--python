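# Methods

## Problem and approach

Given a cells × genes matrix of raw scRNA-seq counts and a class label per
cell, the package selects the subset of genes a deep classifier actually
uses, while controlling the false discovery rate (FDR) of that subset. It is
an embedded backward-elimination procedure: a fully connected network is
trained on all genes plus a set of injected *surrogate* features known to be
null; features are repeatedly scored and the worst are removed; the survival
rate of the surrogates calibrates an FDR estimate for the surviving genes,
and elimination stops once that estimate reaches the user's target.

## Preprocessing

Counts are total-count normalized to the median library size, log1p
transformed, and standardized per gene:

    x_ij = (log(x'_ij · d0 / d_i + 1) − m_j) / s_j

with d_i the total count of cell i, d0 the median of the d_i over the
*training* cells, and m_j, s_j the per-gene mean and standard deviation of
the log-normalized values. The transform is scale-invariant per cell
(doubling a cell's counts leaves its row unchanged). Genes with zero counts
in more than `max_zero_fraction` of cells (default 0.8) are removed before
anything else.

Decisions where the procedure was genuinely open:

* **Fit-on-train only.** d0, m_j, s_j are estimated on the training split
  and applied to validation and test cells, so held-out cells cannot leak
  into the fit.
* **Sample standard deviation** (ddof = 1). The choice only rescales every
  column by the same factor √(n/(n−1)) and is exposed as a parameter.
* **Zero-variance genes** after log-normalization are dropped with a
  warning; the transform is undefined for them and they carry no class
  signal.

## Surrogate null features

q = ⌊p/2⌋ surrogate features are created by pooling all n·p entries of the
processed matrix and sampling n·q of them without replacement into q
columns (`strategy="pooled"`, the default). Because every processed column
has mean 0 and standard deviation 1, the surrogate columns live on the same
scale as real genes but are independent of the label by construction. An
alternative `column_permute` strategy builds each surrogate as a
row-permuted copy of a randomly chosen real column, preserving per-gene
marginal shapes; it is closer to permutation-null practice and available as
a flag. Surrogates are drawn in a single sampling run spanning the training
and validation rows, so validation cells have surrogate values for scoring.

## Data augmentation

Convex pseudodata (CPD): a synthetic sample is x* = (1−α)x_i + αx_j with
α ~ Uniform(0, d) and label y_i, for a uniformly drawn ordered pair i ≠ j.
Default d = 0.2; the number of synthetic samples defaults to n (doubling
the training set), a choice we fixed since the procedure does not pin it
down. Augmentation happens after surrogate injection, so surrogate columns
see the same training distribution as real ones, and it is applied to
training data only — validation scores always come from real cells.
Augmentation can be disabled for large datasets.

## Network and training

Input → 256 ReLU → 128 ReLU → softmax, all layers fully connected, batch
normalization and dropout (rate 0.5) on each hidden layer; cross-entropy
loss, Adam (learning rate 0.001), minibatches of 32. The network is
implemented directly in NumPy with hand-written backpropagation; this keeps
the exact per-sample input gradient — the importance primitive — available
in closed form, and makes evaluation mode (batch-norm frozen at running
statistics, dropout off) strictly deterministic. Weights use float32 by
default; the dtype is configurable, and float64 is used where gradient
checks against finite differences require more resolution than a 1e-4 step
leaves in single precision.

## Importance scores and elimination

After training, feature j is scored on the validation set as

    S_j = (1/n_val) Σ_i |∂L(y_i, O_i)/∂x_ij| ,

the mean absolute gradient of the per-sample loss with respect to input j,
computed in evaluation mode. The network is trained on all p+q features for
30 initialization epochs, after which the null count among the originals is
estimated once and frozen:

    p̂0 = min(2 · #{original j : S_j < S_m}, p),

with S_m the median surrogate score (strict inequality; ties do not count).
With r features still active, r0 of them surrogates, the FDR of the r − r0
surviving originals is estimated as

    η̂ = (r0/q) · p̂0 / (r − r0).

While η̂ > η* (default 0.1), the ⌈ε(1 − η*/η̂)·r0⌉ lowest-scoring active
features are deleted (ε = 0.1; ties broken by feature index), the network
is trained `step_epochs` more epochs (default 3 — enough to adapt the fit
without making the loop quadratic in p), and scores are recomputed. The
loop stops when η̂ ≤ η*, when no surrogates survive (η̂ = 0), or at a
max-step safeguard (10·p steps). One network is kept throughout: eliminated
inputs are removed by slicing the first-layer rows and their Adam state,
which is mathematically identical to zero-masking the columns and freezing
their weights, and optimizer state persists across steps. A deletion batch
is capped so at least one original feature always survives.

Setting `p0_mode="equal_p"` replaces p̂0 by p, the conservative convention;
η̂ is monotone in p̂0, so this variant never reports a smaller FDR and never
selects more genes on the same data and seed.

## Final model and evaluation

The selected genes are the surviving originals. A fresh network is trained
on them using the combined training+validation cells, with an internal
stratified 80/20 split for early stopping (patience 10, max 100 epochs);
CPD augmentation is applied to the internal training portion when enabled.
The 20% test split is touched exactly once, at the very end, to report test
accuracy. The outer split is 64/16/20 (train/validation/test), stratified
by class so small classes appear in every split.

## Simulator

The bundled generator emulates the Splatter family of scRNA-seq
simulators: baseline gene means λ_j ~ Gamma(shape 0.6, rate 0.3); a
`de_prop` fraction of genes receives a log-normal fold change
(location 0.1, scale 0.4) in class 2, up- or down-regulated with equal
probability; library sizes L_i ~ LogNormal(11, 0.2); each cell's expected
counts are its class's mean profile renormalized to sum to L_i; per-entry
gamma noise with biological coefficient of variation 0.18; Poisson counts
(marginally negative binomial); optional logistic dropout, off by default.
Classes are balanced. These hyperparameters are fixed defaults chosen to
resemble Splatter's documented behaviour; they are all exposed in
`SimParams`.

What the simulator does and does not capture: counts are over-dispersed and
sparse with realistic library-size variation, and the compositional
coupling of library-size normalization is present; gene–gene correlation
beyond library size, batch effects, discrete sub-structure within classes
and zero inflation beyond the NB (unless dropout is enabled) are absent.
Passing FDR control here therefore shows the surrogate-null calibration
works when null genes are (nearly) exchangeable with surrogates; on real
data with strongly correlated null genes the estimate can be less accurate.

## Numerical and reproducibility choices

* One global seed fans out through fixed spawn keys into independent streams
  for the split, surrogate sampling, CPD, network initialization/training,
  the final model and the simulator, so any component can be re-run in
  isolation and whole runs are bit-reproducible (byte-identical output
  files for identical config and seed).
* Batch-norm uses eps 1e-5 and running-statistic momentum 0.1; softmax is
  computed with max subtraction; losses are floored at 1e-12 before the log.
* Score ties during elimination are broken by feature index; even-length
  surrogate medians are the midpoint of the central order statistics.
* An empty selection is reported as FDR 0 and power 0 by convention.

## Problem sizes used in validation

The bundled checks exercise the procedure at reduced scale, chosen once:
FDR control is verified on five replicates of 2000 genes × 600 cells with
5% DE genes (the estimator's behaviour there is Monte-Carlo comparable to
larger designs); the trend in the DE proportion uses 500 genes × 400 cells
with three seeds per setting; null calibration uses 200 genes × 160 cells
over ten seeds. At these scales the stopping state involves only a handful
of surviving surrogates, so single-replicate empirical FDR fluctuates more
than it would at full scale; conclusions are drawn from replicate means.

## Known limitations

* The FDR estimate assumes importance scores of null originals and
  surrogates are exchangeable; correlation between null and signal genes
  (present in real data) biases it optimistic.
* Only classification outputs are supported; labels must be categorical.
* Power degrades for weakly shifted or rarely expressed genes, and genes
  removed by the zero filter can never be selected.
* The discrete stopping rule overshoots: the reported η̂ at stop is usually
  below the target rather than at it.
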