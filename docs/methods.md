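# Methods

This note records the model, the numerical conventions, and the scope
of the synthetic-data generator behind `npnets`. Everything stated here
is implemented in the package; no empirical claim is made beyond what
the shipped code computes.

## Scope

`npnets` predicts directed peptidergic (neuropeptide → receptor)
coupling networks among cortical neuron types from single-cell
RNA-sequencing, and benchmarks how well small gene subsets resolve a
hierarchical cell-type taxonomy. Its inputs are an expression matrix
(counts or CPM), a per-cell annotation (area, leaf type, subclass,
class), a cell-type taxonomy, and an annotation table of neuropeptide
precursor (NPP) genes and neuropeptide-selective G-protein-coupled
receptor (NP-GPCR) genes with their cognate links and Gα transduction
families. A curated 47-gene cortical annotation (18 NPP + 29 NP-GPCR,
37 cognate pairs) ships with the package.

## Expression statistics

**Peak expression (pFPKM/pCPM).** The peak expression of a gene is the
ascending nearest-rank 99.9th-percentile of its single-cell expression
values: with the n values sorted ascending, the value at 1-based index
⌈0.999·n⌉ (clamped to [1, n]). This is exact order-statistics
arithmetic, not interpolation; `nearest_rank_quantile` is checked
against a brute-force sort oracle. A gene's *percentile rank* within a
gene universe of size N is 100·(1 − (rank − 1)/N), rank 1 being the
highest peak; ties break lexicographically so tables are
deterministic.

**Detection.** A gene is detected in a cell when its expression is
strictly greater than 1 CPM (parameterized). Co-expression counts and
cognate-pair co-detection use the same strict threshold.

**Type-level profiles.** Per-type expression is the 5% two-sided
trimmed mean (floor of 5% of the sample trimmed from each tail; for
fewer than 20 cells this floors to zero and reduces to the plain
mean). Median and plain mean are available. Within-subclass
coefficient of variation uses the sample standard deviation (ddof = 1)
and excludes singleton subclasses.

## Gene selection

A candidate NPP is retained when its peak percentile is at least 80
(top quintile, parameterized) *and* at least one cognate receptor is
locally expressed; an NP-GPCR is retained when it is locally expressed
and cognate to a retained NPP. "Locally expressed" for receptors is
operationalized as detection in ≥ 0.5% of cells at > 1 CPM *or* peak
percentile ≥ 50 — a deliberately permissive, fully parameterized
default (the shipped receptor panel spans detection fractions down to
~0.5% of cells). The retained lists are mutually closed under the
cognate relation, and the bipartite cognate edges define the directed
signaling channels.

## Coupling networks

For a cognate pair, the predicted type-to-type coupling matrix is the
outer product of the precursor's type-expression profile (rows: source
types) and the receptor's profile (columns: target types), in CPM·CPM
units; displays use log₁₀ with a floor of 10⁻² CPM² before the
logarithm. Because each matrix is rank one, pooling to subclass level
by unweighted block means is exactly the outer product of the
subclass-mean factor vectors (verified to machine precision).

Per-pair matrices aggregate into three Gα-family channels (Gi/o, Gs,
Gq/11): each pair's log matrix is shifted to minimum 0, scaled to
maximum 1, summed within its family, and the family sum renormalized
to [0, 1]. An alternative order (sum linear matrices first, then log
and normalize) is available behind a flag; the default is the
normalize-then-sum reading.

## Latent classification benchmark

**Reference autoencoder.** A feed-forward autoencoder maps a large
highly-expressed (HE) gene set to a d = 5 latent space: input dropout
(rate 0.8) → four 100-unit ReLU layers → linear d-unit latent layer →
batch normalization, mirrored decoder, mean-squared reconstruction
error, Adam, batch size 956. Inputs are log₁₀(CPM+1), per-gene
standardized.

**Linked autoencoder.** A second autoencoder for a small gene subset
(four 50-unit layers, no dropout) is trained with loss L = R + λ·C,
λ = 100, where R is its reconstruction error and
C = MSE(z₂, z₁) + (σ_min − 1)², with z₁ the frozen reference latent
coordinates and σ_min the smallest principal standard deviation of the
z₂ batch (its gradient uses the singular-vector outer product). The
penalty aligns the small-set latent space with the reference space and
prevents collapse of any latent direction.

Both networks are implemented in pure NumPy with explicit
backpropagation (`npnets.nn`): the linked objective is nonstandard, the
implementation is deterministic under a seed, and it removes any deep
learning framework dependency. Epoch counts default to desk-scale
values and are parameters of the spec objects.

**Resolution index (RI).** For a taxonomy with unit merge heights,
RI(v) = 1 − height(v)/height(root) for each node: 1 at leaves, 0 at
the root. Per cross-validation fold (13-fold by default, stratified
when every leaf label has enough cells), a quadratic discriminant
analysis (QDA) classifier with covariance ridge is fit on the training
cells at leaf level; correctly predicted test cells receive RI = 1.
Internal nodes are then merged one at a time in ascending height order
(deterministic tie-break); after each merge the classifier is refit on
the merged labels and still-misclassified cells that now land on their
correct merged label receive that node's RI. Cells wrong even at the
two-class level receive RI = 0. Training labels with a single cell are
dropped from a fit (QDA needs two cells for a covariance) and re-enter
once merged. Mean RI over cells summarizes a gene subset; gene-subset
comparisons use bootstrap resampling of replicate mean RIs, degenerating
to the empirical rank p-value (1 + #{random ≥ observed})/(n + 1) when
the observed set has a single replicate.

**Benchmark gene sets.** HE (top per-gene maximum), DE (one-vs-rest
z-score over leaf-type mean profiles — a stand-in for an externally
supplied differential-expression list), DE47 (most type-variable genes
within the DE pool), Rand47 (uniform draws), and Rand47_ExpMatched
(draws matched decile-by-decile to a reference set's log-maximum
distribution).

## Synthetic-data generator

The generator exists to make every downstream stage testable without
any external download; it is a statistical emulator, not a biological
model. It produces:

- a balanced taxonomy (root → 2 classes → subclasses → leaf types,
  unit merge heights 3/2/1/0; sizes differ by at most one);
- ground-truth per-type means: background genes with moderate
  constitutive expression and low cross-type variance (log-normal,
  sd 0.2 decades); neuropeptide-like genes zero outside a random
  expressor-type subset and log-uniform over four decades inside it;
- two "areas" sharing type means up to an element-wise log-normal
  perturbation exp(N(0, sd)), sd = 0.05 by default;
- cells drawn with a configurable GABAergic fraction (0.47), log-normal
  library sizes, and gamma–Poisson (negative binomial) counts with
  variance = mean + φ·mean² (φ = 0.5 by default).

With the perturbation and dispersion driven toward zero the generator's
ground-truth means are recoverable from the data (tested). The same
seeded RNG prefix reproduces the exact means behind any generated
dataset (`ground_truth_type_means`).

## Numerical choices

- Nearest-rank (no interpolation) percentiles throughout.
- Strict `>` detection threshold.
- ddof = 1 standard deviations for CV.
- log₁₀ floors: 1 (i.e. +1) for expression inputs, 10⁻² CPM² for
  coupling displays.
- All stochastic stages take explicit integer seeds; per-stage seeds
  derive from one master seed via `numpy.random.SeedSequence`.

## Limitations

- Coupling predictions are expression outer products: they assume
  uniform peptide diffusion and receptor efficacy and encode no
  spatial, synaptic, or electrophysiological information.
- The DE gene set is a z-score stand-in, not a replication of any
  external differential-expression pipeline.
- The autoencoder defaults are desk-scale (hundreds of epochs, a few
  thousand cells); results at full scale require raising the epoch
  counts via the spec objects.
- The synthetic generator reproduces marginal and hierarchical
  structure, not gene–gene correlation structure beyond the shared
  type means.
- The shipped annotation is a fixed snapshot of 47 cortical genes;
  applying the pipeline to other gene families requires supplying a
  new annotation table.
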