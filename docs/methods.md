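# Methods

## Why fragment counts

scATAC-seq libraries are made of Tn5 fragments sequenced paired-end. The
common pipeline counts *reads* — deduplicated fragment ends — per peak, so a
fragment fully inside a peak contributes 2 and only fragments straddling a
peak boundary contribute 1. Read counts therefore come predominantly in even
numbers, and their per-peak variance across cells is roughly twice the mean
(if fragments are Poisson with mean mu, doubled counts have mean 2·mu and
variance 4·mu). Neither property is compatible with Poisson modeling.
Fragment counts — obtained either by counting fragment intervals directly or
by the matrix-level approximation r -> ceil(r/2) — restore the Poisson
mean-variance relation and a monotonically decaying count histogram.

`fragments.reads_to_fragments` implements the matrix-level rule exactly
(round odd counts up to the next even number, halve). It is an
approximation: it cannot distinguish a cell with one boundary-straddling
fragment (1 read) from one with a fully contained fragment (2 reads); both
map to 1 fragment. `count_fragments_in_peaks` is the exact route when a
fragment file is available; a fragment overlapping a peak by >= 1 bp counts
once in that peak, and a fragment spanning several peaks counts once in
each. How the original 10x-style pipelines resolve multi-peak fragments is
not standardized; any-overlap counting is this package's convention.

## The models

Both models are variational autoencoders over the cells-by-peaks matrix
X ∈ N^{N×P}, sharing an architecture and differing in likelihood.

**Poisson VAE** (fragment counts x_cp):

    z_c    ~ Normal(f_mu(x_c), f_sigma(x_c))
    rho_cp = g_p(z_c, s_c)
    w_cp   = softmax_p(rho_cp + r_p)
    lam_cp = exp(l_c) · w_cp,   l_c = log Σ_p x_cp
    x_cp   ~ Poisson(lam_cp)

**Bernoulli VAE** (binarized y_cp = 1{x_cp > 0}):

    theta_cp = sigmoid(rho_cp + r_p + ltilde_c),
    ltilde_c = logit((1/P) Σ_p y_cp)
    y_cp     ~ Bernoulli(theta_cp)

The depth offsets l_c and ltilde_c are *precomputed from the data*, not
learned: the softmax ties Σ_p lam_cp = exp(l_c) exactly, and with
rho = r = 0 the Bernoulli model predicts exactly the cell's observed mean
accessibility. Cells with zero total count (or, for the Bernoulli model,
all-zero/all-one rows) have no defined offset and are dropped with a logged
count before training.

The batch covariate s_c (one-hot) enters the decoder only, mirroring the
model equations; a `batch_to_encoder` flag exists but defaults off.
`f_sigma` outputs the posterior *standard deviation* (the literature leaves
the variance/sd convention ambiguous; sd is this package's definition).

### Architecture and training

Encoder and decoder are two blocks of [affine -> dropout -> layer norm ->
leaky ReLU (slope 0.01)] with hidden width round(sqrt(P)); the encoder ends
in affine heads for mu and log sigma (log sigma clipped to ±10 for
numerical safety). The encoder consumes raw fragment counts — no log1p or
TF-IDF. Defaults: learning rate 1e-4, weight decay 1e-3 (L2 coupled into
the Adam gradient, as in the reference deep-learning optimizers), minibatch
128, dropout 0.1, KL weight 1 with no annealing or warm-up (configurable).
Data are split 80/10/10 into train/validation/test; early stopping monitors
the validation reconstruction loss (per-cell NLL at the posterior mean,
dropout off) with patience 20 and min-delta 0, restoring the best-epoch
weights. One integer seed controls the split, initialization, dropout
masks, reparameterization noise and minibatch order, making runs bitwise
reproducible on a single device.

The implementation is pure NumPy with hand-written backpropagation. The
Poisson NLL uses the log-sum-exp-stabilized softmax and a log-gamma
normalizer; its gradient with respect to the decoder logits is
w_cp·T_c − x_cp (T_c the cell total), and the Bernoulli gradient is
theta − y. All gradients are validated against central finite differences
in the test suite (relative error < 1e-5 on sampled coordinates). Sparse
rows are densified per minibatch only.

### Model-derived quantities

- **Latent embedding**: posterior means f_mu(x_c), deterministic.
- **Reconstruction probability**: the Poisson rate is converted to the
  probability of at least one fragment, theta = 1 − exp(−lam); the
  Bernoulli model outputs theta directly. Both use the *observed* offsets.
- **Normalized accessibility**: the decoder output recomputed with every
  cell's offset replaced by the cohort median (median total fragment count,
  or logit of the median mean-accessibility), removing depth as a source of
  between-cell variation.
- **Latent-dimension sweep**: one model per grid value (default 10..100 in
  steps of 10), scored by validation-set average precision on the binarized
  matrix; ties resolve to the smallest dimension.

## Evaluation metrics

Reconstruction is scored with average precision (area under the
precision-recall curve, the scikit-learn estimator) on the flattened
binarized held-out cells — appropriate for heavily imbalanced targets.

Embedding quality uses the standard integration panel. Bioconservation:
NMI and ARI of the best Louvain clustering (k=15 Euclidean kNN graph,
union-symmetrized; resolutions 0.1–2.0 in steps of 0.1, best NMI kept;
Leiden available as an alternative backend), label silhouette rescaled to
[0,1], and isolated-label F1/silhouette where isolated labels are those
present in the fewest batches (ties averaged). Batch correction: batch
silhouette (per cell-type mean of 1 − |silhouette| over batch labels),
graph connectivity (per-label largest-connected-component fraction of the
label-restricted kNN subgraph), and principal-component regression (the
drop in variance-weighted batch R² of the principal components, relative
to an unintegrated reference embedding). ARI is rescaled to [0,1] only
inside report aggregation; the raw value is reported alongside. Degenerate
single-cluster comparisons score 0 by definition.

## Association analyses

Peaks are scored by the fraction of cells whose count exceeds the
binarization threshold (default 1) and grouped by score quantiles (edge
ties go to the lower bin). Each group is tested for enrichment against
annotation interval sets with a one-sided Fisher exact test on the 2×2
group × any-overlap table; odds ratios are reported without continuity
correction (0 or infinity when a cell is empty, flagged as such), and
p-values are Benjamini–Hochberg adjusted.

Promoter-expression correlation: per gene, cells are restricted to the
central total-count band (0.25–0.75 quantiles, inclusive) so depth does not
drive the correlation, and to cells with promoter signal. The default
inclusion threshold is promoter fragment count >= 1; a stricter > 1 variant
is available via `min_promoter_count=2` (the two readings both occur in
practice). Two-sided Spearman correlations are BH-adjusted across genes;
the summary reports the fraction of genes with positive correlation at raw
p < 0.05 and a one-sided binomial test of that fraction against the 5%
nominal rate.

## Synthetic data

The generator realizes exactly the structure the Poisson model assumes:
type profiles w*_t ~ Dirichlet(alpha·1_P) with alpha = 1/type_sharpness
(default sharpness 3, i.e. alpha ≈ 0.33 — spiky, well-separated profiles),
lognormal depths (default median 3000, sigma 0.5, matching the per-cell
depth spread of droplet assays), a multiplicative batch effect of
batch_effect_size log2 units (default 1) on a random 10% peak subset with
renormalization, and Poisson sampling. `fragments_to_reads` produces the
paired-end read artifact: two reads per fragment, or one with probability
q (one end outside the peak), which creates the even-count excess and the
var ≈ 2·mean signature; at q = 0 the conversion is exactly invertible by
`reads_to_fragments`. `plant_expression` ties synthetic expression counts
to promoter-peak fragment counts through a Gaussian copula with the latent
correlation chosen as 2·sin(pi·rho_s/6) to hit a target Spearman rho.

What the generator does *not* emulate: genomic sequence and peak geometry,
Tn5 insertion-site biology, zero inflation beyond Poisson sparsity,
cell-type proportions that differ between batches, doublets, and
overdispersion of biological origin. Passing tests on this data show the
algorithms recover the structure they model; they do not certify
performance on real tissue.

### A density caveat that shapes one experiment

Real peak matrices are extremely sparse: median per-peak fragment counts of
roughly 0.02–0.04. A desk-scale matrix with realistic per-cell depth
(thousands of fragments) over only a few hundred peaks is, per peak, two
orders of magnitude denser than any real dataset. The Poisson-vs-Bernoulli
reconstruction-AP gap is density-dependent: measured on synthetic data it
is large and positive around per-peak means of 0.3–0.8, shrinks toward zero
in the real-data density regime, and *inverts* at per-peak means well above
1, where most binarized targets are 1 and the Bernoulli model optimizes the
evaluation target directly — a regime no real peak matrix occupies. The
downsampling experiment (`experiments.downsampling_gap`) therefore starts
from a dataset with per-peak mean 0.5 (800 cells × 400 peaks, depth median
200) so that the sweep over fractions {1, 0.3, 0.1, 0.03} spans per-peak
densities 0.5 down to 0.015, ending at real-data sparsity. In that regime
the gap decreases monotonically with thinning, reproducing the qualitative
downsampling result on real data. Problem sizes for the other experiments:
overdispersion diagnostics at 20,000 cells × 200 peaks; latent-recovery at
2,000 cells × 1,000 peaks with a 120-epoch cap; the downsampling runs cap
at 300 epochs with early stopping.

## Known limitations

- Decoder-only batch conditioning does not *force* the latent space to be
  batch-invariant: nothing in the objective penalizes the encoder for
  retaining batch information that the decoder's covariate makes redundant.
  On synthetic data with a strong planted batch effect the embedding's
  batch silhouette can be worse than that of a raw-count PCA, because the
  offset removes depth from the latent (tightening type clusters and making
  residual batch structure stand out in scale-relative silhouette terms)
  while raw-count PCA's within-type variance is dominated by depth, which
  masks batch. Feeding the covariate to the encoder (`batch_to_encoder`)
  mitigates this but departs from the printed model equations and is off by
  default.
- The Poisson likelihood cannot express biological overdispersion; a
  negative-binomial variant is the natural extension and is out of scope.
- `reads_to_fragments` is a per-entry approximation, not a realignment.
- The Louvain sweep optimizes NMI against provided labels, as the standard
  benchmarking pipelines do; it is a benchmarking device, not an unbiased
  clustering procedure.
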