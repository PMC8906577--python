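# Methods

## Data model

A profile table is a samples × features matrix plus per-sample metadata
(compound, dose in µM, plate, well, MOA annotation, DMSO flag). Cell
Painting features are grouped into 16 classes: {Cells, Cytoplasm, Nuclei} ×
{DNA, RNA, ER, AGP, Mito} plus AreaShape, parsed from CellProfiler-style
names (compartment = first underscore token; channel = first stain token,
else AreaShape). L1000 features form a single "gene" pseudo-group.

Processing order: feature selection (drop features with missing values,
blocklisted names, variance < 1e−8, or any observation more than 15
population SDs from the feature mean — note a single outlier among n points
can reach at most |z| ≈ √n, so the 15-SD rule needs n ≳ 226 to ever fire);
optional collapse of level-4 replicates into level-5 consensus signatures
(per-feature mean per compound-dose, MOA annotations must agree); 0–1
min–max normalization per feature for Cell Painting (the recorded extremes
make the transform invertible and let held-out data be placed on the
training scale; L1000 tables pass through unchanged because their upstream
processing already standardizes them); plate-stratified 80/10/10
train/validation/test splits (strata under 3 samples go wholly to train).

## The VAE variants

All three variants share one architecture: encoder `x → h → (μ, log σ²)`
and decoder `z → h → x̂`, each with one hidden layer (default width ≈ half
the feature count: 250-ish for morphology, 500 for L1000), LeakyReLU
(slope 0.01), optional batch-norm on the encoder hidden layer, linear or
sigmoid output (sigmoid recommended for 0–1-normalized data), Adam
(lr 1e−3 by default), reparameterization `z = μ + σ ⊙ ε`. The loss is

    L = (1/n) Σᵢ ‖xᵢ − x̂ᵢ‖²  +  R

with reconstruction **summed over features, averaged over the batch** — β
and λ defaults are calibrated to this convention and are not portable to
per-feature-mean conventions. The regularizer R is:

* vanilla: `KL(q(z|x) ‖ N(0,I))`, averaged over the batch (β ≡ 1);
* β-VAE: `β · KL`;
* MMD-VAE: `λ · MMD²(z_batch, prior_batch)` — the biased V-statistic with a
  sum of RBF kernels `exp(−d²/2h)`, bandwidths {1, 2, 4, 8, 16} × latent
  dim, against a fresh equal-size unit-Gaussian draw per batch. The
  regularizer acts on the *reparameterized sample*, not μ, for both
  training and validation (with μ, genuine cluster structure in the
  aggregate posterior inflates the metric that sampling smooths out).

Everything — forward pass, batch-norm, reparameterization, the analytic MMD
gradient — is implemented in numpy; gradient correctness is pinned against
central finite differences to ~1e−9 relative error in the test suite.
Training is deterministic per seed: weight init, batch shuffling,
reparameterization noise, prior draws and validation noise all come from
named substreams of the config seed. Validation losses use a noise draw and
prior sample fixed at the start of training so curves are comparable across
epochs. A non-finite loss raises an error carrying the partial history so
calibration can classify the run as unstable.

Downstream analyses (LSA, interpretation, metrics) encode with the
posterior mean μ(x) — a deliberate, documented choice; sampling is available
via `encode_decode(mode="sample")`.

The PCA baseline (default 10 components, no whitening) and the identity
(original-feature-space) model satisfy the same encode/decode contract, so
every stage runs unchanged on them.

## Calibrating β and λ

β is selected by **simulation fidelity**: for each candidate, train with
fixed settings (latent 50, lr 1e−3, encoder batch-norm, batch 128,
50 epochs), decode as many unit-Gaussian prior draws as training rows, and
measure the symmetric Hausdorff distance between real and simulated clouds;
pick the argmin (ties → smaller β). Too little regularization entangles the
latent space (prior draws decode off-manifold); too much collapses the
posterior (simulations lose data modes). Two numerical caveats, both
documented because they shape the curve:

* The Hausdorff distance is a **max** statistic — one off-scale decoded
  point dominates it. With an unbounded linear output layer this makes the
  curve monotonically favor posterior collapse on bounded data; the sweep
  therefore uses a sigmoid output for 0–1-normalized tables, which restores
  the intended behavior. On such data the selected β is typically ≪ 1,
  consistent with morphology profiles needing weak KL pressure.
* The method is known to bias low relative to what LSA would ideally want;
  the full distance curve is reported so users can inspect it.

λ barely moves simulation fidelity, so it is chosen as the **largest stable
candidate**: a run is stable when `(max − min)/median` of the total training
loss over the last 10 epochs is below 0.1 and all losses are finite.
Injected histories can be scored without retraining.

## Latent interpretation

Because the prior is N(0, I), traversing one latent coordinate to ±3 (three
prior SDs, others fixed at 0) spans its realistic range;
`|decode(+3eⱼ) − decode(−3eⱼ)|` says which output features coordinate j
drives. For a linear decoder this equals exactly 6·|loadingⱼ|, which the
tests exploit as a closed form. Averaging within each feature group (the
caption-level "mean contribution") and normalizing each latent column by
its maximum yields the group × latent contribution matrix; column-sum
normalization is available by flag, all-zero columns are left raw and
flagged. Average-linkage hierarchical clustering provides display ordering
only. Disentanglement is diagnosed by the latent Pearson correlation matrix
(constant coordinates are zeroed with a warning).

## Latent-space arithmetic and significance

Filtering: keep compounds with one or two MOA annotations; keep a
single-MOA group only if it participates in some retained pair; keep DMSO.
A pair whose member lacks a single-MOA group is dropped (the prediction is
undefined without both operands) and reported. All doses of all annotated
compounds enter the group means, unweighted — a documented simplification,
since pair means can mix doses of heterogeneous effect size. Analyses use
the full table (train + validation + test) by default, matching the small
per-MOA sample sizes of real screens; restrict via the split assignment if
held-out-only evaluation is wanted.

Prediction: `decode(mean_z(A) − mean_z(D) + mean_z(B))`, scored against the
mean **raw** (not reconstructed) profile of the pair's samples by L2
distance and Pearson correlation. Null: permute all MOA labels (DMSO
included) across samples, rebuild groups, re-run the prediction, score
against the *real* pair mean; 10 shuffles by default, giving a null ten
times the observed set. `z = (observed − null mean)/null SD` (sample SD,
ddof 1); one-sided normal p-values — low tail for L2, high tail for
Pearson. No multiple-testing correction is applied; n is reported per pair.

Leave-out robustness: remove every compound annotated with a top-predicted
pair or either member MOA, retrain, and recompute the pair's z-scores with
group means taken from the full table encoded by the retrained model — the
removed mechanisms are predicted by a model that never saw them.

Reproducibility vs predictability: per pair, the median per-sample Pearson
correlation between original and reconstructed profiles, against the
Pearson correlation between the real mean and the LSA prediction; the
correlation of these two vectors over pairs summarizes whether
well-modeled mechanisms are the predictable ones.

## Evaluation metrics

Reconstruction MSE averages squared error over samples and features. The
per-sample earth-mover distance is the 1-D Wasserstein-1 distance between a
sample's own feature-value distribution and its reconstruction's (equal
lengths: mean absolute difference of sorted values) — a deliberate
resolution of an ambiguous "per-sample" phrasing, cross-checked against a
transport LP in tests; its mean and 5/95 percentiles are reported.
Per-feature reconstruction MSE feeds group-vs-rest comparisons: for group
G, a one-sample t-test on {mse_f − mean(mse over complement), f ∈ G},
alternative "less". Zero-variance difference samples with zero mean score
t = 0, p = 0.5 (no signal); zero-variance with nonzero mean are skipped.
UMAP overlays (n_neighbors 15, min_dist 0.1, fixed seed) are fit on
original test data only, with reconstructed and simulated blocks
transformed into the fitted space; display-only.

## The synthetic screen generator

Defaults emulate a small repurposing screen: 120 features over the 16
feature groups, 15 single MOAs, 5 pairs, 3 compounds per MOA, 6 doses
(0.04–10 µM, ~3.3× dilution), 5 replicates over 2 plates with 24 DMSO wells
each, saturating dose response `s(d) = d/(d+1)`, plate offsets
(SD 0.01) and i.i.d. Gaussian noise (SD 0.05). A profile is

    x = b + s(d) · Σ_{m ∈ moa} E_m + I_{AB} + plate + ε.

MOA effect vectors `E_m` are random mixtures of a shared low-rank phenotype
basis: 8 basis vectors, each confined to 1–2 feature groups, each MOA
mixing 1–2 of them (so each MOA touches ≤ 4 groups). The shared basis
mirrors the low intrinsic dimensionality of real morphology screens — about
ten latent features suffice for hundreds of correlated readouts — and is
what makes leave-out prediction possible in principle: a mechanism held out
of training still lies in the span of the others. The optional per-pair
interaction term `I_{AB}` (default 0) is the knob for studying non-additive
polypharmacology; it is not a data-derived quantity.

What the generator does **not** emulate: realistic CellProfiler covariance
beyond group-sparse effects, heavy-tailed feature distributions, batch/
plate-position artifacts, dose-dependent noise, or annotation errors.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under additive, low-rank conditions — not performance on
real screens. One consequence worth knowing: on this discrete-cluster
screen, a column-shuffled copy is *easier* for the MMD-VAE to regularize
(cluster-free data maps trivially onto the prior), so the real-vs-shuffled
training-gap control uses the factor-model generator
(`generate_correlated_profiles`: x = b + fW + ε, f ~ N(0, I_rank)), where
destroying correlation genuinely removes what the model exploits and all
three variants train to a clearly lower validation loss on real data.

## Problem sizes and numerical choices

The shipped studies use 120-feature screens (~1,850 level-4 rows, ~360
level-5 rows), 10-dimensional latents, 30–50 epochs, three training seeds
for every stochastic claim, and 10-shuffle nulls — sizes chosen so the full
study retrains in minutes on one CPU while keeping the group means and
z-scores well determined. "Final validation loss" for the training-gap
control is the median of the last 5 epochs on a 30 % held-out set (the
biased MMD estimator is noisy on small sets). log σ² is clipped to ±15;
float64 throughout; Hausdorff distances are exact (no approximate nearest
neighbors); λ defaults (1000 for level-5-scale data) follow the stability
rule under this loss convention.

## Known limitations

* The β sweep's fixed latent dimension (50) follows the calibration recipe
  even when the downstream model uses 10; the selected β transfers on the
  assumption that simulation fidelity is architecture-stable.
* z-scores use a normal approximation on a 10-point null; with so few
  shuffles the p-values are indicative, not exact.
* MOA labels with more than two mechanisms are dropped, not decomposed.
* The PCA-vs-original-space ordering of LSA error is data-dependent under
  noise (truncation also denoises); only the noise-free information-loss
  direction is asserted.
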