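# Methods

`connectogat` implements graph classification of two-group brain-connectome
cohorts with a graph attention network (GAT), together with the
interpretability machinery (attention-head fidelity, gradient saliency,
averaged attention maps, clinical correlation) needed to read the trained
model back in anatomical terms. This note records the model, its
assumptions, the defaults, and the design choices made where the design was
genuinely open.

## Data model and preprocessing

A subject is a pair of symmetric, zero-diagonal weighted graphs over a
fixed parcellation (default: 86 Desikan-Killiany regions, 68 cortical + 18
subcortical), plus per-region morphology and clinical variables.

* **SC** (structural connectivity): nonnegative probabilistic connection
  weights. Sparsified by an absolute threshold, default `t = 0.1`; values
  `>= t` are kept (the strictness of the cutoff is not canonical, so the
  comparison is configurable in one place).
* **FC** (functional connectivity): signed correlations. Normalized with
  Fisher's r-to-z (`arctanh`), then proportionally thresholded: the top
  `ceil(density * n(n-1)/2)` undirected edges by signed value are kept,
  default density 0.5. Signed ranking keeps the strongest positive
  correlations; an absolute-value ranking mode exists
  (`ranking="abs"`) because the field has no consensus. Ties at the
  boundary break by (row, col) order so results are deterministic.
* Input matrices may be asymmetric only up to 1e-6 (numerical noise is
  symmetrized; anything larger is an error, not a silent fix).

## Multimodal node features (F = 24)

Per node: 2 morphological (volume, cortical thickness), then per modality
7 network measures [CC, BC, D, S, LE, Mod, PC] and 4 moments
[mean, std, skew, excess kurtosis] of the node's full off-diagonal row
(zeros included after thresholding; a nonzero-only mode is flag-gated).
Column order is [morphology | SC network | SC moments | FC network |
FC moments]: 13 structural-side and 11 functional-side columns. Unimodal
variants drop morphology and the other modality (11 columns).

Weighted network measures follow the Brain Connectivity Toolbox
conventions: Onnela clustering (weights rescaled to max 1, cube-root
triangle intensities), betweenness on 1/w path lengths (unnormalized,
unordered pairs), weighted local efficiency on the neighborhood-induced
subgraph with cube-root-scaled lengths, strength = row sum, degree =
nonzero count. Community-dependent measures use a seeded Louvain
partition of the nonnegative graph. Two measures needed an explicit
operationalization:

* **Nodal modularity**: `Mod_i = (1/2W) * sum_{j in c_i} (w_ij - s_i s_j / 2W)`
  — node i's within-module contribution to Newman's Q. Chosen because it
  is the unique per-node decomposition that sums exactly to Q (tested).
* **Participation coefficient** uses strength-based module degrees:
  `PC_i = 1 - sum_m (k_im / k_i)^2`.

FC negative weights are zeroed before network measures (standard, since
path-based measures are undefined for negative weights); the statistical
moments use the signed values. Cortical thickness is undefined for the 18
subcortical regions and is imputed as 0 to keep the morphology block
rectangular.

Min–max normalization is fit per feature over all nodes of the training
subjects only and applied to held-out data with the training scaler
(held-out values may leave [0, 1]); constant features map to 0.

## SMOTE balancing

Imbalanced cohorts (default design 75 patients / 34 controls) are balanced
before splitting by SMOTE on flattened subjects (SC upper triangle || FC
upper triangle || morphology): each synthetic minority vector is
`x + U(0,1) * (x_nn - x)` for one of the k = 5 nearest minority neighbors.
Matrices are rebuilt from the triangles (negative synthetic SC clipped at
0) and all graph-derived features are recomputed on the reconstructed
graphs. Synthetic subjects carry no clinical values and are excluded from
clinical correlation. Balancing before the split mirrors the original
experimental design, but it demonstrably leaks: on a zero-effect 75/34
cohort the classifier reaches ~0.72 cross-validated accuracy purely by
recognizing interpolation artifacts of synthetic minority samples that
share parents with training folds. A leakage-safe ordering
(`smote_timing="train_only"`: split first, balance the training split
only) is provided and recommended for real analyses; null-calibration
experiments should use balanced cohorts without augmentation.

## The attention network

Two GAT layers on the binarized thresholded SC graph (or FC graph in the
`*-fc` modes) with self-loops; edge weights are not used inside attention.
Per head, `e_ij = LeakyReLU_0.2(a^T [W h_i || W h_j])` for first-order
neighbors, `alpha_ij = softmax_j(e_ij)`, `h'_i = ELU(sum_j alpha_ij W h_j)`.
Layer 1 has 6 heads of width 8, concatenated (width 48); layer 2 a single
head of width 8. The readout ranks nodes by the L2 norm of their final
embedding (parameter-free and deterministic; ties to the lower index) and
concatenates the top k = 20, giving a 160-dimensional graph embedding fed
to a [64, 16, 2] fully connected head with ReLU, dropout 0.5 and a softmax
output. Hidden width, heads, k and the MLP are configurable; the hidden
sizes are conventional choices at this problem scale.

The network, training loop and all gradients run on a small reverse-mode
automatic-differentiation engine written on numpy (`connectogat.autodiff`),
validated against central finite differences. Training minimizes
cross-entropy with minibatch Adam (batch 32, lr 5e-3, weight decay 5e-4;
one optimizer step per shuffled batch — full-batch stepping was observed
to stall on a long loss plateau at this scale), up to 300 epochs with
early stopping on validation loss (patience 30) and restoration of the
best-epoch parameters. All randomness (init, dropout, SMOTE, splits,
permutations, the generator) flows from explicit integer seeds; reruns are
byte-identical.

## Evaluation

10% of the (balanced) cohort is held out as a test set; the remainder is
split 80/20 into train/validation. The summary statistic is the mean of
the validation accuracies over 10 stratified folds, with the min–max
scaler refit inside each fold. Metrics use patients as the positive class
with `F1 = 2PR/(P+R)`. Significance of the observed accuracy is assessed
by label permutation with full retraining per permutation
(`p = (1 + #{null >= obs}) / (1 + P)`, add-one so p is never 0); a cheap
mode that permutes only evaluation labels exists for calibration smoke
tests and is labelled approximate.

## Interpretability

* **Fidelity** of head (l, p): mean over evaluation graphs of
  `1(yhat = y) - 1(yhat_masked = y)`, where masking replaces that head's
  attention rows with the uniform distribution over each node's
  neighborhood (removing what attention *learned* while preserving message
  scale). A zero mask is flag-gated. Evaluated on the validation split.
* **Saliency**: gradient of the predicted-class probability with respect
  to the n x 24 input, absolute values averaged over correctly predicted
  validation samples (a signed-mean mode is flag-gated). Entries above the
  0.02 default cutoff are "salient". Single-model attributions are
  initialization-dependent — equally accurate models can key on different,
  equally predictive structure — so `ensemble_saliency` (the mean map over
  models trained from consecutive seeds) is the recommended protocol when
  the map is read scientifically, and is what the planted-effect recovery
  tests exercise.
* **Attention summaries**: per-head mean coefficient matrix over correctly
  predicted samples (rows remain stochastic), symmetrized as
  `(A + A^T)/2` with a display threshold for plotting.
* **Clinical correlation**: Pearson r between each salient node-feature
  and each clinical variable (AAO, DOI, UPDRS-III, H&Y, MMSE, LEDD) over
  real patients with non-missing values (n >= 3), significant at
  uncorrected p < 0.005 by default; FDR/Bonferroni options exist but are
  off by default.

## Synthetic cohorts

The generator produces the statistical shape the pipeline assumes, not
images: an SC template with 4 communities and distance decay plus
lognormal subject noise; FC from a latent community-factor time-series
model (150 timepoints) so correlation matrices are valid by construction;
morphology around region-typical values; clinical variables at
published-cohort scales (e.g. UPDRS-III ~ 34.5 +/- 8.3) optionally coupled
linearly to a planted node's channel value, standardized across patients.
Disease is planted by scaling SC edges touching a set of affected nodes by
(1 - sc_effect), reducing FC factor loadings by fc_effect, and shrinking
morphology by morph_effect. Defaults: 75/34 subjects, 86 nodes, 5 evenly
spread affected nodes, sc_effect 0.3, fc_effect 0.2, morph_effect 0.1.

What this does *not* emulate: spatial autocorrelation of real parcels,
site/scanner effects, head-motion artifacts, hemispheric asymmetries, or
realistic tail behavior of tractography weights. Passing recovery tests
therefore shows the pipeline is correct and sensitive under its own
assumptions, not that the effect sizes transfer to real MRI cohorts.

## Problem sizes used in the shipped tests

Unit and property tests run on graphs with n <= 16 nodes where brute-force
enumeration is exact. The end-to-end recovery checks run the full 86-node,
75/34 design with sc_effect 0.5, SMOTE to 150, and 10-fold CV at 40
training epochs (patience 12) — enough for convergence on strongly
separable synthetic data while keeping a CV run to a few minutes on one
CPU; the saliency recovery uses a 3-model ensemble and the zero-effect
calibration a balanced 55/54 cohort without augmentation (the only design
whose chance level is 0.5). The permutation-calibration check uses the
cheap mode at reduced scale (12-node graphs, 19 permutations, 50
replicates).

## Known limitations

* Training is full-batch; minibatching would be needed far beyond ~10^3
  graphs.
* Louvain partitions (and hence Mod/PC) are seed-deterministic but not
  node-relabeling-equivariant, as for any stochastic community heuristic.
* The numpy autodiff engine favors clarity over speed; a 10-fold CV at
  full scale takes minutes, not seconds.
* Top-k readout selects nodes globally per graph; a per-channel variant
  is conceivable but not implemented.
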