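# Methods

`fedrad` implements a personalized ("robust") federated learning pipeline
for binary lesion classification across medical centres that cannot share
raw images, together with the downstream radiomic analysis and the clinical
evaluation statistics used to compare risk models. This note records the
models, the defaults and the design decisions that were genuinely open.

## Problem setting

K centres each hold 2-D grey-level lesion patches with a binary outcome
(postoperative recurrence vs non-recurrence) and a handful of clinical
covariates (sex, age, T-stage, N-stage, CA199 status). Class ratios and
image statistics differ between centres (non-IID), so a single federated
average (FedAvg) underfits some centres. The pipeline instead gives each
centre a personalized model built as a convex combination of all clients'
parameters, with mixing weights derived from how well each client's model
"prefers" each centre's data distribution — assessed on privacy-preserving
surrogate images rather than raw data.

## Local models

Each client trains a residual CNN under the focal loss
`L = -alpha (1 - p_t)^gamma log p_t` (defaults `alpha = 0.25`,
`gamma = 2`, its originating design's canonical values; `gamma = 0, alpha = 1`
recovers cross-entropy). Optimization is minibatch momentum SGD
(default lr `1e-3`, momentum 0.9) or RMSprop; probabilities are clamped at
`1e-7` before logs. Optionally each residual block carries a CBAM attention
pair applied to the residual branch before the identity addition: a channel
gate (shared two-layer MLP over average- and max-pooled channel
descriptors, sigmoid) and a spatial gate (mean and max maps over channels,
one convolution to a single map, sigmoid). Gating the branch rather than
the block output preserves the identity path; gating after the addition
attenuates the whole trunk by the mean gate (~0.25 per block) and in
practice made small-sample training collapse for many initialisations.

Two focal-loss companions matter for optimization at desk scale. First,
the output layer's positive-class bias is initialised to the minority
prior (`log(0.25/0.75)`), the standard pairing with the focal loss, so
training does not start at `p = 0.5` where the `(1 - p_t)^gamma` factor
attenuates every gradient uniformly. Second, the simulation experiments
train with RMSprop (lr `1e-3`): on this small un-normalized network,
momentum SGD was fragile across initialisations (occasionally freezing in
a near-constant-output state), while RMSprop fitted every tested seed.
The focal loss itself uses one `alpha` for both classes, so that
`gamma = 0, alpha = 1` reduces exactly to cross-entropy.

The *canonical* architecture uses ResNet18-style stages (widths
64/128/256/512, two blocks each, 3x3 stem) with **parameter-free
(option-A) shortcuts** — stride-2 subsampling plus zero channel padding —
per-block CBAM, and a trailing 1x1 "feature head" convolution with 537
channels. Kernel count: 64 (stem) + 3840 (stage convolutions) + 8 (one
single-channel spatial-attention convolution per block) + 537 (head)
= **4449** convolution kernels, matching the published total; the channel
gate is built from linear maps and therefore contributes no kernels. The
source architecture's exact layer list is not public, so this decomposition
is a constrained reconstruction: the printed kernel total is the one
verifiable constraint, and the head width is chosen to satisfy it.

All deep components run on `fedrad.nn`, a small reverse-mode engine written
on numpy (im2col convolutions, manual backward passes, seeded
initialisation). It exists because the pipeline needs full control over
parameter flattening, activation capture and per-layer gradients with a
pure-numpy footprint; gradients of every layer are verified against central
differences in the test suite.

## Representative data (WGAN) and privacy perturbation

Each centre trains one Wasserstein GAN per class (a DCGAN-style
convolutional generator/critic pair sized for square patches, default
64x64; RMSprop, critic weight clipping at 0.01 — the original Wasserstein
scheme). Uploaded representative sets are samples from these generators
with i.i.d. Gaussian noise added (default sigma 0.1 on the [-1, 1] image
range, i.e. 5% of the dynamic range; the source's true scale is not
public). `RepresentativeSet` objects can only be constructed from generator
output, so raw patches cannot enter an upload payload by construction.
Gradient-penalty Lipschitz regularisation is not offered: it requires
double backpropagation, which the engine intentionally omits; weight
clipping is the default and only mode.

## Relationship matrix, GCN adjacency, personalization

- **Preference mode** (default): entry `(i, j) = exp(-mean focal loss of
  model i on centre j's perturbed representative set)` — bounded in (0, 1],
  monotone in preference. The scoring formula is this package's choice; the
  source describes only "preference level".
- **Parameter-distance mode** (GAN-free ablation): pairwise Euclidean
  distances between flattened parameter vectors, converted to similarities
  with `exp(-d / median(d))`; the median scaling removes the free bandwidth
  parameter.

A 2-layer graph convolutional network (hidden width 16, symmetric
normalisation with self-loops) embeds the K clients; the row-softmax of the
embedding inner products is the row-stochastic adjacency. Two choices here
were genuinely open:

1. **Node features.** Raw relationship rows tie the feature axis to client
   ordering and would break exact permutation equivariance for a fixed
   seeded weight matrix. Node i's features are therefore its
   self-similarity followed by its *sorted* similarities to the other
   clients — permutation-invariant per node, making the whole
   relationship-to-adjacency map exactly equivariant under client
   relabelling (tested).
2. **Training objective.** The GCN weights are trained (default 300
   gradient steps, lr 0.2) to minimise a first-order surrogate of the
   personalized models' losses on their own representative data:
   `J(W) = sum_i g_i . (theta_hat_i - theta_i)` with
   `g_i = grad L_i(theta_i)`, so the constant matrix `M[i,j] = g_i .
   theta_j` (row-standardised) drives the updates. This linearisation makes
   the inner loop essentially free — no repeated network evaluations — at
   the cost of first-order accuracy around the current parameters. In the
   GAN-free ablation the gradients come from each client's own training
   data. On desk-scale runs the trained adjacency often converges to a
   low-entropy consensus (most rows concentrating on the client whose
   parameters reduce everyone's linearised loss); this is still a convex
   combination and empirically outperforms the FedAvg broadcast under
   non-IID shift.

Personalization is `theta_hat_i = sum_j A[i, j] theta_j`; every robust
weight therefore lies coordinatewise within the clients' range. With one
client the adjacency is [[1.0]] and federation degenerates to local
training; the FedAvg baseline is the sample-size-weighted parameter mean.

A federation round is: local training -> relationship matrix (WGAN
preference or parameter distance) -> GCN adjacency + personalization (or
FedAvg broadcast when the GCN component is off) -> next round. Defaults:
3 rounds (the source's round count is unstated). WGANs are trained once in
the first round and re-sampled each round.

## Federated radiomic features and selection

A feature is the spatial mean of one convolution kernel's activation map —
4449 features under the canonical model, one column per kernel in layer
order. Selection is filter-then-reduce:

- **Mann-Whitney U filter** (two-sided, default alpha 0.05). For
  `n1 + n2 <= 10` the exact tie-aware null is enumerated over all
  `C(n, n1)` assignments of the observed values, with two-sided p =
  `P(|U - n1 n2 / 2| >= |U_obs - n1 n2 / 2|)`; larger samples use scipy's
  tie-corrected normal approximation.
- **mRMR** (greedy MID): repeatedly add
  `argmax_f [I(f; y) - mean_{s in S} I(f; s)]`, mutual information on
  4-quantile-binned features, ties broken by column index; default k = 200.

## Common vs adaptive features

Cross-centre column correlations need a shared sample axis; since centres
have different patients, the convention here is to pool the perturbed
representative images and push them through each centre's model
(privacy-consistent; the source's exact protocol is not public). Per
feature, the *between* score is the mean over other centres of its maximum
absolute Pearson correlation with that centre's features, and the *within*
score is its maximum absolute correlation with its sibling features — "the
features displaying the highest correlation" read as a max, which also
makes planted-structure recovery robust. The top 5 by between score are
*common*; among the remainder the top 5 by (within - between) margin are
*adaptive*; the sets are disjoint by construction. Group dissimilarity is
the mean pairwise Euclidean distance between z-scored feature columns
across centres (z-scoring stops scale from dominating). Class-attention
heatmaps are gradient-weighted activation maps over the last residual
stage's second convolution, ReLU'd, max-normalised and bilinearly
upsampled; an all-zero map falls back to a uniform 0.5.

## SBELM classifier

A frozen random hidden layer (Uniform(-1,1) weights and biases, sigmoid,
appended bias column; default width 50 for ~200 inputs) feeds a Bayesian
logistic output layer with an ARD prior. Fitting alternates a Laplace
approximation of the posterior mode (Newton/IRLS, ridge jitter 1e-8 on a
singular Hessian) with the evidence update `alpha_i <- gamma_i / mu_i^2`,
`gamma_i = 1 - alpha_i Sigma_ii`; weights with `alpha_i > 1e9` are pruned
to exactly zero and never re-enter. Convergence: max relative alpha change
< 1e-4 or 200 outer iterations. Predictions default to the
variance-moderated (probit-approximation) sigmoid
`sigma(m / sqrt(1 + pi s^2 / 8))`. Class imbalance is handled upstream by
the focal loss in the deep stage; the SBELM likelihood is unweighted.

## Evaluation statistics

Trapezoidal AUC over unique thresholds (equal to the tie-halved rank
statistic), standard 2x2 confusion metrics (zero denominators reported as
NaN; default threshold 0.5, Youden-optimal offered), DeLong's
structural-component test for correlated AUCs (identical scores give p = 1
by convention), *continuous* NRI (the category-free variant, since no
categories are specified; a categorical variant would need user cutoffs)
and IDI with bootstrap p-values, and decision curves
`NB(pt) = TP/n - (FP/n) pt/(1-pt)` on a 99-point grid at 0.01 spacing.
Protocols: stratified threefold cross-validation; permutation robustness
(training patients reshuffled uniformly among centres, pipeline re-run,
per-centre mean ± sd of test AUC, sd flagged undefined at one
permutation); and a random-forest clinical baseline over T-stage, N-stage
and CA199 with out-of-fold scores so comparisons against imaging models
are honest.

## Synthetic cohort generator

Real multi-centre CT data is private, so experiments run on a synthetic
cohort that reproduces the published *structure* exactly: four centres,
293/140/109/99 patients (641 total), every train/test x class cell, and
per-cell clinical marginals (sex, age mean ± sd, N-stage, T-stage, CA199)
allocated to match the printed counts exactly when cohort sizes match
(sampled from the same frequencies otherwise; covariates are drawn
independently given the label, as no joint model is published).

Images are 2-D grey-level patches (default 64x64, 16-bit PNG on disk,
0-based half-open coordinates throughout): a background with a
centre-specific intensity offset, noise level and dominant texture
frequency (pairwise distinct across centres, inducing the non-IID shift),
plus an elliptical lesion whose boundary radius carries harmonic
perturbations. Class 1 lesions have stronger margin irregularity (relative
amplitude 0.11 vs 0.04), higher internal texture variance (sd 120 vs 50
grey units) and slightly higher contrast (360 vs 300). These magnitudes
were calibrated once so that a small CNN reaches test AUC ≈ 0.8-0.9 on a
single balanced centre — the performance regime of the real study — and a
linear read-out of raw pixel means reaches AUC ≈ 0.75, then frozen.

What the generator does *not* emulate: 3-D anatomy, scanner-specific
reconstruction artefacts, Hounsfield calibration, inter-observer contour
variability, or any correlation between imaging and clinical covariates.
Passing tests therefore demonstrate that the pipeline's machinery behaves
as specified under controlled distribution shift — not that it would reach
the published AUCs on real CT data, which are not reproducible without the
private cohort.

## Scaled-down experiment sizes

The simulation experiments (`fedrad.experiments`) run a miniature of the
four-centre study: 40 training and 40 test patients per centre with the
published per-centre class fractions, 32x32 inputs, a small CBAM ResNet
(widths 8/16, one block per stage, 74 kernels), 3 federation rounds of 5
local epochs, WGANs trained at 16x16 with 60
generator steps, and 8 representative images per class per centre. The
paired comparison trains both the personalized scheme and FedAvg from the
same initialisation on the same cohorts over 5 seeds; permutation
robustness re-runs the personalized pipeline over 5 reshuffles. These sizes
are the package's desk-scale defaults; all are configurable. Local
training in these experiments is RMSprop at lr 1e-3 (see above), 5 epochs
per round.

## Known limitations

- The GCN-trained adjacency can collapse to consensus on one client; a
  temperature or entropy regulariser would diversify rows but is not part
  of the reconstructed scheme.
- The linearised GCN objective ignores curvature; with large local updates
  the first-order surrogate can misrank clients.
- The Mann-Whitney exact path enumerates all assignments and is only used
  for n1 + n2 <= 10.
- The SBELM log-evidence is not monitored explicitly; convergence is
  declared on alpha stability, which in rare ill-conditioned cases can stop
  one update early.
- FedProx/Moon/HarmoFL/pFedMe-style baselines, DICOM ingestion and 3-D
  volumes are out of scope.
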