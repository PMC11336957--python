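# Methods

## Model

CCAN is a domain separation network for integrating a labeled scRNA-seq
*source* domain with an unlabeled *target* domain (scRNA-seq from another
protocol, or a scATAC-seq gene-activity matrix over the same genes), while
modelling the cell cycle as a circular confounder.

Each domain's cells×genes matrix X is encoded twice:

* a **shared encoder** — one three-layer selu MLP applied to both domains —
  produces the domain-invariant code z_s (default 64-dimensional) used for
  alignment and cell-type classification;
* a domain-specific **private encoder** — a three-layer tanh MLP per domain —
  produces the circular code z_p (default scalar), interpreted as cell-cycle
  pseudotime.

The decoder's first layer is V_circular·[sin z_p ; cos z_p] +
V_acyclic·z_s + b; the remaining two layers are linear and are shared by both
domains (one decoder, as the architecture's symbol reuse implies; a
per-domain decoder switch exists but is off by default).  Because everything
past the first layer is linear, the circular pathway's contribution to the
reconstruction is an exactly separable linear component — this is what
`remove_cycle_effect` subtracts.

A small selu MLP with softmax output classifies cell types from shared codes
only; private codes never reach the classifier.

## Losses

* reconstruction: per-cell-averaged squared Frobenius error summed over the
  two domains, (1/N_s)‖X_s−X̂_s‖² + (1/N_t)‖X_t−X̂_t‖².  The per-cell
  normalisation makes the term invariant to cell count.
* orthogonality: ‖z_ssᵀz_sp‖² + ‖z_tsᵀz_tp‖², pushing shared and private
  embeddings apart within each domain.
* MMD alignment: squared maximum mean discrepancy between the two domains'
  shared codes, multi-bandwidth Gaussian kernel with bandwidths
  {0.25, 0.5, 1, 2, 4} × the median pairwise distance of the pooled sample
  (the median is treated as a constant under differentiation).  A linear
  kernel is available for closed-form unit checks.
* classification: negated cross-entropy on labeled source cells, mean over
  cells, log clamped at 1e-12.  (The sign is the standard minimisation
  convention.)
* cluster alignment (refinement only): for every source–target pair,
  squared-Euclidean distance if the labels match, hinge max(0, m−d)
  otherwise, averaged over all N_s·N_t pairs, plus the mean over classes of
  squared centroid differences.  δ is the same-class indicator per pair;
  the centroid term is read as per-class differences averaged over K (the
  only reading that makes the sum over k meaningful).  Margin m defaults to
  1.0 in the standardised latent space.

Default weights: recons 1, diff 0.05, mmd 1, class 1, ca 0.1.  These are
tuning knobs of this implementation; ca = 0.1 balances the O(margin) scale of
the cluster-alignment term against the O(10⁻²) scale of the MMD so that
refinement tightens classes without degrading distributional alignment.

## Training schedule

Four steps: (1) pretrain on reconstruction + orthogonality + MMD +
classification; (2) transfer labels to the target via the classifier's argmax
on shared codes (ties to the lowest class index); (3) refine with the cluster
alignment term added to the alignment loss, iterating over class-balanced
mini-batches with pseudolabels held fixed (an optional `refine_rounds`
repeats steps 2–3); (4) freeze, re-predict target annotations, emit the joint
profile.  In paired mode (same cells measured in both modalities) step 2 is
skipped and the source labels drive the cluster alignment for both domains;
the joint profile is then the per-cell concatenation of both shared codes,
otherwise the row-stack of all cells in shared space.

Optimisation is Adam at learning rate 1e-3 with gradient-norm clipping at 5.
The epoch budget splits 70% pretrain / 30% refine by default.

**Circular warm-up.**  The first 25% of pretraining epochs (configurable via
`circular_warmup_fraction`) minimise only the reconstruction of the
*class-centred source residual* through the circular pathway, with the
acyclic branch zeroed.  Rationale: cell-cycle variation is within-type
variation, so class-centring removes the discrete type structure from the
warm-up signal; without this phase the higher-capacity shared branch absorbs
the periodic structure and the private code collapses onto a folded,
uninformative embedding (a known local optimum of circular autoencoders).
Both private encoders are warmed on the same residual — the shared decoder
carries the circular gene loadings across domains, so the target private
encoder subsequently locks onto the matching structure in its own domain.
This schedule is this package's design choice; it changes no loss definition.

**Balanced mini-batches (refinement).**  Each batch draws
floor(batch_size/K) cells per class; a remainder is assigned one-per-class by
ascending class index.  Classes are consumed in seeded shuffled cyclic order
and the number of batches per epoch is chosen so every cell appears at least
once — cells are recycled, never discarded.

## Downstream analyses

* **Pseudotime**: the scalar private code reduced modulo 2π.  Extraction
  requires `private_dim = 1`.
* **Phase calls**: a three-component 1-D Gaussian mixture fitted by EM after
  cutting the circle at the middle of the largest gap between sorted
  pseudotimes (so no cluster straddles the cut).  Components map to
  G1/S/G2M in ascending mean order — a naming convention only; biological
  phase identity must be established with marker genes, which is out of
  scope here.
* **Cycle-effect removal**: corrected X = X − (decoder output with the
  acyclic branch zeroed − decoder output with both branches zeroed),
  isolating the V_circular·[sin;cos] pathway through the linear tail.  The
  decomposition is exact because the decoder tail is linear.

## Metrics

kBET is reimplemented at its core: for each cell, a chi-squared
goodness-of-fit test of the k-NN batch composition against global batch
proportions (k defaults to 25); the score is the rejection fraction at
α = 0.05.  The published package's subsampling heuristics are not ported.
Coordinate ties are broken by a seeded jitter so results are deterministic.
RI/ARI/NMI and accuracy/macro-precision/recall/F1 delegate to scikit-learn
(NMI with arithmetic-mean normalisation; 0/0 precision-recall counted as 0).
"Separability" has no single standard formula; it is operationalised as the mean
silhouette coefficient with Euclidean distance, using the population form of
the intra-class mean (the cell's own class average includes the cell itself),
which makes the score exactly invariant to duplicating every cell.

## Synthetic data

The generators reproduce the statistical structure the method's experiments
assume, so everything is testable without downloads:

* **Cyclic base** (mESC-like): expression = softplus(baseline 5 + type
  program + cycle program + N(0,1)), with phase θ uniform on [0, 2π).  Each
  of the n_cycle_genes (default 20% of genes) varies as
  amplitude·sin(θ + gene offset), amplitude 3; each cell type adds a mean
  shift of 3 (log-scale units) on its own 10% gene program.  The baseline
  keeps softplus near-identity in the operating range, so nonnegativity does
  not distort effect sizes.
* **Virtual tumor**: a second subclone doubles a random 25% gene set; the
  merged cells split uniformly into two batches and batch 2 receives additive
  N(0, 0.5²) noise (σ unstated in the source experiments; 0.5 is this
  package's default).  Both batches carry *subclone* labels — in this
  scenario the subclones play the cell-type role and the cycle is the
  confounder.
* **Two-modality data**: the RNA domain is a cyclic base; the gene-activity
  domain pushes the same latent type/cycle factors through a random
  *diagonal* linear map (per-gene lognormal rescaling of the loadings),
  then adds noise, clamps negatives to zero and applies dropout at 0.3.
  The diagonal map preserves gene identity, as Signac-style gene-activity
  matrices do — a dense random map would scramble the gene axes, which no
  real gene-activity computation does.  Paired mode reuses the same cells;
  unpaired mode draws an independent cohort from the same type mixture.

What the generators do **not** emulate: count-depth variation and library
size effects, zero-inflation in RNA, peak-level ATAC structure,
doublets, batch-specific gene dropouts, and non-uniform cell-cycle stage
occupancy.  Passing tests therefore demonstrate the algorithmic behaviour of
the method under its own model assumptions, not performance on real data.

## Numerical choices and degenerate inputs

* Weight initialisation: uniform fan-in scaling, seeded; biases zero.
* Softmax is max-stabilised; cross-entropy clamps log at 1e-12.
* Zero-variance genes stay 0 under scaling; empty library rows are left
  unnormalised rather than divided by zero.
* Classifier ties resolve to the lowest class index; GMM components are
  ordered by mean; gene intersection is case-sensitive and sorted for
  determinism.
* A single-class source is rejected at pretraining (classifier undefined);
  a class with no target pseudolabels is rejected at refinement (its
  centroid is undefined) with a remediation hint.
* Problem sizes in the test and acceptance runs (200–500 cells/domain,
  60–100 genes, encoder [64, 32], latent 16, 20–500 epochs) are scaled-down
  versions of the default configuration (encoder [512, 256], latent 64,
  1000 epochs) chosen so the full suite runs on a laptop-class single CPU;
  the algorithms are size-agnostic.

## Known limitations

* Pseudotime is identified only up to rotation and reflection of the circle;
  the evaluation uses circular correlation, which respects that symmetry.
* The cycle-removal decomposition is exact only because the decoder tail is
  linear; a nonlinear decoder variant would make it an approximation.
* Label transfer assumes the two domains share the same cell-type set; a
  type absent from the source cannot be predicted, and a type absent from
  the target breaks the centroid term (reported as an error, by design).
* The circular warm-up relies on source labels; with very few labeled cells
  per class the class-centring becomes noisy.
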