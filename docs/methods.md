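# Methods

This note documents the models, conventions and numerical choices behind
`ppisxgb`, and what its synthetic benchmarks do and do not demonstrate.

## Feature encoding

Every residue carries a 49-dim vector in a frozen column order:
positions [0,20) the PSSM log-odds in alphabetical amino-acid order
`ACDEFGHIKLMNPQRSTVWY`, [20,29) the one-hot 9-state secondary structure in
order `HGIBETSL-`, [29,49) the one-hot residue identity. Two conventions
resolve ambiguities in the underlying formats:

* Any letter outside the 20 standard codes becomes `'X'`, whose one-hot
  row is all zeros — there is no 21st identity column.
* DSSP emits eight structure codes (blank = loop/irregular, mapped to
  `'L'`); the ninth state `'-'` ("no secondary structure") is reserved for
  residues absent from the DSSP output or for padding, and is filled in at
  record-assembly time. Each of the nine states therefore has exactly one
  home.

PSSM files are read in the ASCII dialect PSI-BLAST prints (two header
lines, a column-header line, one row per residue with 20 log-odds
integers; further columns and trailer statistics ignored) and remapped
from the file's own column order to the package order. PSSM values are
used raw by default; a logistic squash `1/(1+e^-x)` is available and
recorded with any saved model. Raw log-odds are the default because
tree-based learners are invariant to monotone per-feature transforms, so
the squash matters only for the neural encoder.

Local windows are 7 residues (343 dims); positions past a terminus
contribute all-zero rows, matching the zero-padding convention of the
global view. The global view is 500×49: shorter proteins zero-padded,
longer ones truncated at 500 (local features still use the full protein).
Truncation is the minimal completion for the over-length case; splitting
long proteins into tiles was rejected as it would create duplicate
residue identities in one dataset.

Residue positions are 0-based everywhere, including label files.
Unlabelled residues are *excluded* from training and evaluation rather
than imputed as non-sites (a config option restores the imputation).

## Convolutional encoder

The encoder follows the common two-stream design for residue-level
sequence labelling. Global stream: the padded sequence's residue
identities are embedded (21×`embed_dim`, default 32; padding embeds to
zero), concatenated with the 49-dim features, and passed through parallel
1-D convolution banks (kernel sizes {3,5,7}, 64 channels each, valid
padding, ReLU) followed by global max-pooling. Local stream: the 343-dim
window feature. The downstream classifier consumes the input of the first
fully connected layer,

    representation(i) = [pooled conv features ‖ local_343(i)],

so `representation_dim = n_kernels·channels + window·49` (535 at the
defaults). The FC head (512, 256, dropout 0.2) with a single logit exists
only to train the encoder, with class-weighted binary cross-entropy
(weight N_neg/N_pos by default) and Adam (lr 1e-3). Layer sizes are
package defaults, declared rather than claimed canonical; all are
configurable.

The network is implemented directly in numpy — im2col convolution,
hand-written backward passes, seeded initialisation — which keeps the
package dependency-light and bit-reproducible from a seed. Correctness of
the gradients is enforced by a finite-difference test over every
parameter group. Extraction always runs in evaluation mode (dropout off)
and is deterministic; one optimisation step is taken per protein with all
its labelled residues as the batch.

A bypass encoder (representation = raw local feature) removes the neural
stage entirely; with `include_global=True` it appends the 49-dim column
mean of the padded global matrix, giving tree learners access to
whole-protein composition without a network. The bypass mode is the
default for benchmarks because it makes the full pipeline deterministic
to the byte.

## Boosted trees

The classifier is a from-scratch second-order gradient-boosted tree
ensemble. Per round, first/second derivatives (g, h) of the loss at the
current margins are computed; one regression tree is grown by exact
greedy search; margins advance by `eta`·tree(x).

* **Leaf weights.** The per-leaf quadratic `G·ω + ½(H+λ)ω²` is minimised
  by ω* = −G/(H+λ). The minus sign is essential: the positive variant
  sometimes seen in write-ups maximises the objective instead, and our
  tests verify the minimiser by perturbation.
* **Split gain.** `½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − G²/(H+λ)] − γ`,
  verified to equal the before/after difference of the regularised
  objective and, on every small dataset, to agree with brute-force
  enumeration of all axis-aligned bipartitions.
* **Conventions.** Candidate thresholds are midpoints between consecutive
  distinct sorted values; routing is "left iff x < threshold"; ties break
  to the lowest feature index, then the lowest threshold. Because the
  vectorised cumulative-sum scan can perturb the last bits of genuinely
  tied candidates, near-ties are re-scored with direct partition sums
  before the tie-break — this keeps the learner exactly deterministic.
* **max_depth counts node levels**: `max_depth=1` is a single leaf,
  `max_depth=2` allows one split. (The reference XGBoost library counts
  split levels; the cross-check test maps accordingly.)
* **Losses.** Logistic deviance (default, with `pos_weight` for the
  ~15% class imbalance) and squared error (the regression form). Shrinkage
  `eta` defaults to 0.1; `eta=1` recovers the plain additive update.
  Defaults: λ=1, γ=0, max_depth=6, min_child_weight=1 (a Σh bound),
  n_rounds=200.
* **Scope.** Exact greedy only — no quantile sketches, sparsity-aware
  routing, row/column subsampling or parallel split search. The learner
  is a correctness-first reference implementation; on the desk-scale
  problems it targets (≲10⁴ residues × ≲500 features) training takes
  seconds to a couple of minutes.

Models serialise to JSON (params, feature count, nested tree nodes) —
portable and diffable.

## Evaluation

Thresholded metrics (predicted positive iff score ≥ threshold, default
0.5; optional training-calibrated F1-maximising threshold, both recorded)
are computed exactly from integer counts. Any metric with a zero
denominator reports 0 together with an explicit flag, so cross-validation
aggregation never propagates NaN. AUROC uses midrank Mann–Whitney;
AUPRC is the step-wise (right-continuous) sum without precision
interpolation, which equals average precision and reduces to prevalence
under constant scores.

Splits and k-fold cross-validation operate on whole proteins so that a
residue never shares a fold with its own window neighbours; fold sizes
are near-equal in protein count. All randomness flows from one root seed.

## Synthetic data generator

The generator emulates the statistical shape of residue-level interaction
site datasets: uniform sequences over the 20 letters; secondary structure
from a sticky first-order Markov chain (persistence 0.8 for H/E/L, 0.5
for the rarer states); PSSMs as a letter-dependent base profile (own
column ≈ +7, others −2) plus rounded Gaussian noise (sd 2), clipped to
[−10, 12] to mimic PSI-BLAST magnitudes.

Labels are planted by a logistic model. A fixed sparse weight vector
(30 non-zero coordinates over the 343 window dims, internal constant
seed, independent of the user seed) defines a local score; an optional
whole-protein term — the protein's helix content, i.e. the 'H' column
mean of the padded global matrix — defines a global score. Each component
is standardised to unit variance over the dataset and mixed as
`(z_local + γ·z_global)/√(1+γ²)` so that `global_signal` γ is the
relative weight of the protein-level signal and `signal_strength`
multiplies a unit-variance predictor. The intercept is solved (Brent) so
the expected positive rate hits the target, default 0.15.

Default conditions: 50 proteins of length 50–120, positive rate 0.15,
`signal_strength` 3.0. At strength 3 the Bayes-optimal AUROC of the
planting score is ≈0.93, leaving realistic headroom between a competent
learner and perfection; at strength 2 the ceiling is ≈0.88, and at 0 the
labels are independent of the features (verified: the true planting score
ranks held-out labels at AUROC ≈ 0.5).

What passing these benchmarks shows — and does not. Recovery of a planted
signal through the full pipeline demonstrates that encoding, boosting and
evaluation compose correctly and that no information leaks across the
protein-level split. It does not show that the features capture real
interface biology: the generator has no evolutionary conservation
structure, no true solvent-accessibility geometry, and its global term is
a deliberately simple composition property. Results on real datasets
depend on real PSSMs and DSSP assignments and on neural-encoder capacity
well beyond desk scale.

## Benchmark problem sizes

The packaged scientific checks use: 80 proteins (≈6,500 residues,
100 rounds, depth 4) for planted-vs-null signal recovery (held-out AUROC
≥ 0.85 planted, 0.4–0.6 null); 60 proteins with γ=1 for the
local-vs-global ablation (global-aware features must raise held-out
recall); 200 random small datasets plus 10⁴ random partitions for the
boosting-math oracles; 10⁴ random confusion tables for metric exactness;
and a 20-protein run executed twice for byte-identical reproducibility.
These sizes keep the whole suite at a few minutes on one CPU while
leaving each conclusion statistically unambiguous.

## Known limitations

* The convolutional encoder trains by per-protein gradient steps; very
  large datasets would want minibatching across proteins and a compiled
  backend.
* Exact-greedy split search is O(nodes · n · m); histogram-based
  approximations are deliberately out of scope.
* The generator's PSSMs are noise around an identity-like profile, far
  simpler than real evolutionary profiles.
* Proteins longer than 500 residues lose global (but not local)
  information to truncation.
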