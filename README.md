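# ppisxgb

Residue-level prediction of protein–protein interaction sites (PPIS) from
sequence profiles, combining a convolutional feature encoder with a
from-scratch second-order gradient-boosted tree classifier.

## The problem

A protein–protein interaction site is a surface residue through which two
proteins bind. Identifying these residues experimentally is slow and
expensive, so sequence-based predictors are widely used: given a protein's
sequence, its evolutionary profile (a PSSM from iterative homology search)
and a secondary-structure assignment (DSSP), classify every residue as
interface or non-interface. The task is heavily imbalanced — typically
~15% of labelled residues are interaction sites.

`ppisxgb` is for structural-bioinformatics practitioners who have those
three inputs per protein (plus training labels) and want a transparent,
fully reproducible classifier whose every component — feature encoding,
representation learning, boosting mathematics, evaluation — is open and
testable.

## The method

**Features.** Each residue *i* is described by 49 numbers: 20 PSSM
log-odds, a one-hot encoding of its 9-state secondary structure
(H, G, I, B, E, T, S, L and '-' for "no secondary structure"), and a
one-hot encoding of its amino-acid identity. Two views are built:

* *local*: the 49-dim rows of a 7-residue window centred on *i*
  (positions i−3 … i+3), concatenated into a 343-dim vector, with
  all-zero rows past the termini;
* *global*: the whole protein as a fixed 500×49 matrix, zero-padded for
  shorter proteins and truncated for longer ones.

**Encoder.** A multi-scale 1-D convolutional network (embedding of the
residue identities ‖ the 49-dim features → conv banks with kernel sizes
{3,5,7} → ReLU → global max-pooling → two fully connected layers → logit),
implemented directly in numpy with hand-written gradients and Adam. The
*refined representation* of residue *i* is the input of the first fully
connected layer: `[pooled conv features ‖ local₃₄₃(i)]`. A *bypass*
encoder (identity on the local feature, optionally appending the 49-dim
mean of the global matrix) makes the rest of the pipeline trainable and
exactly reproducible without any neural training.

**Classifier.** Gradient-boosted regression trees with the second-order
Taylor objective, written from scratch: at round *t*

```
margin_t(x) = margin_{t-1}(x) + η f_t(x)
obj   = Σᵢ [gᵢ f(xᵢ) + ½ hᵢ f(xᵢ)²] + γT + ½λ Σⱼ ωⱼ²
ωⱼ*   = −Gⱼ / (Hⱼ + λ)
gain  = ½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − G²/(H+λ)] − γ
```

with exact-greedy split search (every midpoint between consecutive
distinct feature values), logistic or squared loss, a positive-class
weight for the imbalance, and deterministic tie-breaking. The learner is
verified against brute-force enumeration oracles and against the
reference XGBoost library under matched hyperparameters.

**Evaluation.** Accuracy, precision, recall, F1 and the Matthews
correlation coefficient from exact integer counts; AUROC by the
Mann–Whitney rank formulation (midranks for ties); AUPRC as the
step-wise precision–recall sum. Train/test splits and k-fold
cross-validation are always at the protein level.

**Synthetic data.** A generator produces complete datasets — sequences,
integer PSSMs, Markov-chain secondary structure, and labels planted by a
logistic model on the true window features (~15% positives) — so the whole
pipeline is testable end-to-end with no downloads.

## Worked example

```python
from ppisxgb import (SimConfig, simulate_proteins, InteractionSiteModel,
                     BoostParams, split_proteins)

records = simulate_proteins(SimConfig(n_proteins=30, seed=0))
parts = split_proteins(records, {"train": 0.8, "test": 0.2}, seed=0)
model = InteractionSiteModel(parts["train"],
                             boost_params=BoostParams(n_rounds=60, max_depth=4))
results = model.fit()
print(results.summary())
report = results.evaluate(parts["test"])
print(f"held-out AUROC {report.auroc:.3f}  AUPRC {report.auprc:.3f}  "
      f"recall {report.recall:.3f}  MCC {report.mcc:.3f}")
```

prints

```
Interaction-site classifier (encoder + boosted trees)
========================================================
Encoder:                    BypassEncoder
Representation dim:         343
Training residues:          2056
Positive fraction:          0.1391
Boosting rounds:            60
eta / lambda / gamma:       0.1 / 1.0 / 0.0
max_depth / min_child_w:    4 / 1.0
pos_weight:                 6.1888
Decision threshold:         0.5
--------------------------------------------------------
In-sample (training) metrics
       ACC      Prec    Recall        F1       MCC
    0.9144    0.6256    0.9580    0.7569    0.7314
AUROC:                      0.9848
AUPRC:                      0.9229
========================================================
held-out AUROC 0.868  AUPRC 0.567  recall 0.660  MCC 0.481
```

The representation here is the raw 343-dim local window feature (bypass
encoder); `pos_weight` was derived automatically from the ~14% positive
rate; the gap between in-sample and held-out metrics is the expected
optimism of training-set evaluation. Held-out AUROC of 0.868 against a
Bayes ceiling of ≈0.93 for this generator setting shows the classifier
recovers most of the planted signal.

The same run is available from the shell:

```bash
ppisxgb simulate --out fixtures --seed 0 --n-proteins 30
ppisxgb train --config run.yaml        # config points at fixtures/manifest.json
ppisxgb crossval --config run.yaml -k 5
```

Label files are tab-separated `id<TAB>position<TAB>{0,1}` with 0-based
positions.

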