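"""Model/Results facade tying the encoder and the boosted trees together.

:class:`InteractionSiteModel` is constructed from assembled protein
records and hyperparameters; :meth:`InteractionSiteModel.fit` trains the
encoder (unless the bypass encoder is used), extracts one representation
per labelled residue, fits the boosted-tree classifier on them and returns
an :class:`InteractionSiteResults` carrying both fitted components, the
in-sample evaluation and a ``summary()`` table.  Scoring new proteins and
evaluating held-out sets hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import encoder_net, gbtree, metrics
from .io_formats import LABEL_MISSING, ProteinRecord


def _extract_dataset(
    encoder, records: list[ProteinRecord]
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Representations and labels for every *labelled* residue."""
    X_parts, y_parts, keys = [], [], []
    for rec in records:
        if rec.labels is None:
            continue
        mask = rec.labels != LABEL_MISSING
        if not mask.any():
            continue
        reps = encoder.extract_all(rec)[mask]
        X_parts.append(reps)
        y_parts.append(rec.labels[mask])
        keys.extend((rec.id, int(i)) for i in np.nonzero(mask)[0])
    if not X_parts:
        raise ValueError("no labelled residues in the dataset")
    return np.concatenate(X_parts), np.concatenate(y_parts), keys


class InteractionSiteModel:
    """Residue-level interaction-site classifier: encoder + boosted trees.

    Parameters
    ----------
    records
        Assembled training proteins (sequence, PSSM, secondary structure,
        labels).
    encoder
        ``"bypass"`` (raw local window features, optionally plus a global
        summary via ``include_global``), ``"cnn"`` (the convolutional
        encoder), or a ready-made encoder object.
    boost_params
        Hyperparameters of the boosted-tree classifier; positive-class
        weight defaults to N_neg/N_pos of the training residues when the
        supplied (or default) value is the neutral 1.0 and
        ``auto_pos_weight`` is left on.
    """

    def __init__(
        self,
        records: list[ProteinRecord],
        encoder: str | object = "bypass",
        encoder_config: encoder_net.EncoderConfig | None = None,
        boost_params: gbtree.BoostParams | None = None,
        include_global: bool = False,
        window_size: int = 7,
        max_len: int = 500,
        encoder_epochs: int = 5,
        encoder_lr: float = 1e-3,
        auto_pos_weight: bool = True,
    ):
        if not records:
            raise ValueError("no training records")
        self.records = records
        self.window_size = window_size
        self.max_len = max_len
        self.encoder_epochs = encoder_epochs
        self.encoder_lr = encoder_lr
        self.auto_pos_weight = auto_pos_weight
        self.boost_params = boost_params or gbtree.BoostParams()
        if isinstance(encoder, str):
            if encoder == "bypass":
                self.encoder = encoder_net.BypassEncoder(
                    window_size=window_size, max_len=max_len, include_global=include_global
                )
                self._needs_training = False
            elif encoder == "cnn":
                cfg = encoder_config or encoder_net.EncoderConfig(
                    window_size=window_size, max_len=max_len
                )
                self.encoder = encoder_net.build_encoder(cfg)
                self._needs_training = True
            else:
                raise ValueError(f"unknown encoder '{encoder}'")
        else:
            self.encoder = encoder
            self._needs_training = isinstance(encoder, encoder_net.EncoderModel)

    def fit(self, train_encoder: bool | None = None) -> "InteractionSiteResults":
        """Train encoder (when applicable) and boosted trees; return results."""
        if train_encoder is None:
            train_encoder = self._needs_training
        if train_encoder:
            encoder_net.train_encoder(
                self.encoder, self.records, epochs=self.encoder_epochs, lr=self.encoder_lr
            )
        X, y, keys = _extract_dataset(self.encoder, self.records)
        params = self.boost_params
        if self.auto_pos_weight and params.pos_weight == 1.0:
            n_pos = int((y == 1).sum())
            if 0 < n_pos < y.size:
                from dataclasses import replace

                params = replace(params, pos_weight=float((y == 0).sum()) / n_pos)
        booster = gbtree.fit(X, y, params)
        scores = booster.predict_proba(X)
        return InteractionSiteResults(model=self, booster=booster, train_keys=keys,
                                      train_scores=scores, train_labels=y)


@dataclass
class InteractionSiteResults:
    """Fitted encoder + booster with training diagnostics."""

    model: InteractionSiteModel
    booster: gbtree.BoostedTreeModel
    train_keys: list[tuple[str, int]]
    train_scores: np.ndarray
    train_labels: np.ndarray
    threshold: float = 0.5

    @property
    def encoder(self):
        return self.model.encoder

    def calibrate_threshold(self) -> float:
        """Set the decision threshold to the training-set F1 maximiser."""
        self.threshold = metrics.best_f1_threshold(self.train_labels, self.train_scores)
        return self.threshold

    def predict(self, records: list[ProteinRecord]) -> pd.DataFrame:
        """Score every residue of every protein: columns id, pos, score, call."""
        rows = []
        for rec in records:
            reps = self.encoder.extract_all(rec)
            scores = self.booster.predict_proba(reps)
            for i, s in enumerate(scores):
                rows.append((rec.id, i, float(s), int(s >= self.threshold)))
        return pd.DataFrame(rows, columns=["id", "pos", "score", "call"])

    def evaluate(
        self, records: list[ProteinRecord], threshold: float | None = None
    ) -> metrics.EvaluationReport:
        """Full residue-level report on labelled residues of ``records``."""
        thr = self.threshold if threshold is None else threshold
        ys, ss = [], []
        for rec in records:
            if rec.labels is None:
                continue
            mask = rec.labels != LABEL_MISSING
            if not mask.any():
                continue
            reps = self.encoder.extract_all(rec)[mask]
            ys.append(rec.labels[mask])
            ss.append(self.booster.predict_proba(reps))
        if not ys:
            raise ValueError("no labelled residues to evaluate")
        return metrics.evaluate(np.concatenate(ys), np.concatenate(ss), thr)

    def training_report(self) -> metrics.EvaluationReport:
        return metrics.evaluate(self.train_labels, self.train_scores, self.threshold)

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-flavoured text table)."""
        rep = self.training_report()
        enc = self.encoder
        enc_name = type(enc).__name__
        lines = [
            "Interaction-site classifier (encoder + boosted trees)",
            "=" * 56,
            f"{'Encoder:':<28}{enc_name}",
            f"{'Representation dim:':<28}{enc.representation_dim}",
            f"{'Training residues:':<28}{self.train_labels.size}",
            f"{'Positive fraction:':<28}{float(np.mean(self.train_labels == 1)):.4f}",
            f"{'Boosting rounds:':<28}{len(self.booster.trees)}",
            f"{'eta / lambda / gamma:':<28}"
            f"{self.booster.params.eta} / {self.booster.params.lambda_} / {self.booster.params.gamma}",
            f"{'max_depth / min_child_w:':<28}"
            f"{self.booster.params.max_depth} / {self.booster.params.min_child_weight}",
            f"{'pos_weight:':<28}{self.booster.params.pos_weight:.4f}",
            f"{'Decision threshold:':<28}{self.threshold}",
            "-" * 56,
            "In-sample (training) metrics",
            f"{'ACC':>10}{'Prec':>10}{'Recall':>10}{'F1':>10}{'MCC':>10}",
            f"{rep.acc:>10.4f}{rep.precision:>10.4f}{rep.recall:>10.4f}{rep.f1:>10.4f}{rep.mcc:>10.4f}",
            f"{'AUROC:':<28}{rep.auroc:.4f}",
            f"{'AUPRC:':<28}{rep.auprc:.4f}",
            "=" * 56,
        ]
        return "\n".join(lines)
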