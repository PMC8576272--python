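"""Convolutional sequence encoder, implemented directly in numpy.

The network mirrors the two-stream architecture common in residue-level
sequence labelling: the *global* stream embeds the residue identities of
the whole (padded/truncated) sequence, concatenates the embedding with the
49-dim per-residue features, runs multi-scale 1-D convolutions (one bank
per kernel size) with ReLU and global max-pooling; the *local* stream is
the 343-dim window feature of the residue under consideration.  The two
streams are concatenated and passed through two fully connected ReLU
layers (with dropout during training) to a single logit, trained with
class-weighted binary cross-entropy and Adam.

The *refined representation* handed to the downstream boosted-tree
classifier is the input of the first fully connected layer:

    representation(i) = [ pooled conv features  ||  local_343(i) ]

so ``representation_dim = n_kernels * conv_channels + window_size * 49``.
Extraction always runs in evaluation mode (dropout off) and is therefore
deterministic.

A :class:`BypassEncoder` replaces the network with the identity on the
local feature (optionally appending a 49-dim mean over the global rows),
so the rest of the pipeline is exercisable without any neural training.

Forward/backward passes are hand-written; convolution uses an im2col
matrix product.  This keeps the whole package dependency-light and exactly
reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import encoding
from .io_formats import AA_INDEX, ProteinRecord


@dataclass
class EncoderConfig:
    embed_dim: int = 32
    conv_kernel_sizes: tuple[int, ...] = (3, 5, 7)
    conv_channels: int = 64
    fc_sizes: tuple[int, int] = (512, 256)
    dropout: float = 0.2
    window_size: int = encoding.DEFAULT_WINDOW
    max_len: int = encoding.DEFAULT_MAX_LEN
    seed: int = 0

    def __post_init__(self) -> None:
        self.conv_kernel_sizes = tuple(int(k) for k in self.conv_kernel_sizes)
        self.fc_sizes = tuple(int(s) for s in self.fc_sizes)
        for name in ("embed_dim", "conv_channels", "window_size", "max_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.conv_kernel_sizes:
            raise ValueError("conv_kernel_sizes must be non-empty")
        for k in self.conv_kernel_sizes:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"conv_kernel_sizes must be odd and >= 1, got {k}")
            if k > self.max_len:
                raise ValueError(f"kernel size {k} exceeds max_len {self.max_len}")
        if len(self.fc_sizes) != 2 or min(self.fc_sizes) < 1:
            raise ValueError("fc_sizes must be a pair of positive ints")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.window_size % 2 == 0:
            raise ValueError("window_size must be odd")

    @property
    def representation_dim(self) -> int:
        return len(self.conv_kernel_sizes) * self.conv_channels + self.window_size * encoding.RESIDUE_DIM

    @property
    def conv_in_channels(self) -> int:
        return encoding.RESIDUE_DIM + self.embed_dim


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class EncoderModel:
    """Parameter container plus forward/backward passes for the encoder."""

    def __init__(self, config: EncoderConfig):
        self.config = config
        self.training_history: list[dict] = []
        rng = np.random.default_rng(config.seed)
        c_in = config.conv_in_channels
        self.params: dict[str, np.ndarray] = {}
        # 21 embedding rows: 20 amino acids + 'X'; padding positions embed to zero
        self.params["embed"] = rng.normal(scale=0.1, size=(21, config.embed_dim))
        for k in config.conv_kernel_sizes:
            fan_in = k * c_in
            self.params[f"convW{k}"] = rng.normal(scale=np.sqrt(2.0 / fan_in), size=(fan_in, config.conv_channels))
            self.params[f"convb{k}"] = np.zeros(config.conv_channels)
        d = config.representation_dim
        f1, f2 = config.fc_sizes
        self.params["W1"] = rng.normal(scale=np.sqrt(2.0 / d), size=(d, f1))
        self.params["b1"] = np.zeros(f1)
        self.params["W2"] = rng.normal(scale=np.sqrt(2.0 / f1), size=(f1, f2))
        self.params["b2"] = np.zeros(f2)
        self.params["W3"] = rng.normal(scale=np.sqrt(2.0 / f2), size=(f2, 1))
        self.params["b3"] = np.zeros(1)

    @property
    def representation_dim(self) -> int:
        return self.config.representation_dim

    # ---- global (convolutional) stream ------------------------------------

    def _conv_input(self, record: ProteinRecord) -> tuple[np.ndarray, np.ndarray]:
        """(max_len, 49+embed_dim) conv input and the padded residue indices."""
        cfg = self.config
        block = encoding.residue_features(record)
        G = encoding.global_feature(block, cfg.max_len)
        idx = np.full(cfg.max_len, -1, dtype=int)
        n = min(len(record), cfg.max_len)
        for i, aa in enumerate(record.sequence[:n]):
            idx[i] = 20 if aa == "X" else AA_INDEX[aa]
        E = np.zeros((cfg.max_len, cfg.embed_dim))
        real = idx >= 0
        E[real] = self.params["embed"][idx[real]]
        return np.concatenate([G, E], axis=1), idx

    def _conv_forward(self, record: ProteinRecord) -> tuple[np.ndarray, dict]:
        """Pooled multi-scale conv vector for one protein plus backprop cache."""
        cfg = self.config
        Cin, idx = self._conv_input(record)
        cache: dict = {"idx": idx, "cols": {}, "argmax": {}, "pre": {}}
        pooled = []
        for k in cfg.conv_kernel_sizes:
            cols = np.lib.stride_tricks.sliding_window_view(Cin, (k, Cin.shape[1]))[:, 0]
            cols = cols.reshape(cols.shape[0], -1)  # (T_out, k*c_in)
            pre = cols @ self.params[f"convW{k}"] + self.params[f"convb{k}"]
            act = _relu(pre)
            arg = act.argmax(axis=0)
            pooled.append(act[arg, np.arange(act.shape[1])])
            cache["cols"][k] = cols
            cache["argmax"][k] = arg
            cache["pre"][k] = pre
        return np.concatenate(pooled), cache

    def _conv_backward(self, dpooled: np.ndarray, cache: dict, grads: dict) -> None:
        """Accumulate conv/embedding gradients given d(loss)/d(pooled vector)."""
        cfg = self.config
        c = cfg.conv_channels
        idx = cache["idx"]
        dCin = None
        off = 0
        for k in cfg.conv_kernel_sizes:
            dp = dpooled[off : off + c]
            off += c
            cols = cache["cols"][k]
            arg = cache["argmax"][k]
            pre = cache["pre"][k]
            dpre = np.zeros_like(pre)
            ch = np.arange(c)
            live = pre[arg, ch] > 0
            dpre[arg[live], ch[live]] = dp[live]
            grads[f"convW{k}"] += cols.T @ dpre
            grads[f"convb{k}"] += dpre.sum(axis=0)
            dcols = dpre @ self.params[f"convW{k}"].T  # (T_out, k*c_in)
            c_in = cfg.conv_in_channels
            if dCin is None:
                dCin = np.zeros((cfg.max_len, c_in))
            dcols = dcols.reshape(-1, k, c_in)
            for dt in range(k):
                dCin[dt : dt + dcols.shape[0]] += dcols[:, dt, :]
        # only the embedding slice of the conv input is learnable
        dE = dCin[:, encoding.RESIDUE_DIM :]
        real = idx >= 0
        np.add.at(grads["embed"], idx[real], dE[real])

    # ---- FC head -----------------------------------------------------------

    def _head_forward(self, reps: np.ndarray, rng: np.random.Generator | None) -> tuple[np.ndarray, dict]:
        """Logits for a batch of representations; rng enables dropout."""
        p = self.params
        cfg = self.config
        z1 = reps @ p["W1"] + p["b1"]
        a1 = _relu(z1)
        m1 = None
        if rng is not None and cfg.dropout > 0:
            m1 = (rng.random(a1.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            a1 = a1 * m1
        z2 = a1 @ p["W2"] + p["b2"]
        a2 = _relu(z2)
        m2 = None
        if rng is not None and cfg.dropout > 0:
            m2 = (rng.random(a2.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            a2 = a2 * m2
        logits = (a2 @ p["W3"] + p["b3"]).ravel()
        return logits, {"reps": reps, "z1": z1, "a1": a1, "m1": m1, "z2": z2, "a2": a2, "m2": m2}

    def _head_backward(self, dlogits: np.ndarray, cache: dict, grads: dict) -> np.ndarray:
        p = self.params
        dl = dlogits[:, None]
        grads["W3"] += cache["a2"].T @ dl
        grads["b3"] += dl.sum(axis=0)
        da2 = dl @ p["W3"].T
        if cache["m2"] is not None:
            da2 = da2 * cache["m2"]
        dz2 = da2 * (cache["z2"] > 0)
        grads["W2"] += cache["a1"].T @ dz2
        grads["b2"] += dz2.sum(axis=0)
        da1 = dz2 @ p["W2"].T
        if cache["m1"] is not None:
            da1 = da1 * cache["m1"]
        dz1 = da1 * (cache["z1"] > 0)
        grads["W1"] += cache["reps"].T @ dz1
        grads["b1"] += dz1.sum(axis=0)
        return dz1 @ p["W1"].T  # gradient w.r.t. the representations

    # ---- public API --------------------------------------------------------

    def extract_all(self, record: ProteinRecord) -> np.ndarray:
        """Deterministic L x representation_dim matrix for every residue."""
        pooled, _ = self._conv_forward(record)
        block = encoding.residue_features(record)
        local = encoding.local_window_features(block, self.config.window_size)
        return np.concatenate([np.tile(pooled, (len(record), 1)), local], axis=1)

    def extract_representation(self, record: ProteinRecord, i: int) -> np.ndarray:
        if not 0 <= i < len(record):
            raise IndexError(f"residue index {i} out of range for length {len(record)}")
        pooled, _ = self._conv_forward(record)
        block = encoding.residue_features(record)
        local = encoding.local_window_feature(block, i, self.config.window_size)
        return np.concatenate([pooled, local])

    def predict_proba(self, record: ProteinRecord) -> np.ndarray:
        logits, _ = self._head_forward(self.extract_all(record), rng=None)
        return _sigmoid(logits)


class BypassEncoder:
    """Identity 'encoder': the representation is the raw local window feature.

    With ``include_global`` the 49-dim column mean of the global feature is
    appended, giving downstream learners access to whole-protein signal
    without any neural machinery.
    """

    def __init__(
        self,
        window_size: int = encoding.DEFAULT_WINDOW,
        max_len: int = encoding.DEFAULT_MAX_LEN,
        include_global: bool = False,
    ):
        self.window_size = window_size
        self.max_len = max_len
        self.include_global = include_global
        self.training_history: list[dict] = []

    @property
    def representation_dim(self) -> int:
        d = self.window_size * encoding.RESIDUE_DIM
        return d + (encoding.RESIDUE_DIM if self.include_global else 0)

    def extract_all(self, record: ProteinRecord) -> np.ndarray:
        block = encoding.residue_features(record)
        local = encoding.local_window_features(block, self.window_size)
        if not self.include_global:
            return local
        gmean = encoding.global_feature(block, self.max_len).mean(axis=0)
        return np.concatenate([local, np.tile(gmean, (len(record), 1))], axis=1)

    def extract_representation(self, record: ProteinRecord, i: int) -> np.ndarray:
        if not 0 <= i < len(record):
            raise IndexError(f"residue index {i} out of range for length {len(record)}")
        return self.extract_all(record)[i]


def build_encoder(config: EncoderConfig) -> EncoderModel:
    """Untrained encoder with seeded parameter initialisation."""
    return EncoderModel(config)


def _adam_step(params, grads, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
    for name, g in grads.items():
        m, v = state[name]
        m[:] = beta1 * m + (1 - beta1) * g
        v[:] = beta2 * v + (1 - beta2) * g * g
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        params[name] -= lr * mhat / (np.sqrt(vhat) + eps)


def train_encoder(
    model: EncoderModel,
    dataset: list[ProteinRecord],
    epochs: int = 10,
    lr: float = 1e-3,
    class_weight: float | None = None,
    val_dataset: list[ProteinRecord] | None = None,
) -> EncoderModel:
    """Train the encoder residue-wise with class-weighted cross-entropy.

    ``class_weight`` is the loss weight of positive residues; ``None``
    derives N_neg/N_pos from the data.  One optimisation step is taken per
    protein (all its labelled residues as one batch).  Appends per-epoch
    mean training (and optional validation) loss to ``training_history``.
    """
    from .io_formats import LABEL_MISSING

    labelled = [r for r in dataset if r.labels is not None and np.any(r.labels != LABEL_MISSING)]
    if not labelled:
        raise ValueError("no labelled residues in the training set")
    if class_weight is None:
        ys = np.concatenate([r.labels[r.labels != LABEL_MISSING] for r in labelled])
        n_pos = int((ys == 1).sum())
        class_weight = float((ys == 0).sum()) / n_pos if n_pos else 1.0

    rng = np.random.default_rng(model.config.seed + 1)
    state = {name: (np.zeros_like(p), np.zeros_like(p)) for name, p in model.params.items()}
    t = 0
    for epoch in range(epochs):
        order = rng.permutation(len(labelled))
        total_loss, total_w = 0.0, 0.0
        for pi in order:
            rec = labelled[pi]
            mask = rec.labels != LABEL_MISSING
            y = rec.labels[mask].astype(float)
            pooled, conv_cache = model._conv_forward(rec)
            block = encoding.residue_features(rec)
            local = encoding.local_window_features(block, model.config.window_size)[mask]
            reps = np.concatenate([np.tile(pooled, (local.shape[0], 1)), local], axis=1)
            logits, head_cache = model._head_forward(reps, rng=rng)
            p = _sigmoid(logits)
            w = np.where(y == 1, class_weight, 1.0)
            pc = np.clip(p, 1e-12, 1 - 1e-12)
            loss = -np.sum(w * (y * np.log(pc) + (1 - y) * np.log(1 - pc)))
            total_loss += float(loss)
            total_w += float(w.sum())
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss on protein {rec.id}")

            grads = {name: np.zeros_like(pm) for name, pm in model.params.items()}
            dlogits = w * (p - y) / max(w.sum(), 1.0)
            dreps = model._head_backward(dlogits, head_cache, grads)
            dpooled = dreps[:, : pooled.size].sum(axis=0)
            model._conv_backward(dpooled, conv_cache, grads)
            t += 1
            if lr > 0:
                _adam_step(model.params, grads, state, lr, t)

        entry = {"epoch": epoch, "train_loss": total_loss / max(total_w, 1.0)}
        if val_dataset:
            entry["val_loss"] = _dataset_loss(model, val_dataset, class_weight)
        model.training_history.append(entry)
    return model


def _dataset_loss(model: EncoderModel, dataset: list[ProteinRecord], class_weight: float) -> float:
    from .io_formats import LABEL_MISSING

    total_loss, total_w = 0.0, 0.0
    for rec in dataset:
        if rec.labels is None:
            continue
        mask = rec.labels != LABEL_MISSING
        if not mask.any():
            continue
        y = rec.labels[mask].astype(float)
        logits, _ = model._head_forward(model.extract_all(rec)[mask], rng=None)
        p = np.clip(_sigmoid(logits), 1e-12, 1 - 1e-12)
        w = np.where(y == 1, class_weight, 1.0)
        total_loss += float(-np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))
        total_w += float(w.sum())
    return total_loss / max(total_w, 1.0)


# ---- checkpointing ---------------------------------------------------------


def save_encoder(model: EncoderModel | BypassEncoder, path) -> None:
    """JSON header + flattened parameter arrays (text, reproducible)."""
    import json
    from pathlib import Path

    path = Path(path)
    if isinstance(model, BypassEncoder):
        path.write_text(
            json.dumps(
                {
                    "kind": "bypass",
                    "window_size": model.window_size,
                    "max_len": model.max_len,
                    "include_global": model.include_global,
                }
            )
        )
        return
    payload = {
        "kind": "cnn",
        "config": asdict(model.config),
        "params": {k: v.tolist() for k, v in model.params.items()},
        "training_history": model.training_history,
    }
    path.write_text(json.dumps(payload))


def load_encoder(path) -> EncoderModel | BypassEncoder:
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    if d["kind"] == "bypass":
        return BypassEncoder(
            window_size=d["window_size"], max_len=d["max_len"], include_global=d["include_global"]
        )
    cfg = d["config"]
    cfg["conv_kernel_sizes"] = tuple(cfg["conv_kernel_sizes"])
    cfg["fc_sizes"] = tuple(cfg["fc_sizes"])
    model = EncoderModel(EncoderConfig(**cfg))
    model.params = {k: np.asarray(v, dtype=float) for k, v in d["params"].items()}
    model.training_history = d.get("training_history", [])
    return model
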