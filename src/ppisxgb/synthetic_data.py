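"""Self-contained synthetic proteins for testing and calibration.

Each simulated protein carries the four ingredients real data would bring:

* a plausible amino-acid sequence (uniform over the 20 standard letters);
* an integer log-odds PSSM — a letter-dependent base profile (high score
  on the residue's own column, mildly negative elsewhere) plus rounded
  Gaussian noise, clipped to [-10, 12] to mimic PSI-BLAST magnitudes;
* a 9-state secondary-structure string from a first-order Markov chain
  with sticky helix/strand states;
* binary interaction-site labels *planted* by a logistic model whose
  linear predictor is a fixed sparse weighting of the residue's true
  window features (optionally plus a whole-protein global term), scaled to
  unit variance, multiplied by ``signal_strength``, with the intercept
  solved so the expected positive rate matches ``positive_rate_target``
  (default 0.15, the class imbalance typical of interaction-site data).

Because labels depend on window features, a learner only recovers them by
actually using the window encoding; switching on ``global_signal`` adds a
protein-wide term that only models with access to global features can
exploit, enabling local-vs-global ablations.  Everything is a
deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from . import encoding
from .io_formats import (
    AA_ORDER,
    SS_ORDER,
    PssmMatrix,
    ProteinRecord,
    write_fasta,
    write_labels,
    write_pssm,
)

# Internal seed for the fixed sparse planting weights: the label function is
# a property of the generator, not of the user's seed.
_PLANT_SEED = 20211026
_N_PLANT_WEIGHTS = 30

PSSM_MIN, PSSM_MAX = -10, 12


def default_ss_transition(stickiness: float = 0.8) -> np.ndarray:
    """Row-stochastic 9x9 transition matrix with sticky H/E/L states.

    Helix, strand and loop persist with probability ``stickiness``; the
    remaining mass is spread uniformly over the other states.  Rarer states
    (3_10/pi-helix, bridge, turn, bend, none) persist less (0.5).
    """
    n = len(SS_ORDER)
    T = np.empty((n, n))
    for i, s in enumerate(SS_ORDER):
        stay = stickiness if s in "HEL" else 0.5
        T[i] = (1.0 - stay) / (n - 1)
        T[i, i] = stay
    return T


@dataclass
class SimConfig:
    """Study conditions for the generator.

    ``signal_strength`` is the standard-deviation multiple of the planted
    linear predictor (0 = labels independent of features); ``global_signal``
    adds a whole-protein term of that relative weight.
    """

    n_proteins: int = 50
    length_min: int = 50
    length_max: int = 120
    positive_rate_target: float = 0.15
    signal_strength: float = 3.0
    global_signal: float = 0.0
    ss_transition: np.ndarray = field(default_factory=default_ss_transition)
    pssm_noise_sd: float = 2.0
    window_size: int = encoding.DEFAULT_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        self.ss_transition = np.asarray(self.ss_transition, dtype=float)
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0 < self.positive_rate_target < 1:
            raise ValueError("positive_rate_target must be in (0, 1)")
        if self.signal_strength < 0 or self.global_signal < 0:
            raise ValueError("signal strengths must be >= 0")
        if self.length_min < self.window_size:
            raise ValueError("length_min must be >= window_size")
        if self.length_max < self.length_min:
            raise ValueError("length_max must be >= length_min")
        if self.ss_transition.shape != (9, 9) or not np.allclose(
            self.ss_transition.sum(axis=1), 1.0
        ):
            raise ValueError("ss_transition must be a 9x9 row-stochastic matrix")
        if self.pssm_noise_sd < 0:
            raise ValueError("pssm_noise_sd must be >= 0")


def _plant_weights(window_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixed sparse weights over window features and per-residue (global) features."""
    rng = np.random.default_rng(_PLANT_SEED)
    dim = window_size * encoding.RESIDUE_DIM
    w = np.zeros(dim)
    pick = rng.choice(dim, size=min(_N_PLANT_WEIGHTS, dim), replace=False)
    w[pick] = rng.choice([-1.0, 1.0], size=pick.size) * rng.uniform(0.5, 1.5, size=pick.size)
    # protein-level term: helix content (the 'H' one-hot column of the
    # padded global feature) -- a single monotone whole-protein property
    v = np.zeros(encoding.RESIDUE_DIM)
    v[encoding.SS_SLICE.start + 0] = 1.0
    return w, v


def _simulate_backbone(config: SimConfig, rng: np.random.Generator) -> list[ProteinRecord]:
    """Sequences, SS strings and PSSMs (no labels yet)."""
    # base profile: a residue's own column scores high, the rest mildly negative
    base = np.full((20, 20), -2.0) + 9.0 * np.eye(20)
    records = []
    for p in range(config.n_proteins):
        L = int(rng.integers(config.length_min, config.length_max + 1))
        seq_idx = rng.integers(0, 20, size=L)
        seq = "".join(AA_ORDER[i] for i in seq_idx)

        states = np.empty(L, dtype=int)
        states[0] = rng.integers(0, 9)
        for i in range(1, L):
            states[i] = rng.choice(9, p=config.ss_transition[states[i - 1]])
        ss = "".join(SS_ORDER[s] for s in states)

        noise = rng.normal(scale=config.pssm_noise_sd, size=(L, 20))
        scores = np.clip(np.rint(base[seq_idx] + noise), PSSM_MIN, PSSM_MAX)
        records.append(
            ProteinRecord(id=f"sp{p:04d}", sequence=seq, pssm=PssmMatrix(scores=scores), ss9=ss)
        )
    return records


def simulate_proteins(config: SimConfig) -> list[ProteinRecord]:
    """Generate ``config.n_proteins`` fully labelled synthetic proteins."""
    rng = np.random.default_rng(config.seed)
    records = _simulate_backbone(config, rng)
    w, v = _plant_weights(config.window_size)

    local_scores, global_scores = [], []
    for rec in records:
        block = encoding.residue_features(rec)
        local = encoding.local_window_features(block, config.window_size)
        local_scores.append(local @ w)
        gmean = encoding.global_feature(block).mean(axis=0)
        global_scores.append(float(gmean @ v) * np.ones(len(rec)))

    def _standardize(parts: list[np.ndarray]) -> np.ndarray:
        flat = np.concatenate(parts)
        sd = flat.std()
        return (flat - flat.mean()) / sd if sd > 0 else flat - flat.mean()

    # local and protein-level components are standardised separately before
    # mixing, so global_signal is the relative weight of the global term and
    # the combined predictor keeps unit variance
    z = _standardize(local_scores)
    if config.global_signal > 0:
        z = (z + config.global_signal * _standardize(global_scores)) / np.sqrt(
            1.0 + config.global_signal**2
        )
    z = config.signal_strength * z

    if np.ptp(z) == 0:
        intercept = float(np.log(config.positive_rate_target / (1 - config.positive_rate_target)))
    else:
        intercept = brentq(
            lambda b: np.mean(1.0 / (1.0 + np.exp(-(z + b)))) - config.positive_rate_target,
            -50.0,
            50.0,
        )
    p = 1.0 / (1.0 + np.exp(-(z + intercept)))
    labels = (rng.random(p.size) < p).astype(np.int64)

    start = 0
    for rec in records:
        L = len(rec)
        rec.labels = labels[start : start + L]
        start += L
        rec.validate()
    return records


def write_fixture_suite(directory: str | Path, config: SimConfig) -> Path:
    """Write a simulated dataset to disk in the exact formats the readers parse.

    Produces ``proteins.fasta``, one ``<id>.pssm`` (PSI-BLAST ASCII
    dialect) and one ``<id>.ss`` (bare 9-state string; a DSSP file cannot
    represent the ninth state ``'-'``) per protein, ``labels.tsv`` and a
    ``manifest.json`` tying them together.  Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = simulate_proteins(config)
    (directory / "proteins.fasta").write_text(write_fasta(records))
    (directory / "labels.tsv").write_text(write_labels(records))
    entries = []
    for rec in records:
        (directory / f"{rec.id}.pssm").write_text(write_pssm(rec.pssm, rec.sequence))
        (directory / f"{rec.id}.ss").write_text(rec.ss9 + "\n")
        entries.append({"id": rec.id, "pssm": f"{rec.id}.pssm", "ss": f"{rec.id}.ss"})
    manifest = {
        "fasta": "proteins.fasta",
        "labels": "labels.tsv",
        "proteins": entries,
        "seed": config.seed,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
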