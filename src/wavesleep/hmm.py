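"""HMM post-correction of predicted whole-night stage sequences.

The classifier's per-night output is treated as the observed sequence of a
hidden Markov model whose hidden states are the true stages; both state
sets are (W, N1, N2, N3, REM).  λ = {A, B, π}: A holds the true-stage
bigram transition probabilities, B the per-true-stage distribution of
predicted labels (the classifier's confusion behaviour), and π = [1,0,0,0,0]
because nights start awake.  A and B are maximum-likelihood count estimates
from held-out validation nights of the same fold, with additive smoothing
so no observation has zero likelihood; Viterbi decoding of each test
night's predicted sequence yields the corrected staging.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .classifier import StageSequencePrediction
from .stages import N_STAGES, STAGES


def _start_awake() -> np.ndarray:
    pi = np.zeros(N_STAGES)
    pi[0] = 1.0
    return pi


@dataclass
class HmmModel:
    """λ = {A, B, π} over the fixed (W, N1, N2, N3, REM) state order."""

    A: np.ndarray
    B: np.ndarray
    pi: np.ndarray = field(default_factory=_start_awake)
    smoothing: float = 1.0
    state_names: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        for name, mat in (("A", self.A), ("B", self.B)):
            if mat.shape != (N_STAGES, N_STAGES):
                raise ValueError(f"{name} must be 5x5")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"rows of {name} must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-12):
            raise ValueError("pi must sum to 1")

    def to_json(self, path) -> None:
        payload = {
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "pi": self.pi.tolist(),
            "smoothing": self.smoothing,
            "state_order": list(self.state_names),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HmmModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            A=np.array(payload["A"]),
            B=np.array(payload["B"]),
            pi=np.array(payload["pi"]),
            smoothing=payload.get("smoothing", 1.0),
            state_names=tuple(payload.get("state_order", STAGES)),
        )


def estimate(
    true_sequences: list[np.ndarray],
    predicted_sequences: list[np.ndarray],
    smoothing: float = 1.0,
) -> HmmModel:
    """Maximum-likelihood λ from aligned (true, predicted) night sequences.

    A is row-normalized from bigram counts of the true sequences, B from
    joint (true, predicted) counts; ``smoothing`` is added to every count.
    A hidden state never seen in the data falls back to a uniform row.
    """
    if not true_sequences:
        raise ValueError("no validation sequences to estimate from")
    if len(true_sequences) != len(predicted_sequences):
        raise ValueError("true/predicted sequence counts differ")
    a_counts = np.zeros((N_STAGES, N_STAGES))
    b_counts = np.zeros((N_STAGES, N_STAGES))
    for true, pred in zip(true_sequences, predicted_sequences):
        true = np.asarray(true, dtype=int)
        pred = np.asarray(pred, dtype=int)
        if true.shape != pred.shape:
            raise ValueError("true and predicted sequences must be aligned")
        np.add.at(a_counts, (true[:-1], true[1:]), 1)
        np.add.at(b_counts, (true, pred), 1)
    a_counts += smoothing
    b_counts += smoothing
    for name, counts in (("A", a_counts), ("B", b_counts)):
        empty = counts.sum(axis=1) == 0
        if empty.any():
            warnings.warn(
                f"states {[STAGES[i] for i in np.flatnonzero(empty)]} never "
                f"observed; using uniform {name} rows",
                stacklevel=2,
            )
            counts[empty] = 1.0
    return HmmModel(
        A=a_counts / a_counts.sum(axis=1, keepdims=True),
        B=b_counts / b_counts.sum(axis=1, keepdims=True),
        smoothing=smoothing,
    )


def viterbi(model: HmmModel, observed: np.ndarray) -> np.ndarray:
    """Most probable hidden stage path given an observed label sequence.

    Log-space dynamic program over the 5 states; ties break toward the
    lower state index (W < N1 < N2 < N3 < REM).
    """
    obs = np.asarray(observed, dtype=int)
    if obs.size == 0:
        raise ValueError("observed sequence is empty")
    if obs.min() < 0 or obs.max() >= N_STAGES:
        raise ValueError("observed labels must be stage codes 0..4")
    with np.errstate(divide="ignore"):
        log_a = np.log(model.A)
        log_b = np.log(model.B)
        log_pi = np.log(model.pi)
    n = obs.size
    delta = log_pi + log_b[:, obs[0]]
    back = np.empty((n, N_STAGES), dtype=int)
    for t in range(1, n):
        scores = delta[:, None] + log_a           # scores[i, j]: from i to j
        back[t] = scores.argmax(axis=0)           # argmax returns lowest index on ties
        delta = scores[back[t], np.arange(N_STAGES)] + log_b[:, obs[t]]
    path = np.empty(n, dtype=int)
    path[-1] = int(delta.argmax())
    assert np.isfinite(delta[path[-1]]), "all paths have zero probability"
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def correct_night(model: HmmModel, prediction: StageSequencePrediction) -> StageSequencePrediction:
    """Viterbi-decode a night's predicted labels into corrected labels."""
    return StageSequencePrediction(
        night_id=prediction.night_id,
        predicted_labels=prediction.predicted_labels,
        class_scores=prediction.class_scores,
        corrected_labels=viterbi(model, prediction.predicted_labels),
    )
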