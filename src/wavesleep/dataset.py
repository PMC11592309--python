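"""Multi-step feature sequences, normalization, and night-level CV splits.

The classifier consumes T×105 windows of consecutive epoch feature vectors
(default T=3, causal: epochs t−2, t−1, t) labelled with the final epoch's
stage.  The first T−1 windows of a night are left-padded by repeating the
first epoch, so every night yields exactly one window per epoch and stays
aligned with whole-night Viterbi decoding.  Cross-validation splits are
made at night granularity: nights are shuffled once, partitioned into k
near-equal test groups, and a validation fraction is carved out of each
fold's training nights (used for early stopping and for fitting the HMM).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_T = 3


@dataclass
class FeatureSequence:
    """One T×105 window plus its target (the last epoch's stage)."""

    matrix: np.ndarray
    target_label: int
    night_id: str
    epoch_index: int


@dataclass
class CvSplit:
    """Night-level train/validation/test partition of one fold."""

    fold_id: int
    train_nights: list[str]
    validation_nights: list[str]
    test_nights: list[str]

    def __post_init__(self) -> None:
        groups = [set(self.train_nights), set(self.validation_nights), set(self.test_nights)]
        for i in range(3):
            for j in range(i + 1, 3):
                if groups[i] & groups[j]:
                    raise ValueError(
                        f"fold {self.fold_id}: nights {groups[i] & groups[j]} "
                        "appear in more than one partition"
                    )


def build_sequences(
    features: np.ndarray,
    labels: np.ndarray,
    night_id: str = "",
    T: int = DEFAULT_T,
) -> list[FeatureSequence]:
    """Window one night's feature matrix into per-epoch T×d sequences.

    Windows are causal and never cross the night boundary; the first
    epoch's row is repeated to pad the initial windows.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if T < 1:
        raise ValueError("T must be >= 1")
    n = len(labels)
    if features.shape[0] != n:
        raise ValueError("features and labels length mismatch")
    if n == 0:
        warnings.warn(f"night {night_id!r} has no epochs; skipped", stacklevel=2)
        return []
    padded = np.vstack([np.repeat(features[:1], T - 1, axis=0), features])
    return [
        FeatureSequence(
            matrix=padded[t : t + T],
            target_label=int(labels[t]),
            night_id=night_id,
            epoch_index=t,
        )
        for t in range(n)
    ]


def sequences_to_arrays(seqs: list[FeatureSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Stack sequences into (n, T, d) inputs and (n,) integer targets."""
    if not seqs:
        raise ValueError("no sequences")
    x = np.stack([s.matrix for s in seqs])
    y = np.array([s.target_label for s in seqs], dtype=int)
    return x, y


@dataclass
class Normalizer:
    """Per-feature z-scoring fitted on training data only."""

    center: np.ndarray = field(default=None)  # type: ignore[assignment]
    scale: np.ndarray = field(default=None)   # type: ignore[assignment]
    scale_floor: float = 1e-8

    def fit(self, x: np.ndarray) -> "Normalizer":
        """Fit column means/SDs; accepts (n, d) rows or (n, T, d) windows."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x.reshape(-1, x.shape[-1])
        self.center = x.mean(axis=0)
        self.scale = np.maximum(x.std(axis=0), self.scale_floor)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.center is None:
            raise RuntimeError("normalizer not fitted")
        return (np.asarray(x, dtype=float) - self.center) / self.scale


def make_folds(
    night_ids: list[str],
    k: int = 10,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> list[CvSplit]:
    """Shuffle nights and build k cross-validation folds.

    Test groups are near-equal (sizes differ by at most one) and partition
    the nights exhaustively; within each fold, ``val_fraction`` of the
    training nights (at least one) become the validation set.
    """
    night_ids = list(night_ids)
    if k > len(night_ids):
        raise ValueError(f"k={k} folds but only {len(night_ids)} nights")
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(night_ids))
    shuffled = [night_ids[i] for i in order]
    test_groups = [list(g) for g in np.array_split(np.array(shuffled, dtype=object), k)]
    folds = []
    for fold_id, test in enumerate(test_groups, start=1):
        rest = [n for n in shuffled if n not in test]
        n_val = max(1, int(round(val_fraction * len(rest))))
        val_idx = rng.choice(len(rest), size=n_val, replace=False)
        validation = [rest[i] for i in sorted(val_idx)]
        train = [n for n in rest if n not in validation]
        folds.append(
            CvSplit(
                fold_id=fold_id,
                train_nights=train,
                validation_nights=validation,
                test_nights=[str(n) for n in test],
            )
        )
    return folds


def save_folds(folds: list[CvSplit], path) -> None:
    """Serialize a split manifest as JSON for exact reproducibility."""
    payload = {
        str(f.fold_id): {
            "train": f.train_nights,
            "validation": f.validation_nights,
            "test": f.test_nights,
        }
        for f in folds
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_folds(path) -> list[CvSplit]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        CvSplit(
            fold_id=int(fid),
            train_nights=spec["train"],
            validation_nights=spec["validation"],
            test_nights=spec["test"],
        )
        for fid, spec in sorted(payload.items(), key=lambda kv: int(kv[0]))
    ]
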