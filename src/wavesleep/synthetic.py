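"""Synthetic whole-night EEG with a known stage sequence.

The generator has two halves: a 5-state Markov chain over the AASM stages
(strongly self-transitioning, starting awake) that produces the ground-truth
hypnogram, and a per-stage spectral recipe that renders each 30 s epoch as a
sum of narrow-band oscillators plus white Gaussian noise.  The default
recipes place each stage's dominant energy in a distinct dyadic sub-band of
the 4-level DWT at 100 Hz, so that sub-band features carry class signal.
That placement is a testing convention — enough statistical structure to
exercise every downstream stage — not a physiological simulation: there are
no spindles, K-complexes or artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import DEFAULT_FS, EPOCH_SECONDS, EpochedRecording
from .stages import N_STAGES


def _default_transition_matrix() -> np.ndarray:
    # Persistent chain: stay probability 0.85, remaining mass spread evenly.
    a = np.full((N_STAGES, N_STAGES), 0.15 / (N_STAGES - 1))
    np.fill_diagonal(a, 0.85)
    return a


def _default_initial() -> np.ndarray:
    # Nights start awake.
    pi = np.zeros(N_STAGES)
    pi[0] = 1.0
    return pi


@dataclass
class StageMarkovSpec:
    """Markov-chain specification of the hidden stage sequence."""

    transition_matrix: np.ndarray = field(default_factory=_default_transition_matrix)
    initial_distribution: np.ndarray = field(default_factory=_default_initial)
    n_epochs: int = 1080  # ~9 h of 30 s epochs
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        if self.transition_matrix.shape != (N_STAGES, N_STAGES):
            raise ValueError("transition_matrix must be 5x5")
        if self.initial_distribution.shape != (N_STAGES,):
            raise ValueError("initial_distribution must have length 5")
        if np.any(self.transition_matrix < 0) or np.any(self.initial_distribution < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition_matrix rows must sum to 1")
        if not np.isclose(self.initial_distribution.sum(), 1.0, atol=1e-12):
            raise ValueError("initial_distribution must sum to 1")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be positive")


#: Per-stage oscillator recipes: (center frequency Hz, bandwidth Hz, amplitude).
#: One dominant oscillator per stage, each in a different DWT sub-band:
#: W -> d1 (25-50), N1 -> d3 (6.25-12.5), N2 -> d2 (12.5-25),
#: N3 -> a4 (0-3.125), REM -> d4 (3.125-6.25).
DEFAULT_STAGE_OSCILLATORS: tuple[tuple[tuple[float, float, float], ...], ...] = (
    ((30.0, 10.0, 2.0),),   # W: fast broadband beta/gamma
    ((9.0, 2.0, 2.0),),     # N1: alpha/theta border
    ((15.0, 3.0, 2.0),),    # N2: sigma/spindle band
    ((1.5, 1.0, 3.0),),     # N3: slow-wave delta
    ((4.5, 1.5, 2.0),),     # REM: theta
)


@dataclass
class StageSpectralSpec:
    """Per-stage oscillator mix used to render epochs."""

    oscillators: tuple[tuple[tuple[float, float, float], ...], ...] = (
        DEFAULT_STAGE_OSCILLATORS
    )
    noise_sd: float = 1.0
    sampling_rate: float = DEFAULT_FS
    epoch_seconds: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        if len(self.oscillators) != N_STAGES:
            raise ValueError("need one oscillator list per stage (5)")
        nyq = self.sampling_rate / 2.0
        for comps in self.oscillators:
            for (f, bw, amp) in comps:
                if f >= nyq:
                    raise ValueError(f"center frequency {f} Hz >= Nyquist {nyq} Hz")
                if bw < 0 or amp < 0:
                    raise ValueError("bandwidth and amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def epoch_samples(self) -> int:
        return int(round(self.sampling_rate * self.epoch_seconds))


def simulate_stage_sequence(spec: StageMarkovSpec) -> np.ndarray:
    """Draw a stage label sequence (codes 0..4) from the Markov spec.

    The first label is drawn from the initial distribution, each subsequent
    one from the transition row of its predecessor.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.empty(spec.n_epochs, dtype=int)
    labels[0] = rng.choice(N_STAGES, p=spec.initial_distribution)
    for t in range(1, spec.n_epochs):
        labels[t] = rng.choice(N_STAGES, p=spec.transition_matrix[labels[t - 1]])
    return labels


def synthesize_night(
    labels: np.ndarray,
    spec: StageSpectralSpec | None = None,
    seed: int = 0,
    night_id: str = "synthetic",
    subject_id: str = "synthetic",
) -> EpochedRecording:
    """Render one 3000-sample epoch per stage label.

    Epoch ``i`` is the sum of its stage's oscillators — each a sinusoid with
    frequency drawn uniformly inside the oscillator band and uniform random
    phase, both redrawn per epoch — plus i.i.d. Gaussian noise.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("label sequence is empty")
    if labels.min() < 0 or labels.max() >= N_STAGES:
        raise ValueError("labels must be stage codes 0..4")
    if spec is None:
        spec = StageSpectralSpec()
    rng = np.random.default_rng(seed)
    n = spec.epoch_samples
    t = np.arange(n) / spec.sampling_rate
    epochs = np.empty((labels.size, n))
    for i, lab in enumerate(labels):
        x = np.zeros(n)
        for (f0, bw, amp) in spec.oscillators[lab]:
            f = f0 if bw == 0 else rng.uniform(f0 - bw / 2.0, f0 + bw / 2.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            x += amp * np.sin(2.0 * np.pi * f * t + phase)
        if spec.noise_sd > 0:
            x += rng.normal(0.0, spec.noise_sd, size=n)
        epochs[i] = x
    return EpochedRecording(
        epochs=epochs,
        labels=labels,
        sampling_rate=spec.sampling_rate,
        night_id=night_id,
        subject_id=subject_id,
    )


def generate_night(
    markov: StageMarkovSpec | None = None,
    spectral: StageSpectralSpec | None = None,
    seed: int = 0,
    night_id: str = "synthetic",
) -> EpochedRecording:
    """Convenience wrapper: draw a stage sequence and render it.

    The chain seed and the rendering seed are derived from ``seed`` so a
    single integer reproduces the whole night.
    """
    if markov is None:
        markov = StageMarkovSpec(seed=seed)
    else:
        markov = StageMarkovSpec(
            transition_matrix=markov.transition_matrix,
            initial_distribution=markov.initial_distribution,
            n_epochs=markov.n_epochs,
            seed=seed,
        )
    labels = simulate_stage_sequence(markov)
    return synthesize_night(
        labels, spectral, seed=seed + 1_000_003, night_id=night_id
    )


def export_night(
    rec: EpochedRecording, edf_path, hypnogram_path, channel: str = "EEG Fpz-Cz"
) -> None:
    """Write a generated night as an EDF file plus a two-column hypnogram.

    The hypnogram dialect (``epoch_index<TAB>label``) is the plain-text one
    the reader accepts, so generated nights round-trip through the io layer.
    """
    from .edf import write_edf, write_hypnogram_text

    write_edf(
        edf_path,
        rec.epochs.ravel(),
        sampling_rate=rec.sampling_rate,
        channel_name=channel,
    )
    write_hypnogram_text(hypnogram_path, rec.labels)
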