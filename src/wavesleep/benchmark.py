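"""Self-contained synthetic benchmarks of the staging pipeline.

Two study set-ups are provided:

* :func:`run_label_noise_benchmark` — isolates the HMM corrector: nights of
  true stages from a persistent Markov chain are observed through symmetric
  label noise, and Viterbi correction is compared with the raw noisy labels.
* :func:`run_end_to_end_benchmark` — the full pipeline (simulate → wavelet
  features → T×105 windows → LSTM → HMM → metrics) on synthetic nights with
  stage-separated sub-band spectra.  Nights of 1000 epochs match the
  label-noise benchmark's scale (and roughly a real ~9 h recording) while
  keeping the whole study to minutes on one CPU; long nights also give the
  HMM estimator enough validation counts that its additive smoothing is a
  small perturbation of B.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import hmm as hmm_mod
from .pipeline import InputConfig, PipelineConfig, SyntheticInput, run
from .stages import N_STAGES
from .synthetic import StageMarkovSpec, simulate_stage_sequence


def add_label_noise(labels: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    """Replace each label with a uniformly drawn *other* label w.p. ``noise``."""
    labels = np.asarray(labels, dtype=int)
    out = labels.copy()
    flip = rng.random(labels.size) < noise
    shift = rng.integers(1, N_STAGES, size=labels.size)
    out[flip] = (labels[flip] + shift[flip]) % N_STAGES
    return out


def run_label_noise_benchmark(
    n_nights: int = 40,
    n_epochs: int = 1000,
    noise: float = 0.15,
    self_transition: float = 0.85,
    seed: int = 0,
    smoothing: float = 1.0,
) -> dict:
    """HMM correction of noisy observations of a persistent stage chain.

    Half the nights estimate λ (their noisy labels play the validation-set
    predictions); the other half are Viterbi-decoded.  Returns raw and
    corrected accuracies over the decoded nights.
    """
    rng = np.random.default_rng(seed)
    a = np.full((N_STAGES, N_STAGES), (1 - self_transition) / (N_STAGES - 1))
    np.fill_diagonal(a, self_transition)
    nights_true, nights_obs = [], []
    for i in range(n_nights):
        spec = StageMarkovSpec(
            transition_matrix=a, n_epochs=n_epochs, seed=int(rng.integers(2**31))
        )
        true = simulate_stage_sequence(spec)
        nights_true.append(true)
        nights_obs.append(add_label_noise(true, noise, rng))
    half = n_nights // 2
    model = hmm_mod.estimate(nights_true[:half], nights_obs[:half], smoothing=smoothing)
    raw_acc, cor_acc = [], []
    for true, obs in zip(nights_true[half:], nights_obs[half:]):
        decoded = hmm_mod.viterbi(model, obs)
        raw_acc.append(np.mean(obs == true))
        cor_acc.append(np.mean(decoded == true))
    return {
        "raw_accuracy": float(np.mean(raw_acc)),
        "corrected_accuracy": float(np.mean(cor_acc)),
        "improvement": float(np.mean(cor_acc) - np.mean(raw_acc)),
        "n_decoded_nights": n_nights - half,
    }


def run_end_to_end_benchmark(
    n_nights: int = 20,
    n_epochs: int = 1000,
    noise_sd: float = 1.0,
    seed: int = 0,
    run_dir=None,
) -> dict:
    """Full pipeline on synthetic nights; returns the run summary dict."""
    config = PipelineConfig(
        seed=seed,
        input=InputConfig(
            kind="synthetic",
            synthetic=SyntheticInput(
                n_nights=n_nights, n_epochs=n_epochs, noise_sd=noise_sd
            ),
        ),
    )
    if run_dir is None:
        with tempfile.TemporaryDirectory() as tmp:
            return run(config, Path(tmp) / "bench")
    return run(config, run_dir)
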