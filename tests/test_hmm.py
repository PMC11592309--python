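"""HMM estimation and Viterbi decoding against enumeration and hmmlearn."""

import numpy as np
import pytest

from wavesleep import HmmModel, StageMarkovSpec, correct_night, estimate, viterbi
from wavesleep import StageSequencePrediction, simulate_stage_sequence
from wavesleep.benchmark import add_label_noise, run_label_noise_benchmark


def path_log_prob(model: HmmModel, path: np.ndarray, obs: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        s = np.log(model.pi[path[0]]) + np.log(model.B[path[0], obs[0]])
        for t in range(1, len(obs)):
            s += np.log(model.A[path[t - 1], path[t]]) + np.log(model.B[path[t], obs[t]])
    return float(s)


def brute_force_decode(model: HmmModel, obs: np.ndarray) -> tuple[np.ndarray, float]:
    """Best path and score over every 5^n hidden path by tensor expansion."""
    with np.errstate(divide="ignore"):
        log_a = np.log(model.A)
        log_b = np.log(model.B)
        log_pi = np.log(model.pi)
    scores = log_pi + log_b[:, obs[0]]
    for o in obs[1:]:
        scores = scores[..., None] + log_a + log_b[:, o]
    best = np.unravel_index(np.argmax(scores), scores.shape)
    return np.array(best), float(scores.max())


def random_model(rng) -> HmmModel:
    a = rng.random((5, 5)) + 0.05
    b = rng.random((5, 5)) + 0.05
    return HmmModel(
        A=a / a.sum(axis=1, keepdims=True),
        B=b / b.sum(axis=1, keepdims=True),
        pi=np.full(5, 0.2),
    )


# ---------------------------------------------------------------- estimate

def test_transition_counts_by_hand():
    model = estimate([np.array([0, 0, 0, 1])], [np.array([0, 0, 0, 1])], smoothing=0.0)
    assert model.A[0, 0] == pytest.approx(2 / 3)
    assert model.A[0, 1] == pytest.approx(1 / 3)


def test_perfect_classifier_gives_identity_emissions():
    seq = np.array([0, 1, 2, 3, 4, 4, 3, 2, 1, 0])
    model = estimate([seq], [seq], smoothing=0.0)
    assert np.allclose(model.B, np.eye(5))


def test_start_distribution_is_wake():
    seq = np.array([2, 2, 3])
    model = estimate([seq], [seq])
    assert model.pi.tolist() == [1.0, 0.0, 0.0, 0.0, 0.0]


def test_estimator_requires_aligned_input():
    with pytest.raises(ValueError, match="aligned"):
        estimate([np.array([0, 1])], [np.array([0, 1, 2])])
    with pytest.raises(ValueError, match="no validation"):
        estimate([], [])


def test_estimator_consistency_at_1e5_transitions(rng):
    a = np.full((5, 5), 0.15 / 4)
    np.fill_diagonal(a, 0.85)
    b = np.full((5, 5), 0.2 / 4)
    np.fill_diagonal(b, 0.8)
    spec = StageMarkovSpec(transition_matrix=a, n_epochs=100_001, seed=77)
    hidden = simulate_stage_sequence(spec)
    u = rng.random(hidden.size)
    observed = np.array(
        [np.searchsorted(np.cumsum(b[h]), x) for h, x in zip(hidden, u)]
    )
    model = estimate([hidden], [observed])
    assert np.max(np.abs(model.A - a)) < 0.02
    assert np.max(np.abs(model.B - b)) < 0.02


# ----------------------------------------------------------------- viterbi

def test_viterbi_equals_enumeration_on_random_models():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        model = random_model(rng)
        n = int(rng.integers(1, 9))
        obs = rng.integers(0, 5, size=n)
        decoded = viterbi(model, obs)
        best_path, best_score = brute_force_decode(model, obs)
        if np.array_equal(decoded, best_path):
            continue
        # summation-order float ties: the decoded path must still attain
        # the enumerated optimum
        assert path_log_prob(model, decoded, obs) == pytest.approx(
            best_score, abs=1e-9
        )


def test_viterbi_matches_hmmlearn():
    from hmmlearn.hmm import CategoricalHMM

    rng = np.random.default_rng(5)
    for _ in range(25):
        model = random_model(rng)
        obs = rng.integers(0, 5, size=200)
        ref = CategoricalHMM(n_components=5)
        ref.startprob_ = model.pi
        ref.transmat_ = model.A
        ref.emissionprob_ = model.B
        score, path = ref.decode(obs[:, None], algorithm="viterbi")
        decoded = viterbi(model, obs)
        if not np.array_equal(decoded, path):
            assert path_log_prob(model, decoded, obs) == pytest.approx(score, abs=1e-9)


def test_identity_emissions_pass_through():
    a = np.full((5, 5), 0.1)
    np.fill_diagonal(a, 0.6)
    model = HmmModel(A=a, B=np.eye(5), pi=np.array([1.0, 0, 0, 0, 0]))
    obs = np.array([0, 2, 2, 1, 4, 4, 0])  # starts with W, compatible with pi
    assert np.array_equal(viterbi(model, obs), obs)


def test_wake_start_constraint():
    rng = np.random.default_rng(8)
    for _ in range(20):
        model = random_model(rng)
        model.pi = np.array([1.0, 0, 0, 0, 0])
        obs = rng.integers(0, 5, size=10)
        assert viterbi(model, obs)[0] == 0


def test_single_epoch_night_closed_form():
    rng = np.random.default_rng(9)
    model = random_model(rng)
    for o in range(5):
        expected = int(np.argmax(model.pi * model.B[:, o]))
        assert viterbi(model, np.array([o]))[0] == expected


def test_empty_observation_rejected():
    rng = np.random.default_rng(10)
    with pytest.raises(ValueError, match="empty"):
        viterbi(random_model(rng), np.array([], dtype=int))


# ----------------------------------------------------------------- correction

def test_correct_night_preserves_raw_labels():
    rng = np.random.default_rng(11)
    model = random_model(rng)
    scores = rng.random((20, 5))
    scores /= scores.sum(axis=1, keepdims=True)
    pred = StageSequencePrediction(
        night_id="n", predicted_labels=scores.argmax(axis=1), class_scores=scores
    )
    out = correct_night(model, pred)
    assert np.array_equal(out.predicted_labels, pred.predicted_labels)
    assert out.corrected_labels is not None
    assert len(out.corrected_labels) == 20


def test_identity_model_correction_is_noop():
    a = np.full((5, 5), 0.04)
    np.fill_diagonal(a, 0.84)
    model = HmmModel(A=a, B=np.eye(5), pi=np.array([1.0, 0, 0, 0, 0]))
    obs = np.array([0, 0, 1, 2, 2, 3, 4])
    scores = np.eye(5)[obs]
    pred = StageSequencePrediction("n", obs, scores)
    assert np.array_equal(correct_night(model, pred).corrected_labels, obs)


def test_correction_improves_noisy_persistent_chain():
    """Viterbi denoising beats raw labels at 15% symmetric noise."""
    result = run_label_noise_benchmark(
        n_nights=40, n_epochs=1000, noise=0.15, seed=21
    )
    assert result["n_decoded_nights"] == 20
    assert result["corrected_accuracy"] > result["raw_accuracy"]
    assert result["improvement"] > 0.0


def test_correction_harmless_at_low_noise():
    """At 2% noise the corrector must not lose more than a noise floor."""
    result = run_label_noise_benchmark(
        n_nights=40, n_epochs=1000, noise=0.02, seed=22
    )
    assert result["improvement"] > -0.01


def test_label_noise_rate():
    rng = np.random.default_rng(30)
    labels = np.zeros(100_000, dtype=int)
    noisy = add_label_noise(labels, 0.15, rng)
    assert np.mean(noisy != labels) == pytest.approx(0.15, abs=0.01)
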