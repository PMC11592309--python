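"""Sequence classifier: a small LSTM over T×105 feature windows.

A single recurrent layer (hidden size 20 by default) reads the T feature
vectors of a window; the final hidden state feeds a linear layer and a
5-way softmax.  Training minimises unweighted cross-entropy with the Adam
optimizer, mini-batches, and early stopping on validation accuracy, and is
exactly reproducible for a fixed seed.  The network and its
backpropagation-through-time gradients are implemented directly in NumPy,
which keeps the model definition transparent and bit-deterministic.

Any object exposing the same ``fit``/``predict_proba`` surface can stand
in for the LSTM (the pipeline only relies on this interface), which is the
plug-in point for alternative classifiers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .stages import N_STAGES


@dataclass
class ClassifierConfig:
    """Architecture and training hyperparameters of the LSTM classifier."""

    input_dim: int = 105
    hidden_size: int = 20
    num_layers: int = 1
    n_classes: int = N_STAGES
    T: int = 3
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1 or self.num_layers < 1:
            raise ValueError("hidden_size and num_layers must be >= 1")


@dataclass
class StageSequencePrediction:
    """Per-epoch stage predictions for one night, before/after correction."""

    night_id: str
    predicted_labels: np.ndarray
    class_scores: np.ndarray
    corrected_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.predicted_labels = np.asarray(self.predicted_labels, dtype=int)
        self.class_scores = np.asarray(self.class_scores, dtype=float)
        if self.class_scores.shape != (len(self.predicted_labels), N_STAGES):
            raise ValueError("class_scores must be (n_epochs, 5)")
        if not np.allclose(self.class_scores.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("class_scores rows must sum to 1")

    @property
    def final_labels(self) -> np.ndarray:
        return (
            self.corrected_labels
            if self.corrected_labels is not None
            else self.predicted_labels
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _LstmLayer:
    """One LSTM layer with cached forward pass and BPTT gradients.

    Gate pre-activations are packed as [input, forget, cell, output]
    blocks of the 4H-wide weight matrices.
    """

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(hidden)
        self.wx = rng.uniform(-k, k, size=(input_dim, 4 * hidden))
        self.wh = rng.uniform(-k, k, size=(hidden, 4 * hidden))
        self.b = rng.uniform(-k, k, size=4 * hidden)
        self.hidden = hidden
        self._cache: list[tuple] = []

    @property
    def params(self) -> list[np.ndarray]:
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, D) -> hidden sequence (B, T, H)."""
        b_sz, t_len, _ = x.shape
        hsz = self.hidden
        h = np.zeros((b_sz, hsz))
        c = np.zeros((b_sz, hsz))
        self._cache = []
        hs = np.empty((b_sz, t_len, hsz))
        for t in range(t_len):
            z = x[:, t] @ self.wx + h @ self.wh + self.b
            i = _sigmoid(z[:, :hsz])
            f = _sigmoid(z[:, hsz : 2 * hsz])
            g = np.tanh(z[:, 2 * hsz : 3 * hsz])
            o = _sigmoid(z[:, 3 * hsz :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((x[:, t], h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        return hs

    def backward(self, dhs: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """dhs: gradient wrt the hidden sequence (B, T, H).

        Returns the gradient wrt the layer input sequence and the
        parameter gradients [dwx, dwh, db].
        """
        b_sz, t_len, hsz = dhs.shape
        dwx = np.zeros_like(self.wx)
        dwh = np.zeros_like(self.wh)
        db = np.zeros_like(self.b)
        dx = np.empty((b_sz, t_len, self.wx.shape[0]))
        dh_next = np.zeros((b_sz, hsz))
        dc_next = np.zeros((b_sz, hsz))
        for t in reversed(range(t_len)):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tc = self._cache[t]
            dh = dhs[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tc**2)
            do = dh * tc
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dwx += x_t.T @ dz
            dwh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.wx.T
            dh_next = dz @ self.wh.T
            dc_next = dc * f
        return dx, [dwx, dwh, db]


class LstmStageClassifier:
    """Trainable LSTM mapping normalized T×105 windows to 5 stage scores."""

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        rng = np.random.default_rng(self.config.seed)
        cfg = self.config
        self.layers = [
            _LstmLayer(cfg.input_dim if l == 0 else cfg.hidden_size, cfg.hidden_size, rng)
            for l in range(cfg.num_layers)
        ]
        k = 1.0 / np.sqrt(cfg.hidden_size)
        self.w_out = rng.uniform(-k, k, size=(cfg.hidden_size, cfg.n_classes))
        self.b_out = rng.uniform(-k, k, size=cfg.n_classes)
        self._rng = rng
        self.history: dict[str, list[float]] = {"train_loss": [], "val_accuracy": []}

    # -- parameter bookkeeping -------------------------------------------
    def _all_params(self) -> list[np.ndarray]:
        params: list[np.ndarray] = []
        for layer in self.layers:
            params.extend(layer.params)
        params.extend([self.w_out, self.b_out])
        return params

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self._all_params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self._all_params(), weights):
            p[...] = w

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for p in self._all_params():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    # -- forward / loss ---------------------------------------------------
    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h)
        return h[:, -1] @ self.w_out + self.b_out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for windows x of shape (n, T, input_dim)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[2] != self.config.input_dim:
            raise ValueError(
                f"expected (n, T, {self.config.input_dim}) input, got {x.shape}"
            )
        return softmax(self._forward(x))

    def _step(self, x: np.ndarray, y: np.ndarray, opt_state: dict) -> float:
        logits = self._forward(x)
        probs = softmax(logits)
        n = len(y)
        loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-300))
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        h_last = self.layers[-1]._cache[-1][6] * self.layers[-1]._cache[-1][8]  # o * tanh(c)
        grads = [h_last.T @ dlogits, dlogits.sum(axis=0)]
        dh_seq = np.zeros((n, x.shape[1], self.config.hidden_size))
        dh_seq[:, -1] = dlogits @ self.w_out.T
        layer_grads: list[np.ndarray] = []
        d = dh_seq
        for layer in reversed(self.layers):
            d, g = layer.backward(d)
            layer_grads = g + layer_grads
        all_grads = layer_grads + grads

        # Adam update
        opt_state["t"] += 1
        t = opt_state["t"]
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self._all_params(), all_grads, opt_state["m"], opt_state["v"]):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g**2
            m_hat = m / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)
        return float(loss)

    # -- training ---------------------------------------------------------
    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "LstmStageClassifier":
        """Train with mini-batch Adam; keep the best-validation checkpoint.

        Without a validation set the final weights are kept.
        """
        x_train = np.asarray(x_train, dtype=float)
        y_train = np.asarray(y_train, dtype=int)
        if len(x_train) == 0:
            raise ValueError("empty training set")
        cfg = self.config
        opt_state = {
            "t": 0,
            "m": [np.zeros_like(p) for p in self._all_params()],
            "v": [np.zeros_like(p) for p in self._all_params()],
        }
        best_acc, best_weights, since_best = -np.inf, None, 0
        n = len(x_train)
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                losses.append(self._step(x_train[idx], y_train[idx], opt_state))
            self.history["train_loss"].append(float(np.mean(losses)))
            if x_val is not None and len(x_val):
                acc = float(
                    np.mean(self.predict_proba(x_val).argmax(axis=1) == y_val)
                )
                self.history["val_accuracy"].append(acc)
                if acc > best_acc:
                    best_acc, best_weights, since_best = acc, self.get_weights(), 0
                else:
                    since_best += 1
                    if since_best >= cfg.patience:
                        break
        if best_weights is not None:
            self.set_weights(best_weights)
        return self


def predict_night(
    model: LstmStageClassifier, sequences: np.ndarray, night_id: str = ""
) -> StageSequencePrediction:
    """Predict one night's per-epoch stages from its windows (epoch order)."""
    probs = model.predict_proba(sequences)
    return StageSequencePrediction(
        night_id=night_id,
        predicted_labels=probs.argmax(axis=1),
        class_scores=probs,
    )
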