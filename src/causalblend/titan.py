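"""Memory-augmented attention network for potential-outcome prediction.

The predictor treats each unit's feature vector (covariates plus the
treatment encoding) as a length-p single-channel sequence: a width-3
convolution projects it to the hidden width, a stack of residual
multi-head self-attention blocks with layer normalization and feed-forward
sublayers contextualizes it, and a gated external memory vector — a running,
sigmoid-gated convex blend of previously seen representations — is
concatenated with the pooled representation before the sigmoid output head.
Counterfactual probabilities per treatment arm are obtained by overriding
the treatment encoding at the input. Dropout stays active on stochastic
forward passes, which is what the uncertainty module's Monte Carlo dropout
relies on.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._autograd import Adam, Tensor, concat

__all__ = ["TitanConfig", "TitanModel", "MLPConfig", "MLPModel",
           "attention_weights", "memory_update", "bce_loss"]


@dataclass
class TitanConfig:
    """Hyperparameters; defaults are the tuned full-size values."""

    hidden: int = 512
    layers: int = 8
    heads: int = 8
    dropout: float = 0.1567
    lr: float = 1.75e-4
    epochs: int = 31
    batch_size: int = 1024
    patience: int = 4
    kernel: int = 3
    memory_slots: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.hidden % self.heads:
            raise ValueError("hidden must be divisible by heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.kernel != 3:
            raise ValueError("only kernel width 3 is supported")


def attention_weights(Q: np.ndarray, K: np.ndarray, d_k: float) -> np.ndarray:
    """Row-stochastic scaled dot-product attention weights."""
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    scores = np.asarray(Q, float) @ np.asarray(K, float).swapaxes(-1, -2) / np.sqrt(d_k)
    shifted = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def memory_update(z: np.ndarray, memory: np.ndarray,
                  W_g: np.ndarray, b_g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sigmoid-gated memory write: M_new = g * M_old + (1 - g) * z.

    Every coordinate of the result lies between the old memory value and the
    incoming representation.
    """
    from scipy.special import expit

    z = np.asarray(z, float)
    g = expit(z @ np.asarray(W_g, float) + np.asarray(b_g, float))
    return g, g * np.asarray(memory, float) + (1.0 - g) * z


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy between probabilities and binary labels."""
    p = np.clip(np.asarray(p, float), eps, 1 - eps)
    y = np.asarray(y, float)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-8) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / ((var + eps) ** 0.5) * gamma + beta


class TitanModel:
    """The predictor; ``treatment_cols`` are the input columns holding the
    (one-hot or binary) treatment encoding, overridden for counterfactuals."""

    def __init__(self, config: TitanConfig, n_features: int,
                 treatment_cols: list[int]):
        self.config = config
        self.n_features = int(n_features)
        self.treatment_cols = list(treatment_cols)
        d, L = config.hidden, config.layers
        rng = np.random.default_rng(config.seed)

        def w(*shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
            return Tensor(rng.normal(0.0, scale, shape), requires_grad=True)

        self.params: dict[str, Tensor] = {}
        P = self.params
        P["conv_w"] = Tensor(rng.normal(0, 0.5, (3, d)), requires_grad=True)
        P["conv_b"] = Tensor(np.zeros(d), requires_grad=True)
        P["pos"] = Tensor(rng.normal(0, 0.1, (self.n_features, d)), requires_grad=True)
        for layer in range(L):
            for name in ("q", "k", "v", "o"):
                P[f"W{name}{layer}"] = w(d, d)
                P[f"b{name}{layer}"] = Tensor(np.zeros(d), requires_grad=True)
            P[f"Wf1_{layer}"] = w(d, d)
            P[f"bf1_{layer}"] = Tensor(np.zeros(d), requires_grad=True)
            P[f"Wf2_{layer}"] = w(d, d)
            P[f"bf2_{layer}"] = Tensor(np.zeros(d), requires_grad=True)
            for ln in ("a", "f"):
                P[f"g{ln}{layer}"] = Tensor(np.ones(d), requires_grad=True)
                P[f"be{ln}{layer}"] = Tensor(np.zeros(d), requires_grad=True)
        P["Wg"] = w(d, d)
        P["bg"] = Tensor(np.zeros(d), requires_grad=True)
        P["Wo"] = w(2 * d, scale=1.0 / np.sqrt(2 * d))
        P["bo"] = Tensor(np.zeros(()), requires_grad=True)
        self.memory = np.zeros(d)  # global memory vector, frozen at inference
        self.loss_trace: list[dict] = []

    # -- forward -------------------------------------------------------------
    def _dropout(self, x: Tensor, training: bool, rng) -> Tensor:
        rate = self.config.dropout
        if not training or rate == 0.0:
            return x
        mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * Tensor(mask)

    def encode(self, X: np.ndarray, training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        """Contextualized representation after conv + attention stack,
        mean-pooled over feature positions -> (batch, hidden)."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}")
        if training and rng is None:
            rng = np.random.default_rng(self.config.seed)
        P = self.params
        B, p = X.shape
        xt = Tensor(X)
        pad = Tensor(np.zeros((B, 1)))
        xp = concat([pad, xt, pad], axis=1)
        left = xp[:, 0:p].reshape(B, p, 1)
        mid = xp[:, 1:p + 1].reshape(B, p, 1)
        right = xp[:, 2:p + 2].reshape(B, p, 1)
        z = (left * P["conv_w"][0] + mid * P["conv_w"][1]
             + right * P["conv_w"][2] + P["conv_b"]).relu()
        z = z + P["pos"]
        d, h = self.config.hidden, self.config.heads
        dk = d // h
        for layer in range(self.config.layers):
            q = (z @ P[f"Wq{layer}"] + P[f"bq{layer}"]).reshape(B, p, h, dk).transpose(0, 2, 1, 3)
            k = (z @ P[f"Wk{layer}"] + P[f"bk{layer}"]).reshape(B, p, h, dk).transpose(0, 2, 1, 3)
            v = (z @ P[f"Wv{layer}"] + P[f"bv{layer}"]).reshape(B, p, h, dk).transpose(0, 2, 1, 3)
            scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
            att = scores.softmax(axis=-1) @ v
            att = att.transpose(0, 2, 1, 3).reshape(B, p, d)
            att = att @ P[f"Wo{layer}"] + P[f"bo{layer}"]
            att = self._dropout(att, training, rng)
            z = _layer_norm(z + att, P[f"ga{layer}"], P[f"bea{layer}"])
            ff = ((z @ P[f"Wf1_{layer}"] + P[f"bf1_{layer}"]).relu()
                  @ P[f"Wf2_{layer}"] + P[f"bf2_{layer}"])
            ff = self._dropout(ff, training, rng)
            z = _layer_norm(z + ff, P[f"gf{layer}"], P[f"bef{layer}"])
        return z.mean(axis=1)

    def _forward(self, X: np.ndarray, training: bool = False,
                 rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        """Probabilities plus the per-sample updated memory (batch, hidden)."""
        z = self.encode(X, training=training, rng=rng)
        P = self.params
        gate = (z @ P["Wg"] + P["bg"]).sigmoid()
        mem = gate * Tensor(self.memory) + (1.0 - gate) * z
        logits = concat([z, mem], axis=1) @ P["Wo"] + P["bo"]
        return logits.sigmoid(), mem

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic outcome probabilities (dropout off, memory frozen)."""
        probs, _ = self._forward(X, training=False)
        return probs.data.copy()

    def predict_stochastic(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One dropout-active forward pass (for Monte Carlo dropout)."""
        probs, _ = self._forward(X, training=True, rng=rng)
        return probs.data.copy()

    def counterfactual_predict(self, X: np.ndarray, arm,
                               rng: np.random.Generator | None = None) -> np.ndarray:
        """Predicted outcome probability with the treatment input forced to ``arm``.

        For a binary treatment (one encoding column) ``arm`` is 0 or 1; for a
        one-hot multi-arm encoding ``arm`` indexes the overridden column.
        """
        X = np.atleast_2d(np.asarray(X, float)).copy()
        tc = self.treatment_cols
        if len(tc) == 1:
            if arm not in (0, 1):
                raise ValueError(f"unknown arm {arm!r} for binary treatment")
            X[:, tc[0]] = float(arm)
        else:
            if not 0 <= int(arm) < len(tc):
                raise ValueError(f"unknown arm {arm!r}")
            X[:, tc] = 0.0
            X[:, tc[int(arm)]] = 1.0
        if rng is None:
            return self.predict(X)
        return self.predict_stochastic(X, rng)

    # -- training -------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None) -> list[dict]:
        """Minimize mean binary cross-entropy with Adam and early stopping.

        The external memory is updated batch-by-batch in a seeded shuffle
        order fixed per epoch and frozen once training ends. Returns the
        loss trace (one record per epoch).
        """
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary")
        if len(np.unique(y)) < 2:
            warnings.warn("single-class labels; training proceeds but the "
                          "fitted probabilities will be degenerate")
        if X_val is None:
            n_val = max(1, int(0.2 * len(X)))
            X_val, y_val = X[-n_val:], y[-n_val:]
            X, y = X[:-n_val], y[:-n_val]
        rng = np.random.default_rng(self.config.seed)
        opt = Adam(list(self.params.values()), lr=self.config.lr)
        best_val = np.inf
        best_state = None
        best_memory = self.memory.copy()
        stale = 0
        self.loss_trace = []
        for epoch in range(self.config.epochs):
            order = rng.permutation(len(X))
            epoch_losses = []
            for start in range(0, len(X), self.config.batch_size):
                idx = order[start:start + self.config.batch_size]
                probs, mem = self._forward(X[idx], training=True, rng=rng)
                p = probs * (1 - 2e-12) + 1e-12
                yb = Tensor(y[idx])
                loss = -(yb * p.log() + (1.0 - yb) * (1.0 - p).log()).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                self.memory = mem.data.mean(axis=0)
                epoch_losses.append(float(loss.data))
            val_loss = bce_loss(self.predict(X_val), y_val)
            self.loss_trace.append({
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
            })
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = {k: v.data.copy() for k, v in self.params.items()}
                best_memory = self.memory.copy()
                stale = 0
            else:
                stale += 1
                if stale >= self.config.patience:
                    break
        if best_state is not None:
            for k, v in self.params.items():
                v.data = best_state[k]
            self.memory = best_memory
        return self.loss_trace

    # -- persistence -----------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint (npz) with a config echo."""
        arrays = {k: v.data for k, v in self.params.items()}
        arrays["__memory__"] = self.memory
        np.savez(path, config=json.dumps({
            **asdict(self.config),
            "n_features": self.n_features,
            "treatment_cols": self.treatment_cols,
        }), **arrays)

    @classmethod
    def load(cls, path) -> "TitanModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["config"]))
            n_features = meta.pop("n_features")
            treatment_cols = meta.pop("treatment_cols")
            model = cls(TitanConfig(**meta), n_features, treatment_cols)
            for k in model.params:
                model.params[k].data = data[k]
            model.memory = data["__memory__"]
        return model

    def write_loss_trace(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss"])
            writer.writeheader()
            writer.writerows(self.loss_trace)


@dataclass
class MLPConfig:
    """Plain feed-forward baseline variant (SiLU activations)."""

    hidden: int = 512
    layers: int = 2
    dropout: float = 0.1029
    lr: float = 1.59e-4
    epochs: int = 29
    batch_size: int = 1024
    patience: int = 4
    seed: int = 0


class MLPModel:
    """Dropout-regularized multilayer perceptron sharing the predictor
    interface (predict / predict_stochastic / counterfactual_predict / fit)."""

    def __init__(self, config: MLPConfig, n_features: int,
                 treatment_cols: list[int]):
        self.config = config
        self.n_features = int(n_features)
        self.treatment_cols = list(treatment_cols)
        rng = np.random.default_rng(config.seed)
        sizes = [self.n_features] + [config.hidden] * config.layers + [1]
        self.params: dict[str, Tensor] = {}
        for i, (fi, fo) in enumerate(zip(sizes[:-1], sizes[1:])):
            self.params[f"W{i}"] = Tensor(
                rng.normal(0, 1.0 / np.sqrt(fi), (fi, fo)), requires_grad=True)
            self.params[f"b{i}"] = Tensor(np.zeros(fo), requires_grad=True)
        self.loss_trace: list[dict] = []

    def _forward(self, X, training=False, rng=None):
        h = Tensor(np.atleast_2d(np.asarray(X, float)))
        n_layers = len(self.params) // 2
        for i in range(n_layers):
            h = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if i < n_layers - 1:
                h = h * h.sigmoid()  # SiLU
                if training and self.config.dropout > 0:
                    mask = (rng.random(h.shape) >= self.config.dropout) / (
                        1.0 - self.config.dropout)
                    h = h * Tensor(mask)
        return h.reshape(h.shape[0]).sigmoid()

    def predict(self, X):
        return self._forward(X, training=False).data.copy()

    def predict_stochastic(self, X, rng):
        return self._forward(X, training=True, rng=rng).data.copy()

    counterfactual_predict = TitanModel.counterfactual_predict

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X_val is None:
            n_val = max(1, int(0.2 * len(X)))
            X_val, y_val = X[-n_val:], y[-n_val:]
            X, y = X[:-n_val], y[:-n_val]
        rng = np.random.default_rng(self.config.seed)
        opt = Adam(list(self.params.values()), lr=self.config.lr)
        best_val, best_state, stale = np.inf, None, 0
        self.loss_trace = []
        for epoch in range(self.config.epochs):
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), self.config.batch_size):
                idx = order[start:start + self.config.batch_size]
                p = self._forward(X[idx], training=True, rng=rng)
                p = p * (1 - 2e-12) + 1e-12
                yb = Tensor(y[idx])
                loss = -(yb * p.log() + (1.0 - yb) * (1.0 - p).log()).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            val_loss = bce_loss(self.predict(X_val), y_val)
            self.loss_trace.append({"epoch": epoch,
                                    "train_loss": float(np.mean(losses)),
                                    "val_loss": val_loss})
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = {k: v.data.copy() for k, v in self.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= self.config.patience:
                    break
        if best_state is not None:
            for k, v in self.params.items():
                v.data = best_state[k]
        return self.loss_trace
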