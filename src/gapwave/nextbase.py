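"""Character-level next-base model: Conv1D -> max-pool -> Bi-LSTM -> softmax.

The network reads a one-hot encoded context of W bases and outputs a
probability distribution over the next base (A, C, G, T). Layer stack:

    one-hot (W, 4)
      -> 1-D convolution, ``conv_filters`` filters, kernel ``kernel_size``,
         "same" padding, ReLU
      -> max pooling along the sequence axis (size = stride = ``pool_size``)
      -> bidirectional LSTM (``bilstm_units`` total output units, half per
         direction; final hidden state of each direction, concatenated)
      -> dense layer with 4 units and softmax

Training minimises categorical cross-entropy with Adam, with early stopping
on a held-out validation split. The implementation is pure NumPy (forward
and backward passes written out explicitly) so that training is exactly
reproducible from the seed; gradients are validated against finite
differences in the test suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .corpus import TrainingWindow, windows_to_arrays

_EPS = 1e-12


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``bilstm_units`` is the total (concatenated) recurrent output dimension,
    i.e. half of it per direction.
    """

    context_length: int = 64
    conv_filters: int = 32
    kernel_size: int = 3
    pool_size: int = 2
    bilstm_units: int = 512
    n_classes: int = 4
    max_epochs: int = 1500
    batch_size: int = 64
    early_stop_patience: int = 20
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "context_length",
            "conv_filters",
            "kernel_size",
            "pool_size",
            "bilstm_units",
            "max_epochs",
            "batch_size",
            "early_stop_patience",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_classes != 4:
            raise ValueError("n_classes is fixed at 4 (A, C, G, T)")
        if self.kernel_size > self.context_length:
            raise ValueError("kernel_size cannot exceed context_length")
        if self.pool_size > self.context_length:
            raise ValueError("pool_size cannot exceed context_length")
        if self.bilstm_units % 2 != 0:
            raise ValueError("bilstm_units must be even (half per direction)")
        if not 0.0 < self.learning_rate:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")


def _glorot(rng: np.random.Generator, shape: Tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class NextBaseModel:
    """Next-base model; query with :meth:`predict_next` / :meth:`predict_proba`."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.history: List[Dict[str, float]] = []
        self._trained = False
        self.params = self._init_params()
        self._adam_m: Optional[Dict[str, np.ndarray]] = None
        self._adam_v: Optional[Dict[str, np.ndarray]] = None
        self._adam_t = 0

    # ------------------------------------------------------------------ init

    def _init_params(self) -> Dict[str, np.ndarray]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        k4 = cfg.kernel_size * 4
        F = cfg.conv_filters
        H = cfg.bilstm_units // 2
        params: Dict[str, np.ndarray] = {
            "Wc": _glorot(rng, (k4, F)),
            "bc": np.zeros(F),
            "Wy": _glorot(rng, (2 * H, cfg.n_classes)),
            "by": np.zeros(cfg.n_classes),
        }
        for d in ("f", "b"):
            params[f"Wx_{d}"] = _glorot(rng, (F, 4 * H))
            params[f"Wh_{d}"] = _glorot(rng, (H, 4 * H))
            bias = np.zeros(4 * H)
            bias[H : 2 * H] = 1.0  # forget-gate bias starts open
            params[f"b_{d}"] = bias
        return params

    # --------------------------------------------------------------- forward

    @property
    def context_length(self) -> int:
        return self.config.context_length

    @property
    def is_trained(self) -> bool:
        return self._trained

    def _conv_cols(self, X: np.ndarray) -> np.ndarray:
        """im2col for "same" 1-D convolution: (B, W, 4) -> (B, W, k*4)."""
        k = self.config.kernel_size
        pad_l, pad_r = (k - 1) // 2, k // 2
        Xp = np.pad(X, ((0, 0), (pad_l, pad_r), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(Xp, k, axis=1)  # (B,W,4,k)
        return win.transpose(0, 1, 3, 2).reshape(X.shape[0], X.shape[1], k * 4)

    def _lstm_forward(self, X: np.ndarray, direction: str) -> Tuple[np.ndarray, list]:
        """Run one LSTM direction over X (B, T, F); returns final hidden state
        and the per-step cache for backprop. ``direction`` 'b' consumes the
        sequence reversed."""
        p = self.params
        Wx, Wh, b = p[f"Wx_{direction}"], p[f"Wh_{direction}"], p[f"b_{direction}"]
        B, T, _ = X.shape
        H = self.config.bilstm_units // 2
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        order = range(T - 1, -1, -1) if direction == "b" else range(T)
        cache = []
        for t in order:
            x_t = X[:, t, :]
            z = x_t @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h = o * tanh_c
            cache.append((t, x_t, h_prev, c_prev, i, f, g, o, tanh_c))
        return h, cache

    def _forward(self, X: np.ndarray, want_cache: bool = False):
        """Full forward pass on one-hot input X (B, W, 4) -> probs (B, 4)."""
        p = self.params
        cfg = self.config
        cols = self._conv_cols(X)
        pre = cols @ p["Wc"] + p["bc"]  # (B, W, F)
        act = np.maximum(pre, 0.0)
        s = cfg.pool_size
        T = cfg.context_length // s
        trim = act[:, : T * s, :].reshape(X.shape[0], T, s, cfg.conv_filters)
        pooled = trim.max(axis=2)
        pool_idx = trim.argmax(axis=2)
        h_f, cache_f = self._lstm_forward(pooled, "f")
        h_b, cache_b = self._lstm_forward(pooled, "b")
        hcat = np.concatenate([h_f, h_b], axis=1)
        logits = hcat @ p["Wy"] + p["by"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        if not want_cache:
            return probs, None
        cache = {
            "cols": cols,
            "pre": pre,
            "pool_idx": pool_idx,
            "pooled": pooled,
            "cache_f": cache_f,
            "cache_b": cache_b,
            "hcat": hcat,
            "probs": probs,
        }
        return probs, cache

    # -------------------------------------------------------------- backward

    def _lstm_backward(
        self, cache: list, dh_final: np.ndarray, direction: str, T: int
    ) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
        p = self.params
        Wx, Wh = p[f"Wx_{direction}"], p[f"Wh_{direction}"]
        B = dh_final.shape[0]
        H = self.config.bilstm_units // 2
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dX = np.zeros((B, T, Wx.shape[0]))
        dh = dh_final
        dc = np.zeros((B, H))
        for t, x_t, h_prev, c_prev, i, f, g, o, tanh_c in reversed(cache):
            do = dh * tanh_c
            dct = dc + dh * o * (1.0 - tanh_c**2)
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dc = dct * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t, :] = dz @ Wx.T
            dh = dz @ Wh.T
        return {f"Wx_{direction}": dWx, f"Wh_{direction}": dWh, f"b_{direction}": db}, dX

    def _backward(self, cache: dict, Y: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradients of mean cross-entropy wrt all parameters; Y is (B,) int."""
        p = self.params
        cfg = self.config
        B = Y.shape[0]
        F = cfg.conv_filters
        H = cfg.bilstm_units // 2
        s = cfg.pool_size
        T = cfg.context_length // s

        dlogits = cache["probs"].copy()
        dlogits[np.arange(B), Y] -= 1.0
        dlogits /= B
        grads: Dict[str, np.ndarray] = {
            "Wy": cache["hcat"].T @ dlogits,
            "by": dlogits.sum(axis=0),
        }
        dhcat = dlogits @ p["Wy"].T
        g_f, dX_f = self._lstm_backward(cache["cache_f"], dhcat[:, :H], "f", T)
        g_b, dX_b = self._lstm_backward(cache["cache_b"], dhcat[:, H:], "b", T)
        grads.update(g_f)
        grads.update(g_b)
        dpooled = dX_f + dX_b  # both directions index dX by true timestep

        dtrim = np.zeros((B, T, s, F))
        np.put_along_axis(dtrim, cache["pool_idx"][:, :, None, :], dpooled[:, :, None, :], axis=2)
        dact = np.zeros_like(cache["pre"])
        dact[:, : T * s, :] = dtrim.reshape(B, T * s, F)
        dpre = dact * (cache["pre"] > 0.0)
        k4 = cfg.kernel_size * 4
        grads["Wc"] = cache["cols"].reshape(-1, k4).T @ dpre.reshape(-1, F)
        grads["bc"] = dpre.sum(axis=(0, 1))
        return grads

    # -------------------------------------------------------------- training

    def _adam_step(self, grads: Dict[str, np.ndarray]) -> None:
        lr = self.config.learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        if self._adam_m is None:
            self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
            self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    @staticmethod
    def _to_onehot(ctx_idx: np.ndarray) -> np.ndarray:
        B, W = ctx_idx.shape
        X = np.zeros((B, W, 4))
        X[np.arange(B)[:, None], np.arange(W)[None, :], ctx_idx] = 1.0
        return X

    def _eval_loss(self, ctx_idx: np.ndarray, labels: np.ndarray, batch: int = 512) -> Tuple[float, float]:
        total, correct = 0.0, 0
        for i in range(0, len(labels), batch):
            X = self._to_onehot(ctx_idx[i : i + batch])
            y = labels[i : i + batch]
            probs, _ = self._forward(X)
            total += -np.log(probs[np.arange(len(y)), y] + _EPS).sum()
            correct += int((probs.argmax(axis=1) == y).sum())
        n = len(labels)
        return total / n, correct / n

    def fit(self, windows: Sequence[TrainingWindow], verbose: bool = False) -> "NextBaseModel":
        """Train on (context, next-base) windows with early stopping.

        The windows are split into train/validation (``val_fraction``) with
        the config seed; training stops when validation loss has not
        improved for ``early_stop_patience`` epochs (or at ``max_epochs``),
        and the best-validation parameters are restored.
        """
        if not windows:
            raise ValueError("cannot train on an empty corpus")
        cfg = self.config
        ctx_idx, labels = windows_to_arrays(windows)
        if ctx_idx.shape[1] != cfg.context_length:
            raise ValueError(
                f"window context length {ctx_idx.shape[1]} != model context_length {cfg.context_length}"
            )
        rng = np.random.default_rng(cfg.seed + 1)
        perm = rng.permutation(len(labels))
        n_val = int(round(cfg.val_fraction * len(labels)))
        n_val = min(n_val, len(labels) - 1)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        tr_ctx, tr_lab = ctx_idx[train_idx], labels[train_idx]
        va_ctx, va_lab = ctx_idx[val_idx], labels[val_idx]

        best_loss = math.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        patience_left = cfg.early_stop_patience
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(len(tr_lab))
            train_loss = 0.0
            for i in range(0, len(order), cfg.batch_size):
                sel = order[i : i + cfg.batch_size]
                X = self._to_onehot(tr_ctx[sel])
                y = tr_lab[sel]
                probs, cache = self._forward(X, want_cache=True)
                train_loss += -np.log(probs[np.arange(len(y)), y] + _EPS).sum()
                grads = self._backward(cache, y)
                self._adam_step(grads)
            train_loss /= len(tr_lab)
            if len(va_lab):
                val_loss, val_acc = self._eval_loss(va_ctx, va_lab)
            else:
                val_loss, val_acc = train_loss, float("nan")
            self.history.append(
                {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "val_acc": val_acc}
            )
            if verbose:
                print(f"epoch {epoch:4d}  train_loss {train_loss:.4f}  val_loss {val_loss:.4f}")
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                patience_left = cfg.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        self.params = best_params
        self._trained = True
        return self

    # ------------------------------------------------------------- inference

    def _encode_contexts(self, contexts: Sequence[str]) -> np.ndarray:
        W = self.config.context_length
        from .corpus import BASE_INDEX

        idx = np.empty((len(contexts), W), dtype=np.uint8)
        for i, ctx in enumerate(contexts):
            if len(ctx) != W:
                raise ValueError(f"context length {len(ctx)} != {W}")
            try:
                idx[i] = [BASE_INDEX[c] for c in ctx]
            except KeyError as exc:
                raise ValueError(f"invalid base {exc.args[0]!r} in context") from None
        return idx

    def predict_proba(self, contexts: Sequence[str], batch: int = 1024) -> np.ndarray:
        """Next-base probabilities, shape (n, 4) in (A, C, G, T) order."""
        idx = self._encode_contexts(contexts)
        out = np.empty((len(contexts), 4))
        for i in range(0, len(contexts), batch):
            X = self._to_onehot(idx[i : i + batch])
            probs, _ = self._forward(X)
            out[i : i + batch] = probs
        return out

    def predict_next(self, context: str) -> np.ndarray:
        """Probability 4-vector over (A, C, G, T) for a single context."""
        return self.predict_proba([context])[0]

    # ----------------------------------------------------------- persistence

    def save(self, directory) -> None:
        """Save config (JSON), weights (npz) and training history (JSON)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "config.json", "w") as fh:
            json.dump({"config": asdict(self.config), "trained": self._trained}, fh, indent=2)
        np.savez(d / "weights.npz", **self.params)
        with open(d / "history.json", "w") as fh:
            json.dump(self.history, fh)

    @classmethod
    def load(cls, directory) -> "NextBaseModel":
        d = Path(directory)
        with open(d / "config.json") as fh:
            meta = json.load(fh)
        model = cls(ModelConfig(**meta["config"]))
        with np.load(d / "weights.npz") as npz:
            model.params = {k: npz[k] for k in npz.files}
        model._trained = bool(meta.get("trained", False))
        hist = d / "history.json"
        if hist.exists():
            with open(hist) as fh:
                model.history = json.load(fh)
        return model


# Functional surface mirroring the build/train/query workflow.

def build_model(config: ModelConfig) -> NextBaseModel:
    """Construct an untrained model with seeded parameter initialisation."""
    return NextBaseModel(config)


def train(model: NextBaseModel, windows: Sequence[TrainingWindow], verbose: bool = False) -> NextBaseModel:
    """Train the model in place on the window corpus; returns the model."""
    return model.fit(windows, verbose=verbose)


def predict_next(model: NextBaseModel, context: str) -> np.ndarray:
    return model.predict_next(context)
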