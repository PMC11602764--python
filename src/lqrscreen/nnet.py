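"""A compact feed-forward binary classifier in numpy.

Architecture: four dense hidden layers, each followed by batch
normalisation, ReLU and dropout, then a sigmoid output unit whose bias is
initialised to the log-odds of the training prevalence so early epochs
start from the base rate.  Training minimises class-weighted binary
cross-entropy with Adam; the learning rate halves when the validation AUC
plateaus and training stops early (restoring the best weights) when it no
longer improves.  Batch normalisation lets raw, unscaled features be fed
directly.

Everything is deterministic given the seed.  Designed for small tabular
problems (n ~ 1e4, d ~ 1e2) where a framework-scale dependency would be
disproportionate; weights serialise to JSON exactly (float64 round-trip).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = ["MLPBinaryClassifier", "roc_auc"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties (rank formula)."""
    from scipy.stats import rankdata

    y = np.asarray(y_true, dtype=bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class _Layer:
    w: np.ndarray
    b: np.ndarray
    gamma: np.ndarray | None = None  # batch-norm scale
    beta: np.ndarray | None = None   # batch-norm shift
    run_mean: np.ndarray | None = None
    run_var: np.ndarray | None = None


class MLPBinaryClassifier:
    """Class-weighted MLP for binary risk prediction.

    Parameters
    ----------
    hidden_layers : sequence of int
        Widths of the hidden layers (default four layers 64/32/16/8).
    dropout : float or sequence of float
        Dropout rate after each hidden layer.
    batch_norm : bool
        Batch-normalise each hidden pre-activation (default on).
    class_weight : {"balanced", None}
        "balanced" weighs each class by ``n / (2 * n_class)``.
    learning_rate, lr_factor, lr_patience
        Adam initial step and reduce-on-plateau schedule (on val AUC).
    early_stopping_patience : int
        Epochs without validation-AUC improvement before stopping; the
        best-epoch weights are restored.
    """

    def __init__(
        self,
        hidden_layers: Sequence[int] = (64, 32, 16, 8),
        dropout: float | Sequence[float] = 0.2,
        batch_norm: bool = True,
        class_weight: str | None = "balanced",
        learning_rate: float = 1e-3,
        lr_factor: float = 0.5,
        lr_patience: int = 3,
        early_stopping_patience: int = 10,
        max_epochs: int = 200,
        batch_size: int = 128,
        seed: int = 0,
    ) -> None:
        self.hidden_layers = tuple(int(h) for h in hidden_layers)
        if np.isscalar(dropout):
            dropout = [float(dropout)] * len(self.hidden_layers)
        self.dropout = tuple(float(d) for d in dropout)
        if len(self.dropout) != len(self.hidden_layers):
            raise ValueError("one dropout rate per hidden layer required")
        if any(not 0 <= d < 1 for d in self.dropout):
            raise ValueError("dropout rates must lie in [0, 1)")
        self.batch_norm = bool(batch_norm)
        self.class_weight = class_weight
        self.learning_rate = float(learning_rate)
        self.lr_factor = float(lr_factor)
        self.lr_patience = int(lr_patience)
        self.early_stopping_patience = int(early_stopping_patience)
        self.max_epochs = int(max_epochs)
        self.batch_size = int(batch_size)
        self.seed = int(seed)
        self.layers_: list[_Layer] | None = None
        self.history_: dict[str, list[float]] = {}

    # ------------------------------------------------------------------
    def _init_params(self, d: int, prevalence: float) -> list[_Layer]:
        rng = np.random.default_rng(self.seed)
        dims = [d, *self.hidden_layers, 1]
        layers: list[_Layer] = []
        for i in range(len(dims) - 1):
            fan_in, fan_out = dims[i], dims[i + 1]
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            b = np.zeros(fan_out)
            layer = _Layer(w, b)
            if self.batch_norm and i < len(dims) - 2:
                layer.gamma = np.ones(fan_out)
                layer.beta = np.zeros(fan_out)
                layer.run_mean = np.zeros(fan_out)
                layer.run_var = np.ones(fan_out)
            layers.append(layer)
        # output bias: log-odds of the training prevalence
        p = np.clip(prevalence, 1e-6, 1 - 1e-6)
        layers[-1].b[:] = np.log(p / (1 - p))
        return layers

    def _forward(self, x: np.ndarray, rng: np.random.Generator | None):
        """Forward pass; ``rng`` enables train mode (dropout, batch stats)."""
        caches = []
        h = x
        train = rng is not None
        for i, layer in enumerate(self.layers_[:-1]):
            z = h @ layer.w + layer.b
            cache = {"h_in": h, "z": z}
            if layer.gamma is not None:
                if train:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    layer.run_mean = (_BN_MOMENTUM * layer.run_mean
                                      + (1 - _BN_MOMENTUM) * mu)
                    layer.run_var = (_BN_MOMENTUM * layer.run_var
                                     + (1 - _BN_MOMENTUM) * var)
                else:
                    mu, var = layer.run_mean, layer.run_var
                inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
                zhat = (z - mu) * inv_sd
                z = layer.gamma * zhat + layer.beta
                cache.update(zhat=zhat, inv_sd=inv_sd)
            act = np.maximum(z, 0.0)
            cache["act_pre_drop"] = act
            if train and self.dropout[i] > 0:
                keep = 1.0 - self.dropout[i]
                mask = (rng.uniform(size=act.shape) < keep) / keep
                act = act * mask
                cache["drop_mask"] = mask
            caches.append(cache)
            h = act
        out = self.layers_[-1]
        logit = h @ out.w + out.b
        caches.append({"h_in": h})
        return logit[:, 0], caches

    def _backward(self, dlogit: np.ndarray, caches) -> list[dict]:
        grads: list[dict] = [None] * len(self.layers_)
        out = self.layers_[-1]
        h = caches[-1]["h_in"]
        grads[-1] = {"w": h.T @ dlogit[:, None], "b": dlogit.sum(keepdims=True)}
        dh = dlogit[:, None] @ out.w.T
        for i in range(len(self.layers_) - 2, -1, -1):
            layer = self.layers_[i]
            cache = caches[i]
            if "drop_mask" in cache:
                dh = dh * cache["drop_mask"]
            dz = dh * (cache["act_pre_drop"] > 0)
            g: dict = {}
            if layer.gamma is not None:
                zhat, inv_sd = cache["zhat"], cache["inv_sd"]
                m = dz.shape[0]
                g["gamma"] = (dz * zhat).sum(axis=0)
                g["beta"] = dz.sum(axis=0)
                dz = (layer.gamma * inv_sd / m) * (
                    m * dz - dz.sum(axis=0) - zhat * (dz * zhat).sum(axis=0)
                )
            g["w"] = cache["h_in"].T @ dz
            g["b"] = dz.sum(axis=0)
            grads[i] = g
            dh = dz @ layer.w.T
        return grads

    # ------------------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "MLPBinaryClassifier":
        """Train with Adam; monitor validation AUC when a val set is given."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if np.isnan(x).any():
            raise ValueError("features contain NaN; impute before training")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        n, d = x.shape
        prevalence = float(y.mean())
        if self.class_weight == "balanced":
            w_pos = n / (2.0 * y.sum())
            w_neg = n / (2.0 * (n - y.sum()))
        else:
            w_pos = w_neg = 1.0
        sample_w = np.where(y == 1, w_pos, w_neg)

        self.layers_ = self._init_params(d, prevalence)
        rng = np.random.default_rng(self.seed + 1)
        # Adam state
        m_state = [
            {k: np.zeros_like(getattr(l, k))
             for k in ("w", "b", "gamma", "beta") if getattr(l, k) is not None}
            for l in self.layers_
        ]
        v_state = [{k: np.zeros_like(v) for k, v in ms.items()}
                   for ms in m_state]
        lr = self.learning_rate
        t = 0
        monitor = x_val is not None and y_val is not None
        best_auc, best_state, best_epoch = -np.inf, None, -1
        lr_wait = stop_wait = 0
        self.history_ = {"loss": [], "val_auc": []}

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                if idx.size < 2 and n > 1:
                    continue  # batch statistics need >= 2 rows
                xb, yb, wb = x[idx], y[idx], sample_w[idx]
                logit, caches = self._forward(xb, rng)
                p = expit(logit)
                eps = 1e-12
                loss = -np.mean(wb * (yb * np.log(p + eps)
                                      + (1 - yb) * np.log(1 - p + eps)))
                epoch_loss += loss * idx.size
                dlogit = wb * (p - yb) / idx.size
                grads = self._backward(dlogit, caches)
                t += 1
                for layer, g, ms, vs in zip(self.layers_, grads, m_state,
                                            v_state):
                    for k, grad in g.items():
                        grad = grad.reshape(getattr(layer, k).shape)
                        ms[k] = 0.9 * ms[k] + 0.1 * grad
                        vs[k] = 0.999 * vs[k] + 0.001 * grad**2
                        mhat = ms[k] / (1 - 0.9**t)
                        vhat = vs[k] / (1 - 0.999**t)
                        getattr(layer, k)[...] -= (
                            lr * mhat / (np.sqrt(vhat) + 1e-8)
                        )
            self.history_["loss"].append(epoch_loss / n)
            if not monitor:
                continue
            val_auc = roc_auc(y_val, self.predict_proba(x_val))
            self.history_["val_auc"].append(val_auc)
            if val_auc > best_auc + 1e-6:
                best_auc, best_epoch = val_auc, epoch
                best_state = self._snapshot()
                lr_wait = stop_wait = 0
            else:
                lr_wait += 1
                stop_wait += 1
                if lr_wait > self.lr_patience:
                    lr *= self.lr_factor
                    lr_wait = 0
                if stop_wait > self.early_stopping_patience:
                    break
        if monitor and best_state is not None:
            self._restore(best_state)
            self.best_val_auc_ = float(best_auc)
            self.best_epoch_ = int(best_epoch)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Risk scores in [0, 1] (inference mode: no dropout, running BN)."""
        if self.layers_ is None:
            raise RuntimeError("model is not fitted")
        x = np.asarray(x, dtype=float)
        logit, _ = self._forward(x, rng=None)
        return expit(logit)

    # ------------------------------------------------------------------
    def _snapshot(self) -> list[dict]:
        out = []
        for l in self.layers_:
            out.append({
                k: np.array(getattr(l, k), copy=True)
                for k in ("w", "b", "gamma", "beta", "run_mean", "run_var")
                if getattr(l, k) is not None
            })
        return out

    def _restore(self, state: list[dict]) -> None:
        for l, s in zip(self.layers_, state):
            for k, v in s.items():
                setattr(l, k, np.array(v, copy=True))

    def get_config(self) -> dict:
        return {
            "hidden_layers": list(self.hidden_layers),
            "dropout": list(self.dropout),
            "batch_norm": self.batch_norm,
            "class_weight": self.class_weight,
            "learning_rate": self.learning_rate,
            "lr_factor": self.lr_factor,
            "lr_patience": self.lr_patience,
            "early_stopping_patience": self.early_stopping_patience,
            "max_epochs": self.max_epochs,
            "batch_size": self.batch_size,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        """Exact (float64 repr) serialisation of config and weights."""
        if self.layers_ is None:
            raise RuntimeError("model is not fitted")
        state = [
            {k: v.tolist() for k, v in snap.items()}
            for snap in self._snapshot()
        ]
        return json.dumps({"config": self.get_config(), "state": state})

    @classmethod
    def from_json(cls, payload: str) -> "MLPBinaryClassifier":
        d = json.loads(payload)
        model = cls(**d["config"])
        model.layers_ = []
        for s in d["state"]:
            layer = _Layer(np.asarray(s["w"]), np.asarray(s["b"]))
            for k in ("gamma", "beta", "run_mean", "run_var"):
                if k in s:
                    setattr(layer, k, np.asarray(s[k]))
            model.layers_.append(layer)
        return model
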