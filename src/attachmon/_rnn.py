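"""Compact seeded recurrent sequence classifier (single-layer GRU).

Binary classifier over fixed-length multivariate sequences: a gated
recurrent unit layer is run over the time axis, the hidden states are
mean-pooled and mapped through a logistic output.  Training is full
backpropagation-through-time with Adam on mini-batches, weighted binary
cross-entropy, and global-norm gradient clipping.  All randomness (weight
initialisation, batch shuffling) comes from a single numpy Generator, so a
fixed seed gives bit-identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GRUClassifier"]

_PARAM_NAMES = ("Wz", "Wr", "Wc", "Uz", "Ur", "Uc", "bz", "br", "bc", "w", "b")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GRUClassifier:
    n_features: int
    hidden_size: int = 16
    epochs: int = 60
    learning_rate: float = 0.02
    batch_size: int = 32
    clip_norm: float = 5.0
    seed: int = 0
    params: dict = field(default_factory=dict, repr=False)
    loss_history_: list = field(default_factory=list, repr=False)

    # -- parameter handling -------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        F, H = self.n_features, self.hidden_size
        sf, sh = 1.0 / np.sqrt(F), 1.0 / np.sqrt(H)
        p = {}
        for name in ("Wz", "Wr", "Wc"):
            p[name] = rng.uniform(-sf, sf, size=(F, H))
        for name in ("Uz", "Ur", "Uc"):
            p[name] = rng.uniform(-sh, sh, size=(H, H))
        for name in ("bz", "br", "bc"):
            p[name] = np.zeros(H)
        p["w"] = rng.uniform(-sh, sh, size=H)
        p["b"] = np.zeros(1)
        self.params = p

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray):
        """X: (n, T, F) -> probabilities (n,) plus cache for BPTT."""
        p = self.params
        n, T, F = X.shape
        H = self.hidden_size
        h = np.zeros((n, H))
        hs = np.empty((T, n, H))
        cache = []
        for t in range(T):
            x = X[:, t, :]
            z = _sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
            c = np.tanh(x @ p["Wc"] + (r * h) @ p["Uc"] + p["bc"])
            h_new = (1.0 - z) * h + z * c
            cache.append((x, h, z, r, c))
            h = h_new
            hs[t] = h
        hbar = hs.mean(axis=0)
        logit = hbar @ p["w"] + p["b"][0]
        prob = _sigmoid(logit)
        return prob, (hbar, hs, cache, T)

    def _backward(self, X, y, sw, prob, fwd_cache):
        p = self.params
        hbar, hs, cache, T = fwd_cache
        n = len(y)
        S = sw.sum()
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogit = sw * (prob - y) / S  # (n,)
        grads["w"] = hbar.T @ dlogit
        grads["b"] = np.array([dlogit.sum()])
        dhbar = np.outer(dlogit, p["w"])  # (n, H)
        dh = dhbar / T  # pooling contribution at the last step
        for t in range(T - 1, -1, -1):
            x, h_prev, z, r, c = cache[t]
            dz = dh * (c - h_prev)
            dc = dh * z
            dh_prev = dh * (1.0 - z)
            dc_pre = dc * (1.0 - c * c)
            grads["Wc"] += x.T @ dc_pre
            grads["Uc"] += (r * h_prev).T @ dc_pre
            grads["bc"] += dc_pre.sum(axis=0)
            drh = dc_pre @ p["Uc"].T
            dr = drh * h_prev
            dh_prev += drh * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            grads["Wz"] += x.T @ dz_pre
            grads["Uz"] += h_prev.T @ dz_pre
            grads["bz"] += dz_pre.sum(axis=0)
            grads["Wr"] += x.T @ dr_pre
            grads["Ur"] += h_prev.T @ dr_pre
            grads["br"] += dr_pre.sum(axis=0)
            dh_prev = dh_prev + dz_pre @ p["Uz"].T + dr_pre @ p["Ur"].T
            dh = dh_prev + (dhbar / T if t > 0 else 0.0)
        return grads

    def _loss(self, prob, y, sw) -> float:
        eps = 1e-12
        bce = -(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
        return float((sw * bce).sum() / sw.sum())

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight=None) -> "GRUClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if sample_weight is None:
            sample_weight = np.ones(len(y))
        sw = np.asarray(sample_weight, dtype=float)
        rng = np.random.default_rng(self.seed)
        self._init_params(rng)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(y)
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                prob, cache = self._forward(X[idx])
                grads = self._backward(X[idx], y[idx], sw[idx], prob, cache)
                epoch_loss += self._loss(prob, y[idx], sw[idx]) * len(idx)
                norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
                if norm > self.clip_norm:
                    scale = self.clip_norm / norm
                    grads = {k: g * scale for k, g in grads.items()}
                step += 1
                for k in self.params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mhat = m[k] / (1 - b1**step)
                    vhat = v[k] / (1 - b2**step)
                    self.params[k] -= (
                        self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                    )
            self.loss_history_.append(epoch_loss / n)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        prob, _ = self._forward(X)
        return prob

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "hidden_size": self.hidden_size,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "clip_norm": self.clip_norm,
            "seed": self.seed,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GRUClassifier":
        obj = cls(
            n_features=d["n_features"],
            hidden_size=d["hidden_size"],
            epochs=d["epochs"],
            learning_rate=d["learning_rate"],
            batch_size=d["batch_size"],
            clip_norm=d["clip_norm"],
            seed=d["seed"],
        )
        obj.params = {k: np.asarray(v) for k, v in d["params"].items()}
        return obj
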