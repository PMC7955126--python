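"""A small bidirectional LSTM sequence labeller in pure numpy.

One biLSTM layer (H units per direction) over a (T, F) feature sequence,
followed by a per-timestep dense layer with sigmoid output. Training uses
masked, class-weighted binary cross-entropy, full backpropagation through
time, and Adam with global-norm gradient clipping. The model is small
enough (F=27, H=20, T=300) that numpy BPTT trains in seconds at desk
scale, and keeping it dependency-free makes runs exactly reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BiLSTM", "Adam", "masked_bce"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


class BiLSTM:
    """Bidirectional LSTM + sigmoid dense head over padded sequences."""

    def __init__(self, n_features: int, hidden: int = 20, seed: int = 0):
        self.n_features = n_features
        self.hidden = hidden
        rng = np.random.default_rng(seed)
        H, F = hidden, n_features
        self.params: dict[str, np.ndarray] = {}
        for d in ("f", "b"):  # forward / backward direction
            self.params[f"W{d}"] = _glorot(rng, (F, 4 * H))
            self.params[f"U{d}"] = _glorot(rng, (H, 4 * H))
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias init
            self.params[f"b{d}"] = b
        self.params["wd"] = _glorot(rng, (2 * H, 1))[:, 0]
        self.params["bd"] = np.zeros(1)

    # -- forward -----------------------------------------------------------

    def _direction(self, X: np.ndarray, M: np.ndarray, d: str):
        """Run one direction over X (B, T, F); returns hidden states and cache.

        Masked timesteps (M == 0) carry the state through unchanged, so
        padded bins never influence real ones in either direction.
        """
        B, T, _ = X.shape
        H = self.hidden
        W, U, b = self.params[f"W{d}"], self.params[f"U{d}"], self.params[f"b{d}"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hs = np.empty((T, B, H))
        cache = []
        xw = X @ W  # (B, T, 4H), hoisted out of the time loop
        for t in range(T):
            a = xw[:, t, :] + h @ U + b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = M[:, t : t + 1]
            cache.append((h, c, i, f, g, o, tc, m))
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
            Hs[t] = h
        return Hs, cache

    def forward(
        self,
        X: np.ndarray,
        mask: np.ndarray | None = None,
        return_cache: bool = False,
    ):
        """Probabilities (B, T) for a batch of padded sequences."""
        X = np.asarray(X, dtype=float)
        M = (
            np.ones(X.shape[:2]) if mask is None
            else np.asarray(mask, dtype=float)
        )
        Hf, cf = self._direction(X, M, "f")
        Hb_rev, cb = self._direction(X[:, ::-1, :], M[:, ::-1], "b")
        Hb = Hb_rev[::-1]
        Hcat = np.concatenate([Hf, Hb], axis=2)  # (T, B, 2H)
        logits = Hcat @ self.params["wd"] + self.params["bd"][0]  # (T, B)
        probs = _sigmoid(logits).T  # (B, T)
        if return_cache:
            return probs, (X, M, Hcat, cf, cb)
        return probs

    # -- backward ----------------------------------------------------------

    def _direction_grads(self, X, cache, dH, d, grads):
        B, T, _ = X.shape
        H = self.hidden
        U = self.params[f"U{d}"]
        dW = np.zeros_like(self.params[f"W{d}"])
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params[f"b{d}"])
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dA = np.empty((T, B, 4 * H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc, m = cache[t]
            dh_total = dH[t] + dh_next
            dc_total = dc_next
            dh_new = m * dh_total  # masked steps pass state straight through
            dc_new = m * dc_total + dh_new * o * (1.0 - tc * tc)
            do = dh_new * tc
            di, df, dg = dc_new * g, dc_new * c_prev, dc_new * i
            da = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dA[t] = da
            dU += h_prev.T @ da
            dh_next = (1.0 - m) * dh_total + da @ U.T
            dc_next = (1.0 - m) * dc_total + dc_new * f
        # accumulate input-weight grads in one contraction
        dW = np.einsum("btf,tbh->fh", X, dA)
        db = dA.sum(axis=(0, 1))
        grads[f"W{d}"] = dW
        grads[f"U{d}"] = dU
        grads[f"b{d}"] = db

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss given d(loss)/d(logit), shape (B, T)."""
        X, M, Hcat, cf, cb = cache
        T = X.shape[1]
        H = self.hidden
        dlog = dlogits.T  # (T, B)
        grads: dict[str, np.ndarray] = {}
        grads["wd"] = np.einsum("tbh,tb->h", Hcat, dlog)
        grads["bd"] = np.array([dlog.sum()])
        dH = dlog[..., None] * self.params["wd"]  # (T, B, 2H)
        self._direction_grads(X, cf, dH[:, :, :H], "f", grads)
        self._direction_grads(
            X[:, ::-1, :], cb, dH[::-1, :, H:], "b", grads
        )
        return grads

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: np.asarray(v, dtype=float).copy() for k, v in params.items()}


def masked_bce(
    probs: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    class_weights: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, np.ndarray]:
    """Weighted BCE over real bins; returns (loss, d(loss)/d(logit)).

    Padded bins get zero weight, so they contribute nothing to the loss or
    the gradient. The loss is the weighted mean, matching the usual
    class_weight semantics of sequence models.
    """
    y = np.asarray(y, dtype=float)
    w = np.where(y > 0.5, class_weights[1], class_weights[0]) * mask
    denom = w.sum()
    if denom == 0:
        return 0.0, np.zeros_like(probs)
    eps = 1e-12
    p = np.clip(probs, eps, 1 - eps)
    loss = -(w * (y * np.log(p) + (1 - y) * np.log(1 - p))).sum() / denom
    dlogit = w * (probs - y) / denom
    return float(loss), dlogit


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float = 5.0,
    ):
        self.lr, self.betas, self.eps, self.clip_norm = lr, betas, eps, clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        scale = self.clip_norm / norm if norm > self.clip_norm else 1.0
        self.t += 1
        b1, b2 = self.betas
        for k, g in grads.items():
            g = g * scale
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
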