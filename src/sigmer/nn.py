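"""Compact 1D convolutional binary classifiers on raw signal windows.

A detector network is deliberately tiny: a few valid-convolution blocks
(conv -> ReLU -> max-pool 2), global max pooling over time and a single
sigmoid unit.  Global max pooling makes the posterior invariant to where
the k-mer signal sits inside the window, and lets a whole read be scanned
by running the convolution stack once and max-pooling over sliding spans
of the feature map.

Everything — initialization, minibatch order, Adam — is driven by explicit
seeds, so identical inputs give identical weights.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32


class TrainingError(RuntimeError):
    """Optimization failed (non-finite loss)."""


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _conv_forward(a, w, b):
    """Valid 1D conv.  a (B,C,L), w (F,C,K) -> out (B,F,L-K+1), im2col cache."""
    B, C, L = a.shape
    F, _, K = w.shape
    xs = np.lib.stride_tricks.sliding_window_view(a, K, axis=2)
    xs2 = np.ascontiguousarray(xs.transpose(0, 2, 1, 3)).reshape(B, L - K + 1, C * K)
    out2 = xs2 @ w.reshape(F, C * K).T + b
    return out2.transpose(0, 2, 1), xs2


def _conv_backward(dout, xs2, w, need_dx):
    B, F, Lp = dout.shape
    C, K = w.shape[1], w.shape[2]
    dout2 = np.ascontiguousarray(dout.transpose(0, 2, 1))
    dw = np.tensordot(xs2, dout2, axes=([0, 1], [0, 1])).T.reshape(w.shape)
    db = dout.sum(axis=(0, 2))
    dx = None
    if need_dx:
        dpad = np.zeros((B, F, Lp + 2 * (K - 1)), dtype=dout.dtype)
        dpad[:, :, K - 1 : K - 1 + Lp] = dout
        ds = np.lib.stride_tricks.sliding_window_view(dpad, K, axis=2)
        ds2 = np.ascontiguousarray(ds.transpose(0, 2, 1, 3)).reshape(B, Lp + K - 1, F * K)
        wb = np.ascontiguousarray(w[:, :, ::-1].transpose(0, 2, 1)).reshape(F * K, C)
        dx = (ds2 @ wb).transpose(0, 2, 1)
    return dw, db, dx


def _pool_forward(a, pool):
    B, F, L = a.shape
    M = L // pool
    t = a[:, :, : M * pool].reshape(B, F, M, pool)
    arg = t.argmax(axis=3)
    out = np.take_along_axis(t, arg[..., None], axis=3)[..., 0]
    return out, (arg, L)


def _pool_backward(dout, arg, L, pool):
    B, F, M = dout.shape
    dx = np.zeros((B, F, L), dtype=dout.dtype)
    idx = (np.arange(M) * pool)[None, None, :] + arg
    np.put_along_axis(dx, idx, dout, axis=2)
    return dx


class TinyConvNet:
    """Conv blocks + global max pool + sigmoid head, trained with Adam/BCE."""

    def __init__(
        self,
        window: int = 200,
        channels: tuple[int, ...] = (8, 16, 16),
        kernel: int = 9,
        pool: int = 2,
        in_channels: int = 1,
        seed: int = 0,
    ):
        self.window = int(window)
        self.channels = tuple(int(c) for c in channels)
        self.kernel = int(kernel)
        self.pool = int(pool)
        self.in_channels = int(in_channels)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.conv_w: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        in_ch = self.in_channels
        for ch in self.channels:
            fan_in = in_ch * kernel
            self.conv_w.append(
                rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(ch, in_ch, kernel)).astype(_F32)
            )
            self.conv_b.append(np.zeros(ch, dtype=_F32))
            in_ch = ch
        self.dense_w = rng.normal(0.0, np.sqrt(2.0 / in_ch), size=in_ch).astype(_F32)
        self.dense_b = np.zeros((), dtype=_F32)
        # feature-map length of one input window (units seen by the head)
        L = self.window
        for _ in self.channels:
            L = (L - self.kernel + 1) // self.pool
        if L < 1:
            raise ValueError(f"window {window} too short for this architecture")
        self.window_units = L

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_params(self) -> int:
        n = sum(w.size + b.size for w, b in zip(self.conv_w, self.conv_b))
        return int(n + self.dense_w.size + 1)

    @property
    def arch(self) -> dict:
        return {
            "window": self.window,
            "channels": list(self.channels),
            "kernel": self.kernel,
            "pool": self.pool,
            "in_channels": self.in_channels,
        }

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (w, b) in enumerate(zip(self.conv_w, self.conv_b)):
            out[f"conv_w{i}"] = w
            out[f"conv_b{i}"] = b
        out["dense_w"] = self.dense_w
        out["dense_b"] = np.asarray(self.dense_b)
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i in range(len(self.conv_w)):
            self.conv_w[i] = np.asarray(weights[f"conv_w{i}"], dtype=_F32)
            self.conv_b[i] = np.asarray(weights[f"conv_b{i}"], dtype=_F32)
        self.dense_w = np.asarray(weights["dense_w"], dtype=_F32)
        self.dense_b = np.asarray(weights["dense_b"], dtype=_F32).reshape(())

    def weights_digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for key in sorted(self.get_weights()):
            h.update(np.ascontiguousarray(self.get_weights()[key]).tobytes())
        return h.hexdigest()

    # -- forward -----------------------------------------------------------

    def conv_features(self, x: np.ndarray) -> np.ndarray:
        """Feature map of a signal batch: (B,L) or (B,C,L) -> (B,F,M)."""
        a = np.asarray(x, dtype=_F32)
        if a.ndim == 2:
            a = a[:, None, :]
        for w, b in zip(self.conv_w, self.conv_b):
            a, _ = _conv_forward(a, w, b)
            np.maximum(a, 0.0, out=a)
            a, _ = _pool_forward(a, self.pool)
        return a

    def head(self, pooled: np.ndarray) -> np.ndarray:
        """Posterior from globally pooled features. pooled (B,F) -> (B,)."""
        return _sigmoid(pooled @ self.dense_w + self.dense_b)

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        X = np.asarray(X, dtype=_F32)
        out = np.empty(X.shape[0], dtype=_F32)
        for lo in range(0, X.shape[0], batch_size):
            feats = self.conv_features(X[lo : lo + batch_size])
            out[lo : lo + batch_size] = self.head(feats.max(axis=2))
        return out

    # -- training ----------------------------------------------------------

    def _forward_train(self, X):
        a = X[:, None, :] if X.ndim == 2 else X
        caches = []
        for w, b in zip(self.conv_w, self.conv_b):
            z, xs2 = _conv_forward(a, w, b)
            mask = z > 0
            r = z * mask
            p, (arg, L) = _pool_forward(r, self.pool)
            caches.append((xs2, mask, arg, L))
            a = p
        g_arg = a.argmax(axis=2)
        pooled = np.take_along_axis(a, g_arg[:, :, None], axis=2)[:, :, 0]
        logit = pooled @ self.dense_w + self.dense_b
        prob = _sigmoid(logit)
        return prob, (caches, a.shape, g_arg, pooled)

    def _backward(self, prob, y, cache):
        caches, a_shape, g_arg, pooled = cache
        B = y.size
        dlogit = (prob - y).astype(_F32) / B
        grads = {
            "dense_w": pooled.T @ dlogit,
            "dense_b": dlogit.sum(),
        }
        dpooled = dlogit[:, None] * self.dense_w[None, :]
        da = np.zeros(a_shape, dtype=_F32)
        np.put_along_axis(da, g_arg[:, :, None], dpooled[:, :, None], axis=2)
        for li in range(len(self.conv_w) - 1, -1, -1):
            xs2, mask, arg, L = caches[li]
            dr = _pool_backward(da, arg, L, self.pool)
            dz = dr * mask
            dw, db, dx = _conv_backward(dz, xs2, self.conv_w[li], need_dx=li > 0)
            grads[f"conv_w{li}"] = dw
            grads[f"conv_b{li}"] = db
            da = dx
        return grads

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 40,
        batch_size: int = 32,
        lr: float = 3e-3,
        seed: int = 0,
        loss_tol: float = 1e-3,
        noise_aug: float = 0.0,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> list[float]:
        """Minimize binary cross-entropy with Adam; returns per-epoch losses.

        ``noise_aug`` adds fresh Gaussian noise to every minibatch (cheap
        regularizer mirroring measurement noise).  When a validation set is
        given, the weights with the best validation loss are restored at
        the end.  Stops early once the epoch loss drops below ``loss_tol``;
        raises TrainingError on non-finite loss.
        """
        X = np.asarray(X, dtype=_F32)
        y = np.asarray(y, dtype=_F32)
        rng = np.random.default_rng(seed)
        params = self.get_weights()
        m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        v = {k: np.zeros_like(val, dtype=np.float64) for k, val in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        losses = []
        best_val = np.inf
        best_weights = None
        n = X.shape[0]
        for _epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, batch_size):
                idx = order[lo : lo + batch_size]
                xb = X[idx]
                if noise_aug > 0:
                    xb = xb + rng.normal(0.0, noise_aug, xb.shape).astype(_F32)
                prob, cache = self._forward_train(xb)
                p = np.clip(prob, 1e-7, 1.0 - 1e-7)
                yb = y[idx]
                loss = float(-(yb * np.log(p) + (1 - yb) * np.log(1 - p)).mean())
                if not np.isfinite(loss):
                    raise TrainingError("non-finite training loss")
                epoch_loss += loss * idx.size
                grads = self._backward(prob, yb, cache)
                step += 1
                bc1 = 1.0 - beta1 ** step
                bc2 = 1.0 - beta2 ** step
                for li in range(len(self.conv_w)):
                    for name, arr in ((f"conv_w{li}", self.conv_w[li]), (f"conv_b{li}", self.conv_b[li])):
                        g = grads[name]
                        m[name] = beta1 * m[name] + (1 - beta1) * g
                        v[name] = beta2 * v[name] + (1 - beta2) * g * g
                        arr -= (lr * (m[name] / bc1) / (np.sqrt(v[name] / bc2) + eps)).astype(_F32)
                for name in ("dense_w", "dense_b"):
                    g = grads[name]
                    m[name] = beta1 * m[name] + (1 - beta1) * g
                    v[name] = beta2 * v[name] + (1 - beta2) * g * g
                    upd = (lr * (m[name] / bc1) / (np.sqrt(v[name] / bc2) + eps))
                    if name == "dense_w":
                        self.dense_w = (self.dense_w - upd).astype(_F32)
                    else:
                        self.dense_b = np.asarray(self.dense_b - upd, dtype=_F32).reshape(())
            losses.append(epoch_loss / n)
            if X_val is not None:
                pv = np.clip(self.predict_proba(X_val), 1e-7, 1 - 1e-7)
                vl = float(-(y_val * np.log(pv) + (1 - y_val) * np.log(1 - pv)).mean())
                if vl < best_val:
                    best_val = vl
                    best_weights = {k: v.copy() for k, v in self.get_weights().items()}
            if losses[-1] < loss_tol:
                break
        if best_weights is not None:
            self.set_weights(best_weights)
        return losses
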