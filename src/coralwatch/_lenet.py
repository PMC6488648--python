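"""A small LeNet-style convolutional network in plain numpy.

Two conv+maxpool blocks followed by two dense layers and a softmax head — the
classic LeNet-5 layout adapted to 46x46x3 colour patches.  Convolutions are
evaluated as matrix products over im2col patches so all heavy lifting is BLAS;
training uses minibatch Adam on the softmax cross-entropy.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LeNet5"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H-k+1, W-k+1, C*k*k) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    n, oh, ow = win.shape[:3]
    return win.reshape(n, oh, ow, -1)


def _col2im(dcol: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    """Scatter-add the patch-matrix gradient back to image layout."""
    n, h, w, c = x_shape
    oh, ow = h - k + 1, w - k + 1
    dcol = dcol.reshape(n, oh, ow, c, k, k)
    dx = np.zeros(x_shape, dtype=dcol.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, i:i + oh, j:j + ow, :] += dcol[:, :, :, :, i, j]
    return dx


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None, :]
    return out, mask


def _maxpool2_back(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n, oh, _, ow, _, c = mask.shape
    d = mask * dout[:, :, None, :, None, :]
    # ties (rare with float activations) split the gradient
    counts = mask.sum(axis=(2, 4), keepdims=True)
    d = d / counts
    return d.reshape(n, oh * 2, ow * 2, c)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class LeNet5:
    """LeNet-5-layout patch classifier: conv6@5 -> pool -> conv16@5 -> pool
    -> fc120 -> fc84 -> softmax."""

    def __init__(self, input_size: int = 46, in_channels: int = 3,
                 n_classes: int = 3, seed: int = 0,
                 in_scale: float = 1.0, in_offset: float = 0.0):
        self.input_size = input_size
        self.in_channels = in_channels
        self.n_classes = n_classes
        # input normalisation applied per batch (keeps uint8 patch stores
        # compact; conversion to float happens just-in-time)
        self.in_scale = float(in_scale)
        self.in_offset = float(in_offset)
        rng = np.random.default_rng(seed)
        s1 = input_size - 4            # after conv1 (5x5)
        p1 = s1 // 2                   # after pool
        s2 = p1 - 4                    # after conv2
        self._crop = s2 % 2            # crop one row/col if odd before pooling
        p2 = (s2 - self._crop) // 2
        self._flat = p2 * p2 * 16

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params = {
            "W1": he((in_channels * 25, 6), in_channels * 25),
            "b1": np.zeros(6, np.float32),
            "W2": he((6 * 25, 16), 6 * 25),
            "b2": np.zeros(16, np.float32),
            "W3": he((self._flat, 120), self._flat),
            "b3": np.zeros(120, np.float32),
            "W4": he((120, 84), 120),
            "b4": np.zeros(84, np.float32),
            "W5": he((84, n_classes), 84),
            "b5": np.zeros(n_classes, np.float32),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ---------------------------------------------------------------- forward

    def _forward(self, x: np.ndarray, want_cache: bool = False):
        p = self.params
        col1 = _im2col(x, 5)
        a1 = np.maximum(col1 @ p["W1"] + p["b1"], 0)
        h1, m1 = _maxpool2(a1)
        col2 = _im2col(h1, 5)
        a2 = np.maximum(col2 @ p["W2"] + p["b2"], 0)
        if self._crop:
            a2c = a2[:, :-1, :-1, :]
        else:
            a2c = a2
        h2, m2 = _maxpool2(a2c)
        flat = h2.reshape(len(x), -1)
        a3 = np.maximum(flat @ p["W3"] + p["b3"], 0)
        a4 = np.maximum(a3 @ p["W4"] + p["b4"], 0)
        logits = a4 @ p["W5"] + p["b5"]
        if not want_cache:
            return logits
        return logits, (x, col1, a1, m1, h1, col2, a2, m2, h2, flat, a3, a4)

    def _prep(self, x: np.ndarray) -> np.ndarray:
        return x.astype(np.float32) * self.in_scale + self.in_offset

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """Class probabilities for a stack of (N, S, S, C) patches."""
        out = np.empty((len(x), self.n_classes), dtype=np.float32)
        for i in range(0, len(x), batch):
            out[i:i + batch] = _softmax(self._forward(self._prep(x[i:i + batch])))
        return out

    # --------------------------------------------------------------- backward

    def _backward(self, cache, probs: np.ndarray, y: np.ndarray) -> dict:
        p = self.params
        x, col1, a1, m1, h1, col2, a2, m2, h2, flat, a3, a4 = cache
        n = len(x)
        dz = probs.copy()
        dz[np.arange(n), y] -= 1.0
        dz /= n
        g = {}
        g["W5"] = a4.T @ dz
        g["b5"] = dz.sum(0)
        da4 = (dz @ p["W5"].T) * (a4 > 0)
        g["W4"] = a3.T @ da4
        g["b4"] = da4.sum(0)
        da3 = (da4 @ p["W4"].T) * (a3 > 0)
        g["W3"] = flat.T @ da3
        g["b3"] = da3.sum(0)
        dflat = da3 @ p["W3"].T
        dh2 = dflat.reshape(h2.shape)
        da2c = _maxpool2_back(dh2, m2)
        if self._crop:
            da2 = np.zeros_like(a2)
            da2[:, :-1, :-1, :] = da2c
        else:
            da2 = da2c
        da2 *= a2 > 0
        d2 = da2.reshape(-1, 16)
        g["W2"] = col2.reshape(-1, col2.shape[-1]).T @ d2
        g["b2"] = d2.sum(0)
        dcol2 = da2 @ p["W2"].T
        dh1 = _col2im(dcol2, h1.shape, 5)
        da1 = _maxpool2_back(dh1, m1)
        da1 *= a1 > 0
        d1 = da1.reshape(-1, 6)
        g["W1"] = col1.reshape(-1, col1.shape[-1]).T @ d1
        g["b1"] = d1.sum(0)
        return g

    def _adam_step(self, grads: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, gk in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk ** 2
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

    # --------------------------------------------------------------- training

    def fit(self, x: np.ndarray, y: np.ndarray, x_val=None, y_val=None,
            epochs: int = 4, lr: float = 1e-3, batch_size: int = 128,
            seed: int = 0, verbose: bool = False) -> list[dict]:
        """Minibatch Adam on softmax cross-entropy; returns per-epoch history."""
        rng = np.random.default_rng(seed)
        history = []
        for epoch in range(epochs):
            order = rng.permutation(len(x))
            losses = []
            for i in range(0, len(x), batch_size):
                idx = order[i:i + batch_size]
                xb = self._prep(x[idx])
                yb = y[idx]
                logits, cache = self._forward(xb, want_cache=True)
                probs = _softmax(logits)
                losses.append(float(-np.log(
                    np.maximum(probs[np.arange(len(yb)), yb], 1e-12)).mean()))
                self._adam_step(self._backward(cache, probs, yb), lr)
            rec = {"epoch": epoch, "loss": float(np.mean(losses))}
            if x_val is not None and len(x_val):
                rec["val_accuracy"] = self.accuracy(x_val, y_val)
            history.append(rec)
            if verbose:
                print(rec)
        return history

    def accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        pred = np.argmax(self.predict_proba(x), axis=1)
        return float(np.mean(pred == y))

    # ------------------------------------------------------------- checkpoint

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)
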