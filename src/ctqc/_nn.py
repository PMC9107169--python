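"""A compact convolutional network implemented on numpy.

This is the desk-scale reference classifier used by the per-plane training
harness: three 3×3 convolution blocks (ReLU + 2×2 max pooling), global
average pooling, and a dense softmax head, trained with Adam on
cross-entropy. Convolutions use im2col so that forward and backward passes
reduce to matrix products. Everything is seeded and single-pass
deterministic: the same data, configuration and seed reproduce identical
weights and predictions.

The implementation favours clarity over throughput; at the 64×64 inputs the
pipeline defaults to, full training runs take seconds to minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallCNN"]


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    """(B, C, H, W) → (B, H·W, C·k·k) patch matrix for same-size convolution."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # B,C,H,W,k,k
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b, h * w, c * k * k)


def _col2im(dcol: np.ndarray, x_shape: tuple, k: int = 3, pad: int = 1) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back onto the image."""
    b, c, h, w = x_shape
    dcol = dcol.reshape(b, h, w, c, k, k)
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, pad:pad + h, pad:pad + w]


class SmallCNN:
    """Conv(3×3)+ReLU+MaxPool blocks → global average pool → softmax.

    Parameters
    ----------
    input_size : int
        Side length of the square single-channel input. Must be divisible by
        ``2 ** len(channels)`` so the pooling stages tile evenly.
    n_classes : int
        Output dimension of the softmax head.
    channels : tuple of int
        Filter counts of the successive conv blocks.
    seed : int
        Seed for He-uniform weight initialization and batch shuffling.
    """

    def __init__(
        self,
        input_size: int,
        n_classes: int,
        channels: tuple[int, ...] = (8, 16, 32),
        seed: int = 0,
    ) -> None:
        if input_size % (2 ** len(channels)) != 0:
            raise ValueError(
                f"input_size {input_size} not divisible by 2^{len(channels)}"
            )
        self.input_size = int(input_size)
        self.n_classes = int(n_classes)
        self.channels = tuple(int(c) for c in channels)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, c_out in enumerate(self.channels):
            fan_in = c_in * 9
            bound = np.sqrt(6.0 / fan_in)
            self.params[f"W{i}"] = rng.uniform(
                -bound, bound, size=(c_out, c_in * 9)
            ).astype(np.float32)
            self.params[f"b{i}"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        bound = np.sqrt(6.0 / c_in)
        self.params["Wfc"] = rng.uniform(
            -bound, bound, size=(c_in, n_classes)
        ).astype(np.float32)
        self.params["bfc"] = np.zeros(n_classes, dtype=np.float32)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ---------------------------------------------------------------- forward

    def _forward(self, x: np.ndarray, keep_cache: bool = False):
        """x: (B, S, S) in [0,1] → probabilities (B, n_classes)."""
        cache: list[dict] = []
        h = x.astype(np.float32)[:, None, :, :]  # B,1,S,S
        for i in range(len(self.channels)):
            col = _im2col(h)
            z = col @ self.params[f"W{i}"].T + self.params[f"b{i}"]
            b, hw, c_out = z.shape
            side = int(np.sqrt(hw))
            z = z.transpose(0, 2, 1).reshape(b, c_out, side, side)
            relu_mask = z > 0
            a = z * relu_mask
            # 2×2 max pool, stride 2; argmax picks the first maximum (deterministic)
            h2, w2 = side // 2, side // 2
            a4 = a.reshape(b, c_out, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
            a4 = a4.reshape(b, c_out, h2, w2, 4)
            idx = a4.argmax(axis=-1)
            pooled = np.take_along_axis(a4, idx[..., None], axis=-1)[..., 0]
            if keep_cache:
                cache.append({
                    "col": col, "x_shape": h.shape, "relu_mask": relu_mask,
                    "pool_idx": idx, "pre_pool_side": side,
                })
            h = pooled
        feat = h.mean(axis=(2, 3))  # global average pool → (B, C)
        logits = feat @ self.params["Wfc"] + self.params["bfc"]
        logits = logits - logits.max(axis=1, keepdims=True)
        ex = np.exp(logits)
        probs = ex / ex.sum(axis=1, keepdims=True)
        if keep_cache:
            return probs, feat, h.shape, cache
        return probs

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch (B, S, S) or single image (S, S)."""
        single = x.ndim == 2
        if single:
            x = x[None]
        probs = self._forward(x)
        return probs[0] if single else probs

    # --------------------------------------------------------------- backward

    def _backward(self, x, y_onehot):
        probs, feat, pooled_shape, cache = self._forward(x, keep_cache=True)
        b = x.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = (probs - y_onehot).astype(np.float32) / b
        grads["Wfc"] = feat.T @ dlogits
        grads["bfc"] = dlogits.sum(axis=0)
        dfeat = dlogits @ self.params["Wfc"].T
        _, c, hp, wp = pooled_shape
        dh = np.broadcast_to(
            dfeat[:, :, None, None] / (hp * wp), pooled_shape
        ).astype(np.float32)
        for i in reversed(range(len(self.channels))):
            ca = cache[i]
            bb, cc, h2, w2 = dh.shape
            da4 = np.zeros((bb, cc, h2, w2, 4), dtype=np.float32)
            np.put_along_axis(da4, ca["pool_idx"][..., None], dh[..., None], axis=-1)
            side = ca["pre_pool_side"]
            da = da4.reshape(bb, cc, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            da = da.reshape(bb, cc, side, side)
            dz = da * ca["relu_mask"]
            dz2 = dz.reshape(bb, cc, side * side).transpose(0, 2, 1)  # B,HW,Cout
            grads[f"W{i}"] = np.einsum("bpo,bpi->oi", dz2, ca["col"], optimize=True)
            grads[f"b{i}"] = dz2.sum(axis=(0, 1))
            if i > 0:
                dcol = dz2 @ self.params[f"W{i}"]
                dh = _col2im(dcol, ca["x_shape"])
        loss = -np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1))
        acc = float((probs.argmax(axis=1) == y_onehot.argmax(axis=1)).mean())
        return grads, float(loss), acc

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

    # ------------------------------------------------------------------- fit

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 30,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        early_stop: bool = True,
        log=None,
    ) -> list[dict]:
        """Train on (N, S, S) images and integer labels (N,).

        Stops early once training accuracy has held at 100% with low loss
        for two consecutive epochs. Returns the per-epoch history.
        """
        n = x.shape[0]
        y_onehot = np.zeros((n, self.n_classes), dtype=np.float32)
        y_onehot[np.arange(n), y] = 1.0
        rng = np.random.default_rng(self.seed + 1)
        history = []
        perfect_streak = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses, accs = [], []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                grads, loss, acc = self._backward(x[idx], y_onehot[idx])
                self._adam_step(grads, learning_rate)
                losses.append(loss)
                accs.append(acc * len(idx))
            epoch_loss = float(np.mean(losses))
            epoch_acc = float(np.sum(accs) / n)
            history.append({"epoch": epoch, "loss": epoch_loss, "accuracy": epoch_acc})
            if log is not None:
                log(f"epoch {epoch + 1}/{epochs} loss {epoch_loss:.4f} acc {epoch_acc:.3f}")
            if early_stop:
                perfect_streak = perfect_streak + 1 if (
                    epoch_acc == 1.0 and epoch_loss < 0.05
                ) else 0
                if perfect_streak >= 2:
                    break
        return history

    # --------------------------------------------------------- serialization

    def state_dict(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)
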