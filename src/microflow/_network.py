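"""Spatio-temporal 3D convolutional network: numpy forward/backward engine.

Architecture (fixed up to sizes): conv(8 filters, 7x7x7, valid, stride 1,
ReLU) -> conv(8 filters, 5x5x5, valid, stride 1, ReLU, dense channel
mixing) -> max-pool 2x2x2 (stride 2, floor) -> flatten -> dense(hidden,
ReLU) -> dense(2) -> soft-max. On the canonical 16x16x200 input block the
flattened vector has length 6840.

Convolutions (forward, weight gradients and the transposed-convolution
input gradient) are evaluated in the frequency domain: real FFTs of the
activations and kernels, channel mixing as a complex contraction, one
inverse transform per output channel. On valid-correlation index ranges
the circular transform introduces no wrap-around, so this is exact linear
(cross-)correlation up to float rounding; it is an order of magnitude
faster than im2col at these grid sizes. The optimizer is Adadelta
(per-parameter accumulators of squared gradients and squared updates;
rho 0.95, eps 1e-6, no learning-rate tuning), matching the adaptive-rate
training procedure the method prescribes.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

K1 = (7, 7, 7)
K2 = (5, 5, 5)
POOL = 2
N_FILTERS = 8
MICRO_BATCH = 8  # vectorization granularity (memory/GEMM trade-off)

_AXES = (-3, -2, -1)


def conv_out_shape(in_shape: tuple[int, int, int], kernel: tuple[int, int, int]) -> tuple:
    out = tuple(i - k + 1 for i, k in zip(in_shape, kernel))
    if any(o < 1 for o in out):
        raise ValueError(f"kernel {kernel} larger than input {in_shape}")
    return out


def pool_out_shape(in_shape: tuple[int, int, int]) -> tuple:
    return tuple(i // POOL for i in in_shape)


def flat_length(input_shape: tuple[int, int, int]) -> int:
    s1 = conv_out_shape(input_shape, K1)
    s2 = conv_out_shape(s1, K2)
    sp = pool_out_shape(s2)
    return int(np.prod(sp)) * N_FILTERS


def _rfft(x: np.ndarray, grid: tuple[int, int, int]) -> np.ndarray:
    return sfft.rfftn(x, s=grid, axes=_AXES)


def _irfft_crop(fx: np.ndarray, grid: tuple[int, int, int], out: tuple[int, int, int]) -> np.ndarray:
    full = sfft.irfftn(fx, s=grid, axes=_AXES)
    return full[..., : out[0], : out[1], : out[2]]


def _mix(fa: np.ndarray, fb: np.ndarray, spec: str) -> np.ndarray:
    """Complex channel contraction in the frequency domain."""
    return np.einsum(spec, fa, fb, optimize=True)


class Adadelta:
    """Zeiler's Adadelta: adaptive per-parameter steps, no learning rate."""

    def __init__(self, params: dict[str, np.ndarray], rho: float = 0.95, eps: float = 1e-6):
        self.rho, self.eps = rho, eps
        self.eg2 = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.ex2 = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            g = g.astype(np.float64)
            self.eg2[k] = self.rho * self.eg2[k] + (1 - self.rho) * g * g
            dx = -np.sqrt(self.ex2[k] + self.eps) / np.sqrt(self.eg2[k] + self.eps) * g
            self.ex2[k] = self.rho * self.ex2[k] + (1 - self.rho) * dx * dx
            params[k] += dx.astype(params[k].dtype)


class ConvNet3D:
    """The two-conv 3D network on blocks of a fixed input shape."""

    def __init__(self, input_shape: tuple[int, int, int], hidden: int = 128, seed: int = 0):
        self.input_shape = tuple(int(v) for v in input_shape)
        self.hidden = hidden
        self.s1 = conv_out_shape(self.input_shape, K1)
        self.s2 = conv_out_shape(self.s1, K2)
        self.sp = pool_out_shape(self.s2)
        self.flat = int(np.prod(self.sp)) * N_FILTERS
        rng = np.random.default_rng(seed)
        f = N_FILTERS

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params = {
            "W1": he((f, 1) + K1, int(np.prod(K1))),
            "b1": np.zeros(f, dtype=np.float32),
            "W2": he((f, f) + K2, f * int(np.prod(K2))),
            "b2": np.zeros(f, dtype=np.float32),
            "W3": he((self.flat, hidden), self.flat),
            "b3": np.zeros(hidden, dtype=np.float32),
            "W4": he((hidden, 2), hidden),
            "b4": np.zeros(2, dtype=np.float32),
        }

    # ---- forward -----------------------------------------------------

    def _forward(self, x: np.ndarray, keep_cache: bool):
        """x: (N, H, W, T) in [0, 1]. Returns soft-max probabilities (+ cache)."""
        p = self.params
        n = x.shape[0]
        g0, g1 = self.input_shape, self.s1
        x = x - np.float32(0.5)  # center the unit-normalized block at zero

        # conv1: valid cross-correlation of x with W1 (single input channel)
        fx = _rfft(x[:, None], g0)  # (n, 1, F0)
        fw1 = _rfft(p["W1"], g0)  # (8, 1, F0)
        z1 = _irfft_crop(_mix(fx, fw1.conj(), "nif...,oif...->nof..."), g0, g1)
        z1 += p["b1"][None, :, None, None, None]
        a1 = np.maximum(z1, 0)  # (n, 8, s1)

        # conv2: dense channel mixing
        fa1 = _rfft(a1, g1)  # (n, 8, F1)
        fw2 = _rfft(p["W2"], g1)  # (8, 8, F1)
        z2 = _irfft_crop(_mix(fa1, fw2.conj(), "nif...,oif...->nof..."), g1, self.s2)
        z2 += p["b2"][None, :, None, None, None]
        a2 = np.maximum(z2, 0)  # (n, 8, s2)

        hp, wp, tp = self.sp
        crop = a2[:, :, : hp * POOL, : wp * POOL, : tp * POOL]
        win = crop.reshape(n, N_FILTERS, hp, POOL, wp, POOL, tp, POOL)
        win = win.transpose(0, 2, 4, 6, 1, 3, 5, 7).reshape(n, hp, wp, tp, N_FILTERS, -1)
        amax = win.argmax(axis=-1)
        pooled = np.take_along_axis(win, amax[..., None], axis=-1)[..., 0]

        flat = pooled.reshape(n, self.flat)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0)
        logits = a3 @ p["W4"] + p["b4"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        prob = e / e.sum(axis=1, keepdims=True)
        cache = (fx, a1, fa1, a2, amax, flat, a3) if keep_cache else None
        return prob, cache

    def predict_proba(self, blocks: np.ndarray) -> np.ndarray:
        """Soft-max probabilities, shape (N, 2); column 1 is the flow class."""
        blocks = np.asarray(blocks, dtype=np.float32)
        out = np.empty((blocks.shape[0], 2), dtype=np.float64)
        for i in range(0, blocks.shape[0], MICRO_BATCH):
            prob, _ = self._forward(blocks[i : i + MICRO_BATCH], keep_cache=False)
            out[i : i + MICRO_BATCH] = prob
        return out

    # ---- backward ----------------------------------------------------

    def _backward(self, cache, prob: np.ndarray, y: np.ndarray, scale: float):
        """Gradients of (scale * mean-over-micro-batch) cross-entropy."""
        p = self.params
        fx, a1, fa1, a2, amax, flat, a3 = cache
        n = prob.shape[0]
        g0, g1 = self.input_shape, self.s1
        dlogits = prob.astype(np.float32).copy()
        dlogits[np.arange(n), y] -= 1
        dlogits *= scale / n

        g = {}
        g["W4"] = a3.T @ dlogits
        g["b4"] = dlogits.sum(axis=0)
        da3 = dlogits @ p["W4"].T
        dz3 = da3 * (a3 > 0)
        g["W3"] = flat.T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T

        hp, wp, tp = self.sp
        dpooled = dflat.reshape(n, hp, wp, tp, N_FILTERS)
        dwin = np.zeros((n, hp, wp, tp, N_FILTERS, POOL**3), dtype=np.float32)
        np.put_along_axis(dwin, amax[..., None], dpooled[..., None], axis=-1)
        dwin = dwin.reshape(n, hp, wp, tp, N_FILTERS, POOL, POOL, POOL)
        dcrop = dwin.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(
            n, N_FILTERS, hp * POOL, wp * POOL, tp * POOL
        )
        da2 = np.zeros((n, N_FILTERS) + self.s2, dtype=np.float32)
        da2[:, :, : hp * POOL, : wp * POOL, : tp * POOL] = dcrop
        dz2 = da2 * (a2 > 0)

        fdz2 = _rfft(dz2, g1)  # zero-padded to the conv1-output grid
        # dW2[o,i] = sum_n corr(a1[n,i], dz2[n,o]); valid lags 0..K2-1
        g["W2"] = _irfft_crop(
            _mix(fa1, fdz2.conj(), "nif...,nof...->oif..."), g1, K2
        ).astype(np.float32)
        g["b2"] = dz2.sum(axis=(0, 2, 3, 4))
        # da1 = full convolution of dz2 with W2, summed over output channels
        fw2 = _rfft(p["W2"], g1)
        da1 = _irfft_crop(_mix(fdz2, fw2, "nof...,oif...->nif..."), g1, g1)
        dz1 = (da1 * (a1 > 0)).astype(np.float32)

        fdz1 = _rfft(dz1, g0)
        g["W1"] = _irfft_crop(
            _mix(fx, fdz1.conj(), "nif...,nof...->oif..."), g0, K1
        ).astype(np.float32)
        g["b1"] = dz1.sum(axis=(0, 2, 3, 4))
        return g

    def loss_and_grads(self, blocks: np.ndarray, y: np.ndarray):
        """Mean categorical cross-entropy over the batch, and its gradients."""
        blocks = np.asarray(blocks, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        n = blocks.shape[0]
        total_loss = 0.0
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        for i in range(0, n, MICRO_BATCH):
            xb, yb = blocks[i : i + MICRO_BATCH], y[i : i + MICRO_BATCH]
            prob, cache = self._forward(xb, keep_cache=True)
            eps = 1e-12
            total_loss += -np.log(prob[np.arange(len(yb)), yb] + eps).sum()
            gb = self._backward(cache, prob, yb, scale=len(yb) / n)
            for k in grads:
                grads[k] += gb[k]
        return total_loss / n, grads
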