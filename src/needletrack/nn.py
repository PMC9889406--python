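"""Minimal CNN engine: 3x3 convolutions, ReLU, residual blocks, Adam.

Implemented directly on numpy.  Convolutions use a flat-offset scheme
in channels-last layout: the zero-padded image is viewed as a flat
sequence of pixels, and each of the nine kernel taps becomes one BLAS
matrix product of a shifted contiguous slice with a [c_in x c_out]
weight matrix.  This keeps all heavy work in contiguous GEMMs with no
im2col gather.  The networks used here are small and fully
convolutional, and a pure-numpy engine makes training bit-reproducible
for a given seed.  Activations are [N, H, W, C] float32; the canonical
weight layout is [c_out, c_in, 3, 3].
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["ResidualCNN", "Adam", "l1_loss"]


def _pad_flat(x: np.ndarray) -> np.ndarray:
    """[N,H,W,C] -> zero-padded flat buffer [N, (H+2)*(W+2)+2, C].

    The two trailing zeros let every kernel-tap slice ``off:off+L``
    with ``off <= 2*(W+2)+2`` stay in bounds.
    """
    n, h, w, c = x.shape
    buf = np.zeros((n, (h + 2) * (w + 2) + 2, c), dtype=np.float32)
    buf[:, : (h + 2) * (w + 2)].reshape(n, h + 2, w + 2, c)[:, 1 : h + 1, 1 : w + 1] = x
    return buf


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Same-size 3x3 convolution. x: [N,H,W,c_in], W: [c_out,c_in,3,3]."""
    n, h, w, _ = x.shape
    c_out = W.shape[0]
    xf = _pad_flat(x)
    Wk = np.ascontiguousarray(W.transpose(2, 3, 1, 0)).reshape(9, W.shape[1], c_out)
    L = h * (w + 2)
    acc = np.zeros((n, L, c_out), dtype=np.float32)
    for k in range(9):
        di, dj = divmod(k, 3)
        off = di * (w + 2) + dj
        acc += xf[:, off : off + L] @ Wk[k]
    y = acc.reshape(n, h, w + 2, c_out)[:, :, :w]
    return y + b if b is not None else np.ascontiguousarray(y)


def _conv_backward(
    dy: np.ndarray, x: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a same-size 3x3 convolution (channels-last).

    Returns (dx, dW, db).  dx is a convolution of dy with the
    channel-transposed, spatially flipped kernels; dW pairs each
    kernel-tap slice of the padded input with the output gradient.
    """
    n, h, w, c_out = dy.shape
    W_t = np.ascontiguousarray(W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx = _conv_forward(dy, W_t, None)

    xf = _pad_flat(x)
    L = h * (w + 2)
    dyq = np.zeros((n, h, w + 2, c_out), dtype=np.float32)
    dyq[:, :, :w] = dy
    dyq = dyq.reshape(n, L, c_out)
    dWk = np.empty((9, W.shape[1], c_out), dtype=np.float32)
    for k in range(9):
        di, dj = divmod(k, 3)
        off = di * (w + 2) + dj
        dWk[k] = np.matmul(xf[:, off : off + L].transpose(0, 2, 1), dyq).sum(axis=0)
    dW = dWk.reshape(3, 3, W.shape[1], c_out).transpose(3, 2, 0, 1)
    db = dy.sum(axis=(0, 1, 2))
    return dx, np.ascontiguousarray(dW), db


@dataclass
class _Arch:
    n_blocks: int
    channels: int
    conv_kernel: int = 3


class ResidualCNN:
    """Residual image-to-image network.

    Architecture: a lifting 3x3 convolution (1 -> ``channels``), then
    ``n_blocks`` residual blocks, each ``conv -> ReLU -> conv`` with an
    additive skip around the block, then a projection 3x3 convolution
    (``channels`` -> 1), an additive skip from the network input, and a
    clamp of the output to [0, 1] so predictions stay in the
    normalized-image solution space.  Fully convolutional: any input of
    shape [H x W] maps to [H x W].
    """

    def __init__(self, n_blocks: int, channels: int, conv_kernel: int = 3, seed: int = 0):
        if n_blocks < 1 or channels < 1 or conv_kernel < 1:
            raise ValueError("n_blocks, channels and conv_kernel must be >= 1")
        if conv_kernel != 3:
            raise ValueError("only 3x3 convolution kernels are supported")
        self.arch = _Arch(n_blocks=n_blocks, channels=channels, conv_kernel=conv_kernel)
        rng = np.random.default_rng(seed)
        self.params: list[np.ndarray] = []  # W, b, W, b, ... in layer order
        self._add_conv(rng, 1, channels)
        for _ in range(n_blocks):
            self._add_conv(rng, channels, channels)
            self._add_conv(rng, channels, channels)
        self._add_conv(rng, channels, 1)

    def _add_conv(self, rng: np.random.Generator, c_in: int, c_out: int) -> None:
        k = self.arch.conv_kernel
        std = np.sqrt(2.0 / (c_in * k * k))  # fan-in (He) scaling
        self.params.append(rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(np.float32))
        self.params.append(np.zeros(c_out, dtype=np.float32))

    # ------------------------------------------------------------------
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_params(self, params: list[np.ndarray]) -> None:
        if len(params) != len(self.params):
            raise ValueError("parameter list length mismatch")
        self.params = [np.asarray(p, dtype=np.float32) for p in params]

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: [N, H, W] in [0, 1]; returns the enhanced [N, H, W] output
        (and, optionally, the activation cache for backprop)."""
        if x.ndim != 3:
            raise ValueError("expected input of shape [N, H, W]")
        x = np.ascontiguousarray(x, dtype=np.float32)[..., None]  # NHWC, C=1
        cache: dict = {"blocks": []}

        i = iter(range(0, len(self.params), 2))
        li = next(i)
        h = _conv_forward(x, self.params[li], self.params[li + 1])
        cache["lift_in"] = x
        for _ in range(self.arch.n_blocks):
            l1 = next(i)
            l2 = next(i)
            a = _conv_forward(h, self.params[l1], self.params[l1 + 1])
            r = np.maximum(a, 0.0)
            s = _conv_forward(r, self.params[l2], self.params[l2 + 1])
            if want_cache:
                cache["blocks"].append((h, a, r))
            h = h + s
        lp = next(i)
        pre = _conv_forward(h, self.params[lp], self.params[lp + 1]) + x
        y = np.clip(pre, 0.0, 1.0)
        if want_cache:
            cache["h_last"] = h
            cache["pre"] = pre
            return y[..., 0], cache
        return y[..., 0]

    def backward(self, dy: np.ndarray, cache: dict) -> list[np.ndarray]:
        """Gradients w.r.t. all parameters, same ordering as ``params``.
        ``dy`` is the loss gradient w.r.t. the clamped output [N, H, W]."""
        dy = dy.astype(np.float32)[..., None]
        # straight-through gradient for the [0,1] clamp: a hard clamp
        # mask permanently silences pixels once the pre-activation
        # leaves [0,1] (the L1 background term drives it there), which
        # collapses training to an all-zero output.
        dpre = dy

        grads = [np.zeros_like(p) for p in self.params]
        lp = len(self.params) - 2
        dh, dWp, dbp = _conv_backward(dpre, cache["h_last"], self.params[lp])
        grads[lp] = dWp
        grads[lp + 1] = dbp

        for bi in range(self.arch.n_blocks - 1, -1, -1):
            l1 = 2 + 4 * bi
            l2 = l1 + 2
            h, a, r = cache["blocks"][bi]
            # h_out = h + conv2(relu(conv1(h)))
            dr, dW2, db2 = _conv_backward(dh, r, self.params[l2])
            da = dr * (a > 0.0)
            dh_inner, dW1, db1 = _conv_backward(da, h, self.params[l1])
            grads[l1], grads[l1 + 1] = dW1, db1
            grads[l2], grads[l2 + 1] = dW2, db2
            dh = dh + dh_inner

        _, dWl, dbl = _conv_backward(dh, cache["lift_in"], self.params[0])
        grads[0], grads[1] = dWl, dbl
        return grads

    # ------------------------------------------------------------------
    def save(self, weights_path, arch_path=None) -> None:
        """Persist weights as .npz plus an architecture JSON sidecar."""
        np.savez(weights_path, **{f"p{i:03d}": p for i, p in enumerate(self.params)})
        if arch_path is not None:
            with open(arch_path, "w") as fh:
                json.dump(vars(self.arch), fh, indent=2)

    @classmethod
    def load(cls, weights_path, arch: dict | None = None, arch_path=None) -> "ResidualCNN":
        if arch is None:
            if arch_path is None:
                raise ValueError("provide either arch or arch_path")
            with open(arch_path) as fh:
                arch = json.load(fh)
        model = cls(**arch)
        with np.load(weights_path) as data:
            model.set_params([data[k] for k in sorted(data.files)])
        return model


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. ``pred``."""
    diff = pred.astype(np.float32) - target.astype(np.float32)
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff, dtype=np.float32) / diff.size
    return loss, grad


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
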