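"""Compact seeded conv-net engine on numpy (NHWC, float32).

Provides exactly the layers the segmentation network needs — 2-D
convolution via im2col, non-overlapping stride-2 transposed convolution,
ReLU, channel concatenation for inception-style parallel branches — with
explicit forward/backward passes and an Adam optimiser. Everything is
deterministic given the initialisation seed; there is no global RNG state
and no threading nondeterminism.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """(N,H,W,C) -> (N,OH,OW,k,k,C) patch view (copied), plus padded shape."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, Hp-k+1, Wp-k+1, C, k, k)
    cols = win[:, ::stride, ::stride].transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(cols), xp.shape


def _col2im(
    dcols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int
) -> np.ndarray:
    """Scatter-add patch gradients back to the input tensor."""
    n, h, w, c = x_shape
    _, oh, ow = dcols.shape[:3]
    dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :] += dcols[
                :, :, :, i, j, :
            ]
    return dxp[:, pad : pad + h, pad : pad + w, :]


class Layer:
    """Base: parameters/grads are parallel dicts of float32 arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv2d(Layer):
    """Same-padded 2-D convolution, stride 1 or 2, He-initialised."""

    def __init__(
        self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1, rng: np.random.Generator | None = None
    ) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = k // 2
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (k * k * in_ch))
        self.params["W"] = rng.normal(0, scale, (k * k * in_ch, out_ch)).astype(np.float32)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, _ = _im2col(x, self.k, self.stride, self.pad)
        self._cols_shape = cols.shape
        self._cols2d = cols.reshape(-1, self.k * self.k * self.in_ch)
        self._x_shape = x.shape
        n, oh, ow = cols.shape[:3]
        y = self._cols2d @ self.params["W"] + self.params["b"]
        return y.reshape(n, oh, ow, self.out_ch)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy2d = dy.reshape(-1, self.out_ch)
        self.grads["W"] = (self._cols2d.T @ dy2d).astype(np.float32)
        self.grads["b"] = dy2d.sum(axis=0).astype(np.float32)
        dcols = (dy2d @ self.params["W"].T).reshape(self._cols_shape)
        return _col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Stride-2, kernel-2 transposed convolution (non-overlapping upsample)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_ch)
        self.params["W"] = rng.normal(0, scale, (in_ch, 2, 2, out_ch)).astype(np.float32)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, h, w, _ = x.shape
        y = np.empty((n, 2 * h, 2 * w, self.out_ch), dtype=x.dtype)
        for i in range(2):
            for j in range(2):
                y[:, i::2, j::2, :] = x @ self.params["W"][:, i, j, :]
        return y + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2d = self._x.reshape(-1, self.in_ch)
        dW = np.empty_like(self.params["W"])
        dx = np.zeros_like(self._x)
        for i in range(2):
            for j in range(2):
                dyij = dy[:, i::2, j::2, :].reshape(-1, self.out_ch)
                dW[:, i, j, :] = x2d.T @ dyij
                dx += (dyij @ self.params["W"][:, i, j, :].T).reshape(self._x.shape)
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 1, 2)).astype(np.float32)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class InceptionBlock(Layer):
    """Parallel 1x1 / 1x1-3x3 / 1x1-3x3-3x3 branches, channel-concatenated.

    A compact analogue of the mixed blocks in inception-style encoders; each
    branch preserves spatial size (stride 1, same padding).
    """

    def __init__(
        self, in_ch: int, b1: int, b2: int, b3: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.branches: list[list[Layer]] = [
            [Conv2d(in_ch, b1, k=1, rng=rng), ReLU()],
            [Conv2d(in_ch, b2, k=1, rng=rng), ReLU(), Conv2d(b2, b2, k=3, rng=rng), ReLU()],
            [
                Conv2d(in_ch, b3, k=1, rng=rng),
                ReLU(),
                Conv2d(b3, b3, k=3, rng=rng),
                ReLU(),
                Conv2d(b3, b3, k=3, rng=rng),
                ReLU(),
            ],
        ]
        self.out_ch = b1 + b2 + b3
        self._splits = (b1, b1 + b2)

    def _all_layers(self) -> list[Layer]:
        return [lay for br in self.branches for lay in br]

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = []
        for branch in self.branches:
            h = x
            for lay in branch:
                h = lay.forward(h)
            outs.append(h)
        return np.concatenate(outs, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        parts = np.split(dy, self._splits, axis=3)
        dx = None
        for branch, dpart in zip(self.branches, parts):
            g = dpart
            for lay in reversed(branch):
                g = lay.backward(g)
            dx = g if dx is None else dx + g
        return dx

    def n_params(self) -> int:
        return sum(lay.n_params() for lay in self._all_layers())

    def param_items(self):
        for bi, branch in enumerate(self.branches):
            for li, lay in enumerate(branch):
                for name, p in lay.params.items():
                    yield f"b{bi}.{li}.{name}", lay, name, p


class Sequential:
    """An ordered stack of layers with a shared backward pass."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def n_params(self) -> int:
        return sum(lay.n_params() for lay in self.layers)

    def param_items(self):
        """Yield (qualified_name, layer, param_name, array) for all params."""
        for i, lay in enumerate(self.layers):
            if isinstance(lay, InceptionBlock):
                for sub, sublay, name, p in lay.param_items():
                    yield f"{i}.{sub}", sublay, name, p
            else:
                for name, p in lay.params.items():
                    yield f"{i}.{name}", lay, name, p

    def state_dict(self) -> dict[str, np.ndarray]:
        return {qn: p for qn, _, _, p in self.param_items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for qn, lay, name, p in self.param_items():
            if qn not in state:
                raise KeyError(f"missing parameter '{qn}' in checkpoint")
            if state[qn].shape != p.shape:
                raise ValueError(
                    f"shape mismatch for '{qn}': checkpoint {state[qn].shape} vs model {p.shape}"
                )
            lay.params[name] = state[qn].astype(np.float32)


class Adam:
    """Adam optimiser over a Sequential's parameters."""

    def __init__(
        self,
        net: Sequential,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        for qn, _, _, p in net.param_items():
            self.m[qn] = np.zeros_like(p)
            self.v[qn] = np.zeros_like(p)

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for qn, lay, name, p in self.net.param_items():
            g = lay.grads[name]
            self.m[qn] = self.b1 * self.m[qn] + (1 - self.b1) * g
            self.v[qn] = self.b2 * self.v[qn] + (1 - self.b2) * g * g
            mhat = self.m[qn] / b1t
            vhat = self.v[qn] / b2t
            lay.params[name] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
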