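"""Minimal reverse-mode autodiff on numpy arrays for image-to-image networks.

Implements exactly the operations the residual-channel-attention UNet needs:
3x3/1x1 convolutions (via im2col and matmul), ReLU, sigmoid, elementwise
add/scale, global average pooling, dense layers, 2x max pooling, 2x nearest
upsampling, channel concatenation, and MSE/MAE losses, plus an Adam optimizer.
Tensors are NCHW float32.  The graph is taped per forward pass and freed after
``backward``; gradients are checked against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam",
           "conv2d", "relu", "sigmoid", "add", "scale_channels",
           "global_avg_pool", "dense", "maxpool2", "upsample2", "concat",
           "mse_loss", "mae_loss"]


# compute dtype; float32 for speed, switchable to float64 for gradient checking
DTYPE = np.float32


class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self._backward = None
        self._parents = parents
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            t._backward = None  # free the tape


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# convolution via im2col

def _im2col(x, k):
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix with same-padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


def conv2d(x: Tensor, weight: Parameter, bias: Parameter) -> Tensor:
    """Same-padding stride-1 convolution; weight (O, C, k, k), bias (O,)."""
    n, c, h, w = x.data.shape
    o, c2, k, _ = weight.data.shape
    assert c == c2, (c, c2)
    if k == 1:
        out_data = np.einsum("nchw,oc->nohw", x.data, weight.data[:, :, 0, 0],
                             optimize=True) + bias.data[None, :, None, None]
        cols = None
    else:
        cols = _im2col(x.data, k)
        out_data = (cols @ weight.data.reshape(o, -1).T).reshape(n, h, w, o)
        out_data = out_data.transpose(0, 3, 1, 2) + bias.data[None, :, None, None]
    out = Tensor(out_data, parents=(x, weight, bias))

    def _bw(g):
        g_flat = g.transpose(0, 2, 3, 1).reshape(-1, o)  # (NHW, O)
        bias._accum(g_flat.sum(axis=0))
        if k == 1:
            weight._accum(np.einsum("nohw,nchw->oc", g, x.data,
                                    optimize=True)[:, :, None, None])
            if x.requires_grad:
                x._accum(np.einsum("nohw,oc->nchw", g, weight.data[:, :, 0, 0],
                                   optimize=True))
        else:
            dw = (g_flat.T @ cols).reshape(o, c, k, k)
            weight._accum(dw)
            if x.requires_grad:
                # input grad = correlation of g with spatially flipped, channel-swapped kernel
                w_flip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                gcols = _im2col(g, k)
                dx = (gcols @ w_flip.reshape(c, -1).T).reshape(n, h, w, c)
                x._accum(dx.transpose(0, 3, 1, 2))

    out._backward = _bw
    return out


def dense(x: Tensor, weight: Parameter, bias: Parameter) -> Tensor:
    """x (N, F) @ weight (F, G) + bias (G,)."""
    out = Tensor(x.data @ weight.data + bias.data, parents=(x, weight, bias))

    def _bw(g):
        weight._accum(x.data.T @ g)
        bias._accum(g.sum(axis=0))
        if x.requires_grad:
            x._accum(g @ weight.data.T)

    out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))

    def _bw(g):
        if x.requires_grad:
            x._accum(g * mask)

    out._backward = _bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, parents=(x,))

    def _bw(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    out._backward = _bw
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(g)

    out._backward = _bw
    return out


def scale_channels(x: Tensor, gate: Tensor) -> Tensor:
    """Multiply feature maps (N,C,H,W) by per-channel gates (N,C)."""
    g4 = gate.data[:, :, None, None]
    out = Tensor(x.data * g4, parents=(x, gate))

    def _bw(g):
        if x.requires_grad:
            x._accum(g * g4)
        if gate.requires_grad:
            gate._accum((g * x.data).sum(axis=(2, 3)))

    out._backward = _bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    n, c, h, w = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3)), parents=(x,))

    def _bw(g):
        if x.requires_grad:
            x._accum(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    out._backward = _bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2 needs even spatial dims"
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = r.max(axis=(3, 5))
    # first-max tie rule for a deterministic gradient
    is_max = r == out_data[:, :, :, None, :, None]
    flat = is_max.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    first = (np.cumsum(flat, axis=-1) == 1) & flat
    mask = first.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    mask = np.ascontiguousarray(mask).reshape(n, c, h, w)
    out = Tensor(out_data, parents=(x,))

    def _bw(g):
        if x.requires_grad:
            gg = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3)
            x._accum(gg * mask)

    out._backward = _bw
    return out


def upsample2(x: Tensor) -> Tensor:
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), parents=(x,))

    def _bw(g):
        if x.requires_grad:
            n, c, h, w = g.shape
            x._accum(g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)))

    out._backward = _bw
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accum(g[:, :ca])
        if b.requires_grad:
            b._accum(g[:, ca:])

    out._backward = _bw
    return out


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - target
    out = Tensor(np.mean(diff ** 2), parents=(pred,))

    def _bw(g):
        if pred.requires_grad:
            pred._accum(g * 2.0 * diff / diff.size)

    out._backward = _bw
    return out


def mae_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - target
    out = Tensor(np.mean(np.abs(diff)), parents=(pred,))

    def _bw(g):
        if pred.requires_grad:
            pred._accum(g * np.sign(diff) / diff.size)

    out._backward = _bw
    return out


class Adam:
    """Adam with the usual bias correction; state kept per parameter."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
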