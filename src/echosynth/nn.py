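"""Compact CPU neural-network stack: reverse-mode autograd, U-Net, PatchGAN.

A small define-by-run autograd over numpy float32 arrays with exactly the
operations the pipeline's networks need -- strided convolution, instance
normalization, leaky ReLU / ReLU / tanh / sigmoid, nearest upsampling,
channel concatenation, and the LSGAN / L1 / cross-entropy losses -- plus an
Adam optimizer.  Convolutions run as matrix products over sliding windows,
which keeps training of the reduced-scale networks used in tests and desk
experiments in the minutes range on one core.

The ``UNet`` here serves both as the CycleGAN generator (tanh output) and as
the segmentation network (class-logit output), mirroring a pipeline that
reuses one architecture for both roles.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError

__all__ = ["Tensor", "UNet", "PatchDiscriminator", "Adam", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self.prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self.prev
        return False


class Tensor:
    """Node in the autograd graph; ``data`` is a float32 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = parents if _GRAD_ENABLED else ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValidationError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def _accum(t: Tensor, g: np.ndarray):
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, (a,))
    out._backward = lambda g: _accum(a, g * s)
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2D convolution, NCHW input, OCkk kernel."""
    N, C, H, W = x.data.shape
    O, _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    Ho, Wo = win.shape[2], win.shape[3]
    win2 = win.transpose(0, 2, 3, 1, 4, 5).reshape(N, Ho, Wo, C * kh * kw)
    wmat = w.data.reshape(O, -1)
    y = win2 @ wmat.T + b.data
    out = Tensor(np.ascontiguousarray(y.transpose(0, 3, 1, 2)), (x, w, b))

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (N,Ho,Wo,O)
        _accum(b, g2.reshape(-1, O).sum(axis=0))
        _accum(w, (g2.reshape(-1, O).T @ win2.reshape(-1, C * kh * kw)).reshape(w.data.shape))
        dwin2 = g2 @ wmat  # (N,Ho,Wo,CKK)
        dwin = dwin2.reshape(N, Ho, Wo, C, kh, kw)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += (
                    dwin[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        _accum(x, dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp)

    out._backward = bw
    return out


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    m = x.data > 0
    out = Tensor(np.where(m, x.data, alpha * x.data), (x,))
    out._backward = lambda g: _accum(x, np.where(m, g, alpha * g))
    return out


def relu(x: Tensor) -> Tensor:
    return leaky_relu(x, 0.0)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, (x,))
    out._backward = lambda g: _accum(x, g * (1.0 - y * y))
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, (x,))
    out._backward = lambda g: _accum(x, g * y * (1.0 - y))
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gb = gamma.data.reshape(1, -1, 1, 1)
    out = Tensor(xhat * gb + beta.data.reshape(1, -1, 1, 1), (x, gamma, beta))

    def bw(g):
        _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        _accum(beta, g.sum(axis=(0, 2, 3)))
        dxhat = g * gb
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        _accum(x, inv * (dxhat - m1 - xhat * m2))

    out._backward = bw
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    out = Tensor(x.data.repeat(factor, axis=2).repeat(factor, axis=3), (x,))

    def bw(g):
        N, C, H, W = x.data.shape
        _accum(x, g.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5)))

    out._backward = bw
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), (a, b))

    def bw(g):
        _accum(a, g[:, :ca])
        _accum(b, g[:, ca:])

    out._backward = bw
    return out


def mse_loss(pred: Tensor, target: np.ndarray | float) -> Tensor:
    t = np.asarray(target, dtype=np.float32)
    d = pred.data - t
    out = Tensor(np.array((d * d).mean()), (pred,))
    out._backward = lambda g: _accum(pred, g * 2.0 * d / d.size)
    return out


def l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    t = np.asarray(target, dtype=np.float32)
    d = pred.data - t
    out = Tensor(np.array(np.abs(d).mean()), (pred,))
    out._backward = lambda g: _accum(pred, g * np.sign(d) / d.size)
    return out


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean pixelwise cross-entropy; logits (N,K,H,W), integer target (N,H,W)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    N, K, H, W = p.shape
    idx = (np.arange(N)[:, None, None], target, np.arange(H)[None, :, None], np.arange(W)[None, None, :])
    nll = -np.log(np.take_along_axis(p, target[:, None], axis=1)[:, 0] + 1e-12)
    out = Tensor(np.array(nll.mean()), (logits,))

    def bw(g):
        grad = p.copy()
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, target[:, None], 1.0, axis=1)
        _accum(logits, g * (grad - onehot) / (N * H * W))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    def parameters(self) -> dict[str, Tensor]:
        raise NotImplementedError

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(state) != set(params):
            raise ValidationError("state dict does not match module architecture")
        for k, v in state.items():
            if params[k].data.shape != v.shape:
                raise ValidationError(f"shape mismatch for parameter {k}")
            params[k].data = v.astype(np.float32).copy()


class _Conv(Module):
    def __init__(self, rng, c_in, c_out, k=3, stride=1, norm=False):
        std = np.sqrt(2.0 / (c_in * k * k))
        self.w = Tensor(rng.normal(0.0, std, (c_out, c_in, k, k)))
        self.b = Tensor(np.zeros(c_out))
        self.stride, self.pad = stride, k // 2
        self.norm = norm
        if norm:
            self.gamma = Tensor(np.ones(c_out))
            self.beta = Tensor(np.zeros(c_out))

    def __call__(self, x, act="lrelu"):
        y = conv2d(x, self.w, self.b, self.stride, self.pad)
        if self.norm:
            y = instance_norm(y, self.gamma, self.beta)
        if act == "lrelu":
            y = leaky_relu(y, 0.2)
        elif act == "relu":
            y = relu(y)
        elif act == "tanh":
            y = tanh(y)
        elif act == "sigmoid":
            y = sigmoid(y)
        return y

    def parameters(self, prefix=""):
        p = {f"{prefix}w": self.w, f"{prefix}b": self.b}
        if self.norm:
            p[f"{prefix}gamma"] = self.gamma
            p[f"{prefix}beta"] = self.beta
        return p


class UNet(Module):
    """Encoder-decoder with skip connections built from strided convolutions.

    ``levels`` down-sampling steps halve the spatial size each; ``image_size``
    must be divisible by ``2**levels``.  Instance norm is skipped at depths
    where the feature map is 2 px or smaller.  ``final`` selects the output
    head: "tanh" (generator, output in [-1, 1]), "sigmoid", or None (logits).
    """

    def __init__(self, in_ch=1, out_ch=1, levels=8, base=16, max_ch=256,
                 image_size=256, final="tanh", seed=0):
        if image_size % (2 ** levels) != 0:
            raise ValidationError(
                f"image_size {image_size} not divisible by 2^{levels}; "
                f"reduce levels or resize inputs"
            )
        rng = np.random.default_rng(seed)
        self.cfg = dict(in_ch=in_ch, out_ch=out_ch, levels=levels, base=base,
                        max_ch=max_ch, image_size=image_size, final=final)
        self.final = final
        ch = [min(base * 2 ** l, max_ch) for l in range(levels)]
        self.enc = []
        c_prev = in_ch
        for l in range(levels):
            size = image_size // 2 ** (l + 1)
            self.enc.append(_Conv(rng, c_prev, ch[l], 3, stride=2, norm=size > 2))
            c_prev = ch[l]
        self.dec = []
        for l in range(levels - 2, -1, -1):
            size = image_size // 2 ** (l + 1)
            self.dec.append(_Conv(rng, c_prev + ch[l], ch[l], 3, 1, norm=size > 2))
            c_prev = ch[l]
        self.head_conv = _Conv(rng, c_prev, base, 3, 1, norm=True)
        self.out_conv = _Conv(rng, base, out_ch, 1, 1, norm=False)

    def __call__(self, x: Tensor) -> Tensor:
        feats = []
        h = x
        for layer in self.enc:
            h = layer(h, act="lrelu")
            feats.append(h)
        for i, layer in enumerate(self.dec):
            skip = feats[len(self.enc) - 2 - i]
            h = layer(concat(upsample_nearest(h), skip), act="relu")
        h = self.head_conv(upsample_nearest(h), act="relu")
        act = {"tanh": "tanh", "sigmoid": "sigmoid", None: "none"}[self.final]
        return self.out_conv(h, act=act)

    def parameters(self):
        p = {}
        for i, l in enumerate(self.enc):
            p.update(l.parameters(f"enc{i}."))
        for i, l in enumerate(self.dec):
            p.update(l.parameters(f"dec{i}."))
        p.update(self.head_conv.parameters("head."))
        p.update(self.out_conv.parameters("out."))
        return p


class PatchDiscriminator(Module):
    """Patch-based discriminator: strided convs to a grid of realness logits."""

    def __init__(self, in_ch=1, base=16, n_layers=3, seed=0):
        rng = np.random.default_rng(seed)
        self.cfg = dict(in_ch=in_ch, base=base, n_layers=n_layers)
        self.layers = []
        c_prev = in_ch
        for l in range(n_layers):
            c_out = base * 2 ** l
            self.layers.append(_Conv(rng, c_prev, c_out, 3, stride=2, norm=l > 0))
            c_prev = c_out
        self.out_conv = _Conv(rng, c_prev, 1, 1, 1, norm=False)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.layers:
            h = layer(h, act="lrelu")
        return self.out_conv(h, act="none")

    def parameters(self):
        p = {}
        for i, l in enumerate(self.layers):
            p.update(l.parameters(f"d{i}."))
        p.update(self.out_conv.parameters("out."))
        return p


class Adam:
    """Adam with optional linear learning-rate decay over late epochs."""

    def __init__(self, params: dict[str, Tensor], lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = params
        self.base_lr = self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def set_epoch(self, epoch: int, total_epochs: int, decay_from: float = 0.5):
        """Linear decay of lr to zero over the last (1 - decay_from) of training."""
        start = decay_from * total_epochs
        if epoch >= start:
            frac = (epoch - start) / max(total_epochs - start, 1)
            self.lr = self.base_lr * max(1.0 - frac, 0.0)
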