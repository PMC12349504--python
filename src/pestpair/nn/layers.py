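"""Neural-network layers on top of the autodiff core.

Conventions follow the common deep-learning stack: NCHW feature maps,
pre-norm transformer blocks, He/Glorot initialisation from an explicit
``numpy.random.Generator`` so every forward pass is reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container tracking named parameters and train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for m_name, buf_name, buf in self._named_buffers():
            out[f"{m_name}{buf_name}"] = buf.copy()
        return out

    def _named_buffers(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                for sub, buf_name, buf in value._named_buffers():
                    yield f"{name}.{sub}", buf_name, buf
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, buf_name, buf in item._named_buffers():
                            yield f"{name}.{i}.{sub}", buf_name, buf
        if isinstance(self, BatchNorm2d):
            yield "", "running_mean", self.running_mean
            yield "", "running_var", self.running_var

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=np.float32).copy()
        for m_name, buf_name, _ in self._named_buffers():
            key = f"{m_name}{buf_name}"
            if key in state:
                mod = self
                for part in m_name.rstrip(".").split("."):
                    if not part:
                        continue
                    mod = getattr(mod, part) if not part.isdigit() else mod[int(part)]
                setattr(mod, buf_name, np.asarray(state[key], dtype=np.float32).copy())


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / (in_dim + out_dim))
        self.weight = Parameter(rng.normal(0.0, scale, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = np.empty((b, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(b, c * k * k, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    b, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = cols.reshape(b, c, k, k, ho, wo)
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


class Conv2d(Module):
    """3x3-style convolution via im2col with a hand-written backward pass."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 1,
        pad: int = 1,
    ):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in)))
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.pad
        cols, ho, wo = _im2col(x.data, k, s, p)
        w, bias = self.weight, self.bias
        out_data = np.matmul(w.data[None], cols) + bias.data[None, :, None]
        b = x.data.shape[0]
        out_data = out_data.reshape(b, -1, ho, wo)
        x_shape = x.data.shape

        def bwd(g):
            gf = g.reshape(b, -1, ho * wo)
            w._accum(np.einsum("bol,bcl->oc", gf, cols))
            bias._accum(gf.sum(axis=(0, 2)))
            if x.requires_grad:
                gcols = np.matmul(np.swapaxes(w.data, 0, 1)[None], gf)
                x._accum(_col2im(gcols, x_shape, k, s, p))

        return Tensor._make(out_data, (x, w, bias), bwd)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, channels, 1, 1), dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data
            ).astype(np.float32)
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) * (x - mu)).mean(axis=-1, keepdims=True)
        return (x - mu) * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over a token sequence."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"embed dim {dim} not divisible by n_heads {n_heads}")
        self.dim, self.n_heads, self.head_dim = dim, n_heads, dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)
        self.last_weights: np.ndarray | None = None  # [B, heads, N, N] diagnostics

    def __call__(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        h, hd = self.n_heads, self.head_dim
        proj = self.qkv(x).reshape(b, n, 3, h, hd).transpose(0, 2, 3, 1, 4)  # [b,3,h,n,hd]
        qs, ks, vs = _split3(proj)
        scores = (qs @ ks.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        att = scores.softmax(axis=-1)
        self.last_weights = att.data.copy()
        ctx = att @ vs  # [b,h,n,hd]
        ctx = ctx.transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.out(ctx)


def _split3(proj: Tensor):
    """Split a [b,3,h,n,hd] tensor into three [b,h,n,hd] tensors along axis 1."""
    outs = []
    for idx in range(3):
        sl = proj.data[:, idx]

        def bwd(g, idx=idx):
            full = np.zeros_like(proj.data)
            full[:, idx] = g
            proj._accum(full)

        outs.append(Tensor._make(sl, (proj,), bwd))
    return outs


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class TransformerEncoderLayer(Module):
    """Pre-norm block: x + MHSA(LN(x)), then x + FF(LN(x))."""

    def __init__(self, dim: int, n_heads: int, ff_mult: int, rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.ff = FeedForward(dim, ff_mult * dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.ff(self.norm2(x))
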