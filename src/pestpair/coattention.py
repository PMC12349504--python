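"""Multi-label co-attention: label embeddings query image patches.

Learned label embeddings ``e_i`` (one per category, plus learned positional
codes) are projected to queries; patch features ``f_j`` supply keys and
values. The score ``Att_ij = (e_i W_Q)(f_j W_K)^T / sqrt(d)`` is softmaxed
over patches and used to aggregate a label-aware semantic vector
``z_i = sum_j softmax(Att_ij) (f_j W_V)``, which passes through a two-layer
MLP, a residual connection with the original embedding, a squeeze-excitation
channel gate, and a per-label linear -> sigmoid head producing one presence
probability per category.

Functional numpy references (:func:`cross_attention_scores`,
:func:`aggregate_label_semantics`) expose the same arithmetic for
verification and diagnostics; :class:`CoAttentionHead` is the trainable
module, and :class:`CoAttentionNet` wires backbone + head with an
``attention_mode`` of ``none`` (pooled conv features), ``self`` (spatial
transformer only) or ``co`` (full model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import BackboneConfig, HybridBackbone
from .nn import Linear, Module, Parameter, Tensor, as_tensor

__all__ = [
    "LabelEmbeddingTable",
    "CoAttentionScores",
    "cross_attention_scores",
    "aggregate_label_semantics",
    "CoAttentionHead",
    "CoAttentionNet",
    "cooccurrence_diagnostic",
]


@dataclass
class LabelEmbeddingTable:
    """Learned [CL, d] label embedding matrix plus positional codes."""

    embeddings: np.ndarray
    positional: np.ndarray

    @property
    def n_labels(self) -> int:
        return self.embeddings.shape[0]

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]

    @property
    def extended(self) -> np.ndarray:
        return self.embeddings + self.positional


@dataclass
class CoAttentionScores:
    scores: np.ndarray  # [B, CL, N] pre-softmax
    weights: np.ndarray  # [B, CL, N] softmax over N


def _softmax_np(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_attention_scores(
    labels: np.ndarray, patches: np.ndarray, w_q: np.ndarray, w_k: np.ndarray
) -> CoAttentionScores:
    """Scaled label-to-patch attention scores and weights.

    ``labels``: [CL, d]; ``patches``: [B, N, d] (or [N, d] for a single
    item); returns scores[b, i, j] = (e_i W_Q)(f_j W_K)^T / sqrt(d).
    """
    patches = np.asarray(patches, dtype=float)
    if patches.ndim == 2:
        patches = patches[None]
    labels = np.asarray(labels, dtype=float)
    d = labels.shape[1]
    if patches.shape[-1] != d:
        raise ValueError("label and patch embedding dims differ")
    q = labels @ w_q  # [CL, d]
    k = patches @ w_k  # [B, N, d]
    scores = np.einsum("id,bnd->bin", q, k) / np.sqrt(d)
    return CoAttentionScores(scores=scores, weights=_softmax_np(scores, axis=-1))


def aggregate_label_semantics(
    scores: CoAttentionScores, patches: np.ndarray, w_v: np.ndarray
) -> np.ndarray:
    """Label-guided aggregation z_i = sum_j weights_ij (f_j W_V): [B, CL, d]."""
    patches = np.asarray(patches, dtype=float)
    if patches.ndim == 2:
        patches = patches[None]
    values = patches @ w_v  # [B, N, d]
    return np.einsum("bin,bnd->bid", scores.weights, values)


def cooccurrence_diagnostic(fused: np.ndarray) -> np.ndarray:
    """CL x CL cosine similarity between fused label representations.

    A read-only interpretability view of the label relationships the model
    has internalised; averaged over the batch if one is present.
    """
    fused = np.asarray(fused, dtype=float)
    if fused.ndim == 2:
        fused = fused[None]
    norm = np.linalg.norm(fused, axis=-1, keepdims=True)
    unit = fused / np.maximum(norm, 1e-12)
    sim = np.einsum("bid,bjd->bij", unit, unit)
    return sim.mean(axis=0)


class CoAttentionHead(Module):
    """Trainable co-attention head over a patch sequence."""

    def __init__(
        self,
        n_labels: int,
        dim: int,
        rng: np.random.Generator,
        mlp_hidden: int | None = None,
        se_reduction: int = 4,
        n_heads: int = 1,
    ):
        super().__init__()
        if n_heads != 1 and dim % n_heads != 0:
            raise ValueError("dim must be divisible by n_heads")
        self.n_labels, self.dim, self.n_heads = n_labels, dim, n_heads
        self.embeddings = Parameter(0.02 * rng.standard_normal((n_labels, dim)))
        self.positional = Parameter(0.02 * rng.standard_normal((n_labels, dim)))
        self.w_q = Linear(dim, dim, rng, bias=False)
        self.w_k = Linear(dim, dim, rng, bias=False)
        self.w_v = Linear(dim, dim, rng, bias=False)
        hidden = mlp_hidden if mlp_hidden is not None else 2 * dim
        self.mlp1 = Linear(dim, hidden, rng)
        self.mlp2 = Linear(hidden, dim, rng)
        se_dim = max(1, dim // se_reduction)
        self.se1 = Linear(dim, se_dim, rng)
        self.se2 = Linear(se_dim, dim, rng)
        self.head_weight = Parameter(0.02 * rng.standard_normal((n_labels, dim)))
        self.head_bias = Parameter(np.zeros(n_labels))
        self.last_weights: np.ndarray | None = None  # [B, CL, N]
        self.last_fused: np.ndarray | None = None  # [B, CL, d]

    def label_table(self) -> LabelEmbeddingTable:
        return LabelEmbeddingTable(self.embeddings.data.copy(), self.positional.data.copy())

    def __call__(self, patches: Tensor) -> Tensor:
        patches = as_tensor(patches)
        b, n, d = patches.shape
        cl, h = self.n_labels, self.n_heads
        e = self.embeddings + self.positional  # [CL, d]
        q = self.w_q(e)  # [CL, d]
        k = self.w_k(patches)  # [B, N, d]
        v = self.w_v(patches)
        if h == 1:
            scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(d))  # [B, CL, N]
            att = scores.softmax(axis=-1)
            z = att @ v  # [B, CL, d]
        else:
            hd = d // h
            qh = q.reshape(cl, h, hd).transpose(1, 0, 2)  # [h, CL, hd]
            kh = k.reshape(b, n, h, hd).transpose(0, 2, 1, 3)  # [b, h, N, hd]
            vh = v.reshape(b, n, h, hd).transpose(0, 2, 1, 3)
            scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))  # [b,h,CL,N]
            att = scores.softmax(axis=-1)
            z = (att @ vh).transpose(0, 2, 1, 3).reshape(b, cl, d)
            att = att.mean(axis=1)  # collapse heads for diagnostics
        self.last_weights = att.data.copy() if att.data.ndim == 3 else att.data
        fused = self.mlp2(self.mlp1(z).gelu()) + e  # residual with original embeddings
        gate = self.se2(self.se1(fused.mean(axis=1)).gelu()).sigmoid()  # [B, d]
        fused = fused * gate.reshape(b, 1, d)
        self.last_fused = fused.data.copy()
        logits = (fused * self.head_weight).sum(axis=-1) + self.head_bias  # [B, CL]
        return logits


class PooledHead(Module):
    """Mean-pool the token sequence and apply a linear multi-label head."""

    def __init__(self, n_labels: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc = Linear(dim, n_labels, rng)

    def __call__(self, patches: Tensor) -> Tensor:
        return self.fc(patches.mean(axis=1))


class CoAttentionNet(Module):
    """Full recognizer: hybrid backbone + label head, three attention modes."""

    def __init__(
        self,
        config: BackboneConfig,
        n_labels: int = 8,
        attention_mode: str = "co",
        rng: np.random.Generator | None = None,
        mlp_hidden: int | None = None,
        cross_heads: int = 1,
    ):
        super().__init__()
        if attention_mode not in ("none", "self", "co"):
            raise ValueError(f"unknown attention_mode {attention_mode!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        self.attention_mode = attention_mode
        self.n_labels = n_labels
        self.backbone = HybridBackbone(config, rng, use_transformer=attention_mode != "none")
        if attention_mode == "co":
            if mlp_hidden is None:
                mlp_hidden = 512 if config.profile == "full" else 2 * config.embed_dim
            self.head = CoAttentionHead(
                n_labels, config.embed_dim, rng, mlp_hidden=mlp_hidden, n_heads=cross_heads
            )
        else:
            self.head = PooledHead(n_labels, config.embed_dim, rng)

    def __call__(self, images: Tensor) -> Tensor:
        seq = self.backbone(as_tensor(images))
        return self.head(seq)

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Presence probabilities [B, CL]; runs in eval mode, no gradients."""
        self.eval()
        outs = []
        for start in range(0, len(images), batch_size):
            logits = self(Tensor(images[start : start + batch_size]))
            outs.append(1.0 / (1.0 + np.exp(-logits.data.astype(np.float64))))
        return np.concatenate(outs, axis=0)

    def attention_maps(self, images: np.ndarray) -> np.ndarray:
        """Per-label attention heatmaps [B, CL, H, W] (co mode only)."""
        if self.attention_mode != "co":
            raise ValueError("attention maps require the co-attention head")
        self.eval()
        self(Tensor(images))
        g = self.config.patch_grid
        return self.head.last_weights.reshape(len(images), self.n_labels, g, g)
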