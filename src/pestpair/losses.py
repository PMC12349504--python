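"""Multi-label BCE, the pairwise label matching loss, and their composition.

For a candidate pair set P and a ground-truth label set Y, the pair indicator
is ``y_ij = 1`` iff both i and j are in Y. The pairwise matching loss treats
the product ``p_ij = p_i * p_j`` as a joint prediction and scores it with
binary cross-entropy:

    L_pair = - sum_{(i,j) in P} [ y_ij log(p_i p_j) + (1 - y_ij) log(1 - p_i p_j) ]

The printed form of this sum is a log-likelihood (it increases with
prediction quality); the implementation returns its negation so training
minimises it — pass ``negate=False`` to audit the raw sum. Products and
per-element probabilities are clamped to ``[eps, 1 - eps]``. The total
objective is ``L_total = L_bce + lambda * L_pair`` with ``lambda = 0.4`` by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .schema import CategorySchema

__all__ = [
    "PairSet",
    "make_pair_set",
    "pair_indicators",
    "pairwise_matching_loss",
    "bce_loss",
    "total_loss",
    "LossBreakdown",
    "DEFAULT_LAMBDA",
    "DEFAULT_EPS",
]

DEFAULT_LAMBDA = 0.4
DEFAULT_EPS = 1e-7


@dataclass(frozen=True)
class PairSet:
    pairs: tuple[tuple[int, int], ...]
    mode: str = "all"

    def __post_init__(self):
        seen = set()
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"pair ({i},{j}) must satisfy i < j")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i},{j})")
            seen.add((i, j))

    def __len__(self):
        return len(self.pairs)

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        arr = np.asarray(self.pairs, dtype=int)
        return arr[:, 0], arr[:, 1]


def make_pair_set(
    n_labels: int, mode: str = "all", schema: CategorySchema | None = None
) -> PairSet:
    """All unordered label pairs, or only predator-pest pairs given a schema."""
    if mode == "all":
        pairs = tuple((i, j) for i in range(n_labels) for j in range(i + 1, n_labels))
    elif mode == "predator_pest":
        if schema is None:
            raise ValueError("predator_pest mode requires a schema")
        roles = [c.role for c in schema.categories]
        pairs = tuple(
            (i, j)
            for i in range(n_labels)
            for j in range(i + 1, n_labels)
            if {roles[i], roles[j]} == {"predator", "pest"}
        )
    else:
        raise ValueError(f"unknown pair mode {mode!r}")
    return PairSet(pairs, mode)


def pair_indicators(labels, pair_set: PairSet) -> np.ndarray:
    """Pair co-presence indicators y_ij for multi-hot labels.

    ``labels`` may be a single multi-hot vector, a batch [B, C], or a set of
    indices. Returns an array of shape [..., |P|] with entries in {0, 1}.
    """
    if isinstance(labels, (set, frozenset, list, tuple)) and not isinstance(
        labels, np.ndarray
    ):
        idx = set(labels)
        return np.asarray([1 if i in idx and j in idx else 0 for i, j in pair_set.pairs])
    labels = np.asarray(labels)
    ii, jj = pair_set.index_arrays()
    hard = (labels >= 0.5).astype(np.int64)
    return hard[..., ii] * hard[..., jj]


def _check_probs(data):
    if np.any(data < 0) or np.any(data > 1):
        raise ValueError("probabilities must lie in [0, 1]")


def _reduce_np(per_pair: np.ndarray, reduction: str, n_terms: int) -> float:
    total = per_pair.sum(axis=-1)
    if reduction == "mean":
        total = total / max(n_terms, 1)
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return float(np.mean(total))


def _reduce(per_pair: Tensor, reduction: str, n_terms: int) -> Tensor:
    # per_pair has pair axis last; reduce over it, then mean over any batch axes
    total = per_pair.sum(axis=-1)
    if reduction == "mean":
        total = total * (1.0 / max(n_terms, 1))
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return total.mean() if total.data.ndim > 0 else total


def pairwise_matching_loss(
    p_hat,
    targets,
    pair_set: PairSet,
    eps: float = DEFAULT_EPS,
    reduction: str = "sum",
    negate: bool = True,
):
    """Pairwise label matching loss over joint probabilities p_i * p_j.

    ``p_hat``: probabilities [..., C] (numpy array or autodiff Tensor);
    ``targets``: indicators [..., |P|] (from :func:`pair_indicators`) or a
    label set / multi-hot to derive them from. Reduction is the sum over P
    by default (``mean`` divides by |P|); batch axes are averaged. Returns a
    float for numpy input, a scalar Tensor for Tensor input.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if not isinstance(targets, np.ndarray) or np.asarray(targets).shape[-1] != len(pair_set):
        targets = pair_indicators(targets, pair_set)
    ii, jj = pair_set.index_arrays()
    if isinstance(p_hat, Tensor):
        _check_probs(p_hat.data)
        y = np.asarray(targets, dtype=np.float32)
        p_ij = (_gather_last(p_hat, ii) * _gather_last(p_hat, jj)).clip(eps, 1.0 - eps)
        ll = Tensor(y) * p_ij.log() + Tensor(1.0 - y) * (1.0 - p_ij).log()
        return _reduce(-ll if negate else ll, reduction, len(pair_set))
    p = np.asarray(p_hat, dtype=np.float64)
    _check_probs(p)
    y = np.asarray(targets, dtype=np.float64)
    p_ij = np.clip(p[..., ii] * p[..., jj], eps, 1.0 - eps)
    ll = y * np.log(p_ij) + (1.0 - y) * np.log(1.0 - p_ij)
    return _reduce_np(-ll if negate else ll, reduction, len(pair_set))


def _gather_last(p: Tensor, idx: np.ndarray) -> Tensor:
    """Differentiable gather along the last axis with a fixed index vector."""
    data = p.data[..., idx]

    def bwd(g):
        full = np.zeros_like(p.data)
        np.add.at(full, (..., idx), g)
        p._accum(full)

    return Tensor._make(data, (p,), bwd)


def bce_loss(
    p_hat,
    targets,
    eps: float = DEFAULT_EPS,
    reduction: str = "sum",
):
    """Element-wise binary cross-entropy with soft-target support.

    Same clamping and reduction conventions as the pairwise loss: per-sample
    reduction over the label axis (sum by default), batch axes averaged.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    t = np.asarray(targets, dtype=np.float64)
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("targets must lie in [0, 1]")
    if isinstance(p_hat, Tensor):
        _check_probs(p_hat.data)
        pc = p_hat.clip(eps, 1.0 - eps)
        tf = t.astype(np.float32)
        ll = Tensor(tf) * pc.log() + Tensor(1.0 - tf) * (1.0 - pc).log()
        return _reduce(-ll, reduction, p_hat.data.shape[-1])
    p = np.asarray(p_hat, dtype=np.float64)
    _check_probs(p)
    pc = np.clip(p, eps, 1.0 - eps)
    ll = t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)
    return _reduce_np(-ll, reduction, p.shape[-1])


@dataclass
class LossBreakdown:
    l_bce: float
    l_pair: float
    lam: float
    l_total: float


def total_loss(l_bce, l_pair, lam: float = DEFAULT_LAMBDA):
    """Compose L_total = L_bce + lambda * L_pair.

    Accepts floats (returns a :class:`LossBreakdown`) or Tensors (returns
    ``(total_tensor, breakdown)`` so the caller can backpropagate).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if isinstance(l_bce, Tensor) or isinstance(l_pair, Tensor):
        total = l_bce + lam * l_pair
        breakdown = LossBreakdown(
            float(np.asarray(l_bce.data if isinstance(l_bce, Tensor) else l_bce)),
            float(np.asarray(l_pair.data if isinstance(l_pair, Tensor) else l_pair)),
            lam,
            float(total.data),
        )
        return total, breakdown
    return LossBreakdown(float(l_bce), float(l_pair), lam, float(l_bce + lam * l_pair))
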