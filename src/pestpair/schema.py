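"""Category schema and planted co-occurrence model for predator-pest scenes.

The default schema covers the eight field categories: four natural enemies
(*Coccinella septempunctata*, *Chrysoperla sinica*, *Orius sauteri*,
*Trichogramma chilonis*) and four target pests (*Aphis gossypii*,
*Thrips tabaci*, *Ostrinia furnacalis*, *Nilaparvata lugens*). Canonical
predator-pest pairs (ladybug-aphid, lacewing-planthopper, pirate-bug-thrips,
trichogramma-corn-borer) carry elevated joint presence probability; all other
category pairs are independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CategoryRecord",
    "DEFAULT_UNSEEN_PAIRS",
    "CategorySchema",
    "CooccurrenceModel",
    "make_default_schema",
    "default_cooccurrence",
    "TABLE1_IMAGE_COUNTS",
]

# Per-category annotated-image counts of the 5037-image field corpus whose
# frequency regime the generator emulates; shapes default class marginals.
TABLE1_IMAGE_COUNTS = (642, 711, 538, 483, 923, 786, 512, 442)

# Ecologically plausible predator-pest combinations that are NOT canonical
# prey relations: ladybug-corn borer, lacewing-aphid, pirate bug-planthopper,
# trichogramma-thrips. These are the default holdout set for the unseen-pair
# generalization protocol — each member species is seen individually in
# training, the joint combination never. They occur in scenes only through
# independent co-presence, so joint test images exist without planted
# structure.
DEFAULT_UNSEEN_PAIRS = ((0, 6), (1, 4), (2, 7), (3, 5))


@dataclass(frozen=True)
class CategoryRecord:
    name: str
    role: str  # "predator" | "pest"
    glyph: str  # shape+colour descriptor used by the renderer
    size_class: str  # "small" | "medium" | "large"


@dataclass(frozen=True)
class CategorySchema:
    categories: tuple[CategoryRecord, ...]
    canonical_pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        roles = [c.role for c in self.categories]
        if roles.count("predator") != 4 or roles.count("pest") != 4:
            raise ValueError("schema requires exactly 4 predators and 4 pests")
        for i, j in self.canonical_pairs:
            if not (0 <= i < len(self.categories) and 0 <= j < len(self.categories)):
                raise ValueError(f"canonical pair ({i},{j}) out of range")
            if self.categories[i].role != "predator" or self.categories[j].role != "pest":
                raise ValueError(f"canonical pair ({i},{j}) must be (predator, pest)")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.categories]

    def index(self, name: str) -> int:
        return self.names.index(name)


def make_default_schema() -> CategorySchema:
    """The 8-category predator/pest schema with canonical prey relations.

    Categories are 0-based and ordered predators first, matching the field
    dataset's category table. Pests are small-bodied on the canvas; predators
    medium.
    """
    cats = (
        CategoryRecord("C. septempunctata", "predator", "red-ellipse-black-spots", "medium"),
        CategoryRecord("C. sinica", "predator", "cyan-lacewing-veined", "medium"),
        CategoryRecord("O. sauteri", "predator", "navy-oval-white-band", "medium"),
        CategoryRecord("T. chilonis", "predator", "amber-wasp-wedge", "medium"),
        CategoryRecord("A. gossypii", "pest", "pink-cluster-dot", "small"),
        CategoryRecord("T. tabaci", "pest", "magenta-sliver", "small"),
        CategoryRecord("O. furnacalis", "pest", "cream-striped-larva", "small"),
        CategoryRecord("N. lugens", "pest", "violet-wedge-hopper", "small"),
    )
    # ladybug-aphid, lacewing-planthopper, pirate bug-thrips, trichogramma-corn borer
    pairs = ((0, 4), (1, 7), (2, 5), (3, 6))
    return CategorySchema(cats, pairs)


@dataclass
class CooccurrenceModel:
    """Pairwise-coupled Bernoulli presence model.

    Each coupled (canonical) pair is drawn from its exact 2x2 joint table
    ``{11: q, 10: m_i - q, 01: m_j - q, 00: 1 - m_i - m_j + q}``; categories
    outside any coupled pair are independent Bernoulli(m). Coupled pairs must
    be disjoint, which makes every entry of the implied joint matrix exact.
    """

    marginals: np.ndarray
    coupled: dict[tuple[int, int], float] = field(default_factory=dict)
    holdout_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.marginals = np.asarray(self.marginals, dtype=float)
        if np.any(self.marginals < 0) or np.any(self.marginals > 1):
            raise ValueError("marginals must be probabilities in [0, 1]")
        seen: set[int] = set()
        for (i, j), q in self.coupled.items():
            if i == j:
                raise ValueError("coupled pair must join two distinct categories")
            if i in seen or j in seen:
                raise ValueError("coupled pairs must be disjoint")
            seen.update((i, j))
            mi, mj = self.marginals[i], self.marginals[j]
            if q > min(mi, mj) + 1e-12:
                raise ValueError(
                    f"joint probability {q} for pair ({i},{j}) exceeds min marginal"
                )
            if q < mi + mj - 1 - 1e-12:
                raise ValueError(f"joint probability {q} for pair ({i},{j}) below Frechet bound")

    @property
    def n_categories(self) -> int:
        return len(self.marginals)

    @property
    def joint_matrix(self) -> np.ndarray:
        """Implied C x C co-presence probability matrix (zero diagonal)."""
        m = self.marginals
        jm = np.outer(m, m)
        np.fill_diagonal(jm, 0.0)
        for (i, j), q in self.coupled.items():
            jm[i, j] = jm[j, i] = q
        return jm

    def sample_presence(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one multi-hot presence vector."""
        c = self.n_categories
        present = np.zeros(c, dtype=np.int64)
        covered: set[int] = set()
        for (i, j), q in self.coupled.items():
            mi, mj = self.marginals[i], self.marginals[j]
            u = rng.random()
            if u < q:
                present[i] = present[j] = 1
            elif u < mi:
                present[i] = 1
            elif u < mi + mj - q:
                present[j] = 1
            covered.update((i, j))
        for k in range(c):
            if k not in covered:
                present[k] = int(rng.random() < self.marginals[k])
        return present


def default_cooccurrence(
    schema: CategorySchema,
    marginal_scale: float = 2.5,
    pair_strength: float = 0.75,
    holdout_pairs: list[tuple[int, int]] | None = None,
) -> CooccurrenceModel:
    """Default presence model mirroring the field dataset's frequency regime.

    Marginals are the per-category image-count ratios scaled by
    ``marginal_scale`` (so scenes are multi-label often enough to train on);
    each canonical pair's joint probability is ``pair_strength`` times the
    smaller of its two marginals, well above the independence product.
    """
    counts = np.asarray(TABLE1_IMAGE_COUNTS, dtype=float)
    marginals = np.clip(marginal_scale * counts / counts.sum(), 0.0, 0.95)
    coupled = {
        (i, j): pair_strength * min(marginals[i], marginals[j])
        for i, j in schema.canonical_pairs
    }
    model = CooccurrenceModel(marginals, coupled, holdout_pairs or [])
    _check_planted_dominance(schema, model)
    return model


def _check_planted_dominance(schema: CategorySchema, model: CooccurrenceModel):
    """Warn if any non-canonical predator-pest joint reaches canonical level."""
    jm = model.joint_matrix
    canon = set(map(tuple, schema.canonical_pairs))
    min_canon = min(jm[i, j] for i, j in canon)
    for i, ci in enumerate(schema.categories):
        for j, cj in enumerate(schema.categories):
            if i < j and ci.role == "predator" and cj.role == "pest" and (i, j) not in canon:
                if jm[i, j] >= min_canon:
                    warnings.warn(
                        f"non-canonical pair ({i},{j}) joint {jm[i, j]:.3f} is not "
                        f"dominated by the weakest canonical joint {min_canon:.3f}"
                    )
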