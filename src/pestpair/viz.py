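"""Attention heatmap visualisation for interpretability dumps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["save_attention_heatmaps"]


def save_attention_heatmaps(
    image: np.ndarray,
    heatmaps: np.ndarray,
    label_names: list[str],
    out_path: str | Path,
    probabilities: np.ndarray | None = None,
) -> Path:
    """Write a per-label attention heatmap panel as one PNG.

    ``image``: H x W x 3 uint8 scene; ``heatmaps``: [CL, g, g] attention
    weights straight from the co-attention head.
    """
    n = len(label_names)
    ncols = 3
    nrows = int(np.ceil((n + 1) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows))
    axes = np.atleast_1d(axes).ravel()
    axes[0].imshow(image)
    axes[0].set_title("scene")
    for k in range(n):
        ax = axes[k + 1]
        ax.imshow(image)
        ax.imshow(
            np.kron(heatmaps[k], np.ones((image.shape[0] // heatmaps[k].shape[0],) * 2)),
            cmap="inferno",
            alpha=0.55,
        )
        title = label_names[k]
        if probabilities is not None:
            title += f" ({probabilities[k]:.2f})"
        ax.set_title(title, fontsize=8)
    for ax in axes:
        ax.axis("off")
    out_path = Path(out_path)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
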