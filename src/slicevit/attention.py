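"""Per-head/per-depth attention map extraction and the global attention
feature map.

The global map is computed exactly as published: every pixel of the
resized source image is multiplied by the sum over the final
fully-connected feature vector, then min-max normalized to 0..255. As
literally defined the normalized output therefore reduces to the
(possibly inverted) min-max-normalized image — the feature vector enters
only through the sign of its sum. That reduction is asserted by a
regression test rather than "fixed" by an invented spatial weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .models import AttentionStack, VisionTransformer

logger = logging.getLogger(__name__)

__all__ = [
    "GlobalAttentionMap",
    "extract_attention_maps",
    "global_attention_feature_map",
    "save_attention_grid",
    "save_global_attention_panel",
]


@dataclass
class GlobalAttentionMap:
    resized_image: np.ndarray       # model-input-sized source image
    fc_vector: np.ndarray
    gafm: np.ndarray                # per-pixel real map
    gafm_normalized: np.ndarray     # integer map in [0, 255]


def extract_attention_maps(model: VisionTransformer,
                           image: np.ndarray) -> AttentionStack:
    """Post-softmax attention maps of every head at every depth for one
    image, arranged depth x heads (rows index depth, columns heads)."""
    if image.ndim == 2:
        image = np.repeat(image[None], model.config.channels, axis=0)
    if image.ndim != 3:
        raise ValueError("image must be 2-D grayscale or CxHxW")
    result = model.forward(image[None], collect_attention=True)
    return result.attention


def resize_bilinear(image: np.ndarray, size: int) -> np.ndarray:
    im = Image.fromarray(np.asarray(image, dtype=np.float32))
    return np.asarray(im.resize((size, size), Image.BILINEAR), dtype=np.float64)


def global_attention_feature_map(image: np.ndarray, fc_vector: np.ndarray,
                                 size: int = 56) -> GlobalAttentionMap:
    """Published global-attention formula.

    ``gafm(pixel) = pixel * sum(fc_vector)``; the normalized map is
    ``(gafm - min) * 255 / (max - min)`` rounded half-up. A constant map
    normalizes to all zeros (with a warning).
    """
    fc_vector = np.asarray(fc_vector, dtype=np.float64)
    if not np.isfinite(fc_vector).all():
        raise ValueError("fc_vector must be finite")
    resized = resize_bilinear(np.asarray(image, dtype=np.float64), size)
    gafm = resized * fc_vector.sum()
    lo, hi = float(gafm.min()), float(gafm.max())
    if hi == lo:
        logger.warning("constant global attention map; normalized output is all zero")
        normalized = np.zeros(gafm.shape, dtype=np.int64)
    else:
        normalized = np.floor((gafm - lo) * 255.0 / (hi - lo) + 0.5).astype(np.int64)
    return GlobalAttentionMap(resized_image=resized, fc_vector=fc_vector,
                              gafm=gafm, gafm_normalized=normalized)


def save_attention_grid(stack: AttentionStack, path: str | Path) -> None:
    """PNG panel with one attention map per cell: rows = depth, cols = heads."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    depth, heads = stack.depth, stack.heads
    fig, axes = plt.subplots(depth, heads, figsize=(1.2 * heads, 1.2 * depth),
                             squeeze=False)
    for d in range(depth):
        for h in range(heads):
            ax = axes[d][h]
            ax.imshow(stack.maps[d, h], cmap="viridis")
            ax.set_xticks([])
            ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def save_global_attention_panel(maps: list[GlobalAttentionMap],
                                path: str | Path) -> None:
    """CIVIDIS-colored global attention maps, one panel per slice."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(maps)
    fig, axes = plt.subplots(1, n, figsize=(2.0 * n, 2.2), squeeze=False)
    for ax, gmap in zip(axes[0], maps):
        ax.imshow(gmap.gafm_normalized, cmap="cividis", vmin=0, vmax=255)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
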