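"""Whole-slide attention heatmaps.

Every foreground patch is rendered — not a top-k subset — as a solid
block at thumbnail scale, colored from pale blue (least attention) to
dark red (most attention).  Attention is min-max normalized per slide,
because softmax weights over bags of different sizes are not on a
common scale; a slide with constant attention maps to the colormap
midpoint, which is visually neutral and avoids a divide-by-zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .errors import ContractViolationError, InvalidInputError
from .model import AttentionMap
from .slides import PatchGrid, SlideImage

# pale blue -> red -> dark red; list order makes colormap position
# strictly monotone in normalized attention
ATTENTION_CMAP = LinearSegmentedColormap.from_list(
    "attention", ["#cfe5f2", "#f7a47c", "#c1121f", "#67000d"]
)


@dataclass
class HeatmapConfig:
    downsample: int = 32
    alpha: float = 0.5
    colormap: str = "attention"


@dataclass
class HeatmapRender:
    """A slide thumbnail with an RGBA attention overlay."""

    thumbnail: np.ndarray
    overlay: np.ndarray
    colormap: str
    bounds: tuple[float, float]
    alpha: float
    n_rendered: int

    def composite(self) -> np.ndarray:
        """Alpha-blend the overlay onto the thumbnail (uint8 RGB)."""
        a = self.overlay[..., 3:4] / 255.0
        out = self.thumbnail * (1 - a) + self.overlay[..., :3] * a
        return out.round().astype(np.uint8)


def normalize_attention(weights: np.ndarray) -> np.ndarray:
    """Per-slide min-max normalization; constant maps to 0.5."""
    w = np.asarray(weights, dtype=np.float64)
    lo, hi = w.min(), w.max()
    if hi - lo < 1e-15:
        return np.full_like(w, 0.5)
    return (w - lo) / (hi - lo)


def render_heatmap(
    attn: AttentionMap,
    grid: PatchGrid,
    slide: SlideImage,
    config: HeatmapConfig | None = None,
) -> HeatmapRender:
    """Block-color every patch of the grid by its normalized attention."""
    config = config or HeatmapConfig()
    if len(attn.weights) != len(grid):
        raise ContractViolationError(
            f"attention length {len(attn.weights)} != grid size {len(grid)}"
        )
    if not 0.0 <= config.alpha <= 1.0:
        raise InvalidInputError("alpha must lie in [0, 1]")
    ds = config.downsample
    thumb = slide.levels[0][::ds, ::ds].copy()
    overlay = np.zeros((*thumb.shape[:2], 4), dtype=np.uint8)
    norm = normalize_attention(attn.weights)
    colors = (ATTENTION_CMAP(norm)[:, :3] * 255).round().astype(np.uint8)
    span = grid.span_base
    for (x, y), col in zip(grid.coords, colors):
        x0, y0 = x // ds, y // ds
        x1 = max(x0 + 1, (x + span) // ds)
        y1 = max(y0 + 1, (y + span) // ds)
        overlay[y0:y1, x0:x1, :3] = col
        overlay[y0:y1, x0:x1, 3] = int(round(config.alpha * 255))
    return HeatmapRender(
        thumbnail=thumb,
        overlay=overlay,
        colormap=config.colormap,
        bounds=(float(np.min(attn.weights)), float(np.max(attn.weights))),
        alpha=config.alpha,
        n_rendered=len(grid),
    )


def export_heatmap(render: HeatmapRender, path: str | Path, task_name: str = "") -> None:
    """Write the composited heatmap with a colorbar legend as PNG.

    Output bytes are deterministic for fixed inputs (fixed dpi, fixed
    metadata, no timestamps).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.cm import ScalarMappable
    from matplotlib.colors import Normalize

    img = render.composite()
    h, w = img.shape[:2]
    fig, ax = plt.subplots(figsize=(max(w / 100, 2), max(h / 100, 2)), dpi=100)
    ax.imshow(img)
    ax.set_axis_off()
    sm = ScalarMappable(norm=Normalize(0, 1), cmap=ATTENTION_CMAP)
    cbar = fig.colorbar(sm, ax=ax, fraction=0.04, pad=0.02)
    cbar.set_label(f"model attention ({task_name})" if task_name else "model attention")
    try:
        fig.savefig(path, format="png", metadata={"Software": "gastromil"})
    except OSError as exc:
        raise InvalidInputError(f"cannot write heatmap to {path}: {exc}") from exc
    finally:
        plt.close(fig)
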