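"""Virtual staining: score overlays on the slide thumbnail.

Two modes. Attention heatmaps min-max rescale the per-tile attention scores
within the slide and blend them through a continuous perceptually uniform
colormap; because of the per-slide rescale, colors compare tiles within one
slide, never across slides. Contribution maps paint each tile with exactly
one of two colors — red for excitatory (sigmoid-bounded score > 0.5), blue
for inhibitory (<= 0.5).

Pixels outside every tile footprint are left bit-identical to the input
thumbnail; rendering is a pure function of its inputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps

from .wsi import TILE_PX, TileRecord

RED = np.array([255, 0, 0], dtype=np.float64)
BLUE = np.array([0, 0, 255], dtype=np.float64)


@dataclass
class OverlaySpec:
    """What to draw: thumbnail, per-tile scores, and tile footprints.

    ``footprints`` are (x, y, w, h) rectangles in thumbnail pixel
    coordinates, one per score.
    """

    mode: str  # "attention_continuous" | "contribution_binary"
    thumbnail: np.ndarray  # (H, W, 3) uint8
    scores: np.ndarray  # (n,)
    footprints: list[tuple[int, int, int, int]]
    opacity: float = 0.5
    colormap: str = "viridis"

    def __post_init__(self) -> None:
        if self.mode not in ("attention_continuous", "contribution_binary"):
            raise ValueError(f"unknown overlay mode {self.mode!r}")
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.footprints) != self.scores.size:
            raise ValueError("one footprint per score required")
        H, W = self.thumbnail.shape[:2]
        for x, y, w, h in self.footprints:
            if x < 0 or y < 0 or x + w > W or y + h > H:
                raise ValueError(
                    f"footprint ({x},{y},{w},{h}) outside thumbnail {W}x{H}"
                )


def tile_footprint_on_thumbnail(
    tile: TileRecord,
    level_downsample: float,
    thumb_downsample: float,
    thumbnail_shape: tuple[int, int],
    tile_px: int = TILE_PX,
) -> tuple[int, int, int, int]:
    """Map a tile's level coordinates to its thumbnail rectangle (clipped)."""
    scale = level_downsample / thumb_downsample
    x = int(np.floor(tile.x * scale))
    y = int(np.floor(tile.y * scale))
    w = max(1, int(round(tile_px * scale)))
    h = max(1, int(round(tile_px * scale)))
    H, W = thumbnail_shape[:2]
    x, y = min(x, W - 1), min(y, H - 1)
    return x, y, min(w, W - x), min(h, H - y)


def _blend(out: np.ndarray, footprint, color: np.ndarray, opacity: float) -> None:
    x, y, w, h = footprint
    region = out[y : y + h, x : x + w].astype(np.float64)
    out[y : y + h, x : x + w] = np.round(
        (1.0 - opacity) * region + opacity * color
    ).astype(out.dtype)


def render_attention(spec: OverlaySpec) -> np.ndarray:
    """Continuous-colormap overlay of per-slide min-max rescaled attention."""
    if spec.mode != "attention_continuous":
        raise ValueError("spec.mode must be 'attention_continuous'")
    out = spec.thumbnail.copy()
    if spec.scores.size == 0:
        return out
    if not np.isclose(spec.scores.sum(), 1.0, atol=1e-6):
        raise ValueError("attention scores must sum to 1")
    lo, hi = spec.scores.min(), spec.scores.max()
    if np.isclose(lo, hi):
        warnings.warn("all attention scores equal; rendering uniform mid-color")
        rescaled = np.full_like(spec.scores, 0.5)
    else:
        rescaled = (spec.scores - lo) / (hi - lo)
    cmap = colormaps[spec.colormap]
    for s, fp in zip(rescaled, spec.footprints):
        color = np.array(cmap(float(s))[:3]) * 255.0
        _blend(out, fp, color, spec.opacity)
    return out


def render_contributions(spec: OverlaySpec) -> np.ndarray:
    """Binary red/blue overlay of bounded contribution scores.

    Excitatory tiles (score > 0.5) are red, inhibitory (<= 0.5) blue;
    exactly two overlay colors are ever used.
    """
    if spec.mode != "contribution_binary":
        raise ValueError("spec.mode must be 'contribution_binary'")
    out = spec.thumbnail.copy()
    if spec.scores.size == 0:
        return out
    if np.any(spec.scores <= 0.0) or np.any(spec.scores >= 1.0):
        raise ValueError("contribution scores must lie strictly inside (0, 1)")
    for s, fp in zip(spec.scores, spec.footprints):
        _blend(out, fp, RED if s > 0.5 else BLUE, spec.opacity)
    return out


def render(spec: OverlaySpec) -> np.ndarray:
    if spec.mode == "attention_continuous":
        return render_attention(spec)
    return render_contributions(spec)


def write_scores_json(
    path: str | Path,
    spec: OverlaySpec,
    slide_id: str = "",
) -> None:
    """Side-car JSON with per-tile scores and footprints for viewers."""
    payload = {
        "slide_id": slide_id,
        "mode": spec.mode,
        "tiles": [
            {"x": x, "y": y, "w": w, "h": h, "score": float(s)}
            for (x, y, w, h), s in zip(spec.footprints, spec.scores)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
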