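"""Whole-slide preprocessing: metadata, tissue masking, tile selection.

The pipeline works coarse-to-fine. Tissue is segmented once on the
thumbnail (grayscale -> Otsu threshold -> darker class -> morphological
closing); marker artifacts and stray background are removed by comparing
each tissue pixel's RGB color to the mean tissue color; surviving thumbnail
pixels are mapped through the pyramid's downsample factors to 512-px tile
coordinates at the requested magnification; each fetched tile is padded to
512 x 512 with the average background color if undersized and accepted iff
its tissue fraction clears a threshold. Tile budgets are kept in check by
fraction sampling at the coarsest magnification and k-means cluster sampling
when descending to finer ones.

Tiles are snapped to a non-overlapping 512-px grid per level; coordinates
are 0-based (x, y) with half-open [x, x+512) footprints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import hed2rgb, rgb2gray, rgb2hed
from skimage.filters import threshold_otsu
from skimage.morphology import closing as morphological_closing
from sklearn.cluster import KMeans

TILE_PX = 512

METADATA_COLUMNS = ["slide_id", "label", "slide_type", "mpp"]


@dataclass
class SlideMetadata:
    """Slide-table row: id, binary label, preparation type, base-level mpp."""

    slide_id: str
    label: int | None
    slide_type: str | None  # "FFPE" or "frozen"
    mpp: float | None


@dataclass
class TileRecord:
    """One candidate/accepted tile at a given magnification level."""

    magnification: str  # e.g. "5x", "10x", "20x"
    x: int  # top-left, level pixel coordinates
    y: int
    tissue_fraction: float = 0.0
    status: str = "candidate"  # candidate | accepted | rejected | padded+accepted


@dataclass
class TissuePixelSet:
    """Thumbnail pixels classified as tissue, with their mean RGB color."""

    coords: np.ndarray  # (m, 2) int array of (x, y)
    mean_color: np.ndarray  # (3,) float
    mask: np.ndarray  # (H, W) bool, equivalent to coords
    otsu_threshold: float | None = None

    @property
    def is_empty(self) -> bool:
        return self.coords.shape[0] == 0


def extract_metadata(slides: list[SlideMetadata]) -> pd.DataFrame:
    """Build the slide metadata table, flagging incomplete rows invalid.

    Rows missing label or mpp (or with non-positive mpp) are kept in the
    table with ``valid=False`` and should be excluded downstream.
    """
    rows = []
    for s in slides:
        valid = (
            s.label in (0, 1)
            and s.mpp is not None
            and np.isfinite(s.mpp)
            and s.mpp > 0
        )
        if not valid:
            warnings.warn(
                f"slide {s.slide_id!r} has incomplete metadata; flagged invalid",
                stacklevel=2,
            )
        rows.append(
            {
                "slide_id": s.slide_id,
                "label": s.label,
                "slide_type": s.slide_type,
                "mpp": s.mpp,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows, columns=METADATA_COLUMNS + ["valid"])


def write_metadata_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"slide_id": str, "slide_type": str}
    )


def tissue_mask(
    thumbnail: np.ndarray, closing_size: int = 3
) -> TissuePixelSet:
    """Segment tissue on the thumbnail.

    Grayscale conversion, Otsu threshold, tissue = darker class, then a
    morphological closing (square structuring element) to fill small holes
    and smooth the mask. A uniform thumbnail has no Otsu split and yields an
    empty set with a warning.
    """
    thumbnail = np.asarray(thumbnail)
    if thumbnail.size == 0:
        raise ValueError("empty thumbnail")
    gray = rgb2gray(thumbnail)
    if np.allclose(gray.min(), gray.max()):
        warnings.warn("uniform thumbnail: Otsu threshold undefined, no tissue")
        return TissuePixelSet(
            coords=np.empty((0, 2), dtype=np.int64),
            mean_color=np.zeros(3),
            mask=np.zeros(gray.shape, dtype=bool),
            otsu_threshold=None,
        )
    thr = threshold_otsu(gray)
    mask = gray < thr
    mask = morphological_closing(
        mask, footprint=np.ones((closing_size, closing_size), dtype=bool)
    )
    ys, xs = np.nonzero(mask)
    coords = np.stack([xs, ys], axis=1).astype(np.int64)
    mean_color = (
        thumbnail[mask].reshape(-1, thumbnail.shape[-1]).mean(axis=0)
        if mask.any()
        else np.zeros(3)
    )
    return TissuePixelSet(
        coords=coords, mean_color=np.asarray(mean_color, dtype=float)[:3],
        mask=mask, otsu_threshold=float(thr),
    )


def artifact_filter(
    pixels: TissuePixelSet, thumbnail: np.ndarray, threshold: float
) -> TissuePixelSet:
    """Drop tissue pixels whose color is far from the mean tissue color.

    The mean is computed once on the input set (not iterated); a pixel is
    retained iff its RGB Euclidean distance to that mean is <= threshold.
    Removes marker-pen strokes and stray background that survived Otsu.
    """
    if threshold < 0:
        raise ValueError(f"color-distance threshold must be >= 0, got {threshold}")
    if pixels.is_empty:
        raise ValueError("artifact_filter requires a non-empty tissue pixel set")
    thumbnail = np.asarray(thumbnail)
    xs, ys = pixels.coords[:, 0], pixels.coords[:, 1]
    colors = thumbnail[ys, xs, :3].astype(float)
    dist = np.linalg.norm(colors - pixels.mean_color, axis=1)
    keep = dist <= threshold
    new_mask = np.zeros_like(pixels.mask)
    new_mask[ys[keep], xs[keep]] = True
    new_mean = colors[keep].mean(axis=0) if keep.any() else np.zeros(3)
    return TissuePixelSet(
        coords=pixels.coords[keep],
        mean_color=new_mean,
        mask=new_mask,
        otsu_threshold=pixels.otsu_threshold,
    )


def background_mean_color(
    thumbnail: np.ndarray, pixels: TissuePixelSet
) -> np.ndarray:
    """Mean RGB of thumbnail pixels outside the tissue set (used for padding)."""
    thumbnail = np.asarray(thumbnail)
    bg = ~pixels.mask
    if not bg.any():
        return np.full(3, 255.0)
    return thumbnail[bg].reshape(-1, thumbnail.shape[-1]).mean(axis=0)[:3]


def map_thumb_to_tiles(
    pixels: TissuePixelSet,
    thumb_downsample: float,
    target_level_downsample: float,
    magnification: str = "",
    tile_px: int = TILE_PX,
) -> list[TileRecord]:
    """Map thumbnail tissue pixels to covering tile indices at a finer level.

    Each thumbnail pixel (x, y) maps to base coordinates
    (x * thumb_downsample, y * thumb_downsample) and then to the tile index
    floor(base / (tile_px * target_level_downsample)). Duplicates collapse to
    one record; output is sorted row-major.
    """
    if thumb_downsample <= 0 or target_level_downsample <= 0:
        raise ValueError("downsample factors must be positive")
    if target_level_downsample > thumb_downsample:
        raise ValueError(
            "target level is coarser than the thumbnail "
            f"({target_level_downsample} > {thumb_downsample})"
        )
    step = tile_px * target_level_downsample
    base = pixels.coords.astype(np.float64) * thumb_downsample
    idx = np.floor(base / step).astype(np.int64)
    uniq = np.unique(idx, axis=0)
    order = np.lexsort((uniq[:, 0], uniq[:, 1]))  # row-major: by y, then x
    return [
        TileRecord(magnification=magnification, x=int(ix) * tile_px, y=int(iy) * tile_px)
        for ix, iy in uniq[order]
    ]


def accept_tile(
    tile: np.ndarray,
    tissue_threshold: float,
    background_color: np.ndarray,
    otsu_threshold: float | None = None,
    magnification: str = "",
    x: int = 0,
    y: int = 0,
    tile_px: int = TILE_PX,
) -> tuple[TileRecord, np.ndarray]:
    """Pad an undersized tile and accept/reject it by tissue fraction.

    The tile is padded on the right/bottom to ``tile_px`` square with the
    average background color. Tissue is classified at tile scale with the
    same darker-than-Otsu criterion used on the thumbnail; pass the
    thumbnail's global threshold as ``otsu_threshold`` (recommended — a
    near-uniform tissue tile has no meaningful per-tile Otsu split), or leave
    it None to threshold on the tile itself. Accepted iff the tissue
    fraction over the padded tile is >= tissue_threshold.
    """
    tile = np.asarray(tile)
    h, w = tile.shape[:2]
    if h > tile_px or w > tile_px:
        raise ValueError(f"tile of shape {tile.shape} exceeds {tile_px} px")
    padded = False
    if h < tile_px or w < tile_px:
        full = np.empty((tile_px, tile_px, 3), dtype=tile.dtype)
        bg = np.asarray(background_color, dtype=float)
        if np.issubdtype(tile.dtype, np.integer):
            bg = np.round(bg)
        full[:] = bg.astype(tile.dtype)
        full[:h, :w] = tile[..., :3]
        tile = full
        padded = True
    gray = rgb2gray(tile)
    if otsu_threshold is None:
        if np.allclose(gray.min(), gray.max()):
            thr = -np.inf  # uniform tile: nothing darker than threshold
        else:
            thr = threshold_otsu(gray)
    else:
        thr = otsu_threshold
    fraction = float(np.mean(gray < thr))
    if fraction >= tissue_threshold:
        status = "padded+accepted" if padded else "accepted"
    else:
        status = "rejected"
    rec = TileRecord(
        magnification=magnification, x=x, y=y,
        tissue_fraction=fraction, status=status,
    )
    return rec, tile


def sample_fraction(
    tiles: list[TileRecord],
    fraction: float = 0.6,
    limit: int = 1000,
    seed: int = 0,
) -> list[TileRecord]:
    """Keep all tiles when at or below the limit, else a uniform random
    sample of round(fraction * count), order-preserving and seeded."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if len(tiles) <= limit:
        return list(tiles)
    rng = np.random.default_rng(seed)
    k = int(round(fraction * len(tiles)))
    keep = np.sort(rng.choice(len(tiles), size=k, replace=False))
    return [tiles[i] for i in keep]


def cluster_sample(
    parent_embeddings: np.ndarray,
    parent_tiles: list[TileRecord],
    k: int = 4,
    n_per_cluster: int = 20,
    seed: int = 0,
) -> list[TileRecord]:
    """K-means the parent-magnification tiles; draw up to ``n_per_cluster``
    tiles uniformly from each cluster (seeded, without replacement)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(parent_tiles) < 1:
        raise ValueError("no parent tiles to sample from")
    E = np.asarray(parent_embeddings, dtype=float)
    if E.shape[0] != len(parent_tiles):
        raise ValueError("one embedding row per parent tile required")
    if k > len(parent_tiles):
        warnings.warn(f"k={k} exceeds tile count {len(parent_tiles)}; clamped")
        k = len(parent_tiles)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assign = km.fit_predict(E)
    rng = np.random.default_rng(seed)
    selected: list[int] = []
    for c in range(k):
        members = np.flatnonzero(assign == c)
        take = min(len(members), n_per_cluster)
        selected.extend(rng.choice(members, size=take, replace=False).tolist())
    return [parent_tiles[i] for i in sorted(selected)]


def expand_to_children(
    parent_tile: TileRecord,
    parent_downsample: float,
    child_downsample: float,
    child_magnification: str = "",
    tile_px: int = TILE_PX,
) -> list[TileRecord]:
    """Tiles at the finer level exactly covering the parent footprint.

    The ratio r = parent/child downsample must be an integer; the result is
    the r x r grid of child tiles whose union in base coordinates equals the
    parent tile's footprint. r = 1 returns the parent itself.
    """
    if child_downsample > parent_downsample:
        raise ValueError("child level must not be coarser than parent level")
    ratio = parent_downsample / child_downsample
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"downsample ratio {ratio} between levels is not an integer"
        )
    r = int(round(ratio))
    children = []
    for dy in range(r):
        for dx in range(r):
            children.append(
                TileRecord(
                    magnification=child_magnification,
                    x=parent_tile.x * r + dx * tile_px,
                    y=parent_tile.y * r + dy * tile_px,
                )
            )
    return children


@dataclass
class AugmentParams:
    """One augmentation draw: HED stain perturbation, noise, rotation, flips."""

    hed_scale: np.ndarray  # (3,) multiplicative, per H/E/D channel
    hed_offset: np.ndarray  # (3,) additive
    noise_sigma: float  # on [0, 1] intensity scale
    rotation_quarters: int  # 0..3 -> 0/90/180/270 degrees
    flip_horizontal: bool
    flip_vertical: bool

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(np.ones(3), np.zeros(3), 0.0, 0, False, False)

    @classmethod
    def sample(cls, rng: np.random.Generator) -> "AugmentParams":
        return cls(
            hed_scale=rng.uniform(0.95, 1.05, size=3),
            hed_offset=rng.uniform(-0.02, 0.02, size=3),
            noise_sigma=float(rng.uniform(0.0, 0.02)),
            rotation_quarters=int(rng.integers(0, 4)),
            flip_horizontal=bool(rng.integers(0, 2)),
            flip_vertical=bool(rng.integers(0, 2)),
        )


def apply_augmentation(
    tile: np.ndarray, params: AugmentParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Apply one augmentation; identity parameters return the tile unchanged."""
    tile = np.asarray(tile)
    out = tile.astype(np.float64) / 255.0
    if not (
        np.allclose(params.hed_scale, 1.0) and np.allclose(params.hed_offset, 0.0)
    ):
        hed = rgb2hed(out)
        hed = hed * params.hed_scale + params.hed_offset
        out = np.clip(hed2rgb(hed), 0.0, 1.0)
    if params.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        out = np.clip(out + rng.normal(scale=params.noise_sigma, size=out.shape), 0, 1)
    if params.rotation_quarters:
        out = np.rot90(out, k=params.rotation_quarters)
    if params.flip_horizontal:
        out = out[:, ::-1]
    if params.flip_vertical:
        out = out[::-1, :]
    return np.round(out * 255.0).astype(tile.dtype)


def augment_tile(tile: np.ndarray, seed: int) -> list[np.ndarray]:
    """Two independent seeded augmentations of a 512 x 512 RGB tile."""
    tile = np.asarray(tile)
    if tile.shape[0] != TILE_PX or tile.shape[1] != TILE_PX:
        raise ValueError(f"augment_tile expects {TILE_PX}x{TILE_PX} tiles")
    rng = np.random.default_rng(seed)
    return [apply_augmentation(tile, AugmentParams.sample(rng), rng) for _ in range(2)]


def tiles_to_manifest(
    slide_id: str, tiles: list[TileRecord]
) -> pd.DataFrame:
    """Tile manifest table: slide_id, magnification, x, y, tissue_fraction, status."""
    return pd.DataFrame(
        [
            {
                "slide_id": slide_id,
                "magnification": t.magnification,
                "x": t.x,
                "y": t.y,
                "tissue_fraction": t.tissue_fraction,
                "status": t.status,
            }
            for t in tiles
        ],
        columns=["slide_id", "magnification", "x", "y", "tissue_fraction", "status"],
    )
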