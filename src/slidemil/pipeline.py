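"""End-to-end slide preparation: pyramid in, embedding store group out.

The ladder of magnifications is fixed at 5x / 10x / 20x with a factor-2
downsample between neighbors. The coarsest magnification (5x) is tiled
directly from the thumbnail tissue mask and thinned by fraction sampling;
finer magnifications follow the hierarchical descent: accepted tiles at the
previous magnification are clustered on their embeddings (k-means), a
capped number of tiles is drawn per cluster, and each drawn tile is
expanded to the grid of child tiles covering its footprint at the next
magnification, which are then fetched and accepted like any tile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pyramid import PyramidHandle
from .store import MAGNIFICATION_CODES, ReferenceEncoder, SlideGroup, encode_tiles
from .wsi import (
    TILE_PX,
    TileRecord,
    accept_tile,
    artifact_filter,
    augment_tile,
    background_mean_color,
    cluster_sample,
    expand_to_children,
    map_thumb_to_tiles,
    sample_fraction,
    tiles_to_manifest,
    tissue_mask,
)

logger = logging.getLogger(__name__)

MAGNIFICATIONS = ("5x", "10x", "20x")


@dataclass
class PrepConfig:
    """Pipeline thresholds and budgets (all slide-preparation knobs).

    ``color_distance_threshold`` is in 8-bit RGB units; ``tissue_threshold``
    is the minimum tissue fraction of a 512 x 512 tile; ``tile_limit`` is the
    per-slide count above which fraction sampling kicks in;
    ``kmeans_k`` / ``tiles_per_cluster`` govern the hierarchical descent.
    """

    magnification: str = "5x"
    base_magnification: str = "20x"
    tissue_threshold: float = 0.3
    color_distance_threshold: float = 100.0
    closing_size: int = 3
    fraction: float = 0.6
    tile_limit: int = 1000
    kmeans_k: int = 4
    tiles_per_cluster: int = 20
    augment: bool = True
    encoder_d: int = 1024
    encoder_seed: int = 0

    def __post_init__(self) -> None:
        if self.magnification not in MAGNIFICATIONS:
            raise ValueError(f"magnification must be one of {MAGNIFICATIONS}")
        if self.base_magnification not in MAGNIFICATIONS:
            raise ValueError(f"base_magnification must be one of {MAGNIFICATIONS}")


def magnification_downsamples(base_magnification: str = "20x") -> dict[str, int]:
    """Downsample factor of each magnification relative to the pyramid base."""
    mags = [m for m in MAGNIFICATIONS]
    powers = {"5x": 0, "10x": 1, "20x": 2}
    base_p = powers[base_magnification]
    return {
        m: 2 ** (base_p - powers[m])
        for m in mags
        if powers[m] <= base_p
    }


def level_for_downsample(pyramid: PyramidHandle, downsample: float) -> int:
    for lvl, ds in enumerate(pyramid.level_downsamples):
        if abs(ds - downsample) < 1e-6:
            return lvl
    raise ValueError(
        f"pyramid has no level with downsample {downsample}; "
        f"available: {pyramid.level_downsamples}"
    )


@dataclass
class PrepResult:
    group: SlideGroup | None
    manifest: pd.DataFrame
    counters: dict[str, int]


def _fetch_and_accept(
    pyramid: PyramidHandle,
    tiles: list[TileRecord],
    level: int,
    magnification: str,
    background_color: np.ndarray,
    otsu_threshold: float | None,
    tissue_threshold: float,
) -> tuple[list[TileRecord], list[np.ndarray], list[TileRecord]]:
    """Fetch candidate tiles, pad/accept them; returns (accepted, images, rejected)."""
    w_lvl, h_lvl = pyramid.level_dimensions[level]
    accepted: list[TileRecord] = []
    images: list[np.ndarray] = []
    rejected: list[TileRecord] = []
    for t in tiles:
        if t.x >= w_lvl or t.y >= h_lvl:
            continue
        block = pyramid.region(level, t.x, t.y, TILE_PX, TILE_PX)
        rec, img = accept_tile(
            block,
            tissue_threshold=tissue_threshold,
            background_color=background_color,
            otsu_threshold=otsu_threshold,
            magnification=magnification,
            x=t.x,
            y=t.y,
        )
        if rec.status == "rejected":
            rejected.append(rec)
        else:
            accepted.append(rec)
            images.append(img)
    return accepted, images, rejected


def prep_slide(
    pyramid: PyramidHandle,
    slide_id: str,
    label: int,
    config: PrepConfig,
    seed: int = 0,
    encoder=None,
) -> PrepResult:
    """Run the full preparation of one slide at ``config.magnification``."""
    if encoder is None:
        encoder = ReferenceEncoder(d=config.encoder_d, seed=config.encoder_seed)
    thumb = pyramid.thumbnail()
    thumb_ds = pyramid.level_downsamples[-1]
    counters: dict[str, int] = {}
    all_records: list[TileRecord] = []

    pixels = tissue_mask(thumb, closing_size=config.closing_size)
    counters["tissue_pixels"] = int(pixels.coords.shape[0])
    if not pixels.is_empty:
        pixels = artifact_filter(pixels, thumb, config.color_distance_threshold)
    counters["tissue_pixels_after_artifact_filter"] = int(pixels.coords.shape[0])
    if pixels.is_empty:
        return PrepResult(
            group=None,
            manifest=tiles_to_manifest(slide_id, []),
            counters=counters,
        )
    bg = background_mean_color(thumb, pixels)

    mag_ds = magnification_downsamples(config.base_magnification)
    chain = [m for m in MAGNIFICATIONS if m in mag_ds]
    chain = chain[: chain.index(config.magnification) + 1]

    # coarsest magnification: direct mapping from the thumbnail mask
    mag0 = chain[0]
    lvl0 = level_for_downsample(pyramid, mag_ds[mag0])
    cand = map_thumb_to_tiles(pixels, thumb_ds, mag_ds[mag0], magnification=mag0)
    counters[f"candidates_{mag0}"] = len(cand)
    tiles, images, rejected = _fetch_and_accept(
        pyramid, cand, lvl0, mag0, bg, pixels.otsu_threshold, config.tissue_threshold
    )
    all_records += tiles + rejected
    counters[f"accepted_{mag0}"] = len(tiles)
    counters[f"rejected_{mag0}"] = len(rejected)
    kept = sample_fraction(
        tiles, fraction=config.fraction, limit=config.tile_limit, seed=seed
    )
    keep_ix = {(t.x, t.y) for t in kept}
    images = [im for t, im in zip(tiles, images) if (t.x, t.y) in keep_ix]
    tiles = kept
    counters[f"sampled_{mag0}"] = len(tiles)

    # hierarchical descent to finer magnifications
    for parent_mag, child_mag in zip(chain, chain[1:]):
        if not tiles:
            break
        parent_emb = encode_tiles(images, encoder)
        parents = cluster_sample(
            parent_emb,
            tiles,
            k=config.kmeans_k,
            n_per_cluster=config.tiles_per_cluster,
            seed=seed,
        )
        counters[f"cluster_sampled_{parent_mag}"] = len(parents)
        child_cand: list[TileRecord] = []
        for p in parents:
            child_cand.extend(
                expand_to_children(
                    p, mag_ds[parent_mag], mag_ds[child_mag],
                    child_magnification=child_mag,
                )
            )
        counters[f"candidates_{child_mag}"] = len(child_cand)
        lvl = level_for_downsample(pyramid, mag_ds[child_mag])
        tiles, images, rejected = _fetch_and_accept(
            pyramid, child_cand, lvl, child_mag, bg,
            pixels.otsu_threshold, config.tissue_threshold,
        )
        all_records += tiles + rejected
        counters[f"accepted_{child_mag}"] = len(tiles)
        counters[f"rejected_{child_mag}"] = len(rejected)

    manifest = tiles_to_manifest(slide_id, all_records)
    if not tiles:
        return PrepResult(group=None, manifest=manifest, counters=counters)

    embeddings = encode_tiles(images, encoder)
    aug_embeddings = None
    if config.augment:
        aug_imgs: list[np.ndarray] = []
        for i, img in enumerate(images):
            aug_imgs.extend(augment_tile(img, seed=seed * 100003 + i))
        aug_embeddings = encode_tiles(aug_imgs, encoder)
    code = MAGNIFICATION_CODES[config.magnification]
    coords = np.array([[code, t.x, t.y] for t in tiles], dtype=np.int64)
    group = SlideGroup(
        slide_id=slide_id,
        embeddings=embeddings,
        coords=coords,
        label=label,
        aug_embeddings=aug_embeddings,
        encoder_name=encoder.name,
    )
    logger.info(
        "slide %s: %d tiles accepted at %s", slide_id, len(tiles), config.magnification
    )
    return PrepResult(group=group, manifest=manifest, counters=counters)
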