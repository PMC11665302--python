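"""Tile encoders and the HDF5 embedding store.

Encoders map 512 x 512 RGB tiles to fixed-length embedding vectors behind a
small contract (``d``, ``name``, batched ``encode``), so any pretrained
histology network can be plugged in. The built-in :class:`ReferenceEncoder`
is a deterministic seeded random projection of pooled image statistics: it
carries real spatial color/intensity information (enough for pipeline and
store tests to be meaningful) without any learned weights.

Store layout (schema 1): one HDF5 group per slide_id with row-chunked,
gzip-compressed datasets ``embeddings`` (float32, n x d), ``aug_embeddings``
(float32, 2n x d; rows 2i, 2i+1 belong to parent i), ``coords`` (int64,
n x 3: magnification code, x, y), and attributes ``label``, ``d``,
``encoder_name``.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .bags import Bag
from .wsi import TILE_PX

SCHEMA_VERSION = 1

#: integer codes used for the magnification column of ``coords``
MAGNIFICATION_CODES = {"5x": 5, "10x": 10, "20x": 20}


class ReferenceEncoder:
    """Deterministic tile encoder: pooled statistics -> random projection.

    Tiles are mean-pooled per channel onto a ``grid x grid`` lattice; the
    flattened statistics are passed through a fixed seeded Gaussian
    projection and a tanh nonlinearity. Output length defaults to the
    conventional 1024 of histology feature extractors.
    """

    def __init__(self, d: int = 1024, seed: int = 0, grid: int = 16):
        self.d = d
        self.grid = grid
        self.seed = seed
        n_feat = grid * grid * 3
        rng = np.random.default_rng(seed)
        self._proj = rng.normal(scale=1.0 / np.sqrt(n_feat), size=(n_feat, d)).astype(
            np.float32
        )
        self.name = f"reference-v1-d{d}-seed{seed}"

    def _features(self, tile: np.ndarray) -> np.ndarray:
        t = tile.astype(np.float32) / 255.0
        h, w = t.shape[:2]
        bh, bw = h // self.grid, w // self.grid
        pooled = t[: bh * self.grid, : bw * self.grid, :3].reshape(
            self.grid, bh, self.grid, bw, 3
        ).mean(axis=(1, 3))
        return pooled.reshape(-1)

    def encode(self, tiles: np.ndarray) -> np.ndarray:
        """Map a (m, H, W, 3) tile stack to (m, d) float32 embeddings."""
        tiles = np.asarray(tiles)
        if tiles.ndim == 3:
            tiles = tiles[None]
        if tiles.ndim != 4 or tiles.shape[-1] != 3:
            raise ValueError(
                f"expected (m, H, W, 3) RGB tiles, got shape {tiles.shape}"
            )
        # project row by row so results are independent of batch size
        rows = [np.tanh(self._features(t) @ self._proj) for t in tiles]
        return np.stack(rows).astype(np.float32)


def encode_tiles(
    tiles, encoder, batch_size: int = 32
) -> np.ndarray:
    """Encode tiles in batches so memory stays bounded by ``batch_size``.

    ``tiles`` may be an array, a list of tiles, or any iterable yielding
    (H, W, 3) arrays.
    """
    out: list[np.ndarray] = []
    batch: list[np.ndarray] = []
    for tile in tiles:
        tile = np.asarray(tile)
        if tile.ndim != 3 or tile.shape[-1] != 3 or tile.shape[0] != TILE_PX:
            raise ValueError(
                f"tile must be {TILE_PX}x{TILE_PX} RGB, got shape {tile.shape}"
            )
        batch.append(tile)
        if len(batch) == batch_size:
            out.append(encoder.encode(np.stack(batch)))
            batch = []
    if batch:
        out.append(encoder.encode(np.stack(batch)))
    if not out:
        return np.empty((0, encoder.d), dtype=np.float32)
    return np.concatenate(out, axis=0)


@dataclass
class SlideGroup:
    """One slide's embeddings and metadata as stored on disk."""

    slide_id: str
    embeddings: np.ndarray  # (n, d) float32
    coords: np.ndarray  # (n, 3) int64
    label: int
    aug_embeddings: np.ndarray | None = None  # (2n, d) float32
    encoder_name: str = ""

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        n = self.embeddings.shape[0]
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} embeddings"
            )
        if self.aug_embeddings is not None:
            self.aug_embeddings = np.asarray(self.aug_embeddings, dtype=np.float32)
            if self.aug_embeddings.shape != (2 * n, self.embeddings.shape[1]):
                raise ValueError("aug_embeddings must have shape (2n, d)")


def write_store(path: str | Path, groups: list[SlideGroup]) -> None:
    """Write slide groups to an HDF5 store, atomically.

    Data is written to a temporary file in the destination directory and
    renamed into place, so a failed write never leaves a truncated store.
    Duplicate slide_ids are rejected.
    """
    path = Path(path)
    ids = [g.slide_id for g in groups]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate slide_id(s): {dupes}")
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".h5.tmp")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            f.attrs["schema"] = SCHEMA_VERSION
            for g in groups:
                grp = f.create_group(g.slide_id)
                d = g.embeddings.shape[1] if g.embeddings.size else 0
                grp.create_dataset(
                    "embeddings",
                    data=g.embeddings,
                    chunks=(1, d) if g.embeddings.size else None,
                    compression="gzip",
                )
                aug = (
                    g.aug_embeddings
                    if g.aug_embeddings is not None
                    else np.empty((0, d), dtype=np.float32)
                )
                grp.create_dataset(
                    "aug_embeddings",
                    data=aug,
                    chunks=(1, d) if aug.size else None,
                    compression="gzip",
                )
                grp.create_dataset("coords", data=g.coords, compression="gzip")
                grp.attrs["label"] = g.label
                grp.attrs["d"] = d
                grp.attrs["encoder_name"] = g.encoder_name
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_groups(path: str | Path, slide_ids: list[str] | None = None) -> list[SlideGroup]:
    """Read slide groups back, field-for-field."""
    with h5py.File(path, "r") as f:
        available = sorted(f.keys())
        wanted = available if slide_ids is None else slide_ids
        groups = []
        for sid in wanted:
            if sid not in f:
                raise KeyError(
                    f"slide {sid!r} not in store; available: {available}"
                )
            grp = f[sid]
            aug = grp["aug_embeddings"][()]
            groups.append(
                SlideGroup(
                    slide_id=sid,
                    embeddings=grp["embeddings"][()],
                    coords=grp["coords"][()],
                    label=int(grp.attrs["label"]),
                    aug_embeddings=aug if aug.size else None,
                    encoder_name=str(grp.attrs["encoder_name"]),
                )
            )
    return groups


def read_store(
    path: str | Path,
    slide_ids: list[str] | None = None,
    include_augmented: bool = False,
) -> list[Bag]:
    """Load slides as training-ready bags.

    With ``include_augmented`` the two augmented embeddings per tile are
    folded into the bag as extra instances (bag size 3n); without, only the
    n original rows are used (evaluation mode).
    """
    bags = []
    for g in read_groups(path, slide_ids):
        H = g.embeddings
        coords = g.coords
        if include_augmented and g.aug_embeddings is not None:
            H = np.concatenate([H, g.aug_embeddings], axis=0)
            coords = np.concatenate(
                [coords, np.repeat(g.coords, 2, axis=0)], axis=0
            )
        bags.append(
            Bag(
                instances=H,
                label=g.label,
                tile_coords=coords,
                slide_id=g.slide_id,
            )
        )
    return bags
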