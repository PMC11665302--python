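"""Bag container for multiple instance learning.

A *bag* is one slide: an ``n x d`` matrix of instance (tile) embeddings with a
single binary slide-level label. Per-instance labels are latent in real data;
synthetic fixtures may carry them for evaluation, hidden from training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Bag:
    """One slide's instances plus its weak label.

    Parameters
    ----------
    instances : ndarray of shape (n, d), float32
        Instance embedding vectors, one row per tile.
    label : int
        Slide-level binary label in {0, 1}.
    instance_labels : ndarray of shape (n,), optional
        Hidden per-instance witness indicators (synthetic fixtures only).
    tile_coords : ndarray of shape (n, 3), optional
        Per-instance (magnification code, x, y) triples.
    slide_id : str
        Identifier used by stores and manifests.
    """

    instances: np.ndarray
    label: int
    instance_labels: np.ndarray | None = None
    tile_coords: np.ndarray | None = None
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.instances = np.asarray(self.instances, dtype=np.float32)
        if self.instances.ndim != 2 or self.instances.shape[0] < 1:
            raise ValueError(
                f"bag instances must be a non-empty 2-D matrix, got shape "
                f"{self.instances.shape}"
            )
        if self.label not in (0, 1):
            raise ValueError(f"bag label must be 0 or 1, got {self.label!r}")
        if self.instance_labels is not None:
            self.instance_labels = np.asarray(self.instance_labels, dtype=np.int64)
            if self.instance_labels.shape != (self.n,):
                raise ValueError("instance_labels length must match instance count")
        if self.tile_coords is not None:
            self.tile_coords = np.asarray(self.tile_coords, dtype=np.int64)
            if self.tile_coords.shape != (self.n, 3):
                raise ValueError("tile_coords must have shape (n, 3)")

    @property
    def n(self) -> int:
        return self.instances.shape[0]

    @property
    def d(self) -> int:
        return self.instances.shape[1]
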