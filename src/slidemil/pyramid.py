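"""Minimal multi-resolution slide pyramid contract.

Scanner formats are out of scope; slides enter through this small interface:
level count, per-level dimensions, per-level downsample factors relative to
the base, and a ``region`` accessor. A plain multi-level TIFF reader and an
in-memory implementation are provided; vendor formats can be adapted by
implementing the same contract.

Coordinates are 0-based (x, y) pixel positions within a level, x running
along image columns; regions are half-open ``[x, x + w) x [y, y + h)``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile


class PyramidHandle:
    """Read-only accessor for a multi-resolution image pyramid."""

    @property
    def level_count(self) -> int:
        raise NotImplementedError

    @property
    def level_dimensions(self) -> list[tuple[int, int]]:
        """Per-level (width, height) in pixels, base level first."""
        raise NotImplementedError

    @property
    def level_downsamples(self) -> list[float]:
        """Per-level downsample factor relative to the base (increasing)."""
        raise NotImplementedError

    def region(self, level: int, x: int, y: int, w: int, h: int) -> np.ndarray:
        """RGB block of shape (h', w', 3), clipped at the level boundary."""
        raise NotImplementedError

    def thumbnail(self) -> np.ndarray:
        """Full image at the coarsest level."""
        lvl = self.level_count - 1
        w, h = self.level_dimensions[lvl]
        return self.region(lvl, 0, 0, w, h)

    def validate(self) -> None:
        ds = self.level_downsamples
        if any(b <= a for a, b in zip(ds, ds[1:])):
            raise ValueError(f"downsample factors must strictly increase: {ds}")
        w0, h0 = self.level_dimensions[0]
        for lvl, (w, h) in enumerate(self.level_dimensions):
            f = ds[lvl]
            if abs(w - w0 / f) > 1 or abs(h - h0 / f) > 1:
                raise ValueError(
                    f"level {lvl} dimensions ({w}, {h}) inconsistent with "
                    f"downsample {f} of base ({w0}, {h0})"
                )


class InMemoryPyramid(PyramidHandle):
    """Pyramid backed by a list of RGB arrays (base level first)."""

    def __init__(self, levels: list[np.ndarray]):
        if not levels:
            raise ValueError("at least one level required")
        self._levels = [np.asarray(lv) for lv in levels]
        base_h, base_w = self._levels[0].shape[:2]
        self._downsamples = [base_w / lv.shape[1] for lv in self._levels]
        self.validate()

    @property
    def level_count(self) -> int:
        return len(self._levels)

    @property
    def level_dimensions(self) -> list[tuple[int, int]]:
        return [(lv.shape[1], lv.shape[0]) for lv in self._levels]

    @property
    def level_downsamples(self) -> list[float]:
        return list(self._downsamples)

    def region(self, level: int, x: int, y: int, w: int, h: int) -> np.ndarray:
        lv = self._levels[level]
        return lv[y : y + h, x : x + w].copy()


class TiffPyramid(InMemoryPyramid):
    """Pyramid loaded from a multi-page TIFF (one page per level)."""

    def __init__(self, path: str | Path):
        with tifffile.TiffFile(str(path)) as tf:
            levels = [page.asarray() for page in tf.pages]
        levels.sort(key=lambda a: -a.shape[1])
        super().__init__(levels)
        self.path = Path(path)


def write_pyramid_tiff(path: str | Path, levels: list[np.ndarray]) -> None:
    """Write levels (base first) as a multi-page uncompressed TIFF."""
    with tifffile.TiffWriter(str(path)) as tw:
        for lv in levels:
            tw.write(lv, photometric="rgb")
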