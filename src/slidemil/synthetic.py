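"""Synthetic fixtures: MIL bags with known witnesses, and pyramidal slides
with ground-truth masks.

The bag generator instantiates the standard MIL assumption — a bag is
positive iff it contains at least one *witness* instance — in embedding
space: background instances are spherical Gaussian noise, witnesses are
shifted by a fixed-norm vector along a seeded random direction. The hidden
``instance_labels`` mark witnesses so localization can be scored after
training without ever showing instance labels to the trainer.

The slide generator emulates what the tiling pipeline must cope with: a
white scanner background, smoothly colored tissue blobs, optional saturated
marker strokes (artifacts), and optional distinct-texture signal regions
inside tissue. Every coarser level is an exact 2x decimation of the base, so
cross-level coordinate math can be checked exactly, and all ground-truth
masks are returned per level.

These generators emulate geometry and contrast, not histology: no stain
physics, no cell morphology, no scanner noise model. Results on them
demonstrate correctness of the machinery, not clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .bags import Bag
from .pyramid import InMemoryPyramid


@dataclass
class BagGenConfig:
    """Conditions of the synthetic bag study.

    Defaults are the documented desk-scale fixture: 200 bags of 20-100
    instances in d = 32 dimensions, unit background noise, witness shift of
    norm 2.0, roughly 30% witnesses per positive bag (tumor slides carry
    substantial tumor fractions), balanced classes.
    """

    n_bags: int = 200
    bag_size_range: tuple[int, int] = (20, 100)
    d: int = 32
    witness_shift: float = 2.0
    witness_rate: float = 0.3
    class_balance: float = 0.5
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.witness_rate <= 1.0:
            raise ValueError("witness_rate must lie in (0, 1]")
        if self.witness_rate * self.bag_size_range[0] < 1.0:
            raise ValueError(
                "infeasible config: witness_rate * min bag size < 1, a "
                "positive bag could fail to contain a witness"
            )
        if self.bag_size_range[0] < 1 or self.bag_size_range[1] < self.bag_size_range[0]:
            raise ValueError("invalid bag_size_range")


def gen_bags(config: BagGenConfig) -> list[Bag]:
    """Generate bags under the MIL rule; deterministic per config.seed."""
    rng = np.random.default_rng(config.seed)
    direction = rng.normal(size=config.d)
    direction /= np.linalg.norm(direction)
    shift = (config.witness_shift * direction).astype(np.float32)

    n_pos = int(round(config.class_balance * config.n_bags))
    labels = np.array([1] * n_pos + [0] * (config.n_bags - n_pos))
    rng.shuffle(labels)

    lo, hi = config.bag_size_range
    bags: list[Bag] = []
    for idx, label in enumerate(labels):
        n = int(rng.integers(lo, hi + 1))
        H = rng.normal(scale=config.noise_scale, size=(n, config.d)).astype(
            np.float32
        )
        inst = np.zeros(n, dtype=np.int64)
        if label == 1:
            n_wit = max(1, int(rng.binomial(n, config.witness_rate)))
            wit_idx = rng.choice(n, size=n_wit, replace=False)
            H[wit_idx] += shift
            inst[wit_idx] = 1
        bags.append(
            Bag(
                instances=H,
                label=int(label),
                instance_labels=inst,
                slide_id=f"synthetic-{idx:04d}",
            )
        )
    return bags


@dataclass
class SlideGenConfig:
    """Geometry and content of a generated pyramidal slide."""

    base_size: int = 4096
    n_levels: int = 4
    n_blobs: int = 3
    blob_radius_range: tuple[float, float] = (0.12, 0.2)  # fraction of base_size
    n_artifacts: int = 1
    n_signal_regions: int = 1
    tissue_color: tuple[int, int, int] = (188, 122, 158)  # eosin-like pink
    artifact_color: tuple[int, int, int] = (0, 168, 60)  # green marker pen
    background_color: tuple[int, int, int] = (252, 252, 252)

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 levels")
        if self.base_size % (2 ** (self.n_levels - 1)) != 0:
            raise ValueError("base_size must be divisible by 2**(n_levels-1)")


@dataclass
class SyntheticSlideTruth:
    """Ground truth for a generated slide, per pyramid level (base first)."""

    tissue_masks: list[np.ndarray]
    artifact_masks: list[np.ndarray]
    signal_masks: list[np.ndarray]
    background_color: tuple[int, int, int]

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.tissue_masks[0]


def _disk_mask(size: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def gen_slide(
    config: SlideGenConfig, seed: int = 0
) -> tuple[InMemoryPyramid, SyntheticSlideTruth]:
    """Generate a pyramid plus ground-truth masks; deterministic per seed.

    Coarser levels are exact ``[::2, ::2]`` decimations of the base for both
    images and masks, so level arithmetic is checkable without interpolation
    ambiguity.
    """
    rng = np.random.default_rng(seed)
    S = config.base_size
    tissue = np.zeros((S, S), dtype=bool)
    for _ in range(config.n_blobs):
        r = rng.uniform(*config.blob_radius_range) * S
        cx = rng.uniform(r, S - r)
        cy = rng.uniform(r, S - r)
        tissue |= _disk_mask(S, cx, cy, r)

    img = np.empty((S, S, 3), dtype=np.float32)
    img[:] = np.array(config.background_color, dtype=np.float32)

    if tissue.any():
        # smooth per-channel color variation so tissue is not flat-colored:
        # bilinear zoom to an S/8 grid, then nearest upsample to full size
        low = rng.normal(size=(S // 64 + 1, S // 64 + 1, 3))
        mid = S // 8
        var = np.stack(
            [ndimage.zoom(low[..., c], mid / low.shape[0], order=1)[:mid, :mid]
             for c in range(3)],
            axis=-1,
        )
        var = np.repeat(np.repeat(var, 8, axis=0), 8, axis=1)[:S, :S]
        tissue_rgb = np.array(config.tissue_color, dtype=np.float32) + 12.0 * var
        img[tissue] = tissue_rgb[tissue]

    signal = np.zeros((S, S), dtype=bool)
    if tissue.any():
        ys, xs = np.nonzero(tissue)
        for _ in range(config.n_signal_regions):
            j = rng.integers(len(xs))
            r = 0.04 * S
            reg = _disk_mask(S, xs[j], ys[j], r) & tissue
            signal |= reg
        if signal.any():
            # denser, darker dotted texture inside signal regions
            yy, xx = np.nonzero(signal)
            dots = ((xx // 4) + (yy // 4)) % 2 == 0
            img[yy[dots], xx[dots]] *= 0.6

    artifact = np.zeros((S, S), dtype=bool)
    for _ in range(config.n_artifacts):
        x0 = rng.integers(0, S - S // 4)
        y0 = rng.integers(0, S - S // 16)
        artifact[y0 : y0 + S // 32, x0 : x0 + S // 4] = True
    if artifact.any():
        img[artifact] = np.array(config.artifact_color, dtype=np.float32)

    base = np.clip(img, 0, 255).astype(np.uint8)
    levels = [base]
    tms, ams, sms = [tissue], [artifact], [signal]
    for _ in range(config.n_levels - 1):
        levels.append(levels[-1][::2, ::2])
        tms.append(tms[-1][::2, ::2])
        ams.append(ams[-1][::2, ::2])
        sms.append(sms[-1][::2, ::2])
    truth = SyntheticSlideTruth(
        tissue_masks=tms,
        artifact_masks=ams,
        signal_masks=sms,
        background_color=config.background_color,
    )
    return InMemoryPyramid(levels), truth
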