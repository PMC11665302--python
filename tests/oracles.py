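"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written in plain Python loops (or the most
naive vectorized form possible), sharing no code with the package internals
it checks.
"""

from __future__ import annotations

import math

import numpy as np


def scalar_attention_weights(H, V, w, activation: str):
    """Hand-unrolled attention: logits w^T act(V h_i), then softmax."""
    n = len(H)
    logits = []
    for i in range(n):
        s = 0.0
        for k in range(len(w)):
            t = 0.0
            for j in range(len(H[i])):
                t += V[k][j] * H[i][j]
            if activation == "tanh":
                u = math.tanh(t)
            else:
                u = t if t > 0 else 0.01 * t
            s += w[k] * u
        logits.append(s)
    m = max(logits)
    exps = [math.exp(s - m) for s in logits]
    z = sum(exps)
    return [e / z for e in exps]


def scalar_softmax(logits):
    m = max(logits)
    exps = [math.exp(v - m) for v in logits]
    z = sum(exps)
    return [e / z for e in exps]


def scalar_amil_forward(H, V, w, W, b, activation="tanh"):
    """Hand-unrolled attention pooling: head applied to sum_i a_i h_i."""
    a = scalar_attention_weights(H, V, w, activation)
    d = len(H[0])
    pooled = [sum(a[i] * H[i][j] for i in range(len(H))) for j in range(d)]
    logits = [
        sum(W[c][j] * pooled[j] for j in range(d)) + b[c] for c in range(len(b))
    ]
    return scalar_softmax(logits), a, logits


def scalar_admil_forward(H, V, w, W, b, activation="leaky_relu"):
    """Hand-unrolled additive head: per-patch logits psi_p(a_i h_i), summed."""
    a = scalar_attention_weights(H, V, w, activation)
    n, d, C = len(H), len(H[0]), len(b)
    patch = [
        [sum(W[c][j] * a[i] * H[i][j] for j in range(d)) + b[c] for c in range(C)]
        for i in range(n)
    ]
    bag_logits = [sum(patch[i][c] for i in range(n)) for c in range(C)]
    return scalar_softmax(bag_logits), a, bag_logits, patch


def mean_pool_forward(H, W, b):
    """Attention-free reference: head applied to the plain instance mean."""
    H = np.asarray(H, dtype=np.float64)
    pooled = H.mean(axis=0)
    logits = W @ pooled + b
    e = np.exp(logits - logits.max())
    return e / e.sum()


def auc_bruteforce(labels, scores) -> float:
    """All-pairs concordance count, ties at half credit."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def _gray(rgb):
    # ITU-R 601 luma, identical weights to skimage.color.rgb2gray
    return (
        0.2125 * rgb[..., 0] + 0.7154 * rgb[..., 1] + 0.0721 * rgb[..., 2]
    ) / 255.0


def count_accepted_tiles_bruteforce(
    pyramid,
    target_level: int,
    target_downsample: float,
    tissue_threshold: float,
    color_threshold: float,
    closing_size: int = 3,
    tile_px: int = 512,
) -> int:
    """Pixel-by-pixel re-enactment of the tile acceptance rules.

    Thumbnail Otsu -> darker class -> explicit 3x3 closing (dilate then
    erode, loops) -> color-distance filter against the mean tissue color ->
    map each surviving pixel to its covering tile -> fetch each candidate,
    pad, and count dark pixels against the same Otsu threshold.
    """
    from skimage.filters import threshold_otsu

    thumb = pyramid.thumbnail().astype(np.float64)
    H, W = thumb.shape[:2]
    gray = _gray(thumb)
    thr = threshold_otsu(gray)
    mask = gray < thr

    r = closing_size // 2
    dil = np.zeros_like(mask)
    for y in range(H):
        for x in range(W):
            y0, y1 = max(0, y - r), min(H, y + r + 1)
            x0, x1 = max(0, x - r), min(W, x + r + 1)
            dil[y, x] = mask[y0:y1, x0:x1].any()
    closed = np.zeros_like(mask)
    for y in range(H):
        for x in range(W):
            y0, y1 = max(0, y - r), min(H, y + r + 1)
            x0, x1 = max(0, x - r), min(W, x + r + 1)
            closed[y, x] = dil[y0:y1, x0:x1].all()

    pix = [(x, y) for y in range(H) for x in range(W) if closed[y, x]]
    if not pix:
        return 0
    mean = np.mean([thumb[y, x, :3] for x, y in pix], axis=0)
    kept = [
        (x, y)
        for x, y in pix
        if math.dist(thumb[y, x, :3], mean) <= color_threshold
    ]
    if not kept:
        return 0
    kept_set = set(kept)
    bg_pix = [
        thumb[y, x, :3]
        for y in range(H)
        for x in range(W)
        if (x, y) not in kept_set
    ]
    bg = np.round(np.mean(bg_pix, axis=0)) if bg_pix else np.full(3, 255.0)

    thumb_ds = pyramid.level_downsamples[-1]
    step = tile_px * target_downsample
    tiles = set()
    for x, y in kept:
        bx, by = x * thumb_ds, y * thumb_ds
        tiles.add((int(bx // step), int(by // step)))

    lw, lh = pyramid.level_dimensions[target_level]
    accepted = 0
    for ix, iy in sorted(tiles):
        x0, y0 = ix * tile_px, iy * tile_px
        if x0 >= lw or y0 >= lh:
            continue
        block = pyramid.region(target_level, x0, y0, tile_px, tile_px)
        padded = np.empty((tile_px, tile_px, 3), dtype=np.float64)
        padded[:] = bg
        padded[: block.shape[0], : block.shape[1]] = block[..., :3]
        frac = np.mean(_gray(padded) < thr)
        if frac >= tissue_threshold:
            accepted += 1
    return accepted
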