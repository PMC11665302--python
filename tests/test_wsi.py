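"""Unit tests for the slide preprocessing operations."""

import numpy as np
import pandas as pd
import pytest

from slidemil.wsi import (
    AugmentParams,
    SlideMetadata,
    TileRecord,
    accept_tile,
    apply_augmentation,
    artifact_filter,
    augment_tile,
    background_mean_color,
    cluster_sample,
    expand_to_children,
    extract_metadata,
    map_thumb_to_tiles,
    read_metadata_csv,
    sample_fraction,
    tissue_mask,
    write_metadata_csv,
)


def _disk_image(size=128, center=(64, 64), radius=30, fg=(120, 60, 90), bg=255):
    img = np.full((size, size, 3), bg, dtype=np.uint8)
    yy, xx = np.ogrid[:size, :size]
    mask = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2
    img[mask] = fg
    return img, mask


class TestMetadata:
    def test_fields_pass_through_and_round_trip(self, tmp_path):
        slides = [
            SlideMetadata("s1", 1, "FFPE", 2.0),
            SlideMetadata("s2", 0, "frozen", 0.25),
        ]
        table = extract_metadata(slides)
        assert table.loc[0, "mpp"] == 2.0
        assert table["valid"].all()
        path = tmp_path / "meta.csv"
        write_metadata_csv(table, path)
        back = read_metadata_csv(path)
        pd.testing.assert_frame_equal(back, table)

    @pytest.mark.parametrize(
        "slide",
        [
            SlideMetadata("bad", None, "FFPE", 2.0),  # absent label
            SlideMetadata("bad", 1, "FFPE", None),  # absent mpp
            SlideMetadata("bad", 1, "FFPE", -1.0),  # nonphysical mpp
        ],
    )
    def test_incomplete_rows_flagged_invalid(self, slide):
        with pytest.warns(UserWarning, match="invalid"):
            table = extract_metadata([slide])
        assert not table.loc[0, "valid"]


class TestTissueMask:
    def test_uniform_thumbnail_yields_empty_set(self):
        white = np.full((32, 32, 3), 255, dtype=np.uint8)
        with pytest.warns(UserWarning):
            pixels = tissue_mask(white)
        assert pixels.is_empty

    def test_dark_disk_recovered_with_high_iou(self):
        img, truth = _disk_image()
        pixels = tissue_mask(img)
        inter = (pixels.mask & truth).sum()
        union = (pixels.mask | truth).sum()
        assert inter / union >= 0.9

    def test_closing_fills_single_pixel_hole(self):
        img, truth = _disk_image()
        img[64, 64] = 255  # a 1-px hole inside tissue
        pixels = tissue_mask(img, closing_size=3)
        assert pixels.mask[64, 64]


class TestArtifactFilter:
    def test_pixel_at_mean_color_retained_at_zero_threshold(self):
        img = np.full((8, 8, 3), 100, dtype=np.uint8)
        img[:4] = 30  # darker half = tissue
        pixels = tissue_mask(img, closing_size=1)
        kept = artifact_filter(pixels, img, threshold=0.0)
        assert kept.coords.shape[0] == pixels.coords.shape[0]

    def test_green_marker_removed_from_pink_tissue(self):
        # dark-green marker pixel sits ~254 RGB units from the tissue mean
        img = np.full((20, 20, 3), 255, dtype=np.uint8)
        img[5:15, 5:15] = (200, 150, 160)
        img[10, 10] = (0, 130, 0)
        pixels = tissue_mask(img, closing_size=1)
        assert any((pixels.coords == [10, 10]).all(axis=1))
        kept = artifact_filter(pixels, img, threshold=100.0)
        assert not any((kept.coords == [10, 10]).all(axis=1))
        assert kept.coords.shape[0] >= pixels.coords.shape[0] - 2

    def test_infinite_threshold_keeps_everything(self):
        img, _ = _disk_image()
        pixels = tissue_mask(img)
        kept = artifact_filter(pixels, img, threshold=np.inf)
        np.testing.assert_array_equal(kept.coords, pixels.coords)

    def test_negative_threshold_rejected(self):
        img, _ = _disk_image()
        pixels = tissue_mask(img)
        with pytest.raises(ValueError):
            artifact_filter(pixels, img, threshold=-1.0)


def _pixelset(coords, shape=(64, 64)):
    from slidemil.wsi import TissuePixelSet

    coords = np.asarray(coords, dtype=np.int64)
    mask = np.zeros(shape, dtype=bool)
    mask[coords[:, 1], coords[:, 0]] = True
    return TissuePixelSet(coords=coords, mean_color=np.zeros(3), mask=mask)


class TestMapThumbToTiles:
    def test_origin_maps_to_origin_tile(self):
        tiles = map_thumb_to_tiles(_pixelset([[0, 0]]), 64, 8)
        assert (tiles[0].x, tiles[0].y) == (0, 0)

    def test_base_coordinate_arithmetic(self):
        # thumb (10,20) at downsample 64 -> base (640,1280) -> tile (0,0) at
        # level downsample 8 since 640 < 512*8
        tiles = map_thumb_to_tiles(_pixelset([[10, 20]]), 64, 8)
        assert len(tiles) == 1
        assert (tiles[0].x, tiles[0].y) == (0, 0)

    def test_pixels_in_same_footprint_deduplicate(self):
        tiles = map_thumb_to_tiles(_pixelset([[0, 0], [1, 1], [40, 0]]), 64, 1)
        assert [(t.x, t.y) for t in tiles] == [(0, 0), (2560, 0)]

    def test_row_major_ordering(self):
        tiles = map_thumb_to_tiles(_pixelset([[40, 40], [0, 40], [40, 0]]), 64, 1)
        assert [(t.x, t.y) for t in tiles] == [(2560, 0), (0, 2560), (2560, 2560)]

    def test_target_coarser_than_thumbnail_rejected(self):
        with pytest.raises(ValueError):
            map_thumb_to_tiles(_pixelset([[0, 0]]), 8, 64)


class TestAcceptTile:
    def test_saturated_tissue_tile_accepted_with_full_fraction(self):
        tile = np.full((512, 512, 3), 40, dtype=np.uint8)
        rec, img = accept_tile(tile, 0.3, np.full(3, 255.0), otsu_threshold=0.5)
        assert rec.status == "accepted"
        assert rec.tissue_fraction == 1.0

    def test_background_tile_rejected(self):
        tile = np.full((512, 512, 3), 250, dtype=np.uint8)
        rec, _ = accept_tile(tile, 0.3, np.full(3, 255.0), otsu_threshold=0.5)
        assert rec.status == "rejected"
        assert rec.tissue_fraction == 0.0

    def test_undersized_half_tissue_tile_padded_then_rejected(self):
        # 300x512 tile, half tissue: fraction (0.5*300*512)/512^2 ~ 0.293 < 0.3
        tile = np.full((300, 512, 3), 250, dtype=np.uint8)
        tile[:150] = 40
        rec, img = accept_tile(tile, 0.3, np.full(3, 250.0), otsu_threshold=0.5)
        assert img.shape == (512, 512, 3)
        assert rec.tissue_fraction == pytest.approx(150 * 512 / 512**2)
        assert rec.status == "rejected"

    def test_undersized_tissue_tile_padded_and_accepted(self):
        tile = np.full((400, 512, 3), 40, dtype=np.uint8)
        rec, _ = accept_tile(tile, 0.3, np.full(3, 250.0), otsu_threshold=0.5)
        assert rec.status == "padded+accepted"

    def test_oversized_tile_rejected_as_contract_violation(self):
        with pytest.raises(ValueError):
            accept_tile(np.zeros((600, 512, 3), np.uint8), 0.3, np.full(3, 255.0))


class TestSampling:
    def test_fraction_sampling_above_limit(self):
        tiles = [TileRecord("5x", i * 512, 0) for i in range(100)]
        out = sample_fraction(tiles, fraction=0.6, limit=50, seed=0)
        assert len(out) == 60

    def test_below_limit_returns_all(self):
        tiles = [TileRecord("5x", i * 512, 0) for i in range(40)]
        assert sample_fraction(tiles, fraction=0.6, limit=50, seed=0) == tiles

    def test_seeded_determinism(self):
        tiles = [TileRecord("5x", i * 512, 0) for i in range(100)]
        s1 = sample_fraction(tiles, limit=50, seed=9)
        s2 = sample_fraction(tiles, limit=50, seed=9)
        assert [(t.x, t.y) for t in s1] == [(t.x, t.y) for t in s2]


class TestClusterSample:
    @staticmethod
    def _clustered_embeddings(sizes, seed=0):
        rng = np.random.default_rng(seed)
        chunks, tiles = [], []
        for c, size in enumerate(sizes):
            center = np.zeros(4)
            center[c % 4] = 50.0 * (c + 1)
            chunks.append(center + rng.normal(size=(size, 4)))
            tiles += [TileRecord("5x", len(tiles) * 512 + i, 0) for i in range(size)]
        return np.vstack(chunks), tiles

    def test_per_cluster_cap(self):
        E, tiles = self._clustered_embeddings([25, 10, 5])
        out = cluster_sample(E, tiles, k=3, n_per_cluster=20, seed=1)
        assert len(out) == 20 + 10 + 5

    def test_single_cluster_reduces_to_uniform_sample(self):
        E, tiles = self._clustered_embeddings([30])
        out = cluster_sample(E, tiles, k=1, n_per_cluster=20, seed=2)
        assert len(out) == 20

    def test_seeded_determinism(self):
        E, tiles = self._clustered_embeddings([25, 10, 5])
        o1 = cluster_sample(E, tiles, k=3, n_per_cluster=7, seed=3)
        o2 = cluster_sample(E, tiles, k=3, n_per_cluster=7, seed=3)
        assert [(t.x, t.y) for t in o1] == [(t.x, t.y) for t in o2]

    def test_k_above_tile_count_is_clamped(self):
        E, tiles = self._clustered_embeddings([3])
        with pytest.warns(UserWarning, match="clamped"):
            out = cluster_sample(E, tiles, k=10, n_per_cluster=5, seed=0)
        assert len(out) == 3


class TestExpandToChildren:
    def test_factor_two_expansion_enumerates_quadrants(self):
        children = expand_to_children(TileRecord("5x", 0, 0), 4, 2)
        assert {(c.x, c.y) for c in children} == {
            (0, 0), (512, 0), (0, 512), (512, 512)
        }

    def test_unit_ratio_is_identity(self):
        children = expand_to_children(TileRecord("5x", 1024, 512), 4, 4)
        assert [(c.x, c.y) for c in children] == [(1024, 512)]

    def test_children_exactly_tile_parent_footprint_in_base_coords(self):
        parent = TileRecord("5x", 1024, 512)
        children = expand_to_children(parent, 4, 1)
        corners = {(c.x, c.y) for c in children}
        xs = sorted({c.x for c in children})
        ys = sorted({c.y for c in children})
        assert xs == [4096, 4608, 5120, 5632]
        assert ys == [2048, 2560, 3072, 3584]
        # union spans exactly the parent footprint [4096, 6144) x [2048, 4096)
        assert xs[0] == parent.x * 4 and xs[-1] + 512 == (parent.x + 512) * 4
        assert ys[0] == parent.y * 4 and ys[-1] + 512 == (parent.y + 512) * 4
        assert len(children) == 16 == len(corners)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            expand_to_children(TileRecord("5x", 0, 0), 3, 2)


class TestAugmentation:
    def test_identity_parameters_leave_tile_unchanged(self):
        rng = np.random.default_rng(0)
        tile = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        out = apply_augmentation(tile, AugmentParams.identity())
        np.testing.assert_array_equal(out, tile)

    def test_horizontal_flip_is_an_involution(self):
        rng = np.random.default_rng(1)
        tile = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        p = AugmentParams.identity()
        p.flip_horizontal = True
        once = apply_augmentation(tile, p)
        twice = apply_augmentation(once, p)
        np.testing.assert_array_equal(twice, tile)

    def test_seeded_augmentations_are_reproducible(self):
        rng = np.random.default_rng(2)
        tile = rng.integers(0, 256, size=(512, 512, 3), dtype=np.uint8)
        a1 = augment_tile(tile, seed=7)
        a2 = augment_tile(tile, seed=7)
        assert len(a1) == 2
        for x, y in zip(a1, a2):
            np.testing.assert_array_equal(x, y)
            assert x.dtype == tile.dtype

    def test_wrong_tile_size_rejected(self):
        with pytest.raises(ValueError):
            augment_tile(np.zeros((64, 64, 3), np.uint8), seed=0)


class TestBackgroundColor:
    def test_mean_of_non_tissue_pixels(self):
        img = np.full((4, 4, 3), 200, dtype=np.uint8)
        img[0, 0] = 0
        pixels = _pixelset([[0, 0]], shape=(4, 4))
        np.testing.assert_allclose(
            background_mean_color(img, pixels), [200, 200, 200]
        )
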