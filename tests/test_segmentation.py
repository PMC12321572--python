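"""Binarization and object extraction against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import ndimage

from arraytomo.config import PipelineConfig
from arraytomo.segmentation import (
    BinaryStack,
    extract_objects,
    flag_somatic,
    local_threshold,
    segment_channel,
    subtract_background_median,
)
from arraytomo.stacks import MultiChannelStack, VoxelGeometry


def brute_force_median_subtract(image, radius):
    """O(n^2 w^2) reference: disk-footprint median under symmetric padding."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = (xx * xx + yy * yy) <= radius * radius
    padded = np.pad(image, radius, mode="symmetric")
    out = np.empty_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            win = padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1]
            out[i, j] = image[i, j] - np.median(win[disk])
    return np.clip(out, 0.0, None)


def brute_force_local_threshold(image, window, offset):
    """O(n^2 w^2) reference for the mean + k*SD rule (symmetric padding)."""
    r = window // 2
    padded = np.pad(image.astype(float), r, mode="symmetric")
    out = np.zeros(image.shape, dtype=bool)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            win = padded[i : i + window, j : j + window]
            out[i, j] = image[i, j] > win.mean() + offset * win.std()
    return out


class TestBackgroundSubtraction:
    def test_constant_image_to_zeros(self):
        assert (subtract_background_median(np.full((40, 40), 7.0), 5) == 0).all()

    def test_never_negative(self, rng):
        img = rng.random((30, 30)) * 100
        assert (subtract_background_median(img, 4) >= 0).all()

    def test_matches_brute_force_median(self, rng):
        img = rng.random((24, 24)) * 50
        got = subtract_background_median(img, 3)
        want = brute_force_median_subtract(img, 3)
        assert np.allclose(got, want, atol=1e-9)

    def test_punctum_preserved_on_flat_background(self):
        img = np.full((64, 64), 10.0)
        img[30:34, 30:34] += 120.0  # punctum much smaller than the radius
        out = subtract_background_median(img, 15)
        assert out[31, 31] == pytest.approx(120.0, rel=0.05)

    def test_radius_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            subtract_background_median(np.zeros((20, 20)), 15)

    def test_downsampled_background_close_to_exact(self, rng):
        img = rng.random((64, 64)) * 20 + 50
        exact = subtract_background_median(img, 8, downsample=1)
        fast = subtract_background_median(img, 8, downsample=4)
        assert np.abs(exact - fast).mean() < 2.0


class TestLocalThreshold:
    def test_constant_image_all_negative(self):
        assert not local_threshold(np.full((32, 32), 5.0), 15, 0.5).any()

    def test_matches_brute_force_on_random_image(self, rng):
        img = rng.random((32, 32)) * 100
        got = local_threshold(img, 9, 0.5)
        want = brute_force_local_threshold(img, 9, 0.5)
        assert np.array_equal(got, want)

    @given(
        img=arrays(
            np.float64, (16, 16),
            elements=st.floats(0, 100, allow_nan=False, allow_infinity=False),
        )
    )
    def test_monotone_in_offset(self, img):
        low = local_threshold(img, 7, 0.5).sum()
        high = local_threshold(img, 7, 1.5).sum()
        assert high <= low

    def test_window_validation(self):
        with pytest.raises(ValueError, match="window"):
            local_threshold(np.zeros((16, 16)), window=8)

    def test_blob_recovery_at_snr5_with_matched_filter(self, rng):
        """Blobs at signal-to-noise 5: per-pixel recall and precision >= 0.9
        against the noise-free segmentation of the same field, using the
        low-SNR operating point (PSF-scale pre-smoothing enabled)."""
        clean = np.zeros((96, 96))
        for i, j in [(20, 20), (20, 70), (48, 48), (70, 25), (75, 70)]:
            clean[i - 3 : i + 4, j - 3 : j + 4] = 100.0
        clean = ndimage.gaussian_filter(clean, 1.0)
        noise_sd = clean.max() / 5.0
        noisy = clean + rng.normal(0, noise_sd, clean.shape)
        smooth = 1.0  # matched filter at PSF scale
        truth = local_threshold(ndimage.gaussian_filter(clean, smooth), 31, 2.5)
        got = local_threshold(ndimage.gaussian_filter(noisy, smooth), 31, 2.5)
        tp = (got & truth).sum()
        recall = tp / truth.sum()
        precision = tp / got.sum()
        assert recall >= 0.9 and precision >= 0.9


class TestExtractObjects:
    def _table(self, mask, **kw):
        stack = BinaryStack(mask=mask, channel="SYO", geometry=VoxelGeometry())
        return extract_objects(stack, PipelineConfig(), **kw)

    def test_single_section_component_removed(self):
        mask = np.zeros((5, 16, 16), dtype=bool)
        mask[2, 4:8, 4:8] = True  # speckle: one section only
        mask[0:3, 10:13, 10:13] = True  # real object: three sections
        table = self._table(mask, min_volume_voxels=1, split_touching=False)
        assert len(table) == 1
        assert table.df.iloc[0]["n_sections"] == 3

    def test_physical_volume_arithmetic(self):
        # 120 voxels at 0.1 x 0.1 x 0.07 um -> 0.084 um^3
        mask = np.zeros((4, 16, 16), dtype=bool)
        mask[0, 2:7, 2:10] = True  # 40 voxels
        mask[1, 2:7, 2:10] = True
        mask[2, 2:7, 2:10] = True
        table = self._table(mask, min_volume_voxels=1, split_touching=False)
        assert len(table) == 1
        assert table.df.iloc[0]["n_voxels"] == 120
        assert table.df.iloc[0]["volume_um3"] == pytest.approx(0.084, abs=1e-12)

    def test_diagonal_voxels_connected_in_26_neighbourhood(self):
        mask = np.zeros((3, 8, 8), dtype=bool)
        mask[0, 2, 2] = True
        mask[1, 3, 3] = True  # touches only diagonally across sections
        table = self._table(mask, min_volume_voxels=1, min_section_span=1,
                            split_touching=False)
        assert len(table) == 1

    def test_empty_mask_empty_table(self):
        table = self._table(np.zeros((3, 8, 8), dtype=bool))
        assert len(table) == 0

    def test_touching_puncta_are_split(self):
        """Two overlapping spheres 0.5 um apart become two objects."""
        g = VoxelGeometry()
        z, y, x = np.mgrid[0:12, 0:24, 0:24]
        zz, yy, xx = z * g.dz, y * g.dy, x * g.dx
        s1 = ((xx - 0.7) ** 2 + (yy - 1.2) ** 2 + (zz - 0.42) ** 2) <= 0.3**2
        s2 = ((xx - 1.2) ** 2 + (yy - 1.2) ** 2 + (zz - 0.42) ** 2) <= 0.3**2
        merged = self._table(s1 | s2, split_touching=False)
        split = self._table(s1 | s2, split_touching=True)
        assert len(merged) == 1
        assert len(split) == 2

    def test_isolated_punctum_not_split(self):
        g = VoxelGeometry()
        z, y, x = np.mgrid[0:12, 0:16, 0:16]
        zz, yy, xx = z * g.dz, y * g.dy, x * g.dx
        ell = (
            ((xx - 0.8) / 0.3) ** 2 + ((yy - 0.8) / 0.3) ** 2 + ((zz - 0.42) / 0.2) ** 2
        ) <= 1
        assert len(self._table(ell, split_touching=True)) == 1


class TestSegmentChannel:
    def test_idempotent_on_binary_rendering(self):
        """Segmenting the 200x rendering of a segmented mask reproduces it."""
        g = VoxelGeometry()
        mask = np.zeros((8, 48, 48), dtype=bool)
        for (k, i, j) in [(2, 10, 10), (3, 30, 35), (4, 20, 24)]:
            mask[k - 1 : k + 2, i - 2 : i + 3, j - 2 : j + 3] = True
        stack = MultiChannelStack(
            channels={"SYO": mask * 200.0}, geometry=g
        )
        got = segment_channel(stack, "SYO", PipelineConfig())
        assert np.array_equal(got.mask, mask)
        t1 = extract_objects(got, PipelineConfig(), min_volume_voxels=1)
        t2 = extract_objects(
            BinaryStack(mask=mask, channel="SYO", geometry=g),
            PipelineConfig(), min_volume_voxels=1,
        )
        assert np.array_equal(np.sort(t1.df["n_voxels"]), np.sort(t2.df["n_voxels"]))


class TestFlagSomatic:
    def test_below_threshold_unflagged(self, rng):
        mask = np.zeros((4, 16, 16), dtype=bool)
        mask[1:3, 2:5, 2:5] = True
        stack = BinaryStack(mask=mask, channel="T22", geometry=VoxelGeometry())
        table = flag_somatic(extract_objects(stack, PipelineConfig()), 2.0)
        assert not table.df["somatic"].any()

    def test_large_aggregate_flagged_and_excluded_from_density(self):
        from arraytomo.quantify import density

        g = VoxelGeometry()
        mask = np.zeros((20, 64, 64), dtype=bool)
        mask[2:19, 5:45, 5:45] = True  # 17*40*40 voxels = 19.04 um^3 aggregate
        mask[0:3, 55:58, 55:58] = True  # small punctum
        stack = BinaryStack(mask=mask, channel="T22", geometry=g)
        table = flag_somatic(
            extract_objects(stack, PipelineConfig(), split_touching=False), 2.0
        )
        assert table.df["somatic"].sum() == 1
        flagged = table.df[table.df["somatic"]].iloc[0]
        assert flagged["volume_um3"] > 2.0
        # brute-force neuropil density: non-somatic count over analyzed volume
        want = (~table.df["somatic"]).sum() / table.analyzed_volume
        assert density(table, exclude_somatic=True) == pytest.approx(want, rel=1e-12)
        assert density(table, exclude_somatic=False) == pytest.approx(
            len(table.df) / table.analyzed_volume, rel=1e-12
        )
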