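import numpy as np
import pytest

from cartfilm import (
    ContactMask,
    ParticleDetector,
    PipelineSettings,
    apply_contact_mask,
    disk_structuring_element,
    label_particles,
    measure_particles,
    morphological_open,
    process_frame,
    process_stack,
    threshold_binarize,
    white_tophat,
)
from cartfilm.io_formats import ImageStack


def bruteforce_open(img, se):
    """Sliding min then max over the SE, clipped at the frame border."""
    pad = tuple(s // 2 for s in se.shape)
    big = np.iinfo(img.dtype).max if img.dtype.kind in "ui" else np.inf
    small = np.iinfo(img.dtype).min if img.dtype.kind in "ui" else -np.inf

    def slide(arr, fill, agg):
        p = np.pad(arr, ((pad[0], pad[0]), (pad[1], pad[1])),
                   mode="constant", constant_values=fill)
        stack = []
        for dy in range(se.shape[0]):
            for dx in range(se.shape[1]):
                if se[dy, dx]:
                    stack.append(p[dy:dy + arr.shape[0], dx:dx + arr.shape[1]])
        return agg(np.stack(stack), axis=0)

    ero = slide(img, big, np.min)
    return slide(ero, small, np.max)


class TestStructuringElement:
    def test_width_one_is_single_pixel(self):
        np.testing.assert_array_equal(disk_structuring_element(1), [[1]])

    def test_width_three_is_plus(self):
        np.testing.assert_array_equal(
            disk_structuring_element(3), [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
        )

    @pytest.mark.parametrize("width", [1, 3, 5, 7, 13, 15])
    def test_rotation_symmetry_and_radius_rule(self, width):
        se = disk_structuring_element(width)
        np.testing.assert_array_equal(se, np.rot90(se))
        np.testing.assert_array_equal(se, se[::-1, ::-1])
        # direct enumeration of the distance rule
        r = (width - 1) / 2
        half = se.shape[0] // 2
        for dy in range(-half, half + 1):
            for dx in range(-half, half + 1):
                assert se[dy + half, dx + half] == (dy**2 + dx**2 <= r**2 + 1e-9)

    def test_width_below_one_rejected(self):
        with pytest.raises(ValueError):
            disk_structuring_element(0)


class TestContactMask:
    def test_covering_mask_is_identity(self):
        frame = np.full((10, 10), 7.0)
        mask = ContactMask(5, 5, 100)
        np.testing.assert_array_equal(apply_contact_mask(frame, mask), frame)

    def test_half_pixel_radius_keeps_one_pixel(self):
        frame = np.ones((5, 5))
        out = apply_contact_mask(frame, ContactMask(2, 3, 0.5))
        assert out.sum() == 1
        assert out[3, 2] == 1

    def test_masked_sum_matches_per_pixel_oracle(self, rng):
        frame = rng.random((20, 24))
        mask = ContactMask(11.0, 9.0, 6.5)
        expected = sum(
            frame[y, x]
            for y in range(20)
            for x in range(24)
            if (y - 9.0) ** 2 + (x - 11.0) ** 2 <= 6.5**2
        )
        assert apply_contact_mask(frame, mask).sum() == pytest.approx(expected)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            ContactMask(0, 0, 0.0)


class TestOpening:
    def test_constant_frame_unchanged(self):
        frame = np.full((9, 9), 13, dtype=np.uint8)
        se = disk_structuring_element(3)
        np.testing.assert_array_equal(morphological_open(frame, se), frame)

    def test_single_bright_pixel_removed(self):
        frame = np.zeros((7, 7), dtype=np.uint8)
        frame[3, 3] = 200
        out = morphological_open(frame, disk_structuring_element(3))
        np.testing.assert_array_equal(out, bruteforce_open(frame, disk_structuring_element(3)))
        assert out[3, 3] == 0

    def test_idempotent_and_antiextensive(self, rng):
        se = disk_structuring_element(5)
        for _ in range(10):
            frame = rng.integers(0, 255, (32, 32)).astype(np.uint8)
            once = morphological_open(frame, se)
            assert np.all(once <= frame)
            np.testing.assert_array_equal(morphological_open(once, se), once)

    def test_se_larger_than_frame_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            morphological_open(np.zeros((4, 4)), disk_structuring_element(9))


class TestWhiteTophat:
    def test_constant_maps_to_zero(self):
        frame = np.full((8, 8), 42, dtype=np.uint16)
        out = white_tophat(frame, disk_structuring_element(3))
        assert out.max() == 0

    def test_isolated_pixel_preserved(self):
        frame = np.zeros((7, 7), dtype=np.uint8)
        frame[2, 4] = 77
        out = white_tophat(frame, disk_structuring_element(3))
        assert out[2, 4] == 77
        assert out.sum() == 77

    def test_ramp_plus_blob_equals_oracle(self, rng):
        # a linear background ramp with one narrow blob: the top-hat keeps
        # the blob and removes the ramp, matching the brute-force oracle
        ramp = np.add.outer(np.arange(16), np.arange(16)).astype(np.int64) * 3
        frame = ramp.copy()
        frame[8, 8] += 120
        se = disk_structuring_element(5)
        out = white_tophat(frame, se)
        np.testing.assert_array_equal(out, frame - bruteforce_open(frame, se))
        assert out[8, 8] >= 100

    def test_nonnegative_and_translation_equivariant(self, rng):
        se = disk_structuring_element(3)
        frame = rng.integers(0, 100, (24, 24)).astype(np.uint8)
        out = white_tophat(frame, se)
        assert np.all(out >= 0)
        shifted = np.roll(frame, (3, 5), axis=(0, 1))
        # equivariance away from wrap-around seams and border-clip halos
        a = white_tophat(shifted, se)[8:-8, 8:-8]
        b = np.roll(out, (3, 5), axis=(0, 1))[8:-8, 8:-8]
        np.testing.assert_array_equal(a, b)


class TestThreshold:
    def test_all_below_gives_empty(self):
        assert threshold_binarize(np.full((5, 5), 3.0), 4.0).sum() == 0

    def test_zero_threshold_gives_all_ones(self):
        assert threshold_binarize(np.zeros((5, 5)), 0.0).min() == 1

    def test_elementwise_oracle(self, rng):
        frame = rng.integers(0, 10, (12, 12))
        out = threshold_binarize(frame, 4)
        np.testing.assert_array_equal(out, (frame >= 4).astype(np.uint8))

    def test_raising_threshold_never_increases_count(self, rng):
        # well-separated unimodal blobs of mixed brightness: each shrinks
        # monotonically as the threshold rises, so counts never increase
        mask = ContactMask(32, 32, 40)
        yy, xx = np.mgrid[:64, :64]
        frame = np.zeros((64, 64))
        for (cy, cx), amp in zip([(12, 12), (12, 48), (48, 12), (48, 48),
                                  (30, 30)], (8, 15, 22, 29, 36)):
            frame += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0**2))
        counts = [
            len(label_particles(threshold_binarize(frame, tau), mask))
            for tau in np.arange(0.5, 40.0, 1.5)
        ]
        assert counts[0] == 5
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestLabeling:
    def test_two_disjoint_squares(self, small_mask):
        binary = np.zeros((20, 20), np.uint8)
        binary[2:5, 2:5] = 1
        binary[10:13, 10:13] = 1
        parts = label_particles(binary, small_mask)
        assert len(parts) == 2
        assert sorted(parts.particles["area_px"]) == [9, 9]

    def test_diagonal_pixels_connect(self, small_mask):
        binary = np.zeros((6, 6), np.uint8)
        binary[2, 2] = binary[3, 3] = 1
        assert len(label_particles(binary, small_mask)) == 1

    def test_planted_blobs_counted(self, small_mask, rng):
        binary = np.zeros((64, 64), np.uint8)
        centers = [(10, 10), (10, 40), (40, 10), (40, 40), (25, 25)]
        for cy, cx in centers:
            binary[cy - 1:cy + 2, cx - 1:cx + 2] = 1
        assert len(label_particles(binary, small_mask)) == len(centers)


class TestMeasurement:
    def test_single_pixel_diameter(self, small_mask):
        binary = np.zeros((8, 8), np.uint8)
        binary[4, 4] = 1
        parts = measure_particles(label_particles(binary, small_mask), 3.75)
        expected = 2 * np.sqrt(1 / np.pi) * 3.75
        assert parts.particles["diameter_um"].iloc[0] == pytest.approx(expected)

    def test_diameter_inverts_disk_area(self, small_mask):
        r = 5
        yy, xx = np.mgrid[:32, :32]
        binary = ((yy - 16) ** 2 + (xx - 16) ** 2 <= r**2).astype(np.uint8)
        area = binary.sum()
        parts = measure_particles(label_particles(binary, small_mask), 2.0)
        assert parts.particles["diameter_um"].iloc[0] == pytest.approx(
            2 * np.sqrt(area / np.pi) * 2.0
        )

    def test_linear_in_pixel_scale(self, small_mask):
        binary = np.zeros((8, 8), np.uint8)
        binary[3:5, 3:5] = 1
        p1 = measure_particles(label_particles(binary, small_mask), 1.0)
        p2 = measure_particles(label_particles(binary, small_mask), 2.0)
        assert (
            p2.particles["diameter_um"].iloc[0]
            == 2 * p1.particles["diameter_um"].iloc[0]
        )


class TestFramePipeline:
    def test_blank_frame(self, small_mask):
        res = process_frame(np.zeros((64, 64)), small_mask,
                            PipelineSettings(15, 4.0), 3.75)
        assert res.particle_count == 0
        assert np.isnan(res.mean_size)

    def test_single_planted_blob(self, small_mask):
        frame = np.full((64, 64), 40.0)
        yy, xx = np.mgrid[:64, :64]
        frame += 30 * np.exp(-((yy - 30) ** 2 + (xx - 30) ** 2) / (2 * 1.5**2))
        res = process_frame(frame, small_mask, PipelineSettings(15, 10.0), 3.75)
        assert res.particle_count == 1
        assert res.mean_size > 0

    def test_constant_stack_constant_trends(self, small_mask):
        frames = np.full((10, 64, 64), 25, dtype=np.uint16)
        stack = ImageStack(frames=frames, timestamps=np.arange(10.0),
                           pixel_scale=3.75)
        counts, sizes = process_stack(stack, small_mask, PipelineSettings(5, 3.0))
        assert len(counts) == len(sizes) == 10
        assert np.all(counts.value == counts.value[0])


class TestParticleDetector:
    def test_sklearn_protocol(self, small_mask):
        from sklearn.base import clone

        det = ParticleDetector(tophat_width=9, threshold=5.0, mask=small_mask)
        params = det.get_params()
        assert params["tophat_width"] == 9
        cloned = clone(det)
        assert cloned.get_params() == params
        det.set_params(threshold=7.0)
        assert det.threshold == 7.0

    def test_requires_mask(self):
        with pytest.raises(ValueError, match="ContactMask"):
            ParticleDetector().fit()

    def test_transform_matches_process_stack(self, small_spec):
        from cartfilm.synthetic import generate_contact_stack

        stack, _ = generate_contact_stack(small_spec)
        det = ParticleDetector(tophat_width=15, threshold=10.0,
                               mask=small_spec.mask).fit(stack)
        table = det.transform(stack)
        counts, sizes = process_stack(stack, small_spec.mask,
                                      PipelineSettings(15, 10.0))
        np.testing.assert_array_equal(table["particle_count"], counts.value)
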