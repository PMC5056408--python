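"""Sub-pixel localization, z profiling and tilt correction."""

import numpy as np
import pytest

from ctfm import lattice_sim as sim
from ctfm.detection import (DetectionError, DetectionParams, detect_xy,
                            detect_z, match_to_truth, tilt_correct)
from ctfm.lattice_sim import (ImagingSpec, LatticeSpec, NanodiscArray,
                              RenderedImage, stack_slice_z)


def _rms_nm(image, truth):
    res = detect_xy(image)
    di, ti = match_to_truth(res.positions.positions, truth)
    assert len(ti) == len(truth)
    err = res.positions.positions[di] - truth[ti]
    return 1e3 * np.sqrt((err ** 2).sum(axis=1).mean())


class TestDetectXY:
    def test_handwritten_island_weighted_centroid(self):
        """5x5 island with hand-picked greys vs an explicit arithmetic mean."""
        img = np.zeros((9, 9))
        grey = [[0, 40, 50, 0, 0],
                [30, 90, 120, 60, 0],
                [50, 140, 200, 110, 40],
                [0, 80, 130, 90, 0],
                [0, 0, 60, 30, 0]]
        img[2:7, 2:7] = grey
        thr = 25.0
        # oracle: plain-python weighted mean over supra-threshold pixels,
        # threshold-subtracted weights, pixel-centre convention
        sw = sx = sy = 0.0
        for r in range(9):
            for c in range(9):
                if img[r, c] > thr:
                    w = img[r, c] - thr
                    sw += w
                    sx += w * (c + 0.5) * 0.1
                    sy += w * (r + 0.5) * 0.1
        rendered = RenderedImage(data=img, pixel_size=0.1,
                                 origin=np.zeros(2))
        res = detect_xy(rendered, DetectionParams(threshold=thr,
                                                  split_merged=False))
        assert len(res.positions) == 1
        assert res.positions.positions[0] == pytest.approx(
            [sx / sw, sy / sw], abs=1e-12)

    def test_noise_free_round_trip_below_1nm(self):
        arr = sim.NanodiscArray(positions=np.array([[5.2143, 4.8767]]),
                                L0=1.5)
        img = sim.render_image(arr, ImagingSpec(noise_sd=0.0))
        assert _rms_nm(img, arr.positions) < 1.0

    def test_localization_error_within_paper_band(self):
        """RMS error at noise s.d. 10 is below 8 nm; degrades with noise."""
        arr = sim.make_lattice(LatticeSpec(L0=1.5, rows=12, cols=12))
        errs = []
        for noise in (0.0, 5.0, 10.0):
            pooled = []
            for s in range(3):
                img = sim.render_image(arr, ImagingSpec(noise_sd=noise),
                                       seed=s)
                pooled.append(_rms_nm(img, arr.positions))
            errs.append(np.mean(pooled))
        assert errs[-1] <= 8.0
        assert errs[0] < errs[1] < errs[2]

    def test_integer_pixel_translation_equivariance(self, noisy_image):
        res = detect_xy(noisy_image)
        shifted = RenderedImage(data=np.roll(noisy_image.data, (3, 5),
                                             axis=(0, 1)),
                                pixel_size=noisy_image.pixel_size,
                                origin=noisy_image.origin)
        res2 = detect_xy(shifted)
        dx = 5 * noisy_image.pixel_size
        dy = 3 * noisy_image.pixel_size
        di, ti = match_to_truth(res2.positions.positions,
                                res.positions.positions + [dx, dy])
        moved = res2.positions.positions[di] - res.positions.positions[ti]
        assert np.allclose(moved, [dx, dy], atol=1e-9)

    def test_count_matches_simulation(self, noisy_image, perfect_lattice):
        res = detect_xy(noisy_image)
        assert len(res.positions) == len(perfect_lattice)

    def test_flat_image_raises(self):
        img = RenderedImage(data=np.full((32, 32), 200.0), pixel_size=0.1,
                            origin=np.zeros(2))
        with pytest.raises(DetectionError):
            detect_xy(img)

    def test_empty_image_warns(self):
        img = RenderedImage(data=np.zeros((32, 32)), pixel_size=0.1,
                            origin=np.zeros(2))
        img.data[3, 3] = 1.0  # single supra-threshold pixel, < min_island
        with pytest.warns(UserWarning):
            res = detect_xy(img, DetectionParams(threshold=0.5))
        assert len(res.positions) == 0


class TestDetectZ:
    @pytest.fixture()
    def stack_case(self):
        arr = sim.make_lattice(LatticeSpec(L0=1.5, rows=6, cols=6))
        z = np.where(arr.positions[:, 0] > 4.0, 0.2, 0.0)
        arr3 = NanodiscArray(
            positions=np.column_stack([arr.positions, z]), L0=1.5)
        spec = ImagingSpec(noise_sd=5.0, n_slices=31, z_step=0.1)
        stack = sim.render_stack(arr3, spec, seed=0)
        return arr3, z, stack, spec

    def test_flat_plane_recovered_near_zero(self, stack_case):
        arr3, z, stack, spec = stack_case
        zs, bad = detect_z(stack, arr3.positions[:, :2], stack_slice_z(spec))
        assert not bad.any()
        assert abs(zs[z == 0].mean()) < 0.02  # well below one slice

    def test_axial_step_recovered(self, stack_case):
        arr3, z, stack, spec = stack_case
        zs, _ = detect_z(stack, arr3.positions[:, :2], stack_slice_z(spec))
        assert zs[z == 0.2].mean() == pytest.approx(0.2, abs=0.03)

    def test_peak_at_stack_boundary_flagged(self):
        arr = sim.make_lattice(LatticeSpec(L0=1.5, rows=3, cols=3))
        arr3 = NanodiscArray(positions=np.column_stack(
            [arr.positions, np.full(len(arr), 0.7)]), L0=1.5)
        spec = ImagingSpec(noise_sd=0.0, n_slices=11, z_step=0.1)
        with pytest.warns(UserWarning):
            stack = sim.render_stack(arr3, spec)
        _, bad = detect_z(stack, arr3.positions[:, :2], stack_slice_z(spec))
        assert bad.all()


class TestTiltCorrect:
    def test_exact_plane_removed(self, perfect_lattice):
        p = perfect_lattice.positions
        z = 0.01 * p[:, 0] + 0.02 * p[:, 1] + 5.0
        corr, (a, b, c) = tilt_correct(np.column_stack([p, z]))
        assert (a, b, c) == pytest.approx((0.01, 0.02, 5.0), abs=1e-9)
        assert np.abs(corr[:, 2]).max() < 1e-9

    def test_bump_survives_plane_removal(self, perfect_lattice):
        p = perfect_lattice.positions
        z = 0.005 * p[:, 0] + 1.0
        bump = np.zeros(len(p))
        bump[10] = 0.3
        corr, _ = tilt_correct(np.column_stack([p, z + bump]))
        assert corr[10, 2] == pytest.approx(0.3, abs=0.02)
        others = np.delete(corr[:, 2], 10)
        assert np.abs(others).max() < 0.02

    def test_noise_sd_preserved(self, perfect_lattice, rng):
        """The plane removes only 3 d.o.f.; residual spread stays ~ sigma."""
        p = perfect_lattice.positions
        noise = rng.normal(0, 0.05, len(p))
        corr, _ = tilt_correct(np.column_stack([p, noise]))
        assert corr[:, 2].std() == pytest.approx(0.05, rel=0.15)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0), np.ones(5)])
        with pytest.raises(DetectionError, match="collinear"):
            tilt_correct(pts)
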