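"""Synthetic lattice generation and image rendering."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from ctfm import lattice_sim as sim
from ctfm.lattice_sim import (ImagingSpec, InvalidSpecError, LatticeSpec,
                              stack_slice_z)


class TestMakeLattice:
    def test_perfect_lattice_nearest_neighbours_at_L0(self):
        arr = sim.make_lattice(LatticeSpec(L0=1.5, rows=10, cols=10))
        tree = cKDTree(arr.positions)
        d, _ = tree.query(arr.positions, k=2)
        assert np.allclose(d[:, 1], 1.5, atol=1e-12)

    def test_equilateral_geometry_closed_form(self):
        # alternate rows shifted by L0/2; row pitch L0*sqrt(3)/2 = 0.8660
        arr = sim.make_lattice(LatticeSpec(L0=1.0, rows=3, cols=3))
        p = arr.positions.reshape(3, 3, 2)
        assert np.allclose(p[1, :, 0] - p[0, :, 0], 0.5)
        assert np.allclose(p[1, 0, 1] - p[0, 0, 1], 0.866025403784, atol=1e-9)

    def test_jitter_sample_sd_35nm_per_axis(self):
        arr = sim.make_lattice(LatticeSpec(L0=1.5, rows=50, cols=50,
                                           jitter_sd=0.035, seed=1))
        offsets = arr.positions - sim.make_lattice(
            LatticeSpec(L0=1.5, rows=50, cols=50)).positions
        assert offsets.std(axis=0) == pytest.approx([0.035, 0.035], rel=0.05)

    def test_invalid_L0_raises(self):
        with pytest.raises(InvalidSpecError):
            LatticeSpec(L0=-1.0)


class TestApplyDeformation:
    def test_zero_field_identity(self, perfect_lattice):
        out = sim.apply_deformation(perfect_lattice, lambda p: 0 * p)
        assert np.array_equal(out.positions, perfect_lattice.positions)

    def test_dipole_peak_amplitude(self, perfect_lattice):
        cen = tuple(perfect_lattice.xy.mean(axis=0))
        fn = sim.contractile_dipole(cen, separation=10.0, sigma=1.0, peak=1.5)
        out = sim.apply_deformation(perfect_lattice, fn)
        # sample the field densely: max |u| equals the peak parameter
        g = np.stack(np.meshgrid(np.linspace(0, 17, 300),
                                 np.linspace(0, 15, 300)), axis=-1)
        u = fn(g.reshape(-1, 2))
        assert np.linalg.norm(u, axis=1).max() == pytest.approx(1.5, rel=1e-3)
        assert np.all(np.isfinite(out.u_true))

    def test_rigid_translation_preserves_distances(self, perfect_lattice):
        out = sim.apply_deformation(perfect_lattice,
                                    sim.uniform_translation((0.3, 0.0)))
        d0 = np.linalg.norm(perfect_lattice.positions[0]
                            - perfect_lattice.positions[-1])
        d1 = np.linalg.norm(out.positions[0] - out.positions[-1])
        assert d1 == pytest.approx(d0, abs=1e-12)
        assert np.allclose(out.u_true, [0.3, 0.0])

    def test_ground_truth_tracks_labels(self, perfect_lattice):
        fn = sim.radial_contraction(tuple(perfect_lattice.xy.mean(axis=0)),
                                    sigma=2.0, peak=0.5)
        out = sim.apply_deformation(perfect_lattice, fn)
        assert np.allclose(out.u_true, out.positions - out.printed)

    def test_nonfinite_field_raises(self, perfect_lattice):
        with pytest.raises(ValueError, match="finite"):
            sim.apply_deformation(perfect_lattice,
                                  lambda p: np.full_like(p, np.nan))


class TestRenderImage:
    def test_single_disc_peak_position(self):
        arr = sim.NanodiscArray(positions=np.array([[10.0, 10.0]]), L0=1.5)
        img = sim.render_image(arr, ImagingSpec(noise_sd=0.0))
        r, c = np.unravel_index(np.argmax(img.data), img.data.shape)
        x = img.origin[0] + (c + 0.5) * img.pixel_size
        y = img.origin[1] + (r + 0.5) * img.pixel_size
        assert abs(x - 10.0) <= img.pixel_size
        assert abs(y - 10.0) <= img.pixel_size

    def test_background_noise_sd_10(self):
        arr = sim.NanodiscArray(positions=np.array([[30.0, 30.0]]), L0=1.5)
        img = sim.render_image(arr, ImagingSpec(noise_sd=10.0, pad=15.0,
                                                 baseline=60.0), seed=3)
        corner = img.data[:80, :80].astype(float)  # far from the spot
        assert corner.std() == pytest.approx(10.0, rel=0.05)

    def test_intensity_superposition(self):
        one = sim.NanodiscArray(positions=np.array([[5.0, 5.0]]), L0=3.0)
        two = sim.NanodiscArray(positions=np.array([[5.0, 5.0], [8.0, 5.0]]),
                                L0=3.0)
        spec = ImagingSpec(noise_sd=0.0, pad=3.0)
        i1 = sim.render_image(one, spec).data.astype(float).sum()
        i2 = sim.render_image(two, spec).data.astype(float).sum()
        assert i2 == pytest.approx(2 * i1, rel=0.01)

    def test_intensity_linear_in_disc_count(self, perfect_lattice):
        spec = ImagingSpec(noise_sd=0.0)
        full = sim.render_image(perfect_lattice, spec).data.astype(float).sum()
        per_disc = full / len(perfect_lattice)
        half = sim.NanodiscArray(
            positions=perfect_lattice.positions[:72].copy(), L0=1.5)
        got = sim.render_image(half, spec).data.astype(float).sum()
        assert got == pytest.approx(72 * per_disc, rel=0.02)


class TestRenderStack:
    def test_axial_peak_at_disc_plane(self):
        arr = sim.make_lattice(LatticeSpec(L0=1.5, rows=4, cols=4))
        pos3 = np.column_stack([arr.positions, np.zeros(len(arr))])
        arr3 = sim.NanodiscArray(positions=pos3, L0=1.5)
        spec = ImagingSpec(noise_sd=0.0, n_slices=31, z_step=0.1)
        stack = sim.render_stack(arr3, spec)
        assert stack.data.shape[0] == 31
        prof = stack.data.astype(float).sum(axis=(1, 2))
        assert np.argmax(prof) == 15  # central slice is z = 0
        assert stack_slice_z(spec)[15] == 0.0

    def test_tilted_plane_peak_slice_monotonic(self):
        arr = sim.make_lattice(LatticeSpec(L0=1.5, rows=3, cols=5))
        z = 0.1 * arr.positions[:, 0]
        arr3 = sim.NanodiscArray(
            positions=np.column_stack([arr.positions, z]), L0=1.5)
        spec = ImagingSpec(noise_sd=0.0, n_slices=31, z_step=0.1)
        stack = sim.render_stack(arr3, spec)
        peaks = []
        for x0, y0 in arr.positions[:5]:
            ci = int((x0 - stack.origin[0]) / spec.pixel_size)
            ri = int((y0 - stack.origin[1]) / spec.pixel_size)
            peaks.append(np.argmax(stack.data[:, ri, ci]))
        assert all(a < b for a, b in zip(peaks, peaks[1:]))

    def test_too_few_slices_rejected(self, perfect_lattice):
        with pytest.raises(InvalidSpecError):
            sim.render_stack(perfect_lattice, ImagingSpec(n_slices=2))
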