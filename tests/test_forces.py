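"""Pressure gradient, force integration, summaries, ratios, planar mode."""

import numpy as np
import pytest

import hemoforce as hf
from hemoforce.core_fields import FluidProperties, GridSpec, InvalidInputError, VelocityField
from hemoforce.forces import planar_force, summarize_forces
from hemoforce.geometry import CardiacTiming, DirectionFrame, VentricleMask


def _interior(validity):
    s = validity.copy()
    s[[0, -1], :, :] = s[:, [0, -1], :] = s[:, :, [0, -1]] = False
    return s


class TestPressureGradient:
    def test_static_fluid_zero(self):
        grid = GridSpec((3e-3,) * 3, 0.05, (8, 8, 8), 4)
        g = hf.pressure_gradient(VelocityField(grid, np.zeros((4, 8, 8, 8, 3))))
        assert np.all(g.values == 0.0)
        assert g.units == "N/m^3"

    def test_accelerating_plug_flow(self):
        # dV/dt = 1 m/s^2 along z, rho = 1050 => g = (0, 0, -1050) N/m^3
        grid = GridSpec((3e-3,) * 3, 0.05, (7, 7, 7), 5)
        t = np.arange(5) * grid.frame_duration
        vals = np.zeros((5, 7, 7, 7, 3))
        vals[..., 2] = t[:, None, None, None]  # V(t) = t
        g = hf.pressure_gradient(VelocityField(grid, vals), periodic=False)
        assert np.allclose(g.values[1:-1, ..., 2], -1050.0)
        assert np.allclose(g.values[..., :2], 0.0)

    def test_rigid_rotation_centripetal_balance(self, rotation_scene):
        # g = rho omega^2 (x, y, 0) at interior voxels, exactly for quadratics
        g = hf.pressure_gradient(rotation_scene.velocity, rotation_scene.fluid)
        ga = rotation_scene.ground_truth["g_analytic"]
        s = _interior(g.validity)
        scale = np.abs(ga[0][s]).max()
        assert np.abs(g.values[0][s] - ga[0][s]).max() < 1e-9 * scale

    def test_too_few_frames_raise(self):
        grid = GridSpec((3e-3,) * 3, 0.05, (7, 7, 7), 2)
        with pytest.raises(InvalidInputError):
            hf.pressure_gradient(VelocityField(grid, np.zeros((2, 7, 7, 7, 3))))


class TestIntegrateForce:
    def test_zero_field_zero_force(self, plug_scene):
        g = hf.pressure_gradient(
            VelocityField(plug_scene.velocity.grid,
                          np.zeros_like(plug_scene.velocity.values))
        )
        F = hf.integrate_force(g, plug_scene.mask)
        assert np.all(F.force == 0.0)

    def test_uniform_g_times_volume(self):
        # uniform g = (0,0,-1050) N/m^3 over ~100 ml => F_z ~ -0.105 N
        grid = GridSpec((3e-3,) * 3, 0.05, (17, 17, 17), 5)
        t = np.arange(5) * grid.frame_duration
        vals = np.zeros((5, 17, 17, 17, 3))
        vals[..., 2] = t[:, None, None, None]
        g = hf.pressure_gradient(VelocityField(grid, vals), periodic=False)
        n_vox = int(round(100e-6 / grid.voxel_volume))
        frames = np.zeros((5, 17, 17, 17), bool)
        frames.reshape(5, -1)[:, :n_vox] = True
        F = hf.integrate_force(g, VentricleMask(grid, frames))
        expected = -1050.0 * n_vox * grid.voxel_volume
        assert F.force[2, 2] == pytest.approx(expected, rel=1e-12)
        assert abs(expected) == pytest.approx(0.105, rel=0.03)

    def test_symmetric_rotation_mask_cancellation(self, rotation_scene):
        g = hf.pressure_gradient(rotation_scene.velocity, rotation_scene.fluid)
        F = hf.integrate_force(g, rotation_scene.mask)
        vol = rotation_scene.velocity.grid.voxel_volume
        total = np.abs(g.values[0][rotation_scene.mask.frames[0]]).sum() * vol
        assert np.linalg.norm(F.force[0]) < 0.01 * total

    def test_additive_over_disjoint_partitions(self, plug_scene):
        g = hf.pressure_gradient(plug_scene.velocity, plug_scene.fluid)
        frames = plug_scene.mask.frames
        half_a = frames.copy()
        half_a[:, :, :, : frames.shape[3] // 2] = False
        half_b = frames & ~half_a
        Fa = hf.integrate_force(g, VentricleMask(plug_scene.velocity.grid, half_a))
        Fb = hf.integrate_force(g, VentricleMask(plug_scene.velocity.grid, half_b))
        F = hf.integrate_force(g, plug_scene.mask)
        assert np.allclose(Fa.force + Fb.force, F.force, atol=1e-15)

    def test_grid_mismatch_raises(self, plug_scene):
        g = hf.pressure_gradient(plug_scene.velocity, plug_scene.fluid)
        other = GridSpec((3e-3,) * 3, 0.05, (5, 5, 5), plug_scene.velocity.n_frames)
        bad = VentricleMask(other, np.ones((plug_scene.velocity.n_frames, 5, 5, 5), bool))
        with pytest.raises(InvalidInputError):
            hf.integrate_force(g, bad)


class TestProjection:
    def test_aligned_force_single_component(self):
        f = DirectionFrame.world_axes()  # b = z
        curves = hf.ForceCurves(np.array([[0.0, 0.0, 0.4]]), 0.05)
        out = hf.project_to_frame(curves, f)
        assert np.allclose(out.force, [[0.4, 0.0, 0.0]])

    def test_norm_preserved(self):
        rng = np.random.default_rng(5)
        n = rng.normal(size=3)
        f = hf.build_direction_frame(n, rng.normal(size=3))
        F = rng.normal(size=(12, 3))
        out = hf.project_to_frame(hf.ForceCurves(F, 0.05), f)
        assert np.allclose(np.linalg.norm(out.force, axis=1),
                           np.linalg.norm(F, axis=1), atol=1e-12)


class TestSummaries:
    def test_rms_constant_and_hand_value(self):
        assert hf.rms_force(np.full(10, 0.2), np.arange(10)) == pytest.approx(0.2)
        # sqrt((0.3^2 + 0.4^2)/2) = 0.35355
        assert hf.rms_force(np.array([0.3, 0.4]), np.arange(2)) == pytest.approx(
            0.35355, abs=5e-6
        )
        assert hf.rms_force(np.array([0.5, -0.5, 0.5]), np.arange(3)) == pytest.approx(0.5)

    def test_peak_value_and_tie_break(self):
        val, at = hf.peak_force(np.array([0.1, -0.5, 0.2]), np.arange(3))
        assert (val, at) == (0.5, 1)
        val, at = hf.peak_force(np.full(5, 0.3), np.arange(5))
        assert (val, at) == (0.3, 0)

    def test_peak_sampling_bound_for_sinusoid(self):
        A, n, T = 0.35, 40, 1.0
        t = np.arange(n) * T / n
        curve = A * np.sin(2 * np.pi * t / T + 0.13)
        val, _ = hf.peak_force(curve, np.arange(n))
        assert A - val <= A * (1 - np.cos(np.pi * (T / n) / T)) + 1e-12

    def test_empty_phase_raises(self):
        with pytest.raises(InvalidInputError):
            hf.rms_force(np.ones(5), np.array([], dtype=int))

    def test_rms_ratio_formula(self):
        # LV systolic group means: sqrt(0.04^2 + 0.11^2) / 0.18 = 0.650
        assert hf.rms_ratio(0.18, 0.11, 0.04) == pytest.approx(0.650, abs=5e-4)
        assert hf.rms_ratio(0.18, 0.0, 0.0) == 0.0
        k = 3.7  # homogeneity
        assert hf.rms_ratio(k * 0.18, k * 0.11, k * 0.04) == pytest.approx(
            hf.rms_ratio(0.18, 0.11, 0.04)
        )

    def test_peak_ratio_formula(self):
        # LV systolic group means: 0.19 / 0.35 = 0.543
        assert hf.peak_ratio(0.35, 0.19) == pytest.approx(0.543, abs=5e-4)
        assert hf.peak_ratio(0.2, 0.2) == 1.0
        with pytest.raises(InvalidInputError):
            hf.peak_ratio(0.0, 0.1)

    def test_summary_uses_dominant_transverse_per_chamber(self):
        rng = np.random.default_rng(9)
        F = rng.normal(size=(20, 3))
        timing = CardiacTiming(8, 20, 0.05)
        lv = summarize_forces(
            hf.ForceCurves(F, 0.05, basis="anatomical", chamber="LV"), timing)
        rv = summarize_forces(
            hf.ForceCurves(F, 0.05, basis="anatomical", chamber="RV"), timing)
        sys_frames = timing.systole_frames
        pk = [hf.peak_force(F[:, c], sys_frames)[0] for c in range(3)]
        assert lv.peak_ratio["systole"] == pytest.approx(pk[1] / pk[0])
        assert rv.peak_ratio["systole"] == pytest.approx(pk[2] / pk[0])
        # RMS ratio identical construction in both chambers
        assert lv.rms_ratio["systole"] == pytest.approx(rv.rms_ratio["systole"])

    def test_summary_matches_brute_force(self, plug_scene):
        g = hf.pressure_gradient(plug_scene.velocity, plug_scene.fluid)
        F = hf.project_to_frame(
            hf.integrate_force(g, plug_scene.mask), DirectionFrame.world_axes())
        summ = summarize_forces(F, plug_scene.timing)
        sf = plug_scene.timing.systole_frames
        brute = np.sqrt(np.mean(F.force[sf, 0] ** 2))
        assert summ.rms["systole"][0] == pytest.approx(brute, rel=1e-12)
        assert summ.peak["systole"][0] == pytest.approx(
            np.abs(F.force[sf, 0]).max(), rel=1e-12)

    def test_ratio_invariant_under_time_reversal(self):
        rng = np.random.default_rng(13)
        F = rng.normal(size=(16, 3))
        timing = CardiacTiming(16 // 2, 16, 0.05)
        a = summarize_forces(hf.ForceCurves(F, 0.05, basis="anatomical"), timing)
        # reverse within each phase so phase membership is unchanged
        Fr = F.copy()
        Fr[:8] = F[:8][::-1]
        Fr[8:] = F[8:][::-1]
        b = summarize_forces(hf.ForceCurves(Fr, 0.05, basis="anatomical"), timing)
        assert a.peak_ratio["systole"] == pytest.approx(b.peak_ratio["systole"])
        assert a.rms_ratio["diastole"] == pytest.approx(b.rms_ratio["diastole"])


class TestPlanarMode:
    def test_static_plane_zero(self):
        out = planar_force(np.zeros((4, 8, 8, 2)), np.ones((8, 8), bool),
                           (1.5e-3, 1.5e-3), 0.01)
        assert np.all(out == 0.0)

    def test_accelerating_plug_area_arithmetic(self):
        # dV/dt = 1 m/s^2, rho = 1050, area 6.25 cm^2 => |f| ~ 0.656 N/m
        n, h = 5, 2.5e-3
        npix = 10  # 10 x 10 pixels of 2.5 mm = 6.25 cm^2
        dt = 0.01
        t = np.arange(n) * dt
        v = np.zeros((n, 14, 14, 2))
        v[..., 1] = t[:, None, None]
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True
        out = planar_force(v, mask, (h, h), dt, periodic=False)
        area = (npix * h) ** 2
        assert out[2, 1] == pytest.approx(-1050.0 * area, rel=1e-9)
        assert abs(out[2, 1]) == pytest.approx(0.656, rel=0.01)

    def test_consistent_with_3d_central_slice(self, plug_scene):
        # planar result equals the 3D g integrated over the same slice area
        g3 = hf.pressure_gradient(plug_scene.velocity, plug_scene.fluid)
        grid = plug_scene.velocity.grid
        mid = grid.shape[1] // 2
        slice_mask = plug_scene.mask.frames[0][:, mid, :]
        v2 = plug_scene.velocity.values[:, :, mid, :, :][..., [0, 2]]
        out = planar_force(v2, slice_mask, (grid.spacing[0], grid.spacing[2]),
                           grid.frame_duration, fluid=plug_scene.fluid)
        pix_area = grid.spacing[0] * grid.spacing[2]
        ref = np.stack([
            (g3.values[t][:, mid, :, :][slice_mask][:, [0, 2]]).sum(axis=0) * pix_area
            for t in range(grid.n_frames)
        ])
        assert np.allclose(out, ref, atol=1e-12)

    def test_too_small_grid_raises(self):
        with pytest.raises(InvalidInputError):
            planar_force(np.zeros((4, 2, 8, 2)), np.ones((2, 8), bool),
                         (1e-3, 1e-3), 0.01)
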