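"""Analytic synthetic scenes: known-truth flows for every pipeline stage.

Real 4D flow acquisitions have no accessible ground truth, so validation
rests on analytic flows whose pressure gradients and forces are known in
closed form:

* ``make_plug_flow`` — spatially uniform pulsatile flow; the convective and
  viscous terms vanish and the force is exactly ``-rho V'(t) Volume``.
* ``make_rigid_rotation`` — solid-body rotation; the pressure gradient is
  the centripetal density ``rho omega^2 r`` pointing outward, and the net
  force over any axis-centered symmetric mask cancels.
* ``make_pulsatile_nozzle`` — a divergence-free axisymmetric jet built
  from a Stokes stream function (Poiseuille-profiled nozzle efflux with a
  translating vortex-ring-like structure), emitting both the 3D field and
  the central-plane 2D view with through-plane components dropped, as a
  planar-velocimetry phantom stand-in.
* ``make_lv_like_scene`` — a half-ellipsoid ventricle with a moving base
  plane producing a configured ejection fraction, with an affine interior
  velocity whose pressure gradient is known in closed form.
* ``corrupt`` — injects a linear background plane, phase wraps and noise,
  recording the injections, to exercise the preprocessing round trip.

Every scene carries its ground truth so tests never re-derive it; scenes
audit themselves at build time (stored force vs. quadrature of the stored
analytic g over the mask).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield
from typing import Callable

import numpy as np

from .core_fields import (
    DEFAULT_DENSITY,
    FluidProperties,
    GridSpec,
    InvalidInputError,
    VelocityField,
)
from .geometry import AVPlaneLandmarks, CardiacTiming, VentricleMask

__all__ = [
    "SyntheticScene",
    "make_plug_flow",
    "make_rigid_rotation",
    "make_pulsatile_nozzle",
    "make_lv_like_scene",
    "corrupt",
]


@dataclass
class SyntheticScene:
    """A velocity field, mask, geometry inputs and their ground truth."""

    velocity: VelocityField
    mask: VentricleMask
    timing: CardiacTiming
    landmarks: AVPlaneLandmarks | None = None
    three_chamber_normal: np.ndarray | None = None
    apex_hint: np.ndarray | None = None
    lateral_hint: np.ndarray | None = None
    fluid: FluidProperties = dfield(default_factory=FluidProperties)
    ground_truth: dict = dfield(default_factory=dict)
    planar: dict | None = None  # central-slice 2D view, when emitted

    def audit(self, rtol: float = 5e-3) -> None:
        """Check stored force against quadrature of the stored analytic g."""
        if "g_analytic" not in self.ground_truth or "force_world" not in self.ground_truth:
            return
        g = self.ground_truth["g_analytic"]
        vol = self.velocity.grid.voxel_volume
        F = np.stack(
            [g[t][self.mask.frames[t]].sum(axis=0) * vol for t in range(g.shape[0])]
        )
        ref = self.ground_truth["force_world"]
        scale = max(np.abs(ref).max(), 1e-300)
        if np.abs(F - ref).max() > rtol * scale:
            raise AssertionError(
                "scene ground truth inconsistent: stored force differs from "
                "quadrature of stored analytic g over the mask"
            )


def _check_bandlimited(v_of_t: Callable, period: float, n_frames: int) -> None:
    dense = v_of_t(np.linspace(0, period, 1024, endpoint=False))
    spec = np.abs(np.fft.rfft(dense))
    nyq = n_frames // 2
    if spec[nyq:].sum() > 1e-6 * max(spec.sum(), 1e-300):
        raise InvalidInputError(
            "V(t) has spectral content at or above the frame-rate Nyquist limit"
        )


def _ball_mask(shape, spacing, center_vox, radius_m):
    idx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    r2 = sum(((idx[a] - center_vox[a]) * spacing[a]) ** 2 for a in range(3))
    return r2 <= radius_m**2


def make_plug_flow(
    v_peak: float = 0.3,
    period: float = 2.0,
    n_frames: int = 40,
    spacing: float = 3e-3,
    mask_volume_ml: float = 100.0,
    density: float = DEFAULT_DENSITY,
    v_of_t: Callable | None = None,
    dv_dt: Callable | None = None,
) -> SyntheticScene:
    """Uniform pulsatile plug flow v = (0, 0, V(t)) with exact force truth.

    Defaults: ``V(t) = v_peak sin(2 pi t / period)`` on a 3 mm grid with 40
    frames per cycle and a spherical 100 ml mask.  The ground-truth force
    is ``-rho V'(t) Volume`` along z, with Volume the voxelized mask
    volume (the same voxel set the pipeline integrates over).
    """
    if v_of_t is None:
        omega = 2 * np.pi / period
        v_of_t = lambda t: v_peak * np.sin(omega * t)  # noqa: E731
        dv_dt = lambda t: v_peak * omega * np.cos(omega * t)  # noqa: E731
    elif dv_dt is None:
        raise InvalidInputError("custom V(t) requires its analytic derivative dv_dt")
    _check_bandlimited(v_of_t, period, n_frames)

    radius = (3.0 * mask_volume_ml * 1e-6 / (4.0 * np.pi)) ** (1.0 / 3.0)
    n_side = int(np.ceil(2 * radius / spacing)) + 7  # >= 3-voxel margin each side
    shape = (n_side, n_side, n_side)
    grid = GridSpec(
        spacing=(spacing,) * 3,
        frame_duration=period / n_frames,
        shape=shape,
        n_frames=n_frames,
    )
    center = tuple((n - 1) / 2.0 for n in shape)
    ball = _ball_mask(shape, grid.spacing, center, radius)
    t = np.arange(n_frames) * grid.frame_duration
    values = np.zeros((n_frames, *shape, 3))
    values[..., 2] = v_of_t(t)[:, None, None, None]
    vfield = VelocityField(grid, values)
    mask = VentricleMask(grid, np.broadcast_to(ball, (n_frames, *shape)).copy())
    volume = ball.sum() * grid.voxel_volume
    rho = density
    g_true = np.zeros((n_frames, *shape, 3))
    g_true[..., 2] = (-rho * dv_dt(t))[:, None, None, None]
    force = np.zeros((n_frames, 3))
    force[:, 2] = -rho * dv_dt(t) * volume
    timing = CardiacTiming(n_frames // 2, n_frames, grid.frame_duration)
    scene = SyntheticScene(
        velocity=vfield,
        mask=mask,
        timing=timing,
        fluid=FluidProperties(density=rho),
        ground_truth={
            "g_analytic": g_true,
            "force_world": force,
            "volume_m3": volume,
            "v_of_t": v_of_t,
            "dv_dt": dv_dt,
        },
    )
    scene.audit()
    return scene


def make_rigid_rotation(
    omega: float = 10.0,
    n_frames: int = 8,
    spacing: float = 3e-3,
    shape: tuple[int, int, int] = (25, 25, 9),
    mask_radius: float = 0.025,
    density: float = DEFAULT_DENSITY,
) -> SyntheticScene:
    """Steady solid-body rotation about the central z axis.

    ``v = omega (-y, x, 0)`` relative to the axis; the analytic pressure
    gradient is the centripetal density ``g = rho omega^2 (x, y, 0)`` and
    the net force over any axis-centered rotationally symmetric mask is
    zero by cancellation.  Both centered stencils are exact here (the
    field is linear in space, steady in time, quadratic in the convective
    term).
    """
    grid = GridSpec(
        spacing=(spacing,) * 3, frame_duration=0.05, shape=shape, n_frames=n_frames
    )
    center = tuple((n - 1) / 2.0 for n in shape)
    idx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    x = (idx[0] - center[0]) * spacing
    y = (idx[1] - center[1]) * spacing
    v = np.zeros((*shape, 3))
    v[..., 0] = -omega * y
    v[..., 1] = omega * x
    values = np.broadcast_to(v, (n_frames, *shape, 3)).copy()
    vfield = VelocityField(grid, values)
    cyl = (x**2 + y**2 <= mask_radius**2) & (np.abs(idx[2] - center[2]) <= 2)
    mask = VentricleMask(grid, np.broadcast_to(cyl, (n_frames, *shape)).copy())
    g = np.zeros((*shape, 3))
    g[..., 0] = density * omega**2 * x
    g[..., 1] = density * omega**2 * y
    g_true = np.broadcast_to(g, (n_frames, *shape, 3)).copy()
    vol = grid.voxel_volume
    force = np.stack([g_true[t][cyl].sum(axis=0) * vol for t in range(n_frames)])
    scene = SyntheticScene(
        velocity=vfield,
        mask=mask,
        timing=CardiacTiming(n_frames // 2, n_frames, grid.frame_duration),
        fluid=FluidProperties(density=density),
        ground_truth={"g_analytic": g_true, "force_world": force, "omega": omega},
    )
    scene.audit()
    return scene


def _nozzle_potential(x, y, z, t_arr, R, sigma, lam, v_amp, t_ej, z0, convect):
    """Vector potential A of the jet (A_phi = psi / r in Cartesian components).

    ``A = (-y, x, 0) V(t) w(z) s(r)`` with ``s(r) = phi(r) / r^2`` smooth
    through the axis.  The generated velocity is the *discrete* curl of
    this potential, so its centered-difference divergence vanishes to
    round-off by construction (difference operators commute), not merely
    to truncation order.
    """
    phi_R = R**2 / 4.0
    r2 = x**2 + y**2
    r = np.sqrt(r2)
    inside = r <= R
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(
            inside,
            0.5 - r2 / (4.0 * R**2),
            phi_R * np.exp(-(np.maximum(r - R, 0.0) / sigma) ** 2)
            / np.maximum(r2, 1e-24),
        )
    out = np.zeros((len(t_arr), *np.broadcast(x, y, z).shape, 3))
    for it, t in enumerate(t_arr):
        V = v_amp * np.sin(np.pi * t / t_ej) if 0 <= t < t_ej else 0.0
        disp = convect * v_amp * (t_ej / np.pi) * (
            1 - np.cos(np.pi * min(max(t, 0.0), t_ej) / t_ej)
        )
        w = np.exp(-((z - (z0 + disp)) / lam) ** 2)
        out[it, ..., 0] = -y * V * w * s
        out[it, ..., 1] = x * V * w * s
    return out


def _discrete_curl(A, spacing):
    """Centered-difference curl (one-sided at domain edges) of (t,x,y,z,3)."""
    d = lambda f, a: np.gradient(f, spacing[a], axis=a)  # noqa: E731
    v = np.empty_like(A)
    for t in range(A.shape[0]):
        Ax, Ay, Az = A[t, ..., 0], A[t, ..., 1], A[t, ..., 2]
        v[t, ..., 0] = d(Az, 1) - d(Ay, 2)
        v[t, ..., 1] = d(Ax, 2) - d(Az, 0)
        v[t, ..., 2] = d(Ay, 0) - d(Ax, 1)
    return v


def _nozzle_velocity(x, y, z, t_arr, R, sigma, lam, v_amp, t_ej, z0, convect):
    """Evaluate the analytic stream-function jet on arbitrary coordinates."""
    out_shape = (len(t_arr), *np.broadcast(x, y, z).shape, 3)
    out = np.zeros(out_shape)
    r = np.sqrt(x**2 + y**2)
    phi_R = R**2 / 4.0
    inside = r <= R
    # phi(r) and phi'(r): Poiseuille core, C2-matched Gaussian skirt
    phi = np.where(
        inside,
        r**2 / 2.0 - r**4 / (4.0 * R**2),
        phi_R * np.exp(-(np.maximum(r - R, 0.0) / sigma) ** 2),
    )
    dphi = np.where(
        inside,
        r - r**3 / R**2,
        phi * (-2.0 * np.maximum(r - R, 0.0) / sigma**2),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        dphi_over_r = np.where(r > 1e-12, dphi / np.maximum(r, 1e-12), 1.0)
        phi_over_r = np.where(r > 1e-12, phi / np.maximum(r, 1e-12), 0.0)
        inv_r = np.where(r > 1e-12, 1.0 / np.maximum(r, 1e-12), 0.0)
    for it, t in enumerate(t_arr):
        V = v_amp * np.sin(np.pi * t / t_ej) if 0 <= t < t_ej else 0.0
        disp = convect * v_amp * (t_ej / np.pi) * (
            1 - np.cos(np.pi * min(max(t, 0.0), t_ej) / t_ej)
        )
        zc = z0 + disp
        w = np.exp(-((z - zc) / lam) ** 2)
        dw = w * (-2.0 * (z - zc) / lam**2)
        vz = V * w * dphi_over_r
        vr = -V * dw * phi_over_r
        out[it, ..., 0] = vr * np.where(r > 1e-12, x * inv_r, 0.0)
        out[it, ..., 1] = vr * np.where(r > 1e-12, y * inv_r, 0.0)
        out[it, ..., 2] = vz
    return out


def make_pulsatile_nozzle(
    pulse_volume_ml: float = 12.3,
    peak_velocity: float = 0.21,
    nozzle_diameter: float = 0.025,
    bpm: float = 57.0,
    n_frames: int = 40,
    spacing: float = 1.5e-3,
    convect: float = 0.5,
) -> SyntheticScene:
    """Axisymmetric pulsatile jet phantom (3D field + central-plane 2D view).

    Built from a Stokes stream function, hence divergence-free by
    construction: a Poiseuille-profiled efflux through a circular nozzle
    whose axial envelope translates with the ejected fluid, resembling a
    vortex ring.  Defaults follow a desk-scale pulsatile pump programme
    (57 bpm, 12.3 ml pulse volume, 21 cm/s peak velocity, 25 mm nozzle).
    The ejection time is set by the pulse-volume constraint
    ``PV = R^2 v_peak t_ej`` of the half-sine drive.

    This is a kinematic stand-in, not a Navier-Stokes solution: its force
    has no closed form, so the stored ground truth records the
    construction constraints (pulse volume, peak centerline velocity)
    rather than a force curve.
    """
    for name, val in [
        ("pulse_volume_ml", pulse_volume_ml),
        ("peak_velocity", peak_velocity),
        ("nozzle_diameter", nozzle_diameter),
        ("bpm", bpm),
    ]:
        if val <= 0:
            raise InvalidInputError(f"{name} must be positive")
    R = nozzle_diameter / 2.0
    period = 60.0 / bpm
    t_ej = pulse_volume_ml * 1e-6 / (R**2 * peak_velocity)
    if t_ej >= period:
        raise InvalidInputError("pulse volume too large for this rate and peak velocity")
    sigma = R / 2.0  # C2 continuity of the radial profile at r = R
    lam = 2.0 * R

    half = int(np.ceil(3.0 * R / spacing))
    nx = ny = 2 * half + 1  # odd: a voxel line lies exactly on the axis
    nz = int(np.ceil(7.0 * R / spacing))
    grid = GridSpec(
        spacing=(spacing,) * 3, frame_duration=period / n_frames,
        shape=(nx, ny, nz), n_frames=n_frames,
    )
    idx = np.meshgrid(*(np.arange(n) for n in grid.shape), indexing="ij")
    x = (idx[0] - half) * spacing
    y = (idx[1] - half) * spacing
    z = idx[2] * spacing
    z0 = 1.5 * R
    t_arr = np.arange(n_frames) * grid.frame_duration
    A = _nozzle_potential(x, y, z, t_arr, R, sigma, lam, peak_velocity, t_ej, z0, convect)
    values = _discrete_curl(A, grid.spacing)
    vfield = VelocityField(grid, values)
    # integration region: cylinder of 2.5 R around the axis, away from z edges
    region = (x**2 + y**2 <= (2.5 * R) ** 2) & (z >= 2 * spacing) & (z <= z.max() - 2 * spacing)
    mask = VentricleMask(grid, np.broadcast_to(region, (n_frames, *grid.shape)).copy())

    # central-plane (y = 0) 2D view, through-plane component dropped
    x2, z2 = np.meshgrid(x[:, half, 0], z[half, half, :], indexing="ij")
    v2 = _nozzle_velocity(
        x2, np.zeros_like(x2), z2, t_arr, R, sigma, lam, peak_velocity, t_ej, z0, convect
    )
    planar = {
        "values": np.stack([v2[..., 0], v2[..., 2]], axis=-1),
        "pixel_spacing": (spacing, spacing),
        "frame_duration": grid.frame_duration,
        "mask": region[:, half, :],
    }
    end_sys = max(1, min(int(round(n_frames * t_ej / period)), n_frames - 1))
    scene = SyntheticScene(
        velocity=vfield,
        mask=mask,
        timing=CardiacTiming(end_sys, n_frames, grid.frame_duration),
        planar=planar,
        ground_truth={
            "pulse_volume_ml": pulse_volume_ml,
            "peak_velocity": peak_velocity,
            "nozzle_radius": R,
            "t_ejection": t_ej,
            "efflux_ml_s": 1e6 * np.pi * R**2 / 2.0
            * peak_velocity * np.sin(np.pi * np.minimum(t_arr, t_ej) / t_ej)
            * (t_arr < t_ej),
        },
    )
    return scene


def make_lv_like_scene(
    edv_ml: float = 175.0,
    ef: float = 0.60,
    bpm: float = 60.0,
    n_frames: int = 40,
    spacing: float = 3e-3,
    transverse_jet: float = 0.0,
    density: float = DEFAULT_DENSITY,
) -> SyntheticScene:
    """Half-ellipsoid ventricle with a configured ejection fraction.

    The blood pool is a half-ellipsoid (flat base, apex along +z) whose
    long axis ``c(t)`` shortens and re-lengthens to produce the requested
    EF (long-axis ventricular function, the dominant component in vivo).
    The interior velocity is the affine field ``v_z = (z - z0) c'(t)/c(t)``
    (base fixed, apex moving; blood leaves and enters through the base),
    for which the pressure gradient is exactly
    ``g_z = -rho (c''/c) (z - z0)``.  An optional uniform transverse jet
    ``v_y = A sin(2 pi t / T)`` adds a closed-form transverse force to
    probe the transverse/longitudinal ratios.

    AV-plane landmarks sit on the base rim; the 3-chamber plane is the x-z
    plane; apex and lateral hints fix the sign convention.
    """
    if not 0 < ef < 1:
        raise InvalidInputError("ejection fraction must be in (0, 1)")
    period = 60.0 / bpm
    v_ed = edv_ml * 1e-6
    c_ed = 0.08  # end-diastolic long axis, m
    a = np.sqrt(3.0 * v_ed / (2.0 * np.pi * c_ed))
    t_es_frac = 0.35
    t_es = t_es_frac * period
    omega_j = 2 * np.pi / period

    def c_funcs(t):
        """long axis c(t), c'(t), c''(t); C1-periodic raised-cosine volume drive"""
        t = np.asarray(t, dtype=float) % period
        h = np.where(
            t <= t_es,
            0.5 * (1 - np.cos(np.pi * t / t_es)),
            0.5 * (1 + np.cos(np.pi * (t - t_es) / (period - t_es))),
        )
        dh = np.where(
            t <= t_es,
            0.5 * np.pi / t_es * np.sin(np.pi * t / t_es),
            -0.5 * np.pi / (period - t_es) * np.sin(np.pi * (t - t_es) / (period - t_es)),
        )
        d2h = np.where(
            t <= t_es,
            0.5 * (np.pi / t_es) ** 2 * np.cos(np.pi * t / t_es),
            -0.5 * (np.pi / (period - t_es)) ** 2
            * np.cos(np.pi * (t - t_es) / (period - t_es)),
        )
        c = c_ed * (1.0 - ef * h)
        return c, -c_ed * ef * dh, -c_ed * ef * d2h

    margin = 3
    nx = ny = 2 * (int(np.ceil(a / spacing)) + margin) + 1
    nz = int(np.ceil(c_ed / spacing)) + 2 * margin
    grid = GridSpec(
        spacing=(spacing,) * 3, frame_duration=period / n_frames,
        shape=(nx, ny, nz), n_frames=n_frames,
    )
    cx = (nx - 1) / 2.0 * spacing
    # base plane sits between voxel layers: avoids a half-voxel volume bias
    z0 = (margin + 0.5) * spacing
    idx = np.meshgrid(*(np.arange(n) for n in grid.shape), indexing="ij")
    x = idx[0] * spacing - cx
    y = idx[1] * spacing - cx
    z = idx[2] * spacing

    t_arr = np.arange(n_frames) * grid.frame_duration
    c_t, dc_t, d2c_t = c_funcs(t_arr)
    frames = np.zeros((n_frames, *grid.shape), dtype=bool)
    values = np.zeros((n_frames, *grid.shape, 3))
    g_true = np.zeros((n_frames, *grid.shape, 3))
    for t in range(n_frames):
        c = c_t[t]
        frames[t] = ((x / a) ** 2 + (y / a) ** 2 + ((z - z0) / c) ** 2 <= 1.0) & (z >= z0)
        values[t, ..., 2] = (z - z0) * dc_t[t] / c
        values[t, ..., 1] = transverse_jet * np.sin(omega_j * t_arr[t])
        g_true[t, ..., 2] = -density * (d2c_t[t] / c) * (z - z0)
        g_true[t, ..., 1] = -density * transverse_jet * omega_j * np.cos(omega_j * t_arr[t])
    vfield = VelocityField(grid, values)
    mask = VentricleMask(grid, frames, chamber="LV")
    vol = grid.voxel_volume
    force = np.stack([g_true[t][frames[t]].sum(axis=0) * vol for t in range(n_frames)])

    theta = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    landmarks = AVPlaneLandmarks(
        np.column_stack([cx + a * np.cos(theta), cx + a * np.sin(theta), np.full(6, z0)])
    )
    end_sys = max(1, int(round(n_frames * t_es_frac)))
    scene = SyntheticScene(
        velocity=vfield,
        mask=mask,
        timing=CardiacTiming(end_sys, n_frames, grid.frame_duration),
        landmarks=landmarks,
        three_chamber_normal=np.array([0.0, 1.0, 0.0]),
        apex_hint=np.array([cx, cx, z0 + c_ed]),
        lateral_hint=np.array([cx + a, cx, z0]),
        fluid=FluidProperties(density=density),
        ground_truth={
            "g_analytic": g_true,
            "force_world": force,
            "edv_ml": edv_ml,
            "esv_ml": edv_ml * (1 - ef),
            "base_z": z0,
            "long_axis": c_funcs,
        },
    )
    scene.audit()
    return scene


def corrupt(
    scene: SyntheticScene,
    background_coeffs: np.ndarray | None = None,
    wrap_venc: float | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Apply, in order: linear background plane, phase wrapping, Gaussian noise.

    ``background_coeffs`` has shape (3, 4): per component [const, x, y, z]
    in SI units (m/s and (m/s)/m), evaluated at world voxel centers.  All
    injections are recorded in the returned scene's ground truth; the RNG
    is seeded, so a fixed seed yields bit-identical output.
    """
    v = scene.velocity.values.copy()
    grid = scene.velocity.grid
    injections: dict = dict(scene.ground_truth)
    if background_coeffs is not None:
        bc = np.asarray(background_coeffs, dtype=float)
        if bc.shape != (3, 4):
            raise InvalidInputError("background coefficients must have shape (3, 4)")
        xw, yw, zw = grid.voxel_centers_world()
        basis = np.stack([np.ones_like(xw), xw, yw, zw], axis=-1)
        for c in range(3):
            v[..., c] += basis @ bc[c]
        injections["background_plane"] = bc
    if wrap_venc is not None:
        if wrap_venc <= 0:
            raise InvalidInputError("venc must be positive")
        wrapped = np.mod(v + wrap_venc, 2.0 * wrap_venc) - wrap_venc
        injections["wrap_multiples"] = np.round((v - wrapped) / (2.0 * wrap_venc)).astype(int)
        injections["venc"] = wrap_venc
        v = wrapped
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sigma, size=v.shape)
        v = v + noise
        injections["noise_sigma"] = noise_sigma
    out = SyntheticScene(
        velocity=VelocityField(grid, v, scene.velocity.validity.copy()),
        mask=scene.mask,
        timing=scene.timing,
        landmarks=scene.landmarks,
        three_chamber_normal=scene.three_chamber_normal,
        apex_hint=scene.apex_hint,
        lateral_hint=scene.lateral_hint,
        fluid=scene.fluid,
        ground_truth=injections,
        planar=scene.planar,
    )
    return out
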