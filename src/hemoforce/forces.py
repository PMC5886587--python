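"""Hemodynamic force quantification from time-resolved velocity fields.

The per-voxel pressure-gradient field is obtained from the Navier-Stokes
momentum balance,

    g = -rho dv/dt - rho (v . grad) v + mu laplacian(v)      [N/m^3]

with all derivatives taken as centered finite differences on the
acquisition grid.  The hemodynamic force is the volume integral of ``g``
over the ventricular blood pool (units N), resolved into the anatomical
triad and summarised per cardiac phase as RMS and peak values, plus the
transverse/longitudinal force ratios.

A planar mode restricts the computation to the two in-plane components of
a 2D velocity series (through-plane velocity and gradients set to zero)
and integrates over an area, yielding force per unit length (N/m); this
mirrors validation against planar optical velocimetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_fields import (
    FluidProperties,
    GridSpec,
    InvalidInputError,
    VelocityField,
    convective_term,
    laplacian,
    spatial_gradient,
    temporal_derivative,
)
from .geometry import CardiacTiming, DirectionFrame, VentricleMask

__all__ = [
    "PressureGradientField",
    "ForceCurves",
    "ForceSummary",
    "pressure_gradient",
    "integrate_force",
    "project_to_frame",
    "rms_force",
    "peak_force",
    "rms_ratio",
    "peak_ratio",
    "planar_force",
]


@dataclass
class PressureGradientField:
    """Per-frame pressure-gradient vector field g, N/m^3."""

    grid: GridSpec
    values: np.ndarray  # (n_frames, nx, ny, nz, 3)
    validity: np.ndarray  # (nx, ny, nz)
    fluid: FluidProperties
    periodic_time: bool = True
    include_viscous: bool = True
    units: str = "N/m^3"


@dataclass
class ForceCurves:
    """Global force per frame (N), either world axes or anatomical triad."""

    force: np.ndarray  # (n_frames, 3)
    frame_duration: float
    basis: str = "world"  # "world" or "anatomical"
    chamber: str = "LV"
    timing: CardiacTiming | None = None
    invalid_voxel_counts: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.force.shape[0]) * self.frame_duration


@dataclass
class ForceSummary:
    """Per-phase, per-direction RMS and peak forces and the two ratios.

    Directions follow the anatomical triad order (basal-apical,
    septal-lateral / septal-freewall, inferior-anterior / diaphragm-RVOT).
    """

    chamber: str
    rms: dict = field(default_factory=dict)  # phase -> (3,) N
    peak: dict = field(default_factory=dict)  # phase -> (3,) N
    peak_frame: dict = field(default_factory=dict)  # phase -> (3,) int
    rms_ratio: dict = field(default_factory=dict)  # phase -> float
    peak_ratio: dict = field(default_factory=dict)  # phase -> float

    def as_dict(self) -> dict:
        d: dict = {"chamber": self.chamber, "units": {"force": "N", "ratio": "1"}}
        for phase in self.rms:
            d[phase] = {
                "rms_N": {
                    "basal_apical": self.rms[phase][0],
                    "septal_lateral": self.rms[phase][1],
                    "inferior_anterior": self.rms[phase][2],
                },
                "peak_N": {
                    "basal_apical": self.peak[phase][0],
                    "septal_lateral": self.peak[phase][1],
                    "inferior_anterior": self.peak[phase][2],
                },
                "peak_frame": [int(i) for i in self.peak_frame[phase]],
                "rms_ratio": self.rms_ratio[phase],
                "peak_ratio": self.peak_ratio[phase],
            }
        return d


def pressure_gradient(
    vfield: VelocityField,
    fluid: FluidProperties | None = None,
    periodic: bool = True,
    include_viscous: bool = True,
) -> PressureGradientField:
    """Navier-Stokes pressure-gradient field g = -rho dv/dt - rho (v.grad)v + mu lap v.

    Computed on the full imaged volume; the mask is applied only at the
    integration stage, so stencils near the blood-pool boundary use real
    measured flow rather than padding.  The viscous term (about three
    orders of magnitude below the inertial terms at these scales) can be
    switched off for term-wise diagnostics; where its full stencil is
    unavailable it contributes zero without invalidating the voxel.
    """
    if vfield.n_frames < 3:
        raise InvalidInputError("pressure gradient needs >= 3 frames")
    if min(vfield.grid.shape) < 3:
        raise InvalidInputError("pressure gradient needs >= 3 voxels per axis")
    fluid = fluid or FluidProperties()
    rho, mu = fluid.density, fluid.viscosity
    dvdt = temporal_derivative(vfield, periodic=periodic)
    g = np.empty_like(vfield.values)
    validity = None
    spacing = vfield.grid.spacing
    for t in range(vfield.n_frames):
        conv, conv_valid = convective_term(vfield.values[t], spacing, vfield.validity)
        g[t] = -rho * dvdt.values[t] - rho * conv
        if include_viscous and mu > 0:
            for c in range(3):
                lap, lap_valid = laplacian(vfield.values[t, ..., c], spacing, vfield.validity)
                g[t, ..., c] += mu * np.where(lap_valid, lap, 0.0)
        frame_valid = conv_valid & dvdt.validity
        validity = frame_valid if validity is None else (validity & frame_valid)
    return PressureGradientField(
        grid=vfield.grid,
        values=g,
        validity=validity,
        fluid=fluid,
        periodic_time=periodic,
        include_viscous=include_viscous,
    )


def integrate_force(
    g: PressureGradientField, mask: VentricleMask, timing: CardiacTiming | None = None
) -> ForceCurves:
    """Volume integral of g over the per-frame blood-pool mask -> force in N.

    Mask voxels whose pressure gradient is invalid (no usable stencil) are
    dropped from the integral and counted; a warning is raised if they
    exceed 5% of the mask in any frame, an error if a whole frame is
    invalid.
    """
    if mask.grid.shape != g.grid.shape:
        raise InvalidInputError("mask grid does not match pressure-gradient grid")
    n_frames = g.values.shape[0]
    vol = g.grid.voxel_volume
    force = np.zeros((n_frames, 3))
    invalid_counts = np.zeros(n_frames, dtype=int)
    for t in range(n_frames):
        m = mask.frames[t]
        usable = m & g.validity
        invalid_counts[t] = int(m.sum() - usable.sum())
        if m.sum() > 0 and usable.sum() == 0:
            raise InvalidInputError(f"all mask voxels invalid in frame {t}")
        force[t] = g.values[t][usable].sum(axis=0) * vol
    frac = invalid_counts / np.maximum(mask.frames.reshape(n_frames, -1).sum(axis=1), 1)
    if np.any(frac > 0.05):
        worst = int(np.argmax(frac))
        warnings.warn(
            f"{invalid_counts[worst]} mask voxels ({100 * frac[worst]:.1f}%) had no valid "
            f"pressure-gradient estimate in frame {worst}; they were excluded",
            RuntimeWarning,
        )
    return ForceCurves(
        force=force,
        frame_duration=g.grid.frame_duration,
        basis="world",
        chamber=mask.chamber,
        timing=timing,
        invalid_voxel_counts=invalid_counts,
    )


def project_to_frame(curves: ForceCurves, frame: DirectionFrame) -> ForceCurves:
    """Resolve world-axis force curves into the anatomical triad (norm-preserving)."""
    if curves.basis != "world":
        raise InvalidInputError("curves are already projected")
    projected = curves.force @ frame.matrix.T
    return ForceCurves(
        force=projected,
        frame_duration=curves.frame_duration,
        basis="anatomical",
        chamber=frame.chamber,
        timing=curves.timing,
        invalid_voxel_counts=curves.invalid_voxel_counts,
    )


def rms_force(curve: np.ndarray, phase_frames: np.ndarray) -> float:
    """Temporal root-mean-square of a force component over one cardiac phase."""
    phase_frames = np.asarray(phase_frames, dtype=int)
    if phase_frames.size == 0:
        raise InvalidInputError("phase has no frames")
    f = np.asarray(curve, dtype=float)[phase_frames]
    return float(np.sqrt(np.mean(np.abs(f) ** 2)))


def peak_force(curve: np.ndarray, phase_frames: np.ndarray) -> tuple[float, int]:
    """Maximum absolute force in a phase; ties broken by the earliest frame."""
    phase_frames = np.asarray(phase_frames, dtype=int)
    if phase_frames.size == 0:
        raise InvalidInputError("phase has no frames")
    f = np.abs(np.asarray(curve, dtype=float)[phase_frames])
    k = int(np.argmax(f))  # argmax returns the first maximal index
    return float(f[k]), int(phase_frames[k])


def rms_ratio(
    rms_basal_apical: float, rms_transverse_1: float, rms_transverse_2: float
) -> float:
    """Transverse/longitudinal force ratio from per-phase RMS values.

    ``sqrt(rms_t1^2 + rms_t2^2) / rms_basal_apical`` — for the LV the
    transverse pair is (septal-lateral, inferior-anterior), for the RV
    (septal-freewall, diaphragm-RVOT); the construction is identical.
    """
    if rms_basal_apical <= 0:
        raise InvalidInputError("longitudinal RMS is zero; ratio undefined")
    return float(np.hypot(rms_transverse_1, rms_transverse_2) / rms_basal_apical)


def peak_ratio(peak_basal_apical: float, peak_main_transverse: float) -> float:
    """Transverse/longitudinal ratio from peak values.

    Uses only the dominant transverse component (septal-lateral in the LV,
    diaphragm-RVOT in the RV); the secondary transverse component is
    deliberately excluded in this formulation.
    """
    if peak_basal_apical <= 0:
        raise InvalidInputError("longitudinal peak is zero; ratio undefined")
    return float(peak_main_transverse / peak_basal_apical)


def summarize_forces(curves: ForceCurves, timing: CardiacTiming | None = None) -> ForceSummary:
    """Per-phase RMS/peak values and both transverse/longitudinal ratios.

    Expects anatomical-basis curves ordered (basal-apical, septal-lateral,
    inferior-anterior) for the LV or (basal-apical, septal-freewall,
    diaphragm-RVOT) for the RV.  Ratios are always per phase, never across
    the whole cycle.  The RMS ratio combines both transverse components;
    the peak ratio uses the dominant one (septal-lateral for LV,
    diaphragm-RVOT for RV).
    """
    if curves.basis != "anatomical":
        raise InvalidInputError("summaries require anatomical-basis curves")
    timing = timing or curves.timing
    if timing is None:
        raise InvalidInputError("cardiac timing required for phase summaries")
    out = ForceSummary(chamber=curves.chamber)
    for phase, frames in (
        ("systole", timing.systole_frames),
        ("diastole", timing.diastole_frames),
    ):
        rms = np.array([rms_force(curves.force[:, c], frames) for c in range(3)])
        pk_pairs = [peak_force(curves.force[:, c], frames) for c in range(3)]
        pk = np.array([p for p, _ in pk_pairs])
        pk_at = np.array([i for _, i in pk_pairs])
        out.rms[phase] = rms
        out.peak[phase] = pk
        out.peak_frame[phase] = pk_at
        out.rms_ratio[phase] = rms_ratio(rms[0], rms[1], rms[2])
        # dominant transverse: LV septal-lateral (index 1), RV diaphragm-RVOT (index 2)
        main_t = 1 if curves.chamber == "LV" else 2
        out.peak_ratio[phase] = peak_ratio(pk[0], pk[main_t])
    return out


def planar_force(
    v2d: np.ndarray,
    mask2d: np.ndarray,
    pixel_spacing: tuple[float, float],
    frame_duration: float,
    fluid: FluidProperties | None = None,
    periodic: bool = True,
) -> np.ndarray:
    """In-plane force per unit length (N/m) from a planar 2-component series.

    The momentum balance is restricted to the two in-plane components with
    through-plane velocity and through-plane derivatives set to zero, and
    the resulting in-plane pressure gradient is integrated over the masked
    plane (area integral of N/m^3 -> N/m).

    Parameters
    ----------
    v2d
        ``(n_frames, nx, ny, 2)`` in-plane velocities, m/s.
    mask2d
        ``(nx, ny)`` or ``(n_frames, nx, ny)`` integration mask.
    pixel_spacing
        In-plane pixel size (m).
    """
    v2d = np.asarray(v2d, dtype=float)
    if v2d.ndim != 4 or v2d.shape[-1] != 2:
        raise InvalidInputError("planar velocities must have shape (t, nx, ny, 2)")
    if v2d.shape[0] < 3:
        raise InvalidInputError("planar mode needs >= 3 frames")
    if v2d.shape[1] < 3 or v2d.shape[2] < 3:
        raise InvalidInputError("planar grid must be at least 3x3")
    fluid = fluid or FluidProperties()
    n_frames, nx, ny, _ = v2d.shape
    # embed as a 3-voxel-thick z-invariant 3D field so the 3D kernels apply
    v3 = np.zeros((n_frames, nx, ny, 3, 3))
    v3[..., 0] = v2d[..., None, 0]
    v3[..., 1] = v2d[..., None, 1]
    grid = GridSpec(
        spacing=(float(pixel_spacing[0]), float(pixel_spacing[1]), 1.0),
        frame_duration=frame_duration,
        shape=(nx, ny, 3),
        n_frames=n_frames,
    )
    g = pressure_gradient(
        VelocityField(grid, v3), fluid=fluid, periodic=periodic, include_viscous=True
    )
    mask2d = np.asarray(mask2d, dtype=bool)
    if mask2d.ndim == 2:
        mask2d = np.broadcast_to(mask2d, (n_frames, nx, ny))
    area = float(pixel_spacing[0]) * float(pixel_spacing[1])
    out = np.zeros((n_frames, 2))
    mid = 1  # central z-slice of the embedded field
    for t in range(n_frames):
        m = mask2d[t] & g.validity[..., mid]
        out[t] = g.values[t, :, :, mid, :2][m].sum(axis=0) * area
    return out
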