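"""Gridded field containers and the finite-difference calculus.

All downstream force and pressure computations are built from the four
derivative operators defined here: temporal derivative, spatial gradient,
convective term and Laplacian, all using centered differences on the
rectilinear voxel grid, with first-order one-sided fallbacks at domain or
validity boundaries.

Conventions
-----------
* Internal units are SI throughout (m, s, kg, Pa, N).
* Velocity arrays have shape ``(n_frames, nx, ny, nz, 3)``.
* Per-voxel validity is a boolean array of shape ``(nx, ny, nz)``; a voxel
  is valid when its velocity is actually measured (inside the imaged
  volume).  Derivative outputs carry their own validity: a voxel is valid
  in the output when at least a one-sided stencil was available along every
  differentiated axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "VelocityField",
    "ScalarField",
    "VectorField",
    "FluidProperties",
    "temporal_derivative",
    "spatial_gradient",
    "convective_term",
    "laplacian",
]

#: blood density used throughout, kg/m^3
DEFAULT_DENSITY = 1050.0
#: blood dynamic viscosity, N s/m^2
DEFAULT_VISCOSITY = 4.0e-3


class InvalidInputError(ValueError):
    """Raised when an operation's preconditions are violated."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry and timing metadata of a rectilinear acquisition grid.

    Parameters
    ----------
    spacing
        Voxel edge length along each axis, meters.
    frame_duration
        Time per cardiac frame, seconds.
    shape
        Voxel counts ``(nx, ny, nz)``.
    n_frames
        Frames per cardiac cycle (>= 2).
    origin
        World position of voxel ``(0, 0, 0)``, meters.
    axes_orientation
        3x3 direction-cosine matrix mapping voxel axes to world axes;
        must be orthonormal with determinant +1.
    """

    spacing: tuple[float, float, float]
    frame_duration: float
    shape: tuple[int, int, int]
    n_frames: int
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes_orientation: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    def __post_init__(self):
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise InvalidInputError("grid spacing must be 3 positive lengths")
        if self.frame_duration <= 0:
            raise InvalidInputError("frame_duration must be positive")
        if self.n_frames < 2:
            raise InvalidInputError("need at least 2 frames per cycle")
        R = np.asarray(self.axes_orientation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise InvalidInputError("axes_orientation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidInputError("axes_orientation must be right-handed (det +1)")
        object.__setattr__(self, "spacing", tuple(float(s) for s in sp))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, m^3."""
        return float(np.prod(self.spacing))

    def voxel_centers_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of all voxel centers, three (nx,ny,nz) arrays (m)."""
        idx = np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij")
        local = np.stack([idx[a] * self.spacing[a] for a in range(3)], axis=-1)
        R = np.asarray(self.axes_orientation, dtype=float)
        world = local @ R.T + np.asarray(self.origin)
        return world[..., 0], world[..., 1], world[..., 2]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates (m) to fractional voxel indices."""
        R = np.asarray(self.axes_orientation, dtype=float)
        local = (np.atleast_2d(points) - np.asarray(self.origin)) @ R
        return local / np.asarray(self.spacing)


@dataclass(frozen=True)
class FluidProperties:
    """Fluid density rho (kg/m^3) and dynamic viscosity mu (N s/m^2)."""

    density: float = DEFAULT_DENSITY
    viscosity: float = DEFAULT_VISCOSITY

    def __post_init__(self):
        if self.density <= 0:
            raise InvalidInputError("density must be positive")
        if self.viscosity < 0:
            raise InvalidInputError("viscosity must be non-negative")


@dataclass
class VelocityField:
    """Time-resolved 3-component velocity on a rectilinear grid (m/s)."""

    grid: GridSpec
    values: np.ndarray  # (n_frames, nx, ny, nz, 3)
    validity: np.ndarray | None = None  # (nx, ny, nz) bool

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        expected = (self.grid.n_frames, *self.grid.shape, 3)
        if v.shape != expected:
            raise InvalidInputError(
                f"velocity values have shape {v.shape}, expected {expected}"
            )
        if self.validity is None:
            self.validity = np.ones(self.grid.shape, dtype=bool)
        else:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape != self.grid.shape:
                raise InvalidInputError("validity shape must match grid shape")
        if not np.all(np.isfinite(v[:, self.validity])):
            raise InvalidInputError("velocity must be finite on valid voxels")
        self.values = v

    @property
    def n_frames(self) -> int:
        return self.grid.n_frames

    def copy(self) -> "VelocityField":
        return VelocityField(self.grid, self.values.copy(), self.validity.copy())


@dataclass
class ScalarField:
    """Single-frame scalar voxel field with a mandatory units tag."""

    grid: GridSpec
    values: np.ndarray  # (nx, ny, nz)
    units: str
    validity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.units:
            raise InvalidInputError("units tag is mandatory")
        if self.validity is None:
            self.validity = np.ones(self.values.shape, dtype=bool)


@dataclass
class VectorField:
    """Single- or multi-frame 3-vector voxel field with a units tag."""

    grid: GridSpec
    values: np.ndarray  # (..., nx, ny, nz, 3)
    units: str
    validity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.units:
            raise InvalidInputError("units tag is mandatory")
        if self.validity is None:
            self.validity = np.ones(self.values.shape[-4:-1], dtype=bool)


# ---------------------------------------------------------------------------
# finite-difference kernels
# ---------------------------------------------------------------------------


def _shift(a: np.ndarray, step: int, axis: int, fill=0.0) -> np.ndarray:
    """Return a with entries taken from index i+step along axis, edge-filled."""
    out = np.full_like(a, fill)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if step > 0:
        src[axis] = slice(step, None)
        dst[axis] = slice(None, -step)
    elif step < 0:
        src[axis] = slice(None, step)
        dst[axis] = slice(-step, None)
    else:
        return a.copy()
    out[tuple(dst)] = a[tuple(src)]
    return out


def _diff_axis(
    f: np.ndarray, valid: np.ndarray, h: float, axis: int
) -> tuple[np.ndarray, np.ndarray]:
    """First derivative of f along one axis honouring a validity mask.

    Centered where both neighbours are valid, one-sided where only one is,
    invalid where neither is.  Returns ``(derivative, output_validity)``.
    """
    fp = _shift(f, +1, axis)
    fm = _shift(f, -1, axis)
    vp = _shift(valid, +1, axis, fill=False)
    vm = _shift(valid, -1, axis, fill=False)

    d = np.zeros_like(f)
    both = valid & vp & vm
    fwd = valid & vp & ~vm
    bwd = valid & vm & ~vp
    d[both] = (fp[both] - fm[both]) / (2.0 * h)
    d[fwd] = (fp[fwd] - f[fwd]) / h
    d[bwd] = (f[bwd] - fm[bwd]) / h
    return d, both | fwd | bwd


def temporal_derivative(vfield: VelocityField, periodic: bool = True) -> VectorField:
    """Frame-to-frame velocity derivative dv/dt, m/s^2.

    Centered differences ``(v[t+1] - v[t-1]) / (2 dt)``.  With
    ``periodic=True`` (retrospectively gated data covering the full cycle)
    frame indices wrap modulo ``n_frames``; otherwise the first and last
    frames use first-order one-sided differences.
    """
    n = vfield.n_frames
    if periodic and n < 3:
        raise InvalidInputError("periodic temporal derivative needs >= 3 frames")
    if n < 2:
        raise InvalidInputError("temporal derivative needs >= 2 frames")
    v = vfield.values
    dt = vfield.grid.frame_duration
    if periodic:
        dvdt = (np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)) / (2.0 * dt)
    else:
        dvdt = np.empty_like(v)
        dvdt[1:-1] = (v[2:] - v[:-2]) / (2.0 * dt)
        dvdt[0] = (v[1] - v[0]) / dt
        dvdt[-1] = (v[-1] - v[-2]) / dt
    return VectorField(vfield.grid, dvdt, units="m/s^2", validity=vfield.validity.copy())


def spatial_gradient(
    values: np.ndarray, spacing: Sequence[float], validity: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of a scalar voxel array: centered interior, one-sided at edges.

    Parameters
    ----------
    values
        Scalar array of shape (nx, ny, nz).
    spacing
        Voxel spacing per axis (m).
    validity
        Boolean mask of defined voxels; domain edges behave like validity
        boundaries.

    Returns
    -------
    grad : (nx, ny, nz, 3) array
    valid_out : (nx, ny, nz) bool — True where a stencil existed on *every* axis
    """
    f = np.asarray(values, dtype=float)
    if f.ndim != 3:
        raise InvalidInputError("spatial_gradient expects a 3D scalar array")
    if min(f.shape) < 2:
        raise InvalidInputError(
            f"degenerate axis: grid shape {f.shape} has an axis with < 2 voxels"
        )
    if validity is None:
        validity = np.ones(f.shape, dtype=bool)
    grad = np.zeros(f.shape + (3,))
    valid_out = validity.copy()
    for axis in range(3):
        d, va = _diff_axis(f, validity, float(spacing[axis]), axis)
        grad[..., axis] = d
        valid_out &= va
    return grad, valid_out


def convective_term(
    v_frame: np.ndarray, spacing: Sequence[float], validity: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(v . grad) v for one frame: component i is sum_j v_j dv_i/dx_j (m/s^2)."""
    v = np.asarray(v_frame, dtype=float)
    if v.ndim != 4 or v.shape[-1] != 3:
        raise InvalidInputError("convective_term expects a (nx,ny,nz,3) frame")
    out = np.zeros_like(v)
    valid_out = None
    for i in range(3):
        grad_i, va = spatial_gradient(v[..., i], spacing, validity)
        out[..., i] = np.einsum("...j,...j->...", v, grad_i)
        valid_out = va if valid_out is None else (valid_out & va)
    return out, valid_out


def laplacian(
    values: np.ndarray, spacing: Sequence[float], validity: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Standard 7-point Laplacian; voxels lacking a full stencil are invalid."""
    f = np.asarray(values, dtype=float)
    if f.ndim != 3:
        raise InvalidInputError("laplacian expects a 3D scalar array")
    if min(f.shape) < 3:
        raise InvalidInputError("laplacian needs >= 3 voxels along each axis")
    if validity is None:
        validity = np.ones(f.shape, dtype=bool)
    out = np.zeros_like(f)
    valid_out = validity.copy()
    for axis in range(3):
        h2 = float(spacing[axis]) ** 2
        fp = _shift(f, +1, axis)
        fm = _shift(f, -1, axis)
        vp = _shift(validity, +1, axis, fill=False)
        vm = _shift(validity, -1, axis, fill=False)
        out += (fp - 2.0 * f + fm) / h2
        valid_out &= vp & vm
    out[~valid_out] = 0.0
    return out, valid_out
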