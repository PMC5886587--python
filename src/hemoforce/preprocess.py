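"""Velocity-data conditioning applied before force computation.

Phase-contrast velocity data carry two characteristic artifacts that must
be removed before Navier-Stokes pressure gradients are meaningful:

* a slowly varying background phase offset from eddy currents, removed by
  subtracting a first-order (linear) polynomial fitted to velocities in
  static tissue;
* phase wraps (aliasing), where true velocities beyond the velocity
  encoding limit VENC appear shifted by multiples of 2*VENC.

A rigid translation utility resamples segmentation masks drawn on the cine
grid onto the velocity grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_fields import GridSpec, InvalidInputError, VelocityField

__all__ = [
    "StaticTissueMask",
    "background_correct",
    "unwrap_velocity",
    "align_mask",
]

_AXES = "xyz"


@dataclass
class StaticTissueMask:
    """Boolean voxel mask of static tissue used for background fitting."""

    mask: np.ndarray  # (nx, ny, nz) bool

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.sum() < 100:
            raise InvalidInputError(
                "static-tissue mask needs >= 100 voxels for a well-posed fit"
            )


def _design_matrix(grid: GridSpec, mask: np.ndarray) -> np.ndarray:
    x, y, z = grid.voxel_centers_world()
    return np.column_stack(
        [np.ones(mask.sum()), x[mask], y[mask], z[mask]]
    )


def background_correct(
    vfield: VelocityField,
    static: StaticTissueMask,
    per_frame: bool = False,
) -> tuple[VelocityField, np.ndarray]:
    """Subtract a first-order polynomial fit of static-tissue velocities.

    For each velocity component, a plane ``a + b x + c y + d z`` is fitted
    by least squares over the static-tissue voxels and subtracted from the
    whole field.  By default the fit is to the time-averaged velocity
    (eddy-current offsets are stationary over the cycle); ``per_frame=True``
    fits and subtracts a separate plane per frame.

    Returns the corrected field and the fit coefficients, shaped ``(3, 4)``
    (component x [const, x, y, z]) or ``(n_frames, 3, 4)`` when per-frame.
    """
    mask = static.mask & vfield.validity
    for axis in range(3):
        spans = np.any(mask, axis=tuple(a for a in range(3) if a != axis))
        if spans.sum() < 2:
            raise InvalidInputError(
                f"static-tissue voxels are degenerate along axis {_AXES[axis]}: "
                "cannot fit a spatial slope there"
            )
    X = _design_matrix(vfield.grid, mask)
    # guard against coplanar voxel clouds that still span >1 voxel per axis
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise InvalidInputError("static-tissue voxels are coplanar; fit is rank-deficient")

    x, y, z = vfield.grid.voxel_centers_world()
    basis = np.stack([np.ones_like(x), x, y, z], axis=-1)  # (nx,ny,nz,4)
    corrected = vfield.values.copy()

    if per_frame:
        coefs = np.empty((vfield.n_frames, 3, 4))
        for t in range(vfield.n_frames):
            for c in range(3):
                beta, *_ = np.linalg.lstsq(X, vfield.values[t][mask][:, c], rcond=None)
                coefs[t, c] = beta
                corrected[t, ..., c] -= basis @ beta
    else:
        vbar = vfield.values.mean(axis=0)  # (nx,ny,nz,3)
        coefs = np.empty((3, 4))
        for c in range(3):
            beta, *_ = np.linalg.lstsq(X, vbar[mask][:, c], rcond=None)
            coefs[c] = beta
            corrected[..., c] -= basis @ beta
    return VelocityField(vfield.grid, corrected, vfield.validity.copy()), coefs


def unwrap_velocity(
    vfield: VelocityField,
    venc: float,
    manual_overrides: list[tuple[int, int, int, int, int, int]] | None = None,
) -> VelocityField:
    """Resolve phase wraps by temporal then spatial continuity.

    Measured values must lie in [-venc, +venc].  The temporal pass scans
    frames in order per voxel and shifts each frame by the multiple of
    2*venc that minimises the jump from the previous (already unwrapped)
    frame.  The spatial pass then shifts voxels that differ from the median
    of their valid 6-neighbours by more than venc.  Alias-free fields pass
    through unchanged; every change is an integer multiple of 2*venc.

    ``manual_overrides`` entries are ``(frame, i, j, k, component, multiple)``
    and are applied last, adding ``multiple * 2 * venc``.
    """
    if venc <= 0:
        raise InvalidInputError("venc must be positive")
    v = vfield.values
    valid = vfield.validity
    if np.any(np.abs(v[:, valid]) > venc * (1 + 1e-9)):
        raise InvalidInputError("input velocities exceed [-venc, +venc]; not raw wrapped data")

    out = v.copy()
    # temporal pass: continuity with the previous unwrapped frame
    for t in range(1, vfield.n_frames):
        jump = out[t] - out[t - 1]
        k = np.round(jump / (2.0 * venc))
        out[t] -= 2.0 * venc * k

    # spatial pass: compare against median of valid 6-neighbours
    flips_total = 0
    proposed: list[tuple[int, np.ndarray, np.ndarray]] = []
    for t in range(vfield.n_frames):
        for c in range(3):
            med = _neighbor_median(out[t, ..., c], valid)
            diff = out[t, ..., c] - med
            k = np.round(diff / (2.0 * venc))
            flip = valid & np.isfinite(med) & (np.abs(diff) > venc)
            proposed.append((flips_total, flip, -2.0 * venc * k))
            flips_total += int(flip.sum())
    n_valid = max(int(valid.sum()) * vfield.n_frames * 3, 1)
    if flips_total > 0.3 * n_valid:
        warnings.warn(
            "spatial unwrap would flip >30% of voxels (checkerboard-like pattern); "
            "unresolvable automatically, spatial pass skipped",
            RuntimeWarning,
        )
    else:
        idx = 0
        for t in range(vfield.n_frames):
            for c in range(3):
                _, flip, delta = proposed[idx]
                out[t, ..., c][flip] += delta[flip]
                idx += 1

    for ov in manual_overrides or []:
        t, i, j, k_, c, mult = ov
        out[t, i, j, k_, c] += 2.0 * venc * mult
    return VelocityField(vfield.grid, out, valid.copy())


def _neighbor_median(f: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Median over the valid 6-neighbourhood; NaN where no valid neighbour."""
    stacks = []
    for axis in range(3):
        for step in (+1, -1):
            g = np.full_like(f, np.nan)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if step > 0:
                src[axis], dst[axis] = slice(1, None), slice(None, -1)
            else:
                src[axis], dst[axis] = slice(None, -1), slice(1, None)
            g[tuple(dst)] = np.where(valid, f, np.nan)[tuple(src)]
            stacks.append(g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighbourhoods
        return np.nanmedian(np.stack(stacks), axis=0)


def align_mask(
    mask_frames: np.ndarray,
    source_grid: GridSpec,
    target_grid: GridSpec,
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Rigidly translate a per-frame binary mask and resample it to a grid.

    The user-supplied translation (mm, world axes) is applied to the mask,
    which is then resampled onto ``target_grid`` with nearest-neighbour
    interpolation so membership stays binary.

    Parameters
    ----------
    mask_frames
        Boolean array ``(n_frames, nx, ny, nz)`` on ``source_grid``.
    shift_mm
        Rigid translation in millimetres.

    Returns
    -------
    Boolean array on ``target_grid`` with the same frame count.
    """
    shift = np.asarray(shift_mm, dtype=float) * 1e-3
    if not np.all(np.isfinite(shift)):
        raise InvalidInputError("shift must be finite")
    mask_frames = np.asarray(mask_frames, dtype=bool)
    tx, ty, tz = target_grid.voxel_centers_world()
    pts = np.stack([tx, ty, tz], axis=-1).reshape(-1, 3)
    # target center maps back to source index after undoing the shift
    src_idx = np.round(source_grid.world_to_index(pts - shift)).astype(int)
    inb = np.all((src_idx >= 0) & (src_idx < np.asarray(source_grid.shape)), axis=1)
    out = np.zeros((mask_frames.shape[0], *target_grid.shape), dtype=bool)
    flat = out.reshape(mask_frames.shape[0], -1)
    ii, jj, kk = src_idx[inb].T
    for t in range(mask_frames.shape[0]):
        flat[t, inb] = mask_frames[t, ii, jj, kk]
    if mask_frames.any() and not out.any():
        raise InvalidInputError("shift moved the mask entirely outside the target grid")
    return out
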