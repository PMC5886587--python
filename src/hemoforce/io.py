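"""Readers and writers for the formats the pipeline touches.

Velocity fields and masks travel as NIfTI (the neutral interchange format
for resampled 4D flow data; vendor DICOM ingestion happens upstream):

* velocity: 5D NIfTI ``(x, y, z, t, component)``, voxel size from the
  affine (mm), frame duration in ``pixdim[4]`` (s); stored values may be
  cm/s or m/s — the caller declares the unit and everything internal is SI;
* masks: 4D NIfTI ``(x, y, z, t)`` of 0/1;
* pressure fields: 4D NIfTI in Pa with NaN outside the mask;
* landmarks / timing / summaries: JSON; force curves: CSV with unit-bearing
  headers;
* synthetic scenes: HDF5 with ground truth attached.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .core_fields import GridSpec, InvalidInputError, VelocityField
from .forces import ForceCurves
from .geometry import AVPlaneLandmarks, VentricleMask

__all__ = [
    "read_velocity_nifti",
    "write_velocity_nifti",
    "read_mask_nifti",
    "write_mask_nifti",
    "write_pressure_nifti",
    "read_landmarks_json",
    "write_landmarks_json",
    "write_force_csv",
    "write_summary_json",
    "save_scene_hdf5",
    "load_scene_hdf5",
]

_UNIT_SCALE = {"m/s": 1.0, "cm/s": 0.01}


def _affine(grid: GridSpec) -> np.ndarray:
    A = np.eye(4)
    R = np.asarray(grid.axes_orientation)
    A[:3, :3] = R * (np.asarray(grid.spacing) * 1e3)  # NIfTI affines are in mm
    A[:3, 3] = np.asarray(grid.origin) * 1e3
    return A


def _grid_from_img(img, n_frames: int) -> GridSpec:
    zooms = img.header.get_zooms()
    spacing = tuple(float(s) * 1e-3 for s in zooms[:3])
    if len(zooms) < 4 or zooms[3] <= 0:
        raise InvalidInputError(
            "NIfTI header lacks a positive frame duration (pixdim[4]); "
            "set it to the time per cardiac frame in seconds"
        )
    A = img.affine
    R = A[:3, :3] / (np.asarray(spacing) * 1e3)
    return GridSpec(
        spacing=spacing,
        frame_duration=float(zooms[3]),
        shape=tuple(int(n) for n in img.shape[:3]),
        n_frames=n_frames,
        origin=tuple(float(v) * 1e-3 for v in A[:3, 3]),
        axes_orientation=tuple(tuple(row) for row in R),
    )


def write_velocity_nifti(vfield: VelocityField, path, units: str = "m/s") -> None:
    scale = _UNIT_SCALE.get(units)
    if scale is None:
        raise InvalidInputError(f"unknown velocity units {units!r}; use m/s or cm/s")
    data = np.moveaxis(vfield.values, 0, 3) / scale  # -> (x, y, z, t, comp)
    img = nib.Nifti1Image(data.astype(np.float32), _affine(vfield.grid))
    img.header.set_zooms(
        (*[s * 1e3 for s in vfield.grid.spacing], vfield.grid.frame_duration, 1.0)
    )
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_velocity_nifti(path, units: str = "m/s", venc: float | None = None) -> VelocityField:
    """Load a 5D (x,y,z,t,component) velocity NIfTI; values converted to m/s."""
    scale = _UNIT_SCALE.get(units)
    if scale is None:
        raise InvalidInputError(f"unknown velocity units {units!r}; use m/s or cm/s")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 5 or data.shape[4] != 3:
        raise InvalidInputError(
            f"velocity NIfTI must be 5D (x,y,z,t,3); got shape {data.shape}"
        )
    grid = _grid_from_img(img, n_frames=data.shape[3])
    values = np.moveaxis(data, 3, 0) * scale
    validity = np.all(np.isfinite(values), axis=(0, 4))
    values = np.where(np.isfinite(values), values, 0.0)
    if venc is not None and np.any(np.abs(values[:, validity]) > venc * 1.001):
        raise InvalidInputError("velocities exceed the declared VENC; check units")
    return VelocityField(grid, values, validity)


def write_mask_nifti(mask: VentricleMask, path) -> None:
    data = np.moveaxis(mask.frames, 0, 3).astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(mask.grid))
    img.header.set_zooms(
        (*[s * 1e3 for s in mask.grid.spacing], mask.grid.frame_duration)
    )
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask_nifti(path, chamber: str = "LV") -> VentricleMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise InvalidInputError(f"mask NIfTI must be 4D (x,y,z,t); got shape {data.shape}")
    grid = _grid_from_img(img, n_frames=data.shape[3])
    return VentricleMask(grid, np.moveaxis(data > 0, 3, 0), chamber=chamber)


def write_pressure_nifti(pressures: list, path) -> None:
    """Stack per-frame relative-pressure fields into a 4D NIfTI (Pa)."""
    grid = pressures[0].grid
    data = np.stack([p.values for p in pressures], axis=3).astype(np.float32)
    img = nib.Nifti1Image(data, _affine(grid))
    img.header.set_zooms((*[s * 1e3 for s in grid.spacing], grid.frame_duration))
    img.header.set_xyzt_units("mm", "sec")
    img.header["descrip"] = b"relative pressure, Pa, NaN outside mask"
    nib.save(img, str(path))


def read_landmarks_json(path) -> dict:
    """Landmark/orientation bundle: points_mm, three_chamber_normal, hints."""
    with open(path) as f:
        d = json.load(f)
    out = {
        "landmarks": AVPlaneLandmarks(np.asarray(d["points_mm"], dtype=float) * 1e-3),
        "three_chamber_normal": np.asarray(d["three_chamber_normal"], dtype=float),
    }
    for key in ("apex_hint_mm", "lateral_hint_mm"):
        if key in d:
            out[key.replace("_mm", "")] = np.asarray(d[key], dtype=float) * 1e-3
    return out


def write_landmarks_json(path, landmarks: AVPlaneLandmarks, three_chamber_normal,
                         apex_hint=None, lateral_hint=None) -> None:
    d = {
        "points_mm": (landmarks.points * 1e3).tolist(),
        "three_chamber_normal": np.asarray(three_chamber_normal, dtype=float).tolist(),
    }
    if apex_hint is not None:
        d["apex_hint_mm"] = (np.asarray(apex_hint) * 1e3).tolist()
    if lateral_hint is not None:
        d["lateral_hint_mm"] = (np.asarray(lateral_hint) * 1e3).tolist()
    with open(path, "w") as f:
        json.dump(d, f, indent=1, sort_keys=True)


def write_force_csv(curves: ForceCurves, path) -> None:
    """Force curves as CSV: frame, time_s, and the three components in N."""
    if curves.basis == "anatomical":
        cols = ["F_basal_apical_N", "F_septal_lateral_N", "F_inferior_anterior_N"]
        if curves.chamber == "RV":
            cols = ["F_basal_apical_N", "F_septal_freewall_N", "F_diaphragm_rvot_N"]
    else:
        cols = ["F_x_N", "F_y_N", "F_z_N"]
    df = pd.DataFrame(curves.force, columns=cols)
    df.insert(0, "time_s", curves.times)
    df.insert(0, "frame", np.arange(curves.force.shape[0]))
    df.to_csv(path, index=False, float_format="%.9g")


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(summary, f, indent=1, sort_keys=True, default=float)
        f.write("\n")


def save_scene_hdf5(scene, path) -> None:
    """Persist a synthetic scene (velocity, mask, geometry, ground truth)."""
    with h5py.File(path, "w") as f:
        g = scene.velocity.grid
        f.attrs["spacing_m"] = g.spacing
        f.attrs["frame_duration_s"] = g.frame_duration
        f.attrs["origin_m"] = g.origin
        f.attrs["end_systole"] = scene.timing.end_systole
        f.attrs["chamber"] = scene.mask.chamber
        f.attrs["density"] = scene.fluid.density
        f.attrs["viscosity"] = scene.fluid.viscosity
        f.create_dataset("velocity_m_per_s", data=scene.velocity.values, compression="gzip")
        f.create_dataset("mask", data=scene.mask.frames, compression="gzip")
        if scene.landmarks is not None:
            f.create_dataset("landmark_points_m", data=scene.landmarks.points)
            f.create_dataset("three_chamber_normal", data=scene.three_chamber_normal)
            f.create_dataset("apex_hint_m", data=scene.apex_hint)
            f.create_dataset("lateral_hint_m", data=scene.lateral_hint)
        gt = f.create_group("ground_truth")
        for k, v in scene.ground_truth.items():
            if isinstance(v, np.ndarray):
                gt.create_dataset(k, data=v)
            elif isinstance(v, (int, float)):
                gt.attrs[k] = v


def load_scene_hdf5(path):
    from .core_fields import FluidProperties
    from .geometry import CardiacTiming
    from .synthetic import SyntheticScene

    with h5py.File(path, "r") as f:
        values = f["velocity_m_per_s"][...]
        frames = f["mask"][...].astype(bool)
        grid = GridSpec(
            spacing=tuple(f.attrs["spacing_m"]),
            frame_duration=float(f.attrs["frame_duration_s"]),
            shape=values.shape[1:4],
            n_frames=values.shape[0],
            origin=tuple(f.attrs["origin_m"]),
        )
        scene = SyntheticScene(
            velocity=VelocityField(grid, values),
            mask=VentricleMask(grid, frames, chamber=str(f.attrs["chamber"])),
            timing=CardiacTiming(int(f.attrs["end_systole"]), grid.n_frames,
                                 grid.frame_duration),
            fluid=FluidProperties(float(f.attrs["density"]), float(f.attrs["viscosity"])),
            ground_truth={k: v[...] for k, v in f["ground_truth"].items()},
        )
        scene.ground_truth.update(dict(f["ground_truth"].attrs))
        if "landmark_points_m" in f:
            scene.landmarks = AVPlaneLandmarks(f["landmark_points_m"][...])
            scene.three_chamber_normal = f["three_chamber_normal"][...]
            scene.apex_hint = f["apex_hint_m"][...]
            scene.lateral_hint = f["lateral_hint_m"][...]
    return scene
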