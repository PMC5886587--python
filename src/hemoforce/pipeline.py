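"""End-to-end pipeline: files in, force curves and summaries out.

Stages: preprocessing (background correction, unwrapping) -> geometry
(mask alignment, anatomical frame, cardiac timing) -> pressure gradient ->
force integration, projection and per-phase summaries -> optional relative
pressure reconstruction.  Every run writes the force CSV, a summary JSON
embedding the configuration hash and every design-setting value used, and
optionally a pressure NIfTI.  Outputs are deterministic: rerunning the
same configuration reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .core_fields import FluidProperties, InvalidInputError
from .forces import integrate_force, pressure_gradient, project_to_frame, summarize_forces
from .geometry import (
    CardiacTiming,
    DirectionFrame,
    VentricleMask,
    build_direction_frame,
    fit_av_plane,
    mask_volume_curve,
)
from .io import (
    read_landmarks_json,
    read_mask_nifti,
    read_velocity_nifti,
    write_force_csv,
    write_pressure_nifti,
    write_summary_json,
)
from .preprocess import StaticTissueMask, align_mask, background_correct, unwrap_velocity

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; paths are validated up front."""

    velocity_path: str
    mask_path: str
    out_dir: str
    units: str = "m/s"
    chamber: str = "LV"
    landmarks_path: str | None = None
    static_mask_path: str | None = None
    venc: float | None = None
    unwrap: bool = False
    end_systole: int | None = None
    density: float = 1050.0
    viscosity: float = 4.0e-3
    mask_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    periodic_time: bool = True
    include_viscous: bool = True
    compute_pressure: bool = False
    pressure_frames: tuple[int, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        for p in (self.velocity_path, self.mask_path,
                  self.landmarks_path, self.static_mask_path):
            if p is not None and not Path(p).exists():
                raise InvalidInputError(f"input path does not exist: {p}")
        if self.units not in ("m/s", "cm/s"):
            raise InvalidInputError("velocity units must be declared as m/s or cm/s")
        if self.chamber not in ("LV", "RV"):
            raise InvalidInputError("chamber must be LV or RV")

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full quantification pipeline; returns the result bundle.

    Writes ``forces.csv`` and ``summary.json`` (and ``pressure.nii.gz`` if
    requested) into ``config.out_dir``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"hemoforce {__version__}", f"config hash {config.hash()}"]

    vfield = read_velocity_nifti(config.velocity_path, units=config.units, venc=config.venc)
    log.append(f"velocity: {vfield.grid.shape} x {vfield.n_frames} frames, "
               f"dt={vfield.grid.frame_duration:.4g}s")

    if config.static_mask_path:
        static_img = read_mask_nifti(config.static_mask_path)
        vfield, coefs = background_correct(vfield, StaticTissueMask(static_img.frames[0]))
        log.append(f"background correction applied, max |plane offset| "
                   f"{np.abs(coefs[:, 0]).max():.3g} m/s")
    if config.unwrap:
        if config.venc is None:
            raise InvalidInputError("unwrapping requires --venc")
        vfield = unwrap_velocity(vfield, config.venc)
        log.append(f"velocity unwrapped at venc {config.venc} m/s")

    mask_in = read_mask_nifti(config.mask_path, chamber=config.chamber)
    frames = align_mask(mask_in.frames, mask_in.grid, vfield.grid, config.mask_shift_mm)
    if frames.shape[0] == 1 and vfield.n_frames > 1:
        frames = np.broadcast_to(frames, (vfield.n_frames, *vfield.grid.shape)).copy()
    if frames.shape[0] != vfield.n_frames:
        raise InvalidInputError("mask frame count does not match velocity frames")
    mask = VentricleMask(vfield.grid, frames, chamber=config.chamber)

    if config.landmarks_path:
        lm = read_landmarks_json(config.landmarks_path)
        apex = lm.get("apex_hint", mask.centroid_world(0))
        point, normal = fit_av_plane(lm["landmarks"], apex_reference=apex)
        frame = build_direction_frame(
            normal, lm["three_chamber_normal"], chamber=config.chamber,
            apex_hint=apex, lateral_hint=lm.get("lateral_hint"), plane_point=point,
        )
        log.append("anatomical frame from AV-plane landmarks")
    else:
        frame = DirectionFrame.world_axes(config.chamber)
        warnings.warn("no landmarks supplied; using world-axis direction frame",
                      RuntimeWarning)
        log.append("anatomical frame: world axes fallback")

    volume_ml = mask_volume_curve(mask)
    if config.end_systole is not None:
        es = int(config.end_systole)
        log.append(f"end-systole: user override frame {es}")
    else:
        es = int(np.argmin(volume_ml))
        warnings.warn(f"no end-systole override; using minimum-volume frame {es}",
                      RuntimeWarning)
        log.append(f"end-systole: minimum-volume frame {es}")
    timing = CardiacTiming(es, vfield.n_frames, vfield.grid.frame_duration)

    fluid = FluidProperties(config.density, config.viscosity)
    g = pressure_gradient(vfield, fluid, periodic=config.periodic_time,
                          include_viscous=config.include_viscous)
    world = integrate_force(g, mask, timing)
    anat = project_to_frame(world, frame)
    summary = summarize_forces(anat, timing)

    bundle = {
        "config_hash": config.hash(),
        "version": __version__,
        "settings": {
            "density_kg_m3": config.density,
            "viscosity_Ns_m2": config.viscosity,
            "periodic_time": config.periodic_time,
            "include_viscous": config.include_viscous,
            "units_in": config.units,
            "end_systole_frame": es,
            "direction_frame": frame.matrix.tolist(),
        },
        "volume_curve_ml": volume_ml.tolist(),
        "forces": summary.as_dict(),
        "log": log,
    }
    write_force_csv(anat, out_dir / "forces.csv")
    write_summary_json(bundle, out_dir / "summary.json")

    if config.compute_pressure:
        from .pressure_field import solve_ppe

        frames_to_solve = config.pressure_frames or tuple(range(vfield.n_frames))
        fields = [solve_ppe(g, mask, t) for t in frames_to_solve]
        write_pressure_nifti(fields, out_dir / "pressure.nii.gz")
        bundle["pressure_frames"] = list(frames_to_solve)

    bundle["force_curves"] = anat
    bundle["world_curves"] = world
    bundle["timing"] = timing
    return bundle
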