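"""Anatomical reference frames, cardiac-phase bookkeeping and mask utilities.

Force components are reported in an anatomically defined orthonormal triad:

* basal-apical ``b`` — normal of the atrioventricular (AV) plane, fitted to
  manually placed landmarks from long-axis views, oriented apex -> base so
  that force toward the base is positive;
* septal-lateral (LV) / septal-freewall (RV) ``s`` — perpendicular to ``b``
  and parallel to the 3-chamber slice plane, oriented septum -> lateral wall;
* inferior-anterior (LV) / diaphragm-RVOT (RV) ``a`` — completes the
  right-handed triad.

The cardiac cycle is split at end-systole, estimated from the cessation of
aortic outflow and onset of transmitral inflow, and always overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .core_fields import GridSpec, InvalidInputError, VelocityField

__all__ = [
    "AVPlaneLandmarks",
    "DirectionFrame",
    "CardiacTiming",
    "VentricleMask",
    "fit_av_plane",
    "build_direction_frame",
    "mask_volume_curve",
    "compute_flux_curve",
    "estimate_end_systole",
    "resample_curve",
]


@dataclass
class AVPlaneLandmarks:
    """AV-plane landmark points in world coordinates (m)."""

    points: np.ndarray  # (n, 3)
    views: list[str] | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 3 or self.points.shape[1] != 3:
            raise InvalidInputError("need >= 3 landmark points in 3D")


@dataclass(frozen=True)
class DirectionFrame:
    """Right-handed orthonormal anatomical triad (basal-apical, transverse x2)."""

    basal_apical: tuple[float, float, float]
    septal_lateral: tuple[float, float, float]
    inferior_anterior: tuple[float, float, float]
    chamber: str = "LV"

    def __post_init__(self):
        M = self.matrix
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-9):
            raise InvalidInputError("direction frame must be orthonormal")
        if not np.allclose(np.cross(M[0], M[1]), M[2], atol=1e-9):
            raise InvalidInputError("direction frame must be right-handed (b x s = a)")

    @property
    def matrix(self) -> np.ndarray:
        """Rows are (b, s, a) in world coordinates."""
        return np.array(
            [self.basal_apical, self.septal_lateral, self.inferior_anterior], dtype=float
        )

    @classmethod
    def world_axes(cls, chamber: str = "LV") -> "DirectionFrame":
        """Fallback frame aligned with the world axes (b=z, s=x, a=y)."""
        return cls((0, 0, 1), (1, 0, 0), (0, 1, 0), chamber=chamber)


@dataclass(frozen=True)
class CardiacTiming:
    """Systole = frames [0, end_systole); diastole = [end_systole, n_frames)."""

    end_systole: int
    n_frames: int
    frame_duration: float

    def __post_init__(self):
        if not (0 < self.end_systole < self.n_frames):
            raise InvalidInputError("end_systole must lie strictly inside the cycle")

    @property
    def systole_frames(self) -> np.ndarray:
        return np.arange(0, self.end_systole)

    @property
    def diastole_frames(self) -> np.ndarray:
        return np.arange(self.end_systole, self.n_frames)


@dataclass
class VentricleMask:
    """Per-frame binary blood-pool mask of one ventricle."""

    grid: GridSpec
    frames: np.ndarray  # (n_frames, nx, ny, nz) bool
    chamber: str = "LV"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=bool)
        expected = (self.grid.n_frames, *self.grid.shape)
        if self.frames.shape != expected:
            raise InvalidInputError(
                f"mask has shape {self.frames.shape}, expected {expected}"
            )
        if self.chamber not in ("LV", "RV"):
            raise InvalidInputError("chamber must be 'LV' or 'RV'")

    def centroid_world(self, frame: int = 0) -> np.ndarray:
        x, y, z = self.grid.voxel_centers_world()
        m = self.frames[frame]
        return np.array([x[m].mean(), y[m].mean(), z[m].mean()])


def fit_av_plane(
    landmarks: AVPlaneLandmarks, apex_reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through the AV-plane landmarks.

    Returns ``(point, normal)`` with ``point`` the landmark centroid and
    ``normal`` the smallest-variance direction of the point cloud.  When
    ``apex_reference`` (e.g. the mask centroid, which lies on the apex side)
    is given, the normal is oriented from base toward apex.
    """
    P = landmarks.points
    centroid = P.mean(axis=0)
    Q = P - centroid
    _, s, Vt = np.linalg.svd(Q, full_matrices=False)
    if P.shape[0] >= 3 and s[1] < 1e-12 * max(s[0], 1e-300):
        raise InvalidInputError("landmark points are collinear; plane is undefined")
    normal = Vt[-1]
    if apex_reference is not None:
        if np.dot(normal, np.asarray(apex_reference) - centroid) < 0:
            normal = -normal
    return centroid, normal / np.linalg.norm(normal)


def build_direction_frame(
    av_normal: np.ndarray,
    three_chamber_normal: np.ndarray,
    chamber: str = "LV",
    apex_hint: np.ndarray | None = None,
    lateral_hint: np.ndarray | None = None,
    plane_point: np.ndarray | None = None,
) -> DirectionFrame:
    """Build the anatomical triad from the AV-plane and 3-chamber normals.

    ``b`` is the AV-plane normal oriented away from ``apex_hint`` (apex ->
    base); ``s`` is ``normalize(b x n3ch)``, which lies in the 3-chamber
    plane and is perpendicular to ``b``, oriented toward ``lateral_hint``;
    ``a = b x s``.  The construction is identical for LV and RV (the RV
    septal-freewall axis is parallel to the LV septal-lateral axis).
    """
    n_av = np.asarray(av_normal, dtype=float)
    n3 = np.asarray(three_chamber_normal, dtype=float)
    n_av = n_av / np.linalg.norm(n_av)
    n3 = n3 / np.linalg.norm(n3)
    if np.linalg.norm(np.cross(n_av, n3)) < 1e-9:
        raise InvalidInputError(
            "AV-plane normal is parallel to the 3-chamber normal; "
            "the septal-lateral direction is undefined"
        )
    origin = np.zeros(3) if plane_point is None else np.asarray(plane_point, dtype=float)
    b = n_av
    if apex_hint is not None and np.dot(b, np.asarray(apex_hint) - origin) > 0:
        b = -b  # base is on the opposite side of the plane from the apex
    s = np.cross(b, n3)
    s = s / np.linalg.norm(s)
    if lateral_hint is not None and np.dot(s, np.asarray(lateral_hint) - origin) < 0:
        s = -s
    a = np.cross(b, s)
    return DirectionFrame(tuple(b), tuple(s), tuple(a), chamber=chamber)


def mask_volume_curve(mask: VentricleMask) -> np.ndarray:
    """Per-frame mask volume in millilitres (voxel count x voxel volume)."""
    counts = mask.frames.reshape(mask.frames.shape[0], -1).sum(axis=1)
    if np.any(counts == 0):
        warnings.warn("mask has empty frames (0 ml)", RuntimeWarning)
    return counts * mask.grid.voxel_volume * 1e6


def compute_flux_curve(
    vfield: VelocityField,
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
    roi_radius: float,
    samples_per_radius: int = 20,
) -> np.ndarray:
    """Through-plane flow over a disc ROI, per frame, in ml/s.

    The through-plane velocity component is sampled trilinearly on a square
    quadrature lattice restricted to the disc of ``roi_radius`` (m) around
    ``plane_point`` and integrated with equal-area weights.
    """
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    p0 = np.asarray(plane_point, dtype=float)
    # orthonormal basis of the plane
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, n)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    delta = roi_radius / samples_per_radius
    g = (np.arange(-samples_per_radius, samples_per_radius + 1) + 0.0) * delta
    U, V = np.meshgrid(g, g, indexing="ij")
    keep = U**2 + V**2 <= roi_radius**2
    pts = p0 + U[keep, None] * e1 + V[keep, None] * e2
    idx = vfield.grid.world_to_index(pts)  # (m, 3) fractional indices
    shp = np.asarray(vfield.grid.shape)
    if np.all((idx < -0.5) | (idx > shp - 0.5)):
        raise InvalidInputError("flux ROI lies outside the imaged volume")
    coords = idx.T
    area = delta**2
    flux = np.empty(vfield.n_frames)
    for t in range(vfield.n_frames):
        vn = np.zeros(idx.shape[0])
        for c in range(3):
            vn += n[c] * map_coordinates(
                vfield.values[t, ..., c], coords, order=1, mode="nearest"
            )
        flux[t] = vn.sum() * area
    return flux * 1e6  # m^3/s -> ml/s


def estimate_end_systole(
    aortic_flux: np.ndarray,
    mitral_flux: np.ndarray,
    threshold: float = 0.05,
    override: int | None = None,
) -> int:
    """End-systole: aortic outflow has ceased, transmitral inflow not yet begun.

    Returns the first frame where the aortic flux has fallen below
    ``threshold`` of its peak while the mitral flux has not yet exceeded
    ``threshold`` of its peak.  If the curves overlap with no such gap, the
    crossing of the two peak-normalised curves is returned with a warning.
    A user ``override`` always wins verbatim.
    """
    if override is not None:
        return int(override)
    ao = np.abs(np.asarray(aortic_flux, dtype=float))
    mi = np.abs(np.asarray(mitral_flux, dtype=float))
    if ao.max() == 0 or mi.max() == 0:
        raise InvalidInputError("flux curves are identically zero")
    ao_n = ao / ao.max()
    mi_n = mi / mi.max()
    ao_started = False
    for t in range(len(ao_n)):
        if ao_n[t] >= threshold:
            ao_started = True
        if ao_started and ao_n[t] < threshold and mi_n[t] < threshold:
            return t
    warnings.warn(
        "no gap between aortic cessation and mitral onset; "
        "using the crossing of the normalised curves",
        RuntimeWarning,
    )
    diff = ao_n - mi_n
    sign_change = np.nonzero((diff[:-1] > 0) & (diff[1:] <= 0))[0]
    if len(sign_change) == 0:
        raise InvalidInputError("cannot locate end-systole from these flux curves")
    return int(sign_change[0] + 1)


def resample_curve(
    curve: np.ndarray,
    timing: CardiacTiming,
    target_frames: int,
    target_end_systole: int | None = None,
) -> np.ndarray:
    """Resample a per-frame curve to an average heartbeat.

    Systole and diastole are linearly resampled on normalised phase time
    *separately*, so that the phase boundary lands on the same output frame
    for every subject.
    """
    if target_frames < 2:
        raise InvalidInputError("need >= 2 target frames")
    curve = np.asarray(curve, dtype=float)
    if len(curve) != timing.n_frames:
        raise InvalidInputError("curve length must equal timing.n_frames")
    if target_end_systole is None:
        target_end_systole = int(round(target_frames * timing.end_systole / timing.n_frames))
        target_end_systole = min(max(target_end_systole, 1), target_frames - 1)
    out = np.empty(target_frames)
    for (lo, hi, tlo, thi) in (
        (0, timing.end_systole, 0, target_end_systole),
        (timing.end_systole, timing.n_frames, target_end_systole, target_frames),
    ):
        src = curve[lo:hi]
        n_t = thi - tlo
        if len(src) == 1:
            out[tlo:thi] = src[0]
        else:
            xi = np.linspace(0.0, len(src) - 1.0, n_t)
            out[tlo:thi] = np.interp(xi, np.arange(len(src)), src)
    return out
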