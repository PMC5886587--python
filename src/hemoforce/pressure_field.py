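"""Relative pressure field reconstruction from the pressure-gradient field.

The relative pressure p on the blood pool satisfies the pressure Poisson
equation, grad p = g in the least-squares sense on the masked domain:

    minimise  || G p - g ||^2   over mask voxels,

where G is the *same* discrete gradient stencil used everywhere else in
the package (centered differences in the mask interior, first-order
one-sided at the mask boundary).  The normal equations G^T G p = G^T g are
the discrete Poisson equation with Neumann-type boundary closure, and are
solved by conjugate gradients.  Because the solver inverts the package's
own discrete gradient, a field constructed as g = G q is recovered exactly
(up to the gauge constant) — the gradient -> Poisson -> gradient round
trip is exact at the discrete level, not just to truncation order.

Pressure is defined only up to a constant; the gauge is fixed to zero mean
over the mask (per connected component).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import label, map_coordinates
from scipy.sparse.linalg import LinearOperator, cg

from .core_fields import GridSpec, InvalidInputError
from .forces import PressureGradientField
from .geometry import VentricleMask

__all__ = ["RelativePressureField", "solve_ppe", "pressure_probe", "gradient_matrix"]


class ConvergenceError(RuntimeError):
    """Raised when the Poisson solve does not reach tolerance."""

    def __init__(self, msg: str, residual_history: list[float]):
        super().__init__(msg)
        self.residual_history = residual_history


@dataclass
class RelativePressureField:
    """Relative pressure (Pa) on the mask voxels of one frame; NaN outside.

    Gauge convention: zero mean over each connected mask component.
    """

    grid: GridSpec
    values: np.ndarray  # (nx, ny, nz), NaN outside mask
    mask: np.ndarray  # (nx, ny, nz) bool
    frame: int
    residual: float
    n_iterations: int
    units: str = "Pa"


def gradient_matrix(mask: np.ndarray, spacing) -> sp.csr_matrix:
    """Sparse discrete gradient over mask voxels (3*n rows, n columns).

    Row block a*n + i is the a-axis derivative at mask voxel i: centered
    where both axis neighbours are in the mask, one-sided where only one
    is, an all-zero row where neither is (that component is simply not
    observed there).  Matches ``core_fields.spatial_gradient`` restricted
    to the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    index = -np.ones(mask.shape, dtype=np.int64)
    index[mask] = np.arange(n)
    coords = np.argwhere(mask)
    rows, cols, vals = [], [], []
    shape = mask.shape
    for a in range(3):
        h = float(spacing[a])
        for r, (i, j, k) in enumerate(coords):
            c = [i, j, k]
            cp, cm = c.copy(), c.copy()
            cp[a] += 1
            cm[a] -= 1
            has_p = cp[a] < shape[a] and mask[tuple(cp)]
            has_m = cm[a] >= 0 and mask[tuple(cm)]
            row = a * n + r
            me = index[i, j, k]
            if has_p and has_m:
                rows += [row, row]
                cols += [index[tuple(cp)], index[tuple(cm)]]
                vals += [1.0 / (2 * h), -1.0 / (2 * h)]
            elif has_p:
                rows += [row, row]
                cols += [index[tuple(cp)], me]
                vals += [1.0 / h, -1.0 / h]
            elif has_m:
                rows += [row, row]
                cols += [me, index[tuple(cm)]]
                vals += [1.0 / h, -1.0 / h]
            # isolated along this axis: leave the row empty
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(3 * n, n)
    )


def _solve_component(
    G: sp.csr_matrix, g_flat: np.ndarray, tol: float, maxiter: int
) -> tuple[np.ndarray, float, int, list[float]]:
    """CG on the normal equations with the constant-mode gauge projected out."""
    n = G.shape[1]
    b = G.T @ g_flat
    b = b - b.mean()  # project RHS onto the solvable subspace
    A = G.T @ G

    def matvec(x):
        y = A @ x
        return y - y.mean()

    op = LinearOperator((n, n), matvec=matvec, dtype=float)
    history: list[float] = []

    def callback(xk):
        history.append(float(np.linalg.norm(matvec(xk) - b)))

    bnorm = float(np.linalg.norm(b))
    if bnorm == 0.0:
        return np.zeros(n), 0.0, 0, [0.0]
    x, info = cg(op, b, rtol=tol, atol=0.0, maxiter=maxiter, callback=callback)
    res = float(np.linalg.norm(matvec(x) - b)) / bnorm
    if info != 0:
        raise ConvergenceError(
            f"pressure Poisson solve did not converge (relative residual {res:.3e})",
            history,
        )
    x = x - x.mean()
    return x, res, len(history), history


def solve_ppe(
    g: PressureGradientField,
    mask: VentricleMask,
    frame: int,
    tol: float = 1e-8,
    maxiter: int = 20000,
) -> RelativePressureField:
    """Solve the pressure Poisson equation on the masked domain of one frame.

    Disconnected masks are solved per connected component (6-connectivity),
    each gauge-fixed to zero mean independently, with a warning.
    """
    if tol <= 0:
        raise InvalidInputError("tolerance must be positive")
    m = mask.frames[frame] & g.validity
    if m.sum() == 0:
        raise InvalidInputError("mask frame has no valid voxels")
    labels, n_comp = label(m)
    if n_comp > 1:
        warnings.warn(
            f"mask frame {frame} has {n_comp} connected components; "
            "each is solved and gauge-fixed separately",
            RuntimeWarning,
        )
    p = np.full(g.grid.shape, np.nan)
    worst_res, total_iter = 0.0, 0
    for comp in range(1, n_comp + 1):
        sub = labels == comp
        if sub.sum() == 1:
            p[sub] = 0.0  # single voxel: gauge only
            continue
        G = gradient_matrix(sub, g.grid.spacing)
        gm = g.values[frame][sub]  # (n, 3)
        g_flat = np.concatenate([gm[:, a] for a in range(3)])
        x, res, iters, _ = _solve_component(G, g_flat, tol, maxiter)
        p[sub] = x
        worst_res = max(worst_res, res)
        total_iter += iters
    return RelativePressureField(
        grid=g.grid, values=p, mask=m, frame=frame,
        residual=worst_res, n_iterations=total_iter,
    )


def pressure_probe(field: RelativePressureField, points_world: np.ndarray) -> np.ndarray:
    """Trilinear pressure at world points; NaN for points outside the mask.

    Interpolation weights are restricted to mask voxels (no extrapolation
    across the blood-pool boundary).
    """
    pts = np.atleast_2d(np.asarray(points_world, dtype=float))
    idx = field.grid.world_to_index(pts)
    vals = np.full(idx.shape[0], np.nan)
    filled = np.where(field.mask, field.values, 0.0)
    weights_in = field.mask.astype(float)
    shp = np.asarray(field.grid.shape)
    for i, f in enumerate(idx):
        if np.any(f < 0) or np.any(f > shp - 1):
            continue
        num = map_coordinates(filled, f[:, None], order=1)
        den = map_coordinates(weights_in, f[:, None], order=1)
        if den[0] > 1e-12:
            # nearest voxel must itself be inside the mask to count as "inside"
            nearest = tuple(np.round(f).astype(int))
            if field.mask[nearest]:
                vals[i] = num[0] / den[0]
    return vals
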