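"""Extracellular potential computation for monopolar unit-current stimulation.

Two field models are provided:

* :func:`point_source_potential` / :class:`AnalyticPointSource` — the classic
  homogeneous-medium point source, ``Ve = I / (4 pi sigma r)``.
* :func:`solve_field` — a 7-point finite-volume discretization of
  ``div(sigma grad V) = -source`` over a voxelized conductivity map, with
  harmonic-mean face conductivities, 1 uA injected uniformly over the active
  contact's voxels, and a Dirichlet (grounded) outer boundary standing in for
  the distant return electrode.  The sparse symmetric positive-definite system
  is solved with Jacobi-preconditioned conjugate gradients.

Potentials are stored in mV per 1 uA of injected current; by linearity they
are rescaled during threshold search instead of being re-solved per amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import cg

from .geometry import ConductivityMap

__all__ = [
    "point_source_potential",
    "AnalyticPointSource",
    "FieldSolution",
    "FieldSolverError",
    "solve_field",
    "sample_potential",
    "potential_along_carrier",
    "enclosed_current",
]


class FieldSolverError(RuntimeError):
    def __init__(self, msg, residual_history=None):
        super().__init__(msg)
        self.residual_history = residual_history or []


def point_source_potential(i_ua, sigma, r_um):
    """Extracellular potential (mV) of a point source in a homogeneous medium.

    ``Ve = I / (4 pi sigma r)`` with I in uA, sigma in S/m, r in um.
    """
    sigma = np.asarray(sigma, dtype=float)
    r = np.asarray(r_um, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if np.any(r <= 0):
        raise ZeroDivisionError("r must be positive (point-source singularity at r=0)")
    return 1000.0 * np.asarray(i_ua, dtype=float) / (4.0 * math.pi * sigma * r)


@dataclass(frozen=True)
class AnalyticPointSource:
    """Homogeneous-medium point-source field (mV per uA), sampleable like a
    finite-volume :class:`FieldSolution`."""

    position: np.ndarray        # (3,) um
    sigma: float = 1.43         # S/m, perilymph default
    contact_id: str = "point"

    def sample(self, points) -> np.ndarray:
        r = np.linalg.norm(np.atleast_2d(np.asarray(points, float)) - self.position, axis=1)
        r = np.maximum(r, 1.0)  # clip inside a 1 um core to avoid the singularity
        return point_source_potential(1.0, self.sigma, r)


@dataclass
class FieldSolution:
    """Unit-current extracellular potential on a conductivity grid."""

    ve: np.ndarray              # (nx,ny,nz) mV per 1 uA injected
    cond_map: ConductivityMap
    contact_id: str
    injected_current_ua: float = 1.0
    residual: float = 0.0
    iterations: int = 0
    meta: dict = field(default_factory=dict)

    def sample(self, points) -> np.ndarray:
        return sample_potential(self, points)


def _face_conductance(sigma: np.ndarray, axis: int, h_m: float) -> np.ndarray:
    """Harmonic-mean face conductances (S) between voxel neighbours along axis."""
    a = np.swapaxes(sigma, 0, axis)
    s1, s2 = a[:-1], a[1:]
    harm = np.where(s1 + s2 > 0, 2.0 * s1 * s2 / np.maximum(s1 + s2, 1e-300), 0.0)
    return np.swapaxes(harm, 0, axis) * h_m


def _assemble(cond_map: ConductivityMap):
    """Sparse SPD operator over interior voxels (Dirichlet outer layer)."""
    shape = cond_map.shape
    n = int(np.prod(shape))
    h_m = cond_map.spacing * 1e-6
    sigma = cond_map.sigma
    lin = np.arange(n).reshape(shape)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis in range(3):
        g = _face_conductance(sigma, axis, h_m).reshape(-1)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        i_lo = lin[tuple(sl_lo)].reshape(-1)
        i_hi = lin[tuple(sl_hi)].reshape(-1)
        rows.append(i_lo); cols.append(i_hi); vals.append(-g)
        rows.append(i_hi); cols.append(i_lo); vals.append(-g)
        np.add.at(diag, i_lo, g)
        np.add.at(diag, i_hi, g)
    rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    boundary = np.zeros(shape, dtype=bool)
    for axis in range(3):
        sl = [slice(None)] * 3
        sl[axis] = 0
        boundary[tuple(sl)] = True
        sl[axis] = -1
        boundary[tuple(sl)] = True
    interior = ~boundary.reshape(-1)
    return A, interior


def solve_field(
    cond_map: ConductivityMap,
    contact_id: str | None = None,
    source_voxels: np.ndarray | None = None,
    current_ua: float = 1.0,
    rtol: float = 1e-8,
    maxiter: int = 60000,
    boundary_values: np.ndarray | None = None,
) -> FieldSolution:
    """Solve the voxel Poisson problem for one active contact at unit current.

    ``source_voxels`` (k,3 integer indices) may be given instead of a contact
    id, e.g. for oracle problems on synthetic maps.  ``boundary_values``
    optionally prescribes an inhomogeneous Dirichlet boundary (same grid
    shape); the default is the grounded (zero) outer box.
    """
    if source_voxels is None:
        if contact_id is None:
            raise ValueError("need contact_id or source_voxels")
        if contact_id not in cond_map.contact_voxels:
            raise KeyError(f"conductivity map has no contact {contact_id!r}")
        source_voxels = cond_map.contact_voxels[contact_id]
    source_voxels = np.atleast_2d(np.asarray(source_voxels, dtype=np.int64))
    if len(source_voxels) == 0:
        raise ValueError("contact has no voxels")

    shape = cond_map.shape
    n = int(np.prod(shape))
    A, interior = _assemble(cond_map)
    b = np.zeros(n)
    flat = np.ravel_multi_index(source_voxels.T, shape)
    b[flat] += current_ua * 1e-6 / len(flat)   # amps, uniform over contact voxels

    v_full = np.zeros(n)
    if boundary_values is not None:
        bv = np.asarray(boundary_values, dtype=float).reshape(-1)
        v_full[~interior] = bv[~interior] * 1e-3  # mV -> V
        b = b - A @ v_full

    Ai = A[interior][:, interior]
    bi = b[interior]
    d = Ai.diagonal()
    if np.any(d <= 0):
        raise FieldSolverError("singular operator: disconnected or zero-conductivity voxels")
    M = sparse.diags(1.0 / d)
    history: list[float] = []

    def cb(xk):
        history.append(float(np.linalg.norm(bi - Ai @ xk)))

    x, info = cg(Ai, bi, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
    res = float(np.linalg.norm(bi - Ai @ x) / max(np.linalg.norm(bi), 1e-300))
    if info != 0 or not np.isfinite(res) or res > 10 * rtol:
        raise FieldSolverError(
            f"field solve did not converge (info={info}, rel residual={res:.3e}); "
            "check for a disconnected conductive path from contact to boundary",
            history,
        )
    v_full[interior] = x
    ve = (v_full * 1000.0).reshape(shape)  # V -> mV per uA
    return FieldSolution(
        ve=ve, cond_map=cond_map, contact_id=contact_id or "source",
        injected_current_ua=current_ua, residual=res, iterations=len(history) or -1,
        meta={"rtol": rtol},
    )


def sample_potential(field_sol: FieldSolution, points) -> np.ndarray:
    """Trilinear interpolation of Ve (mV per uA) at arbitrary points (um)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    axes = field_sol.cond_map.axes()
    for k in range(3):
        bad = (pts[:, k] < axes[k][0]) | (pts[:, k] > axes[k][-1])
        if np.any(bad):
            p = pts[np.flatnonzero(bad)[0]]
            raise ValueError(f"point {p.tolist()} outside field grid")
    interp = RegularGridInterpolator(axes, field_sol.ve, method="linear")
    return interp(pts)


def potential_along_carrier(field_sol: FieldSolution, centerline, active_alpha: float,
                            tol_deg: float = 25.0):
    """Normalized potential magnitude profile along the array centerline.

    Returns ``(alphas, profile)`` with ``max(profile) == 1``; the maximum must
    fall near the active contact's insertion angle.
    """
    ve = sample_potential(field_sol, centerline.points)
    peak = float(np.max(np.abs(ve)))
    if peak == 0:
        raise FieldSolverError("zero field along carrier")
    profile = np.abs(ve) / peak
    a_peak = centerline.alphas[int(np.argmax(np.abs(ve)))]
    if abs(a_peak - active_alpha) > tol_deg:
        raise FieldSolverError(
            f"carrier potential peaks at {a_peak:.0f} deg, not at the active "
            f"contact ({active_alpha:.0f} deg)"
        )
    return centerline.alphas, profile


def enclosed_current(field_sol: FieldSolution, center_voxel, radius_vox: int = 3) -> float:
    """Net current (uA) flowing out through the faces of a voxel box around
    ``center_voxel`` — a discrete conservation check."""
    cmap = field_sol.cond_map
    v = field_sol.ve * 1e-3  # mV -> V
    sigma = cmap.sigma
    h_m = cmap.spacing * 1e-6
    c = np.asarray(center_voxel, dtype=int)
    lo = np.maximum(c - radius_vox, 1)
    hi = np.minimum(c + radius_vox, np.asarray(cmap.shape) - 2)
    total = 0.0
    for axis in range(3):
        g = _face_conductance(sigma, axis, h_m)

        def face_flux(face_index, outward_sign):
            sl_in = [slice(lo[k], hi[k] + 1) for k in range(3)]
            sl_out = list(sl_in)
            sl_g = list(sl_in)
            if outward_sign > 0:
                sl_in[axis] = slice(face_index, face_index + 1)
                sl_out[axis] = slice(face_index + 1, face_index + 2)
                sl_g[axis] = slice(face_index, face_index + 1)
            else:
                sl_in[axis] = slice(face_index, face_index + 1)
                sl_out[axis] = slice(face_index - 1, face_index)
                sl_g[axis] = slice(face_index - 1, face_index)
            dv = v[tuple(sl_in)] - v[tuple(sl_out)]
            return float(np.sum(g[tuple(sl_g)] * dv))

        total += face_flux(hi[axis], +1) + face_flux(lo[axis], -1)
    return total * 1e6  # A -> uA
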