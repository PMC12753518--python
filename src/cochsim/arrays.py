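"""Electrode-array construction.

Four arrays are modelled: peri-modiolar (pm) and lateral-wall (lw) placements
in the scala tympani (ST) and scala vestibuli (SV).  Each array consists of a
smooth centerline fitted inside its canal, a silicone carrier tapering from
600 um diameter at the basal entry to 300 um at the apex, and cylindrical
contacts at requested insertion angles.

The centerline fit is an iterative constrained cubic-spline procedure: the
fiber set dictates the vertical profile while the lateral position is moved
toward the 255 um iso-distance surface of the nearest fiber, re-splined, and
clamped into the canal cross-section, until the update falls below tolerance.
Optionally the lwST/lwSV (or pmST/pmSV) pair is laterally coupled so both
share the radial coordinate dictated by the narrower canal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .geometry import ANFPath, CochlearGeometry

__all__ = [
    "Centerline",
    "Contact",
    "ElectrodeArray",
    "CenterlineFitError",
    "fit_centerline",
    "place_contacts",
    "min_distance_profile",
    "TARGET_MIN_DISTANCE",
    "CARRIER_RADIUS",
]

#: Target minimum centerline-to-fiber distance (um).
TARGET_MIN_DISTANCE = 255.0

#: Carrier radius at the basal start and apical end (um); diameter 0.6→0.3 mm.
CARRIER_RADIUS = (300.0, 150.0)

#: Default contact cylinder dimensions (um); the source morphometry does not
#: fix these, so they are configurable.
CONTACT_RADIUS = 150.0
CONTACT_HEIGHT = 50.0


class CenterlineFitError(RuntimeError):
    def __init__(self, msg: str, residuals: dict[str, float] | None = None):
        super().__init__(msg)
        self.residuals = residuals or {}


@dataclass
class Centerline:
    """Fitted array centerline, C2-smooth via cubic-spline interpolation."""

    points: np.ndarray          # (N, 3) um, fine sampling
    alphas: np.ndarray          # (N,) deg, matching points
    scala: str                  # "ST" | "SV"
    style: str                  # "pm" | "lw"
    residuals: dict[str, float] = field(default_factory=dict)  # per-fiber |min dist - target|

    @property
    def arc(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arc[-1])

    def point_at_alpha(self, alpha_deg: float) -> np.ndarray:
        out = np.empty(3)
        for k in range(3):
            out[k] = np.interp(alpha_deg, self.alphas, self.points[:, k])
        return out

    def arc_at_alpha(self, alpha_deg) -> np.ndarray:
        return np.interp(alpha_deg, self.alphas, self.arc)


@dataclass(frozen=True)
class Contact:
    id: str
    alpha_deg: float
    center: np.ndarray           # (3,) um
    orientation: np.ndarray      # unit vector, cylinder axis
    radius: float = CONTACT_RADIUS
    height: float = CONTACT_HEIGHT


@dataclass
class ElectrodeArray:
    centerline: Centerline
    contacts: list[Contact] = field(default_factory=list)
    orientation_mode: str = "default"

    @property
    def tag(self) -> str:
        return f"{self.centerline.style}{self.centerline.scala}"

    def carrier_radius(self, arc):
        """Carrier radius (um) at arc position(s); tapers linearly 300→150 um."""
        frac = np.clip(np.asarray(arc, dtype=float) / self.centerline.total_length, 0, 1)
        return CARRIER_RADIUS[0] + (CARRIER_RADIUS[1] - CARRIER_RADIUS[0]) * frac

    def contact(self, contact_id: str) -> Contact:
        for ct in self.contacts:
            if ct.id == contact_id:
                return ct
        raise KeyError(f"no contact {contact_id!r} in {self.tag}")


# ---------------------------------------------------------------------------
# Centerline fitting
# ---------------------------------------------------------------------------

def _fiber_cloud(anfs: list[ANFPath], max_arc: float = 3000.0):
    """Stack fiber polyline points (restricted to the peri-dendritic span that
    faces the canals) with per-point fiber indices."""
    pts, owner = [], []
    for i, f in enumerate(anfs):
        arc = f.arc_lengths
        keep = arc <= min(max_arc, arc[-1])
        pts.append(f.polyline[keep])
        owner.append(np.full(keep.sum(), i))
    return np.vstack(pts), np.concatenate(owner)


def _min_distances(points: np.ndarray, cloud: np.ndarray, owner: np.ndarray, n_fibers: int):
    """Per-fiber minimum distance from ``points`` to each fiber, with argmins."""
    d = np.full(n_fibers, np.inf)
    i_pt = np.zeros(n_fibers, dtype=int)
    i_cl = np.zeros(n_fibers, dtype=int)
    # chunk over the cloud to bound memory
    step = 20000
    for s in range(0, len(cloud), step):
        block = cloud[s:s + step]
        dist = np.linalg.norm(points[:, None, :] - block[None, :, :], axis=2)
        own = owner[s:s + step]
        for f in range(n_fibers):
            cols = np.flatnonzero(own == f)
            if len(cols) == 0:
                continue
            sub = dist[:, cols]
            j = np.unravel_index(np.argmin(sub), sub.shape)
            if sub[j] < d[f]:
                d[f] = sub[j]
                i_pt[f] = j[0]
                i_cl[f] = cols[j[1]] + s
    return d, i_pt, i_cl


def fit_centerline(
    geom: CochlearGeometry,
    anfs: list[ANFPath],
    scala: str,
    style: str,
    couple_lateral: bool = False,
    target: float = TARGET_MIN_DISTANCE,
    tol: float = 1.0,
    max_iter: int = 200,
    control_step_deg: float = 15.0,
    fine_step_deg: float = 3.0,
    init_frac: float | None = None,
) -> Centerline:
    """Fit the ``style`` centerline inside ``scala`` at the target fiber distance.

    With ``couple_lateral`` the matching centerline in the other scala is fitted
    too and both are forced to share the radial (lateral) coordinate dictated by
    the narrower canal before the vertical profile is re-converged.
    """
    if scala not in ("ST", "SV") or style not in ("pm", "lw"):
        raise ValueError("scala must be ST|SV and style pm|lw")
    if not anfs:
        raise ValueError("need at least one ANF")
    if not couple_lateral:
        return _fit_single(geom, anfs, scala, style, target, tol, max_iter,
                           control_step_deg, fine_step_deg, init_frac)
    other = "SV" if scala == "ST" else "ST"
    own = _fit_single(geom, anfs, scala, style, target, tol, max_iter,
                      control_step_deg, fine_step_deg, init_frac)
    mate = _fit_single(geom, anfs, other, style, target, tol, max_iter,
                       control_step_deg, fine_step_deg, init_frac)
    coupled = _couple_lateral(geom, {scala: own, other: mate}, anfs, target,
                              tol, max_iter, control_step_deg, fine_step_deg)
    return coupled[scala]


def _control_grid(geom: CochlearGeometry, control_step: float, fine_step: float):
    a_max = geom.config.turns_deg
    ctrl = np.arange(0.0, a_max + 1e-9, control_step)
    if ctrl[-1] < a_max:
        ctrl = np.append(ctrl, a_max)
    fine = np.arange(0.0, a_max + 1e-9, fine_step)
    if fine[-1] < a_max:
        fine = np.append(fine, a_max)
    return ctrl, fine


def _assemble(geom, scala, ctrl, fine, u, w):
    """Spline local offsets over alpha and map to world points on the fine grid."""
    su = CubicSpline(ctrl, u)
    sw = CubicSpline(ctrl, w)
    y_c = geom.canal_center_local(fine, scala)
    return geom.local_to_world(fine, su(fine), y_c + sw(fine))


def _clamp(geom, scala, ctrl, u, w, margin=10.0):
    r = geom.canal_radius(ctrl, scala) - margin
    mag = np.hypot(u, w)
    over = mag > r
    scale = np.where(over, r / np.maximum(mag, 1e-12), 1.0)
    return u * scale, w * scale


def _fit_single(geom, anfs, scala, style, target, tol, max_iter,
                control_step, fine_step, init_frac=None) -> Centerline:
    ctrl, fine = _control_grid(geom, control_step, fine_step)
    r_ctrl = geom.canal_radius(ctrl, scala)
    # style bias: lateral-wall arrays start near the outer wall, peri-modiolar
    # arrays moderately toward the cochlear axis
    if init_frac is None:
        init_frac = 0.8 if style == "lw" else -0.55
    u = init_frac * (r_ctrl - 10.0)
    w = np.zeros_like(u)               # vertical offset from canal center
    cloud, owner = _fiber_cloud(anfs)
    n_f = len(anfs)
    f_alpha = np.array([f.alpha_deg for f in anfs])
    e_r_ctrl, _, _ = geom.frame(ctrl)

    damping = 0.6
    bw = 30.0  # deg, influence bandwidth of a fiber on control points
    converged = False
    for _ in range(max_iter):
        pts = _assemble(geom, scala, ctrl, fine, u, w)
        d, i_pt, i_cl = _min_distances(pts, cloud, owner, n_f)
        if np.any(d < 1e-6):
            raise CenterlineFitError("centerline collapsed onto a fiber")
        # displacement that would place each argmin point on the target sphere
        disp = np.zeros((n_f, 3))
        for f in range(n_f):
            p, q = pts[i_pt[f]], cloud[i_cl[f]]
            disp[f] = (q + (p - q) * (target / d[f])) - p
        # gaussian spread of fiber displacements onto control points
        wgt = np.exp(-0.5 * ((ctrl[:, None] - f_alpha[None, :]) / bw) ** 2)
        norm = wgt.sum(axis=1, keepdims=True)
        active = norm[:, 0] > 1e-3
        delta = np.zeros((len(ctrl), 3))
        delta[active] = (wgt[active] @ disp) / norm[active]
        du = damping * np.einsum("ij,ij->i", delta, e_r_ctrl)
        dw = damping * delta[:, 2]
        u_new, w_new = _clamp(geom, scala, ctrl, u + du, w + dw)
        step = float(np.max(np.hypot(u_new - u, w_new - w)))
        u, w = u_new, w_new
        if step < tol:
            converged = True
            break
    pts = _assemble(geom, scala, ctrl, fine, u, w)
    d, _, _ = _min_distances(pts, cloud, owner, n_f)
    residuals = {f.id: float(abs(dd - target)) for f, dd in zip(anfs, d)}
    if not converged:
        raise CenterlineFitError(
            f"centerline fit did not converge within {max_iter} iterations", residuals
        )
    cl = Centerline(points=pts, alphas=fine, scala=scala, style=style,
                    residuals=residuals)
    cl._control = (ctrl, u.copy(), w.copy())  # type: ignore[attr-defined]
    return cl


def _couple_lateral(geom, pair: dict[str, Centerline], anfs, target, tol,
                    max_iter, control_step, fine_step) -> dict[str, Centerline]:
    """Force a shared radial coordinate, dictated by the narrower canal."""
    ctrl_st, u_st, w_st = pair["ST"]._control        # type: ignore[attr-defined]
    ctrl_sv, u_sv, w_sv = pair["SV"]._control        # type: ignore[attr-defined]
    assert np.allclose(ctrl_st, ctrl_sv)
    ctrl = ctrl_st
    narrower = np.where(
        geom.canal_radius(ctrl, "ST") <= geom.canal_radius(ctrl, "SV"), 0, 1
    )
    u_shared = np.where(narrower == 0, u_st, u_sv)
    out: dict[str, Centerline] = {}
    cloud, owner = _fiber_cloud(anfs)
    n_f = len(anfs)
    _, fine = _control_grid(geom, control_step, fine_step)
    f_alpha = np.array([f.alpha_deg for f in anfs])
    for scala, w in (("ST", w_st), ("SV", w_sv)):
        # clamp shared radial offset into this canal, then re-converge vertical
        u, w = _clamp(geom, scala, ctrl, u_shared.copy(), w.copy())
        u = u_shared.copy()  # lateral coordinate is frozen (shared)
        for _ in range(max_iter):
            pts = _assemble(geom, scala, ctrl, fine, u, w)
            d, i_pt, i_cl = _min_distances(pts, cloud, owner, n_f)
            disp = np.zeros(n_f)
            for f in range(n_f):
                p, q = pts[i_pt[f]], cloud[i_cl[f]]
                disp[f] = ((q + (p - q) * (target / d[f])) - p)[2]
            wgt = np.exp(-0.5 * ((ctrl[:, None] - f_alpha[None, :]) / 30.0) ** 2)
            norm = wgt.sum(axis=1, keepdims=True)
            active = norm[:, 0] > 1e-3
            dw = np.zeros(len(ctrl))
            dw[active] = 0.6 * (wgt[active] @ disp) / norm[active, 0]
            _, w_new = _clamp(geom, scala, ctrl, u, w + dw)
            step = float(np.max(np.abs(w_new - w)))
            w = w_new
            if step < tol:
                break
        pts = _assemble(geom, scala, ctrl, fine, u, w)
        d, _, _ = _min_distances(pts, cloud, owner, n_f)
        cl = Centerline(points=pts, alphas=fine, scala=scala,
                        style=pair[scala].style,
                        residuals={f.id: float(abs(dd - target))
                                   for f, dd in zip(anfs, d)})
        cl._control = (ctrl, u.copy(), w.copy())  # type: ignore[attr-defined]
        out[scala] = cl
    return out


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def place_contacts(
    centerline: Centerline,
    alphas,
    orientation_mode: str = "default",
    radius: float = CONTACT_RADIUS,
    height: float = CONTACT_HEIGHT,
) -> ElectrodeArray:
    """Place one cylindrical contact per requested insertion angle.

    Default mode orients contacts toward the fibers (up in ST, down in SV);
    alternative mode orients them toward the cochlear axis.  Contact centers
    sit on the carrier surface.
    """
    if orientation_mode not in ("default", "alternative"):
        raise ValueError("orientation_mode must be 'default' or 'alternative'")
    arr = ElectrodeArray(centerline=centerline, orientation_mode=orientation_mode)
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    a_max = centerline.alphas[-1]
    for a in alphas:
        if a < centerline.alphas[0] - 1e-9 or a > a_max + 1e-9:
            raise ValueError(f"contact angle {a} deg beyond array tip ({a_max} deg)")
        p = centerline.point_at_alpha(float(a))
        arc = float(centerline.arc_at_alpha(float(a)))
        if orientation_mode == "default":
            n = np.array([0.0, 0.0, 1.0 if centerline.scala == "ST" else -1.0])
        else:
            ar = np.deg2rad(a)
            n = -np.array([np.cos(ar), np.sin(ar), 0.0])
        r_carrier = float(arr.carrier_radius(arc))
        center = p + n * r_carrier
        arr.contacts.append(
            Contact(id=f"EL{int(round(a))}", alpha_deg=float(a), center=center,
                    orientation=n, radius=radius, height=height)
        )
    return arr


def contact_clearance(array: ElectrodeArray, anf: ANFPath, contact_id: str) -> float:
    """Minimum signed distance (um) from a fiber polyline to the contact's
    metal cylinder surface; negative when the fiber intersects the metal.

    Pairs with non-positive clearance are geometrically degenerate (the fiber
    would run through the electrode) and are excluded from pair-level
    excitation claims.
    """
    ct = array.contact(contact_id)
    rel = anf.polyline - ct.center
    axial = rel @ ct.orientation
    radial = np.linalg.norm(rel - np.outer(axial, ct.orientation), axis=1)
    dz = np.abs(axial) - ct.height / 2.0
    dr = radial - ct.radius
    outside = np.hypot(np.maximum(dz, 0.0), np.maximum(dr, 0.0))
    inside = np.minimum(np.maximum(dz, dr), 0.0)
    return float(np.min(outside + inside))


def min_distance_profile(array: ElectrodeArray, anf: ANFPath, contact_id: str):
    """Distances from a contact center to points along a fiber.

    Returns ``(arc_positions, distances, min_distance, argmin_arc)`` with arc
    measured from the peripheral terminal.  Ties break toward the terminal.
    """
    ct = array.contact(contact_id)
    arc = anf.arc_lengths
    d = np.linalg.norm(anf.polyline - ct.center, axis=1)
    i = int(np.argmin(d))  # np.argmin returns the first (most basal/terminal) tie
    return arc, d, float(d[i]), float(arc[i])
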