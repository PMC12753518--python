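"""Synthetic cochlear geometry: spiral ducts, auditory-nerve-fiber paths, conductivity maps.

The cochlea is represented as a parametric two-turn spiral (insertion angle
``alpha`` in degrees, 0 at the basal entry, increasing apically) carrying three
stacked circular duct cross-sections — scala tympani (ST, bottom), scala media
(SM), scala vestibuli (SV, top) — a conical modiolus around the central axis,
and a bone capsule.  Twenty-five auditory nerve fibers (ANFs) run radially from
a peripheral terminal near the ST/SM boundary, medially across the osseous
spiral lamina, down to a soma in Rosenthal's canal inside the modiolus, and on
as a central axon toward the internal auditory canal.

All lengths are in micrometres, conductivities in S/m.  The frame is
right-handed with the cochlear axis along +z.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryConfig",
    "CochlearGeometry",
    "ANFPath",
    "ConductivityMap",
    "DEFAULT_CONDUCTIVITIES",
    "OSSIFICATION_SIGMAS",
    "NAMED_ANGLES",
    "build_geometry",
    "place_anfs",
    "voxelize",
]

#: Default domain conductivities (S/m).  Perilymph fills ST and SV, endolymph
#: the SM; the silicone carrier is a near-perfect insulator (a tiny non-zero
#: value keeps the discrete operator non-singular).
DEFAULT_CONDUCTIVITIES: dict[str, float] = {
    "ST": 1.43,
    "SV": 1.43,
    "SM": 1.67,
    "modiolus": 0.0334,
    "bone": 0.016,
    "carrier": 1e-6,
    "contact": 1000.0,
    "exterior": 0.016,
}

#: ST conductivity for progressive ossification stages (S/m).
OSSIFICATION_SIGMAS: dict[str, float] = {
    "developing": 1.0,
    "moderate": 0.65,
    "severe": 0.3,
    "complete": 0.03,
}

#: Fiber insertion angles named in the result tables; the remaining fibers of
#: the default 25-fiber set are spaced evenly between the extremes.
NAMED_ANGLES: tuple[float, ...] = (23.0, 77.0, 195.0, 256.0, 416.0, 467.0, 494.0, 680.0)

LABELS: tuple[str, ...] = (
    "exterior",
    "bone",
    "modiolus",
    "ST",
    "SM",
    "SV",
    "carrier",
    "contact",
)
LABEL_INDEX = {name: i for i, name in enumerate(LABELS)}


class ConfigurationError(ValueError):
    """Raised for physically impossible geometry configurations."""


@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of the synthetic cochlear spiral.

    The defaults produce a ~1.9-turn spiral (alpha 0–690 deg) whose duct and
    fiber proportions match the morphometry used throughout the analyses:
    an electrode-array path of 23–27 mm and dendritic lengths spanning
    1,320–2,312 um.
    """

    turns_deg: float = 690.0          # apical end of the spiral (deg)
    basal_radius: float = 3195.0      # duct-center radius at alpha=0 (um)
    apical_radius: float = 1226.0     # duct-center radius at the apex (um)
    total_height: float = 2800.0      # rise of the duct center over the spiral (um)
    st_radius: tuple[float, float] = (380.0, 220.0)   # basal→apical (um)
    sm_radius: tuple[float, float] = (200.0, 150.0)
    sv_radius: tuple[float, float] = (360.0, 200.0)
    stack_gap: float = 20.0           # bone septum between stacked ducts (um)
    modiolus_clearance: float = 50.0  # gap between modiolus cone and medial duct wall
    bone_margin: float = 150.0        # bone shell beyond the widest duct (um)
    fiber_alpha_range: tuple[float, float] = (23.0, 680.0)
    dendrite_lengths: tuple[float, float, float] = (1320.0, 1732.0, 2312.0)  # min/median/max
    terminal_lateral_frac: float = 0.05  # terminal radial offset as fraction of ST radius
    terminal_rise: float = 70.0           # extra height of the band waypoint (um)
    tip_height: float = 30.0             # terminal height above the ST roof (um)
    lamina_frac: float = 0.6             # medial lamina span as fraction of ST radius
    axon_length: float = 5600.0          # central-process polyline length (um)
    point_step: float = 20.0             # polyline sampling step (um)
    z_extra_below: float = 900.0         # extra bone below the base (soma/axon region, um)

    def validate(self) -> None:
        positive = (
            self.turns_deg,
            self.basal_radius,
            self.apical_radius,
            self.total_height,
            *self.st_radius,
            *self.sm_radius,
            *self.sv_radius,
            self.axon_length,
            self.point_step,
        )
        if any(v <= 0 for v in positive):
            raise ConfigurationError("all geometry dimensions must be positive")
        if self.apical_radius >= self.basal_radius:
            raise ConfigurationError("spiral radius must decrease toward the apex")
        lo, mid, hi = self.dendrite_lengths
        if not (0 < lo <= mid <= hi):
            raise ConfigurationError("dendrite length order statistics must be ordered")


def _lerp(pair: tuple[float, float], frac):
    return pair[0] + (pair[1] - pair[0]) * frac


@dataclass(frozen=True)
class CochlearGeometry:
    """Parametric cochlear volume: spiral, duct cross-sections, domain solids."""

    config: GeometryConfig

    # -- spiral ------------------------------------------------------------
    def spiral(self, alpha_deg):
        """Duct-center (ST) radius and height at insertion angle ``alpha_deg``.

        Radius decays log-linearly from basal to apical; height rises linearly.
        """
        a = np.asarray(alpha_deg, dtype=float)
        c = self.config
        frac = a / c.turns_deg
        radius = c.basal_radius * np.exp(np.log(c.apical_radius / c.basal_radius) * frac)
        height = c.total_height * frac
        return radius, height

    def frame(self, alpha_deg):
        """Local orthonormal frame at ``alpha_deg``: (radial, tangential, vertical)."""
        a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
        e_r = np.stack([np.cos(a), np.sin(a), np.zeros_like(a)], axis=-1)
        e_t = np.stack([-np.sin(a), np.cos(a), np.zeros_like(a)], axis=-1)
        e_z = np.zeros_like(e_r)
        e_z[..., 2] = 1.0
        return e_r, e_t, e_z

    def canal_radius(self, alpha_deg, scala: str):
        c = self.config
        frac = np.asarray(alpha_deg, dtype=float) / c.turns_deg
        pair = {"ST": c.st_radius, "SM": c.sm_radius, "SV": c.sv_radius}[scala]
        return _lerp(pair, frac)

    def canal_center_local(self, alpha_deg, scala: str):
        """Vertical offset of the canal center relative to the ST center."""
        c = self.config
        if scala == "ST":
            return np.zeros_like(np.asarray(alpha_deg, dtype=float))
        r_st = self.canal_radius(alpha_deg, "ST")
        r_sm = self.canal_radius(alpha_deg, "SM")
        if scala == "SM":
            return r_st + c.stack_gap + r_sm
        r_sv = self.canal_radius(alpha_deg, "SV")
        return r_st + 2 * c.stack_gap + 2 * r_sm + r_sv

    def canal_center(self, alpha_deg, scala: str):
        """Absolute 3D canal-center point(s) at ``alpha_deg``."""
        radius, height = self.spiral(alpha_deg)
        e_r, _, _ = self.frame(alpha_deg)
        z_off = self.canal_center_local(alpha_deg, scala)
        pts = e_r * radius[..., None]
        pts[..., 2] = height + z_off
        return pts

    def local_to_world(self, alpha_deg, x_local, y_local):
        """Map cross-section coordinates (radial offset, vertical offset relative
        to the ST center) at angle ``alpha_deg`` into absolute 3D points."""
        radius, height = self.spiral(alpha_deg)
        a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
        rho = radius + np.asarray(x_local, dtype=float)
        z = height + np.asarray(y_local, dtype=float)
        return np.stack([rho * np.cos(a), rho * np.sin(a), z], axis=-1)

    # -- derived solids ----------------------------------------------------
    def modiolus_radius_at_z(self, z):
        """Radius of the conical modiolus at height ``z`` (clamped at the ends)."""
        c = self.config
        frac = np.clip(np.asarray(z, dtype=float) / c.total_height, 0.0, 1.0)
        duct_r = c.basal_radius * np.exp(np.log(c.apical_radius / c.basal_radius) * frac)
        return duct_r - _lerp(c.st_radius, frac) - c.modiolus_clearance

    @property
    def outer_radius(self) -> float:
        c = self.config
        return c.basal_radius + c.st_radius[0] + c.bone_margin

    @property
    def z_range(self) -> tuple[float, float]:
        c = self.config
        return (-c.st_radius[0] - c.bone_margin - c.z_extra_below,
                c.total_height + float(self.canal_center_local(c.turns_deg, "SV"))
                + c.sv_radius[1] + c.bone_margin)

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        r = self.outer_radius
        z0, z1 = self.z_range
        return (np.array([-r, -r, z0]), np.array([r, r, z1]))

    @property
    def alpha_range(self) -> tuple[float, float]:
        return (0.0, self.config.turns_deg)

    def analytic_duct_volume(self, scala: str, n: int = 4000) -> float:
        """Volume (um^3) of a duct as a tube integral ``∫ pi R(alpha)^2 ds``
        along its own center curve — the reference for voxel convergence."""
        alphas = np.linspace(0.0, self.config.turns_deg, n)
        centers = self.canal_center(alphas, scala)
        ds = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        r = self.canal_radius(alphas, scala)
        r_mid = 0.5 * (r[:-1] + r[1:])
        return float(np.sum(math.pi * r_mid**2 * ds))


@dataclass(frozen=True)
class ANFPath:
    """A single auditory-nerve-fiber trajectory.

    ``polyline`` runs from the peripheral terminal to the central axon end.
    ``dendrite_length`` is the arc length from the terminal to the start of the
    soma (i.e. through the pre-somatic segment); ``soma_arc_pos`` is the arc
    position of the soma center.
    """

    id: str
    alpha_deg: float
    polyline: np.ndarray           # (N, 3) um
    dendrite_length: float         # um
    soma_arc_pos: float            # um

    def __post_init__(self):
        if not np.all(np.isfinite(self.polyline)):
            raise ValueError(f"{self.id}: non-finite polyline points")

    @property
    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arc_lengths[-1])

    def point_at_arc(self, arc):
        """Interpolate point(s) on the polyline at arc position(s) from the terminal."""
        s = self.arc_lengths
        arc = np.asarray(arc, dtype=float)
        if np.any(arc < -1e-9) or np.any(arc > s[-1] + 1e-9):
            raise ValueError(f"{self.id}: arc position outside polyline span")
        out = np.empty(arc.shape + (3,))
        for k in range(3):
            out[..., k] = np.interp(arc, s, self.polyline[:, k])
        return out


def build_geometry(config: GeometryConfig | None = None) -> CochlearGeometry:
    """Construct the parametric cochlear geometry (deterministic for a fixed config)."""
    config = config or GeometryConfig()
    config.validate()
    geom = CochlearGeometry(config=config)
    # sanity: stacked cross-sections are disjoint by construction; verify once
    alphas = np.linspace(0, config.turns_deg, 64)
    st_top = geom.canal_radius(alphas, "ST")
    sm_c = geom.canal_center_local(alphas, "SM")
    sm_r = geom.canal_radius(alphas, "SM")
    sv_c = geom.canal_center_local(alphas, "SV")
    sv_r = geom.canal_radius(alphas, "SV")
    if np.any(sm_c - sm_r <= st_top) or np.any(sv_c - sv_r <= sm_c + sm_r):
        raise ConfigurationError("duct cross-sections overlap")
    return geom


# ---------------------------------------------------------------------------
# ANF placement
# ---------------------------------------------------------------------------

def default_fiber_angles(n: int = 25) -> np.ndarray:
    """The named result-table angles plus evenly spaced fillers, sorted."""
    named = np.array(NAMED_ANGLES)
    if n < len(named):
        return named[np.round(np.linspace(0, len(named) - 1, n)).astype(int)]
    n_fill = n - len(named)
    fillers = np.linspace(NAMED_ANGLES[0], NAMED_ANGLES[-1], n_fill + 2)[1:-1]
    # nudge fillers off named angles
    for i, f in enumerate(fillers):
        while np.any(np.abs(named - fillers[i]) < 1.0):
            fillers[i] += 1.5
    return np.sort(np.concatenate([named, fillers]))


def dendrite_length_profile(n: int, anchors: tuple[float, float, float]) -> np.ndarray:
    """Deterministic monotone-decreasing dendritic-length profile over fiber index.

    Basal fibers are the longest (they carry the largest internode counts) and
    the profile is piecewise linear through the three anchor order statistics,
    so for the default n=25 the min / median / max are reproduced exactly.
    """
    lo, mid, hi = anchors
    idx = np.arange(n, dtype=float)
    half = (n - 1) / 2.0
    out = np.where(
        idx <= half,
        hi + (mid - hi) * idx / max(half, 1.0),
        mid + (lo - mid) * (idx - half) / max(half, 1.0),
    )
    return out


def _fiber_polyline(geom: CochlearGeometry, alpha: float, dendrite_length: float) -> np.ndarray:
    """Build one fiber polyline in the cross-section plane at ``alpha``.

    The fiber runs: terminal at the scala-tympani roof (the basilar-membrane
    level, inside the scala-media pocket) → short distal curl up to the
    inter-scalar band → lamina run medially → steep descent to the soma in
    Rosenthal's canal; the central axon then heads toward the cochlear axis.
    """
    c = geom.config
    R = float(geom.canal_radius(alpha, "ST"))
    x_t = c.terminal_lateral_frac * R
    y_band = float(geom.canal_center_local(alpha, "SM")) + c.terminal_rise
    terminal = np.array([x_t, R + c.tip_height])
    # distal curl: rises from the basilar-membrane level into the inter-scalar
    # band (habenular region), then the lamina course runs medially
    band_pt = np.array([x_t - 30.0, y_band])
    lamina_end = np.array([-c.lamina_frac * R, y_band + 10.0])
    fixed_span = (
        float(np.linalg.norm(band_pt - terminal))
        + float(np.linalg.norm(lamina_end - band_pt))
    )
    # descent: short connector to Rosenthal's canal just medial of the ST
    # wall, then straight down (the canal hugs the scala's medial side)
    wall_pt = np.array([-R - 120.0, y_band - 200.0])
    connector = float(np.linalg.norm(wall_pt - lamina_end))
    descent = dendrite_length - fixed_span - connector
    if descent <= 30.0:
        raise ConfigurationError(
            f"dendrite length {dendrite_length} um too short for the layout"
        )
    soma_start = wall_pt + np.array([0.0, -descent])
    # 2D waypoints (radial offset, vertical offset) up to the soma start
    pts2d = [terminal]
    for a, b in ((terminal, band_pt), (band_pt, lamina_end),
                 (lamina_end, wall_pt), (wall_pt, soma_start)):
        L = float(np.linalg.norm(b - a))
        n = max(2, int(L / c.point_step))
        for t in np.linspace(0, 1, n + 1)[1:]:
            pts2d.append(a + (b - a) * t)
    pts2d = np.array(pts2d)
    world = geom.local_to_world(alpha, pts2d[:, 0], pts2d[:, 1])
    # central axon: straight run from the soma region toward a point on the
    # cochlear axis below the base (internal auditory canal stand-in)
    soma_w = world[-1]
    target = np.array([0.0, 0.0, -1500.0])
    d = target - soma_w
    d = d / np.linalg.norm(d)
    n3 = max(2, int(c.axon_length / c.point_step))
    axon = soma_w[None, :] + d[None, :] * np.linspace(0, c.axon_length, n3 + 1)[1:, None]
    return np.vstack([world, axon])


def place_anfs(
    geom: CochlearGeometry,
    n: int = 25,
    alphas: np.ndarray | None = None,
    seed: int | None = None,
    jitter_deg: float = 0.0,
) -> list[ANFPath]:
    """Place ``n`` ANF paths along the spiral.

    The default set includes the named result-table angles with the remainder
    evenly spaced; dendritic lengths follow the fixed monotone profile anchored
    at the printed min/median/max.  ``seed`` only matters when a non-zero
    angular ``jitter_deg`` is requested.
    """
    if n < 1:
        raise ValueError("need at least one fiber")
    lo, hi = geom.alpha_range
    if alphas is None:
        alphas = default_fiber_angles(n)
    else:
        alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
        if len(alphas) != n:
            raise ValueError("len(alphas) must equal n")
    if np.any(alphas < lo) or np.any(alphas > hi):
        raise ValueError("fiber angle outside geometry range")
    if jitter_deg:
        rng = np.random.default_rng(seed)
        alphas = np.clip(
            alphas + rng.uniform(-jitter_deg, jitter_deg, size=len(alphas)),
            *geom.config.fiber_alpha_range,
        )
    order = np.argsort(alphas)
    alphas = np.asarray(alphas, dtype=float)[order]
    lengths = dendrite_length_profile(n, geom.config.dendrite_lengths)
    fibers = []
    for a, L in zip(alphas, lengths):
        poly = _fiber_polyline(geom, float(a), float(L))
        fibers.append(
            ANFPath(
                id=f"ANF{int(round(a))}",
                alpha_deg=float(a),
                polyline=poly,
                dendrite_length=float(L),
                soma_arc_pos=float(L) + 10.0,  # soma center = start + radius
            )
        )
    return fibers


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

@dataclass
class ConductivityMap:
    """Voxelized conductivity grid with per-voxel domain labels."""

    spacing: float                # um
    origin: np.ndarray            # (3,) um, center of voxel [0,0,0]
    labels: np.ndarray            # (nx,ny,nz) uint8, indices into LABELS
    sigma_by_label: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES)
    )
    contact_ids: list[str] = field(default_factory=list)
    contact_voxels: dict[str, np.ndarray] = field(default_factory=dict)  # (k,3) int

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def sigma(self) -> np.ndarray:
        lut = np.array([self.sigma_by_label[name] for name in LABELS])
        return lut[self.labels]

    def with_sigma(self, **overrides: float) -> "ConductivityMap":
        """Return a copy with conductivities overridden per domain label.

        Example: ``m.with_sigma(modiolus=0.334)`` or ``m.with_sigma(ST=0.03)``.
        """
        new = dict(self.sigma_by_label)
        for k, v in overrides.items():
            if k not in new:
                raise KeyError(f"unknown domain label {k!r}")
            if v < 0:
                raise ValueError("conductivity must be non-negative")
            new[k] = float(v)
        return dataclasses.replace(self, sigma_by_label=new)

    def with_ossification(self, level: str) -> "ConductivityMap":
        if level not in OSSIFICATION_SIGMAS:
            raise KeyError(f"unknown ossification level {level!r}")
        return self.with_sigma(ST=OSSIFICATION_SIGMAS[level])

    def world_to_index(self, points) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, idx) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing * np.arange(self.shape[k]) for k in range(3)
        )  # type: ignore[return-value]

    def domain_volume(self, label: str) -> float:
        return float(np.count_nonzero(self.labels == LABEL_INDEX[label])) * self.spacing**3


def _label_cochlea(
    geom: CochlearGeometry,
    pts: np.ndarray,
    spacing: float,
    protect: np.ndarray | None = None,
) -> np.ndarray:
    """Label raw cochlear domains (no arrays) at the given points.

    The bony septum between the stacked scalae (osseous spiral lamina /
    basilar-membrane partition) is rasterized conservatively: it is dilated by
    half a voxel into the adjacent scalae so that it never disappears at
    coarse grid spacings.  The scala-media disc is kept open as the conductive
    window between the ducts.
    """
    c = geom.config
    rho = np.hypot(pts[:, 0], pts[:, 1])
    phi = np.degrees(np.arctan2(pts[:, 1], pts[:, 0])) % 360.0
    z = pts[:, 2]
    labels = np.full(len(pts), LABEL_INDEX["exterior"], dtype=np.uint8)

    z0, z1 = geom.z_range
    in_bone = (rho <= geom.outer_radius) & (z >= z0) & (z <= z1)
    labels[in_bone] = LABEL_INDEX["bone"]

    in_mod = in_bone & (rho <= geom.modiolus_radius_at_z(z)) & (z >= z0 + 100.0)
    labels[in_mod] = LABEL_INDEX["modiolus"]

    half = spacing / 2.0
    # duct membership: candidate winding angles phi + k*360 within range
    for k in range(int(c.turns_deg // 360.0) + 1):
        alpha = phi + 360.0 * k
        ok = alpha <= c.turns_deg
        if not np.any(ok):
            continue
        radius, height = geom.spiral(alpha)
        x_local = rho - radius
        y_local = z - height
        for scala in ("ST", "SM", "SV"):
            r_can = geom.canal_radius(alpha, scala)
            y_c = geom.canal_center_local(alpha, scala)
            inside = ok & (x_local**2 + (y_local - y_c) ** 2 <= r_can**2)
            labels[inside] = LABEL_INDEX[scala]
        # conservative spiral-lamina septum between the stacked scalae: the
        # shelf carrying the dendrites belongs to the modiolus domain (which
        # includes the osseous spiral lamina); the scala-media disc stays open
        r_st = geom.canal_radius(alpha, "ST")
        r_sm = geom.canal_radius(alpha, "SM")
        y_sm = geom.canal_center_local(alpha, "SM")
        y_sv = geom.canal_center_local(alpha, "SV")
        r_sv = geom.canal_radius(alpha, "SV")
        in_sm_disc = x_local**2 + (y_local - y_sm) ** 2 <= r_sm**2
        sep_lo = (y_local >= r_st - half) & (y_local <= y_sm - r_sm + half)
        sep_hi = (y_local >= y_sm + r_sm - half) & (y_local <= y_sv - r_sv + half)
        septum = ok & (sep_lo | sep_hi) & ~in_sm_disc & (np.abs(x_local) <= r_st + half)
        if protect is not None:
            septum &= ~protect
        labels[septum & (labels != LABEL_INDEX["exterior"])] = LABEL_INDEX["modiolus"]
    return labels


def voxelize(
    geom: CochlearGeometry,
    arrays=(),
    spacing: float = 60.0,
    pad: float | None = None,
) -> ConductivityMap:
    """Voxelize the cochlea plus any electrode arrays into a conductivity map.

    Label priority: contact > carrier > ducts > modiolus > bone > exterior.
    The exterior padding defaults to one cochlear diameter on every side and
    stands in for the grounded far-field sphere of the continuum problem.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lo, hi = geom.bounding_box
    if pad is None:
        pad = float(2 * geom.outer_radius)  # one cochlear diameter
    lo = lo - pad
    hi = hi + pad
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    origin = lo
    ax = [origin[k] + spacing * np.arange(shape[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    # restrict expensive duct labelling to the cochlear bounding box
    glo, ghi = geom.bounding_box
    near = np.all((pts >= glo - spacing) & (pts <= ghi + spacing), axis=1)
    labels = np.full(len(pts), LABEL_INDEX["exterior"], dtype=np.uint8)
    labels[near] = _label_cochlea(geom, pts[near], spacing)

    cmap = ConductivityMap(spacing=spacing, origin=origin,
                           labels=labels.reshape(shape))
    for arr in arrays:
        _stamp_array(cmap, arr, pts)
    return cmap


def _stamp_array(cmap: ConductivityMap, array, pts: np.ndarray) -> None:
    """Rasterize an electrode array (carrier + contacts) into the label grid."""
    from scipy.spatial import cKDTree

    labels = cmap.labels.reshape(-1)
    cl_pts = array.centerline.points
    cl_arc = array.centerline.arc
    tree = cKDTree(cl_pts)
    rmax = float(np.max(array.carrier_radius(cl_arc)))
    # carrier: voxel centers within the local carrier radius of the centerline
    lo = cl_pts.min(axis=0) - (rmax + cmap.spacing)
    hi = cl_pts.max(axis=0) + (rmax + cmap.spacing)
    cand = np.flatnonzero(np.all((pts >= lo) & (pts <= hi), axis=1))
    d, idx = tree.query(pts[cand])
    local_r = array.carrier_radius(cl_arc[idx])
    inside = d <= local_r
    labels[cand[inside]] = LABEL_INDEX["carrier"]

    half = cmap.spacing / 2.0
    for ct in array.contacts:
        if 2.0 * (ct.radius + ct.height) < cmap.spacing:
            raise ValueError(
                f"spacing {cmap.spacing} um too coarse to resolve contact {ct.id}"
            )
        rel = pts[cand] - ct.center
        axial = rel @ ct.orientation
        radial = np.linalg.norm(rel - np.outer(axial, ct.orientation), axis=1)
        # dilate by half a voxel so a contact always occupies >= 1 voxel
        inside_ct = (np.abs(axial) <= ct.height / 2 + half) & (radial <= ct.radius + half)
        vox = cand[inside_ct]
        if len(vox) == 0:
            raise ValueError(f"contact {ct.id} occupies zero voxels at spacing {cmap.spacing}")
        labels[vox] = LABEL_INDEX["contact"]
        cmap.contact_ids.append(ct.id)
        cmap.contact_voxels[ct.id] = np.array(
            np.unravel_index(vox, cmap.shape)
        ).T.astype(np.int64)
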