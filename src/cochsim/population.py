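"""Population-level analyses: stimulation specificity and selectivity maps,
conductivity sensitivity, and scala-tympani ossification sweeps.

Specificity asks how sharply a given contact excites its best fiber compared
with all others (column-wise normalization of the fiber x contact threshold
matrix); selectivity asks how sharply a given fiber is best excited by one
contact (row-wise).  The sweeps re-solve the volume conductor under modified
domain conductivities and compare per-fiber target-contact thresholds against
the default condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cable import assemble_chain
from .fields import solve_field
from .geometry import OSSIFICATION_SIGMAS
from .thresholds import ThresholdMatrix, threshold_search

__all__ = [
    "SpecificityMap",
    "SweepResult",
    "SweepRunner",
    "specificity_map",
    "selectivity_map",
    "conductivity_sensitivity",
    "ossification_sweep",
]


@dataclass
class SpecificityMap:
    """Per-entry percentage increase over the column (contact-wise) minimum."""

    increases_pct: np.ndarray       # (n_fibers, n_contacts), NaN where masked
    argmin_fiber: list[int]         # per contact, row index of the minimum
    argmax_fiber: list[int]
    fiber_ids: list[str]
    contact_ids: list[str]
    median_increase_pct: float      # over unmasked non-argmin entries
    axis: str = "contact"           # normalization axis

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.increases_pct, index=self.fiber_ids,
                            columns=self.contact_ids)


def specificity_map(matrix: ThresholdMatrix, include_argmin: bool = False) -> SpecificityMap:
    """Percentage increase from the minimum threshold for each contact.

    ``inc(f, c) = 100 * (T(f, c) / min_f T(f, c) - 1)``.  The summary median is
    taken over unmasked entries, excluding each column's 0% argmin entry unless
    ``include_argmin`` is set.
    """
    T = matrix.values
    inc = np.full_like(T, np.nan)
    argmin, argmax = [], []
    for c in range(T.shape[1]):
        col = T[:, c]
        ok = ~np.isnan(col)
        if not np.any(ok):
            raise ValueError(f"column {matrix.contact_ids[c]!r} fully masked")
        i_min = int(np.nanargmin(col))
        i_max = int(np.nanargmax(col))
        argmin.append(i_min)
        argmax.append(i_max)
        inc[ok, c] = 100.0 * (col[ok] / col[i_min] - 1.0)
    sel = ~np.isnan(inc)
    if not include_argmin:
        for c, i_min in enumerate(argmin):
            sel[i_min, c] = False
    median = float(np.median(inc[sel])) if np.any(sel) else 0.0
    return SpecificityMap(
        increases_pct=inc, argmin_fiber=argmin, argmax_fiber=argmax,
        fiber_ids=list(matrix.fiber_ids), contact_ids=list(matrix.contact_ids),
        median_increase_pct=median,
    )


def selectivity_map(matrix: ThresholdMatrix, include_argmin: bool = False) -> SpecificityMap:
    """Row-normalized analogue: thresholds normalized for each fiber across
    contacts.  Implemented as specificity of the transposed matrix."""
    transposed = ThresholdMatrix(
        values=matrix.values.T.copy(), fiber_ids=list(matrix.contact_ids),
        contact_ids=list(matrix.fiber_ids), array_tag=matrix.array_tag,
        condition=matrix.condition, polarity=matrix.polarity,
    )
    out = specificity_map(transposed, include_argmin=include_argmin)
    out.axis = "fiber"
    return out


@dataclass
class SweepResult:
    """Per-fiber default-vs-new target-contact thresholds for one condition."""

    label: str
    fiber_ids: list[str]
    default_ua: np.ndarray
    new_ua: np.ndarray
    sis_default: list[str] = field(default_factory=list)
    sis_new: list[str] = field(default_factory=list)

    @property
    def pct_change(self) -> np.ndarray:
        return 100.0 * (self.new_ua - self.default_ua) / self.default_ua

    @property
    def median_pct_change(self) -> float:
        return float(np.nanmedian(self.pct_change))

    @property
    def regression(self) -> tuple[float, float]:
        """OLS slope and intercept of new-vs-default thresholds."""
        ok = ~(np.isnan(self.default_ua) | np.isnan(self.new_ua))
        slope, intercept = np.polyfit(self.default_ua[ok], self.new_ua[ok], 1)
        return float(slope), float(intercept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fiber": self.fiber_ids,
            "default_ua": self.default_ua,
            "new_ua": self.new_ua,
            "pct_change": self.pct_change,
            "sis_default": self.sis_default or [""] * len(self.fiber_ids),
            "sis_new": self.sis_new or [""] * len(self.fiber_ids),
        })


class SweepRunner:
    """Computes per-fiber target-contact thresholds on a conductivity map.

    Holds the fixed experiment pieces (fibers, array, base map, cable and
    solver settings) so sweeps only vary the conductivity assignment.  Field
    solutions are cached per (map signature, contact).
    """

    def __init__(self, fibers, array, base_map, condition="healthy",
                 polarity="cathodic", dt_ms=1e-3, solver_rtol=1e-8):
        if len(fibers) != len(array.contacts):
            raise ValueError("need one target contact per fiber")
        self.fibers = fibers
        self.array = array
        self.base_map = base_map
        self.condition = condition
        self.polarity = polarity
        self.dt_ms = dt_ms
        self.solver_rtol = solver_rtol
        self.chains = [assemble_chain(f, condition=condition) for f in fibers]
        self._cache: dict = {}

    def thresholds(self, cond_map=None, label="default"):
        """Target-contact thresholds (uA) and SIS kinds under ``cond_map``."""
        cond_map = cond_map if cond_map is not None else self.base_map
        sig = tuple(sorted(cond_map.sigma_by_label.items()))
        out, sis = [], []
        from .cable import PulseSpec

        pulse = PulseSpec(polarity=self.polarity)
        for chain, ct in zip(self.chains, self.array.contacts):
            key = (sig, ct.id)
            if key not in self._cache:
                self._cache[key] = solve_field(cond_map, ct.id,
                                               rtol=self.solver_rtol)
            r = threshold_search(chain, self._cache[key], contact_id=ct.id,
                                 pulse_template=pulse,
                                 array_tag=self.array.tag, dt_ms=self.dt_ms)
            out.append(r.threshold_ua if r.converged else np.nan)
            sis.append(r.sis_kind or "")
        return np.array(out), sis


def _sweep(runner: SweepRunner, label: str, cond_map) -> SweepResult:
    d, sis_d = runner.thresholds(label="default")
    n, sis_n = runner.thresholds(cond_map, label=label)
    return SweepResult(label=label, fiber_ids=[f.id for f in runner.fibers],
                       default_ua=d, new_ua=n, sis_default=sis_d, sis_new=sis_n)


def conductivity_sensitivity(
    runner: SweepRunner,
    modiolus_factor: float = 10.0,
    bone_factor: float = 2.0,
    include_both: bool = True,
) -> dict[str, SweepResult]:
    """Threshold changes under elevated modiolus and bone conductivities.

    Returns sweeps labelled ``modiolus_x<f>``, ``bone_x<f>`` and optionally
    ``both`` (both factors applied simultaneously).
    """
    if modiolus_factor <= 0 or bone_factor <= 0:
        raise ValueError("conductivity factors must be positive")
    base = runner.base_map.sigma_by_label
    out: dict[str, SweepResult] = {}
    mod = runner.base_map.with_sigma(modiolus=base["modiolus"] * modiolus_factor)
    out[f"modiolus_x{modiolus_factor:g}"] = _sweep(runner, f"modiolus_x{modiolus_factor:g}", mod)
    bone = runner.base_map.with_sigma(bone=base["bone"] * bone_factor,
                                      exterior=base["exterior"] * bone_factor)
    out[f"bone_x{bone_factor:g}"] = _sweep(runner, f"bone_x{bone_factor:g}", bone)
    if include_both:
        both = runner.base_map.with_sigma(
            modiolus=base["modiolus"] * modiolus_factor,
            bone=base["bone"] * bone_factor,
            exterior=base["exterior"] * bone_factor,
        )
        out["both"] = _sweep(runner, "both", both)
    return out


def ossification_sweep(
    runner: SweepRunner,
    st_sigmas: dict[str, float] | None = None,
) -> dict[str, SweepResult]:
    """Progressive ST-ossification sweep (decreasing ST conductivity).

    The default ladder runs 1.0 (developing), 0.65 (moderate), 0.3 (severe)
    and 0.03 S/m (complete ossification).
    """
    st_sigmas = st_sigmas or dict(OSSIFICATION_SIGMAS)
    default_st = runner.base_map.sigma_by_label["ST"]
    out: dict[str, SweepResult] = {}
    for label, sigma in st_sigmas.items():
        if sigma <= 0:
            raise ValueError("ossified ST conductivity must be positive")
        if sigma > default_st:
            raise ValueError(
                f"ossified sigma {sigma} must not exceed the patent value {default_st}"
            )
        out[label] = _sweep(runner, label, runner.base_map.with_sigma(ST=sigma))
    return out
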