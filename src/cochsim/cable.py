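"""Multi-compartment cable model of a human type-I spiral ganglion cell.

A fiber is discretized into an ordered chain of compartments laid along its
3D trajectory (arc-length parameterized, so internode curvature is respected):

``terminal → [p-internode, p-node]* → presomatic → soma → postsomatic →
[c-internode, c-node]*``

Electrically active compartments (terminal, nodes of Ranvier, pre- and
post-somatic segments) carry temperature-adjusted Hodgkin–Huxley kinetics with
a tenfold conductance boost reflecting their high ion-channel density; the
spherical soma is active with membrane quantities divided by the number of
surrounding membrane layers; myelinated internodes are passive RC sheets whose
capacitance and conductance scale inversely with the sheet count (40 for the
dendrite, 80 for the axon).

Voltages use the reduced convention (rest = 0 mV).  Units throughout:
mV, ms, uA, mS, uF; geometry in um, membrane areas in cm^2.

Extracellular stimulation enters through the axial coupling of the
extracellular potential sampled at compartment centers, scaled by the signed
pulse amplitude during the pulse window (the activating-function drive).
Integration is semi-implicit first-order (implicit axial + linearized membrane,
implicit gating), unconditionally stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ANFPath

__all__ = [
    "MembraneSpec",
    "PulseSpec",
    "CompartmentChain",
    "VoltageTrace",
    "peripheral_layout",
    "assemble_chain",
    "simulate",
    "detect_spike",
    "find_sis",
    "CONDITIONS",
]

CONDITIONS = ("healthy", "thin_dendrite", "no_dendrite")

KIND_TERMINAL = "terminal"
KIND_PNODE = "p-node"
KIND_PINTER = "p-internode"
KIND_PRESOMA = "presomatic"
KIND_SOMA = "soma"
KIND_POSTSOMA = "postsomatic"
KIND_CNODE = "c-node"
KIND_CINTER = "c-internode"

PERIPHERAL_KINDS = {KIND_TERMINAL, KIND_PNODE, KIND_PINTER, KIND_PRESOMA}


@dataclass(frozen=True)
class MembraneSpec:
    """Electrical membrane and cable parameters.

    The temperature factor ``k`` multiplies all Hodgkin–Huxley rate constants
    so the action-potential duration is sub-millisecond, as appropriate for
    the human cochlea.
    """

    rho_i_ohm_cm: float = 100.0       # intracellular resistivity, 0.1 kOhm*cm
    c_sheet: float = 1.0              # uF/cm^2 per membrane sheet
    g_sheet: float = 0.1              # mS/cm^2 per membrane sheet
    sheets_dendrite: int = 40
    sheets_axon: int = 80
    soma_layers: int = 3
    active_boost: float = 10.0
    g_na: float = 120.0               # mS/cm^2 (before boost)
    g_k: float = 36.0
    g_l: float = 0.3
    e_na: float = 115.0               # mV, reduced convention
    e_k: float = -12.0
    k_temp: float = 9.0               # rate-constant temperature factor
    d_dendrite: float = 1.3           # um
    d_dendrite_thin: float = 0.5
    d_axon: float = 2.6
    d_soma: float = 20.0
    l_terminal: float = 10.0          # um, unmyelinated
    l_node: float = 2.5
    l_presomatic: float = 100.0
    presomatic_segments: int = 10     # electrical subdivision of the 100 um segment
    l_postsomatic: float = 5.0
    l_c_internode: float = 500.0
    internode_target: float = 250.0   # peripheral internode target length
    internode_segments: int = 2       # electrical subdivision of internodes
                                      # (2 is converged: thresholds move <1%
                                      # on further halving)
    n_axon_nodes: int = 10

    def __post_init__(self):
        if min(self.c_sheet, self.g_sheet, self.g_na, self.g_k, self.g_l,
               self.rho_i_ohm_cm, self.k_temp) <= 0:
            raise ValueError("conductances, capacitances and rates must be positive")


@dataclass(frozen=True)
class PulseSpec:
    """Monophasic rectangular current pulse at the active contact."""

    polarity: str = "cathodic"        # "cathodic" | "anodic"
    duration_ms: float = 0.05         # 50 us
    amplitude_ua: float = 0.0         # magnitude
    onset_ms: float = 0.1

    def __post_init__(self):
        if self.polarity not in ("cathodic", "anodic"):
            raise ValueError("polarity must be 'cathodic' or 'anodic'")
        if self.duration_ms <= 0:
            raise ValueError("pulse duration must be positive")
        if self.amplitude_ua < 0:
            raise ValueError("amplitude is a magnitude (>= 0)")

    @property
    def signed_amplitude(self) -> float:
        return -self.amplitude_ua if self.polarity == "cathodic" else self.amplitude_ua


# resting gating state of the classic HH kinetics at V = 0 (reduced convention)
def _rates(v: float) -> tuple[float, float, float, float, float, float]:
    def vtrap(x, y):
        if abs(x / y) < 1e-7:
            return y * (1.0 - x / y / 2.0)
        return x / math.expm1(x / y)

    a_m = 0.1 * vtrap(25.0 - v, 10.0)
    b_m = 4.0 * math.exp(-v / 18.0)
    a_h = 0.07 * math.exp(-v / 20.0)
    b_h = 1.0 / (math.exp((30.0 - v) / 10.0) + 1.0)
    a_n = 0.01 * vtrap(10.0 - v, 10.0)
    b_n = 0.125 * math.exp(-v / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def resting_gates() -> tuple[float, float, float]:
    a_m, b_m, a_h, b_h, a_n, b_n = _rates(0.0)
    return a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n)


def leak_reversal(spec: MembraneSpec) -> float:
    """Leak reversal (mV) making V = 0 the exact resting equilibrium."""
    m0, h0, n0 = resting_gates()
    g_na_eff = spec.g_na * m0**3 * h0
    g_k_eff = spec.g_k * n0**4
    return -(g_na_eff * spec.e_na + g_k_eff * spec.e_k) / spec.g_l


@dataclass
class CompartmentChain:
    """Discretized fiber: geometry, membrane and axial electrical quantities."""

    anf_id: str
    condition: str
    spec: MembraneSpec
    kind: list[str]
    length: np.ndarray            # um
    diameter: np.ndarray          # um
    arc_pos: np.ndarray           # um, compartment centers from the terminal
    centers: np.ndarray           # (N,3) um
    area_cm2: np.ndarray
    c_uF: np.ndarray
    g_pas_mS: np.ndarray          # passive membrane conductance (0 for active)
    active: np.ndarray            # bool
    g_na_mS: np.ndarray
    g_k_mS: np.ndarray
    g_l_mS: np.ndarray
    e_l: float
    g_axial_mS: np.ndarray        # (N-1,) coupling conductances

    @property
    def n(self) -> int:
        return len(self.kind)

    def index_of(self, kind: str, which: int = 0) -> int:
        hits = [i for i, k in enumerate(self.kind) if k == kind]
        return hits[which]

    @property
    def central_node_indices(self) -> list[int]:
        return [i for i, k in enumerate(self.kind) if k == KIND_CNODE]


def peripheral_layout(
    dendrite_length: float,
    target: float = 250.0,
    n_range: tuple[int, int] = (4, 10),
    l_terminal: float = 10.0,
    l_node: float = 2.5,
    l_presomatic: float = 100.0,
) -> tuple[int, float]:
    """Number and effective length of peripheral internodes for a dendrite.

    The span left after the unmyelinated terminal and the pre-somatic segment
    is divided into ``n`` internodes separated by ``n - 1`` nodes of Ranvier;
    ``n`` is chosen to bring the effective internode length closest to the
    target (250 um, half the central internode).
    """
    if dendrite_length <= l_terminal + l_presomatic + l_node:
        raise ValueError(f"dendrite length {dendrite_length} um too short for layout")
    span = dendrite_length - l_terminal - l_presomatic
    best: tuple[float, int, float] | None = None
    for n in range(n_range[0], n_range[1] + 1):
        eff = (span - l_node * (n - 1)) / n
        if eff <= l_node:
            continue
        err = abs(eff - target)
        if best is None or err < best[0]:
            best = (err, n, eff)
    if best is None:
        raise ValueError(f"no feasible internode count in {n_range} for span {span}")
    return best[1], best[2]


def _half_axial_ohm(spec: MembraneSpec, length_um: float, diam_um: float) -> float:
    """Half-compartment axial resistance 2*rho*L/(pi*d^2) in Ohm."""
    l_cm = length_um * 1e-4
    d_cm = diam_um * 1e-4
    return 2.0 * spec.rho_i_ohm_cm * l_cm / (math.pi * d_cm * d_cm)


def assemble_chain(
    anf: ANFPath,
    spec: MembraneSpec | None = None,
    condition: str = "healthy",
    internode_target: float | None = None,
    n_range: tuple[int, int] = (4, 10),
    electrical_dendrite_length: float | None = None,
) -> CompartmentChain:
    """Lay the compartment chain along the fiber polyline.

    ``electrical_dendrite_length`` overrides the dendritic length used for the
    internode layout and for membrane/axial quantities, while compartment
    centers stay on the fiber's actual geometric path (arc positions in the
    peripheral region are rescaled); used by the fixed-dendrite robustness
    variant.
    """
    spec = spec or MembraneSpec()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    target = spec.internode_target if internode_target is None else internode_target
    d_dend = spec.d_dendrite_thin if condition == "thin_dendrite" else spec.d_dendrite

    l_elec = electrical_dendrite_length or anf.dendrite_length
    geo_scale = anf.dendrite_length / l_elec  # electrical -> physical arc

    kinds: list[str] = []
    lengths: list[float] = []
    diams: list[float] = []
    arc_elec: list[float] = []    # electrical arc of compartment start

    if condition != "no_dendrite":
        n_int, eff = peripheral_layout(
            l_elec, target=target, n_range=n_range,
            l_terminal=spec.l_terminal, l_node=spec.l_node,
            l_presomatic=spec.l_presomatic,
        )
        pos = 0.0

        def add(kind, L, d):
            nonlocal pos
            kinds.append(kind)
            lengths.append(L)
            diams.append(d)
            arc_elec.append(pos)
            pos += L

        add(KIND_TERMINAL, spec.l_terminal, d_dend)
        for i in range(n_int):
            for _ in range(spec.internode_segments):
                add(KIND_PINTER, eff / spec.internode_segments, d_dend)
            if i < n_int - 1:
                add(KIND_PNODE, spec.l_node, d_dend)
        # the 100 um pre-somatic segment is subdivided electrically so an AP
        # can charge the high-capacitance soma progressively instead of seeing
        # it as one lumped load
        for _ in range(spec.presomatic_segments):
            add(KIND_PRESOMA, spec.l_presomatic / spec.presomatic_segments, d_dend)
        assert abs(pos - l_elec) < 1e-6
    else:
        pos = l_elec

        def add(kind, L, d):  # noqa: F811 - same helper, dendrite skipped
            nonlocal pos
            kinds.append(kind)
            lengths.append(L)
            diams.append(d)
            arc_elec.append(pos)
            pos += L

    add(KIND_SOMA, spec.d_soma, spec.d_soma)
    add(KIND_POSTSOMA, spec.l_postsomatic, spec.d_axon)
    for _ in range(spec.n_axon_nodes):
        for _ in range(spec.internode_segments):
            add(KIND_CINTER, spec.l_c_internode / spec.internode_segments,
                spec.d_axon)
        add(KIND_CNODE, spec.l_node, spec.d_axon)

    lengths_a = np.array(lengths)
    diams_a = np.array(diams)
    arc_start = np.array(arc_elec)
    # physical arc: peripheral region rescaled, soma and beyond shifted so the
    # soma always starts at the fiber's anatomical soma position
    arc_phys = np.where(
        arc_start < l_elec - 1e-9,
        arc_start * geo_scale,
        arc_start - l_elec + anf.dendrite_length,
    )
    centers_elec_len = np.where(arc_start < l_elec - 1e-9, lengths_a * geo_scale, lengths_a)
    arc_center = arc_phys + centers_elec_len / 2.0
    if arc_center[-1] > anf.total_length:
        raise ValueError(
            f"{anf.id}: polyline ({anf.total_length:.0f} um) too short for chain "
            f"({arc_center[-1]:.0f} um)"
        )
    centers = anf.point_at_arc(arc_center)

    # membrane areas (cm^2): lateral cylinder for processes, full sphere for soma
    area = math.pi * diams_a * lengths_a * 1e-8
    kinds_arr = np.array(kinds)
    i_soma = np.flatnonzero(kinds_arr == KIND_SOMA)
    area[i_soma] = math.pi * spec.d_soma**2 * 1e-8

    active = np.isin(kinds_arr, [KIND_TERMINAL, KIND_PNODE, KIND_PRESOMA,
                                 KIND_POSTSOMA, KIND_CNODE, KIND_SOMA])
    c = np.empty(len(kinds))
    g_pas = np.zeros(len(kinds))
    g_na = np.zeros(len(kinds))
    g_k = np.zeros(len(kinds))
    g_l = np.zeros(len(kinds))
    for i, k in enumerate(kinds):
        a = area[i]
        if k == KIND_PINTER:
            c[i] = spec.c_sheet / spec.sheets_dendrite * a
            g_pas[i] = spec.g_sheet / spec.sheets_dendrite * a
        elif k == KIND_CINTER:
            c[i] = spec.c_sheet / spec.sheets_axon * a
            g_pas[i] = spec.g_sheet / spec.sheets_axon * a
        elif k == KIND_SOMA:
            c[i] = spec.c_sheet / spec.soma_layers * a
            g_na[i] = spec.g_na / spec.soma_layers * a
            g_k[i] = spec.g_k / spec.soma_layers * a
            g_l[i] = spec.g_l / spec.soma_layers * a
        else:  # boosted HH compartments
            c[i] = spec.c_sheet * a
            g_na[i] = spec.g_na * spec.active_boost * a
            g_k[i] = spec.g_k * spec.active_boost * a
            g_l[i] = spec.g_l * spec.active_boost * a

    half = np.array(
        [_half_axial_ohm(spec, L, d) for L, d in zip(lengths_a, diams_a)]
    )
    g_ax = 1000.0 / (half[:-1] + half[1:])  # Ohm -> mS

    return CompartmentChain(
        anf_id=anf.id, condition=condition, spec=spec,
        kind=kinds, length=lengths_a, diameter=diams_a,
        arc_pos=arc_center, centers=centers, area_cm2=area,
        c_uF=c, g_pas_mS=g_pas, active=active,
        g_na_mS=g_na, g_k_mS=g_k, g_l_mS=g_l,
        e_l=leak_reversal(spec), g_axial_mS=g_ax,
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _step_loop(v, m, h, n_g, C, g_pas, act, g_na, g_k, g_l, e_l, e_na, e_k,
               g_ax, ext_drive, dt, k_temp, n_steps, pulse_on_from, pulse_on_to,
               v_out):
    N = v.shape[0]
    lower = np.empty(N)
    diag = np.empty(N)
    upper = np.empty(N)
    rhs = np.empty(N)
    cp = np.empty(N)
    dp = np.empty(N)
    for s in range(n_steps):
        pulse = 1.0 if (pulse_on_from <= s < pulse_on_to) else 0.0
        for i in range(N):
            vi = v[i]
            if act[i]:
                x = (25.0 - vi) / 10.0
                if abs(x) < 1e-7:
                    a_m = 0.1 * 10.0 * (1.0 - x / 2.0)
                else:
                    a_m = 0.1 * (25.0 - vi) / (math.exp(x) - 1.0)
                b_m = 4.0 * math.exp(-vi / 18.0)
                a_h = 0.07 * math.exp(-vi / 20.0)
                b_h = 1.0 / (math.exp((30.0 - vi) / 10.0) + 1.0)
                x = (10.0 - vi) / 10.0
                if abs(x) < 1e-7:
                    a_n = 0.01 * 10.0 * (1.0 - x / 2.0)
                else:
                    a_n = 0.01 * (10.0 - vi) / (math.exp(x) - 1.0)
                b_n = 0.125 * math.exp(-vi / 80.0)
                m[i] = (m[i] + dt * k_temp * a_m) / (1.0 + dt * k_temp * (a_m + b_m))
                h[i] = (h[i] + dt * k_temp * a_h) / (1.0 + dt * k_temp * (a_h + b_h))
                n_g[i] = (n_g[i] + dt * k_temp * a_n) / (1.0 + dt * k_temp * (a_n + b_n))
                gna = g_na[i] * m[i] ** 3 * h[i]
                gk = g_k[i] * n_g[i] ** 4
                g_mem = gna + gk + g_l[i]
                drive = gna * e_na + gk * e_k + g_l[i] * e_l
            else:
                g_mem = g_pas[i]
                drive = 0.0
            diag[i] = C[i] / dt + g_mem
            rhs[i] = C[i] / dt * vi + drive + pulse * ext_drive[i]
            lower[i] = 0.0
            upper[i] = 0.0
        for i in range(N - 1):
            g = g_ax[i]
            diag[i] += g
            diag[i + 1] += g
            upper[i] = -g
            lower[i + 1] = -g
        # Thomas algorithm
        cp[0] = upper[0] / diag[0]
        dp[0] = rhs[0] / diag[0]
        for i in range(1, N):
            denom = diag[i] - lower[i] * cp[i - 1]
            cp[i] = upper[i] / denom
            dp[i] = (rhs[i] - lower[i] * dp[i - 1]) / denom
        v[N - 1] = dp[N - 1]
        for i in range(N - 2, -1, -1):
            v[i] = dp[i] - cp[i] * v[i + 1]
        for i in range(N):
            v_out[i, s + 1] = v[i]
    return v


try:  # optional numba acceleration; the pure-python loop is the fallback
    from numba import njit

    _kernel = njit(cache=True, fastmath=False)(_step_loop)
except Exception:  # pragma: no cover - exercised only without numba
    _kernel = _step_loop


@dataclass
class VoltageTrace:
    """Per-compartment reduced membrane voltage over time."""

    dt_ms: float
    t_ms: np.ndarray              # (T,)
    v_mV: np.ndarray              # (N, T)
    chain: CompartmentChain
    pulse: PulseSpec
    gates: np.ndarray | None = None

    def peak_time(self, i: int) -> float:
        return float(self.t_ms[int(np.argmax(self.v_mV[i]))])

    def peak_value(self, i: int) -> float:
        return float(np.max(self.v_mV[i]))


def simulate(
    chain: CompartmentChain,
    ve_per_unit_current: np.ndarray,
    pulse: PulseSpec,
    t_end_ms: float = 1.6,
    dt_ms: float = 1e-3,
    auto_extend: bool = True,
) -> VoltageTrace:
    """Integrate the chain under extracellular stimulation.

    ``ve_per_unit_current`` is the extracellular potential (mV per +1 uA) at
    the compartment centers; it is scaled by the signed pulse amplitude during
    the pulse window and zero otherwise.  The window is extended automatically
    if the most central compartments are still depolarizing at ``t_end_ms``.
    """
    ve = np.asarray(ve_per_unit_current, dtype=float)
    if ve.shape != (chain.n,):
        raise ValueError(
            f"ve has length {ve.shape}, chain has {chain.n} compartments"
        )
    if dt_ms > 2e-3 + 1e-12:
        raise ValueError("dt must be <= 2 us for the implicit scheme's accuracy contract")

    # constant extracellular axial drive (uA) per unit pulse amplitude
    g = chain.g_axial_mS
    ext = np.zeros(chain.n)
    dve = np.diff(ve)
    ext[:-1] += g * dve
    ext[1:] -= g * dve
    ext *= pulse.signed_amplitude

    m0, h0, n0 = resting_gates()
    v = np.zeros(chain.n)
    m = np.full(chain.n, m0)
    h = np.full(chain.n, h0)
    n_g = np.full(chain.n, n0)

    chunks = []
    t0 = 0.0
    max_extensions = 3
    total_steps_done = 0
    while True:
        n_steps = int(round((t_end_ms - t0) / dt_ms))
        on_from = int(round(pulse.onset_ms / dt_ms)) - total_steps_done
        on_to = int(round((pulse.onset_ms + pulse.duration_ms) / dt_ms)) - total_steps_done
        v_out = np.empty((chain.n, n_steps + 1))
        v_out[:, 0] = v
        v = _kernel(
            v.copy(), m, h, n_g, chain.c_uF, chain.g_pas_mS,
            chain.active.astype(np.int64), chain.g_na_mS, chain.g_k_mS,
            chain.g_l_mS, chain.e_l, chain.spec.e_na, chain.spec.e_k,
            chain.g_axial_mS, ext, dt_ms, chain.spec.k_temp, n_steps,
            max(on_from, 0), max(on_to, 0), v_out,
        )
        if not np.all(np.isfinite(v_out)):
            raise FloatingPointError(f"integration diverged (dt={dt_ms} ms)")
        chunks.append(v_out if not chunks else v_out[:, 1:])
        total_steps_done += n_steps
        t0 = t_end_ms
        # extend while an AP is still in flight anywhere along the chain
        still_active = np.max(v) > 40.0
        if not (auto_extend and still_active and max_extensions > 0):
            break
        max_extensions -= 1
        t_end_ms = t_end_ms + 1.0

    v_all = np.concatenate(chunks, axis=1)
    t = np.arange(v_all.shape[1]) * dt_ms
    return VoltageTrace(dt_ms=dt_ms, t_ms=t, v_mV=v_all, chain=chain, pulse=pulse)


SPIKE_THRESHOLD_MV = 60.0


def detect_spike(trace: VoltageTrace, threshold: float = SPIKE_THRESHOLD_MV):
    """Spike = reduced voltage crossing ``threshold`` at either of the two most
    central nodes; latency is the first crossing time (ms)."""
    central = trace.chain.central_node_indices[-2:]
    v = trace.v_mV[central]
    over = np.any(v > threshold, axis=0)
    if not np.any(over):
        return False, None
    return True, float(trace.t_ms[int(np.argmax(over))])


def find_sis(trace: VoltageTrace, threshold: float = SPIKE_THRESHOLD_MV):
    """Spike initiation site: among compartments whose voltage exceeds the
    spike criterion, the one whose peak occurs earliest (ties break toward the
    terminal).  Returns ``(index, kind)``."""
    spiked, _ = detect_spike(trace, threshold)
    if not spiked:
        raise ValueError("no spike in trace")
    peaks = np.max(trace.v_mV, axis=1)
    cand = np.flatnonzero(peaks > threshold)
    peak_t = np.array([np.argmax(trace.v_mV[i]) for i in cand])
    i = int(cand[np.argmin(peak_t)])  # argmin takes the first (most terminal) tie
    return i, trace.chain.kind[i]
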