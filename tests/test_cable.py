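"""Multi-compartment ANF model: layout rule, chain assembly, membrane
dynamics, spike detection and initiation-site identification."""

import numpy as np
import pytest

from cochsim import (AnalyticPointSource, MembraneSpec, PulseSpec,
                     assemble_chain, detect_spike, find_sis, peripheral_layout,
                     simulate)
from cochsim.cable import VoltageTrace, _half_axial_ohm, leak_reversal


class TestPeripheralLayout:
    @pytest.mark.parametrize("dendrite,expected_n,expected_eff", [
        (2312.0, 9, 242.444),   # longest basal fiber
        (1732.0, 6, 268.25),    # median fiber
        (1320.0, 5, 240.0),     # shortest fiber
    ])
    def test_internode_count_and_length(self, dendrite, expected_n, expected_eff):
        n, eff = peripheral_layout(dendrite)
        assert n == expected_n
        assert eff == pytest.approx(expected_eff, abs=1e-3)

    def test_all_default_fibers_within_printed_count_range(self, fibers):
        counts = [peripheral_layout(f.dendrite_length)[0] for f in fibers]
        assert min(counts) >= 5 and max(counts) <= 9

    def test_too_short_dendrite_rejected(self):
        with pytest.raises(ValueError):
            peripheral_layout(100.0)

    def test_infeasible_count_range_rejected(self):
        # a 20 um free span cannot host 8+ internodes longer than a node
        with pytest.raises(ValueError):
            peripheral_layout(130.0, n_range=(8, 10))


class TestAssembly:
    def test_soma_postsomatic_center_distance(self, fibers):
        chain = assemble_chain(fibers[12])
        d = chain.arc_pos[chain.index_of("postsomatic")] - chain.arc_pos[chain.index_of("soma")]
        assert d == pytest.approx(12.5, abs=1e-9)

    def test_peripheral_node_axial_resistance(self):
        # 4*rho*L/(pi d^2) for a 2.5 um node of 1.3 um diameter, rho=100 Ohm cm
        r = 2 * _half_axial_ohm(MembraneSpec(), 2.5, 1.3)
        assert r == pytest.approx(1.88e6, rel=0.01)

    def test_no_dendrite_starts_at_soma(self, fibers):
        chain = assemble_chain(fibers[12], condition="no_dendrite")
        assert chain.kind[0] == "soma"
        assert not any(k.startswith("p-") or k in ("terminal", "presomatic")
                       for k in chain.kind)

    def test_thin_condition_thins_all_peripheral_diameters(self, fibers):
        chain = assemble_chain(fibers[12], condition="thin_dendrite")
        for k, d in zip(chain.kind, chain.diameter):
            if k in ("terminal", "p-node", "p-internode", "presomatic"):
                assert d == 0.5
            elif k in ("postsomatic", "c-node", "c-internode"):
                assert d == 2.6

    def test_unknown_condition_rejected(self, fibers):
        with pytest.raises(ValueError):
            assemble_chain(fibers[12], condition="mild")

    def test_leak_reversal_balances_rest(self):
        spec = MembraneSpec()
        el = leak_reversal(spec)
        from cochsim.cable import resting_gates
        m0, h0, n0 = resting_gates()
        i_rest = (spec.g_na * m0**3 * h0 * (0 - spec.e_na)
                  + spec.g_k * n0**4 * (0 - spec.e_k) + spec.g_l * (0 - el))
        assert i_rest == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def median_chain(fibers):
    return assemble_chain(fibers[12])


@pytest.fixture(scope="module")
def terminal_source(median_chain):
    return AnalyticPointSource(
        position=median_chain.centers[0] + np.array([0.0, 0.0, 255.0]))


class TestDynamics:
    def test_resting_stability(self, median_chain, terminal_source):
        ve = terminal_source.sample(median_chain.centers)
        trace = simulate(median_chain, ve, PulseSpec(amplitude_ua=0.0),
                         t_end_ms=10.0)
        assert np.max(np.abs(trace.v_mV)) < 0.1

    def test_suprathreshold_ap_propagates_to_central_end(self, median_chain,
                                                         terminal_source):
        ve = terminal_source.sample(median_chain.centers)
        trace = simulate(median_chain, ve, PulseSpec(amplitude_ua=900.0),
                         t_end_ms=3.0)
        spiked, latency = detect_spike(trace)
        assert spiked and latency > 0.1
        last = median_chain.central_node_indices[-1]
        assert trace.peak_value(last) > 80.0  # full overshoot, reduced scale

    def test_somatic_delay(self, median_chain, terminal_source):
        ve = terminal_source.sample(median_chain.centers)
        trace = simulate(median_chain, ve, PulseSpec(amplitude_ua=900.0),
                         t_end_ms=3.0)
        last_pnode = max(i for i, k in enumerate(median_chain.kind) if k == "p-node")
        assert trace.peak_time(median_chain.index_of("soma")) > trace.peak_time(last_pnode)

    def test_activating_function_polarity(self, median_chain):
        """During a cathodic pulse the compartment nearest the electrode is
        depolarized and its neighbours hyperpolarized; reversed for anodic."""
        mid_node = [i for i, k in enumerate(median_chain.kind) if k == "p-node"][2]
        src = AnalyticPointSource(
            position=median_chain.centers[mid_node] + np.array([0, 0, 120.0]))
        ve = src.sample(median_chain.centers)
        d = np.linalg.norm(median_chain.centers - src.position, axis=1)
        nearest = int(np.argmin(d))
        end = int(round(0.15 / 1e-3))  # end of the 50 us pulse at onset 0.1 ms
        tr_c = simulate(median_chain, ve, PulseSpec(amplitude_ua=5.0), t_end_ms=0.3)
        tr_a = simulate(median_chain, ve,
                        PulseSpec(polarity="anodic", amplitude_ua=5.0), t_end_ms=0.3)
        assert tr_c.v_mV[nearest, end] > 0 > tr_a.v_mV[nearest, end]
        for j in (nearest - 2, nearest + 2):
            assert tr_c.v_mV[j, end] < 0 < tr_a.v_mV[j, end]

    def test_ve_length_mismatch_rejected(self, median_chain):
        with pytest.raises(ValueError):
            simulate(median_chain, np.zeros(3), PulseSpec(amplitude_ua=1.0))

    def test_too_large_dt_rejected(self, median_chain):
        ve = np.zeros(median_chain.n)
        with pytest.raises(ValueError):
            simulate(median_chain, ve, PulseSpec(amplitude_ua=1.0), dt_ms=0.01)


class TestSpikeDetection:
    def _synthetic_trace(self, chain, peaks):
        """Trace with hand-placed gaussian peaks: {comp_index: (t_ms, amp)}."""
        t = np.arange(0, 2.0, 1e-3)
        v = np.zeros((chain.n, len(t)))
        for i, (tp, amp) in peaks.items():
            v[i] = amp * np.exp(-((t - tp) / 0.05) ** 2)
        return VoltageTrace(dt_ms=1e-3, t_ms=t, v_mV=v, chain=chain,
                            pulse=PulseSpec(amplitude_ua=1.0))

    def test_resting_trace_has_no_spike(self, median_chain):
        tr = self._synthetic_trace(median_chain, {})
        assert detect_spike(tr) == (False, None)
        with pytest.raises(ValueError):
            find_sis(tr)

    def test_earliest_peak_wins(self, median_chain):
        c1, c2 = median_chain.central_node_indices[-2:]
        tr = self._synthetic_trace(median_chain, {
            0: (0.5, 95.0), 5: (0.8, 95.0), c1: (1.2, 95.0), c2: (1.3, 95.0)})
        i, kind = find_sis(tr)
        assert i == 0 and kind == "terminal"

    def test_tie_breaks_toward_terminal(self, median_chain):
        c1, c2 = median_chain.central_node_indices[-2:]
        tr = self._synthetic_trace(median_chain, {
            2: (0.5, 95.0), 6: (0.5, 95.0), c1: (1.0, 95.0), c2: (1.1, 95.0)})
        i, _ = find_sis(tr)
        assert i == 2

    def test_subthreshold_peaks_ignored(self, median_chain):
        c1, c2 = median_chain.central_node_indices[-2:]
        tr = self._synthetic_trace(median_chain, {
            0: (0.3, 40.0), c1: (1.0, 95.0), c2: (1.1, 95.0)})
        i, kind = find_sis(tr)
        assert kind == "c-node"


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.floats(min_value=400.0, max_value=4000.0))
def test_layout_reconstructs_span_exactly(dendrite):
    """For any feasible dendritic length the chosen internodes and nodes tile
    the free span exactly and the count stays in the configured range."""
    n, eff = peripheral_layout(dendrite)
    span = dendrite - 10.0 - 100.0
    assert 4 <= n <= 10
    assert eff > 2.5
    assert n * eff + 2.5 * (n - 1) == pytest.approx(span, abs=1e-9)
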