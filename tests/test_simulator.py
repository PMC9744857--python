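"""Traveling-wave engine: junction scattering, chains, branches, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonoline import (
    SimConfig,
    SourcePulse,
    analytic_cascade_response,
    junction_scatter,
    simulate,
)

from conftest import chain_model, star_model

DT = 10e-9

impedance = st.floats(min_value=0.1, max_value=10.0, allow_nan=False)


class TestJunctionScatter:
    def test_matched_junction_is_transparent(self):
        refl, node_v = junction_scatter(1.0, 2.0, [2.0])
        assert refl == 0.0
        assert node_v == 1.0

    def test_step_up_closed_form(self):
        refl, node_v = junction_scatter(1.0, 1.5, [3.0])
        assert refl == pytest.approx(1 / 3)
        assert node_v == pytest.approx(4 / 3)

    def test_symmetric_split_closed_form(self):
        z = 2.7
        refl, node_v = junction_scatter(1.0, z, [z, z])
        assert refl == pytest.approx(-1 / 3)
        assert node_v == pytest.approx(2 / 3)

    def test_shunt_load_combines_in_parallel(self):
        # matched termination expressed as shunt only
        refl, node_v = junction_scatter(1.0, 2.0, [], shunt_load=2.0)
        assert refl == 0.0 and node_v == 1.0

    def test_open_end_rejected(self):
        with pytest.raises(ValueError):
            junction_scatter(1.0, 2.0, [])

    @given(impedance, st.lists(impedance, min_size=1, max_size=5))
    @settings(max_examples=300, derandomize=True)
    def test_power_conservation(self, z_in, downstream):
        """Reflected + transmitted power equals incident power at any junction."""
        refl, node_v = junction_scatter(1.0, z_in, downstream)
        z_load = 1.0 / sum(1.0 / z for z in downstream)
        gamma = refl
        balance = gamma**2 + node_v**2 * z_in / z_load
        assert balance == pytest.approx(1.0, rel=1e-12)


class TestSimulate:
    def test_matched_uniform_chain_is_delayed_copy(self, unit_source):
        delays = [4e-7, 7e-7, 3e-7]
        model = chain_model([2.0, 2.0, 2.0], delays)
        config = SimConfig(duration=5e-6, time_step=DT)
        trace = simulate(model, unit_source, config)["T3:B+"]
        shift = round(sum(delays) / DT)
        expected = np.zeros_like(trace.voltages)
        src = unit_source.sample(trace.times)
        expected[shift:] = src[: len(src) - shift]
        assert np.max(np.abs(trace.voltages - expected)) < 1e-12
        assert np.max(np.abs(trace.voltages)) == pytest.approx(unit_source.amplitude)

    def test_two_segment_step_up_amplitude(self, unit_source):
        model = chain_model([1.5, 3.0], [4e-7, 6e-7])
        trace = simulate(model, unit_source, SimConfig(duration=4e-6, time_step=DT))["T2:B+"]
        arrival = round(1e-6 / DT)
        assert trace.voltages[arrival] == pytest.approx(4 / 3 * unit_source.amplitude, rel=1e-12)

    @pytest.mark.parametrize("n_branches", [2, 3, 4])
    def test_symmetric_star_transmits_2_over_n_plus_1(self, unit_source, n_branches):
        z = 1.7
        model = star_model(z, [z] * n_branches, trunk_delay=5e-7, branch_delay=5e-7)
        traces = simulate(model, unit_source, SimConfig(duration=3e-6, time_step=DT))
        arrival = round(1e-6 / DT)
        for i in range(n_branches):
            v = traces[f"T{i + 2}:B+"].voltages[arrival]
            assert v == pytest.approx(2 / (n_branches + 1) * unit_source.amplitude, rel=1e-12)

    def test_linearity_in_source_amplitude(self):
        model = chain_model([1.0, 2.5, 0.7], [3e-7, 5e-7, 4e-7])
        config = SimConfig(duration=4e-6, time_step=DT)
        lo = simulate(model, SourcePulse(amplitude=1.0), config)["T3:B+"]
        hi = simulate(model, SourcePulse(amplitude=7.5), config)["T3:B+"]
        assert np.allclose(hi.voltages, 7.5 * lo.voltages, rtol=1e-12, atol=1e-15)

    def test_delay_shorter_than_step_rejected(self, unit_source):
        model = chain_model([1.0], [3e-9])
        with pytest.raises(ValueError, match="smaller time_step"):
            simulate(model, unit_source, SimConfig(duration=1e-6, time_step=10e-9))

    def test_sample_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            SimConfig(duration=1.0, time_step=1e-9, sample_cap=1000)

    def test_matched_source_absorbs_returns(self, unit_source):
        # mismatched interface sends an echo back; an ideal source re-reflects
        # it, a matched source does not, so the terminal sees a second arrival
        # only in ideal mode.
        model = chain_model([1.0, 4.0], [4e-7, 4e-7])
        config = SimConfig(duration=4e-6, time_step=DT)
        ideal = simulate(model, unit_source, config)["T2:B+"]
        matched = simulate(model, unit_source, config, source_mode="matched")["T2:B+"]
        # direct arrival occupies [0.8, 1.8] us; the source-re-reflected echo
        # occupies [1.6, 2.6] us, so look strictly after the direct pulse
        after = slice(round(2.0e-6 / DT), None)
        assert np.max(np.abs(ideal.voltages[after])) > 1e-3
        assert np.max(np.abs(matched.voltages[after])) < 1e-12


class TestSourcePulse:
    def test_rectangular_waveform(self):
        s = SourcePulse(amplitude=2.0, period=10e-6, width=1e-6)
        t = np.array([0.0, 0.5e-6, 1.5e-6, 10.2e-6])
        assert list(s.sample(t)) == [2.0, 2.0, 0.0, 2.0]

    def test_tone_burst_is_gated_sine(self):
        s = SourcePulse(amplitude=1.0, period=10e-6, width=2e-6, shape="tone_burst", frequency=1.1e6)
        t = np.arange(0, 10e-6, 1e-8)
        v = s.sample(t)
        assert np.max(np.abs(v)) <= 1.0
        assert np.all(v[(t % 10e-6) >= 2e-6] == 0.0)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            SourcePulse(amplitude=1.0, period=1e-6, width=2e-6)


class TestOracleEquivalence:
    def test_single_matched_segment_single_arrival(self, unit_source):
        model = chain_model([2.0], [5e-7])
        trace = analytic_cascade_response(model.segments, unit_source, 3e-6, DT)
        sim = simulate(model, unit_source, SimConfig(duration=3e-6, time_step=DT))["T1:B+"]
        assert np.max(np.abs(trace.voltages - sim.voltages)) < 1e-12

    def test_mismatched_end_produces_echo_arrivals(self, unit_source):
        # unmatched termination: first two arrivals at t1+t2 and t1+3*t2
        segs = chain_model([1.0, 2.0], [4e-7, 3e-7]).segments
        trace = analytic_cascade_response(segs, unit_source, 4e-6, DT, end_load=8.0)
        t12 = (4e-7 + 3e-7, 4e-7 + 3 * 3e-7)
        i1, i2 = (round(t / DT) for t in t12)
        gamma_if = (2.0 - 1.0) / 3.0
        gamma_end = (8.0 - 2.0) / 10.0
        first = (1 + gamma_if) * (1 + gamma_end)
        second = (1 + gamma_if) * gamma_end * (-gamma_if) * (1 + gamma_end)
        assert trace.voltages[i1] == pytest.approx(first, rel=1e-12)
        assert trace.voltages[i2] == pytest.approx(first + second, rel=1e-12)

    def test_random_cascades_match_engine(self, unit_source):
        """simulate() and the multipath summation agree on random short chains."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(60):
            n = int(rng.integers(1, 5))
            z = rng.uniform(0.3, 5.0, n)
            delays = rng.integers(20, 80, n) * DT
            model = chain_model(list(z), list(delays))
            sim = simulate(model, unit_source, SimConfig(duration=6e-6, time_step=DT))
            oracle = analytic_cascade_response(model.segments, unit_source, 6e-6, DT)
            dev = np.max(np.abs(sim[f"T{n}:B+"].voltages - oracle.voltages))
            worst = max(worst, dev)
        assert worst < 1e-9 * unit_source.amplitude

    def test_branch_free_guard(self, unit_source):
        with pytest.raises(ValueError):
            analytic_cascade_response([], unit_source, 1e-6, DT)
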