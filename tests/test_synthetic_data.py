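"""Trace synthesis round-trips, the rule-based grid response, fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famscape.activity_classifier import summarize_cell
from famscape.burst_metrics import characteristics, detect_spikes, segment_bursts
from famscape.gridspace import GridSpec, ParameterPoint, VARIED_FRACTIONS
from famscape.synthetic_data import (
    BurstSpec,
    ResponseModel,
    grid_response,
    load_fixtures,
    make_synthetic_db,
    synthesize_trace_pair,
)

CANONICAL = ParameterPoint(1, 1, 1, 1, 1, 1, 1, -60.0)


def recover(pair):
    window = (float(pair.t[0]), float(pair.t[-1]))
    trains = []
    for cell in "AB":
        times, amps = detect_spikes(pair.t, pair.voltage(cell))
        trains.append(segment_bursts(times, amps, window=window))
    return characteristics(*trains)


class TestTraceSynthesis:
    def test_parameter_recovery_canonical_spec(self):
        pair = synthesize_trace_pair(BurstSpec(period=10.0, duty=60.0,
                                               spike_freq=15.0, phase=0.5))
        ch_A, ch_B = recover(pair)
        assert ch_A.period_s == pytest.approx(10.0, abs=0.01)
        assert ch_A.duty_pct == pytest.approx(60.0, abs=1.0)
        assert ch_A.spike_freq_hz == pytest.approx(15.0, abs=0.5)
        assert ch_B.phase == pytest.approx(0.5, abs=0.01)

    def test_subthreshold_peak_yields_no_spikes(self):
        pair = synthesize_trace_pair(BurstSpec(spike_peak=-30.0))
        times, _ = detect_spikes(pair.t, pair.v_A)
        assert len(times) == 0

    def test_zero_spike_frequency_is_silent(self):
        pair = synthesize_trace_pair(BurstSpec(spike_freq=0.0))
        times, _ = detect_spikes(pair.t, pair.v_A)
        assert len(times) == 0

    def test_too_short_burst_window_rejected(self):
        with pytest.raises(ValueError, match="three spike widths"):
            synthesize_trace_pair(BurstSpec(period=0.1, duty=10.0))

    def test_deterministic_given_seed(self):
        spec = BurstSpec(noise_sd=1.0, seed=42)
        a = synthesize_trace_pair(spec)
        b = synthesize_trace_pair(spec)
        assert np.array_equal(a.v_A, b.v_A) and np.array_equal(a.v_B, b.v_B)

    @settings(max_examples=25)
    @given(
        period=st.floats(5.0, 15.0),
        duty=st.floats(45.0, 75.0),
        freq=st.floats(8.0, 25.0),
        phase=st.floats(0.25, 0.75),
    )
    def test_recovery_property(self, period, duty, freq, phase):
        """Noise-free synthesis then metrics recovers the generating values."""
        pair = synthesize_trace_pair(
            BurstSpec(period=period, duty=duty, spike_freq=freq, phase=phase)
        )
        ch_A, ch_B = recover(pair)
        assert ch_A.period_s == pytest.approx(period, abs=2 * 1e-3)
        assert ch_A.duty_pct == pytest.approx(duty, abs=1.0)
        assert ch_A.spike_freq_hz == pytest.approx(freq, abs=0.5)
        assert ch_B.phase == pytest.approx(phase, abs=0.01)


class TestGridResponse:
    def test_canonical_point_is_rhco(self):
        rec = grid_response(CANONICAL)
        assert rec.label == "rHCO"
        assert rec.period_s == pytest.approx(10.0)
        assert rec.spike_freq_hz == pytest.approx(15.0)
        assert rec.duty_pct == pytest.approx(60.0)

    def test_no_persistent_current_is_silent(self):
        assert grid_response(CANONICAL.replace(x_P=0.0)).label == "silent"

    def test_period_strictly_decreasing_in_h(self):
        periods = [grid_response(CANONICAL.replace(x_h=v)).period_s
                   for v in GridSpec().x_h]
        assert all(b < a for a, b in zip(periods, periods[1:]))

    def test_monotone_signs_on_bursting_branch(self):
        """Each parameter moves period/frequency in its documented direction."""
        model = ResponseModel()
        for param, sign in [("x_CaS", 1), ("x_P", 1), ("x_SynS", 1),
                            ("x_h", -1), ("x_K2", -1), ("x_Leak", -1)]:
            lo = model.period(CANONICAL.replace(**{param: 0.75}))
            hi = model.period(CANONICAL.replace(**{param: 1.5}))
            assert np.sign(hi - lo) == sign, param
        for param, sign in [("x_CaS", 1), ("x_P", 1), ("x_h", 1),
                            ("x_K2", -1), ("x_Leak", -1), ("x_SynS", -1)]:
            lo = model.freq(CANONICAL.replace(**{param: 0.75}))
            hi = model.freq(CANONICAL.replace(**{param: 1.5}))
            assert np.sign(hi - lo) == sign, param

    def test_labels_match_independent_rule_oracle(self, toy_spec, toy_db):
        """Label counts equal a from-scratch evaluation of the rule set."""

        def oracle(p):
            if p.x_P < 0.25:
                return "silent"
            if p.x_SynS == 0 and p.x_SynG == 0:
                if p.x_CaS >= 0.5 and p.x_h >= 0.25:
                    return "burster-class"
                return "spiking"
            if p.x_K2 == 0:
                return "plateau"
            if p.x_SynS < 0.5 and p.x_SynG < 0.5:
                return "spiking"
            if p.x_CaS < 0.75:
                return "asymmetric"
            return "hco-class"

        for rec in toy_db:
            got = rec.label
            want = oracle(rec.point)
            if want == "hco-class":
                assert got in {"rHCO", "fHCO"}
            elif want == "burster-class":
                assert got in {"burster", "realistic_burster"}
            else:
                assert got == want

    def test_synthetic_db_deterministic(self, toy_spec):
        a = make_synthetic_db(toy_spec, seed=7)
        b = make_synthetic_db(toy_spec, seed=7)
        assert a == b


class TestFixtures:
    def test_table1_h_row_examples(self, fixtures):
        assert fixtures.table1_counts("h", 8) == (144, 144)
        assert fixtures.table1_counts("h", 2) == (9895, 5545)

    def test_table2_example(self, fixtures):
        assert fixtures.table2_count(7, "duty cycle") == 393

    def test_table3_example(self, fixtures):
        assert fixtures.table3_counts(8) == (35, 57, 52)

    def test_size_weighted_sums_identical_across_parameters(self, fixtures):
        sizes = {fixtures.group_size(p)
                 for p in ("P", "K2", "Leak", "CaS", "SynS", "h", "SynG")}
        assert sizes == {99_066}

    def test_noninterrupted_never_exceeds_total(self, fixtures):
        t1 = fixtures.table1.dropna()
        assert (t1["noninterrupted"] <= t1["total"]).all()

    def test_checksum_guard(self, monkeypatch, tmp_path):
        import famscape.synthetic_data as sd

        real = sd._read_packaged

        def corrupt(name):
            digest, df = real(name)
            return "0" * 64, df

        monkeypatch.setattr(sd, "_read_packaged", corrupt)
        with pytest.raises(ValueError, match="checksum"):
            load_fixtures()
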