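"""Trace arithmetic, window statistics, per-cell percentage summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from knotopt import ephys as E
from knotopt import synth
from knotopt.synth import TraceComponent


def _flat_trace(value, n=10000, rate=50_000.0, onset=0.15, cap=10.0):
    return E.CurrentTrace(
        samples=np.full(n, float(value)), sample_rate=rate, step_onset=onset,
        capacitance=cap,
    )


class TestZeroSubtract:
    def test_constant_offset_removed(self):
        out = E.zero_subtract(_flat_trace(5.0))
        assert np.allclose(out.samples, 0.0)

    def test_zero_trace_unchanged(self):
        out = E.zero_subtract(_flat_trace(0.0))
        assert np.array_equal(out.samples, np.zeros_like(out.samples))

    def test_offset_plus_signal_recovers_signal_exactly(self):
        comp = TraceComponent(-800.0, 2e-4, 5e-3)
        total, _ = synth.gen_traces([comp], baseline_offset=12.5, noise_sd=0.0)
        out = E.zero_subtract(total)
        expected = comp.evaluate(total.times - total.step_onset)
        assert np.allclose(out.samples, expected, atol=1e-9)

    def test_window_not_fitting_rejected(self):
        t = _flat_trace(1.0, onset=0.05)
        with pytest.raises(ValueError, match="does not fit"):
            E.zero_subtract(t, baseline_window=0.14)


class TestWindowStatistics:
    def test_constant_current_density(self):
        assert E.window_mean_density(_flat_trace(-480.0)) == pytest.approx(-48.0)
        assert E.window_mean_density(_flat_trace(0.0)) == 0.0

    def test_matches_analytic_average_at_50khz(self):
        # gentle kinetics: fast activation, slow inactivation
        comp = TraceComponent(-1000.0, 1e-4, 2e-2)
        total, _ = synth.gen_traces([comp], noise_sd=0.0, capacitance=10.0)
        numeric = E.window_mean_density(E.zero_subtract(total))
        analytic = comp.window_average(0.4e-3, 1.0e-3) / 10.0
        assert numeric == pytest.approx(analytic, rel=1e-3)

    def test_discretization_error_shrinks_with_sample_rate(self):
        comp = TraceComponent(-1000.0, 3e-4, 2e-3)
        errors = []
        for rate in (25_000.0, 100_000.0, 400_000.0):
            total, _ = synth.gen_traces(
                [comp], sample_rate=rate, noise_sd=0.0, capacitance=10.0
            )
            numeric = E.window_mean_density(E.zero_subtract(total))
            analytic = comp.window_average(0.4e-3, 1.0e-3) / 10.0
            errors.append(abs(numeric - analytic))
        assert errors[0] > errors[1] > errors[2]

    def test_missing_capacitance_rejected(self):
        t = _flat_trace(-100.0)
        t.capacitance = None
        with pytest.raises(ValueError, match="capacitance"):
            E.window_mean_density(t)


class TestPeak:
    def test_triangular_pulse_peak_time(self):
        rate, onset = 50_000.0, 0.15
        n = int(0.17 * rate)
        t = np.arange(n) / rate - onset
        samples = np.zeros(n)
        apex = 1.2e-3
        rising = (t >= 0) & (t <= apex)
        falling = (t > apex) & (t <= 2 * apex)
        samples[rising] = -1000.0 * (t[rising] / apex)
        samples[falling] = -1000.0 * (2 - t[falling] / apex)
        trace = E.CurrentTrace(samples, rate, onset, capacitance=10.0)
        density, peak_ms = E.peak_density_and_time(trace)
        assert peak_ms == pytest.approx(1.2, abs=0.05)
        assert density == pytest.approx(-100.0, rel=1e-3)

    def test_monotonic_decay_peaks_at_first_window_sample(self):
        rate, onset = 50_000.0, 0.15
        n = int(0.17 * rate)
        t = np.arange(n) / rate - onset
        samples = np.where(t >= 0, -1000.0 * np.exp(-t / 1e-3), 0.0)
        trace = E.CurrentTrace(samples, rate, onset, capacitance=10.0)
        _, peak_ms = E.peak_density_and_time(trace)
        assert peak_ms == pytest.approx(0.4, abs=0.021)

    def test_fast_component_peaks_before_slow(self):
        fast = TraceComponent(-1500.0, 1e-4, 1e-3)
        slow = TraceComponent(-1500.0, 1e-4, 2e-2)
        t_fast = E.peak_density_and_time(
            E.zero_subtract(synth.gen_traces([fast], capacitance=10.0)[0])
        )[1]
        t_slow = E.peak_density_and_time(
            E.zero_subtract(synth.gen_traces([slow], capacitance=10.0)[0])
        )[1]
        assert t_fast < t_slow


class TestSubtractTraces:
    def test_total_minus_slow_recovers_fast_exactly(self):
        fast = TraceComponent(-1500.0, 1e-4, 1e-3)
        slow = TraceComponent(-600.0, 1e-4, 2e-2)
        total, slow_only = synth.gen_traces([fast, slow], baseline_offset=3.0, noise_sd=0.0)
        sens = E.subtract_traces(E.zero_subtract(total), E.zero_subtract(slow_only))
        expected = fast.evaluate(total.times - total.step_onset)
        assert np.allclose(sens.samples, expected, atol=1e-9)

    def test_conservation_is_exact(self):
        total, slow_only = synth.gen_traces(
            [TraceComponent(-900.0, 2e-4, 1.5e-3), TraceComponent(-400.0, 2e-4, 3e-2)],
            noise_sd=0.5, seed=4,
        )
        zt, zs = E.zero_subtract(total), E.zero_subtract(slow_only)
        sens = E.subtract_traces(zt, zs)
        # conservation: (pre - post) + post returns pre (to float roundoff)
        assert np.allclose(sens.samples + zs.samples, zt.samples, atol=1e-9)
        # and the subtraction itself is the exact samplewise difference
        assert np.array_equal(sens.samples, zt.samples - zs.samples)

    def test_identical_traces_give_zero(self):
        t = _flat_trace(-100.0)
        assert np.array_equal(E.subtract_traces(t, t).samples, np.zeros(len(t.samples)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            E.subtract_traces(
                _flat_trace(0.0, n=100, onset=0.0), _flat_trace(0.0, n=101, onset=0.0)
            )


class TestPercentMetrics:
    @pytest.mark.parametrize(
        "drug,baseline,expected",
        [(47, 120, 39.2), (120, 120, 100.0), (0, 120, 0.0), (1, 32, 3.1), (119, 120, 99.2)],
    )
    def test_remaining_ap(self, drug, baseline, expected):
        assert E.remaining_ap_percent(drug, baseline) == expected

    def test_remaining_ap_zero_baseline_flagged_nan(self):
        assert math.isnan(E.remaining_ap_percent(5, 0))

    @pytest.mark.parametrize(
        "drug,baseline,expected",
        [(640, 500, 28.0), (600, 300, 100.0), (500, 500, 0.0), (280, 300, -6.7)],
    )
    def test_rheobase_change(self, drug, baseline, expected):
        assert E.rheobase_change_percent(drug, baseline) == expected

    def test_rheobase_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            E.rheobase_change_percent(100.0, 0.0)

    def test_rounding_half_away_from_zero(self):
        assert E.round_half_away(1.25, 1) == 1.3
        assert E.round_half_away(-1.25, 1) == -1.3
        assert E.round_half_away(1.24, 1) == 1.2


class TestSummarizeCells:
    def test_printed_rheobase_averages(self, cell_table_text):
        table = E.load_cell_table(cell_table_text)
        out = E.summarize_cells(table, "rheobase_change").set_index("dose")
        assert out.loc["1", "mean"] == 49.1
        assert out.loc["1", "sem"] == 10.3
        assert out.loc["0.01", "mean"] == 4.9
        assert out.loc["0.1", "sem"] == 5.1

    def test_printed_remaining_ap_average(self, cell_table_text):
        table = E.load_cell_table(cell_table_text)
        out = E.summarize_cells(table, "remaining_ap").set_index(["dose", "frequency_Hz"])
        assert out.loc[("0.1", 1.0), "mean"] == 84.8
        assert out.loc[("1", 10.0), "mean"] == 17.8
        assert out.loc[("1", 0.1), "sem"] == 16.7

    def test_identical_values_zero_sem(self):
        rows = []
        for i in range(10):
            rows.append((f"c{i}", "baseline", 100, 10, 120, 120, 120))
            rows.append((f"c{i}", "1", 150, 10, 120, 120, 120))
        df = pd.DataFrame(
            rows,
            columns=["cell_id", "dose", "rheobase_pA", "aps_0.1Hz", "aps_1Hz", "aps_3Hz", "aps_10Hz"],
        )
        out = E.summarize_cells(df, "rheobase_change").set_index("dose")
        assert out.loc["1", "mean"] == 50.0
        assert out.loc["1", "sem"] == 0.0

    def test_single_cell_sem_undefined(self):
        df = pd.DataFrame(
            [
                ("c1", "baseline", 100, 10, 120, 120, 120),
                ("c1", "1", 150, 10, 120, 120, 120),
            ],
            columns=["cell_id", "dose", "rheobase_pA", "aps_0.1Hz", "aps_1Hz", "aps_3Hz", "aps_10Hz"],
        )
        out = E.summarize_cells(df, "rheobase_change").set_index("dose")
        assert out.loc["1", "mean"] == 50.0
        assert math.isnan(out.loc["1", "sem"])

    def test_exclusion_flag_drops_cells(self, cell_table_text):
        df = pd.read_csv(pd.io.common.StringIO(cell_table_text))
        df["include"] = df["cell_id"] != "Cell 1"
        table = E.load_cell_table(df.to_csv(index=False))
        assert "Cell 1" not in set(table["cell_id"])

    def test_baseline_remaining_ap_always_100(self, cell_table_text):
        table = E.load_cell_table(cell_table_text)
        m = E.cell_metrics(table)
        base = m[(m.dose == "baseline") & (m.metric == "remaining_ap")]
        assert (base.value == 100.0).all()
        assert (m[m.metric == "remaining_ap"].value.dropna() >= 0).all()

    def test_ttest_reports_statistic_df_p(self):
        t, df, p = E.two_group_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert df == 4
        assert p == pytest.approx(0.2878641347266908, rel=1e-6)
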