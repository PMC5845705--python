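import numpy as np
import pandas as pd
import pytest

from neurosync import synth, traces
from neurosync._filters import minmax_scale
from neurosync.protocol import Epoch, PharmacologyProtocol, qc_protocol
from tests.conftest import prominence_oracle


def _qc_prot():
    return qc_protocol()  # baseline 0-540 s, K+ 560-620 s


def _frame(*cols):
    return pd.DataFrame({i: c for i, c in enumerate(cols)})


class TestQcFilter:
    n = 1280  # 640 s at 2 Hz

    def _t(self):
        return np.arange(self.n) * 0.5

    def _quiet_with_kplus(self, step=0.3):
        t = self._t()
        x = np.full(self.n, 0.2)
        x[(t >= 560) & (t < 620)] += step
        return x

    def test_flat_trace_removed_as_inactive(self):
        kept, log = traces.qc_filter(_frame(np.zeros(self.n)), _qc_prot())
        assert kept.shape[1] == 0
        assert list(log.reason) == ["inactive"]

    def test_slow_sine_removed_as_noisy(self):
        # amplitude 0.2 at 0.01 Hz is squarely in the QC band; its filtered
        # sd is ~amplitude/sqrt(2) = 0.14 >> 0.05
        x = 0.5 + 0.2 * np.sin(2 * np.pi * 0.01 * self._t())
        kept, log = traces.qc_filter(_frame(x), _qc_prot())
        assert list(log.reason) == ["noisy"]

    def test_kplus_responder_kept(self):
        kept, log = traces.qc_filter(_frame(self._quiet_with_kplus()), _qc_prot())
        assert kept.shape[1] == 1 and log.empty

    def test_weak_kplus_response_removed(self):
        kept, log = traces.qc_filter(_frame(self._quiet_with_kplus(step=0.05)), _qc_prot())
        assert list(log.reason) == ["inactive"]

    def test_missing_kplus_epoch_warns_and_skips(self):
        prot = PharmacologyProtocol([Epoch("baseline", None, "", 0, 640)])
        with pytest.warns(UserWarning, match="K\\+"):
            kept, log = traces.qc_filter(_frame(np.zeros(self.n)), prot)
        assert kept.shape[1] == 1  # the viability filter was skipped

    def test_mixed_population(self):
        good = self._quiet_with_kplus()
        noisy = good + 0.2 * np.sin(2 * np.pi * 0.005 * self._t())
        kept, log = traces.qc_filter(_frame(good, noisy, np.zeros(self.n)), _qc_prot())
        assert kept.shape[1] == 1
        assert sorted(log.reason) == ["inactive", "noisy"]


class TestFindPeaks:
    def test_monotone_trace_has_no_peaks(self):
        assert traces.find_peaks(np.linspace(0, 1, 100), 0.01) == []

    def test_triangular_bump_prominence(self):
        x = np.zeros(100)
        x[40:51] = np.linspace(0, 0.3, 11)
        x[50:61] = np.linspace(0.3, 0, 11)
        peaks = traces.find_peaks(x, 0.025, dt=1.0)
        assert len(peaks) == 1
        assert peaks[0].prominence == pytest.approx(0.3)
        assert peaks[0].time_s == 50.0
        # full width at half prominence of a symmetric triangle = half base
        assert peaks[0].width_s == pytest.approx(10.0, abs=0.5)

    def test_two_bumps_threshold_selects(self):
        x = np.zeros(200)
        x[40:51] = np.linspace(0, 0.3, 11)
        x[50:61] = np.linspace(0.3, 0, 11)
        x[140:146] = np.linspace(0, 0.04, 6)
        x[145:151] = np.linspace(0.04, 0, 6)
        assert len(traces.find_peaks(x, 0.025)) == 2
        assert len(traces.find_peaks(x, 0.05)) == 1

    def test_agrees_with_quadratic_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=300).cumsum() / 10 + rng.normal(size=300) * 0.3
            expected = [(i, p) for i, p in prominence_oracle(x) if p >= 0.2]
            got = traces.find_peaks(x, 0.2, dt=1.0)
            assert [int(p.time_s) for p in got] == [i for i, _ in expected]
            np.testing.assert_allclose([p.prominence for p in got], [p for _, p in expected], rtol=1e-12)

    def test_count_non_increasing_in_prominence(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500).cumsum() / 5
        counts = [len(traces.find_peaks(x, p)) for p in [0.05, 0.1, 0.2, 0.5, 1.0, 2.0]]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_prominence_bounded_by_height_range(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=400).cumsum() / 8
        for p in traces.find_peaks(x, 0.1, dt=1.0):
            assert p.prominence <= p.height - x.min() + 1e-12
            assert p.width_s > 0

    def test_non_finite_trace_rejected(self):
        with pytest.raises(ValueError):
            traces.find_peaks(np.array([0.0, np.nan, 1.0]), 0.1)


class TestNetworkTrace:
    def test_identical_traces_collapse_to_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=600).cumsum() / 20
        single = traces.network_trace(_frame(x))
        many = traces.network_trace(_frame(*[x] * 10))
        np.testing.assert_allclose(single, many, atol=1e-12)

    def test_maximum_is_one(self):
        rng = np.random.default_rng(4)
        net = traces.network_trace(_frame(*[rng.normal(size=400) for _ in range(5)]))
        assert net.max() == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            traces.network_trace(pd.DataFrame())

    def test_synchrony_amplifies_network_peaks(self):
        # 50 synchronous vs 50 asynchronous cells: synchronous transients
        # reinforce in the sum (peak ~ N) while asynchronous ones average
        # out (~ sqrt(N)), so on the un-normalized network sum the top peak
        # prominence of the synchronous recording is far larger
        def top_prominence(mode, seed):
            sched = synth.generate_event_schedule(
                mode, 600.0, n_cells=50, seed=seed, **synth.default_schedule_params(mode)
            )
            gt = synth.make_ground_truth(sched, seed=seed + 1)
            tr = minmax_scale(synth.render_cell_traces(gt, None), axis=1)
            net = traces.network_trace(pd.DataFrame(tr.T), normalize=False)
            peaks = traces.find_peaks(net, 0.025)
            return max(p.prominence for p in peaks)

        for seed in range(3):
            assert top_prominence("synchronous", seed) > 2 * top_prominence("asynchronous", seed + 50)


def _peak(t, prom=0.1, height=None):
    return traces.ActivityPeak(time_s=t, height=height or prom, prominence=prom, width_s=5.0)


class TestEpochMetrics:
    prot = PharmacologyProtocol(
        [
            Epoch("baseline", None, "", 0, 300),
            Epoch("GABA", 100.0, "uM", 300, 600),
            Epoch("CBX", 25.0, "uM", 700, 1000),
        ]
    )

    def test_interval_median(self):
        peaks = [_peak(300.0), _peak(330.0), _peak(360.0)]
        m = traces.epoch_metrics(None, peaks, self.prot, "GABA")
        assert list(m.intervals_s) == [30.0, 30.0]
        assert m.median_interval_s == 30.0

    def test_change_and_relative_change(self):
        peaks = [_peak(100.0, 0.2), _peak(200.0, 0.2), _peak(400.0, 0.1), _peak(500.0, 0.1)]
        m = traces.epoch_metrics(None, peaks, self.prot, "GABA")
        assert m.prominence_change == pytest.approx(-0.1)
        assert m.prominence_relative_change == pytest.approx(-0.5)

    def test_empty_epoch_flagged_with_nan(self):
        peaks = [_peak(100.0, 0.2), _peak(180.0, 0.2)]
        m = traces.epoch_metrics(None, peaks, self.prot, "GABA")
        assert np.isnan(m.median_prominence) and np.isnan(m.prominence_change)
        assert np.isnan(m.prominence_relative_change)  # never infinity

    def test_cbx_uses_final_window_only(self):
        early = [_peak(720.0, 0.3), _peak(750.0, 0.3)]
        late = [_peak(850.0, 0.1), _peak(900.0, 0.1), _peak(950.0, 0.1)]
        m = traces.epoch_metrics(None, early + late, self.prot, "CBX")
        assert len(m.peaks) == 3  # only the last 3 min (820-1000 s)
        assert m.median_prominence == pytest.approx(0.1)


class TestGabaResponse:
    prot = PharmacologyProtocol(
        [Epoch("baseline", None, "", 0, 180), Epoch("GABA", 100.0, "uM", 180, 360)]
    )

    def test_identical_epochs_give_zero(self):
        x = np.full(720, 0.4)
        assert traces.gaba_excitatory_response(x, self.prot) == pytest.approx(0.0, abs=1e-9)

    def test_sustained_step_integrates_to_expected_sum(self):
        # +0.2 step confined to the 180-s GABA epoch: the low-passed step
        # sums to ~0.2 * 360 samples = 72, minus symmetric edge leakage
        t = np.arange(720) * 0.5
        x = np.where((t >= 180) & (t < 360), 0.2, 0.0)
        params = traces.TraceParams(gaba_reference_duration_s=None)  # raw sums
        resp = traces.gaba_excitatory_response(x, self.prot, params)
        assert resp == pytest.approx(72.0, rel=0.10)

    def test_inhibition_is_negative(self):
        t = np.arange(720) * 0.5
        x = np.where((t >= 180) & (t < 360), 0.0, 0.1)
        assert traces.gaba_excitatory_response(x, self.prot) < 0

    def test_duration_normalization_equalizes_unequal_epochs(self):
        prot = PharmacologyProtocol(
            [Epoch("baseline", None, "", 0, 360), Epoch("GABA", 100.0, "uM", 360, 540)]
        )
        x = np.full(1080, 0.3)  # same level throughout
        normalized = traces.gaba_excitatory_response(x, prot)
        raw = traces.gaba_excitatory_response(x, prot, traces.TraceParams(gaba_reference_duration_s=None))
        assert normalized == pytest.approx(0.0, abs=1e-9)
        assert raw < 0  # raw sums penalize the shorter epoch

    def test_missing_epoch_rejected(self):
        with pytest.raises(Exception):
            traces.gaba_excitatory_response(np.zeros(720), qc_protocol())


class TestResponseHistograms:
    def test_single_value_single_bin(self):
        h = traces.response_histograms([0.42], 0.05)
        assert len(h) == 1
        assert h.percent.iloc[0] == 100.0

    def test_cumulative_ends_at_100(self):
        rng = np.random.default_rng(5)
        h = traces.response_histograms(rng.normal(size=500), 0.1)
        assert h.cumulative_percent.iloc[-1] == pytest.approx(100.0)
        assert (np.diff(h.cumulative_percent) >= -1e-12).all()

    def test_reverse_cumulative_starts_at_100(self):
        rng = np.random.default_rng(6)
        h = traces.response_histograms(rng.normal(size=500), 0.1, direction="reverse")
        assert h.cumulative_percent.iloc[0] == pytest.approx(100.0)
        assert (np.diff(h.cumulative_percent) <= 1e-12).all()

    def test_uniform_values_spread_evenly(self):
        rng = np.random.default_rng(7)
        h = traces.response_histograms(rng.uniform(0, 1, 10_000), 0.05)
        inner = h.percent.iloc[1:-1]  # edge bins depend on sample extremes
        assert np.all(np.abs(inner - 5.0) < 1.0)

    def test_empty_values_empty_histogram(self):
        assert traces.response_histograms([], 0.1).empty

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            traces.response_histograms([1.0], 0.0)
        with pytest.raises(ValueError):
            traces.response_histograms([1.0], 0.1, direction="sideways")
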