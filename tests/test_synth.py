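import numpy as np
import pytest
from scipy import stats

from neurosync import mea, synth
from neurosync.protocol import qc_protocol


class TestEventSchedule:
    def test_zero_rates_give_empty_schedule(self):
        s = synth.generate_event_schedule(
            "loosely_synchronous", 600.0, network_rate_hz=0.0, per_cell_rate_hz=0.0, n_cells=5, seed=0
        )
        assert len(s.network_events) == 0
        assert all(len(v) == 0 for v in s.per_cell_events.values())

    def test_unknown_mode_rejected(self):
        with pytest.raises(synth.UnknownModeError):
            synth.generate_event_schedule("chaotic", 600.0, seed=0)

    def test_event_count_matches_rate(self):
        # 600 s at 0.03 Hz: expectation 18; every seed's count must fall in
        # the Poisson 99% interval for that expectation
        lo, hi = stats.poisson.interval(0.99, 0.03 * 600)
        counts = [
            len(synth.generate_event_schedule("synchronous", 600.0, seed=seed).network_events)
            for seed in range(200)
        ]
        assert lo <= min(counts) and max(counts) <= hi
        assert abs(np.mean(counts) - 18) < 2

    def test_all_times_inside_recording(self):
        s = synth.generate_event_schedule("loosely_synchronous", 300.0, n_cells=20, seed=3)
        for ev in s.per_cell_events.values():
            assert np.all((ev >= 0) & (ev < 300.0))

    def test_synchronous_cells_are_jittered_event_copies(self):
        jitter = 0.5
        s = synth.generate_event_schedule("synchronous", 600.0, jitter_s=jitter, n_cells=10, seed=4)
        for ev in s.per_cell_events.values():
            if not len(ev):
                continue
            dist = np.abs(ev[:, None] - s.network_events[None, :]).min(axis=1)
            assert dist.max() <= jitter + 1e-9

    def test_asynchronous_cells_uncorrelated(self):
        # mean pairwise lag-0 correlation of binned event trains must be
        # indistinguishable from a circular-shift surrogate
        rng = np.random.default_rng(0)
        s = synth.generate_event_schedule("asynchronous", 600.0, per_cell_rate_hz=0.05, n_cells=30, seed=5)
        bins = np.arange(0, 601)
        trains = np.stack([np.histogram(ev, bins=bins)[0] for ev in s.per_cell_events.values()]).astype(float)

        def mean_pairwise_corr(tr):
            c = np.corrcoef(tr)
            return c[np.triu_indices_from(c, k=1)].mean()

        observed = mean_pairwise_corr(trains)
        null = []
        for _ in range(200):
            shifts = rng.integers(0, trains.shape[1], size=len(trains))
            null.append(mean_pairwise_corr(np.stack([np.roll(t, k) for t, k in zip(trains, shifts)])))
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo <= observed <= hi

    def test_deterministic_under_seed(self):
        a = synth.generate_event_schedule("loosely_synchronous", 400.0, n_cells=8, seed=42)
        b = synth.generate_event_schedule("loosely_synchronous", 400.0, n_cells=8, seed=42)
        assert np.array_equal(a.network_events, b.network_events)
        for k in a.per_cell_events:
            assert np.array_equal(a.per_cell_events[k], b.per_cell_events[k])


class TestResponseClasses:
    def test_degenerate_proportions(self):
        classes = synth.assign_response_classes(20, (1, 0, 0, 0), seed=0)
        assert all(rc.label == "strongly_depolarized" for rc in classes)

    def test_proportions_converge(self):
        p = (0.1, 0.2, 0.4, 0.3)
        classes = synth.assign_response_classes(10_000, p, seed=1)
        labels = [rc.label for rc in classes]
        for target, name in zip(p, synth.CLASS_ORDER):
            assert abs(labels.count(name) / 10_000 - target) < 0.02

    def test_negative_proportions_rejected(self):
        with pytest.raises(ValueError):
            synth.assign_response_classes(10, (-0.1, 0.5, 0.3, 0.3), seed=0)

    def test_same_seed_same_assignment(self):
        a = synth.assign_response_classes(100, seed=7)
        b = synth.assign_response_classes(100, seed=7)
        assert [x.label for x in a] == [y.label for y in b]

    def test_class_amplitude_ordering(self):
        rc = synth.RESPONSE_CLASSES
        assert rc["strongly_depolarized"].baseline_shift > rc["weakly_depolarized"].baseline_shift > 0
        assert rc["inhibited"].baseline_shift < 0


def _single_cell_truth(events, duration=300.0, seed=0):
    schedule = synth.EventSchedule(
        mode="synchronous",
        duration_s=duration,
        network_events=np.asarray(events, dtype=float),
        per_cell_events={0: np.asarray(events, dtype=float)},
    )
    gt = synth.make_ground_truth(schedule, width_px=64, height_px=64, seed=seed)
    gt.centroids = np.array([[32.0, 32.0]])
    gt.event_amplitudes = {0: np.full(len(events), 0.12)}
    return gt


class TestCalciumRendering:
    def test_zero_cells_pure_noise(self):
        schedule = synth.EventSchedule("asynchronous", 100.0, np.empty(0), {})
        gt = synth.make_ground_truth(schedule, width_px=64, height_px=64, seed=0)
        movie = synth.render_calcium_movie(gt, 64, 64, noise_sd=0.01, baseline_intensity=0.2, seed=1)
        assert abs(float(movie.data.mean()) - 0.2) < 1e-3
        assert abs(float(movie.data.std()) - 0.01) < 1e-3

    def test_one_cell_no_events_constant_trace(self):
        gt = _single_cell_truth([])
        movie = synth.render_calcium_movie(gt, 64, 64, noise_sd=0.0, seed=0)
        pixel = movie.data[:, 32, 32]
        assert np.ptp(pixel) == 0

    def test_transient_peaks_within_rise_time(self):
        gt = _single_cell_truth([100.0])
        movie = synth.render_calcium_movie(gt, 64, 64, noise_sd=0.0, seed=0)
        peak_t = np.argmax(movie.data[:, 32, 32]) * movie.frame_interval_s
        assert 100.0 <= peak_t <= 100.0 + gt.rise_time_s + movie.frame_interval_s

    def test_cells_outside_frame_rejected(self):
        gt = _single_cell_truth([])
        gt.centroids = np.array([[200.0, 32.0]])
        with pytest.raises(ValueError, match="outside"):
            synth.render_calcium_movie(gt, 64, 64, seed=0)

    def test_movie_bit_identical_under_seed(self):
        gt = _single_cell_truth([50.0, 120.0])
        a = synth.render_calcium_movie(gt, 64, 64, noise_sd=0.02, seed=9)
        b = synth.render_calcium_movie(gt, 64, 64, noise_sd=0.02, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_values_clipped_non_negative(self):
        gt = _single_cell_truth([50.0])
        movie = synth.render_calcium_movie(gt, 64, 64, noise_sd=0.3, seed=2)
        assert movie.data.min() >= 0
        assert movie.data.max() <= 1.5

    def test_kplus_raises_all_neurons(self):
        protocol = qc_protocol(baseline_s=100.0, washout_s=10.0, kplus_s=60.0)
        schedule = synth.EventSchedule("synchronous", 200.0, np.empty(0), {0: np.empty(0)})
        gt = synth.make_ground_truth(schedule, width_px=64, height_px=64, seed=0)
        gt.centroids = np.array([[32.0, 32.0]])
        traces = synth.render_cell_traces(gt, protocol)
        t = np.arange(traces.shape[1]) * 0.5
        in_k = (t >= 110.0) & (t < 170.0)
        assert np.all(traces[0, in_k] - traces[0, ~in_k].mean() >= gt.kplus_amplitude - 1e-9)


class TestMeaRendering:
    def test_common_mode_removed_by_median_reference(self):
        schedule = synth.generate_event_schedule("synchronous", 30.0, n_cells=1, seed=0)
        t = np.arange(int(30.0 * 10_000)) / 10_000
        cm = 100.0 * np.sin(2 * np.pi * 7 * t)
        plain, _ = synth.render_mea_recording(schedule, n_electrodes=12, seed=3)
        with_cm, _ = synth.render_mea_recording(schedule, n_electrodes=12, common_mode_waveform=cm, seed=3)
        a = mea.median_reference(plain).voltages
        b = mea.median_reference(with_cm).voltages
        assert np.allclose(a, b, atol=1e-3)

    def test_true_spikes_returned_and_in_range(self):
        schedule = synth.generate_event_schedule("synchronous", 60.0, n_cells=1, seed=1)
        rec, spikes = synth.render_mea_recording(schedule, n_electrodes=8, seed=4)
        assert rec.voltages.shape == (8, int(60.0 * 10_000))
        assert len(spikes[rec.reference_index]) == 0
        for elec, times in spikes.items():
            assert np.all((times >= 0) & (times <= 60.0))

    def test_template_longer_than_recording_rejected(self):
        schedule = synth.EventSchedule("synchronous", 0.0005, np.empty(0), {})
        with pytest.raises(ValueError, match="template"):
            synth.render_mea_recording(schedule, n_electrodes=4, seed=0)

    def test_recording_bit_identical_under_seed(self):
        schedule = synth.generate_event_schedule("synchronous", 20.0, n_cells=1, seed=2)
        a, _ = synth.render_mea_recording(schedule, n_electrodes=6, seed=5)
        b, _ = synth.render_mea_recording(schedule, n_electrodes=6, seed=5)
        assert np.array_equal(a.voltages, b.voltages)
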