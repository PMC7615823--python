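import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfpkit import (
    ChannelTrace,
    DetectionParams,
    EventInterval,
    FilterParams,
    GeneralizedSeizureParams,
    LfpRecording,
    SpikeEvent,
    ValidationError,
    bandpass,
    detect_generalized,
    detect_spikes,
    estimate_baseline,
    group_events,
    summarize_rates,
)
from lfpkit.event_detection import PROFILES

from conftest import make_sine

RATE = 500.0


def spikes_at(times, amp=-50.0):
    return [SpikeEvent(time=float(t), amplitude=amp) for t in times]


class TestBandpass:
    def test_passband_sine_preserved(self):
        ch = make_sine(6.0, 100.0, 20.0, RATE)
        out = bandpass(ch, RATE)
        mid = out.samples[2000:-2000]
        assert np.max(np.abs(mid)) == pytest.approx(100.0, rel=0.05)

    def test_stopband_sine_attenuated(self):
        ch = make_sine(120.0, 100.0, 20.0, RATE)
        out = bandpass(ch, RATE)
        assert np.max(np.abs(out.samples[2000:-2000])) < 15.0

    def test_dc_removed(self):
        ch = ChannelTrace("hippocampus_ipsi", np.full(10000, 250.0))
        out = bandpass(ch, RATE)
        assert np.max(np.abs(out.samples[2000:-2000])) < 1.0

    def test_rate_too_low_rejected(self):
        ch = make_sine(6.0, 10.0, 10.0, 100.0)
        with pytest.raises(ValueError):
            bandpass(ch, 100.0)  # 100 < 2 * 70

    def test_output_length_preserved(self):
        ch = make_sine(6.0, 10.0, 10.0, RATE)
        assert len(bandpass(ch, RATE)) == len(ch)


class TestEstimateBaseline:
    def test_forced_extrema_example(self):
        # per-second minima exactly -10, maxima exactly +4
        x = np.zeros(60 * int(RATE))
        x[:: int(RATE)] = -10.0
        x[250 :: int(RATE)] = 4.0
        base = estimate_baseline(ChannelTrace("hippocampus_ipsi", x), RATE)
        assert base.polarity == "negative"
        assert base.mode_amplitude == pytest.approx(-10.0)
        assert base.threshold == pytest.approx(-20.0)
        assert base.n_segments == 60

    def test_dense_negative_spikes_detected_as_negative(self, rng):
        # asymmetric fixture: a -200 uV transient in nearly every second
        n = 300 * int(RATE)
        x = rng.normal(0, 20.0, n)
        for s in range(5, 295):
            x[s * int(RATE) + 100] -= 200.0
        base = estimate_baseline(ChannelTrace("hippocampus_ipsi", x), RATE)
        assert base.polarity == "negative"
        assert base.threshold < -100.0

    def test_positive_polarity(self, rng):
        n = 120 * int(RATE)
        x = rng.normal(0, 10.0, n)
        for s in range(2, 118):
            x[s * int(RATE) + 37] += 150.0
        base = estimate_baseline(ChannelTrace("hippocampus_ipsi", x), RATE)
        assert base.polarity == "positive"

    def test_override_wins(self, rng):
        x = rng.normal(0, 10.0, 60 * int(RATE))
        base = estimate_baseline(
            ChannelTrace("hippocampus_ipsi", x), RATE, polarity_override="positive"
        )
        assert base.polarity == "positive"

    def test_too_short_rejected(self, rng):
        x = rng.normal(0, 10.0, 5 * int(RATE))
        with pytest.raises(ValueError):
            estimate_baseline(ChannelTrace("hippocampus_ipsi", x), RATE)


def _baseline(threshold):
    from lfpkit import BaselineEstimate

    return BaselineEstimate(
        polarity="negative" if threshold < 0 else "positive",
        mode_amplitude=threshold / 2.0,
        threshold=threshold,
        segment_length=1.0,
        n_segments=60,
        bin_width=1.0,
    )


def _trace_with_dips(times, amp=-25.0, duration=5.0):
    x = np.zeros(int(duration * RATE))
    for t in times:
        x[int(round(t * RATE))] = amp
    return ChannelTrace("hippocampus_ipsi", x)


class TestDetectSpikes:
    def test_refractory_50ms_merges(self):
        ch = _trace_with_dips([1.00, 1.05])
        out = detect_spikes(ch, RATE, _baseline(-20.0))
        assert len(out) == 1
        assert out[0].time == pytest.approx(1.00)

    def test_refractory_80ms_keeps_both(self):
        ch = _trace_with_dips([1.00, 1.08])
        out = detect_spikes(ch, RATE, _baseline(-20.0))
        assert [s.time for s in out] == pytest.approx([1.00, 1.08])

    def test_subthreshold_ignored(self):
        ch = _trace_with_dips([1.0], amp=-15.0)
        assert detect_spikes(ch, RATE, _baseline(-20.0)) == []

    def test_amplitude_recorded(self):
        ch = _trace_with_dips([2.0], amp=-33.0)
        (s,) = detect_spikes(ch, RATE, _baseline(-20.0))
        assert s.amplitude == pytest.approx(-33.0)

    def test_positive_polarity_spikes(self):
        x = np.zeros(int(5 * RATE))
        x[1000] = 30.0
        out = detect_spikes(ChannelTrace("hippocampus_ipsi", x), RATE, _baseline(25.0))
        assert len(out) == 1


def brute_force_group(times, params: DetectionParams):
    """Independent oracle: test every contiguous subsequence against the
    definitional predicates and keep maximal chains (gap rule)."""
    times = list(times)
    n = len(times)
    prof = PROFILES[params.definition_profile]
    events = []
    i = 0
    while i < n:
        # grow the maximal chain starting at i
        j = i
        while j + 1 < n and times[j + 1] - times[j] <= params.gap + 1e-12:
            j += 1
        count = j - i + 1
        if count >= params.train_min_spikes:
            duration = times[j] - times[i]
            rate = (
                (count - 1) / duration
                if params.rate_convention == "isi"
                else count / duration
            ) if duration > 0 else float("inf")
            lo, hi = params.train_duration
            if (
                duration >= prof["min_dur"]
                and rate >= prof["min_rate"]
                and (prof["max_rate"] is None or rate <= prof["max_rate"])
            ):
                events.append((times[i], times[j], prof["kind"], count))
            elif lo <= duration < hi and rate >= params.train_min_rate:
                events.append((times[i], times[j], "spike_train", count))
        i = j + 1
    return events


class TestGroupEvents:
    def test_four_spikes_make_a_train(self):
        ev = group_events(spikes_at([0.0, 0.5, 1.0, 1.5]))
        assert len(ev) == 1
        assert ev[0].kind == "spike_train"
        assert ev[0].n_spikes == 4
        assert ev[0].duration == pytest.approx(1.5)

    def test_fifteen_spikes_make_an_hpd(self):
        times = [0.75 * k for k in range(15)]  # 0.0 .. 10.5 s
        ev = group_events(spikes_at(times))
        assert len(ev) == 1
        assert ev[0].kind == "hpd"
        assert ev[0].duration == pytest.approx(10.5)
        assert ev[0].mean_rate >= 1.33

    def test_two_spikes_no_event(self):
        assert group_events(spikes_at([0.0, 0.5])) == []

    def test_sub_second_triplet_discarded(self):
        assert group_events(spikes_at([0.0, 0.3, 0.6])) == []

    def test_five_five_profile_rejects_slow_trains(self):
        # 3.5 Hz spikes for 12 s: an HPD under the paper profile, nothing
        # >=5 Hz under five_five
        times = np.arange(0, 12.0, 1 / 3.5)
        paper = group_events(spikes_at(times), DetectionParams())
        alt = group_events(
            spikes_at(times), DetectionParams(definition_profile="five_five")
        )
        assert [e.kind for e in paper] == ["hpd"]
        assert all(e.kind != "hpd" for e in alt)

    def test_sle_profile_classifies_3s_events(self):
        times = np.arange(0, 4.0, 0.5)
        ev = group_events(spikes_at(times), DetectionParams(definition_profile="sle_klein"))
        assert [e.kind for e in ev] == ["sle"]

    def test_unsorted_rejected(self):
        with pytest.raises(ValidationError):
            group_events(spikes_at([1.0, 0.5]))

    def test_gap_splits_chains(self):
        # two trains separated by a 2 s silent gap
        times = [0.0, 0.5, 1.0, 1.5, 3.5, 4.0, 4.5, 5.0]
        ev = group_events(spikes_at(times))
        assert len(ev) == 2
        assert all(e.kind == "spike_train" for e in ev)

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=120.0, allow_nan=False),
            min_size=0,
            max_size=60,
        ),
        st.sampled_from(["paper", "sle_klein", "five_five", "twele"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, raw_times, profile):
        times = sorted(set(round(t, 3) for t in raw_times))
        params = DetectionParams(definition_profile=profile)
        got = [(e.onset, e.offset, e.kind, e.n_spikes) for e in group_events(spikes_at(times), params)]
        want = brute_force_group(times, params)
        assert got == [(pytest.approx(a), pytest.approx(b), k, c) for a, b, k, c in want]

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=60.0, allow_nan=False),
            min_size=3,
            max_size=40,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_widening_gap_never_decreases_total_duration(self, raw_times):
        times = sorted(set(round(t, 3) for t in raw_times))
        narrow = group_events(spikes_at(times), DetectionParams(max_gap=0.5))
        wide = group_events(spikes_at(times), DetectionParams(max_gap=1.5))
        assert sum(e.duration for e in wide) >= sum(e.duration for e in narrow) - 1e-9


class TestThresholdMonotonicity:
    def test_raising_threshold_never_adds_spikes(self, rng):
        x = rng.normal(0, 20.0, int(60 * RATE))
        ch = ChannelTrace("hippocampus_ipsi", x)
        counts = [
            len(detect_spikes(ch, RATE, _baseline(thr)))
            for thr in (-30.0, -40.0, -50.0, -60.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestDetectGeneralized:
    def test_pure_background_clean(self, rng):
        chans = tuple(
            ChannelTrace(role, rng.normal(0, 20.0, int(300 * RATE)))
            for role in ("hippocampus_ipsi", "cortex")
        )
        rec = LfpRecording(RATE, chans)
        assert detect_generalized(rec) == []

    def test_single_channel_rejected(self, rng):
        rec = LfpRecording(
            RATE, (ChannelTrace("hippocampus_ipsi", rng.normal(0, 20, int(60 * RATE))),)
        )
        with pytest.raises(ValueError):
            detect_generalized(rec)

    def test_ipsi_only_burst_not_flagged(self, rng):
        n = int(300 * RATE)
        ipsi = rng.normal(0, 20.0, n)
        cortex = rng.normal(0, 20.0, n)
        t = np.arange(int(20 * RATE)) / RATE
        ipsi[n // 2 : n // 2 + t.size] += 400 * np.sin(2 * np.pi * 25 * t)
        rec = LfpRecording(
            RATE,
            (
                ChannelTrace("hippocampus_ipsi", ipsi),
                ChannelTrace("cortex", cortex),
            ),
        )
        assert detect_generalized(rec) == []

    def test_synthetic_generalized_seizure_found(self):
        from lfpkit import EventSchedule, sample_schedule, synthesize_recording

        sched = EventSchedule(
            spike_rate=0, train_rate=0, hpd_rate=0, generalized_rate=1.0
        )
        # retry seeds until the Poisson draw contains exactly one seizure
        for seed in range(5, 50):
            truth = sample_schedule(sched, 3600.0, seed=seed)
            if len(truth.of_kind("generalized_seizure")) == 1:
                break
        rec = synthesize_recording(truth, seed=seed)
        found = detect_generalized(rec)
        assert len(found) == 1
        t = truth.of_kind("generalized_seizure")[0].interval
        overlap = max(
            0.0, min(found[0].offset, t.offset) - max(found[0].onset, t.onset)
        )
        assert overlap / t.duration >= 0.8


class TestSummarizeRates:
    def test_hpd_arithmetic(self):
        events = [
            EventInterval(100.0 * k, 100.0 * k + dur, "hpd", 30, 3.0)
            for k, dur in enumerate([20, 20, 20, 20, 20, 22], start=1)
        ]
        s = summarize_rates(events, (0.0, 3540.0))
        assert s.n_hpds == pytest.approx(6 * 3600 / 3540)
        assert s.dur_hpds == pytest.approx(122 * 3600 / 3540)

    def test_empty(self):
        s = summarize_rates([], (0.0, 3600.0))
        assert (
            s.n_spike_trains == s.dur_spike_trains == s.n_hpds == s.dur_hpds == 0
        )
        assert s.n_generalized == 0

    def test_straddling_event_clipped(self):
        # HPD with onset inside, 4 s inside the window before it ends
        ev = [EventInterval(3596.0, 3612.0, "hpd", 40, 3.0)]
        s = summarize_rates(ev, (0.0, 3600.0))
        assert s.n_hpds == pytest.approx(1 * 3600 / 3600)
        assert s.dur_hpds == pytest.approx(4.0 * 3600 / 3600)

    def test_onset_before_window_contributes_duration_only(self):
        ev = [EventInterval(-5.0, 7.0, "hpd", 40, 3.0)]
        s = summarize_rates(ev, (0.0, 3600.0))
        assert s.n_hpds == 0
        assert s.dur_hpds == pytest.approx(7.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            summarize_rates([], (10.0, 10.0))

    def test_generalized_counted_per_window(self):
        ev = [EventInterval(100.0, 130.0, "generalized_seizure", 0, 0.0)]
        assert summarize_rates(ev, (0.0, 3600.0)).n_generalized == 1
        assert summarize_rates(ev, (200.0, 3600.0)).n_generalized == 0


class TestParams:
    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(definition_profile="bogus")

    def test_default_gap_is_reciprocal_min_rate(self):
        assert DetectionParams().gap == pytest.approx(1 / 1.33)

    def test_generalized_params_ordering(self):
        with pytest.raises(ValueError):
            GeneralizedSeizureParams(cross_channel_factor=0.5)

    def test_filter_params_ordering(self):
        with pytest.raises(ValueError):
            FilterParams(low_cut=80.0, high_cut=70.0)
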