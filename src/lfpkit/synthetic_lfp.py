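"""Seeded synthetic multi-channel LFP with known ground-truth events.

Background is 1/f^alpha Gaussian noise plus one sinusoid. Focal events
(single spikes, spike trains, HPDs) are sharp biphasic transients injected
into the ipsilateral hippocampal channel only; generalized seizures are
high-amplitude 15-40 Hz activity on all channels followed by a suppression
epoch where the background is scaled down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal_core import ChannelTrace, EventInterval, LfpRecording

__all__ = [
    "BackgroundParams",
    "EventSchedule",
    "GroundTruth",
    "TreatmentEffect",
    "SchedulingError",
    "generate_background",
    "sample_schedule",
    "synthesize_recording",
    "apply_treatment_effect",
    "sample_session_truth",
    "simulate_session",
]


class SchedulingError(RuntimeError):
    """Raised when events cannot be placed without overlap."""


@dataclass(frozen=True)
class BackgroundParams:
    noise_sd: float = 20.0
    spectral_exponent: float = 1.0
    oscillation_freq: float = 7.0
    oscillation_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.spectral_exponent <= 2:
            raise ValueError("spectral_exponent must lie in [0, 2]")


@dataclass(frozen=True)
class EventSchedule:
    """Per-kind event rates (events/hour) and event-shape parameters."""

    spike_rate: float = 60.0
    train_rate: float = 60.0
    hpd_rate: float = 10.0
    generalized_rate: float = 0.0
    intra_train_rate: tuple[float, float] = (3.0, 4.0)
    train_duration_range: tuple[float, float] = (1.5, 9.0)
    hpd_duration_range: tuple[float, float] = (10.0, 25.0)
    generalized_duration_range: tuple[float, float] = (20.0, 40.0)
    spike_amp: float = 3.0  # multiples of background SD
    polarity: str = "negative"

    def __post_init__(self) -> None:
        for r in (self.spike_rate, self.train_rate, self.hpd_rate, self.generalized_rate):
            if r < 0:
                raise ValueError("rates must be nonnegative")
        if self.hpd_duration_range[0] < 10.0:
            raise ValueError("hpd durations must be >= 10 s")
        lo, hi = self.train_duration_range
        if not (1.0 <= lo < hi <= 10.0):
            raise ValueError("train durations must lie within [1, 10) s")
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")


@dataclass(frozen=True)
class ScheduledEvent:
    """One ground-truth event with its exact spike times."""

    interval: EventInterval
    spike_times: tuple[float, ...]


@dataclass(frozen=True)
class GroundTruth:
    events: tuple[ScheduledEvent, ...]
    duration: float
    seed: int
    schedule: EventSchedule
    single_spikes: tuple[float, ...] = ()

    @property
    def intervals(self) -> list[EventInterval]:
        return [e.interval for e in self.events]

    def of_kind(self, *kinds: str) -> list[ScheduledEvent]:
        return [e for e in self.events if e.interval.kind in kinds]


@dataclass(frozen=True)
class TreatmentEffect:
    """Per-kind rate multipliers active within the drug-effect window."""

    spike_mult: float = 1.0
    train_mult: float = 1.0
    hpd_mult: float = 1.0
    generalized_mult: float = 1.0
    onset_delay: float = 35 * 60.0
    offset: float = 94 * 60.0

    def __post_init__(self) -> None:
        for m in (self.spike_mult, self.train_mult, self.hpd_mult, self.generalized_mult):
            if m < 0:
                raise ValueError("multipliers must be nonnegative")


def generate_background(
    duration: float,
    rate: float,
    params: BackgroundParams = BackgroundParams(),
    seed: int | np.random.Generator = 0,
) -> ChannelTrace:
    """1/f^alpha Gaussian noise plus a sinusoid, SD calibrated to noise_sd."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate))

    white = rng.standard_normal(n)
    if params.spectral_exponent > 0:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / rate)
        shaping = np.ones_like(f)
        nz = f > 0
        shaping[nz] = f[nz] ** (-params.spectral_exponent / 2.0)
        shaping[0] = 0.0
        noise = np.fft.irfft(spec * shaping, n)
    else:
        noise = white
    sd = noise.std()
    if sd > 0:
        noise *= params.noise_sd / sd

    if params.oscillation_amp > 0:
        t = np.arange(n) / rate
        phase = rng.uniform(0, 2 * math.pi)
        noise = noise + params.oscillation_amp * np.sin(
            2 * math.pi * params.oscillation_freq * t + phase
        )
    return ChannelTrace(role="other", samples=noise)


def _sample_spike_times(
    rng: np.random.Generator, onset: float, duration: float, intra_rate: float
) -> tuple[float, ...]:
    """Renewal process: ISIs jittered +/-20% around 1/intra_rate, spanning duration."""
    isi0 = 1.0 / intra_rate
    times = [0.0]
    while times[-1] < duration:
        times.append(times[-1] + isi0 * rng.uniform(0.8, 1.2))
    times[-1] = duration  # pin the last spike so the event spans its interval
    return tuple(onset + t for t in times)


def _make_event(
    rng: np.random.Generator, kind: str, onset: float, schedule: EventSchedule
) -> ScheduledEvent:
    if kind == "spike_train":
        duration = rng.uniform(*schedule.train_duration_range)
    elif kind == "hpd":
        duration = rng.uniform(*schedule.hpd_duration_range)
    else:  # generalized_seizure
        duration = rng.uniform(*schedule.generalized_duration_range)
        return ScheduledEvent(
            interval=EventInterval(
                onset=onset,
                offset=onset + duration,
                kind="generalized_seizure",
                n_spikes=0,
                mean_rate=0.0,
            ),
            spike_times=(),
        )

    intra = rng.uniform(*schedule.intra_train_rate)
    spikes = _sample_spike_times(rng, onset, duration, intra)
    n = len(spikes)
    mean_rate = (n - 1) / duration
    return ScheduledEvent(
        interval=EventInterval(
            onset=onset,
            offset=onset + duration,
            kind=kind,
            n_spikes=n,
            mean_rate=mean_rate,
        ),
        spike_times=spikes,
    )


_MAX_PLACEMENT_RETRIES = 1000
_EVENT_MARGIN = 2.0  # s of clearance between events


def sample_schedule(
    schedule: EventSchedule,
    duration: float,
    seed: int | np.random.Generator = 0,
    rates_override: dict[str, float] | None = None,
) -> GroundTruth:
    """Draw Poisson event counts per kind and place events without overlap.

    Placement is rejection resampling: a uniformly drawn onset is retried (up
    to 1000 times per event) until the event, padded by a 2 s margin, avoids
    every previously placed event. Single spikes are placed last and only
    need to avoid event intervals.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, int) else -1

    rates = {
        "generalized_seizure": schedule.generalized_rate,
        "hpd": schedule.hpd_rate,
        "spike_train": schedule.train_rate,
    }
    if rates_override:
        rates.update({k: v for k, v in rates_override.items() if k in rates})
    hours = duration / 3600.0

    placed: list[ScheduledEvent] = []
    occupied: list[tuple[float, float]] = []

    def collides(a: float, b: float) -> bool:
        return any(a < hi + _EVENT_MARGIN and b + _EVENT_MARGIN > lo for lo, hi in occupied)

    # place longest kinds first so dense schedules still fit
    for kind in ("generalized_seizure", "hpd", "spike_train"):
        count = rng.poisson(rates[kind] * hours)
        for _ in range(count):
            for attempt in range(_MAX_PLACEMENT_RETRIES):
                onset = rng.uniform(0.0, duration)
                ev = _make_event(rng, kind, onset, schedule)
                if ev.interval.offset <= duration and not collides(
                    ev.interval.onset, ev.interval.offset
                ):
                    placed.append(ev)
                    occupied.append((ev.interval.onset, ev.interval.offset))
                    break
            else:
                raise SchedulingError(
                    f"could not place {kind} after {_MAX_PLACEMENT_RETRIES} attempts"
                )

    spike_rate = schedule.spike_rate
    if rates_override and "spike" in rates_override:
        spike_rate = rates_override["spike"]
    singles: list[float] = []
    n_singles = rng.poisson(spike_rate * hours)
    for _ in range(n_singles):
        for attempt in range(_MAX_PLACEMENT_RETRIES):
            t = rng.uniform(0.5, duration - 0.5)
            if not collides(t, t):
                singles.append(t)
                occupied.append((t, t))
                break
        else:
            raise SchedulingError("could not place single spike")

    placed.sort(key=lambda e: e.interval.onset)
    return GroundTruth(
        events=tuple(placed),
        duration=duration,
        seed=seed_val,
        schedule=schedule,
        single_spikes=tuple(sorted(singles)),
    )


def _spike_waveform(rate: float, rng: np.random.Generator) -> np.ndarray:
    """Biphasic difference-of-exponentials transient, 20-50 ms wide.

    Normalized so its peak survives the 0.5-70 Hz analysis bandpass at unit
    amplitude: the scheduled spike amplitude is defined in the analysis band,
    where the detector operates.
    """
    width = rng.uniform(0.020, 0.050)
    tau_fast = width / 8.0
    tau_slow = width / 2.5
    t = np.arange(0, 2.5 * width, 1.0 / rate)
    w = np.exp(-t / tau_slow) - np.exp(-t / tau_fast)
    w /= np.abs(w).max()
    # small opposite-polarity rebound makes it biphasic
    reb = 0.25 * np.exp(-((t - 1.2 * width) ** 2) / (2 * (width / 3) ** 2))
    w = w - reb
    return w / _filtered_peak(w, rate)


def _filtered_peak(w: np.ndarray, rate: float) -> float:
    """Peak retained by the 0.5-70 Hz analysis bandpass for this waveform.

    Narrow transients lose up to ~12% of their peak to the 70 Hz low-pass
    edge; dividing by this factor makes the scheduled amplitude hold on the
    filtered trace the detector sees.
    """
    from scipy.signal import butter, sosfiltfilt

    pad = np.zeros(int(rate))  # 1 s of padding on both sides
    x = np.concatenate([pad, w, pad])
    sos = butter(2, [0.5, 70.0], btype="bandpass", fs=rate, output="sos")
    return float(np.abs(sosfiltfilt(sos, x)).max() / np.abs(w).max())


def synthesize_recording(
    truth: GroundTruth,
    background: BackgroundParams = BackgroundParams(),
    n_channels: int = 3,
    rate: float = 500.0,
    seed: int | np.random.Generator = 0,
    animal_id: str = "sim",
) -> LfpRecording:
    """Render ground truth over 1/f background into a multi-channel recording.

    Channel 0 is hippocampus_ipsi and receives all focal events; generalized
    seizures are rendered on every channel as 15-40 Hz high-amplitude activity
    followed by 30 s of background scaled to 0.15x (post-ictal suppression).
    """
    if truth.of_kind("generalized_seizure") and n_channels < 2:
        raise ValueError("generalized seizures require >= 2 channels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(truth.duration * rate))
    roles = ["hippocampus_ipsi", "hippocampus_contra", "cortex"] + ["other"] * max(
        0, n_channels - 3
    )
    roles = roles[:n_channels]

    traces = [
        generate_background(truth.duration, rate, background, rng).samples
        for _ in range(n_channels)
    ]

    sign = -1.0 if truth.schedule.polarity == "negative" else 1.0
    amp = truth.schedule.spike_amp * background.noise_sd

    def add_spike(x: np.ndarray, t: float) -> None:
        # spike_amp is the amplitude floor; per-spike variability only upward
        w = _spike_waveform(rate, rng) * sign * amp * rng.uniform(1.0, 1.5)
        i = int(round(t * rate)) - len(w) // 4  # peak lands near t
        i0, i1 = max(0, i), min(n, i + len(w))
        if i1 > i0:
            x[i0:i1] += w[i0 - i : i1 - i]

    ipsi = traces[0]
    for t in truth.single_spikes:
        add_spike(ipsi, t)
    for ev in truth.of_kind("spike_train", "hpd"):
        for t in ev.spike_times:
            add_spike(ipsi, t)

    suppression_len = 30.0
    for ev in truth.of_kind("generalized_seizure"):
        i0 = int(round(ev.interval.onset * rate))
        i1 = min(n, int(round(ev.interval.offset * rate)))
        dur = (i1 - i0) / rate
        tt = np.arange(i1 - i0) / rate
        env = np.sin(np.pi * np.linspace(0, 1, i1 - i0)) ** 0.5  # ramp on/off
        for x in traces:
            f = rng.uniform(15.0, 40.0)
            ictal = (
                6.0
                * amp
                * env
                * np.sin(2 * math.pi * f * tt + rng.uniform(0, 2 * math.pi))
            )
            ictal += 2.0 * amp * env * rng.standard_normal(i1 - i0) * 0.3
            x[i0:i1] += ictal
            s1 = min(n, i1 + int(round(suppression_len * rate)))
            x[i1:s1] *= 0.15

    channels = tuple(
        ChannelTrace(role=roles[k], samples=traces[k]) for k in range(n_channels)
    )
    return LfpRecording(
        sampling_rate=rate, channels=channels, start_time=0.0, animal_id=animal_id
    )


def apply_treatment_effect(
    schedule: EventSchedule, effect: TreatmentEffect, injection_time: float
) -> list[tuple[float, float, dict[str, float]]]:
    """Piecewise-constant per-kind rates induced by a treatment.

    Returns ``(start, end, rates)`` pieces covering [0, inf): baseline before
    ``injection_time + onset_delay``, multiplied rates during the drug-effect
    window, baseline again afterwards.
    """
    base = {
        "spike": schedule.spike_rate,
        "spike_train": schedule.train_rate,
        "hpd": schedule.hpd_rate,
        "generalized_seizure": schedule.generalized_rate,
    }
    mult = {
        "spike": effect.spike_mult,
        "spike_train": effect.train_mult,
        "hpd": effect.hpd_mult,
        "generalized_seizure": effect.generalized_mult,
    }
    t1 = injection_time + effect.onset_delay
    t2 = injection_time + effect.offset
    during = {k: base[k] * mult[k] for k in base}
    return [(0.0, t1, dict(base)), (t1, t2, during), (t2, float("inf"), dict(base))]


def sample_session_truth(
    schedule: EventSchedule,
    effect: TreatmentEffect,
    injection_time: float,
    duration: float,
    seed: int | np.random.Generator = 0,
) -> GroundTruth:
    """Ground truth for one treatment session without rendering a signal.

    Events are sampled independently within each constant-rate piece of the
    treatment-modulated schedule and shifted to absolute session time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, int) else -1
    pieces = apply_treatment_effect(schedule, effect, injection_time)

    all_events: list[ScheduledEvent] = []
    all_singles: list[float] = []
    for start, end, rates in pieces:
        end = min(end, duration)
        if end <= start:
            continue
        piece_truth = sample_schedule(
            schedule,
            end - start,
            rng,
            rates_override=rates,
        )
        for ev in piece_truth.events:
            iv = ev.interval
            if iv.offset + start > duration:
                continue
            shifted = EventInterval(
                onset=iv.onset + start,
                offset=iv.offset + start,
                kind=iv.kind,
                n_spikes=iv.n_spikes,
                mean_rate=iv.mean_rate,
                channel_role=iv.channel_role,
            )
            all_events.append(
                ScheduledEvent(
                    interval=shifted,
                    spike_times=tuple(t + start for t in ev.spike_times),
                )
            )
        all_singles.extend(t + start for t in piece_truth.single_spikes)

    all_events.sort(key=lambda e: e.interval.onset)
    return GroundTruth(
        events=tuple(all_events),
        duration=duration,
        seed=seed_val,
        schedule=schedule,
        single_spikes=tuple(sorted(all_singles)),
    )


def simulate_session(
    schedule: EventSchedule,
    effect: TreatmentEffect,
    injection_time: float,
    duration: float,
    background: BackgroundParams = BackgroundParams(),
    rate: float = 500.0,
    n_channels: int = 3,
    seed: int = 0,
    animal_id: str = "sim",
) -> tuple[LfpRecording, GroundTruth]:
    """One treatment session: piecewise schedule -> ground truth -> recording."""
    rng = np.random.default_rng(seed)
    truth = sample_session_truth(schedule, effect, injection_time, duration, rng)
    rec = synthesize_recording(
        truth, background, n_channels=n_channels, rate=rate, seed=rng, animal_id=animal_id
    )
    return rec, truth
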