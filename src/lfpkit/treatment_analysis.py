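"""Pre/post treatment comparison: window placement, exclusion, grouping,
chi-square on generalized-seizure occurrence, and paired summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .event_detection import (
    DetectionParams,
    GeneralizedSeizureParams,
    RateSummary,
    detect_events,
    summarize_rates,
)
from .signal_core import LfpRecording, ValidationError, slice_window
from .spectral_analysis import (
    BandPowerSummary,
    SpectralParams,
    band_power,
    spectrogram,
    windowed_coastline,
)

__all__ = [
    "AnalysisWindows",
    "SessionResult",
    "GroupAssignment",
    "OccurrenceTable",
    "make_windows",
    "evaluate_session",
    "assign_groups",
    "occurrence_chisq",
    "paired_prepost_summary",
    "sidak_alpha",
]

PRE_START = 64 * 60.0  # s before injection
PRE_END = 5 * 60.0
POST_START = 35 * 60.0  # s after injection
POST_END = 94 * 60.0


@dataclass(frozen=True)
class AnalysisWindows:
    """Pre [inj-64 min, inj-5 min) and post [inj+35 min, inj+94 min)."""

    pre: tuple[float, float]
    post: tuple[float, float]

    @property
    def pre_duration(self) -> float:
        return self.pre[1] - self.pre[0]

    @property
    def post_duration(self) -> float:
        return self.post[1] - self.post[0]


def make_windows(injection_time: float, recording_duration: float | None = None) -> AnalysisWindows:
    """Place the paired 59 min analysis windows around an injection."""
    if injection_time < PRE_START:
        raise ValueError(
            f"injection at {injection_time} s leaves no room for the "
            f"{PRE_START / 60:.0f} min pre window"
        )
    if recording_duration is not None and injection_time + POST_END > recording_duration:
        raise ValueError("recording too short for the 94 min post window")
    return AnalysisWindows(
        pre=(injection_time - PRE_START, injection_time - PRE_END),
        post=(injection_time + POST_START, injection_time + POST_END),
    )


@dataclass(frozen=True)
class SessionResult:
    session_id: str
    animal_id: str
    treatment_label: str
    rates_pre: RateSummary
    rates_post: RateSummary
    bands_pre: BandPowerSummary
    bands_post: BandPowerSummary
    excluded_from_events: bool
    exclusion_reason: str
    generalized_in_post: bool

    def __post_init__(self) -> None:
        if self.generalized_in_post and not self.excluded_from_events:
            raise ValidationError(
                "sessions with a post-window generalized seizure must be excluded"
            )


def evaluate_session(
    rec: LfpRecording,
    session_id: str,
    treatment_label: str,
    injection_time: float,
    det: DetectionParams = DetectionParams(),
    spec: SpectralParams = SpectralParams(),
    gen: GeneralizedSeizureParams = GeneralizedSeizureParams(),
    shared_baseline: bool = False,
) -> SessionResult:
    """Run detection + spectral analysis on the pre and post windows.

    The mode baseline is re-estimated in each window unless
    ``shared_baseline`` is set, in which case the pre-window polarity is
    forced onto the post window. The exclusion flag is set when any
    generalized seizure is detected in the post window.
    """
    if "hippocampus_ipsi" not in rec.roles:
        raise ValueError("recording lacks a hippocampus_ipsi channel")
    windows = make_windows(injection_time, rec.duration)

    def analyze(win: tuple[float, float], det_params: DetectionParams):
        sub = slice_window(rec, win[0], win[1])
        gen_params = gen if len(sub.channels) >= 2 else None
        events, baseline = detect_events(sub, det_params, gen_params)
        rates = summarize_rates(events, (0.0, win[1] - win[0]))
        sgram = spectrogram(sub.ipsi, sub.sampling_rate, spec)
        cl = windowed_coastline(sub.ipsi, sub.sampling_rate, spec)
        bands = band_power(sgram, spec.bands, cl)
        return events, baseline, rates, bands

    _, baseline_pre, rates_pre, bands_pre = analyze(windows.pre, det)
    det_post = det
    if shared_baseline:
        from dataclasses import replace as _replace

        det_post = _replace(det, polarity_override=baseline_pre.polarity)
    _, _, rates_post, bands_post = analyze(windows.post, det_post)

    generalized_in_post = rates_post.n_generalized > 0
    return SessionResult(
        session_id=session_id,
        animal_id=rec.animal_id,
        treatment_label=treatment_label,
        rates_pre=rates_pre,
        rates_post=rates_post,
        bands_pre=bands_pre,
        bands_post=bands_post,
        excluded_from_events=generalized_in_post,
        exclusion_reason="generalized seizure in post window" if generalized_in_post else "",
        generalized_in_post=generalized_in_post,
    )


@dataclass(frozen=True)
class GroupAssignment:
    animal_id: str
    hpd_s_per_h: float
    group: str  # high_hpds | low_hpds
    cutoff: float


def assign_groups(
    summaries: dict[str, float] | pd.Series, cutoff: float = 50.0
) -> list[GroupAssignment]:
    """Split animals by cumulative HPD duration (s/h); strict > is high."""
    items = summaries.items() if hasattr(summaries, "items") else summaries
    seen: set[str] = set()
    out = []
    for animal, dur in items:
        if animal in seen:
            raise ValidationError(f"duplicate animal {animal!r}")
        seen.add(animal)
        out.append(
            GroupAssignment(
                animal_id=animal,
                hpd_s_per_h=float(dur),
                group="high_hpds" if dur > cutoff else "low_hpds",
                cutoff=cutoff,
            )
        )
    return out


@dataclass(frozen=True)
class OccurrenceTable:
    """Per-treatment counts of animals with vs without a generalized seizure."""

    treatments: tuple[str, ...]
    n_with: tuple[int, ...]
    n_without: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.treatments) != len(self.n_with) or len(self.n_with) != len(self.n_without):
            raise ValidationError("ragged occurrence table")
        if any(w < 0 or wo < 0 for w, wo in zip(self.n_with, self.n_without)):
            raise ValidationError("counts must be nonnegative")

    @classmethod
    def from_results(cls, results: list[SessionResult]) -> "OccurrenceTable":
        df = pd.DataFrame(
            {
                "treatment": [r.treatment_label for r in results],
                "gen": [r.generalized_in_post for r in results],
            }
        )
        grp = df.groupby("treatment", sort=False)["gen"]
        treatments = tuple(grp.sum().index)
        n_with = tuple(int(v) for v in grp.sum())
        n_tot = grp.count()
        return cls(
            treatments=treatments,
            n_with=n_with,
            n_without=tuple(int(t - w) for t, w in zip(n_tot, n_with)),
        )


def occurrence_chisq(table: OccurrenceTable) -> tuple[float, int, float]:
    """Pearson chi-square on the 2 x k occurrence table, no continuity correction."""
    if len(table.treatments) < 2:
        raise ValidationError("need >= 2 treatments")
    obs = np.array([table.n_with, table.n_without], dtype=float)
    if np.any(obs.sum(axis=0) == 0):
        raise ValidationError("every treatment needs at least one session")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(dof), float(p)


def sidak_alpha(alpha: float = 0.05, m: int = 8) -> float:
    """Per-comparison significance threshold: 1 - (1 - alpha)^(1/m)."""
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


_EVENT_MEASURES = {
    "n_spike_trains": lambda r: (r.rates_pre.n_spike_trains, r.rates_post.n_spike_trains),
    "dur_spike_trains": lambda r: (r.rates_pre.dur_spike_trains, r.rates_post.dur_spike_trains),
    "n_hpds": lambda r: (r.rates_pre.n_hpds, r.rates_post.n_hpds),
    "dur_hpds": lambda r: (r.rates_pre.dur_hpds, r.rates_post.dur_hpds),
}


def _band_measure(band: str):
    return lambda r: (r.bands_pre.log10_power[band], r.bands_post.log10_power[band])


def _measure_fn(measure: str):
    if measure in _EVENT_MEASURES:
        return _EVENT_MEASURES[measure], True
    if measure == "coastline":
        return (lambda r: (r.bands_pre.log10_coastline, r.bands_post.log10_coastline)), False
    if measure.startswith("log10_"):
        return _band_measure(measure.removeprefix("log10_")), False
    raise ValueError(f"unknown measure {measure!r}")


def paired_prepost_summary(
    results: list[SessionResult],
    measure: str,
    alpha: float = 0.05,
    m_comparisons: int = 8,
) -> pd.DataFrame:
    """Tidy per-treatment paired pre/post table for one measure.

    Event-rate measures (``n_spike_trains``, ``dur_spike_trains``, ``n_hpds``,
    ``dur_hpds``) use only non-excluded sessions; spectral measures
    (``log10_<band>``, ``coastline``) use every session. Columns: treatment,
    n, mean_pre, sd_pre, mean_post, sd_post, mean_diff, t_stat, p_value,
    alpha_sidak, significant, estimable.
    """
    fn, is_event = _measure_fn(measure)
    a_adj = sidak_alpha(alpha, m_comparisons)

    rows = []
    treatments = list(dict.fromkeys(r.treatment_label for r in results))
    for trt in treatments:
        sel = [
            r
            for r in results
            if r.treatment_label == trt and not (is_event and r.excluded_from_events)
        ]
        pre = np.array([fn(r)[0] for r in sel], dtype=float)
        post = np.array([fn(r)[1] for r in sel], dtype=float)
        n = pre.size
        row = {
            "treatment": trt,
            "measure": measure,
            "n": n,
            "mean_pre": pre.mean() if n else np.nan,
            "sd_pre": pre.std(ddof=1) if n > 1 else np.nan,
            "mean_post": post.mean() if n else np.nan,
            "sd_post": post.std(ddof=1) if n > 1 else np.nan,
            "mean_diff": (post - pre).mean() if n else np.nan,
            "alpha_sidak": a_adj,
            "estimable": n >= 2,
        }
        if n >= 2 and np.std(post - pre) > 0:
            t, p = stats.ttest_rel(post, pre)
            row["t_stat"] = float(t)
            row["p_value"] = float(p)
            row["significant"] = bool(p < a_adj)
        else:
            row["t_stat"] = np.nan
            row["p_value"] = np.nan
            row["significant"] = False
        rows.append(row)
    return pd.DataFrame(rows)
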