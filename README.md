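# lfpkit

Analysis pipeline for multi-channel local field potential (LFP) recordings
from chronic epilepsy experiments, together with a seeded synthetic LFP
generator that provides ground-truth inputs so the whole analysis can be run
and validated without animal data.

## What it does

- **`lfpkit.signal_core`** — recording/event/schedule data model with EDF,
  delimited CSV and npz-container I/O, half-open time-window slicing, and
  BED-like TSV event annotations. Amplitudes are microvolts everywhere.
- **`lfpkit.synthetic_lfp`** — 1/f background + sinusoid, Poisson event
  schedules (single spikes, spike trains, hippocampal paroxysmal discharges
  (HPDs), generalized seizures), biphasic spike waveforms, treatment effects
  as piecewise rate multipliers, fully deterministic per seed.
- **`lfpkit.event_detection`** — 0.5–70 Hz second-order Butterworth
  zero-phase bandpass; spike threshold at 2× the mode of per-second signal
  extrema with a 70 ms refractory period; chaining into spike trains
  (1–10 s, ≥3 spikes, ≥1.33 Hz) and HPDs (≥10 s); alternative event
  definitions (SLE ≥3 s; ≥5 s & ≥5 Hz; ≥20 s & 10–20 Hz); cross-channel RMS
  flagging of generalized seizures with post-ictal suppression; per-hour
  rate summaries.
- **`lfpkit.spectral_analysis`** — sliding 10 s Hanning-window one-sided PSD
  (5 s step), band powers (delta 1–4, theta 4–8, alpha 8–13, beta 13–30,
  gamma 30–80 Hz), coastline (line length), normalization to the
  pretreatment maximum.
- **`lfpkit.treatment_analysis`** — paired pre ([−64, −5) min) / post
  ([+35, +94) min) windows around an injection, exclusion of sessions with
  post-window generalized seizures from event-rate analysis (spectral
  summaries keep all sessions), high/low-HPDs grouping at 50 s/h, Pearson
  chi-square on generalized-seizure occurrence, paired pre/post tables with
  Šídák-adjusted paired t-tests.

## CLI

```sh
# simulate a 1 h recording with ground truth
lfpkit simulate --duration 3600 --seed 1 \
    --out-recording sim.csv --out-truth truth.tsv

# detect events (writes a BED-like TSV and a rate summary)
lfpkit detect --in sim.csv --profile paper \
    --out-events events.tsv --out-summary rates.csv

# band powers and coastline for two windows
lfpkit spectra --in sim.csv --window-pre 0 1800 --window-post 1800 3600 \
    --out-bands bands.csv

# convert between formats (EDF / CSV / npz)
lfpkit convert --in sim.csv --out sim.edf

# full pre/post treatment report from a manifest CSV
# (columns: session_id, path, animal, treatment, injection_time_s)
lfpkit treatment-report --recordings manifest.csv --out-dir report/
```

## Conventions

Time is seconds from session origin; intervals are half-open
`[onset, offset)`; sample *i* covers `[i/rate, (i+1)/rate)`. Event mean rate
defaults to `(n_spikes − 1) / duration` (reciprocal mean inter-spike
interval); the `n / duration` convention is available via
`DetectionParams(rate_convention="count")`.
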