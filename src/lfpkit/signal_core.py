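"""Core data model: recordings, channels, event intervals, schedules, and I/O.

Conventions used throughout the package:

* time is expressed in seconds from the session origin;
* intervals are half-open ``[onset, offset)``;
* sample ``i`` covers the time span ``[i/rate, (i+1)/rate)``;
* amplitudes are always microvolts at module boundaries.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ChannelTrace",
    "LfpRecording",
    "EventInterval",
    "TreatmentSchedule",
    "ValidationError",
    "FormatError",
    "read_recording",
    "write_recording",
    "slice_window",
    "read_events",
    "write_events",
]

EVENT_KINDS = ("spike_train", "hpd", "sle", "generalized_seizure")
CHANNEL_ROLES = ("hippocampus_ipsi", "hippocampus_contra", "cortex", "other")

DEFAULT_TREATMENTS = (
    "vehicle",
    "DZP2.5",
    "LTG10",
    "LTG30",
    "OXC10",
    "OXC30",
    "LEV100",
    "LEV300",
)


class ValidationError(ValueError):
    """Raised when data violate a domain invariant."""


class FormatError(ValueError):
    """Raised for unknown or malformed file formats."""


@dataclass(frozen=True)
class ChannelTrace:
    """A single channel of microvolt samples with a semantic role."""

    role: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise ValidationError(f"unknown channel role {self.role!r}")
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            raise ValidationError("channel samples must be one-dimensional")
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValidationError(f"channel {self.role!r} contains non-finite amplitudes")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class LfpRecording:
    """Multi-channel LFP recording at a common sampling rate.

    Parameters
    ----------
    sampling_rate
        Samples per second (500 or 512 typical).
    channels
        Ordered channel traces; all must share one length.
    start_time
        Seconds since session origin covered by sample 0.
    animal_id
        Opaque subject label.
    """

    sampling_rate: float
    channels: tuple[ChannelTrace, ...]
    start_time: float = 0.0
    animal_id: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        chans = tuple(self.channels)
        if not chans:
            raise ValidationError("recording needs at least one channel")
        lengths = {len(c) for c in chans}
        if len(lengths) != 1:
            raise ValidationError(f"channel lengths differ: {sorted(lengths)}")
        ipsi = [c for c in chans if c.role == "hippocampus_ipsi"]
        if len(ipsi) > 1:
            raise ValidationError("at most one hippocampus_ipsi channel allowed")
        object.__setattr__(self, "channels", chans)

    @property
    def n_samples(self) -> int:
        return len(self.channels[0])

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(c.role for c in self.channels)

    def channel(self, role: str) -> ChannelTrace:
        for c in self.channels:
            if c.role == role:
                return c
        raise KeyError(f"no channel with role {role!r}")

    @property
    def ipsi(self) -> ChannelTrace:
        """The single ipsilateral hippocampal channel (analysis channel)."""
        return self.channel("hippocampus_ipsi")


@dataclass(frozen=True)
class EventInterval:
    """A classified event on one channel, half-open ``[onset, offset)``."""

    onset: float
    offset: float
    kind: str
    n_spikes: int = 0
    mean_rate: float = 0.0
    channel_role: str = "hippocampus_ipsi"

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if not self.offset > self.onset:
            raise ValidationError("offset must exceed onset")
        if self.kind in ("spike_train", "hpd") and self.n_spikes < 3:
            raise ValidationError(f"{self.kind} requires n_spikes >= 3")
        if self.n_spikes < 0 or self.mean_rate < 0:
            raise ValidationError("counts and rates must be nonnegative")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class TreatmentSchedule:
    """Injection schedule rows plus the washout constraint (hours)."""

    rows: pd.DataFrame
    washout_hours: float = 72.0
    allowed_labels: tuple[str, ...] = DEFAULT_TREATMENTS

    REQUIRED = ("animal_id", "treatment_label", "dose_mg_kg", "injection_time_s", "session_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValidationError(f"schedule missing columns {missing}")
        bad = set(self.rows["treatment_label"]) - set(self.allowed_labels)
        if bad:
            raise ValidationError(f"unknown treatment labels {sorted(bad)}")
        min_gap = self.washout_hours * 3600.0
        for animal, grp in self.rows.groupby("animal_id"):
            t = np.sort(grp["injection_time_s"].to_numpy(dtype=float))
            if t.size > 1 and np.min(np.diff(t)) < min_gap:
                raise ValidationError(
                    f"animal {animal!r}: injections closer than washout of "
                    f"{self.washout_hours} h"
                )


# ---------------------------------------------------------------------------
# Delimited (CSV) format
# ---------------------------------------------------------------------------

_CSV_ROLE_MAP = {"ipsi_uV": "hippocampus_ipsi", "contra_uV": "hippocampus_contra", "cortex_uV": "cortex"}
_CSV_COL_MAP = {v: k for k, v in _CSV_ROLE_MAP.items()}


def _read_delimited(path: Path) -> LfpRecording:
    meta: dict[str, str] = {}
    sidecar = path.with_suffix(path.suffix + ".meta")
    if sidecar.exists():
        cp = configparser.ConfigParser()
        cp.read(sidecar)
        meta = dict(cp["recording"]) if cp.has_section("recording") else {}

    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise FormatError("delimited recording needs a 'time_s' column")
    if df.isna().any().any():
        raise ValidationError("delimited recording contains missing/NaN values")

    t = df["time_s"].to_numpy(dtype=float)
    if "sampling_rate" in meta:
        rate = float(meta["sampling_rate"])
    elif t.size >= 2:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
            raise ValidationError("time column is not uniformly sampled")
        rate = 1.0 / float(np.mean(dt))
    else:
        raise ValidationError("cannot infer sampling rate from <2 samples")

    channels = []
    for col in df.columns:
        if col == "time_s":
            continue
        role = _CSV_ROLE_MAP.get(col, meta.get(f"role_{col}", "other"))
        channels.append(ChannelTrace(role=role, samples=df[col].to_numpy(dtype=float)))
    if not channels:
        raise FormatError("delimited recording has no channel columns")
    return LfpRecording(
        sampling_rate=rate,
        channels=tuple(channels),
        start_time=float(t[0]) if t.size else 0.0,
        animal_id=meta.get("animal_id", ""),
    )


def _write_delimited(rec: LfpRecording, path: Path) -> None:
    t = rec.start_time + np.arange(rec.n_samples) / rec.sampling_rate
    data: dict[str, np.ndarray] = {"time_s": t}
    extra_roles: dict[str, str] = {}
    other_idx = 0
    for ch in rec.channels:
        col = _CSV_COL_MAP.get(ch.role)
        if col is None:
            col = f"ch{other_idx}_uV"
            other_idx += 1
            extra_roles[f"role_{col}"] = ch.role
        data[col] = ch.samples
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")

    cp = configparser.ConfigParser()
    cp["recording"] = {
        "sampling_rate": repr(rec.sampling_rate),
        "animal_id": rec.animal_id,
        **extra_roles,
    }
    with open(path.with_suffix(path.suffix + ".meta"), "w") as fh:
        cp.write(fh)


# ---------------------------------------------------------------------------
# EDF (European Data Format): minimal single-data-record implementation.
# 16-bit quantization per the EDF standard; physical range spans the data.
# ---------------------------------------------------------------------------


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


# channel labels must fit EDF's 16-char field; full role names do not
_EDF_LABELS = {
    "hippocampus_ipsi": "EEG hc-ipsi",
    "hippocampus_contra": "EEG hc-contra",
    "cortex": "EEG cortex",
    "other": "other",
}
_EDF_ROLES = {v: k for k, v in _EDF_LABELS.items()}


def _write_edf(rec: LfpRecording, path: Path) -> None:
    ns = len(rec.channels)
    n_samples = rec.n_samples
    # One data record holding the entire trace keeps record bookkeeping trivial;
    # EDF allows record durations up to the full file for non-streamed use.
    record_duration = n_samples / rec.sampling_rate

    header = b""
    header += _edf_field("0", 8)  # version
    header += _edf_field(rec.animal_id or "X", 80)  # patient id
    header += _edf_field(f"start_time={rec.start_time!r}", 80)  # recording id
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(str(256 + ns * 256), 8)
    # exact sampling rate in the reserved field: the 8-char duration field
    # cannot always carry n/rate losslessly
    header += _edf_field(f"rate={rec.sampling_rate!r}", 44)
    header += _edf_field("1", 8)  # number of data records
    header += _edf_field(f"{record_duration:.6f}"[:8], 8)
    header += _edf_field(str(ns), 4)

    phys_min, phys_max, dig = [], [], []
    for ch in rec.channels:
        # integer uV bounds always fit the 8-char ASCII header fields exactly
        lo = float(np.floor(np.min(ch.samples))) if len(ch) else -1.0
        hi = float(np.ceil(np.max(ch.samples))) if len(ch) else 1.0
        if hi <= lo:
            hi = lo + 1.0
        scale = (hi - lo) / 65535.0
        d = np.round((ch.samples - lo) / scale).astype(np.int64) - 32768
        dig.append(np.clip(d, -32768, 32767).astype("<i2"))
        phys_min.append(lo)
        phys_max.append(hi)

    for ch in rec.channels:
        header += _edf_field(_EDF_LABELS[ch.role], 16)
    header += b" " * (80 * ns)  # transducer
    for _ in rec.channels:
        header += _edf_field("uV", 8)
    for lo in phys_min:
        header += _edf_field(f"{lo:.0f}", 8)
    for hi in phys_max:
        header += _edf_field(f"{hi:.0f}", 8)
    for _ in rec.channels:
        header += _edf_field("-32768", 8)
    for _ in rec.channels:
        header += _edf_field("32767", 8)
    header += b" " * (80 * ns)  # prefiltering
    for _ in rec.channels:
        header += _edf_field(str(n_samples), 8)
    header += b" " * (32 * ns)

    with open(path, "wb") as fh:
        fh.write(header)
        for d in dig:
            fh.write(d.tobytes())


def _read_edf(path: Path) -> LfpRecording:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise FormatError("file too short to be EDF")

    def fld(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    if fld(0, 8) != "0":
        raise FormatError("not an EDF file (bad version field)")
    animal_id = fld(8, 80)
    rid = fld(88, 80)
    start_time = 0.0
    if rid.startswith("start_time="):
        start_time = float(rid.split("=", 1)[1])
    reserved = fld(192, 44)
    n_records = int(fld(236, 8))
    record_duration = float(fld(244, 8))
    ns = int(fld(252, 4))

    off = 256
    labels = [fld(off + 16 * i, 16) for i in range(ns)]
    off += 16 * ns + 80 * ns + 8 * ns  # labels, transducer, units
    pmin = [float(fld(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns
    pmax = [float(fld(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns
    dmin = [int(fld(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns
    dmax = [int(fld(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns + 80 * ns
    nsamp = [int(fld(off + 8 * i, 8)) for i in range(ns)]
    header_bytes = 256 + ns * 256

    per_chan: list[list[np.ndarray]] = [[] for _ in range(ns)]
    pos = header_bytes
    for _ in range(n_records):
        for i in range(ns):
            nb = nsamp[i] * 2
            seg = np.frombuffer(raw[pos : pos + nb], dtype="<i2")
            per_chan[i].append(seg.astype(np.float64))
            pos += nb

    channels = []
    total_samples = None
    for i in range(ns):
        d = np.concatenate(per_chan[i]) if per_chan[i] else np.empty(0)
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = pmin[i] + (d - dmin[i]) * scale
        role = _EDF_ROLES.get(labels[i], "other")
        channels.append(ChannelTrace(role=role, samples=phys))
        total_samples = len(phys)

    if record_duration <= 0 or not total_samples:
        raise ValidationError("EDF header lacks a usable sampling rate")
    if reserved.startswith("rate="):
        rate = float(reserved.split("=", 1)[1])
    else:
        rate = nsamp[0] / record_duration
    return LfpRecording(
        sampling_rate=rate,
        channels=tuple(channels),
        start_time=start_time,
        animal_id=animal_id if animal_id != "X" else "",
    )


# ---------------------------------------------------------------------------
# Container format (npz): lossless float round trip
# ---------------------------------------------------------------------------


def _write_container(rec: LfpRecording, path: Path) -> None:
    arrays = {f"ch{i}": c.samples for i, c in enumerate(rec.channels)}
    np.savez(
        path,
        sampling_rate=np.float64(rec.sampling_rate),
        start_time=np.float64(rec.start_time),
        animal_id=np.str_(rec.animal_id),
        roles=np.array(rec.roles),
        **arrays,
    )


def _read_container(path: Path) -> LfpRecording:
    with np.load(path, allow_pickle=False) as z:
        roles = [str(r) for r in z["roles"]]
        channels = tuple(
            ChannelTrace(role=roles[i], samples=z[f"ch{i}"]) for i in range(len(roles))
        )
        return LfpRecording(
            sampling_rate=float(z["sampling_rate"]),
            channels=channels,
            start_time=float(z["start_time"]),
            animal_id=str(z["animal_id"]),
        )


_FORMATS = {"edf", "delimited", "container"}


def _infer_format(path: Path) -> str:
    suf = path.suffix.lower()
    if suf == ".edf":
        return "edf"
    if suf in (".csv", ".txt", ".tsv"):
        return "delimited"
    if suf == ".npz":
        return "container"
    raise FormatError(f"cannot infer format from suffix {suf!r}")


def read_recording(path: str | Path, format: str | None = None) -> LfpRecording:
    """Read a recording from EDF, delimited CSV, or the npz container format."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {sorted(_FORMATS)}")
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "delimited":
        return _read_delimited(path)
    return _read_container(path)


def write_recording(rec: LfpRecording, path: str | Path, format: str | None = None) -> None:
    """Write a recording; readable back by :func:`read_recording`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {sorted(_FORMATS)}")
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "delimited":
        _write_delimited(rec, path)
    else:
        _write_container(rec, path)


# ---------------------------------------------------------------------------
# Window slicing
# ---------------------------------------------------------------------------


def slice_window(rec: LfpRecording, start: float, end: float) -> LfpRecording:
    """Return the half-open window ``[start, end)`` as a new recording.

    ``start``/``end`` are seconds relative to the recording's own sample 0
    (i.e. offsets into the trace, not absolute session time). The returned
    recording has ``floor((end - start) * rate)`` samples per channel and its
    ``start_time`` shifted by ``start``.
    """
    if not (0 <= start < end):
        raise ValueError(f"need 0 <= start < end, got [{start}, {end})")
    if end > rec.duration + 1e-9:
        raise ValueError(f"window [{start}, {end}) exceeds duration {rec.duration}")
    i0 = int(round(start * rec.sampling_rate))
    n = int(np.floor((end - start) * rec.sampling_rate + 1e-9))
    channels = tuple(
        ChannelTrace(role=c.role, samples=c.samples[i0 : i0 + n]) for c in rec.channels
    )
    return replace(rec, channels=channels, start_time=rec.start_time + start)


# ---------------------------------------------------------------------------
# Event annotation I/O (BED-like TSV)
# ---------------------------------------------------------------------------

_EVENT_COLS = ("channel_role", "onset_s", "offset_s", "kind", "n_spikes", "mean_rate")


def write_events(events: Iterable[EventInterval], path: str | Path) -> None:
    """Serialize events as a BED-like tab-separated file."""
    rows = [
        (e.channel_role, e.onset, e.offset, e.kind, e.n_spikes, e.mean_rate)
        for e in events
    ]
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[EventInterval]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EVENT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"event file missing columns {missing}")
    return [
        EventInterval(
            onset=float(r.onset_s),
            offset=float(r.offset_s),
            kind=str(r.kind),
            n_spikes=int(r.n_spikes),
            mean_rate=float(r.mean_rate),
            channel_role=str(r.channel_role),
        )
        for r in df.itertuples()
    ]
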