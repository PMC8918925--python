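"""RR-interval series: data model, I/O, relative-RR transform, segmentation.

The pipeline starts from annotated RR intervals (ms), one stream per
patient, with a binary label (AF-HF vs control).  A recording is split
into fixed-duration windows of cumulative RR time (5 min by default) and
each window is tagged as day or night by its start clock time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABEL_POSITIVE = "AF-HF"
LABEL_NEGATIVE = "control"

#: daytime window [08:00, 22:00), nighttime the complement, in seconds
DAY_START_S = 8 * 3600
DAY_END_S = 22 * 3600
SECONDS_PER_DAY = 86_400

CircadianTag = Literal["day", "night"]
WindowDef = Literal["day", "night", "full"]


@dataclass(frozen=True)
class RRSeries:
    """One patient's consecutive RR intervals.

    Parameters
    ----------
    patient_id : str
        Opaque identifier.
    label : str
        ``"AF-HF"`` or ``"control"``.
    rr : np.ndarray
        Ordered RR intervals in milliseconds, all positive, length >= 2.
    start_clock : float
        Time of day of the first beat, seconds since midnight.
        Defaults to 08:00 (24-h Holter recordings conventionally run
        8 a.m. to 8 a.m. the next day).
    """

    patient_id: str
    label: str
    rr: np.ndarray
    start_clock: float = float(DAY_START_S)

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr, dtype=float)
        object.__setattr__(self, "rr", rr)
        if rr.ndim != 1 or rr.size < 2:
            raise ValueError(
                f"patient {self.patient_id!r}: need >= 2 RR intervals, got {rr.size}"
            )
        if not np.all(rr > 0):
            raise ValueError(f"patient {self.patient_id!r}: RR intervals must be > 0")
        if self.label not in (LABEL_POSITIVE, LABEL_NEGATIVE):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def beat_times(self) -> np.ndarray:
        """Cumulative beat onset times in seconds since recording start.

        ``beat_times[0] == 0`` (first beat defines the origin) and
        ``beat_times[i] - beat_times[i-1] == rr[i] / 1000``.
        """
        t = np.empty(self.rr.size, dtype=float)
        t[0] = 0.0
        np.cumsum(self.rr[1:] / 1000.0, out=t[1:])
        return t

    @property
    def duration_s(self) -> float:
        return float(np.sum(self.rr[1:]) / 1000.0)

    def __len__(self) -> int:
        return int(self.rr.size)


@dataclass(frozen=True)
class RelRRSeries:
    """Relative RR intervals (%), one value per consecutive beat pair."""

    values: np.ndarray
    parent: RRSeries | None = None

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class Segment:
    """A contiguous window of one patient's RR stream."""

    patient_id: str
    label: str
    rr: np.ndarray
    start_clock: float
    circadian_tag: CircadianTag
    duration_s: float
    segment_idx: int = 0


def circadian_tag_for(start_clock: float) -> CircadianTag:
    """Day/night tag for a clock time (s since midnight), half-open windows."""
    s = float(start_clock) % SECONDS_PER_DAY
    return "day" if DAY_START_S <= s < DAY_END_S else "night"


def to_relative(
    rr: RRSeries | Segment | Sequence[float],
    mode: Literal["ratio", "symmetric"] = "ratio",
) -> RelRRSeries:
    """Relative RR series: each interval as a percentage of its predecessor.

    ``ratio`` (default): values[i] = 100 * rr[i+1] / rr[i].
    ``symmetric``: 200 * (rr[i+1] - rr[i]) / (rr[i+1] + rr[i]), the
    symmetrised relative-RR variant from the arrhythmia literature.
    """
    parent = rr if isinstance(rr, RRSeries) else None
    x = rr.rr if isinstance(rr, (RRSeries, Segment)) else np.asarray(rr, dtype=float)
    if x.size < 2:
        raise ValueError("relative RR needs at least 2 intervals")
    if mode == "ratio":
        values = 100.0 * x[1:] / x[:-1]
    elif mode == "symmetric":
        values = 200.0 * (x[1:] - x[:-1]) / (x[1:] + x[:-1])
    else:
        raise ValueError(f"unknown relrr_mode {mode!r}")
    return RelRRSeries(values=values, parent=parent)


def read_rr_table(
    path,
    sep: str | None = None,
) -> list[RRSeries]:
    """Read per-patient RR streams from a long-format CSV/TSV.

    Required columns: ``patient_id``, ``label``, ``rr_ms``; optional
    ``clock_time`` (seconds since midnight of the first beat, or
    ``HH:MM:SS``).  Rows with missing or non-positive RR are dropped with
    a logged count; patients with fewer than two remaining beats are
    skipped with a warning.  Row order within a patient is preserved.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    required = {"patient_id", "label", "rr_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing mandatory column(s): {sorted(missing)}")

    rr = pd.to_numeric(df["rr_ms"], errors="coerce")
    bad = rr.isna() | (rr <= 0)
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info("read_rr_table: dropped %d invalid RR rows", n_dropped)
    df = df.loc[~bad.to_numpy()].assign(rr_ms=rr[~bad])

    series: list[RRSeries] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        if len(grp) < 2:
            logger.warning("patient %r has < 2 beats; skipped", pid)
            continue
        start_clock = float(DAY_START_S)
        if "clock_time" in grp.columns:
            raw = grp["clock_time"].iloc[0]
            start_clock = _parse_clock(raw)
        series.append(
            RRSeries(
                patient_id=str(pid),
                label=str(grp["label"].iloc[0]),
                rr=grp["rr_ms"].to_numpy(dtype=float),
                start_clock=start_clock,
            )
        )
    return series


def _parse_clock(raw) -> float:
    if isinstance(raw, str) and ":" in raw:
        h, m, s = (float(x) for x in raw.split(":"))
        return h * 3600 + m * 60 + s
    return float(raw)


def write_rr_table(series: Iterable[RRSeries], path) -> None:
    """Write RR streams in the long CSV dialect ``read_rr_table`` accepts."""
    frames = [
        pd.DataFrame(
            {
                "patient_id": s.patient_id,
                "label": s.label,
                "rr_ms": s.rr,
                "clock_time": s.start_clock,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def segment_series(
    series: RRSeries,
    duration_s: float = 300.0,
    min_beats: int = 100,
) -> list[Segment]:
    """Split a series into consecutive fixed-duration windows.

    Windows are defined on cumulative RR time, not wall clock; a beat
    belongs to the window containing its onset.  The trailing partial
    window is discarded, as is any window with fewer than ``min_beats``
    beats (artifact-dominated windows).  Each segment's ``start_clock``
    is the series start clock plus the window offset (mod 24 h).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    # window membership is computed in milliseconds so that integer-ms
    # RR streams (the common case) segment exactly, with no cumsum
    # rounding at window boundaries
    t_ms = np.concatenate(([0.0], np.cumsum(series.rr[1:])))
    duration_ms = duration_s * 1000.0
    n_windows = int(t_ms[-1] // duration_ms)
    # the window containing onset t is floor(t / duration); beats at or
    # past n_windows * duration fall in the discarded trailing partial
    win_of_beat = (t_ms / duration_ms).astype(int)
    segments: list[Segment] = []
    for w in range(n_windows):
        mask = win_of_beat == w
        n = int(mask.sum())
        if n < min_beats:
            continue
        start_clock = (series.start_clock + w * duration_s) % SECONDS_PER_DAY
        segments.append(
            Segment(
                patient_id=series.patient_id,
                label=series.label,
                rr=series.rr[mask],
                start_clock=start_clock,
                circadian_tag=circadian_tag_for(start_clock),
                duration_s=float(duration_s),
                segment_idx=w,
            )
        )
    return segments


def circadian_filter(
    segments: Iterable[Segment], window_def: WindowDef
) -> list[Segment]:
    """Keep segments whose start clock lies in the requested window.

    ``day`` keeps [08:00, 22:00) starts, ``night`` the complement,
    ``full`` keeps everything.
    """
    if window_def not in ("day", "night", "full"):
        raise ValueError(f"unknown circadian window {window_def!r}")
    if window_def == "full":
        return list(segments)
    return [s for s in segments if s.circadian_tag == window_def]


def segments_to_frame(segments: Iterable[Segment]) -> pd.DataFrame:
    """Long-format table: one row per beat with segment lineage."""
    rows = []
    for s in segments:
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "segment_idx": s.segment_idx,
                    "circadian_tag": s.circadian_tag,
                    "start_clock": s.start_clock,
                    "beat_idx": np.arange(s.rr.size),
                    "rr_ms": s.rr,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
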