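"""Turn detection logs into presence series, behaviour bouts and summaries.

Resource use is proxied by marker presence inside a resource ROI.  A *bout*
(event) is a contiguous episode of engagement: presence runs separated by a
gap shorter than the bout-gap threshold belong to the same event, and a gap
of at least the threshold starts a new one.  The ethogram convention is a
1-minute disengagement rule — 60 s, or 1800 frames at the sustained 30 fps
frame rate — so the default thresholds are 1800 frame units or 60 second
units depending on the series resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PresenceSeries",
    "BehaviourBout",
    "presence_series",
    "series_from_values",
    "frame_to_second",
    "segment_bouts",
    "summarize",
    "DEFAULT_FPS",
    "BOUT_GAP_FRAMES",
    "BOUT_GAP_SECONDS",
]

DEFAULT_FPS = 30.0
BOUT_GAP_SECONDS = 60
BOUT_GAP_FRAMES = 1800  # 60 s at 30 fps


@dataclass
class PresenceSeries:
    """Binary per-unit presence of one subject in one ROI.

    ``resolution`` is "frame" or "second"; ``start`` is the offset of the
    first element in series units; ``rate`` is the source frame rate.
    """

    subject: int
    roi: int
    resolution: str
    values: np.ndarray
    start: int = 0
    rate: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("values must be binary")
        if self.resolution not in ("frame", "second"):
            raise ValueError("resolution must be 'frame' or 'second'")

    @property
    def default_gap(self) -> int:
        return BOUT_GAP_FRAMES if self.resolution == "frame" else BOUT_GAP_SECONDS

    @property
    def unit_seconds(self) -> float:
        return 1.0 / self.rate if self.resolution == "frame" else 1.0


@dataclass(frozen=True)
class BehaviourBout:
    """One contiguous resource-use event, inclusive in series units."""

    subject: int
    roi: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("bout start must not exceed end")

    @property
    def duration(self) -> int:
        return self.end - self.start + 1


def series_from_values(values, resolution: str = "frame", subject: int = -1,
                       roi: int = -1, start: int = 0,
                       rate: float = DEFAULT_FPS) -> PresenceSeries:
    """Convenience constructor for hand-built series."""
    return PresenceSeries(subject=subject, roi=roi, resolution=resolution,
                          values=np.asarray(values), start=start, rate=rate)


def presence_series(log: pd.DataFrame, subject: int, roi: int,
                    resolution: str = "frame", rate: float = DEFAULT_FPS,
                    n_frames: int | None = None) -> PresenceSeries:
    """Binary presence of ``subject`` in ``roi`` from a session log.

    Frame resolution: unit f is 1 iff the log has at least one record with
    ``id == subject`` whose ``rois`` include ``roi`` at frame f.  Second
    resolution: 1 iff any such frame falls within that second.  The series
    spans frames 0..n_frames-1 (n_frames defaults to max logged frame + 1).
    """
    if resolution not in ("frame", "second"):
        raise ValueError("resolution must be 'frame' or 'second'")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    hits = log[log["id"] == subject]
    frames = []
    for _, row in hits.iterrows():
        roi_field = row["rois"]
        if isinstance(roi_field, (list, tuple)):
            members = [int(i) for i in roi_field]
        else:
            members = [int(i) for i in str(roi_field).split(";") if i != ""]
        if roi in members:
            frames.append(int(row["frame"]))
    if n_frames is None:
        n_frames = (int(log["frame"].max()) + 1) if len(log) else 0
    frame_vals = np.zeros(n_frames, dtype=np.uint8)
    for f in frames:
        if 0 <= f < n_frames:
            frame_vals[f] = 1
    series = PresenceSeries(subject=subject, roi=roi, resolution="frame",
                            values=frame_vals, start=0, rate=rate)
    if resolution == "second":
        return frame_to_second(series)
    return series


def frame_to_second(series: PresenceSeries) -> PresenceSeries:
    """Downsample a frame series to seconds by the any-presence rule.

    A second is marked present iff at least one of its frames is present,
    so downsampling never creates presence where none existed.
    """
    if series.resolution != "frame":
        return series
    fpb = int(round(series.rate))
    n = len(series.values)
    n_sec = int(np.ceil((series.start + n) / fpb)) - series.start // fpb if n else 0
    sec_start = series.start // fpb
    out = np.zeros(max(n_sec, 0), dtype=np.uint8)
    for i, v in enumerate(series.values):
        if v:
            out[(series.start + i) // fpb - sec_start] = 1
    return PresenceSeries(subject=series.subject, roi=series.roi,
                          resolution="second", values=out, start=sec_start,
                          rate=series.rate)


def segment_bouts(series: PresenceSeries,
                  gap_threshold: int | None = None) -> list[BehaviourBout]:
    """Merge presence runs into bouts using the disengagement-gap rule.

    Runs separated by a gap strictly smaller than ``gap_threshold`` units
    belong to one bout; a gap of at least the threshold starts a new bout.
    Bout start/end are inclusive unit indices of actual presence (gaps
    inside a bout are bridged but do not extend its ends).  Defaults to
    1800 frames or 60 seconds depending on resolution.
    """
    if gap_threshold is None:
        gap_threshold = series.default_gap
    if gap_threshold <= 0:
        raise ValueError("gap_threshold must be > 0")
    idx = np.flatnonzero(series.values) + series.start
    if len(idx) == 0:
        return []
    bouts: list[BehaviourBout] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        gap = i - prev - 1
        if gap >= gap_threshold:
            bouts.append(BehaviourBout(series.subject, series.roi, start, prev))
            start = i
        prev = i
    bouts.append(BehaviourBout(series.subject, series.roi, start, prev))
    return bouts


def summarize(bouts: list[BehaviourBout], bin: str = "day",
              unit_seconds: float = 1.0) -> pd.DataFrame:
    """Per-bin bout counts and total in-bout durations.

    ``bin`` is "day" or "hour"; bout units are converted to seconds via
    ``unit_seconds`` (1/fps for frame series, 1 for second series).  A bout
    straddling a bin boundary is split with its duration conserved across
    bins.  Columns: subject, roi, bin, bout_count, duration_s, first_start_s,
    last_end_s.
    """
    if bin not in ("day", "hour"):
        raise ValueError("bin must be 'day' or 'hour'")
    bin_s = 86400.0 if bin == "day" else 3600.0
    rows: dict[tuple, dict] = {}
    for b in bouts:
        t0 = b.start * unit_seconds
        t1 = (b.end + 1) * unit_seconds  # exclusive end in seconds
        first_bin = int(t0 // bin_s)
        seg_start = t0
        for k in range(first_bin, int(np.ceil(t1 / bin_s))):
            seg_end = min(t1, (k + 1) * bin_s)
            key = (b.subject, b.roi, k)
            row = rows.setdefault(key, {"subject": b.subject, "roi": b.roi,
                                        "bin": k, "bout_count": 0,
                                        "duration_s": 0.0,
                                        "first_start_s": seg_start,
                                        "last_end_s": seg_end})
            if k == first_bin:
                row["bout_count"] += 1  # a split bout counts once, in its start bin
            row["duration_s"] += seg_end - seg_start
            row["first_start_s"] = min(row["first_start_s"], seg_start)
            row["last_end_s"] = max(row["last_end_s"], seg_end)
            seg_start = seg_end
    cols = ["subject", "roi", "bin", "bout_count", "duration_s",
            "first_start_s", "last_end_s"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return (pd.DataFrame(list(rows.values()), columns=cols)
            .sort_values(["subject", "roi", "bin"]).reset_index(drop=True))
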