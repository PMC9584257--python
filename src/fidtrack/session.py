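"""Session driver: run detection over a frame source and log events.

Two deployment modes mirror the two field workflows:

* **post-event** — offline analysis of stored footage.  Every frame is
  analyzed, in order, and the log is a pure function of the input, so two
  runs over the same clip produce byte-identical CSVs.  Timestamps are media
  time (frame / fps).
* **real-time** — live monitoring where temporal currency outranks
  completeness.  The processor always takes the *newest* available frame;
  frames that arrived while it was busy are dropped and counted.  Log rows
  are flushed incrementally so a session interrupted mid-stream (e.g. power
  loss) still leaves a valid partial log.

Log schema (CSV): ``frame,timestamp,id,x,y,rois`` with ``rois`` the
semicolon-joined ROI indices, empty when the detection lies in none.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .codec import MarkerDictionary
from .detector import DetectorParams, MarkerDetection, detect_markers
from .roi import RegionOfInterest, assign_rois

__all__ = [
    "DetectionRecord",
    "SessionReport",
    "LOG_COLUMNS",
    "run_post_event",
    "run_real_time",
    "annotate_frame",
    "open_frames",
    "write_log",
    "read_log",
]

LOG_COLUMNS = ["frame", "timestamp", "id", "x", "y", "rois"]


@dataclass(frozen=True)
class DetectionRecord:
    """One logged detection: frame count, timestamp, id, center, ROI hits."""

    frame: int
    timestamp: float
    id: int
    x: float
    y: float
    rois: tuple[int, ...] = ()

    def to_row(self) -> str:
        roi_str = ";".join(str(i) for i in self.rois)
        return (f"{self.frame},{self.timestamp:.3f},{self.id},"
                f"{self.x:.2f},{self.y:.2f},{roi_str}")


@dataclass
class SessionReport:
    mode: str
    frames_total: int = 0
    frames_analyzed: int = 0
    frames_dropped: int = 0
    start_time: float = 0.0
    end_time: float = 0.0
    truncated: bool = False

    def validate(self) -> None:
        if self.mode == "post_event":
            assert self.frames_analyzed == self.frames_total
            assert self.frames_dropped == 0
        else:
            assert self.frames_analyzed + self.frames_dropped == self.frames_total

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def open_frames(source):
    """Yield grayscale/RGB frames from a source.

    Accepts: a directory of numbered PNG frames, a single image file, an
    iterable of ndarrays, or a video file readable by an installed imageio
    plugin.  Raises ``IOError`` for unreadable paths.
    """
    import imageio.v3 as iio

    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.is_dir():
            for f in sorted(p.glob("*.png")) or sorted(p.glob("*.jpg")):
                yield iio.imread(f)
            return
        if not p.exists():
            raise IOError(f"unreadable frame source: {p}")
        if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff"):
            yield iio.imread(p)
            return
        # container formats need an ffmpeg-backed plugin
        for frame in iio.imiter(p):
            yield frame
        return
    yield from source


def _records_for_frame(frame_idx: int, timestamp: float,
                       detections: list[MarkerDetection],
                       rois: list[RegionOfInterest]) -> list[DetectionRecord]:
    records = []
    for det in detections:
        cx, cy = det.center
        records.append(DetectionRecord(
            frame=frame_idx, timestamp=timestamp, id=det.id,
            x=cx, y=cy, rois=tuple(assign_rois((cx, cy), rois))))
    return records


def run_post_event(source, dictionary: MarkerDictionary,
                   rois: list[RegionOfInterest],
                   params: DetectorParams | None = None,
                   fps: float = 30.0,
                   log_path=None,
                   annotate_dir=None) -> tuple[pd.DataFrame, SessionReport]:
    """Analyze every frame of a stored clip in order.

    Returns the detection log as a DataFrame plus a SessionReport with
    ``frames_analyzed == frames_total``.  Output is deterministic for a
    fixed input.  Corrupt frames are skipped with a note but still counted
    as analyzed attempts only if decodable; unreadable sources raise.
    """
    params = params or DetectorParams()
    records: list[DetectionRecord] = []
    n = 0
    for frame in open_frames(source):
        t = n / fps
        dets = detect_markers(frame, dictionary, params)
        records.extend(_records_for_frame(n, t, dets, rois))
        if annotate_dir is not None:
            out = annotate_frame(frame, dets, rois)
            _write_png(Path(annotate_dir) / f"frame_{n:06d}.png", out)
        n += 1
    report = SessionReport(mode="post_event", frames_total=n,
                           frames_analyzed=n, frames_dropped=0,
                           start_time=0.0, end_time=(n - 1) / fps if n else 0.0)
    report.validate()
    log = records_to_frame(records)
    if log_path is not None:
        write_log(log, log_path)
    return log, report


def run_real_time(stream, dictionary: MarkerDictionary,
                  rois: list[RegionOfInterest],
                  params: DetectorParams | None = None,
                  processing_time=0.0,
                  log_file=None) -> tuple[pd.DataFrame, SessionReport]:
    """Process a live stream, always taking the newest available frame.

    ``stream`` yields ``(frame, arrival_time)`` pairs with non-decreasing
    arrival times.  ``processing_time`` is the per-frame cost in the same
    time units — a float or a callable ``f(frame) -> float`` — driving a
    discrete-event clock: while the processor is busy, arriving frames
    queue up, and on becoming free it processes only the most recent one,
    dropping the rest.  Rows are flushed to ``log_file`` (path or file
    object) as they are produced, so a partial log is always valid.  A
    stream that raises mid-iteration ends the session with ``truncated``
    set and whatever was logged so far.
    """
    params = params or DetectorParams()
    cost = processing_time if callable(processing_time) else (lambda _f: processing_time)
    records: list[DetectionRecord] = []
    report = SessionReport(mode="real_time")

    own_handle = False
    fh = None
    if log_file is not None:
        if isinstance(log_file, (str, Path)):
            fh = open(log_file, "w")
            own_handle = True
        else:
            fh = log_file
        fh.write(",".join(LOG_COLUMNS) + "\n")
        fh.flush()

    free_at = -np.inf
    pending: tuple[np.ndarray, float, int] | None = None  # frame, t, index
    n_seen = 0
    first_t = None

    def process(frame, t, idx):
        nonlocal free_at
        dets = detect_markers(frame, dictionary, params)
        new = _records_for_frame(idx, t, dets, rois)
        records.extend(new)
        if fh is not None:
            for r in new:
                fh.write(r.to_row() + "\n")
            fh.flush()
        report.frames_analyzed += 1
        free_at = max(free_at, t) + cost(frame)
        report.end_time = t

    try:
        for frame, t in stream:
            if first_t is None:
                first_t = t
                report.start_time = t
            n_seen += 1
            idx = n_seen - 1
            if t >= free_at:
                # processor idle: flush any stale pending frame first
                if pending is not None:
                    report.frames_dropped += 1  # superseded before processing
                    pending = None
                process(frame, t, idx)
            else:
                # busy: this frame supersedes any previously pending one
                if pending is not None:
                    report.frames_dropped += 1
                pending = (frame, t, idx)
        if pending is not None:
            process(pending[0], max(pending[1], free_at), pending[2])
            pending = None
    except Exception:
        report.truncated = True
        if pending is not None:
            report.frames_dropped += 1
            pending = None
    finally:
        if own_handle and fh is not None:
            fh.close()

    report.frames_total = n_seen
    report.validate()
    return records_to_frame(records), report


def records_to_frame(records: list[DetectionRecord]) -> pd.DataFrame:
    rows = [{"frame": r.frame, "timestamp": round(r.timestamp, 3), "id": r.id,
             "x": round(r.x, 2), "y": round(r.y, 2),
             "rois": ";".join(str(i) for i in r.rois)} for r in records]
    df = pd.DataFrame(rows, columns=LOG_COLUMNS)
    return df.sort_values(["frame", "id"], kind="stable").reset_index(drop=True)


def write_log(log: pd.DataFrame, path) -> None:
    buf = io.StringIO()
    buf.write(",".join(LOG_COLUMNS) + "\n")
    for _, r in log.iterrows():
        roi_str = r["rois"] if isinstance(r["rois"], str) else ""
        buf.write(f"{int(r['frame'])},{float(r['timestamp']):.3f},{int(r['id'])},"
                  f"{float(r['x']):.2f},{float(r['y']):.2f},{roi_str}\n")
    Path(path).write_text(buf.getvalue())


def read_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"rois": str}, keep_default_na=False)
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"log missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_frame(frame: np.ndarray, detections: list[MarkerDetection],
                   rois: list[RegionOfInterest]) -> np.ndarray:
    """Overlay ROI rectangles and detection quads with "id=[N]" labels.

    Returns a new RGB image; the input frame is untouched.
    """
    from PIL import Image, ImageDraw

    arr = np.asarray(frame)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.dtype != np.uint8:
        arr = np.clip(arr * 255 if arr.max() <= 1.5 else arr, 0, 255).astype(np.uint8)
    img = Image.fromarray(arr.copy())
    draw = ImageDraw.Draw(img)
    for roi in rois:
        draw.rectangle([roi.x, roi.y, roi.x + roi.width, roi.y + roi.height],
                       outline=(0, 200, 255), width=1)
        draw.text((roi.x + 2, roi.y + 2), f"ROI {roi.index} [{roi.label}]",
                  fill=(0, 200, 255))
    for det in detections:
        pts = [tuple(p) for p in det.corners]
        draw.polygon(pts, outline=(0, 255, 0))
        cx, cy = det.center
        draw.text((cx + 4, cy + 4), f"id=[{det.id}]", fill=(0, 255, 0))
    return np.asarray(img)


def _write_png(path, image: np.ndarray) -> None:
    from PIL import Image

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image).save(path)
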