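"""Regions of interest: labelled pixel rectangles around physical resources.

A detection is attributed to a resource when the marker *center* falls
inside the resource's rectangle.  Rectangles are axis-aligned and static for
a session; users are expected to size them so that the collar marker of an
animal using the resource lands inside.  Containment is half-open on the
right and bottom edges so that adjacent, touching rectangles partition the
plane without double counting on the shared edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "RegionOfInterest",
    "point_in_roi",
    "assign_rois",
    "validate_layout",
    "load_rois",
    "save_rois",
]


@dataclass(frozen=True)
class RegionOfInterest:
    index: int
    label: str
    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"ROI {self.index}: width and height must be > 0")


def point_in_roi(point: tuple[float, float], roi: RegionOfInterest) -> bool:
    """True iff x in [rx, rx+w) and y in [ry, ry+h)."""
    px, py = point
    return (roi.x <= px < roi.x + roi.width) and (roi.y <= py < roi.y + roi.height)


def assign_rois(center: tuple[float, float],
                rois: list[RegionOfInterest]) -> list[int]:
    """Indices of all ROIs containing the point, ascending.

    Accepts either a bare (x, y) point or any object with a ``center``
    attribute (e.g. a MarkerDetection).  Multiple indices occur when ROIs
    overlap or a marker sits in the intersection of close rectangles.
    """
    if hasattr(center, "center"):
        center = center.center
    return sorted(r.index for r in rois if point_in_roi(center, r))


def _rect_gap(a: RegionOfInterest, b: RegionOfInterest) -> float:
    """Euclidean gap between two rectangles; 0 when touching, < 0 never."""
    dx = max(a.x - (b.x + b.width), b.x - (a.x + a.width), 0.0)
    dy = max(a.y - (b.y + b.height), b.y - (a.y + a.height), 0.0)
    return (dx * dx + dy * dy) ** 0.5


def _overlaps(a: RegionOfInterest, b: RegionOfInterest) -> bool:
    return (a.x < b.x + b.width and b.x < a.x + a.width
            and a.y < b.y + b.height and b.y < a.y + a.height)


def validate_layout(rois: list[RegionOfInterest],
                    min_separation: float = 0.0) -> list[str]:
    """Warn about ROI pairs that overlap or sit closer than ``min_separation``.

    Resources placed too close to one another cause detections in the
    neighbouring region while the animal uses a different one, so layouts
    should keep an adequate gap between rectangles.
    """
    warnings: list[str] = []
    for i, a in enumerate(rois):
        for b in rois[i + 1:]:
            if _overlaps(a, b):
                warnings.append(
                    f"ROI {a.index} [{a.label}] overlaps ROI {b.index} [{b.label}]")
            else:
                gap = _rect_gap(a, b)
                if gap < min_separation:
                    warnings.append(
                        f"ROI {a.index} [{a.label}] is only {gap:.1f} px from "
                        f"ROI {b.index} [{b.label}] (< {min_separation:g} px)")
    return warnings


def load_rois(path) -> list[RegionOfInterest]:
    """Read ROIs from a YAML/JSON config: a list of {index, label, x, y, w, h}."""
    data = yaml.safe_load(Path(path).read_text())
    items = data["rois"] if isinstance(data, dict) else data
    rois = []
    for item in items:
        rois.append(RegionOfInterest(
            index=int(item["index"]), label=str(item.get("label", "")),
            x=float(item["x"]), y=float(item["y"]),
            width=float(item.get("w", item.get("width"))),
            height=float(item.get("h", item.get("height")))))
    return sorted(rois, key=lambda r: r.index)


def save_rois(rois: list[RegionOfInterest], path) -> None:
    items = [{"index": r.index, "label": r.label, "x": r.x, "y": r.y,
              "w": r.width, "h": r.height} for r in rois]
    Path(path).write_text(yaml.safe_dump({"rois": items}, sort_keys=False))
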