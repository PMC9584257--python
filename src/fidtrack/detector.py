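"""Detection and decoding of square fiducial markers in single frames.

Pipeline: adaptive-mean thresholding -> dark-blob contour extraction ->
polygon simplification to convex quadrilaterals -> perspective unwarp ->
cell sampling -> dictionary matching under all four rotations with a bounded
error-correction budget.  A marker is only accepted if its black border ring
is intact and a white quiet zone is visible around it; a marker flush
against a dark background is therefore rejected, which mirrors the physical
deployment constraint that the white edge of the collar sticker must be
visible to the camera.

Coordinates are pixels, origin top-left, x rightward, y downward, sub-pixel
floats.  Corner localization is refined by fitting total-least-squares lines
to the contour points of each quad edge and intersecting adjacent lines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.transform import ProjectiveTransform, warp

from .codec import MarkerDictionary, rotate_code

logger = logging.getLogger(__name__)

__all__ = [
    "DetectorParams",
    "MarkerDetection",
    "detect_markers",
    "threshold_image",
    "extract_quads",
    "decode_quad",
    "to_grayscale",
]

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def estimate_projective(src: np.ndarray, dst: np.ndarray) -> ProjectiveTransform | None:
    """4-point homography estimate; None when degenerate."""
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(src, dst)
        return tf if tf else None
    tf = ProjectiveTransform()
    return tf if tf.estimate(src, dst) else None


@dataclass
class DetectorParams:
    """Tunable detector parameters; defaults suit markers >= ~30 px across.

    adaptive_window      sliding-window side for adaptive mean threshold (px)
    adaptive_c_frac      threshold offset as a fraction of the frame's
                         intensity range (keeps the binarization invariant
                         under affine intensity scaling with positive gain)
    min_area_frac        minimum candidate-quad area as a fraction of frame area
    max_area_frac        maximum candidate-quad area fraction
    approx_tol_frac      polygon simplification tolerance, fraction of perimeter
    aspect_max           maximum ratio of longest to shortest quad side
    min_corner_angle_deg reject quads with a sharper interior corner
    quad_fit_max_px      reject candidates whose contour strays farther
                         than this from the fitted quad (marker borders are
                         straight; noise blobs are jagged)
    unwarp_cell_px       canonical cell size used when unwarping a candidate
    cell_sample_frac     central fraction of each cell sampled for its bit
    max_hamming          error-correction budget; None -> floor((min_dist-1)/2)
    quiet_zone_min_frac  minimum fraction of outer-ring samples that must be
                         white for the quiet-zone check to pass
    """

    adaptive_window: int = 15
    adaptive_c_frac: float = 0.05
    min_area_frac: float = 1e-4
    max_area_frac: float = 0.4
    approx_tol_frac: float = 0.03
    aspect_max: float = 2.5
    min_corner_angle_deg: float = 35.0
    quad_fit_max_px: float = 1.5
    unwarp_cell_px: int = 12
    cell_sample_frac: float = 0.5
    max_hamming: int | None = None
    quiet_zone_min_frac: float = 0.75

    def correction_budget(self, min_distance: int) -> int:
        if self.max_hamming is not None:
            return self.max_hamming
        return max(0, (min_distance - 1) // 2)


@dataclass
class MarkerDetection:
    """One decoded marker: id, its quad corners and center, bit errors.

    ``corners`` are 4 (x, y) points ordered clockwise starting from the
    decoded top-left of the marker content; ``center`` is their mean.
    """

    id: int
    corners: np.ndarray
    hamming: int
    orientation: int = 0

    @property
    def center(self) -> tuple[float, float]:
        c = self.corners.mean(axis=0)
        return float(c[0]), float(c[1])


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert a frame to float grayscale in [0, 1]."""
    frame = np.asarray(frame)
    if frame.ndim == 3:
        frame = frame[..., :3] @ _LUMA
    frame = frame.astype(np.float64)
    if frame.max() > 1.5:  # assume 8-bit input
        frame = frame / 255.0
    return frame


def threshold_image(frame: np.ndarray, params: DetectorParams | None = None) -> np.ndarray:
    """Adaptive mean binarization; returns a {0, 1} uint8 image (1 = light).

    A pixel is dark (0) when it falls below its local window mean minus an
    offset proportional to the frame's global intensity range, which makes
    the output invariant under affine intensity maps with positive gain.
    Falls back to a global threshold (with a warning) if the window exceeds
    the frame.
    """
    params = params or DetectorParams()
    gray = to_grayscale(frame)
    if gray.size == 0:
        raise ValueError("empty frame")
    span = float(gray.max() - gray.min())
    c = params.adaptive_c_frac * span
    w = params.adaptive_window
    if w >= min(gray.shape):
        logger.warning("adaptive window %d exceeds frame %s; using global "
                       "threshold", w, gray.shape)
        thr = gray.mean() - c
        return (gray >= thr).astype(np.uint8)
    local_mean = ndimage.uniform_filter(gray, size=w, mode="nearest")
    return (gray >= local_mean - c).astype(np.uint8)


# ---------------------------------------------------------------------------
# quad extraction
# ---------------------------------------------------------------------------

def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _is_convex(quad: np.ndarray) -> bool:
    d = np.roll(quad, -1, axis=0) - quad
    cross = d[:, 0] * np.roll(d, -1, axis=0)[:, 1] - d[:, 1] * np.roll(d, -1, axis=0)[:, 0]
    return bool(np.all(cross > 0) or np.all(cross < 0))


def _max_contour_deviation(contour_xy: np.ndarray, quad: np.ndarray) -> float:
    """Largest distance from any contour point to the nearest quad edge."""
    dists = np.full(len(contour_xy), np.inf)
    for i in range(4):
        a, b = quad[i], quad[(i + 1) % 4]
        ab = b - a
        L2 = float(ab @ ab)
        if L2 < 1e-12:
            continue
        t = np.clip((contour_xy - a) @ ab / L2, 0.0, 1.0)
        proj = a + t[:, None] * ab
        dists = np.minimum(dists, np.hypot(*(contour_xy - proj).T))
    return float(dists.max())


def _min_corner_angle(quad: np.ndarray) -> float:
    """Smallest interior angle of a quadrilateral, radians."""
    angles = []
    for i in range(4):
        a, b, c = quad[i - 1], quad[i], quad[(i + 1) % 4]
        u, v = a - b, c - b
        cosang = (u @ v) / max(np.hypot(*u) * np.hypot(*v), 1e-12)
        angles.append(np.arccos(np.clip(cosang, -1, 1)))
    return min(angles)


def _order_clockwise(quad: np.ndarray) -> np.ndarray:
    """Order corners clockwise in image coordinates (y down)."""
    c = quad.mean(axis=0)
    ang = np.arctan2(quad[:, 1] - c[1], quad[:, 0] - c[0])
    order = np.argsort(ang)  # with y down, increasing angle is clockwise
    return quad[order]


def _simplify_to_quad(contour_xy: np.ndarray, tol: float) -> np.ndarray | None:
    """Douglas-Peucker simplification of a closed contour; return 4 corners
    or None if the contour does not reduce to a quadrilateral."""
    pts = measure.approximate_polygon(contour_xy, tolerance=tol)
    if len(pts) and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # the contour's arbitrary start point is always kept as a vertex; prune
    # vertices that are nearly collinear with their neighbours
    while len(pts) > 4:
        devs = []
        for i in range(len(pts)):
            a, b, c = pts[i - 1], pts[i], pts[(i + 1) % len(pts)]
            ac = c - a
            ab = b - a
            L = np.hypot(*ac)
            dev = abs(ac[0] * ab[1] - ac[1] * ab[0]) / L if L > 1e-9 else 0.0
            devs.append(dev)
        i_min = int(np.argmin(devs))
        if devs[i_min] > tol:
            break
        pts = np.delete(pts, i_min, axis=0)
    if len(pts) != 4:
        return None
    return pts


def _refine_corners(contour_xy: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Sub-pixel corner refinement: fit a TLS line to the contour points of
    each edge (dropping points near corners) and intersect adjacent lines."""
    n = len(quad)
    lines = []
    for i in range(n):
        a, b = quad[i], quad[(i + 1) % n]
        ab = b - a
        L = np.hypot(*ab)
        if L < 1e-9:
            return quad
        u = ab / L
        rel = contour_xy - a
        t = rel @ u
        perp = np.abs(rel @ np.array([-u[1], u[0]]))
        sel = (t > 0.15 * L) & (t < 0.85 * L) & (perp < max(2.0, 0.08 * L))
        pts = contour_xy[sel]
        if len(pts) < 4:
            lines.append(None)
            continue
        mean = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - mean, full_matrices=False)
        d = vt[0]  # direction of the edge
        nvec = np.array([-d[1], d[0]])
        lines.append((nvec, float(nvec @ mean)))  # n.x = c
    refined = quad.astype(np.float64).copy()
    for i in range(n):
        l1, l2 = lines[(i - 1) % n], lines[i]
        if l1 is None or l2 is None:
            continue
        A = np.vstack([l1[0], l2[0]])
        b = np.array([l1[1], l2[1]])
        det = np.linalg.det(A)
        if abs(det) < 1e-9:
            continue
        p = np.linalg.solve(A, b)
        if np.hypot(*(p - quad[i])) < 5.0:  # guard against wild intersections
            refined[i] = p
    return refined


def extract_quads(binary: np.ndarray, params: DetectorParams | None = None
                  ) -> list[np.ndarray]:
    """Find convex quadrilateral outlines of dark regions in a binary image.

    Returns a list of (4, 2) float arrays of (x, y) corners ordered
    clockwise, filtered by area fraction and side-aspect bounds.
    """
    params = params or DetectorParams()
    binary = np.asarray(binary)
    frame_area = binary.shape[0] * binary.shape[1]
    quads: list[np.ndarray] = []
    # contours of the dark regions at the 0.5 level; rows are (row, col)
    for contour in measure.find_contours(binary.astype(float), 0.5):
        if len(contour) < 8 or not np.allclose(contour[0], contour[-1]):
            continue
        xy = contour[:, ::-1]  # -> (x, y)
        perim = float(np.hypot(*np.diff(xy, axis=0).T).sum())
        quad = _simplify_to_quad(xy, params.approx_tol_frac * perim)
        if quad is None or not _is_convex(quad):
            continue
        quad = _order_clockwise(_refine_corners(xy[:-1], _order_clockwise(quad)))
        if not _is_convex(quad):
            continue
        area = abs(_polygon_area(quad))
        if not (params.min_area_frac * frame_area <= area
                <= params.max_area_frac * frame_area):
            continue
        sides = np.hypot(*np.diff(np.vstack([quad, quad[:1]]), axis=0).T)
        if sides.min() < 3 or sides.max() / sides.min() > params.aspect_max:
            continue
        if _min_corner_angle(quad) < np.deg2rad(params.min_corner_angle_deg):
            continue
        if _max_contour_deviation(xy[:-1], quad) > params.quad_fit_max_px:
            continue
        quads.append(quad)
    return quads


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _sample_cells(patch: np.ndarray, n_cells: int, cell_px: int,
                  frac: float) -> np.ndarray:
    """Majority-sample each cell over its central ``frac`` area; 1 = light."""
    thr = patch.mean()
    lo, hi = patch.min(), patch.max()
    if hi - lo > 1e-6:
        thr = 0.5 * (lo + hi)
    m = int(round(cell_px * (1 - frac) / 2))
    bits = np.zeros((n_cells, n_cells), dtype=np.uint8)
    for r in range(n_cells):
        for c in range(n_cells):
            cell = patch[r * cell_px + m:(r + 1) * cell_px - m,
                         c * cell_px + m:(c + 1) * cell_px - m]
            bits[r, c] = 1 if cell.mean() > thr else 0
    return bits


def decode_quad(frame: np.ndarray, quad: np.ndarray, dictionary: MarkerDictionary,
                params: DetectorParams | None = None
                ) -> tuple[int, int, int] | None:
    """Unwarp a candidate quad and match its bits against the dictionary.

    Returns ``(id, hamming, orientation)`` with orientation in quarter turns
    clockwise, or ``None`` on rejection (broken border ring, missing white
    quiet zone, distance above the correction budget, or a tie between two
    code words).
    """
    params = params or DetectorParams()
    gray = to_grayscale(frame)
    gs = dictionary.grid_size
    u = params.unwarp_cell_px
    side_cells = gs + 2          # data grid + border ring
    ext_cells = side_cells + 2   # + one quiet-zone ring for the white check
    side = ext_cells * u
    # map the quad (border outline) to the inner (side_cells x side_cells)
    # region of the extended canonical square
    dst = np.array([[u, u], [side - u, u], [side - u, side - u], [u, side - u]],
                   dtype=np.float64)
    tf = estimate_projective(dst, np.asarray(quad, dtype=np.float64))
    if tf is None:
        return None
    patch = warp(gray, tf, output_shape=(side, side), order=1, mode="edge")
    cells = _sample_cells(patch, ext_cells, u, params.cell_sample_frac)

    # white quiet zone must surround the border ring
    ring = np.concatenate([cells[0, :], cells[-1, :], cells[1:-1, 0], cells[1:-1, -1]])
    if ring.mean() < params.quiet_zone_min_frac:
        return None
    inner = cells[1:-1, 1:-1]
    # border ring must be entirely black
    border = np.concatenate([inner[0, :], inner[-1, :], inner[1:-1, 0], inner[1:-1, -1]])
    if border.any():
        return None
    grid = inner[1:-1, 1:-1]

    budget = params.correction_budget(dictionary.min_distance)
    matches = [(int((grid != rotate_code(code.bits, r)).sum()), code.id, r)
               for code in dictionary.codes for r in range(4)]
    matches.sort()
    d, marker_id, r = matches[0]
    if d > budget:
        return None
    if len(matches) > 1 and matches[1][0] == d:  # ambiguous match
        return None
    return marker_id, d, r


def _dedup(detections: list[MarkerDetection]) -> list[MarkerDetection]:
    """Suppress duplicate quads for the same physical marker: keep the
    lowest-hamming, then largest-area detection among overlapping quads."""
    kept: list[MarkerDetection] = []
    for det in sorted(detections,
                      key=lambda d: (d.hamming, -abs(_polygon_area(d.corners)))):
        cx, cy = det.center
        size = math.sqrt(abs(_polygon_area(det.corners)))
        dup = False
        for k in kept:
            kx, ky = k.center
            ksize = math.sqrt(abs(_polygon_area(k.corners)))
            if math.hypot(cx - kx, cy - ky) < 0.5 * max(size, ksize):
                dup = True
                break
        if not dup:
            kept.append(det)
    return kept


def detect_markers(frame: np.ndarray, dictionary: MarkerDictionary,
                   params: DetectorParams | None = None
                   ) -> list[MarkerDetection]:
    """Detect and decode all dictionary markers in a frame.

    Results are deterministic: sorted by id, then center y, then center x.
    Returns an empty list when nothing is found.
    """
    params = params or DetectorParams()
    frame = np.asarray(frame)
    if frame.size == 0 or frame.ndim not in (2, 3):
        raise ValueError("malformed frame")
    if len(dictionary) == 0:
        raise ValueError("empty dictionary")
    binary = threshold_image(frame, params)
    detections: list[MarkerDetection] = []
    for quad in extract_quads(binary, params):
        decoded = decode_quad(frame, quad, dictionary, params)
        if decoded is None:
            continue
        marker_id, hamming, orientation = decoded
        # roll so corners[0] is the decoded top-left of the marker content
        corners = np.roll(quad, -orientation, axis=0)
        detections.append(MarkerDetection(id=marker_id, corners=corners,
                                          hamming=hamming,
                                          orientation=orientation))
    detections = _dedup(detections)
    detections.sort(key=lambda d: (d.id, d.center[1], d.center[0]))
    return detections
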