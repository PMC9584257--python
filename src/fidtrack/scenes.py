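"""Synthetic ground-truth scenes: rendered marker video plus known truth.

Every downstream module is testable without any camera footage: markers of
known id are warped onto a textured background at known poses, degraded by
sensor noise, blur, illumination changes and "fur" occlusion (opaque
soft-edged ellipses over part of the code, emulating a long coat blocking
the sticker), and the exact per-frame geometry, ROI membership and latent
behaviour state (actively using the resource vs merely present in the ROI)
are recorded alongside.  A seeded coder simulator corrupts the latent truth
with miss / false-alarm / boundary-jitter errors to emulate human coding.

All generation is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import ProjectiveTransform, warp

from .codec import MarkerDictionary, render_marker
from .roi import RegionOfInterest, assign_rois

__all__ = [
    "Pose",
    "TrackSegment",
    "SceneSpec",
    "GroundTruth",
    "place_marker",
    "pose_transform",
    "border_quad",
    "generate_scene",
    "simulate_coder",
    "expected_kappa",
    "failure_fixtures",
]

_QUIET_CELLS = 1
_BORDER_CELLS = 1


@dataclass(frozen=True)
class Pose:
    """Marker pose in the frame: center (px), side of the black border
    square (px), in-plane rotation (deg, clockwise) and out-of-plane tilt
    (deg) about the horizontal axis through the center."""

    center: tuple[float, float]
    side: float = 48.0
    rotation_deg: float = 0.0
    tilt_deg: float = 0.0


@dataclass(frozen=True)
class TrackSegment:
    """One span of a subject's trajectory: frames [start, end) at ``pose``
    (linearly interpolated to ``pose_end`` when given).  ``using`` marks the
    latent behaviour state — True only while the subject actively uses the
    resource; a subject can be present in an ROI without using it."""

    start: int
    end: int
    pose: Pose
    pose_end: Pose | None = None
    using: bool = False
    occluded_frac: float = 0.0


@dataclass
class SceneSpec:
    """Full description of a synthetic monitoring session."""

    frame_shape: tuple[int, int] = (240, 320)  # rows, cols
    fps: float = 30.0
    n_frames: int = 60
    rois: list[RegionOfInterest] = field(default_factory=list)
    tracks: dict[int, list[TrackSegment]] = field(default_factory=dict)  # marker id -> segments
    noise_sigma: float = 0.0
    blur_sigma: float = 0.0
    illumination_gain: float = 1.0
    illumination_offset: float = 0.0
    background_level: float = 0.78
    seed: int = 0


@dataclass
class GroundTruth:
    """Per-frame truth: visible markers with geometry and ROI membership,
    plus the latent per-subject behaviour state."""

    frames: pd.DataFrame      # frame, id, cx, cy, corners (8 floats), rois, occluded_frac
    behaviour: pd.DataFrame   # frame, id, present_roi, using

    def visible_ids(self, frame: int) -> list[int]:
        sub = self.frames[self.frames["frame"] == frame]
        return sorted(int(i) for i in sub["id"])


def pose_transform(pose: Pose, marker_px: int, grid_size: int = 4) -> ProjectiveTransform:
    """Homography mapping rendered-marker pixel coords to frame coords.

    The rendered marker (quiet zone included) spans ``marker_px`` square;
    the pose's ``side`` refers to the black border square, which occupies
    the central fraction of the render.  Tilt is a rotation about the
    horizontal axis through the marker center, pinhole-projected with focal
    length 2x the marker side, producing mild perspective foreshortening.
    """
    side_cells = grid_size + 2 * _BORDER_CELLS + 2 * _QUIET_CELLS
    border_cells = grid_size + 2 * _BORDER_CELLS
    full_side = pose.side * side_cells / border_cells

    half = marker_px / 2.0
    corners = np.array([[-half, -half], [half, -half],
                        [half, half], [-half, half]])
    scale = full_side / marker_px
    pts3 = np.column_stack([corners * scale, np.zeros(4)])
    tilt = np.deg2rad(pose.tilt_deg)
    rot = np.deg2rad(pose.rotation_deg)
    # tilt about x axis, then in-plane rotation, then project
    Rx = np.array([[1, 0, 0],
                   [0, np.cos(tilt), -np.sin(tilt)],
                   [0, np.sin(tilt), np.cos(tilt)]])
    Rz = np.array([[np.cos(rot), -np.sin(rot), 0],
                   [np.sin(rot), np.cos(rot), 0],
                   [0, 0, 1]])
    pts3 = pts3 @ Rx.T @ Rz.T
    f = 2.0 * full_side
    z = f + pts3[:, 2]
    proj = pts3[:, :2] * (f / z)[:, None]
    dst = proj + np.asarray(pose.center)
    src = np.array([[0, 0], [marker_px, 0], [marker_px, marker_px], [0, marker_px]],
                   dtype=float)
    from .detector import estimate_projective

    tf = estimate_projective(src, dst)
    if tf is None:
        raise ValueError("degenerate pose")
    return tf


def border_quad(pose: Pose, marker_px: int, grid_size: int = 4) -> np.ndarray:
    """Frame coordinates of the black border square's outer corners,
    clockwise from the marker's canonical top-left — the quad a detector
    should localize."""
    tf = pose_transform(pose, marker_px, grid_size)
    side_cells = grid_size + 2 * _BORDER_CELLS + 2 * _QUIET_CELLS
    cell = marker_px / side_cells
    q = _QUIET_CELLS * cell
    src = np.array([[q, q], [marker_px - q, q],
                    [marker_px - q, marker_px - q], [q, marker_px - q]])
    return tf(src)


def place_marker(canvas: np.ndarray, marker_img: np.ndarray,
                 pose: Pose, grid_size: int = 4) -> np.ndarray:
    """Warp a rendered marker onto a float canvas in [0, 1] at ``pose``."""
    tf = pose_transform(pose, marker_img.shape[0], grid_size)
    m = marker_img.astype(np.float64) / 255.0
    warped = warp(m, tf.inverse, output_shape=canvas.shape, order=1, cval=0.0)
    mask = warp(np.ones_like(m), tf.inverse, output_shape=canvas.shape,
                order=1, cval=0.0)
    return canvas * (1 - mask) + warped * mask


def _interp_pose(a: Pose, b: Pose, t: float) -> Pose:
    return Pose(center=(a.center[0] + t * (b.center[0] - a.center[0]),
                        a.center[1] + t * (b.center[1] - a.center[1])),
                side=a.side + t * (b.side - a.side),
                rotation_deg=a.rotation_deg + t * (b.rotation_deg - a.rotation_deg),
                tilt_deg=a.tilt_deg + t * (b.tilt_deg - a.tilt_deg))


def _segment_at(segments: list[TrackSegment], frame: int
                ) -> tuple[TrackSegment, Pose] | None:
    for seg in segments:
        if seg.start <= frame < seg.end:
            if seg.pose_end is not None and seg.end - seg.start > 1:
                t = (frame - seg.start) / (seg.end - 1 - seg.start)
                return seg, _interp_pose(seg.pose, seg.pose_end, t)
            return seg, seg.pose
    return None


def _occlusion_mask(shape, quad: np.ndarray, frac: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Soft-edged opaque ellipse covering ~``frac`` of the marker quad."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    cx, cy = quad.mean(axis=0)
    side = np.sqrt(abs(_quad_area(quad)))
    # ellipse area = pi a b = frac * quad area -> pick aspect 1.6
    area = frac * abs(_quad_area(quad))
    aspect = 1.6
    b_ax = np.sqrt(area / (np.pi * aspect))
    a_ax = aspect * b_ax
    # anchor the ellipse at one edge of the quad so part of the code survives
    off = 0.5 * side * (1 - frac)
    mask = (((xx - cx) / max(a_ax, 1e-6)) ** 2
            + ((yy - (cy - off)) / max(b_ax, 1e-6)) ** 2) <= 1.0
    soft = ndimage.gaussian_filter(mask.astype(float), 1.0)
    return np.clip(soft, 0, 1)


def _quad_area(q: np.ndarray) -> float:
    x, y = q[:, 0], q[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def generate_scene(spec: SceneSpec, dictionary: MarkerDictionary,
                   marker_px: int = 96) -> tuple[list[np.ndarray], GroundTruth]:
    """Render all frames of a scene and the matching ground truth.

    Degradations are applied after compositing, in this order: occlusion
    ellipses, blur, illumination gain/offset, additive Gaussian noise.
    Frames are uint8 grayscale.  Raises if a pose pushes the marker outside
    a feasible size.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.frame_shape
    # textured background: smooth low-frequency field around background_level
    base = rng.normal(0, 1, size=(rows // 8 + 2, cols // 8 + 2))
    base = ndimage.zoom(base, 8, order=1)[:rows, :cols]
    background = np.clip(spec.background_level + 0.04 * base, 0, 1)

    renders = {mid: render_marker(dictionary, mid, cell_px=max(4, marker_px // 8))
               for mid in spec.tracks}
    truth_rows = []
    behaviour_rows = []
    frames = []
    for f in range(spec.n_frames):
        canvas = background.copy()
        occl_masks = []
        for mid, segments in sorted(spec.tracks.items()):
            hit = _segment_at(segments, f)
            if hit is None:
                continue
            seg, pose = hit
            marker_img = renders[mid]
            if pose.side >= min(rows, cols):
                raise ValueError("marker larger than frame")
            canvas = place_marker(canvas, marker_img, pose,
                                  dictionary.grid_size)
            quad = border_quad(pose, marker_img.shape[0], dictionary.grid_size)
            cx, cy = quad.mean(axis=0)
            rois_hit = assign_rois((float(cx), float(cy)), spec.rois)
            if seg.occluded_frac > 0:
                occl_masks.append(_occlusion_mask((rows, cols), quad,
                                                  seg.occluded_frac, rng))
            truth_rows.append({
                "frame": f, "id": mid, "cx": float(cx), "cy": float(cy),
                **{f"{ax}{i}": float(quad[i, j])
                   for i in range(4) for j, ax in enumerate("xy")},
                "rois": ";".join(str(i) for i in rois_hit),
                "occluded_frac": seg.occluded_frac,
            })
            behaviour_rows.append({
                "frame": f, "id": mid,
                "present_roi": rois_hit[0] if rois_hit else -1,
                "using": bool(seg.using),
            })
        for mask in occl_masks:
            canvas = canvas * (1 - mask) + 0.25 * mask  # dark "fur"
        if spec.blur_sigma > 0:
            canvas = ndimage.gaussian_filter(canvas, spec.blur_sigma)
        canvas = spec.illumination_gain * canvas + spec.illumination_offset
        if spec.noise_sigma > 0:
            canvas = canvas + rng.normal(0, spec.noise_sigma, canvas.shape)
        frames.append((np.clip(canvas, 0, 1) * 255).astype(np.uint8))

    truth = GroundTruth(
        frames=pd.DataFrame(truth_rows, columns=[
            "frame", "id", "cx", "cy",
            "x0", "y0", "x1", "y1", "x2", "y2", "x3", "y3",
            "rois", "occluded_frac"]),
        behaviour=pd.DataFrame(behaviour_rows,
                               columns=["frame", "id", "present_roi", "using"]))
    return frames, truth


# ---------------------------------------------------------------------------
# simulated human coder
# ---------------------------------------------------------------------------

def latent_series(truth: GroundTruth, subject: int, n_frames: int,
                  state: str = "using", roi: int | None = None) -> np.ndarray:
    """Binary frame series of the latent truth for one subject.

    ``state``: "using" (actively using the resource) or "present"
    (present in any ROI, or in ``roi`` when given).
    """
    out = np.zeros(n_frames, dtype=np.uint8)
    sub = truth.behaviour[truth.behaviour["id"] == subject]
    for _, r in sub.iterrows():
        f = int(r["frame"])
        if f >= n_frames:
            continue
        if state == "using":
            out[f] = 1 if r["using"] else 0
        else:
            pr = int(r["present_roi"])
            out[f] = 1 if (pr >= 0 and (roi is None or pr == roi)) else 0
    return out


def simulate_coder(truth_series: np.ndarray, miss_rate: float = 0.0,
                   false_alarm_rate: float = 0.0, boundary_jitter: int = 0,
                   seed: int = 0) -> np.ndarray:
    """Corrupt a binary truth series the way a human coder would.

    Bout boundaries are first jittered by integers drawn uniformly from
    [-boundary_jitter, +boundary_jitter] (independently per bout edge),
    then each unit is flipped independently: 1 -> 0 with ``miss_rate``,
    0 -> 1 with ``false_alarm_rate``.  Seeded and deterministic.
    """
    if not (0 <= miss_rate <= 1 and 0 <= false_alarm_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    x = np.asarray(truth_series, dtype=np.uint8).copy()
    n = len(x)
    if boundary_jitter > 0 and n:
        jittered = np.zeros(n, dtype=np.uint8)
        # runs of presence
        padded = np.concatenate([[0], x, [0]])
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1) - 1
        for s, e in zip(starts, ends):
            s2 = int(np.clip(s + rng.integers(-boundary_jitter,
                                              boundary_jitter + 1), 0, n - 1))
            e2 = int(np.clip(e + rng.integers(-boundary_jitter,
                                              boundary_jitter + 1), 0, n - 1))
            if s2 <= e2:
                jittered[s2:e2 + 1] = 1
        x = jittered
    u = rng.random(n)
    out = x.copy()
    out[(x == 1) & (u < miss_rate)] = 0
    out[(x == 0) & (u < false_alarm_rate)] = 1
    return out


def expected_kappa(prevalence: float, miss_rate: float,
                   false_alarm_rate: float) -> float:
    """Closed-form expected Cohen's kappa of a coder vs the truth.

    With truth X ~ Bernoulli(prevalence) and coder Y flipping 1->0 with the
    miss rate and 0->1 with the false-alarm rate, the large-n kappa follows
    from the expected 2x2 table.
    """
    pi, m, fa = prevalence, miss_rate, false_alarm_rate
    p_o = pi * (1 - m) + (1 - pi) * (1 - fa)
    p2 = pi * (1 - m) + (1 - pi) * fa  # coder marginal
    p_e = pi * p2 + (1 - pi) * (1 - p2)
    if np.isclose(p_e, 1.0):
        return np.nan
    return (p_o - p_e) / (1 - p_e)


# ---------------------------------------------------------------------------
# named failure fixtures
# ---------------------------------------------------------------------------

def failure_fixtures(dictionary: MarkerDictionary, seed: int = 0
                     ) -> dict[str, tuple[SceneSpec, list[np.ndarray], GroundTruth]]:
    """Deterministic scenes reproducing the field failure classes.

    * ``adjacent_rois`` — two resources so close that one marker's center
      sits in both rectangles, producing double ROI membership.
    * ``separated_rois`` — the corrected layout: adequate spacing, single
      membership everywhere.
    * ``drifting_resource`` — the marker (riding a lightweight bowl) drifts
      from one ROI into another across the clip.
    * ``presence_without_use`` — the subject occupies the ROI the whole
      time but only uses the resource in the middle third, so detector
      presence over-reports use.
    * ``fur_occlusion`` — an occlusion episode covers half the code and
      detection drops out during it.
    """
    rows, cols = 240, 320
    mid = 0
    fixtures = {}

    overlapping = [RegionOfInterest(0, "wet food", 60, 60, 110, 110),
                   RegionOfInterest(1, "dry food", 150, 60, 110, 110)]
    spec = SceneSpec(frame_shape=(rows, cols), n_frames=10, rois=overlapping,
                     tracks={mid: [TrackSegment(0, 10,
                                                Pose((157, 115), 48), using=True)]},
                     seed=seed)
    fixtures["adjacent_rois"] = (spec, *generate_scene(spec, dictionary))

    separated = [RegionOfInterest(0, "water", 20, 60, 100, 100),
                 RegionOfInterest(1, "dry food", 200, 60, 100, 100)]
    spec = SceneSpec(frame_shape=(rows, cols), n_frames=10, rois=separated,
                     tracks={mid: [TrackSegment(0, 10,
                                                Pose((70, 110), 48), using=True)]},
                     seed=seed + 1)
    fixtures["separated_rois"] = (spec, *generate_scene(spec, dictionary))

    spec = SceneSpec(frame_shape=(rows, cols), n_frames=20, rois=separated,
                     tracks={mid: [TrackSegment(0, 20, Pose((70, 110), 48),
                                                pose_end=Pose((250, 110), 48),
                                                using=True)]},
                     seed=seed + 2)
    fixtures["drifting_resource"] = (spec, *generate_scene(spec, dictionary))

    one_roi = [RegionOfInterest(0, "food", 80, 40, 160, 160)]
    spec = SceneSpec(frame_shape=(rows, cols), n_frames=30, rois=one_roi,
                     tracks={mid: [
                         TrackSegment(0, 10, Pose((160, 120), 48), using=False),
                         TrackSegment(10, 20, Pose((160, 120), 48), using=True),
                         TrackSegment(20, 30, Pose((160, 120), 48), using=False),
                     ]},
                     seed=seed + 3)
    fixtures["presence_without_use"] = (spec, *generate_scene(spec, dictionary))

    spec = SceneSpec(frame_shape=(rows, cols), n_frames=30, rois=one_roi,
                     tracks={mid: [
                         TrackSegment(0, 10, Pose((160, 120), 48), using=True),
                         TrackSegment(10, 20, Pose((160, 120), 48), using=True,
                                      occluded_frac=0.5),
                         TrackSegment(20, 30, Pose((160, 120), 48), using=True),
                     ]},
                     seed=seed + 4)
    fixtures["fur_occlusion"] = (spec, *generate_scene(spec, dictionary))
    return fixtures
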