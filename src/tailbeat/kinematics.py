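"""Video -> midline -> 30-segment bend angles -> per-segment spectra.

Mirrors the high-speed (500 fps) video pipeline used on head-embedded
larvae: each frame is thresholded to a binary silhouette, smoothed by a
one-pixel dilation, hole-filled, skeletonized, and the skeleton's longest
geodesic path becomes the body midline.  The midline is resampled to 31
arc-length-uniform points bounding 30 segments; each segment's local bend
angle is the arctangent of its slope minus the same quantity on the rest
posture.  An FFT per segment then localizes the 20–40 Hz tail-beat band
along the body.

Normalized body coordinate: the extreme caudal segment is 1.0 and the
rostral (head) end 0.0 by default (``caudal_is_one=True``); the source
descriptions of this convention conflict, so it is an explicit option
rather than a constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters as _skfilters
from skimage import morphology as _skmorph

__all__ = [
    "MidlineFrame",
    "BodyAngleMatrix",
    "SegmentSpectra",
    "binarize_and_clean",
    "extract_midline",
    "segment_angles",
    "per_segment_fft",
    "analyze_video",
]


@dataclass
class MidlineFrame:
    """Ordered (x, y) midline pixel coordinates, rostral to caudal."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")

    @property
    def arc_length(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class BodyAngleMatrix:
    """Local bend angles: (n_segments, n_frames), radians, rest-relative."""

    angles: np.ndarray
    positions: np.ndarray  # normalized segment centers in [0, 1]


@dataclass
class SegmentSpectra:
    """Per-segment FFT magnitudes: (n_segments, n_freqs)."""

    positions: np.ndarray
    freqs_hz: np.ndarray
    magnitude: np.ndarray


def binarize_and_clean(frame: np.ndarray, threshold: float | None = None
                       ) -> np.ndarray:
    """Threshold a grayscale frame into a single clean body silhouette.

    Pixels above ``threshold`` (Otsu when omitted) are foreground; the mask
    is dilated by one pixel to smooth the body edge, interior holes are
    filled, and only the largest connected component is kept.
    """
    frame = np.asarray(frame)
    if threshold is None:
        if np.ptp(frame) == 0:
            raise ValueError("blank frame: no foreground")
        threshold = _skfilters.threshold_otsu(frame)
    mask = frame > threshold
    if not mask.any():
        raise ValueError("empty foreground after thresholding")
    mask = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool))
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _longest_path(skel: np.ndarray) -> list[tuple[int, int]]:
    """Longest geodesic path through an 8-connected skeleton (pixel list)."""
    pix = set(map(tuple, np.argwhere(skel)))
    if not pix:
        raise ValueError("zero-length skeleton")

    def bfs(src):
        dist = {src: 0.0}
        parent = {src: None}
        frontier = [src]
        far, fard = src, 0.0
        while frontier:
            nxt = []
            for p in frontier:
                for dr, dc in _NBRS:
                    q = (p[0] + dr, p[1] + dc)
                    if q in pix and q not in dist:
                        dist[q] = dist[p] + np.hypot(dr, dc)
                        parent[q] = p
                        nxt.append(q)
                        if dist[q] > fard:
                            far, fard = q, dist[q]
            frontier = nxt
        return far, parent

    # double-BFS diameter heuristic; ties broken toward the caudal-most
    # (largest-coordinate) endpoint by scan order stability
    a, _ = bfs(next(iter(sorted(pix))))
    b, parent = bfs(a)
    path = []
    node = b
    while node is not None:
        path.append(node)
        node = parent[node]
    return path


def _prune_cap_spurs(path: np.ndarray, edt: np.ndarray) -> np.ndarray:
    """Trim medial-axis spurs that run into blunt body ends.

    At a blunt cap the skeleton continues diagonally toward the corner with
    the distance-to-background falling ~1 per step; along the true
    centerline (even a tapered tail) it changes slowly.  From each end,
    drop pixels while the EDT climbs steeply inward.
    """
    def trim_front(p: np.ndarray) -> np.ndarray:
        k = 0
        limit = min(len(p) // 4, int(edt.max() * 2) + 2)
        while k < limit:
            d0 = edt[p[k][0], p[k][1]]
            d1 = edt[p[k + 1][0], p[k + 1][1]]
            step = np.hypot(*(p[k + 1] - p[k]))
            if (d1 - d0) / step >= 0.5:
                k += 1
            else:
                break
        return p[k:]

    path = trim_front(path)
    path = trim_front(path[::-1])[::-1]
    return path


def extract_midline(mask: np.ndarray, head_side: str = "left") -> MidlineFrame:
    """Skeletonize a silhouette and return its midline, rostral first.

    The morphological skeleton is pruned to its longest geodesic path (with
    blunt-end spurs trimmed); the end nearest the embedded head — the
    ``head_side`` image border — comes first.
    """
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("empty mask")
    if n > 1:
        raise ValueError("mask is not a single connected component")
    skel = _skmorph.skeletonize(mask)
    path = np.array(_longest_path(skel))  # (row, col) order
    edt = ndimage.distance_transform_edt(mask)
    path = _prune_cap_spurs(path, edt)
    if len(path) < 2:
        raise ValueError("skeleton too short for a midline")

    pts = path[:, ::-1].astype(float)  # -> (x, y)
    first, last = pts[0], pts[-1]
    if head_side == "left":
        flip = first[0] > last[0]
    elif head_side == "right":
        flip = first[0] < last[0]
    elif head_side == "top":
        flip = first[1] > last[1]
    elif head_side == "bottom":
        flip = first[1] < last[1]
    else:
        raise ValueError(f"unknown head_side {head_side!r}")
    return MidlineFrame(pts[::-1] if flip else pts)


def _resample(points: np.ndarray, n_points: int) -> np.ndarray:
    d = np.diff(points, axis=0)
    arclen = np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])
    if arclen[-1] == 0:
        raise ValueError("degenerate midline of zero length")
    targets = np.linspace(0.0, arclen[-1], n_points)
    return np.column_stack([np.interp(targets, arclen, points[:, 0]),
                            np.interp(targets, arclen, points[:, 1])])


def _smooth(points: np.ndarray, win: int = 7) -> np.ndarray:
    """Light moving-average smoothing against pixel quantization."""
    if len(points) < win:
        return points
    kernel = np.ones(win) / win
    sm = np.column_stack([
        np.convolve(points[:, 0], kernel, mode="valid"),
        np.convolve(points[:, 1], kernel, mode="valid")])
    return np.vstack([points[: win // 2], sm, points[-(win // 2):]])


def segment_angles(midline: MidlineFrame, rest_midline: MidlineFrame,
                   n_segments: int = 30, smooth: bool = True) -> np.ndarray:
    """Per-segment bend angles relative to the rest posture.

    Both midlines are resampled to ``n_segments + 1`` equally spaced
    arc-length points; the angle of segment i is arctan of its slope
    (dy/dx across the segment) minus the matching rest-posture angle.
    """
    def seg_angles(m: MidlineFrame) -> np.ndarray:
        pts = _smooth(m.points) if smooth else m.points
        if len(pts) < n_segments + 1:
            raise ValueError(
                f"midline has {len(pts)} points; need >= {n_segments + 1}")
        r = _resample(pts, n_segments + 1)
        d = np.diff(r, axis=0)
        theta = np.arctan2(d[:, 1], d[:, 0])
        # slope angle, independent of traversal direction: fold to (-pi/2, pi/2]
        theta = np.where(theta > np.pi / 2, theta - np.pi, theta)
        theta = np.where(theta <= -np.pi / 2, theta + np.pi, theta)
        return theta

    return seg_angles(midline) - seg_angles(rest_midline)


def per_segment_fft(angle_matrix: BodyAngleMatrix | np.ndarray,
                    fps: float = 500.0,
                    positions: np.ndarray | None = None) -> SegmentSpectra:
    """FFT magnitude of each segment's angle time series (DC removed)."""
    if isinstance(angle_matrix, BodyAngleMatrix):
        angles = angle_matrix.angles
        positions = angle_matrix.positions
    else:
        angles = np.asarray(angle_matrix)
    if angles.shape[1] < 2:
        raise ValueError("need at least two frames for a spectrum")
    if positions is None:
        n = angles.shape[0]
        positions = (np.arange(n) + 0.5) / n
    centered = angles - angles.mean(axis=1, keepdims=True)
    mag = np.abs(np.fft.rfft(centered, axis=1))
    freqs = np.fft.rfftfreq(angles.shape[1], d=1.0 / fps)
    return SegmentSpectra(positions=np.asarray(positions), freqs_hz=freqs,
                          magnitude=mag)


def analyze_video(frames: np.ndarray,
                  fps: float = 500.0,
                  n_segments: int = 30,
                  threshold: float | None = None,
                  rest_frame: int = 0,
                  head_side: str = "left",
                  caudal_is_one: bool = True,
                  ) -> tuple[BodyAngleMatrix, SegmentSpectra]:
    """Full pipeline: frames -> angle matrix -> per-segment spectra.

    The rest posture defaults to the first frame.  With
    ``caudal_is_one=True`` segment positions run 0.0 (rostral) to 1.0
    (caudal); the opposite convention flips positions and row order.
    """
    masks = [binarize_and_clean(f, threshold) for f in frames]
    midlines = [extract_midline(m, head_side=head_side) for m in masks]
    rest = midlines[rest_frame]
    angles = np.column_stack(
        [segment_angles(m, rest, n_segments=n_segments) for m in midlines])
    positions = (np.arange(n_segments) + 0.5) / n_segments
    if not caudal_is_one:  # legacy convention: extreme caudal segment = 0.0
        positions = 1.0 - positions
    mat = BodyAngleMatrix(angles=angles, positions=positions)
    return mat, per_segment_fft(mat, fps=fps)
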