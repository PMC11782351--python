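"""Organelle tracking: centroid extraction, frame linking, speeds in um/s.

Chloroplast-style objects are segmented per frame by Otsu thresholding, their
intensity-weighted centroids linked between consecutive frames by greedy
mutual-nearest-neighbor matching under a distance gate, and speeds computed
from centroid displacements with the recording's pixel size and frame
interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .morph import AgreementReport, agreement, otsu_threshold

__all__ = ["LinkConfig", "Track", "extract_centroids", "link_tracks", "speed_agreement"]


@dataclass(frozen=True)
class LinkConfig:
    """Linking gate and the physical calibration of the recording."""

    max_disp_px: float = 15.0
    dt_s: float = 0.5
    pixel_size_um: float = 0.28

    def __post_init__(self) -> None:
        if min(self.max_disp_px, self.dt_s, self.pixel_size_um) <= 0:
            raise ValueError("max_disp_px, dt_s, pixel_size_um must all be positive")


@dataclass
class Track:
    """One object's trajectory: (frame, x, y) points and per-interval speeds."""

    id: int
    points: list = field(default_factory=list)   # (frame_index, x_px, y_px)
    speeds_um_s: list = field(default_factory=list)

    @property
    def start(self):
        return self.points[0]

    def positions(self) -> np.ndarray:
        return np.array([(x, y) for _, x, y in self.points])


def extract_centroids(frame: np.ndarray, min_area_px: int = 9) -> list:
    """Intensity-weighted centroids (x, y) of Otsu-thresholded bright objects."""
    img = np.asarray(frame, dtype=float)
    if np.ptp(img) == 0:
        warnings.warn("constant frame: no objects detected", stacklevel=2)
        return []
    thr = otsu_threshold(img)
    mask = img > thr
    labels, n = ndi.label(mask, structure=np.ones((3, 3), int))
    out = []
    for i in range(1, n + 1):
        obj = labels == i
        if obj.sum() < min_area_px:
            continue
        w = np.where(obj, img, 0.0)
        cy, cx = ndi.center_of_mass(w)
        out.append((float(cx), float(cy)))
    return out


def link_tracks(per_frame_centroids, cfg: LinkConfig = LinkConfig()) -> list:
    """Greedy mutual-nearest-neighbor linking of detections across frames.

    Candidate matches between consecutive frames are taken in ascending
    distance order, each detection used at most once, pairs beyond
    ``max_disp_px`` rejected.  Unmatched detections start new tracks;
    unmatched track ends terminate.  Single-point stub tracks are retained
    (with empty speed lists).
    """
    frames = [list(f) for f in per_frame_centroids]
    if not frames:
        raise ValueError("empty frame list")
    tracks = []
    active = {}  # index into current frame detections -> Track
    for j, (x, y) in enumerate(frames[0]):
        t = Track(id=len(tracks) + 1, points=[(0, float(x), float(y))])
        tracks.append(t)
        active[j] = t

    for fi in range(1, len(frames)):
        prev, curr = frames[fi - 1], frames[fi]
        cand = []
        for i, p in enumerate(prev):
            if i not in active:
                continue
            for j, q in enumerate(curr):
                d = float(np.hypot(p[0] - q[0], p[1] - q[1]))
                if d <= cfg.max_disp_px:
                    cand.append((d, i, j))
        cand.sort()
        used_prev, used_curr = set(), set()
        new_active = {}
        for d, i, j in cand:
            if i in used_prev or j in used_curr:
                continue
            used_prev.add(i)
            used_curr.add(j)
            t = active[i]
            x, y = curr[j]
            t.points.append((fi, float(x), float(y)))
            t.speeds_um_s.append(d * cfg.pixel_size_um / cfg.dt_s)
            new_active[j] = t
        for j, (x, y) in enumerate(curr):
            if j not in used_curr:
                t = Track(id=len(tracks) + 1, points=[(fi, float(x), float(y))])
                tracks.append(t)
                new_active[j] = t
        active = new_active
    return tracks


def speed_agreement(truth, tracks, match_gate_px: float = 10.0,
                    min_track_points: int = 2) -> AgreementReport:
    """R^2 of tracked speeds against ground-truth speeds.

    Tracks are matched to truth objects by their initial position (nearest
    start within ``match_gate_px``); speeds are paired per interval by frame
    index.  ``truth`` is an ``imgen.TimeLapseTruth``.
    """
    starts = [tr[0] for tr in truth.tracks]
    recovered, expected = [], []
    used = set()
    for t in tracks:
        if len(t.points) < min_track_points:
            continue
        f0, x0, y0 = t.points[0]
        d = [np.hypot(x0 - sx, y0 - sy) if i not in used else np.inf
             for i, (sx, sy) in enumerate(starts)]
        i = int(np.argmin(d))
        if d[i] > match_gate_px:
            continue
        used.add(i)
        truth_speeds = truth.speeds_um_s[i]
        for k, s in enumerate(t.speeds_um_s):
            interval = t.points[k][0]  # speed k covers frames interval..interval+1
            if interval < len(truth_speeds):
                recovered.append(s)
                expected.append(float(truth_speeds[interval]))
    if not recovered:
        raise ValueError("no tracks matched to truth objects")
    return agreement(expected, recovered, metric="speed_um_s")
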