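"""Seeded synthetic microscopy-scene generator.

Produces paired bright-field / fluorescence scenes with exact ground truth for
every downstream stage of the pipeline:

* ``by2_file`` — files of elongated suspension-culture-style cells (BY-2-like),
  each with a nucleus and a large vacuole;
* ``pavement`` — confluent puzzle-shaped epidermal pavement cells, built as a
  Voronoi tessellation whose boundaries are displaced sinusoidally by
  ``lobe_amplitude`` (0 gives convex, straight-walled cells);
* ``chloroplast_field`` — sparse bright organelles (chloroplast-like disks) on
  a cytoplasm background, at the finer pixel size typical of such recordings;
* ``viability_crop`` — single-cell crops, either an intact elongated cell with
  a smooth interior and crisp boundary ("living") or a shrunken cell with a
  collapsed, speckled membrane ("dead").

Bright-field rendering emulates slightly defocused transmitted-light contrast:
a transmittance map (background bright, cell interior slightly dark) plus a
signed difference-of-Gaussians halo along edges, plus Gaussian read noise.
All randomness flows from one per-call ``numpy`` generator, so identical
specs regenerate bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "SceneSpec", "ScenePair", "TimeLapseTruth", "SpeedModel",
    "generate_scene", "generate_timelapse", "generate_viability_set",
]

SHAPE_MODELS = ("by2_file", "pavement", "chloroplast_field", "viability_crop")

# bright-field appearance constants (transmittance units, [0, 1])
_BG_TRANSMITTANCE = 1.0
_CELL_TRANSMITTANCE = 0.85
_NUCLEUS_TRANSMITTANCE = 0.78
_CHLOROPLAST_TRANSMITTANCE = 0.55
_HALO_GAIN = 1.5


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field of view."""

    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = 0.56
    n_cells: int = 12
    shape_model: str = "pavement"
    lobe_amplitude: float = 4.0
    defocus_sigma_px: float = 2.0
    noise_sd: float = 0.02
    seed: int = 0
    elongation: float = 2.5  # major/minor axis ratio of by2-style cells

    def __post_init__(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ValueError("canvas must be at least 64x64 px")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.shape_model not in SHAPE_MODELS:
            raise ValueError(f"unknown shape_model {self.shape_model!r}")
        if self.lobe_amplitude < 0 or self.defocus_sigma_px < 0 or self.noise_sd < 0:
            raise ValueError("lobe_amplitude, defocus_sigma_px, noise_sd must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without overlap on the canvas."""


@dataclass(frozen=True)
class ScenePair:
    """A bright-field image with its ground-truth channels and label mask."""

    spec: SceneSpec
    brightfield: np.ndarray            # float64 in [0, 1]
    channels: dict                     # name -> float image in [0, 1]
    labels: np.ndarray                 # int32; 0 = background
    truth: tuple                       # per-object dicts (id, centroid px, ...)


@dataclass(frozen=True)
class SpeedModel:
    """Correlated random walk parameters for organelle motion."""

    mean_um_s: float = 1.0
    sd: float = 0.3
    direction_persistence: float = 0.8  # 0 = fresh heading each frame, 1 = straight line

    def __post_init__(self) -> None:
        if self.mean_um_s < 0:
            raise ValueError("mean speed must be >= 0")
        if self.sd < 0:
            raise ValueError("speed sd must be >= 0")
        if not (0.0 <= self.direction_persistence <= 1.0):
            raise ValueError("direction_persistence must be in [0, 1]")


@dataclass(frozen=True)
class TimeLapseTruth:
    """Frames plus ground-truth tracks of a simulated time-lapse recording."""

    frames: tuple                      # of ScenePair
    dt_s: float
    tracks: tuple                      # per object: array (n_frames, 2) of (x, y) px
    speeds_um_s: tuple                 # per object: array (n_frames - 1,)


# ---------------------------------------------------------------------------
# geometry helpers

def _poisson_disk(rng, n, width, height, min_dist, margin, retries=200):
    """Rejection-sampled point set with pairwise spacing >= min_dist."""
    pts = []
    for _ in range(n):
        for attempt in range(retries):
            p = np.array([margin + rng.random() * (width - 2 * margin),
                          margin + rng.random() * (height - 2 * margin)])
            if all(np.hypot(*(p - q)) >= min_dist for q in pts):
                pts.append(p)
                break
        else:
            raise PlacementError(
                f"could not place {n} objects with spacing {min_dist:.1f} px "
                f"on a {width}x{height} canvas after {retries} retries")
    return np.array(pts)


def _pavement_labels(spec: SceneSpec, rng) -> np.ndarray:
    """Wavy Voronoi tessellation: nearest seed in sinusoidally warped coordinates."""
    w, h, n = spec.width_px, spec.height_px, spec.n_cells
    target_sep = 0.7 * np.sqrt(w * h / n)
    seeds = _poisson_disk(rng, n, w, h, min_dist=target_sep, margin=2)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # Lloyd relaxation regularizes the tessellation (no sliver cells)
    for _ in range(2):
        d2 = (xx[..., None] - seeds[:, 0]) ** 2 + (yy[..., None] - seeds[:, 1]) ** 2
        lab = np.argmin(d2, axis=-1)
        for i in range(n):
            rows, cols = np.nonzero(lab == i)
            if rows.size:
                seeds[i] = (cols.mean(), rows.mean())
    a = spec.lobe_amplitude
    if a > 0:
        wavelength = max(4.0 * a, 12.0)
        phases = rng.random(4) * 2 * np.pi
        xw = xx + a * np.sin(2 * np.pi * yy / wavelength + phases[0]) \
                + a * np.sin(2 * np.pi * xx / (2.3 * wavelength) + phases[1])
        yw = yy + a * np.sin(2 * np.pi * xx / wavelength + phases[2]) \
                + a * np.sin(2 * np.pi * yy / (2.3 * wavelength) + phases[3])
    else:
        xw, yw = xx, yy
    d2 = (xw[..., None] - seeds[:, 0]) ** 2 + (yw[..., None] - seeds[:, 1]) ** 2
    labels = np.argmin(d2, axis=-1).astype(np.int32) + 1
    present = np.unique(labels)
    if len(present) != n:
        raise PlacementError(f"warp left {n - len(present)} of {n} cells without support")
    return labels


def _by2_labels(spec: SceneSpec, rng) -> np.ndarray:
    """Files of elongated elliptical cells on background."""
    w, h, n = spec.width_px, spec.height_px, spec.n_cells
    elong = max(spec.elongation, 1.0)
    # size cells so that n of them fit loosely
    b = np.sqrt(w * h / (n * np.pi * elong)) * 0.55   # semi-minor axis
    a = b * elong
    centers = _poisson_disk(rng, n, w, h, min_dist=2.05 * b + 2,
                            margin=max(b + 2, 4))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    labels = np.zeros((h, w), dtype=np.int32)
    order = np.argsort(centers[:, 0])
    for i, idx in enumerate(order, start=1):
        cx, cy = centers[idx]
        theta = rng.normal(0.0, 0.12)  # near-horizontal files
        ca, sa = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        ai = a * rng.uniform(0.85, 1.15)
        mask = (u / ai) ** 2 + (v / b) ** 2 <= 1.0
        mask &= labels == 0
        if not mask.any():
            raise PlacementError("cell placed without support")
        labels[mask] = i
    return labels


def _chloroplast_labels(spec: SceneSpec, rng, centers=None, radii=None):
    w, h, n = spec.width_px, spec.height_px, spec.n_cells
    if radii is None:
        radii = rng.uniform(4.0, 7.0, size=n)
    if centers is None:
        centers = _poisson_disk(rng, n, w, h, min_dist=2 * radii.max() + 4,
                                margin=radii.max() + 2)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    labels = np.zeros((h, w), dtype=np.int32)
    d_best = np.full((h, w), np.inf)
    for i, ((cx, cy), r) in enumerate(zip(centers, radii), start=1):
        d = np.hypot(xx - cx, yy - cy)
        inside = d <= r
        take = inside & (d < d_best)
        labels[take] = i
        d_best[take] = d[take]
    if len(np.unique(labels)) - 1 != n:
        raise PlacementError("chloroplast placement produced empty objects")
    return labels, centers, radii


# ---------------------------------------------------------------------------
# rendering

def _membrane_channel(labels: np.ndarray, outer_only: bool = False) -> np.ndarray:
    """Fluorescence band along label boundaries (distance-profile Gaussian)."""
    boundary = np.zeros(labels.shape, dtype=bool)
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    if outer_only:
        boundary &= ndi.binary_dilation(labels > 0)
    if not boundary.any():
        return np.zeros(labels.shape)
    d = ndi.distance_transform_edt(~boundary)
    return np.exp(-d ** 2 / (2 * 1.0 ** 2))


def _interior_blob(mask_label, labels, rng, shrink, jitter=0.3):
    """Per-cell interior organelle mask: eroded cell region around a jittered center."""
    out = np.zeros(labels.shape, dtype=bool)
    for lab in np.unique(labels[labels > 0]):
        cell = labels == lab
        rows, cols = np.nonzero(cell)
        cy, cx = rows.mean(), cols.mean()
        r_eq = np.sqrt(cell.sum() / np.pi)
        rr = max(2.0, shrink * r_eq)
        cy += rng.normal(0, jitter * rr)
        cx += rng.normal(0, jitter * rr)
        yy, xx = np.mgrid[0:labels.shape[0], 0:labels.shape[1]]
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= rr ** 2
        out |= blob & cell
    return out


def _render_brightfield(transmittance: np.ndarray, spec: SceneSpec, rng) -> np.ndarray:
    bf = transmittance.astype(float).copy()
    s = spec.defocus_sigma_px
    if s > 0:
        halo = ndi.gaussian_filter(bf, s) - ndi.gaussian_filter(bf, 2 * s)
        bf = bf + _HALO_GAIN * halo
    if spec.noise_sd > 0:
        bf = bf + rng.normal(0.0, spec.noise_sd, size=bf.shape)
    return np.clip(bf, 0.0, 1.0)


def _soften(channel: np.ndarray, sigma: float = 0.7) -> np.ndarray:
    out = ndi.gaussian_filter(channel.astype(float), sigma)
    m = out.max()
    return out / m if m > 0 else out


def generate_scene(spec: SceneSpec, rng: Optional[np.random.Generator] = None) -> ScenePair:
    """Render one paired bright-field / fluorescence scene with ground truth."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    channels = {}
    if spec.shape_model == "pavement":
        labels = _pavement_labels(spec, rng)
        transmittance = np.where(labels > 0, _CELL_TRANSMITTANCE, _BG_TRANSMITTANCE)
        # confluent tissue: walls darker than interiors
        membrane = _membrane_channel(labels)
        transmittance = transmittance - 0.12 * membrane
        channels["membrane"] = membrane
    elif spec.shape_model == "by2_file":
        labels = _by2_labels(spec, rng)
        nucleus = _interior_blob(None, labels, rng, shrink=0.35)
        vacuole = ndi.binary_erosion(labels > 0, iterations=2) & ~ndi.binary_dilation(nucleus)
        transmittance = np.where(labels > 0, _CELL_TRANSMITTANCE, _BG_TRANSMITTANCE)
        transmittance = np.where(nucleus, _NUCLEUS_TRANSMITTANCE, transmittance)
        channels["membrane"] = _membrane_channel(labels, outer_only=True)
        channels["nucleus"] = _soften(nucleus)
        channels["vacuole"] = _soften(vacuole)
    elif spec.shape_model == "chloroplast_field":
        labels, centers, radii = _chloroplast_labels(spec, rng)
        transmittance = np.where(labels > 0, _CHLOROPLAST_TRANSMITTANCE,
                                 _CELL_TRANSMITTANCE)
        channels["chloroplast"] = _soften(labels > 0)
    elif spec.shape_model == "viability_crop":
        labels, channels, transmittance = _viability_cell(spec, rng)
    else:  # pragma: no cover - guarded by SceneSpec
        raise ValueError(spec.shape_model)

    bf = _render_brightfield(transmittance, spec, rng)
    truth = []
    for lab in np.unique(labels[labels > 0]):
        rows, cols = np.nonzero(labels == lab)
        truth.append({"id": int(lab), "centroid_px": (float(cols.mean()), float(rows.mean())),
                      "area_px": int(rows.size)})
    return ScenePair(spec=spec, brightfield=bf, channels=channels,
                     labels=labels, truth=tuple(truth))


# ---------------------------------------------------------------------------
# viability crops

def _viability_cell(spec: SceneSpec, rng, dead: Optional[bool] = None):
    """Single-cell crop; ``dead`` may be passed via spec.n_cells (1=live, 2=dead)."""
    if dead is None:
        dead = spec.n_cells == 2
    h, w = spec.height_px, spec.width_px
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy = h / 2 + rng.normal(0, h * 0.04)
    cx = w / 2 + rng.normal(0, w * 0.04)
    theta = rng.uniform(0, np.pi)
    ca, sa = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    a = w * rng.uniform(0.32, 0.40)
    b = a / rng.uniform(2.0, 2.8)
    # per-crop severity: how far the cell's state shows in bright-field.
    # Early-stage dead cells look nearly normal under transmitted light even
    # though the membrane channel already shows the collapse; weakly granular
    # living cells are likewise featureless.  This graded overlap is what
    # makes bright-field classification genuinely harder than stain-based.
    severity = rng.uniform(0.0, 1.0)
    if dead:
        shrink = 0.95 - 0.35 * severity
        a *= shrink
        b *= shrink
        wob = 0.25 * severity * b * np.sin(
            np.arctan2(v, u) * rng.integers(4, 7) + rng.random() * 6.28)
    else:
        wob = 0.0
    cell = (u / (a + wob)) ** 2 + (v / (b + wob)) ** 2 <= 1.0
    labels = cell.astype(np.int32)

    membrane_band = cell ^ ndi.binary_erosion(cell)
    d = ndi.distance_transform_edt(~membrane_band)
    membrane = np.exp(-d ** 2 / 2.0)
    # per-crop illumination variability (background level and a tilted
    # illumination plane) blurs the class statistics in bright-field; the
    # fluorescence channel is unaffected by it
    bg = _BG_TRANSMITTANCE - rng.uniform(0.0, 0.06)
    transmittance = np.where(cell, _CELL_TRANSMITTANCE - rng.uniform(0.0, 0.04), bg)
    tilt = rng.uniform(-0.10, 0.10, size=2)
    transmittance = transmittance + tilt[0] * (xx / w - 0.5) + tilt[1] * (yy / h - 0.5)
    yy_, xx_ = np.mgrid[0:h, 0:w]
    if dead:
        # collapsed internal membranes: dense sharp speckle inside the cell,
        # subtle in bright-field but strong in the membrane channel
        # crumple pattern: blobs a few px across (thresholded smooth noise)
        noise_field = ndi.gaussian_filter(rng.random((h, w)), 1.5)
        cut = np.quantile(noise_field, rng.uniform(0.60, 0.72))
        crumple = (noise_field > cut) & ndi.binary_erosion(cell, iterations=2)
        membrane = np.clip(membrane + 2.2 * ndi.gaussian_filter(crumple.astype(float), 0.5), 0, 1)
        # two bright-field manifestations of the collapse: a sharp component
        # that fades with early-stage cells (severity), and a smooth
        # low-amplitude shadow of the crumple that is always present but too
        # gradual for distance-1 co-occurrence statistics to resolve
        transmittance = (transmittance
                         - 0.16 * severity * crumple.astype(float)
                         - 0.22 * ndi.gaussian_filter(crumple.astype(float), 2.0))
    else:
        # living cells are not featureless in bright-field: benign organelle
        # granules give them texture that partially confounds the dead-cell
        # speckle (the membrane channel stays a clean single band)
        interior = ndi.gaussian_filter(cell.astype(float), 4.0)
        transmittance = transmittance - 0.03 * interior
        # nucleus: one large smooth dark body (widens the intensity range
        # without contributing high-frequency texture)
        nu = rng.uniform(0.25, 0.45) * b
        ncy = cy + rng.normal(0, 0.3 * b)
        ncx = cx + rng.normal(0, 0.3 * a)
        nucleus = ((yy - ncy) ** 2 + (xx - ncx) ** 2 <= nu ** 2) & cell
        transmittance = transmittance - 0.30 * ndi.gaussian_filter(
            nucleus.astype(float), 1.5)
        inner = ndi.binary_erosion(cell, iterations=2)
        rows, cols = np.nonzero(inner)
        if rows.size:
            k = int(rng.integers(3, 14))
            depth = 0.24 * severity
            for _ in range(k):
                j = rng.integers(0, rows.size)
                gr = rng.uniform(1.0, 2.5)
                blob = (yy_ - rows[j]) ** 2 + (xx_ - cols[j]) ** 2 <= gr ** 2
                transmittance = transmittance - depth * ndi.gaussian_filter(
                    (blob & cell).astype(float), 0.5)
    channels = {"membrane": np.clip(membrane, 0.0, 1.0)}
    return labels, channels, np.clip(transmittance, 0.0, 1.0)


def generate_viability_set(n_per_class: int, seed: int, crop_px: int = 64,
                           pixel_size_um: float = 0.56):
    """Class-balanced living/dead crops: list of (ScenePair, label) tuples.

    Labels are the strings ``"living"`` and ``"dead"``.  Crops alternate so any
    prefix is near-balanced.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    crops = []
    for i in range(n_per_class):
        for label, code in (("living", 1), ("dead", 2)):
            spec = SceneSpec(width_px=crop_px, height_px=crop_px,
                             pixel_size_um=pixel_size_um, n_cells=code,
                             shape_model="viability_crop", lobe_amplitude=0.0,
                             defocus_sigma_px=float(rng.uniform(1.0, 2.5)),
                             noise_sd=float(rng.uniform(0.015, 0.05)),
                             seed=int(rng.integers(0, 2 ** 31 - 1)))
            crops.append((generate_scene(spec), label))
    return crops


# ---------------------------------------------------------------------------
# time lapse

def _reflect_step(pos, step, lo, hi):
    """Bounce a step vector off the canvas walls, preserving its length.

    The offending component(s) of the step are negated before the move, so the
    displacement magnitude — and hence the recorded speed — is unchanged.
    Requires step length smaller than the canvas, which the generator's speed
    scales guarantee.
    """
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            new = pos + step * np.array([sx, sy])
            if lo[0] <= new[0] <= hi[0] and lo[1] <= new[1] <= hi[1]:
                return new
    raise PlacementError("step larger than canvas: cannot reflect")


def generate_timelapse(spec: SceneSpec, n_frames: int,
                       speed_model: SpeedModel = SpeedModel(),
                       dt_s: float = 0.5) -> TimeLapseTruth:
    """Simulate moving chloroplasts as a seeded correlated random walk.

    Per frame each object takes a step of length ``speed * dt / pixel_size``
    pixels with speed drawn from N(mean, sd) truncated at 0 and a heading that
    persists between frames (``direction_persistence`` 1 = straight line).
    Steps that would leave the canvas are reflected off the walls; a mirror
    reflection preserves the step length, so recorded truth speeds — which are
    recomputed from the positions as ``|dx| * pixel_size / dt`` — equal the
    drawn speeds exactly.
    """
    if spec.shape_model != "chloroplast_field":
        raise ValueError("time lapse requires shape_model='chloroplast_field'")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    sm = speed_model
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    radii = rng.uniform(4.0, 7.0, size=n)
    margin = radii.max() + 2
    centers = _poisson_disk(rng, n, spec.width_px, spec.height_px,
                            min_dist=2 * radii.max() + 6, margin=margin)
    lo = np.array([margin, margin])
    hi = np.array([spec.width_px - margin, spec.height_px - margin])
    headings = rng.uniform(0, 2 * np.pi, size=n)
    positions = [centers.copy()]
    for _ in range(n_frames - 1):
        if sm.sd > 0:
            speeds = np.maximum(rng.normal(sm.mean_um_s, sm.sd, size=n), 0.0)
        else:
            speeds = np.full(n, sm.mean_um_s)
        turn_sd = (1.0 - sm.direction_persistence) * np.pi
        headings = headings + rng.normal(0.0, turn_sd, size=n)
        step_len_px = speeds * dt_s / spec.pixel_size_um
        prev = positions[-1]
        new = prev.copy()
        # objects are solid bodies: steps that would bring two within contact
        # distance are rotated to a free heading of the same length, so truth
        # speeds remain exact
        for i in range(n):
            placed = False
            for dtheta in (0.0, 0.4, -0.4, 0.8, -0.8, 1.2, -1.2, 1.6, -1.6,
                           2.0, -2.0, 2.4, -2.4, 2.8, -2.8):
                th = headings[i] + dtheta
                step = step_len_px[i] * np.array([np.cos(th), np.sin(th)])
                cand = _reflect_step(prev[i], step, lo, hi)
                ok = True
                for j in range(n):
                    if j == i:
                        continue
                    other = new[j] if j < i else prev[j]
                    if np.hypot(*(cand - other)) < radii[i] + radii[j] + 3.0:
                        ok = False
                        break
                if ok:
                    new[i] = cand
                    headings[i] = th
                    placed = True
                    break
            if not placed:
                new[i] = prev[i]  # boxed in: stay put this frame
        positions.append(new)

    frames = []
    for pos in positions:
        frame_rng = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))
        labels, _, _ = _chloroplast_labels(spec, frame_rng, centers=pos, radii=radii)
        transmittance = np.where(labels > 0, _CHLOROPLAST_TRANSMITTANCE,
                                 _CELL_TRANSMITTANCE)
        bf = _render_brightfield(transmittance, spec, frame_rng)
        channels = {"chloroplast": _soften(labels > 0)}
        truth = tuple({"id": i + 1, "centroid_px": (float(p[0]), float(p[1])),
                       "radius_px": float(radii[i])} for i, p in enumerate(pos))
        frames.append(ScenePair(spec=spec, brightfield=bf, channels=channels,
                                labels=labels, truth=truth))

    tracks = tuple(np.array([pos[i] for pos in positions]) for i in range(n))
    speeds_um_s = tuple(
        np.hypot(*np.diff(tr, axis=0).T) * spec.pixel_size_um / dt_s for tr in tracks)
    return TimeLapseTruth(frames=tuple(frames), dt_s=dt_s,
                          tracks=tracks, speeds_um_s=speeds_um_s)
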