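"""Vocal-fold edge detection from the intensity gradient.

The glottis appears as a dark slit between two bright folds, so each fold's
medial edge is a strong intensity gradient whose direction tells the sides
apart: at the left-fold edge the intensity drops toward the glottis, i.e. the
gradient x-component is negative, and conversely on the right.  Per image row
the sub-pixel edge abscissa is the gradient-magnitude-weighted mean of the
surviving pixel columns.  Rows with no surviving gradient mass emit no point;
that data loss is the signal the tracking stage gates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import reconstruction

from .geometry import ROI, AttachmentLine

__all__ = [
    "GradientField",
    "EdgePointSet",
    "DetectionConfig",
    "fill_bright_regions",
    "compute_gradient",
    "detect_edges",
    "smooth_temporal",
    "detect_sequence",
]


@dataclass
class GradientField:
    """Thresholded gradient magnitude with per-pixel direction components."""

    G: np.ndarray
    phase: np.ndarray
    gx: np.ndarray
    gy: np.ndarray

    def __post_init__(self) -> None:
        if self.G.shape != self.phase.shape:
            raise ValueError("magnitude/phase shape mismatch")


@dataclass
class EdgePointSet:
    """Detected sub-pixel edge points of one fold in one frame.

    ``points`` is a list of (x_bar, y): real-valued column and integer row.
    """

    frame: int
    side: str
    points: list[tuple[float, int]] = field(default_factory=list)

    @property
    def D(self) -> int:
        return len(self.points)

    @property
    def rows(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=int)

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)


@dataclass
class DetectionConfig:
    """Edge-detection parameters.

    t_h : relative gradient threshold (fraction of the per-frame max).
    temporal_window : odd moving-average length in frames.
    polarity : +1 for bright folds / dark glottis, -1 for inverted contrast.
    """

    t_h: float = 0.25
    temporal_window: int = 5
    D_T: int | None = None
    polarity: int = 1
    threshold_scope: str = "recording"
    #: rows where the opposing edge centroids are closer than this are
    #: censored: within the gradient kernel's support the two edge
    #: responses merge and the weighted-mean positions are no longer
    #: separable, so such rows count as detection loss
    min_separation_px: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_h <= 1.0:
            raise ValueError("t_h must lie in [0, 1]")
        if self.temporal_window < 1 or self.temporal_window % 2 == 0:
            raise ValueError("temporal_window must be odd and >= 1")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.threshold_scope not in ("recording", "frame"):
            raise ValueError("threshold_scope must be 'recording' or 'frame'")


def fill_bright_regions(frame: np.ndarray) -> np.ndarray:
    """Attenuate interior bright blobs (specular highlights on the mucosa).

    Grayscale hole filling applied to the inverted image: regional maxima not
    connected to the image border are lowered toward their surround, while
    border-connected structure — and any dark region, the glottal slit in
    particular — is left untouched.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.min() < -1e-9 or frame.max() > 1 + 1e-9:
        raise ValueError("intensities must lie in [0, 1]")
    if frame.shape[0] < 3 or frame.shape[1] < 3:
        return frame.copy()
    inv = 1.0 - frame
    seed = np.copy(inv)
    seed[1:-1, 1:-1] = inv.max()
    filled = reconstruction(seed, inv, method="erosion")
    return 1.0 - filled


def compute_gradient(frame: np.ndarray, t_h: float, g_ref: float | None = None) -> GradientField:
    """Prewitt gradient with a relative magnitude threshold.

    Entries below ``t_h`` times the reference magnitude are zeroed; the
    phase (atan2 of y/x components) is kept only where magnitude survives.
    The reference is the frame's own maximum unless ``g_ref`` is given —
    sequence processing passes the recording-wide maximum so that frames
    where the glottis is almost closed (globally weak gradients) lose their
    detections instead of being renormalized, which is the data-loss signal
    the tracking stage relies on.
    """
    if not 0.0 <= t_h <= 1.0:
        raise ValueError("t_h must lie in [0, 1]")
    frame = np.asarray(frame, dtype=float)
    gx = ndimage.prewitt(frame, axis=1, mode="reflect")
    gy = ndimage.prewitt(frame, axis=0, mode="reflect")
    G = np.hypot(gx, gy)
    gmax = G.max() if g_ref is None else g_ref
    if gmax > 0:
        mask = G >= t_h * gmax
    else:
        mask = np.zeros_like(G, dtype=bool)
    G = np.where(mask, G, 0.0)
    phase = np.where(mask, np.arctan2(gy, gx), 0.0)
    return GradientField(G=G, phase=phase, gx=np.where(mask, gx, 0.0), gy=np.where(mask, gy, 0.0))


def detect_edges(
    field: GradientField,
    line: AttachmentLine,
    roi: ROI,
    frame_index: int = 0,
    polarity: int = 1,
) -> EdgePointSet:
    """Weighted-mean edge abscissa per row for one fold.

    For each integer row strictly between the fold's attachment rows, only
    gradient pixels whose x-component points toward this fold survive
    (left fold: gx < 0 with normal polarity); if any mass survives the edge
    position is the gradient-weighted mean column, otherwise the row is
    skipped.
    """
    ya, yb = line.a[1], line.b[1]
    y_lo, y_hi = (ya, yb) if ya <= yb else (yb, ya)
    y0 = max(int(np.floor(y_lo)) + 1, roi.y_min)
    y1 = min(int(np.ceil(y_hi)) - 1, roi.y_max - 1)
    sign = -1 if line.side == "left" else 1
    sign *= polarity
    pts: list[tuple[float, int]] = []
    xs = np.arange(roi.x_min, roi.x_max, dtype=float)
    for y in range(y0, y1 + 1):
        g = field.G[y, roi.x_min : roi.x_max]
        gx = field.gx[y, roi.x_min : roi.x_max]
        on_side = (g > 0) & (np.sign(gx) == sign)
        mass = g[on_side].sum()
        if mass <= 0:
            continue
        xbar = float((xs[on_side] * g[on_side]).sum() / mass)
        pts.append((xbar, y))
    return EdgePointSet(frame=frame_index, side=line.side, points=pts)


def smooth_temporal(series: list[EdgePointSet], window: int = 5) -> list[EdgePointSet]:
    """Centered uniform moving average of the edge abscissae over frames.

    Averaging is done per row over the frames where that row was detected
    inside the window (missing frames are excluded, not zero-filled), so no
    points are created or destroyed — closing-phase gaps remain gaps.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    if window == 1 or not series:
        return [EdgePointSet(s.frame, s.side, list(s.points)) for s in series]
    n = len(series)
    all_rows = sorted({y for s in series for _, y in s.points})
    row_idx = {y: j for j, y in enumerate(all_rows)}
    grid = np.full((n, len(all_rows)), np.nan)
    for k, s in enumerate(series):
        for xbar, y in s.points:
            grid[k, row_idx[y]] = xbar
    half = window // 2
    valid = ~np.isnan(grid)
    filled = np.where(valid, grid, 0.0)
    # centered masked running mean via cumulative sums
    csum = np.cumsum(np.vstack([np.zeros(grid.shape[1]), filled]), axis=0)
    ccnt = np.cumsum(np.vstack([np.zeros(grid.shape[1]), valid]), axis=0)
    out_series: list[EdgePointSet] = []
    for k, s in enumerate(series):
        lo, hi = max(0, k - half), min(n, k + half + 1)
        ssum = csum[hi] - csum[lo]
        scnt = ccnt[hi] - ccnt[lo]
        pts = []
        for xbar, y in s.points:
            j = row_idx[y]
            pts.append((float(ssum[j] / scnt[j]), y))
        out_series.append(EdgePointSet(s.frame, s.side, pts))
    return out_series


def detect_sequence(
    frames: np.ndarray,
    line: AttachmentLine,
    roi: ROI,
    cfg: DetectionConfig,
    fill: bool = True,
    smooth: bool = True,
) -> list[EdgePointSet]:
    """Run fill → gradient → per-row detection → temporal smoothing.

    The gradient threshold is applied relative to the recording-wide
    maximum magnitude, so a single user threshold governs the whole video.
    Callers that post-filter detections jointly across folds (see
    :func:`censor_merged_rows`) pass ``smooth=False`` and smooth afterwards.
    """
    filled = [fill_bright_regions(frames[k]) if fill else frames[k] for k in range(frames.shape[0])]
    g_ref = None
    if cfg.threshold_scope == "recording":
        # reference magnitude measured inside the ROI only, so stray
        # structure (e.g. rotation fill borders) cannot swamp the threshold
        g_ref = 0.0
        for f in filled:
            crop = roi.crop(f)
            gx = ndimage.prewitt(crop, axis=1, mode="reflect")
            gy = ndimage.prewitt(crop, axis=0, mode="reflect")
            g_ref = max(g_ref, float(np.hypot(gx, gy).max()))
    series = []
    for k, f in enumerate(filled):
        field = compute_gradient(f, cfg.t_h, g_ref=g_ref)
        series.append(detect_edges(field, line, roi, frame_index=k, polarity=cfg.polarity))
    if smooth:
        return smooth_temporal(series, cfg.temporal_window)
    return series


def censor_merged_rows(
    left: list[EdgePointSet],
    right: list[EdgePointSet],
    min_separation: float = 2.0,
) -> tuple[list[EdgePointSet], list[EdgePointSet]]:
    """Drop rows whose left/right edge centroids are unresolvably close.

    When the glottal slit in a row is narrower than the gradient kernel's
    support, the opposing edge responses overlap and both weighted means
    collapse toward the kernel flanks; such rows are removed from both
    folds so they register as detection loss rather than biased positions.
    """
    out_l, out_r = [], []
    for sl, sr in zip(left, right):
        xl = {y: x for x, y in sl.points}
        xr = {y: x for x, y in sr.points}
        drop = {y for y in xl.keys() & xr.keys() if xr[y] - xl[y] < min_separation}
        out_l.append(EdgePointSet(sl.frame, sl.side, [(x, y) for x, y in sl.points if y not in drop]))
        out_r.append(EdgePointSet(sr.frame, sr.side, [(x, y) for x, y in sr.points if y not in drop]))
    return out_l, out_r


def default_D_T(line: AttachmentLine) -> int:
    """Number of integer rows strictly between the attachment rows."""
    ya, yb = sorted((line.a[1], line.b[1]))
    return max(0, int(np.ceil(yb)) - int(np.floor(ya)) - 1)
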