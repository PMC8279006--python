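"""Video pre-processing and the attachment-line coordinate system.

Laryngeal high-speed video arrives with an arbitrary camera roll and a slow
drift from endoscope handling.  This module stabilizes the frame stack,
rotates it so the glottal axis is vertical, and defines the rotated
(u, v) coordinate frame attached to each vocal fold's anterior/posterior
attachment line — the reference frame in which all edge curves are fitted.

Conventions: 0-based pixel indices, origin at the top-left corner,
x increases rightward (medial–lateral), y increases downward
(anterior–posterior).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

logger = logging.getLogger(__name__)

__all__ = [
    "FrameSequence",
    "AttachmentLine",
    "ROI",
    "estimate_glottal_angle",
    "rotate_frames",
    "stabilize",
    "to_attachment_frame",
    "from_attachment_frame",
    "InvalidGeometryError",
]


class InvalidGeometryError(ValueError):
    """Raised for degenerate geometric input (e.g. coincident endpoints)."""


@dataclass
class FrameSequence:
    """Ordered grayscale frames with a fixed sampling rate.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Intensities in [0, 1].
    fs : float
        Sampling rate in frames per second.
    """

    frames: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) stack")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lo, hi = float(self.frames.min(initial=0.0)), float(self.frames.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities outside [0, 1]: range [{lo}, {hi}]")

    @property
    def dt(self) -> float:
        """Time lapse between successive frames, in seconds."""
        return 1.0 / self.fs

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, k: int) -> np.ndarray:
        return self.frames[k]


def estimate_glottal_angle(endpoint_anterior, endpoint_posterior) -> float:
    """Angle of the line through the glottal endpoints w.r.t. the vertical axis.

    Returns the angle in radians within (-pi/2, pi/2]; zero means the glottis
    is already vertical in the image.

    Raises
    ------
    InvalidGeometryError
        If the two endpoints coincide.
    """
    xa, ya = endpoint_anterior
    xb, yb = endpoint_posterior
    dx, dy = xb - xa, yb - ya
    if dx == 0 and dy == 0:
        raise InvalidGeometryError("glottal endpoints coincide")
    ang = math.atan2(dx, dy)
    # fold into (-pi/2, pi/2]: the line is undirected
    if ang > math.pi / 2:
        ang -= math.pi
    elif ang <= -math.pi / 2:
        ang += math.pi
    return ang


@dataclass
class AttachmentLine:
    """Anterior/posterior attachment points of one fold and their rest line.

    phi is the rotation angle of the line w.r.t. the vertical image axis;
    it is derived from the endpoints and kept consistent with them.
    """

    a: tuple[float, float]
    b: tuple[float, float]
    side: str = "left"
    phi: float = field(init=False)

    def __post_init__(self) -> None:
        if tuple(self.a) == tuple(self.b):
            raise InvalidGeometryError("attachment endpoints coincide")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        self.phi = estimate_glottal_angle(self.a, self.b)

    def anchors_uv(self) -> tuple[float, float, float]:
        """Return (u_a, v_a, v_b): the attachment points in the rotated frame.

        Both endpoints map to the same u by construction of phi (the line is
        vertical in the (u, v) frame); u_a is taken from the anterior point.
        """
        ua, va = to_attachment_frame(self.a, self)
        _, vb = to_attachment_frame(self.b, self)
        return ua, va, vb


@dataclass
class ROI:
    """Axis-aligned analysis rectangle (x_min, y_min, width, height)."""

    x_min: int
    y_min: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 1:
            raise ValueError("ROI must be at least 2 px wide")

    @property
    def x_max(self) -> int:
        return self.x_min + self.width

    @property
    def y_max(self) -> int:
        return self.y_min + self.height

    def validate_within(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.x_min < 0 or self.y_min < 0 or self.x_max > w or self.y_max > h:
            raise ValueError(f"ROI {self} outside frame bounds {shape}")

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.y_min : self.y_max, self.x_min : self.x_max]


def rotate_frames(seq: FrameSequence, angle: float) -> FrameSequence:
    """Rotate every frame by ``-angle`` about the frame center.

    A positive ``angle`` (glottal axis tilted clockwise when viewed with y
    down) is undone so the glottis becomes vertical.  Bilinear interpolation,
    zero fill outside, shape preserved.
    """
    if not math.isfinite(angle):
        raise ValueError("angle must be finite")
    if angle == 0.0:
        return FrameSequence(seq.frames.copy(), seq.fs)
    # Undoing a tilt of +angle means content points transform as
    # p' = c + R(angle) (p - c) in (x, y) with y down, which brings the
    # glottal direction (sin angle, cos angle) onto the vertical axis;
    # ndimage.rotate's positive angle moves content by R(-angle) in these
    # coordinates, hence the sign flip.
    deg = -math.degrees(angle)
    out = np.empty_like(seq.frames)
    for k in range(seq.n_frames):
        out[k] = ndimage.rotate(
            seq.frames[k], deg, reshape=False, order=1, mode="constant", cval=0.0
        )
    np.clip(out, 0.0, 1.0, out=out)
    return FrameSequence(out, seq.fs)


def _centroid_trajectory(frames: np.ndarray) -> np.ndarray:
    """Intensity centroid (x, y) per frame, shape (n, 2)."""
    n, h, w = frames.shape
    ys = np.arange(h)
    xs = np.arange(w)
    mass = frames.sum(axis=(1, 2))
    mass = np.where(mass > 0, mass, 1.0)
    cy = (frames.sum(axis=2) * ys).sum(axis=1) / mass
    cx = (frames.sum(axis=1) * xs).sum(axis=1) / mass
    return np.column_stack([cx, cy])


def stabilize(seq: FrameSequence, cutoff_hz: float = 20.0, roi: ROI | None = None) -> FrameSequence:
    """Remove slow camera drift below ``cutoff_hz``.

    The intensity-centroid trajectory of the ROI (or full frame) is low-pass
    filtered below the cutoff; the zero-mean part of that slow trajectory is
    subtracted from each frame by a translation, so endoscope wander is
    removed while the phonatory oscillation (hundreds of Hz) is untouched.
    """
    if cutoff_hz >= seq.fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    n = seq.n_frames
    b, a = signal.butter(2, cutoff_hz / (seq.fs / 2), btype="low")
    padlen = 3 * max(len(a), len(b))
    if n < 3 or n <= padlen:
        logger.warning("sequence too short for stabilization filter; no-op")
        return FrameSequence(seq.frames.copy(), seq.fs)
    crops = seq.frames if roi is None else seq.frames[:, roi.y_min : roi.y_max, roi.x_min : roi.x_max]
    traj = _centroid_trajectory(crops)
    drift = signal.filtfilt(b, a, traj, axis=0)
    drift = drift - drift.mean(axis=0)  # mean translation over the sequence is zero
    drift[np.abs(drift) < 1e-9] = 0.0  # sub-numerical shifts would only erode borders
    out = np.empty_like(seq.frames)
    for k in range(n):
        dx, dy = drift[k]
        if dx == 0.0 and dy == 0.0:
            out[k] = seq.frames[k]
        else:
            out[k] = ndimage.shift(seq.frames[k], (-dy, -dx), order=1, mode="constant", cval=0.0)
    np.clip(out, 0.0, 1.0, out=out)
    return FrameSequence(out, seq.fs)


def to_attachment_frame(pt, line: "AttachmentLine | float"):
    """Rotate an (x, y) point into the attachment-line (u, v) frame.

    (u, v) = R(phi) (x, y) with R = [[cos phi, -sin phi], [sin phi, cos phi]].
    ``line`` may be an :class:`AttachmentLine` or a bare angle in radians.
    """
    phi = line.phi if isinstance(line, AttachmentLine) else float(line)
    x, y = pt
    c, s = math.cos(phi), math.sin(phi)
    return (c * x - s * y, s * x + c * y)


def from_attachment_frame(pt_uv, line: "AttachmentLine | float"):
    """Inverse of :func:`to_attachment_frame`."""
    phi = line.phi if isinstance(line, AttachmentLine) else float(line)
    u, v = pt_uv
    c, s = math.cos(phi), math.sin(phi)
    return (c * u + s * v, -s * u + c * v)
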