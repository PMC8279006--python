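"""Frame readers/writers, analysis configuration, and kymogram export."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .geometry import ROI, FrameSequence

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "read_frames",
    "write_frames",
    "export_kymogram",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

# ITU-R BT.601 luma weights, matching the common rgb2gray convention
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class AnalysisConfig:
    """Every knob of the analysis chain with validated defaults.

    Defaults follow the recommended in vivo setup: relative gradient
    threshold 0.25 (0.5 suits clean synthetic footage), sigmoid gain 20 and
    threshold 0.5, quadratic fits, Poisson ratio 0.5 and a population
    Young's modulus of 24.75 kPa for dimensional output.
    """

    fs: float = 8000.0
    attachment_left: list = field(default_factory=list)  # [[xa, ya], [xb, yb]]
    attachment_right: list = field(default_factory=list)
    roi: list | None = None  # [x_min, y_min, width, height]
    stabilize_cutoff_hz: float | None = None
    rotate: bool = True
    t_h: float = 0.25
    temporal_window: int = 5
    fill_bright: bool = True
    polarity: int = 1
    p: int = 2
    beta: float = 20.0
    gamma: float = 0.5
    xi: float = 0.01
    sigma_d: float = 1e-3
    sigma_e: float = 1e-2
    damping_convention: str = "damping-ratio"
    w_r_init_hz: float = 150.0
    alpha: float = 1.679
    E_pa: float | None = 24750.0
    nu: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 <= self.t_h <= 1:
            raise ValueError("t_h must lie in [0, 1]")
        if self.temporal_window < 1 or self.temporal_window % 2 == 0:
            raise ValueError("temporal_window must be odd")
        if self.p < 2:
            raise ValueError("polynomial order must be >= 2")
        if not 0 <= self.xi < 1:
            raise ValueError("xi must lie in [0, 1)")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.E_pa is not None and self.E_pa <= 0:
            raise ValueError("E must be positive")
        if not -1 < self.nu <= 0.5:
            raise ValueError("nu must lie in (-1, 0.5]")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def roi_obj(self, shape: tuple[int, int]) -> ROI:
        if self.roi is None:
            return ROI(0, 0, shape[1], shape[0])
        r = ROI(*self.roi)
        r.validate_within(shape)
        return r


def _to_gray01(arr: np.ndarray) -> np.ndarray:
    """Convert one frame to float grayscale in [0, 1]."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
        scale = 255.0
    else:
        scale = {np.dtype("uint8"): 255.0, np.dtype("uint16"): 65535.0}.get(arr.dtype, None)
    arr = arr.astype(float)
    if scale is not None:
        arr = arr / scale
    elif arr.max() > 1.0:
        arr = arr / (255.0 if arr.max() <= 255 else 65535.0)
    return np.clip(arr, 0.0, 1.0)


def read_frames(path, fs: float) -> FrameSequence:
    """Load a frame stack from a directory of PNG/TIFF files, a multi-page
    TIFF, or an AVI; frames are converted to grayscale intensities in [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise ValueError(f"no PNG/TIFF frames in {path}")
        for f in files:
            frames.append(_to_gray01(iio.imread(f)))
    elif path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames = [_to_gray01(f) for f in stack]
    elif path.suffix.lower() == ".avi":
        try:
            for f in iio.imiter(path):
                frames.append(_to_gray01(f))
        except Exception as exc:  # codec failure
            raise ValueError(f"unreadable video {path}: {exc}") from exc
    else:
        raise ValueError(f"unsupported container: {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame shapes: {sorted(shapes)}")
    logger.info("read %d frames of shape %s from %s", len(frames), frames[0].shape, path)
    return FrameSequence(np.stack(frames), fs)


def write_frames(seq: FrameSequence, out_dir) -> list[Path]:
    """Write a sequence as zero-padded 8-bit PNG frames."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(seq.n_frames):
        p = out_dir / f"frame_{k:05d}.png"
        iio.imwrite(p, np.round(seq.frames[k] * 255).astype(np.uint8))
        paths.append(p)
    return paths


def export_kymogram(source, row: int) -> np.ndarray:
    """Time-by-x kymogram at one scanline.

    From a :class:`FrameSequence` this is the intensity scanline per frame
    (shape n_frames x width).  From a fitted results object it is the pair
    of tracked edge positions at that row (shape n_frames x 2).
    """
    if isinstance(source, FrameSequence):
        h = source.shape[0]
        if not 0 <= row < h:
            raise ValueError(f"row {row} outside frame height {h}")
        return source.frames[:, row, :].copy()
    # results object: expects edge_positions_at(row)
    return source.edge_positions_at(row)
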