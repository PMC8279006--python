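"""Contact Pressure Analysis as a fit-able model.

:class:`ContactPressureModel` bundles a frame stack, the user-identified
attachment points, and the analysis configuration; :meth:`fit` runs the
five-stage chain — pre-processing, edge detection, constrained curve
fitting, Kalman-filter edge tracking, Hertzian contact evaluation — and
returns a :class:`ContactPressureResults` carrying per-frame penetration,
contact length, normalized (and optionally dimensional) peak pressure,
cycle-aggregated summaries and per-stage diagnostics.

Example
-------
>>> from glottipress import simulate, ContactPressureModel
>>> seq, gt = simulate.generate_phantom(simulate.PhantomConfig())
>>> model = ContactPressureModel.from_ground_truth(seq, gt, t_h=0.5)
>>> res = model.fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import contact as _contact
from . import curves as _curves
from . import edges as _edges
from . import geometry as _geom
from . import tracking as _tracking
from .io import AnalysisConfig
from .simulate import GroundTruth

logger = logging.getLogger(__name__)

__all__ = ["ContactPressureModel", "ContactPressureResults"]


def _default_roi(line_l, line_r, shape) -> _geom.ROI:
    """Glottis-centered analysis box: the attachment-point bounding box
    padded laterally by a quarter of the frame width and axially by a few
    rows, clipped to the frame."""
    h, w = shape
    xs = [line_l.a[0], line_l.b[0], line_r.a[0], line_r.b[0]]
    ys = [line_l.a[1], line_l.b[1], line_r.a[1], line_r.b[1]]
    pad_x = max(10, int(0.25 * w))
    pad_y = 5
    x0 = max(0, int(np.floor(min(xs))) - pad_x)
    x1 = min(w, int(np.ceil(max(xs))) + pad_x)
    y0 = max(0, int(np.floor(min(ys))) - pad_y)
    y1 = min(h, int(np.ceil(max(ys))) + pad_y)
    return _geom.ROI(x0, y0, x1 - x0, y1 - y0)


def _rotate_point(pt, angle: float, center) -> tuple[float, float]:
    """Where a content point lands after the frames rotate by -angle."""
    cx, cy = center
    x, y = pt[0] - cx, pt[1] - cy
    c, s = np.cos(angle), np.sin(angle)
    # content transform of rotate_frames: p' = c + R(angle) (p - c)
    return (c * x - s * y + cx, s * x + c * y + cy)


class ContactPressureModel:
    """Normalized vocal-fold collision pressure from uncalibrated video.

    Parameters
    ----------
    frames : FrameSequence
        Grayscale stack with known frame rate.
    config : AnalysisConfig
        Attachment points (required), detection/tracking/contact parameters.
    """

    def __init__(self, frames: _geom.FrameSequence, config: AnalysisConfig):
        if not config.attachment_left or not config.attachment_right:
            raise ValueError("attachment points for both folds are required")
        self.frames = frames
        self.config = config

    @classmethod
    def from_ground_truth(cls, frames, gt: GroundTruth, **overrides) -> "ContactPressureModel":
        """Build a model for simulator output, reusing its attachment geometry."""
        ua, va, vb = gt.anchors
        al = gt.attach_left or ((ua, va), (ua, vb))
        ar = gt.attach_right or ((ua, va), (ua, vb))
        cfg = AnalysisConfig(
            fs=gt.fs,
            attachment_left=[list(al[0]), list(al[1])],
            attachment_right=[list(ar[0]), list(ar[1])],
            t_h=overrides.pop("t_h", 0.5),
            rotate=False,
            **overrides,
        )
        return cls(frames, cfg)

    def fit(self) -> "ContactPressureResults":
        cfg = self.config
        seq = self.frames

        # -- stage 1: pre-processing -------------------------------------
        if cfg.stabilize_cutoff_hz:
            seq = _geom.stabilize(seq, cfg.stabilize_cutoff_hz, roi=None)
        pts_l = [tuple(p) for p in cfg.attachment_left]
        pts_r = [tuple(p) for p in cfg.attachment_right]
        angle = 0.0
        if cfg.rotate:
            mid_ant = tuple(np.mean([pts_l[0], pts_r[0]], axis=0))
            mid_post = tuple(np.mean([pts_l[1], pts_r[1]], axis=0))
            angle = _geom.estimate_glottal_angle(mid_ant, mid_post)
            if abs(angle) > 1e-9:
                seq = _geom.rotate_frames(seq, angle)
                h, w = seq.shape
                center = ((w - 1) / 2.0, (h - 1) / 2.0)
                pts_l = [_rotate_point(p, angle, center) for p in pts_l]
                pts_r = [_rotate_point(p, angle, center) for p in pts_r]
        line_l = _geom.AttachmentLine(pts_l[0], pts_l[1], side="left")
        line_r = _geom.AttachmentLine(pts_r[0], pts_r[1], side="right")
        if cfg.roi is not None:
            roi = cfg.roi_obj(seq.shape)
        else:
            roi = _default_roi(line_l, line_r, seq.shape)

        det_cfg = _edges.DetectionConfig(
            t_h=cfg.t_h, temporal_window=cfg.temporal_window, polarity=cfg.polarity
        )
        track_cfg = _tracking.TrackingConfig(
            beta=cfg.beta,
            gamma=cfg.gamma,
            xi=cfg.xi,
            sigma_e=cfg.sigma_e,
            sigma_d=cfg.sigma_d,
            damping_convention=cfg.damping_convention,
            w_r_init=2 * np.pi * cfg.w_r_init_hz,
        )

        # -- stage 2: edge detection (joint left/right censoring) ---------
        raw_l = _edges.detect_sequence(seq.frames, line_l, roi, det_cfg, fill=cfg.fill_bright,
                                       smooth=False)
        raw_r = _edges.detect_sequence(seq.frames, line_r, roi, det_cfg, fill=cfg.fill_bright,
                                       smooth=False)
        raw_l, raw_r = _edges.censor_merged_rows(raw_l, raw_r, det_cfg.min_separation_px)
        detections = {
            "left": _edges.smooth_temporal(raw_l, det_cfg.temporal_window),
            "right": _edges.smooth_temporal(raw_r, det_cfg.temporal_window),
        }

        sides = {}
        for line in (line_l, line_r):
            pts = detections[line.side]
            # -- stage 3: constrained curve fitting ----------------------
            anchors = line.anchors_uv()
            to_uv = lambda p, _phi=line.phi: _geom.to_attachment_frame(p, _phi)
            cs = _curves.fit_sequence(pts, to_uv, anchors, cfg.p, seq.dt, side=line.side)
            # -- stage 4: Kalman-filter tracking -------------------------
            D_T = _edges.default_D_T(line)
            tr = _tracking.track_sequence(cs, D_T, track_cfg)
            sides[line.side] = dict(points=pts, curves=cs, tracking=tr, line=line)

        # -- stage 5: Hertzian contact -----------------------------------
        va = max(min(line_l.a[1], line_l.b[1]), min(line_r.a[1], line_r.b[1]))
        vb = min(max(line_l.a[1], line_l.b[1]), max(line_r.a[1], line_r.b[1]))
        rows = np.arange(int(np.floor(va)) + 1, int(np.ceil(vb)))
        cl = [
            _curves.EdgeCurve(sides["left"]["tracking"].theta[k], sides["left"]["curves"].anchors)
            for k in range(seq.n_frames)
        ]
        cr = [
            _curves.EdgeCurve(sides["right"]["tracking"].theta[k], sides["right"]["curves"].anchors)
            for k in range(seq.n_frames)
        ]
        series = _contact.compute_contact_series(cl, cr, rows, alpha=cfg.alpha)
        tissue = (
            _contact.TissueProperties(E1=cfg.E_pa, nu1=cfg.nu, alpha=cfg.alpha)
            if cfg.E_pa
            else None
        )
        summary = _contact.summarize_contact(series, tissue)

        return ContactPressureResults(
            model=self,
            processed=seq,
            rotation_angle=angle,
            sides=sides,
            rows=rows,
            contact_series=series,
            contact_summary=summary,
        )


@dataclass
class ContactPressureResults:
    """Fitted per-frame contact quantities and cycle summaries."""

    model: ContactPressureModel
    processed: _geom.FrameSequence
    rotation_angle: float
    sides: dict
    rows: np.ndarray
    contact_series: list
    contact_summary: _contact.ContactSummary
    _frame_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return self.processed.n_frames

    @property
    def cycle_peaks_pnorm(self) -> list[float]:
        return self.contact_summary.cycle_peaks_pnorm

    @property
    def cycle_peaks_delta(self) -> list[float]:
        return self.contact_summary.cycle_peaks_delta

    @property
    def mean_peak_pnorm(self) -> float | None:
        return self.contact_summary.mean_peak_pnorm

    @property
    def mean_peak_pressure_pa(self) -> float | None:
        return self.contact_summary.mean_peak_pressure_pa

    @property
    def frame_table(self) -> pd.DataFrame:
        """Per-frame results: delta, contact length, P_norm, glottal area."""
        if self._frame_table is None:
            dt = self.processed.dt
            rows = []
            for r in self.contact_series:
                rows.append(
                    dict(
                        frame=r.frame,
                        time_s=r.frame * dt,
                        delta_px=r.delta,
                        Lc_px=r.L_c,
                        Pnorm=r.P_norm,
                        area_px2=r.area,
                        rho_left=self.sides["left"]["tracking"].rho[r.frame],
                        rho_right=self.sides["right"]["tracking"].rho[r.frame],
                    )
                )
            self._frame_table = pd.DataFrame(rows)
        return self._frame_table

    def edge_positions_at(self, row: int) -> np.ndarray:
        """Tracked left/right edge x at one scanline per frame (kymogram)."""
        if row not in set(self.rows.tolist()):
            raise ValueError(f"row {row} outside the common glottal span")
        out = np.empty((self.n_frames, 2))
        for j, side in enumerate(("left", "right")):
            cs = self.sides[side]["curves"]
            tr = self.sides[side]["tracking"]
            for k in range(self.n_frames):
                out[k, j] = _curves.evaluate_curve(
                    _curves.EdgeCurve(tr.theta[k], cs.anchors), float(row)
                )
        return out

    def summary(self) -> str:
        """Human-readable run summary."""
        s = self.contact_summary
        cfg = self.model.config
        lines = [
            "Contact Pressure Analysis Results",
            "=" * 49,
            f"{'Frames analyzed':32s} {self.n_frames}",
            f"{'Frame rate (fps)':32s} {self.model.frames.fs:g}",
            f"{'Rotation applied (rad)':32s} {self.rotation_angle:.4f}",
            f"{'Polynomial order p':32s} {cfg.p}",
            f"{'Contact cycles':32s} {s.n_cycles}",
        ]
        if s.n_cycles:
            lines += [
                f"{'Mean peak penetration (px)':32s} {np.mean(s.cycle_peaks_delta):.3f}",
                f"{'Mean peak P_c/E* (-)':32s} {s.mean_peak_pnorm:.4f}",
            ]
            if s.mean_peak_pressure_pa is not None:
                lines += [
                    f"{'Effective modulus E* (kPa)':32s} {s.E_star / 1e3:.1f}",
                    f"{'Mean peak pressure (kPa)':32s} {s.mean_peak_pressure_pa / 1e3:.2f}",
                ]
        else:
            lines.append("No vocal-fold contact detected.")
        lines.append("=" * 49)
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        s = self.contact_summary
        cfg = self.model.config
        return {
            "schema_version": 1,
            "n_frames": int(self.n_frames),
            "cycles": int(s.n_cycles),
            "cycle_peaks_pnorm": [float(v) for v in s.cycle_peaks_pnorm],
            "cycle_peaks_delta_px": [float(v) for v in s.cycle_peaks_delta],
            "mean_peak_pnorm": None if s.mean_peak_pnorm is None else float(s.mean_peak_pnorm),
            "mean_peak_pc_pa": None
            if s.mean_peak_pressure_pa is None
            else float(s.mean_peak_pressure_pa),
            "parameters": {
                "alpha": cfg.alpha,
                "E_pa": cfg.E_pa,
                "nu": cfg.nu,
                "fs": cfg.fs,
                "p": cfg.p,
                "t_h": cfg.t_h,
                "beta": cfg.beta,
                "gamma": cfg.gamma,
            },
        }

    def plot_waveforms(self, ax=None):
        """Penetration and normalized pressure vs time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.frame_table["time_s"]
        ax.plot(t, self.frame_table["delta_px"], label=r"$\delta$ (px)")
        ax2 = ax.twinx()
        ax2.plot(t, self.frame_table["Pnorm"], color="C1", label=r"$P_c/E^*$")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("penetration (px)")
        ax2.set_ylabel(r"$P_c/E^*$")
        return ax
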