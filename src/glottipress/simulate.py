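"""Synthetic high-speed video with known ground truth.

Two generators back the validation of the analysis chain:

* an analytic *kinematic phantom* — two quadratic fold edges oscillating in
  antiphase about a vertical glottal midline, clipped where they would
  cross, so the fictitious pre-clip overlap (the quantity the tracker must
  reconstruct) is known in closed form per frame; and

* a *lumped-element collision surrogate* — each fold's medial point is a
  mass-normalized spring-damper driven by a subglottal-pressure-
  proportional force that acts while the glottis is (nearly) closed, with a
  penalty spring during overlap and a triangular anterior-medial-posterior
  fold shape.  Posterior/membranous gap offsets model incomplete closure.
  It reproduces the features the analysis consumes (threshold onset of
  contact, amplitude growth with driving pressure, fragmented contact with
  end gaps); it is not a physiological voice-production model.

Frames show bright folds (0.8) around a dark glottal gap (0.1), rendered
with sub-pixel area coverage, plus optional Gaussian noise and specular
highlight blobs.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import FrameSequence

__all__ = [
    "PhantomConfig",
    "SurrogateConfig",
    "GroundTruth",
    "generate_phantom",
    "simulate_surrogate",
    "render_surrogate",
    "render_frames",
    "InstabilityError",
]

FOLD_INTENSITY = 0.8
GAP_INTENSITY = 0.1


class InstabilityError(RuntimeError):
    """Surrogate trajectories diverged for the given parameters."""


@dataclass
class PhantomConfig:
    """Analytic phantom parameters (pixel/frame units)."""

    fs: float = 8000.0
    n_frames: int = 160
    size: tuple[int, int] = (200, 200)  # (height, width)
    f0: float = 200.0
    amplitude: float = 10.0  # half peak-to-peak medial excursion of one edge, px
    overlap_max: float = 3.0  # peak fictitious overlap at mid-cycle, px
    attachment_rows: tuple[int, int] = (30, 170)
    noise_sd: float = 0.0
    highlight_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 >= self.fs / 2:
            raise ValueError("f0 must be below Nyquist")
        if self.overlap_max < 0:
            raise ValueError("overlap_max must be >= 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        va, vb = self.attachment_rows
        if not (0 <= va < vb < self.size[0]):
            raise ValueError("attachment rows must be ordered inside the frame")
        if self.overlap_max + 4 * self.amplitude > self.size[1]:
            raise ValueError("oscillation exceeds frame width")


@dataclass
class GroundTruth:
    """Simulator truth channels aligned with the rendered frames.

    ``edge_left``/``edge_right`` are the *unclipped* edge positions at the
    integer glottal rows; ``delta_true`` is the apparent penetration (max
    positive pre-clip overlap); ``theta_*`` are the exact quadratic
    coefficients when the edges are quadratics (phantom only).
    """

    rows: np.ndarray
    edge_left: np.ndarray  # (n_frames, n_rows)
    edge_right: np.ndarray
    delta_true: np.ndarray  # (n_frames,)
    contact_rows: np.ndarray  # (n_frames,) int
    anchors: tuple[float, float, float]  # (u_a, v_a, v_b)
    fs: float
    theta_left: np.ndarray | None = None
    theta_right: np.ndarray | None = None
    pressure_au: np.ndarray | None = None  # surrogate penalty pressure channel
    #: per-fold attachment points ((x_a, y_a), (x_b, y_b)) when the rest
    #: lines do not coincide with the glottal midline (surrogate end gaps)
    attach_left: tuple | None = None
    attach_right: tuple | None = None


def _render_row(width: int, gap_lo: float, gap_hi: float) -> np.ndarray:
    """One image row: bright fold with a dark gap, sub-pixel coverage."""
    row = np.full(width, FOLD_INTENSITY)
    if gap_hi <= gap_lo:
        return row
    x = np.arange(width)
    cov = np.clip(np.minimum(gap_hi, x + 0.5) - np.maximum(gap_lo, x - 0.5), 0.0, 1.0)
    return row - (FOLD_INTENSITY - GAP_INTENSITY) * cov


def render_frames(
    edge_left: np.ndarray,
    edge_right: np.ndarray,
    rows: np.ndarray,
    size: tuple[int, int] = (300, 300),
    fs: float = 8750.0,
    noise_sd: float = 0.0,
    highlight_prob: float = 0.0,
    seed: int = 0,
) -> FrameSequence:
    """Render per-frame left/right edge positions into an intensity stack.

    The gap between the clipped edges is dark, fold tissue bright; edges are
    anti-aliased by exact area coverage so sub-pixel localization is
    meaningful.  Rows outside the glottal span are pure fold tissue.
    """
    n, n_rows = edge_left.shape
    h, w = size
    if edge_left.min() < -0.5 or edge_right.max() > w - 0.5:
        raise ValueError("trajectories leave the frame")
    rng = np.random.default_rng(seed)
    frames = np.full((n, h, w), FOLD_INTENSITY)
    for k in range(n):
        for j, y in enumerate(rows):
            a, b = edge_left[k, j], edge_right[k, j]
            frames[k, int(y)] = _render_row(w, a, b)
        if highlight_prob > 0 and rng.random() < highlight_prob:
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            yy, xx = np.mgrid[0:h, 0:w]
            frames[k] += 0.15 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0**2))
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)
    np.clip(frames, 0.0, 1.0, out=frames)
    return FrameSequence(frames, fs)


def _phantom_vertex_offset(t: np.ndarray, f0: float, A: float, overlap_max: float) -> np.ndarray:
    """Medial offset h(t) of the left edge vertex: piecewise-harmonic cycle.

    Each period splits into an open half-wave h = -A sin(pi tau / T_o) about
    the rest (attachment) line and a collision half-wave of peak
    ``overlap_max/2`` at the higher frequency that keeps the velocity
    continuous at the crossings — the trajectory a linear spring-mass fold
    with a stiffer contact spring actually follows, with the contact
    duration T_c = T_o * overlap_max / (2A) set by the impact velocity.
    """
    T0 = 1.0 / f0
    r = overlap_max / (2.0 * A)
    T_o = T0 / (1.0 + r)
    T_c = T0 - T_o
    tau = np.mod(t, T0)
    h = np.where(
        tau < T_o,
        -A * np.sin(np.pi * tau / T_o),
        (overlap_max / 2.0) * np.sin(np.pi * (tau - T_o) / max(T_c, 1e-300)),
    )
    if overlap_max == 0:
        h = -A * np.sin(np.pi * tau / T0)
    return h


def generate_phantom(cfg: PhantomConfig) -> tuple[FrameSequence, GroundTruth]:
    """Render the analytic phantom and its exact ground truth.

    Both edges are quadratics through the shared glottal endpoints moving in
    antiphase; the vertex offset follows the piecewise-harmonic collision
    cycle of :func:`_phantom_vertex_offset`, so the fictitious (pre-clip)
    overlap reaches ``overlap_max`` at mid-contact.  Rendering clips the
    edges where they cross.
    """
    h, w = cfg.size
    va, vb = cfg.attachment_rows
    x_mid = (w - 1) / 2.0
    rows = np.arange(va + 1, vb)
    norm = ((vb - va) / 2.0) ** 2  # max of (v - va)(vb - v)
    q = (rows - va) * (vb - rows) / norm

    t = np.arange(cfg.n_frames) / cfg.fs
    h_l = _phantom_vertex_offset(t, cfg.f0, cfg.amplitude, cfg.overlap_max)

    edge_left = x_mid + np.outer(h_l, q)  # unclipped
    edge_right = x_mid - np.outer(h_l, q)
    delta_true = np.maximum(0.0, 2.0 * h_l)
    contact_rows = np.where(h_l > 0, len(rows), 0).astype(int)
    theta_left = -h_l / norm  # M(v) = theta (v-va)(v-vb) + x_mid
    theta_right = h_l / norm

    seq = render_frames(
        np.minimum(edge_left, x_mid),
        np.maximum(edge_right, x_mid),
        rows,
        size=cfg.size,
        fs=cfg.fs,
        noise_sd=cfg.noise_sd,
        highlight_prob=cfg.highlight_prob,
        seed=cfg.seed,
    )
    gt = GroundTruth(
        rows=rows,
        edge_left=edge_left,
        edge_right=edge_right,
        delta_true=delta_true,
        contact_rows=contact_rows,
        anchors=(x_mid, float(va), float(vb)),
        fs=cfg.fs,
        theta_left=theta_left,
        theta_right=theta_right,
    )
    return seq, gt


@dataclass
class SurrogateConfig:
    """Lumped-element collision surrogate parameters.

    Forces are mass-normalized (accelerations, px/s^2).  ``drive_gain``
    converts subglottal pressure (Pa) into drive acceleration; the drive
    acts on each fold, pushing laterally, while the medial gap is below
    ``gap_on`` px, emulating pressure build-up under a (nearly) closed
    glottis.  ``rest_gap`` is the total medial gap at rest; posterior and
    membranous (anterior) end gaps shift the rest line ends outward.
    """

    P_s: float = 1500.0  # subglottal pressure, Pa
    fs: float = 8750.0
    n_frames: int = 300
    f_natural: float = 140.0  # natural frequency of each fold, Hz
    xi: float = 0.05  # damping ratio of each fold
    rest_gap: float = 1.0  # medial glottal gap at rest, px (total)
    #: net oscillation onset pressure: below it the flow-induced (negative)
    #: damping does not overcome the structural damping and the folds settle
    #: at rest — static equilibrium, no contact
    P_onset_pa: float = 650.0
    #: amplitude calibration of the saturating (Rayleigh) self-oscillation:
    #: the free medial half-amplitude reaches amp_ref_px at P_ref_pa
    amp_ref_px: float = 2.0
    P_ref_pa: float = 1000.0
    penalty_ratio: float = 4.0  # penalty stiffness / fold stiffness
    pgo_gap: float = 0.0  # posterior end gap, px (total)
    mgo_gap: float = 0.0  # anterior/membranous end gap, px (total)
    n_sections: int = 21
    size: tuple[int, int] = (300, 300)
    attachment_rows: tuple[int, int] = (40, 260)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penalty_ratio <= 1:
            raise ValueError("penalty stiffness must exceed fold stiffness")
        if min(self.rest_gap, self.pgo_gap, self.mgo_gap) < 0:
            raise ValueError("gaps must be >= 0")
        if self.P_ref_pa <= self.P_onset_pa:
            raise ValueError("P_ref_pa must exceed P_onset_pa")

    @classmethod
    def complete_closure(cls, P_s: float, **kw) -> "SurrogateConfig":
        """Adducted configuration: folds nearly touch at rest."""
        return cls(P_s=P_s, rest_gap=1.0, pgo_gap=0.0, mgo_gap=0.0, **kw)

    @classmethod
    def incomplete_closure(cls, P_s: float, **kw) -> "SurrogateConfig":
        """Persistent posterior/membranous opening: contact needs a larger
        oscillation amplitude, so its pressure threshold is higher."""
        return cls(P_s=P_s, rest_gap=3.0, pgo_gap=2.0, mgo_gap=2.0, **kw)


def _fold_shape(x_ant: float, x_med: float, x_post: float, frac: np.ndarray) -> np.ndarray:
    """Triangular fold surface: linear anterior-medial and medial-posterior."""
    lower = frac <= 0.5
    out = np.empty_like(frac)
    out[lower] = x_ant + (x_med - x_ant) * (frac[lower] / 0.5)
    out[~lower] = x_med + (x_post - x_med) * ((frac[~lower] - 0.5) / 0.5)
    return out


def simulate_surrogate(cfg: SurrogateConfig) -> tuple[dict, GroundTruth]:
    """Integrate the two-fold collision surrogate.

    Returns a dict with the medial trajectories and per-frame edge surfaces
    plus the GroundTruth channels (overlap, contact rows, penalty pressure).
    Semi-implicit Euler with sub-stepping keeps the stiff penalty stable.
    """
    h, w = cfg.size
    va, vb = cfg.attachment_rows
    x_mid = (w - 1) / 2.0
    rows = np.arange(va + 1, vb)
    frac = (rows - va) / (vb - va)

    k_spring = (2 * np.pi * cfg.f_natural) ** 2
    c_damp = 2 * cfg.xi * np.sqrt(k_spring)
    k_pen = cfg.penalty_ratio * k_spring
    # Rayleigh-type self-oscillation: the airflow and structural damping
    # combine into a net linear damping coefficient g = mu (P_s - P_onset)
    # (negative below onset: the folds settle at rest); a cubic velocity
    # term saturates the limit cycle, with nu calibrated so the free medial
    # half-amplitude is amp_ref_px at P_ref_pa
    w_n = 2 * np.pi * cfg.f_natural
    mu = c_damp / (cfg.P_ref_pa - cfg.P_onset_pa)
    g_ref = mu * (cfg.P_ref_pa - cfg.P_onset_pa)
    nu = 4.0 * g_ref / (3.0 * cfg.amp_ref_px**2 * w_n**2)
    g_net = mu * (cfg.P_s - cfg.P_onset_pa)

    # rest geometry: left fold edge offsets (negative x side), mirrored right
    ant_off = (cfg.rest_gap + cfg.mgo_gap) / 2.0
    post_off = (cfg.rest_gap + cfg.pgo_gap) / 2.0
    med_rest = cfg.rest_gap / 2.0

    dt = 1.0 / cfg.fs
    n_sub = max(1, int(np.ceil(np.sqrt(k_pen * dt**2 / 0.05))))
    dts = dt / n_sub

    xl = -med_rest  # medial point of left fold, relative to midline
    xr = med_rest
    # a mirror-symmetric velocity kick seeds the oscillation; below the
    # onset pressure it simply decays back to rest
    vl = 0.5 * w_n
    vr = -0.5 * w_n
    traj_l = np.empty(cfg.n_frames)
    traj_r = np.empty(cfg.n_frames)
    edge_left = np.empty((cfg.n_frames, len(rows)))
    edge_right = np.empty((cfg.n_frames, len(rows)))
    delta_true = np.empty(cfg.n_frames)
    contact_rows = np.empty(cfg.n_frames, dtype=int)
    pressure_au = np.empty(cfg.n_frames)

    for kf in range(cfg.n_frames):
        for _ in range(n_sub):
            surf_l = _fold_shape(-ant_off, xl, -post_off, frac)
            surf_r = _fold_shape(ant_off, xr, post_off, frac)
            overlap = surf_l - surf_r
            mean_pos = np.maximum(overlap, 0.0).mean()
            a_l = -k_spring * (xl + med_rest) + g_net * vl - nu * vl**3
            a_r = -k_spring * (xr - med_rest) + g_net * vr - nu * vr**3
            if mean_pos > 0:
                a_l -= k_pen * mean_pos
                a_r += k_pen * mean_pos
            vl += a_l * dts
            vr += a_r * dts
            xl += vl * dts
            xr += vr * dts
            if abs(xl) > w / 2 or abs(xr) > w / 2:
                raise InstabilityError(
                    f"surrogate diverged (P_s={cfg.P_s}, penalty_ratio={cfg.penalty_ratio})"
                )
        surf_l = _fold_shape(-ant_off, xl, -post_off, frac)
        surf_r = _fold_shape(ant_off, xr, post_off, frac)
        overlap = surf_l - surf_r
        traj_l[kf], traj_r[kf] = xl, xr
        edge_left[kf] = x_mid + surf_l
        edge_right[kf] = x_mid + surf_r
        delta_true[kf] = max(0.0, float(overlap.max()))
        contact_rows[kf] = int(np.count_nonzero(overlap > 0))
        pressure_au[kf] = k_pen * max(0.0, float(overlap.max()))

    gt = GroundTruth(
        rows=rows,
        edge_left=edge_left,
        edge_right=edge_right,
        delta_true=delta_true,
        contact_rows=contact_rows,
        anchors=(x_mid, float(va), float(vb)),
        fs=cfg.fs,
        pressure_au=pressure_au,
        attach_left=((x_mid - ant_off, float(va)), (x_mid - post_off, float(vb))),
        attach_right=((x_mid + ant_off, float(va)), (x_mid + post_off, float(vb))),
    )
    trajectories = {
        "t": np.arange(cfg.n_frames) * dt,
        "medial_left": traj_l,
        "medial_right": traj_r,
        "edge_left": edge_left,
        "edge_right": edge_right,
        "rows": rows,
    }
    return trajectories, gt


def render_surrogate(cfg: SurrogateConfig) -> tuple[FrameSequence, GroundTruth]:
    """Simulate the surrogate and render its frames (clipped at crossing)."""
    traj, gt = simulate_surrogate(cfg)
    mid = np.minimum(gt.edge_left, gt.edge_right) / 2 + np.maximum(gt.edge_left, gt.edge_right) / 2
    seq = render_frames(
        np.minimum(gt.edge_left, mid),
        np.maximum(gt.edge_right, mid),
        gt.rows,
        size=cfg.size,
        fs=cfg.fs,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )
    return seq, gt
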