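"""Kalman-filter bridging of the collision phase.

During collision the glottis closes, the edge detector loses its points and
the polynomial fit degenerates — precisely when the fictitious overlap must
be known.  Each curve coefficient is therefore tracked by an independent
two-state Kalman filter whose process model is a mass-normalized
spring-damper oscillating at the fold's resonance:

    X_{k+1} = A X_k,   A = [[1, dt], [-K dt, 1 - b dt]],
    K = w_r^2 / (1 - xi^2).

A sigmoid uncertainty factor rho computed from the fraction of lost edge
rows gates between the measured coefficients (rho -> 0, open phase) and the
model prediction (rho -> 1, collision), and the resonance w_r is re-fitted
per contact event from the pre-impact position/velocity so the bridged
trajectory rejoins the observations at contact release.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .curves import CurveSequence

logger = logging.getLogger(__name__)

__all__ = [
    "OscillatorParams",
    "KFState",
    "TrackingConfig",
    "TrackingResult",
    "compute_uncertainty",
    "estimate_resonance",
    "oscillator_matrices",
    "kf_step",
    "track_sequence",
    "UndefinedAmplitudeError",
]


class UndefinedAmplitudeError(ValueError):
    """Zero pre-impact position and velocity: resonance is unidentifiable."""


@dataclass
class OscillatorParams:
    """Discretized spring-damper process model for one coefficient."""

    w_r: float
    xi: float
    dt: float
    K: float
    b: float
    A: np.ndarray


def compute_uncertainty(D_k: int, D_T: int, beta: float = 20.0, gamma: float = 0.5):
    """Non-detected ratio lambda and sigmoid uncertainty factor rho.

    lambda = (D_T - D_k)/D_T in [0, 1];  rho = 1/(1 + exp(-beta (lambda - gamma))).
    rho is monotone increasing in lambda and equals 1/2 at lambda = gamma.
    """
    if D_T < 1:
        raise ValueError("D_T must be >= 1")
    if D_k < 0:
        raise ValueError("D_k must be >= 0")
    if D_k > D_T:
        logger.warning("D_k=%d exceeds D_T=%d; clamping", D_k, D_T)
        D_k = D_T
    lam = (D_T - D_k) / D_T
    rho = 1.0 / (1.0 + np.exp(-beta * (lam - gamma)))
    return lam, float(rho)


def estimate_resonance(
    theta_k0: float,
    theta_dot_k0: float,
    theta_k1: float,
    t_k1: float,
    bounds: tuple[float, float] | None = None,
    n_grid: int = 2000,
    require_crossing: bool = False,
) -> float:
    """Resonance that carries the pre-impact state to the release position.

    Minimizes |F(w) - theta_k1| with F(w) = theta_k0 cos(w t) +
    (theta_dot_k0 / w) sin(w t) over a bounded w grid followed by a local
    refine; deterministic for fixed inputs.

    With ``require_crossing`` the trajectory must reach the contact plane
    (change sign relative to the pre-impact position) somewhere inside
    (0, t_k1): the tracker sets this because the detection loss being
    bridged asserts that a collision actually happened, which rules out
    degenerate slow solutions that merely drift back to the release value.
    """
    if t_k1 <= 0:
        raise ValueError("t_k1 must be positive")
    if theta_k0 == 0.0 and theta_dot_k0 == 0.0:
        raise UndefinedAmplitudeError("zero pre-impact state")
    if bounds is None:
        bounds = (2 * np.pi * 30.0, np.pi / t_k1)
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("invalid resonance search bounds")

    def objective(w):
        return abs(theta_k0 * np.cos(w * t_k1) + theta_dot_k0 / w * np.sin(w * t_k1) - theta_k1)

    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([objective(w) for w in grid])
    # refine every local minimum; when several solve the return condition
    # equally well (the endpoint equation aliases in w), keep the smallest
    # resonance — the physically slowest oscillation consistent with the data
    cand: list[tuple[float, float]] = []
    for j in range(n_grid):
        left = vals[j - 1] if j > 0 else np.inf
        right = vals[j + 1] if j < n_grid - 1 else np.inf
        if vals[j] <= left and vals[j] <= right:
            a, b = grid[max(0, j - 1)], grid[min(n_grid - 1, j + 1)]
            if a < b:
                res = minimize_scalar(
                    objective, bounds=(a, b), method="bounded", options={"xatol": 1e-8}
                )
                w_j, f_j = float(res.x), float(res.fun)
                if f_j > vals[j]:
                    w_j, f_j = float(grid[j]), float(vals[j])
            else:
                w_j, f_j = float(grid[j]), float(vals[j])
            cand.append((w_j, f_j))
    scale = max(abs(theta_k0), abs(theta_k1), abs(theta_dot_k0) * t_k1, 1e-300)
    best = min(f for _, f in cand)
    good = [w for w, f in cand if f <= best + 1e-6 * scale]
    if require_crossing and theta_k0 != 0.0:
        # prefer, among equally good solutions, one whose swing reaches the
        # contact plane — but never trade endpoint fidelity for it
        tau = np.linspace(0.0, t_k1, 64)[1:]

        def crosses(w):
            traj = theta_k0 * np.cos(w * tau) + theta_dot_k0 / w * np.sin(w * tau)
            return bool(np.any(np.sign(traj) == -np.sign(theta_k0)))

        crossing = [w for w in good if crosses(w)]
        if crossing:
            return float(min(crossing))
    return float(min(good))


def oscillator_matrices(
    w_r: float,
    xi: float,
    dt: float,
    damping_convention: str = "damping-ratio",
    discretization: str = "exact",
) -> OscillatorParams:
    """Assemble K, b and the one-step transition matrix A.

    K = w_r^2/(1 - xi^2).  The damping parameter follows the chosen
    convention: "damping-ratio" uses b = 2 xi sqrt(K) (underdamped for the
    physiological xi range), "as-printed" uses b = 2 xi K.

    By default A is the exact matrix exponential of the continuous
    spring-damper over one frame, which neither gains nor loses energy at
    xi = 0 and agrees with the closed-form oscillation used for resonance
    fitting; ``discretization="euler"`` gives the first-order matrix
    [[1, dt], [-K dt, 1 - b dt]], whose spectral radius exceeds one for
    lightly damped folds (energy grows by about (1 + (w dt)^2)^(1/2) per
    frame), so it is only advisable at w_r dt << 1.
    """
    if not 0 <= xi < 1:
        raise ValueError("xi must lie in [0, 1)")
    if dt <= 0:
        raise ValueError("dt must be positive")
    K = w_r**2 / (1 - xi**2)
    if damping_convention == "damping-ratio":
        b = 2 * xi * np.sqrt(K)
    elif damping_convention == "as-printed":
        b = 2 * xi * K
    else:
        raise ValueError("damping_convention must be 'damping-ratio' or 'as-printed'")
    if discretization == "euler":
        A = np.array([[1.0, dt], [-K * dt, 1.0 - b * dt]])
        if xi > 0:
            radius = np.max(np.abs(np.linalg.eigvals(A)))
            if radius > 1 + 1e-6:
                logger.debug(
                    "explicit discretization unstable (spectral radius %.4f) at w_r=%.1f",
                    radius,
                    w_r,
                )
    elif discretization == "exact":
        A = expm(np.array([[0.0, 1.0], [-K, -b]]) * dt)
    else:
        raise ValueError("discretization must be 'exact' or 'euler'")
    return OscillatorParams(w_r=w_r, xi=xi, dt=dt, K=K, b=b, A=A)


@dataclass
class KFState:
    """Two-dimensional Kalman filter state for one coefficient."""

    x_pred: np.ndarray  # X_{k|k-1}
    P_pred: np.ndarray  # P_{k|k-1}
    P_E: np.ndarray
    P_V: np.ndarray

    def copy(self) -> "KFState":
        return KFState(self.x_pred.copy(), self.P_pred.copy(), self.P_E, self.P_V)


def kf_step(state: KFState, Y_k: np.ndarray, rho_k: float, params: OscillatorParams):
    """One measure-update-predict cycle with the rho-gated update.

    The gain acts on the blended observation Ybar = (1 - rho) Y + rho Yhat
    and the covariance contraction is scaled by (1 - rho): at rho = 1 the
    filter ignores the measurement entirely (pure prediction), at rho = 0 it
    is a standard Kalman update.  Returns the advanced state and Ybar.
    """
    C = np.eye(2)
    y_hat = C @ state.x_pred
    y_bar = (1.0 - rho_k) * np.asarray(Y_k, dtype=float) + rho_k * y_hat
    S = C @ state.P_pred @ C.T + state.P_E
    if abs(np.linalg.det(S)) < 1e-300:
        S = S + 1e-12 * np.eye(2)
    J = state.P_pred @ C.T @ np.linalg.inv(S)
    x_filt = (np.eye(2) - J @ C) @ state.x_pred + J @ y_bar
    P_filt = state.P_pred - (1.0 - rho_k) * J @ C @ state.P_pred
    P_filt = 0.5 * (P_filt + P_filt.T)  # keep symmetric against roundoff
    x_next = params.A @ x_filt
    P_next = params.A @ P_filt @ params.A.T + state.P_V
    new_state = KFState(x_next, 0.5 * (P_next + P_next.T), state.P_E, state.P_V)
    return new_state, y_bar, y_hat, x_filt


@dataclass
class TrackingConfig:
    """Tracker parameters (defaults follow the recommended analysis setup)."""

    beta: float = 20.0
    gamma: float = 0.5
    xi: float = 0.01
    sigma_e: float = 1e-2
    sigma_d: float = 1e-3
    damping_convention: str = "damping-ratio"
    discretization: str = "exact"
    w_r_init: float = 2 * np.pi * 150.0
    rho_contact: float = 0.5
    f_min_hz: float = 30.0
    #: detected frames used per open-phase harmonic fit around each contact
    m_open_fit: int = 400


@dataclass
class TrackingResult:
    """Bridged coefficient trajectories and per-contact diagnostics.

    y_bar[k, i, :] = blended (value, rate) of coefficient i at frame k;
    ``contacts`` lists (k0, k1, w_r) per contact event: the anchor frame
    before detection loss, the recovery frame, and the fitted resonance.
    """

    y_bar: np.ndarray  # (n, p-1, 2)
    rho: np.ndarray  # (n,)
    lam: np.ndarray  # (n,)
    source: np.ndarray  # (n,) of 'detected' | 'predicted'
    contacts: list[tuple[int, int, float]] = field(default_factory=list)
    open_at_end: bool = False

    @property
    def theta(self) -> np.ndarray:
        """Blended coefficient values, shape (n_frames, p-1)."""
        return self.y_bar[:, :, 0]


def _contact_intervals(rho: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of rho > threshold as [start, stop) index pairs."""
    above = rho > threshold
    runs = []
    k = 0
    n = len(above)
    while k < n:
        if above[k]:
            start = k
            while k < n and above[k]:
                k += 1
            runs.append((start, k))
        else:
            k += 1
    return runs


def _run_filter(
    seq: CurveSequence,
    rho: np.ndarray,
    params_per_frame,
    cfg: TrackingConfig,
    resets: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """One filter pass over the whole sequence; returns y_bar (n, p-1, 2).

    ``params_per_frame[k][i]`` is the oscillator model for coefficient i at
    frame k (per-coefficient resonances are independent).  ``resets`` maps a
    contact-onset frame to its de-biased anchor state (per coefficient,
    columns (value, rate) defined one frame earlier); at such a frame the
    predicted state is replaced by the anchor propagated one step, so the
    bridge launches from the pre-impact kinematics instead of the
    bias-contaminated near-closure fits.
    """
    resets = resets or {}
    n, ncoef = seq.theta.shape
    y_bar = np.zeros((n, ncoef, 2))
    for i in range(ncoef):
        valid = np.isfinite(seq.theta[:, i])
        if not valid.any():
            raise ValueError("no detected frames: cannot anchor the tracker")
        # sigma_e / sigma_d are relative noise levels: the covariances scale
        # with the observed spread of each channel, so the filter behaves
        # identically under pixel rescaling or a change of glottal length
        s_val = float(np.nanstd(seq.theta[:, i]))
        s_val = s_val if s_val > 0 else 1.0
        s_rate = float(np.nanstd(seq.theta_dot[:, i])) if np.isfinite(seq.theta_dot[:, i]).any() else 0.0
        s_rate = s_rate if s_rate > 0 else s_val / seq.dt
        P_E = np.diag([(cfg.sigma_e * s_val) ** 2, (cfg.sigma_e * s_rate) ** 2])
        P_V = np.diag([(cfg.sigma_d * s_val) ** 2, (cfg.sigma_d * s_rate) ** 2])
        k_start = int(np.argmax(valid))
        th0 = seq.theta[k_start, i]
        thd0 = seq.theta_dot[k_start, i] if np.isfinite(seq.theta_dot[k_start, i]) else 0.0
        state = KFState(np.array([th0, thd0]), np.diag([s_val**2, s_rate**2]), P_E, P_V)
        # frames before the first detection carry the initial state
        y_bar[:k_start, i, 0] = th0
        y_bar[:k_start, i, 1] = thd0
        for k in range(k_start, n):
            if k in resets:
                state.x_pred = params_per_frame[k][i].A @ resets[k][i]
            y_hat = state.x_pred.copy()
            Y = np.array([seq.theta[k, i], seq.theta_dot[k, i]])
            Y = np.where(np.isfinite(Y), Y, y_hat)
            state, yb, _, _ = kf_step(state, Y, rho[k], params_per_frame[k][i])
            y_bar[k, i] = yb
    return y_bar


def fit_open_harmonic(
    t: np.ndarray,
    y: np.ndarray,
    w_bounds: tuple[float, float] = (2 * np.pi * 20.0, 2 * np.pi * 600.0),
    n_grid: int = 400,
    dc: str = "auto",
) -> tuple[float, float, float, float]:
    """Least-squares harmonic fit y ~ c + a cos(w t) + b sin(w t).

    The open-phase resonance of a fold is identifiable from its visible
    (detected) coefficient samples; the frequency is found on a grid with
    linear LS for the remaining parameters, then refined locally.
    Returns (w, c, a, b).

    A detected open phase is a single arc, over which the offset c and the
    frequency trade off almost freely; since the fold's rest position is the
    attachment line (y = 0) whenever the glottis closes fully, c is pinned
    to zero unless freeing it cuts the residual by more than half
    (``dc="auto"``; "free"/"zero" force either choice) — the free offset is
    what incomplete closure, which keeps the fold away from the midline,
    looks like.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 samples for a harmonic fit")

    def solve(w, with_dc):
        cols = [np.cos(w * t), np.sin(w * t)]
        if with_dc:
            cols.insert(0, np.ones_like(t))
        X = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        if not with_dc:
            coef = np.concatenate([[0.0], coef])
        return float(r @ r), coef

    def search(with_dc):
        grid = np.linspace(w_bounds[0], w_bounds[1], n_grid)
        costs = np.array([solve(w, with_dc)[0] for w in grid])
        j = int(np.argmin(costs))
        a, b = grid[max(0, j - 1)], grid[min(n_grid - 1, j + 1)]
        w_best, f_best = float(grid[j]), float(costs[j])
        if a < b:
            res = minimize_scalar(lambda w: solve(w, with_dc)[0], bounds=(a, b),
                                  method="bounded", options={"xatol": 1e-6})
            if res.fun <= f_best:
                w_best, f_best = float(res.x), float(res.fun)
        return w_best, f_best

    if dc not in ("auto", "free", "zero"):
        raise ValueError("dc must be 'auto', 'free' or 'zero'")
    if dc == "free":
        w_best, _ = search(True)
        use_dc = True
    else:
        w_zero, f_zero = search(False)
        use_dc = False
        w_best = w_zero
        if dc == "auto":
            w_free, f_free = search(True)
            if f_free < 0.5 * f_zero:
                w_best, use_dc = w_free, True
    _, coef = solve(w_best, use_dc)
    return w_best, float(coef[0]), float(coef[1]), float(coef[2])


def _bridge_timing(
    th0: float,
    thd0: float,
    dc: float,
    w_open: float,
    th1: float,
    t1: float,
) -> tuple[float, float, float] | None:
    """Contact timing for the two-regime bridge.

    From the anchor state the fold swings at its open-phase resonance about
    ``dc`` until it reaches the contact plane theta = 0 (time t_x, speed
    v_cross); symmetrically, it leaves the plane t_back before reaching the
    recovery value th1.  Returns (t_x, v_cross, T_c) with T_c the implied
    contact duration, or None if the free oscillation never reaches the
    plane (no crossing: the gate fired without a collision geometry).
    """
    tau = np.linspace(0.0, t1, 512)
    a0, b0 = th0 - dc, thd0 / w_open
    traj = dc + a0 * np.cos(w_open * tau) + b0 * np.sin(w_open * tau)
    s0 = np.sign(th0) if th0 != 0 else np.sign(traj[1])
    crossing = np.nonzero(np.sign(traj) == -s0)[0]
    if crossing.size == 0 or crossing[0] == 0:
        return None
    j = crossing[0]
    # refine crossing instant linearly
    t_a, t_b = tau[j - 1], tau[j]
    y_a, y_b = traj[j - 1], traj[j]
    t_x = t_a + (t_b - t_a) * (0.0 - y_a) / (y_b - y_a)
    v_cross = abs(-a0 * w_open * np.sin(w_open * t_x) + b0 * w_open * np.cos(w_open * t_x))
    if v_cross <= 0:
        return None
    # time to travel from the plane back out to the recovery value
    amp_out = np.hypot(a0, b0)
    arg = min(1.0, abs(th1 - dc) / max(amp_out, 1e-300))
    t_back = float(np.arcsin(arg) / w_open)
    T_c = t1 - t_x - t_back
    if T_c <= 0:
        # the free flight fills the whole window: a touch, not a dwell
        return None
    return float(t_x), float(v_cross), float(T_c)


def track_sequence(
    seq: CurveSequence,
    D_T: int,
    cfg: TrackingConfig | None = None,
) -> TrackingResult:
    """Bridge a fold\'s coefficient sequence through its collision phases.

    Two passes per contact event.  The first pass (nominal resonance)
    locates the maximal runs of rho above the contact threshold.  For each
    run, the open-phase resonance fitted to the preceding detected samples
    fixes the pre-impact state and the instant and speed of midline
    crossing; the contact resonance w_r then follows from requiring the
    stiff half-oscillation plus the return swing to land on the recovery
    value at the end of the run (the endpoint condition).  The second pass
    re-runs the filter with the transition matrix switched to the contact
    resonance inside the collision and the open resonance on the bridged
    frames around it.  The output trajectory is gap-free.
    """
    cfg = cfg or TrackingConfig()
    n = seq.n_frames
    if n == 0:
        raise ValueError("empty sequence")
    ncoef = seq.theta.shape[1]
    lam = np.zeros(n)
    rho = np.zeros(n)
    for k in range(n):
        lam[k], rho[k] = compute_uncertainty(int(seq.D[k]), D_T, cfg.beta, cfg.gamma)

    base = oscillator_matrices(cfg.w_r_init, cfg.xi, seq.dt, cfg.damping_convention,
                               cfg.discretization)
    params = [[base] * ncoef for _ in range(n)]
    y_bar1 = _run_filter(seq, rho, params, cfg)

    intervals = _contact_intervals(rho, cfg.rho_contact)
    contacts: list[tuple[int, int, float]] = []
    open_at_end = False
    last_w_r = cfg.w_r_init
    detected = np.isfinite(seq.theta).all(axis=1) & (rho <= cfg.rho_contact)
    resets: dict[int, np.ndarray] = {}
    bounces: list[tuple[int, int, np.ndarray]] = []
    osc_cache: dict[float, OscillatorParams] = {}

    def osc(w):
        if w not in osc_cache:
            osc_cache[w] = oscillator_matrices(w, cfg.xi, seq.dt, cfg.damping_convention,
                                               cfg.discretization)
        return osc_cache[w]

    prev_stop = 0
    for start, stop in intervals:
        k0 = start - 1  # anchor instant just before the bridge
        pre = np.nonzero(detected[prev_stop:start])[0] + prev_stop
        prev_stop = stop
        pre = pre[-cfg.m_open_fit:]
        if pre.size == 0:
            continue
        k1 = stop
        post_all = np.nonzero(detected[stop:])[0] + stop
        post = post_all[:6]
        if post.size == 0:
            open_at_end = True
        w_r_list = []
        bounce_signs = np.zeros(ncoef)
        anchor = np.empty((ncoef, 2))
        frame_params = [[osc(last_w_r)] * ncoef for _ in range(start, min(k1, n))]
        for i in range(ncoef):
            th_pre = seq.theta[pre, i]
            use_harmonic = pre.size >= 10
            if use_harmonic:
                try:
                    w_o, dc, ca, cb = fit_open_harmonic((pre - k0) * seq.dt, th_pre)
                except (ValueError, np.linalg.LinAlgError):
                    use_harmonic = False
            if use_harmonic:
                th0 = dc + ca
                thd0 = cb * w_o
            else:
                w_o = cfg.w_r_init
                dc = 0.0
                tq = (pre - k0) * seq.dt
                cq = np.polyfit(tq, th_pre, min(2, pre.size - 1))
                th0 = float(np.polyval(cq, 0.0))
                thd0 = float(np.polyval(np.polyder(cq), 0.0)) if pre.size > 1 else 0.0
            anchor[i] = (th0, thd0)
            if post.size == 0:
                w_c = last_w_r
                timing = None
            else:
                tq = (post - k1) * seq.dt
                cq = np.polyfit(tq, seq.theta[post, i], min(2, post.size - 1))
                th1 = float(np.polyval(cq, 0.0))
                t1 = (k1 - k0) * seq.dt
                timing = _bridge_timing(th0, thd0, dc if use_harmonic else 0.0, w_o, th1, t1)
                if timing is None and use_harmonic:
                    # the free open-phase motion explains the window without
                    # dwelling past the contact plane: a touch-and-rebound —
                    # bridge with the open resonance and no fictitious overlap
                    bounce_signs[i] = np.sign(th0)
                    w_c = w_o
                elif timing is None:
                    # too little context for the two-regime bridge: fall back
                    # to the single-resonance endpoint fit
                    try:
                        w_c = estimate_resonance(th0, thd0, th1, t1,
                                                 bounds=(2 * np.pi * cfg.f_min_hz,
                                                         np.pi / seq.dt),
                                                 require_crossing=True)
                    except (UndefinedAmplitudeError, ValueError):
                        w_c = last_w_r
                else:
                    t_x, v_cross, T_c = timing
                    w_c = float(np.clip(np.pi / T_c, 2 * np.pi * cfg.f_min_hz,
                                        np.pi / seq.dt))
            w_r_list.append(w_c)
            for k in range(start, min(k1, n)):
                if timing is not None:
                    t_rel = (k - k0) * seq.dt
                    inside = timing[0] <= t_rel < timing[0] + np.pi / w_c
                    frame_params[k - start][i] = osc(w_c) if inside else osc(w_o)
                else:
                    frame_params[k - start][i] = osc(w_c)
        for k in range(start, min(k1, n)):
            params[k] = frame_params[k - start]
        resets[start] = anchor
        if np.any(bounce_signs != 0):
            bounces.append((start, min(k1, n), bounce_signs.copy()))
        w_r = float(np.median(w_r_list)) if w_r_list else last_w_r
        if open_at_end and post.size == 0:
            logger.warning("contact interval open at sequence end; bridged with w_r=%.1f", w_r)
        contacts.append((k0, min(k1, n - 1), w_r))
        last_w_r = w_r

    y_bar = _run_filter(seq, rho, params, cfg, resets) if contacts else y_bar1
    # touch-and-rebound events carry no fictitious overlap: clamp the value
    # channel of the bridged frames to the pre-impact side
    for b_start, b_stop, signs in bounces:
        for i in range(ncoef):
            s0 = signs[i]
            if s0 == 0:
                continue
            vals = y_bar[b_start:b_stop, i, 0]
            y_bar[b_start:b_stop, i, 0] = s0 * np.maximum(s0 * vals, 0.0)
    source = np.where(rho > cfg.rho_contact, "predicted", "detected")
    return TrackingResult(
        y_bar=y_bar, rho=rho, lam=lam, source=source, contacts=contacts, open_at_end=open_at_end
    )
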