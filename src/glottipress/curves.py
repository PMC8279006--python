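"""Root-constrained polynomial edge models.

Each fold's detected edge points are fitted, in the attachment-line (u, v)
frame, with a polynomial that is forced through the attachment points:

    M(v) = (sum_i theta_i v^i) (v - v_a)(v - v_b) + u_a,   i = 0 .. p-2,

so the fitted curve always meets the fold's fixed anterior and posterior
ends exactly.  The root factors are folded into the regressor matrix and the
coefficients are estimated by least squares; the normal-equations form is
ill-conditioned when the point count collapses at closure, so the solve goes
through numpy's SVD-based lstsq.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EdgeCurve",
    "CurveSequence",
    "InsufficientDataError",
    "IllConditionedError",
    "fit_constrained_polynomial",
    "evaluate_curve",
    "differentiate_coefficients",
]


class InsufficientDataError(ValueError):
    """Fewer points than free coefficients; caller falls back to prediction."""


class IllConditionedError(ValueError):
    """Regressor matrix is rank deficient."""


@dataclass
class EdgeCurve:
    """A fitted edge model: coefficients Theta (theta_{p-2} .. theta_0),
    polynomial order p, and the attachment anchors (u_a, v_a, v_b)."""

    theta: np.ndarray
    anchors: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("non-finite coefficients")

    @property
    def p(self) -> int:
        return len(self.theta) + 1

    def __call__(self, v):
        return evaluate_curve(self, v)


def _design_matrix(v: np.ndarray, anchors: tuple[float, float, float], p: int) -> np.ndarray:
    _, va, vb = anchors
    vt = (v - va) * (v - vb)
    # columns v^{p-2} .. v^0, each multiplied by the root factor
    cols = [vt * v**i for i in range(p - 2, -1, -1)]
    return np.column_stack(cols)


def fit_constrained_polynomial(
    points_uv: np.ndarray,
    anchors: tuple[float, float, float],
    p: int = 2,
) -> tuple[np.ndarray, float]:
    """Least-squares fit of the root-constrained polynomial.

    Parameters
    ----------
    points_uv : ndarray, shape (D, 2)
        Edge points (u, v) in the attachment frame.
    anchors : (u_a, v_a, v_b)
        Attachment coordinates; v_a != v_b.
    p : int
        Polynomial order (p - 1 free coefficients).

    Returns
    -------
    theta : ndarray, shape (p - 1,), ordered theta_{p-2} .. theta_0
    rms : float
        Root-mean-square residual of the fit in u units.
    """
    if p < 2:
        raise ValueError("polynomial order must be >= 2")
    ua, va, vb = anchors
    if va == vb:
        raise ValueError("anchors must have v_a != v_b")
    points_uv = np.asarray(points_uv, dtype=float)
    D = points_uv.shape[0]
    if D < p - 1:
        raise InsufficientDataError(f"need at least {p - 1} points, got {D}")
    u, v = points_uv[:, 0], points_uv[:, 1]
    V = _design_matrix(v, anchors, p)
    U = u - ua
    theta, _, rank, _ = np.linalg.lstsq(V, U, rcond=None)
    if rank < p - 1:
        raise IllConditionedError("rank-deficient design matrix")
    resid = U - V @ theta
    rms = float(np.sqrt(np.mean(resid**2)))
    return theta, rms


def evaluate_curve(curve: EdgeCurve, v):
    """Evaluate M(v); exactly u_a at both anchors regardless of Theta."""
    ua, va, vb = curve.anchors
    v = np.asarray(v, dtype=float)
    poly = np.polyval(curve.theta, v)
    out = poly * (v - va) * (v - vb) + ua
    return float(out) if out.ndim == 0 else out


def differentiate_coefficients(theta_k: np.ndarray, theta_prev: np.ndarray | None, dt: float):
    """Backward difference of the coefficient vector between frames.

    Returns (theta_dot, is_valid); the first frame has no predecessor and
    yields a zero vector flagged invalid.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    theta_k = np.atleast_1d(np.asarray(theta_k, dtype=float))
    if theta_prev is None:
        return np.zeros_like(theta_k), False
    theta_prev = np.atleast_1d(np.asarray(theta_prev, dtype=float))
    return (theta_k - theta_prev) / dt, True


@dataclass
class CurveSequence:
    """Per-frame fitted coefficients for one fold.

    theta[k] is NaN-filled where the fit failed (insufficient points);
    theta_dot is the backward difference where both frames are defined.
    """

    theta: np.ndarray  # (n_frames, p-1), NaN where undefined
    theta_dot: np.ndarray  # (n_frames, p-1), NaN where undefined
    D: np.ndarray  # (n_frames,) detected point counts
    residual_rms: np.ndarray  # (n_frames,), NaN where undefined
    anchors: tuple[float, float, float]
    dt: float
    side: str = "left"

    @property
    def n_frames(self) -> int:
        return self.theta.shape[0]

    @property
    def p(self) -> int:
        return self.theta.shape[1] + 1

    def curve(self, k: int) -> EdgeCurve:
        return EdgeCurve(self.theta[k], self.anchors)


def fit_sequence(
    point_sets,
    to_uv,
    anchors: tuple[float, float, float],
    p: int,
    dt: float,
    side: str = "left",
) -> CurveSequence:
    """Fit every frame of an edge-point series and differentiate in time.

    ``to_uv`` maps an (x, y) point into the attachment frame (a closure over
    the fold's rotation angle).  Frames where the fit is impossible or
    ill-conditioned get NaN coefficients; the point count D is always
    recorded, since the tracker's uncertainty gate consumes it.
    """
    n = len(point_sets)
    theta = np.full((n, p - 1), np.nan)
    resid = np.full(n, np.nan)
    D = np.zeros(n, dtype=int)
    for k, ps in enumerate(point_sets):
        D[k] = ps.D
        if ps.D < p - 1:
            continue
        uv = np.array([to_uv((x, y)) for x, y in ps.points], dtype=float)
        try:
            theta[k], resid[k] = fit_constrained_polynomial(uv, anchors, p)
        except (InsufficientDataError, IllConditionedError):
            continue
    theta_dot = np.full_like(theta, np.nan)
    for k in range(1, n):
        if np.all(np.isfinite(theta[k])) and np.all(np.isfinite(theta[k - 1])):
            theta_dot[k], _ = differentiate_coefficients(theta[k], theta[k - 1], dt)
    return CurveSequence(theta, theta_dot, D, resid, anchors, dt, side)
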