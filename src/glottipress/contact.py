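"""Hertzian contact pressure from bridged edge curves.

Near its vertex a quadratic edge is locally circular, so the collision of
the two folds is modeled as Hertz contact between parallel cylinders.  For
that geometry the peak pressure normalized by the effective modulus depends
only on the ratio of apparent penetration to contact length,

    P_c / E* = 4 alpha delta_c / L_c,

which is scale-free: uncalibrated pixel units cancel.  alpha is a fixed
geometric correction (default 1.679) compensating the inferior-superior
contact variation invisible from the superior endoscopic view.  Dimensional
pressure additionally needs tissue properties through the effective Young's
modulus E* = 1/((1-nu1^2)/E1 + (1-nu2^2)/E2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import EdgeCurve, evaluate_curve

__all__ = [
    "DEFAULT_ALPHA",
    "TissueProperties",
    "ContactFrameResult",
    "ContactSummary",
    "effective_modulus",
    "equivalent_modulus",
    "overlap_profile",
    "penetration_depth",
    "contact_length",
    "normalized_pressure",
    "glottal_area",
    "compute_contact_series",
    "summarize_contact",
    "InconsistentContactError",
]

#: Inferior-superior geometric correction for the parallel-cylinder model,
#: calibrated against a self-oscillating lumped-element reference model.
DEFAULT_ALPHA = 1.679


class InconsistentContactError(ValueError):
    """Positive penetration reported with zero contact length."""


def effective_modulus(E1: float, nu1: float, E2: float = None, nu2: float = None) -> float:
    """Effective Young's modulus of two elastic bodies in contact, in Pa.

    E* = 1/((1-nu1^2)/E1 + (1-nu2^2)/E2); for identical folds this reduces
    to E/(2(1-nu^2)).  Symmetric under swapping the two folds.
    """
    if E2 is None:
        E2 = E1
    if nu2 is None:
        nu2 = nu1
    for E, nu in ((E1, nu1), (E2, nu2)):
        if E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not -1 < nu <= 0.5:
            raise ValueError("Poisson ratio must lie in (-1, 0.5]")
    return 1.0 / ((1 - nu1**2) / E1 + (1 - nu2**2) / E2)


def equivalent_modulus(p_contact: float, p_norm: float) -> float:
    """Equivalent elastic modulus implied by a measured contact pressure.

    Inverts the normalized Hertz relation: E* = P_c / (P_c/E*), used to
    estimate the elasticity involved in contact when a reference pressure
    measurement is available.  Units follow ``p_contact``.
    """
    if p_norm <= 0:
        raise ValueError("normalized pressure must be positive")
    return p_contact / p_norm


@dataclass
class TissueProperties:
    """Fold tissue elasticity; defaults are typical vocal-fold values."""

    E1: float = 24750.0  # Pa
    nu1: float = 0.5
    E2: float | None = None
    nu2: float | None = None
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def E_star(self) -> float:
        return effective_modulus(self.E1, self.nu1, self.E2, self.nu2)


def overlap_profile(curve_left: EdgeCurve, curve_right: EdgeCurve, rows) -> np.ndarray:
    """Fictitious overlap Delta-x per row: M_left(y) - M_right(y).

    Positive entries mean the extrapolated edges cross (apparent
    penetration); negative entries are the open gap width.
    """
    rows = np.asarray(rows, dtype=float)
    return np.asarray(evaluate_curve(curve_left, rows) - evaluate_curve(curve_right, rows))


def penetration_depth(profile: np.ndarray) -> float:
    """Maximum strictly positive overlap; 0 when there is no contact."""
    profile = np.asarray(profile, dtype=float)
    pos = profile[profile > 0]
    return float(pos.max()) if pos.size else 0.0


def contact_length(profile: np.ndarray, row_spacing: float = 1.0) -> float:
    """Total extent of rows in contact (overlap > 0) along the glottal axis.

    Disjoint contact runs — as occur with incomplete posterior closure —
    are summed, not the longest run.
    """
    if row_spacing <= 0:
        raise ValueError("row_spacing must be positive")
    profile = np.asarray(profile, dtype=float)
    return float(np.count_nonzero(profile > 0) * row_spacing)


def normalized_pressure(delta: float, L_c: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Peak Hertz pressure over effective modulus: 4 alpha delta / L_c.

    Dimensionless and invariant under uniform rescaling of delta and L_c,
    so uncalibrated pixel units suffice.
    """
    if delta < 0:
        raise ValueError("penetration must be non-negative")
    if delta == 0:
        return 0.0
    if L_c <= 0:
        raise InconsistentContactError("positive penetration with zero contact length")
    return 4.0 * alpha * delta / L_c


def glottal_area(profile: np.ndarray, row_spacing: float = 1.0) -> float:
    """Open glottal area: gap width integrated along the glottal axis, px^2."""
    if row_spacing <= 0:
        raise ValueError("row_spacing must be positive")
    profile = np.asarray(profile, dtype=float)
    return float(np.maximum(-profile, 0.0).sum() * row_spacing)


@dataclass
class ContactFrameResult:
    """Per-frame contact quantities (pixel units; P_norm dimensionless)."""

    frame: int
    profile: np.ndarray
    delta: float
    L_c: float
    P_norm: float
    area: float


@dataclass
class ContactSummary:
    """Cycle-aggregated collision pressure.

    Contact cycles are the maximal runs of frames with positive penetration;
    the summary pressure is the arithmetic mean of the per-cycle peaks.
    """

    cycle_peaks_pnorm: list[float] = field(default_factory=list)
    cycle_peaks_delta: list[float] = field(default_factory=list)
    cycle_bounds: list[tuple[int, int]] = field(default_factory=list)
    E_star: float | None = None

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_peaks_pnorm)

    @property
    def mean_peak_pnorm(self) -> float | None:
        if not self.cycle_peaks_pnorm:
            return None
        return float(np.mean(self.cycle_peaks_pnorm))

    @property
    def mean_peak_pressure_pa(self) -> float | None:
        """Mean peak dimensional pressure in Pa (requires tissue properties)."""
        if self.E_star is None or self.mean_peak_pnorm is None:
            return None
        return self.mean_peak_pnorm * self.E_star


def compute_contact_series(
    curves_left: list[EdgeCurve],
    curves_right: list[EdgeCurve],
    rows,
    row_spacing: float = 1.0,
    alpha: float = DEFAULT_ALPHA,
) -> list[ContactFrameResult]:
    """Per-frame overlap, penetration, contact length, pressure and area."""
    if len(curves_left) != len(curves_right):
        raise ValueError("left/right curve sequences differ in length")
    out = []
    for k, (cl, cr) in enumerate(zip(curves_left, curves_right)):
        prof = overlap_profile(cl, cr, rows)
        delta = penetration_depth(prof)
        L_c = contact_length(prof, row_spacing)
        p = normalized_pressure(delta, L_c, alpha) if delta > 0 else 0.0
        out.append(
            ContactFrameResult(
                frame=k,
                profile=prof,
                delta=delta,
                L_c=L_c,
                P_norm=p,
                area=glottal_area(prof, row_spacing),
            )
        )
    return out


def summarize_contact(
    series: list[ContactFrameResult],
    tissue: TissueProperties | None = None,
) -> ContactSummary:
    """Aggregate a frame series into per-cycle peak pressures.

    Cycles are delimited by maximal runs of delta > 0 (no debounce: a single
    zero-penetration frame splits a run).  Returns an empty summary when no
    frame shows contact.
    """
    if not series:
        raise ValueError("empty series")
    summary = ContactSummary(E_star=tissue.E_star if tissue else None)
    k = 0
    n = len(series)
    while k < n:
        if series[k].delta > 0:
            start = k
            while k < n and series[k].delta > 0:
                k += 1
            run = series[start:k]
            summary.cycle_bounds.append((start, k - 1))
            summary.cycle_peaks_pnorm.append(max(r.P_norm for r in run))
            summary.cycle_peaks_delta.append(max(r.delta for r in run))
        else:
            k += 1
    return summary
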