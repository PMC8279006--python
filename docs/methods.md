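# Methods

`glottipress` estimates the peak collision pressure of the vocal folds from
uncalibrated laryngeal high-speed video (HSV). This note records the model,
the numerical choices, what the synthetic generators do and do not emulate,
and the known limitations.

## The estimation chain

**Geometry.** The user supplies the anterior and posterior attachment points
of each fold; the line between them is the fold's rest reference. The frame
stack is optionally stabilized (slow intensity-centroid drift below a cutoff,
default 20 Hz, removed by translation — endoscope wander is far below
phonation frequencies) and rotated once, about the frame center with bilinear
interpolation, so the glottal axis is vertical. All curve fitting happens in
the (u, v) frame obtained by rotating image coordinates by the attachment
line's angle φ: (u, v) = R(φ)(x, y).

**Edge detection.** Specular highlights are attenuated by grayscale hole
filling on the inverted image (border-connected structure, and any dark
region — the glottis in particular — is untouched). A Prewitt gradient with a
relative threshold `t_h` (fraction of the recording-wide maximum magnitude
inside the ROI; 0.5 for clean synthetic footage, 0.25 in vivo) keeps strong
edges, and the sign of the gradient x-component assigns pixels to the left
(dI/dx < 0) or right fold. Per image row the sub-pixel edge abscissa is the
gradient-magnitude-weighted mean of the surviving columns. Rows whose
opposing centroids are closer than the kernel support (2 px) are censored
from both folds: within that separation the two edge responses merge and the
weighted means freeze about a pixel off, so such rows are treated as honest
detection loss rather than biased positions. A 5-frame uniform moving
average smooths each row's trajectory over the frames where it was detected;
gaps are never filled at this stage.

**Curve fitting.** Each frame's edge points are fitted with the
root-constrained polynomial

    M(v) = (Σ_{i=0}^{p-2} θ_i v^i) (v − v_a)(v − v_b) + u_a,

which passes through the fold's fixed attachment points by construction.
The root factors are folded into the regressor matrix and the system is
solved by SVD least squares — the explicit normal-equations inverse is badly
conditioned exactly when the point count collapses at closure. Quadratic
fits (p = 2) are the default and the recommended setting; higher orders are
supported but their coefficients are poorly served by the harmonic tracking
model. Coefficient rates are backward differences between frames.

**Tracking through collision.** Detection dies during contact, which is
precisely when the fictitious overlap of the extrapolated edges is needed.
Each coefficient is tracked by an independent two-state Kalman filter whose
process model is a mass-normalized spring–damper at resonance w_r
(K = w_r²/(1 − ξ²); damping b = 2ξ√K by default, ξ = 0.01; the literal
convention b = 2ξK is available but overdamps). The transition matrix is the
exact matrix exponential of the continuous system over one frame: the
first-order explicit matrix (also available) grows energy by
√(1 + (w_r Δt)²) per step, which at the w_r Δt ≈ 0.5 reached during contact
bridging inflates the bridged penetration severely.

A sigmoid uncertainty factor ρ = 1/(1 + e^{−β(λ−γ)}) of the lost-row ratio
λ = (D_T − D_k)/D_T (β = 20, γ = 0.5) gates the filter: the blended output
Ȳ = (1 − ρ)Y + ρŶ follows the measurements in open phases and the model
prediction during collision, and the covariance contraction is scaled by
(1 − ρ). Measurement and process noises are specified as *relative* levels
(σ_e = 10⁻², σ_d = 10⁻³ of each channel's observed spread), which makes the
filter invariant under pixel rescaling and glottal length — consistent with
the method's uncalibrated-video premise.

Per contact event (a maximal run of ρ > 0.5) the resonance is re-fitted in
two passes. The open-phase resonance w_open is identified from the detected
coefficient samples of the preceding inter-contact segment by least-squares
harmonic fit; the DC term is pinned to the attachment line (zero) unless
freeing it halves the residual, which is what incomplete closure looks like.
Evolving the pre-impact state under w_open gives the crossing instant and
speed; requiring the stiff contact half-oscillation plus the return swing to
land on the recovery value fixes the contact duration and hence
w_r = π/T_c. The filter is re-run with the transition matrix switched to
w_r inside the collision. The endpoint-matching special case (anchor at
impact, single resonance over the window) is implemented verbatim as
`estimate_resonance` and used when too little context exists for the
harmonic fit; among aliased solutions the smallest resonance is taken, and
solutions that actually reach the contact plane are preferred as a
tie-break. Events whose free open-phase flight already explains the whole
blanked window are classified as touch-and-rebound and bridged with no
fictitious overlap — this is what makes a never-closing glottis report zero
contact.

**Contact pressure.** Near its vertex a quadratic is locally circular, so
collision is modeled as Hertz contact between parallel cylinders:

    P_c / E* = 4 α δ_c / L_c,

with δ_c the maximum positive overlap of the two bridged curves across the
glottal rows, L_c the total extent of overlapping rows (disjoint runs are
summed — incomplete closure fragments contact), and α = 1.679 a fixed
geometric correction for the inferior–superior contact variation invisible
from the superior view. The ratio δ_c/L_c is dimensionless, so uncalibrated
pixels suffice; dimensional pressure additionally needs the effective
modulus E* = 1/((1−ν₁²)/E₁ + (1−ν₂²)/E₂) (defaults E = 24.75 kPa, ν = 0.5).
Cycles are maximal runs of δ > 0; the summary pressure is the arithmetic
mean of per-cycle peaks.

## Synthetic data

**Kinematic phantom.** Two quadratic edges through shared glottal endpoints
move in antiphase about a vertical midline. The vertex offset follows a
piecewise-harmonic collision cycle: an open half-wave of amplitude A about
the rest line and a contact half-wave of peak `overlap_max/2` at the stiffer
frequency that keeps velocity continuous at the crossings — the trajectory a
linear spring fold with a contact spring actually follows, and exactly the
model class the tracker assumes. The contact duration is therefore tied to
the impact velocity, T_c = T_open · overlap_max/(2A). Frames are rendered
with exact sub-pixel area coverage (bright folds 0.8, dark gap 0.1), plus
optional seeded Gaussian noise and specular blobs. Ground truth stores the
unclipped curves and the analytic overlap. A plain sinusoid with a clipping
offset was deliberately rejected: its occluded-phase kinematics are
inconsistent with any spring bridge, so no estimator of this family could
recover them even in principle.

**Collision surrogate.** Each fold's medial point is a mass-normalized
spring with a Rayleigh-type drive: net linear damping μ(P_s − P_onset)
(negative above the onset pressure, the reduced abstraction of flow-induced
energy transfer) saturated by a cubic velocity term, plus a penalty spring
(4× fold stiffness) acting on the mean positive overlap of the triangular
anterior–medial–posterior fold surfaces. Semi-implicit Euler with
sub-stepping keeps the penalty stable. Below P_onset (650 Pa) the folds
settle at rest — static, no contact; above it the limit-cycle amplitude
grows smoothly as √(P_s − P_onset), calibrated to 2 px at 1 kPa. The
complete-closure preset rests with a 1 px medial gap; the incomplete-closure
preset (3 px rest gap, 2 px posterior/membranous end offsets) needs roughly
1.0–1.1 kPa before contact begins. These working-point constants are the
surrogate's fixed design conditions. The penalty "pressure" channel is in
arbitrary consistent units and is used only for trend checks, never for
absolute comparison. The surrogate is deliberately not a physiological
voice-production model: no aerodynamic coupling, vocal-tract acoustics,
mucosal wave, or muscle-activation rules.

**What passing on synthetic data does not show.** The phantom's contact
kinematics satisfy the tracker's own model family; real tissue shows
waveform asymmetry and hysteresis that the symmetric linear-spring bridge
cannot represent, so real-data accuracy is expected to be worse than the
phantom numbers. Rendering is high-contrast with stationary lighting;
shadowing, mucus reflections, and endoscope defocus degrade the gradient
detector in ways the noise model does not emulate. The surrogate's
triangular fold surface also means the quadratic curve model underestimates
its sharp medial overlap, which is why surrogate comparisons are held to
qualitative (monotone-trend) standards only.

## Study sizes and numerical choices

The end-to-end recovery study uses 200 Hz oscillation sampled at 20 kfps
(the frame rate of the silicone-model experiments this package's validation
design mirrors), 460 frames per condition, and an opening amplitude of
max(2·overlap, 6) px — a constant 20% closed quotient with a floor on
amplitude. Gradient edge localization has an intrinsic ~1 px floor once a
slit narrows below the kernel support, so overlaps of 1 px per fold pair are
only resolvable when amplitude and frame rate keep the approach well
sampled; these conditions keep all four tested overlaps (1, 2, 3, 5 px)
within a 5% recovery error. At 8 kfps and small amplitudes the 1 px case is
below the optical floor of any gradient-based method.

Other fixed choices: resonance grid of 2000 points with bounded local
refinement (deterministic, no RNG); contact-interval threshold ρ > 0.5 (the
sigmoid midpoint); anchor extrapolation by local quadratic over up to 6
well-detected frames; open-harmonic fits use the full inter-contact segment
(a quarter-arc leaves the frequency/offset pair unidentified); innovation
covariances are regularized by 10⁻¹² only if numerically singular; the
first frame of a recording has undefined coefficient rate and is flagged.
All randomness in the simulators flows from a single integer seed; reruns
are bit-identical, and the analysis itself is deterministic.

## Limitations

- The penetration depth is a *fictitious* Hertz overlap, not a tissue
  displacement; α transfers a calibration performed against a separate
  reference model and its universality across subjects is unknown.
- Absolute pressures inherit the uncertainty of the assumed tissue modulus;
  within-subject relative comparisons are the intended use.
- Contact length is read from the overlap profile of the fitted curves, so
  it saturates quickly for parallel-closing glottides and is overestimated
  relative to the true inferior-superior contact area.
- Attachment-point identification is manual and critical: errors tilt the
  (u, v) frame and bias every downstream stage.
- No lens-distortion correction, no physical-unit calibration, no automatic
  glottis localization, no RTS smoothing, no nonlinear contact springs.
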