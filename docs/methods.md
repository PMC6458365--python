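# Methods

This note documents the models, defaults and numerical choices behind
`cytovisc`, and what the synthetic benchmark does and does not establish.

## Physical model

The analysis rests on the Newtonian liquid-drop idealization of a cell
entering a pipette: a homogeneous viscous interior (viscosity μ_c, Pa·s)
bounded by a cortical membrane of tension T₀ (N/m).  The one-dimensional
entry law relates the steady tongue-advance rate to the driving pressure,

    dL_p/dt = R_p (ΔP − P_cr) / [6 μ_c (1 − R_p/R_c)],

and the cortical tension sets the threshold suction
P_cr = 2 T₀ (1/R_p − 1/R_c).  The model homogenizes the cytoplasm —
internal structure such as the nucleus is deliberately outside its scope —
and assumes R_c > R_p.  We enforce that strictly and additionally flag
R_c/R_p < 1.1 (`marginal_geometry`), where the thin annulus makes the
geometric factor unreliable; no correction is attempted.

**Units.** All public interfaces take radii in µm, pressures in Pa
(suction stored as a positive magnitude; a nominal "−10 kPa" is 10 000 Pa),
rates in µm/s; computation converts to SI internally and viscosity is
returned in Pa·s.

**P_cr policy.** With T₀ = 10⁻⁵ N/m (literature order of magnitude for
tumour cells; configurable) P_cr ≤ 2.4 Pa over the experimental size range,
versus 5–10 kPa suction.  The default `auto` policy drops P_cr whenever
ΔP/P_cr > 100 and records the decision per cell (`pcr_neglected`); forcing
inclusion changes μ_c by ≤ 0.05% at these pressures.  The 100× ratio is our
quantification of the usual order-of-magnitude argument; `include` and
`neglect` are first-class alternatives.

## Synthetic data: what it emulates

The generator exists so that every downstream stage can be tested against
known ground truth; no experimental recordings ship with the package.

**Populations.** Single-cell viscosities are modelled log-normally.  From
reported quartiles (q₁, m, q₃) we set `log_median = ln m` and
`log_sigma = ln(q₃/q₁)/(2 z₀.₇₅)` with z₀.₇₅ ≈ 0.67449.  The fit is
symmetric in log space: it preserves the quartile ratio exactly and imposes
q₁′q₃′ = m², discarding any asymmetry of the reported quartiles about the
median (for the built-in cohorts the residual asymmetry is a few percent).
Log-normal is the minimal two-parameter family consistent with the strong
right skew of measured viscosity distributions.  Cell radii are drawn
uniformly on 6.0–12.5 µm, the reported experimental range; radii and
viscosities are sampled independently because no joint distribution is
published — measured populations may well be correlated, and nothing here
should be read as evidence otherwise.  At the cohort sizes used (600–800
cells) the quartile sampling error is 7–8% (1 sd) on Q1/Q3, which is why
population-level checks use seed fractions or pooled replicates rather
than single draws.

**Traces.** Section I (the elastic response) is phenomenological: a linear
ramp to `elastic_jump` (default 2 µm, a pipette-radius-scale deformation)
over `elastic_duration` (default 2 ms, i.e. faster than viscous entry for
essentially all cells — the defining feature of the elastic phase).  Only
the section boundary matters downstream; no viscoelastic model is fitted.
Section II advances at the liquid-drop rate.  The trace ends when the
tongue holds the whole cell volume, `L_full = (4/3) R_c³/R_p²`
(cylindrical tongue, end caps ignored — the same convention the volume
bookkeeping of the renderer uses), or at `max_duration` (default 5 s,
truncation flagged).  Measurement noise is i.i.d. Gaussian on L_p (default
0.3 µm ≈ 0.6 pixel); no drift or motion blur.  Frame rates of 50–5000 fps
are accepted; defaults follow the few-hundred-fps regime of high-speed
aspiration imaging.

**Rendering.** Frames are grayscale in [0, 1]: two opaque pipette walls
bounding a channel of radius R_p, the cell body outside the mouth as a
disk whose radius shrinks by volume conservation
(r³ = R_c³ − ¾ R_p² L_p), and the aspirated tongue as a channel-filling
slug with a hemispherical leading cap.  Edges are drawn with a 1-pixel
linear coverage feather, so iso-contours at the mid-level localize the
true boundary to sub-pixel accuracy; additive Gaussian pixel noise
(default sd 0.008 against a 0.75 contrast) completes the model.  No
optical physics (PSF, defocus, diffraction) and no internal structure are
rendered: passing the round-trip tests shows the measurement chain is
unbiased on clean, well-contrasted videos, not that it is robust to
debris, defocus or multi-cell scenes.

## Trace extraction

The measurement chain is the classical one for this assay: frame
differencing (for motion QC), thresholding (Otsu by default, fixed value
as override; the threshold used is logged), particle removal by
morphological opening (1-pixel disk) plus small-component filtering,
edge detection and contour fitting.  Pipette geometry — centreline row and
mouth column — comes from the acquisition config; auto-detection is out of
scope.  Coordinates are 0-based row/column, origin top-left, half-open
pixel intervals, columns increasing into the pipette.

*Cell radius*: the largest component outside the mouth is segmented, its
edge is localized at sub-pixel precision as the grayscale iso-contour at
the midpoint of the estimated foreground/background levels, and a
total-least-squares circle is fitted (fit residual reported; a pre-entry
frame is required — cells already partially aspirated at video start are
an error, not a guess).

*Aspiration length*: per frame, the cleaned mask is scanned along a
3-pixel band on the pipette axis; L_p is the furthest foreground column of
the run attached to the mouth, pixel-centre convention, clipped at zero.
Frames with degenerate contrast are linearly interpolated from neighbours
and flagged; a trace with > 20% failed frames is rejected (our QC choice).

## Kinetics

The section I/II boundary is found by exhaustive continuous two-segment
piecewise-linear least squares over the window from first contact (first
sample above a 1-pixel detection floor) to full entry, ties toward the
earliest breakpoint.  For long traces the scan is strided to ≤ ~200
candidates and refined locally (the objective is smooth in the breakpoint).
A two-segment fit that does not beat the single line at an F-test
p < 10⁻³ — or an exactly linear trace — yields the `no_elastic_section`
flag with the boundary at the contact anchor.  The section-II rate is an
OLS slope over frames from the boundary up to 95% of L_full (terminal
frames excluded: the geometry changes as the cell rear passes the mouth);
fits with R² < 0.9 are flagged.  Traces too short for segmentation
(< 8 frames before full entry, the fastest few percent of cells at
800 fps) fall back to fitting from one frame after contact — the elastic
phase lasts under two frame periods at supported camera speeds — flagged
`short_trace_no_segmentation`; without this fallback the fastest tail of a
population would be silently censored and its quartiles biased upward.
The aspiration time T_c runs from first contact to the first frame at
L_full, with a flagged 0.95·L_full fallback for traces that terminate
marginally short.

## Classification

Each cell contributes one scalar.  The default input transform is log10
(viscosities span three decades); identity is available, and the
separable/ordering tests pass under both.  The network is 1 → 10 sigmoid →
2 softmax, cross-entropy loss, full-batch Adam (lr 0.05, ≤ 400 epochs),
early stopping on validation cross-entropy with patience 30 and
best-weight restore.  Splits are stratified per class at 70/15/15.  The
headline rate is computed over all three splits combined — matching the
reporting convention of the pattern-recognition tooling this emulates —
with per-split rates also emitted (held-out-only reporting is better
practice; both numbers are in every report).  Exact posterior ties
resolve to the first label.  Training is deterministic given (data, seed).
`bayes_rate_oracle` integrates the class-weighted log-scale densities on a
dense grid (trapezoid, 2×10⁵ points) to give the best achievable accuracy
for known log-normal populations; the trained network is required (and
observed) to sit within 3 percentage points of it on these 1-D problems.

## Validation design and problem sizes

The test suite validates by forward–inverse consistency, since per-cell
experimental raw data are not available: simulate → render → extract →
fit → invert must return each cell's ground-truth viscosity within 2%
(noiseless) and 5% (default noise).  Problem sizes were chosen as the
smallest that make each check statistically meaningful: per-cell image
round-trips use 8-cell batches at 800 fps on 72×288-px frames; population
quartile recovery pools two replicate cohorts of n = 652; boundary-recovery
Monte Carlo uses 200 seeds; classification checks average 3–10 training
replicates.  The acceptance script trains 10 replicates per comparison at
the full published cohort sizes (652/785/651/600).

## Known limitations

- The liquid-drop inversion inherits all assumptions above; it is not a
  rheometer.  Shear-thinning or power-law behaviour would appear as
  curvature in section II (watch the R² flags), not as a corrected value.
- The renderer's clean contrast model means imaging-chain tolerances
  (1 pixel on L_p, 2% on R_c) are best-case figures for real videos.
- Radius–viscosity independence in the generator is an assumption of
  convenience, not a biological claim.
- Classification uses a single feature by design; rates near the Bayes
  bound of the generating populations are the ceiling of this setup, and
  multi-feature or multi-class extensions are out of scope.
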