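# Methods

## Model and definitions

Thermal expansion of a crystal is treated as linear over the analysis
window (90–300 K).  The volumetric coefficient is the fractional volume
change per kelvin, α_V = (1/V)(ΔV/ΔT); because ΔV/ΔT is constant under the
linear approximation while V is not, a reference volume must be fixed, and
all coefficients here are referenced to the cell extrapolated to 298 K.
The same convention applies to the principal (linear) coefficients α_L: a
raw strain rate k (per kelvin, referenced to the lowest-temperature cell)
is converted by α(298) = 10⁶·k / (1 + k(298 − T_ref)) p.p.m. K⁻¹, and the
correction factor 1 + k(298 − T_ref) is reported alongside.  For small
strains α_V ≃ Σα_L; the package checks this first-order identity on
synthetic data (agreement within 2% for |strain| < 0.05).

Shape change is captured by the linear Lagrangian strain tensor
e = ½(F + Fᵀ) − I, where F = A(T)·A(T_ref)⁻¹ and A is the cell
orthogonalization matrix (x ∥ a, y in the a–b plane, z ∥ c*).  This is the
classical construction of expansion tensors from unit-cell parameters
alone.  Working from parameters means the orientation information is the
conventional frame, not the physical crystal orientation; eigenvalues are
invariant to the convention, and for monoclinic lattices one eigenvector
falls exactly on b (the twofold axis), for orthorhombic on all three cell
axes.

### Why the slope tensor is diagonalised, not per-pair eigenvalues

For families with ≥3 points, each of the six independent components of
e(T) is fitted linearly against T (free intercept — it absorbs small
errors in the reference structure) and the slope tensor dε/dT is
diagonalised once.  Diagonalising per-pair strains and averaging
eigenvalues would face unstable eigenvector ordering and sign flips from
pair to pair; under the linearity assumption the two procedures coincide,
and the slope-tensor route realises "the average orientation" of the
unconstrained axes deterministically.  Per-axis standard uncertainties
come from re-fitting the strain projected onto each (fixed) eigenvector
against T with a heteroscedasticity-consistent covariance.  Two-point
families use the single available strain tensor divided by ΔT, with no
uncertainty estimates; such families carry a `two_point` flag in every
report.

The linear (infinitesimal) form truncates at second order: when the
deformation includes a frame re-alignment rotation, zero-noise recovery of
planted rates is exact only to ~0.5% of the dominant rate.  This is a
property of the method, shared by any tool using the linear Lagrangian
tensor, and is far below experimental noise for real families.

### Uncertainties

Slope standard errors use the HC1 sandwich estimator (the common
small-sample heteroscedasticity-consistent default; the variant is
configurable).  Propagation to the 298 K reference uses the first-order
derivative of the conversion formula: for α_V, dα/d(slope) at fixed
intercept (10⁶·c/V²₉₈); for α_L, 10⁶/(1 + kΔT*)².

## Family curation

Entry-level screening removes non-ambient-pressure, coordinate-free,
non-organic and polymeric entries.  Within a refcode family, entries are
partitioned into structure families by single-linkage clustering on the
metric deformation measure between Niggli-reduced cells — the Frobenius
norm of the finite Lagrangian strain ½(FᵀF − I) between the two reduced
bases — with tolerance 0.12.  Single linkage (entries joined through
chains of pairwise measures ≤ 0.12, clusters merged when bridged) was
chosen because the underlying notion is "same phase, possibly drifted
across the temperature range"; the iteration order is fixed (refcode
suffix, then temperature) so the partition is deterministic.  The 0.12
threshold is exposed as configuration since variants of the deformation
measure normalisation exist.  Cells that fail to reduce are quarantined
with a logged warning rather than silently dropped, keeping data errors
auditable.

Niggli reduction uses the Krivý–Gruber iteration with ε-stabilised
comparisons (relative ε, default 10⁻⁵, scaled by the geometric mean of the
squared cell lengths) and an iteration cap of 100 to guard against cycling
on degenerate input; the integer unimodular change-of-basis matrix is
returned with the reduced cell.  The reduced cell is discontinuous at the
boundaries of its defining conditions: nearly identical lattices can
reduce to different settings, which can split a valid family.  The
pipeline only logs such cases; they are rare in practice.

Temperature handling: entries with no recorded temperature are assigned
293 K ("room temperature"); explicitly recorded values inside 283–303 K
are *not* snapped — the assumption applies to unrecorded values only.
Deduplication walks the ascending temperature list grouping entries within
10 K of the group's first member and keeps the lowest-R representative
(missing R loses to any reported R; remaining ties go to the earliest
suffix).  Window filters then require all entries in 90–300 K, a
representative at ≥273 K, span ≥50 K and ≥2 survivors.

## Population statistics

Coefficient histograms use half-open 25 p.p.m. K⁻¹ bins anchored at zero.
Distribution fits minimise squared differences between an
amplitude-scaled density and the counts at bin midpoints; the amplitude is
free so shape recovery is decoupled from bin-count normalisation (at a
perfect fit the amplitude equals N·bin width).  The pooled α_L histogram
(three values per family — any coefficient compared to all coefficients)
is fitted by a skew-normal (location/scale/shape) and then summarised by
two half-normal curves: the composite is centred on the skew-normal's
mode, shares its peak height (hence is continuous there), and each side's
width comes from a least-squares fit of a half-normal to the skew-normal
curve over six scale-lengths.  That mode-centred, equal-peak recipe is
this package's own construction for turning an awkward three-parameter
shape into a quotable "centre ± asymmetric sd" summary; for a symmetric
input it collapses to sd_lower = sd_upper = ω.  Exceptionality thresholds
are mean ± kσ for the normal fit and centre − k·sd_lower / centre +
k·sd_upper for the two-half-normal, with k = 3 by default.

The linearity screen partitions multi-point families at R² > 0.96 for the
V-vs-T fit and attaches per-point residual diagnostics to failures, which
is how temperature mislabels, unflagged pressure determinations and
phase-transition anomalies surface.  Outlier tabulation reports (i)
families above the upper α_V threshold with ≥4 points, (ii) two-point
families at or below the lower threshold, flagged *suspect* (apparent
zero/negative expansion on two points is characteristically a data
error), and (iii) families whose anisotropy exceeds a configurable
reference (default 3.16, the most anisotropic reliable benchmark) on a
good linear fit.  The anisotropy denominator is Σα_L by default with α_V
as an option; negative anisotropy can only arise from a negative
denominator and is treated as invalid downstream.

## Synthetic data generator

`thermex.synthetic` emulates the statistical shape of a large structure
database so the pipeline is testable offline:

- **Family sizes**: 84.5% two-entry, 9.3% three, 2.5% four, a geometric
  tail to 14 — the observed redetermination spectrum.
- **Temperatures**: a room-temperature point at 293 K (recorded as missing
  half the time) plus lower points down to a minimum drawn in 90–210 K,
  spaced ≥12 K so legitimate points stay outside the dedup tolerance.
- **Coefficients**: α_V ~ Normal(161, 51) p.p.m. K⁻¹, split across axes as
  α_V/3 plus zero-sum skew-normal deviations (scale 95 p.p.m. K⁻¹, shape
  4).  The NTE rate is emergent rather than a dial — at the defaults about
  a third of families show uniaxial and ~4–5% biaxial NTE, and the pooled
  α_L distribution is positively skewed, echoing the surveyed population.
  An explicit NTE probability would conflict with Σα_L = α_V, so the split
  scale/shape are the exposed knobs.
- **Cells**: reference cells are drawn per crystal system (30% triclinic,
  50% monoclinic, 20% orthorhombic) and evolved by the exact finite
  deformation (I + ΔT·dε/dT), so the linear-fit approximation error is
  realistic rather than zero by construction.  Monoclinic slope tensors
  keep b as an eigenvector; orthorhombic ones are diagonal.  References
  are drawn with a safety margin inside the Niggli conditions and ≥1.2 Å
  length gaps, so families do not straddle a reduced-cell discontinuity by
  construction (real data can; the pipeline logs it).
- **Noise**: 0.02% relative on lengths, 0.02° on symmetry-free angles.
- **Error modes** (default 2% of families each, mutually exclusive):
  a mid-series entry recorded ~100 K off (placed clear of the dedup
  tolerance and inside the window); the warmest entry's volume shrunk
  5–10% without a pressure flag; a mid-series volume anomaly of 3–6%
  (phase-transition proximity); an exact duplicate under a new refcode and
  publication with a higher R-factor; one entry re-based by a unimodular
  transformation (P2₁/c↔P2₁/n style for monoclinic).  Temperature
  mislabels and transition anomalies are only diagnosable by the linearity
  screen, so families selected for those modes draw their size from the
  ≥4-point tail.  R-factors are uniform on [0.02, 0.08].

What the generator does *not* emulate: real space-group frequencies,
atomic structure, correlated noise between parameters refined together,
genuinely non-linear expansion, or lattices near reduced-cell boundaries.
Passing tests therefore demonstrate the pipeline's correctness and its
robustness to the modelled error processes — not performance on every
archival pathology.

## Problem sizes and numerics

The statistical recovery checks run on a 1000-family synthetic survey
(~2 500 entries), which gives sampling errors of about ±2 on the fitted
mean/sd and ≥20 injections per error mode; the acceptance script uses the
same size.  Histogram fits use `scipy.optimize.curve_fit` with
moment-based starting values (and a small grid of starting shapes for the
skew-normal); non-convergence raises a fit-failure with diagnostics rather
than returning garbage.  Degenerate inputs are guarded: fits require ≥4
non-empty bins, a collapsed sd (< bin width/10) is an error, duplicate
temperatures in a fit are an error (deduplication should have removed
them), anisotropy with Σα_L = 0 is an error, and cells that are not
positive definite are rejected at construction.  Eigenvalues are reported
ascending with eigenvector signs fixed by making the largest-magnitude
component positive.

## Known limitations

- Metric-only: no space groups, no coordinates; polymorphs with nearly
  identical reduced cells cannot be distinguished, and reduced-cell
  discontinuities can split valid families (logged, not repaired).
- The linear model is wrong for structures with phase transitions or
  strongly curved V(T); the R² screen removes the obvious cases but a
  quadratic/Grüneisen treatment is out of scope.
- Two-point families (the bulk of any archive extract) have no
  uncertainty estimates; their apparent NTE should never be taken at face
  value, which is why the suspect flag exists.
- The half-normal summary is a deliberate simplification of the fitted
  skew-normal; its parameters depend mildly on the fitting range
  (six scale-lengths per side).
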