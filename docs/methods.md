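# Methods

## Model and assumptions

`vesidens` treats a membrane vesicle as a steady-state mixture of
discrete-but-interconnected components whose overall mass density is the
volume-weighted sum of intrinsic component densities, ρ = Σ ρ_j V_j with
Σ V_j = 1. Two components are distinguished: a treatment-sensitive
component (cholesterol plus whatever else cyclodextrin desorbs, modeled
with cholesterol's literature density ρ_s = 1.067 g/mL) and a residual
component of unknown density ρ_r. The central physical assumption is that
extraction removes the sensitive component *at its own intrinsic density*:
if a mass fraction M remains, a volume fraction M of that component
remains too, which yields the post-treatment density

ρ_post = (V_r ρ_r + V_s ρ_s M) / (V_r + V_s M).

Further assumptions, inherited by every derived quantity:

- the residual component is unaffected by treatment (no protein or
  residual-lipid loss);
- measurement errors on ρ_pre, ρ_post and M are independent Gaussians with
  SD equal to the reported SEMs (no distributional or covariance
  information is available for the source measurements);
- vesicles are spheres, so volume ratios map to diameter ratios by a cube
  root;
- densities are in g/mL throughout. (Source tabulations of these
  quantities sometimes write "mg/mL" for what is physically g/mL — water
  is ≈ 1 g/mL; the package standardizes on g/mL.)

## Inversion

The three simultaneous equations (pre-density, volume normalization,
post-density) are solved in closed form,

V_s = (ρ_pre − ρ_post) / ((1 − M)(ρ_s − ρ_post)),
ρ_r = (ρ_pre − V_s ρ_s) / (1 − V_s),

rather than with a generic nonlinear solver: the solution is exact, has no
tolerance or starting-point dependence, and its residuals in all three
equations are checked to 1e-9 in tests. Degenerate inputs raise typed
errors: M = 1 (pre- and post-equations coincide; composition
unidentifiable), ρ_s = ρ_post (division by zero), V_s = 1 (ρ_r
indeterminate). A solved V_s outside [0, 1] raises an infeasibility error
whose message states the ρ_pre interval compatible with the other
measurements — noisy measurements can leave the physical domain and must
not invert silently.

Two useful identities: re-inflating the post-treatment composition with
1/M recovers ρ_pre exactly (a consistency check carried in the tests at
1e-9), and the relative volume is algebraically independent of M given the
densities, RV = 1 − (ρ_pre − ρ_post)/(ρ_s − ρ_post).

## Printed-precision reporting

Internally everything is computed at full precision; the analysis report
additionally carries a "printed-precision" view rounded to the number of
decimals these quantities are conventionally printed with (3 for volume
fractions and densities, 2 for the diameter ratio). The two views can
differ visibly in one place: the full-precision post-treatment cholesterol
fraction is 0.1784 (printed view 0.178), whereas chaining from the
*printed* composition 0.567/0.433 gives 0.179. The reference analysis
published the chained value, so the reproduction script follows the same
chain; both numbers are available in the report.

## Uncertainty propagation

`propagate` draws (ρ_pre, ρ_post, M) independently from Gaussians at the
measured means and SEMs, inverts each draw vectorized, and summarizes
every derived quantity by mean, SD and empirical percentile CI (default
95 %). Draws whose inversion leaves the physical domain are *rejected and
counted*, not clipped — clipping would bias the propagated mean toward the
boundary; if more than half the draws are infeasible the measurements are
declared incompatible with the model and an error is raised. Defaults:
n_draws = 100 000, fixed documented seed (20151027), percentile CIs.
At the reference operating point no draws are rejected.

`delta_method` is the independent analytic cross-check: first-order error
propagation using the exact partial derivatives of the closed form (listed
in the docstring), evaluated at the deterministic solution. At the
reference SEM scale the Monte-Carlo and delta SDs agree to ≈ 0.1 % for
V_s (0.0682 vs 0.0683), relative volume and diameter ratio; ρ_r (MC 0.0051
vs delta 0.0044) and the post-treatment fraction (0.056 vs 0.053) show the
second-order curvature of those maps in M at this noise level, and the two
routes converge (< 2 % everywhere) once SEMs shrink a few-fold — both
regimes are asserted in the test suite. The ± values attached to the
original bench analysis were produced by an unstated method; this package
asserts only approximate agreement with them (the propagated SD of V_s,
0.068, sits within 15 % of the published ± 0.072) and makes no attempt to
reproduce them digit-for-digit.

When every SEM is zero the propagated distribution is degenerate; the
implementation returns exactly the deterministic solution with SD 0 rather
than the ulp-level noise that floating-point summation of a constant
sample would produce.

## Refractometry

Refractive-index readings of gradient fractions are converted to
densities through a packaged calibration table of standard 20 °C aqueous
sucrose data (refractive index and density by mass percent, 0–50 % w/w in
5 % steps; % w/v derived as w/w × density) and an ordinary least-squares
regression of density on refractive index. The relation is near-linear
over the working range (R² > 0.999, asserted), and regression
interpolation — not nearest-row lookup — is the default, matching how
bench refractometry is normally reduced. Readings outside the table's
refractive-index range raise unless extrapolation is explicitly enabled.
Temperature is fixed at 20 °C (refractometer standard); a different
temperature means supplying a replacement table. The main-band density
shift is measured as density at the treated profile's peak fraction minus
density at the control's peak fraction, with the peak optionally located
from an accompanying assay-signal profile.

## Synthetic experiments

The generator emulates the statistical structure the analysis assumes,
with defaults at the reference operating point: v_s = 0.567, ρ_r = 1.134
g/mL, ρ_s = 1.067 g/mL, M = 0.166, dense-band control diameter 453 nm
with CV 177.1/453 ≈ 0.39, and measurement SEMs (0.003, 0.0005, 0.0275).
Forward-simulated measurements are the model densities plus Gaussian
noise; DLS diameters are log-normal (positive, right-skewed, matching the
large spread of real dense-band populations), with the treated mean equal
to the control mean times RV^(1/3); gradient assay profiles are Gaussian
bands over 12 fractions (buoyant = 5–8, dense = 9–12, configurable) obeying
three construction laws: treated/control total cholesterol signal equals
M exactly, total protein signal is conserved but redistributed toward the
dense band, and the buoyant ganglioside signal is halved at the reference
treatment strength. Protein redistribution and ganglioside loss scale
linearly with treatment strength 1 − M, so a null treatment (M = 1)
generates identical control and treated gradients.

Setting all noise SEMs to zero switches the generator to a fully
deterministic forward pass (analytic log-normal summaries, exact
conservation); this is the regime in which generator/solver adjointness is
asserted to 1e-10.

What the generator does *not* emulate: vesicle heterogeneity beyond a
single log-normal population, the near-total collapse of the buoyant band
seen in real data (a phenomenon outside the compositional model),
correlated measurement errors, cyclodextrin binding kinetics, or
sonication physics. Passing recovery tests therefore demonstrate that the
*inference machinery* is unbiased and calibrated under the model's own
assumptions — not that the two-component model is a complete description
of real membranes.

`recovery_study` runs generate → invert over replicates (seeds spawned
deterministically from the truth seed) and reports bias, RMSE and 95 % CI
coverage for v_s, ρ_r and the relative volume. At the reference operating
point with 1000 replicates: |bias(v_s)| < 0.001, coverage ≈ 0.96.
Infeasible replicates are counted as failures, never crashes.

## Pipeline and problem sizes

`run_analysis` chains read → solve → propagate → size comparison →
report. The report is byte-deterministic for a fixed config: all
randomness flows through one recorded seed, JSON keys are sorted and no
timestamps are embedded. The DLS comparison uses the dense gradient band —
the band whose vesicles persist through treatment and the one the model
describes; the buoyant band (780 → 42 nm) can be compared on request but
is flagged as outside model scope. Two internally inconsistent published
summaries of the same data (a "49.1 %" restatement of the 0.527 relative
volume, and an "88.8 %" observed volume fall where the printed diameters
give 78.8 %) are reported alongside the arithmetic-consistent values and
flagged, never silently corrected; the attribution fraction is therefore
given against both observed-volume figures (0.60 and 0.53 — "about half").

Default problem sizes — 100 000 Monte-Carlo draws for one-shot
propagation, 2000 draws per replicate × 1000 replicates for the recovery
study — were chosen so that Monte-Carlo error is well below the quantities'
SDs while a full analysis completes in seconds on a laptop.

## Known limitations

- Two components only; a k-component extension is underdetermined by the
  three available measurements.
- ρ_s is treated as exact; its literature value carries unquantified
  uncertainty that would add to all propagated SDs.
- The delta method is first-order; its disagreement with Monte-Carlo for
  ρ_r at full SEM scale (≈ 15 %) is real curvature, not error, and the
  Monte-Carlo result is the one reported.
- DLS mean diameters are taken at face value (intensity-weighting and
  polydispersity corrections are upstream of this package).
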