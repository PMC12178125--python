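# Methods

## Problem and pipeline

The package scores the treatments of a two-factor field trial — biochar
pyrolysis temperature T (°C) and application rate C (t ha⁻¹), plus an
untreated control — against up to ten indicators spanning economic benefit
(tuber yield Z11, net income Z12), tuber quality (starch Z21, vitamin C
Z22, reducing sugar Z23), water/fertilizer use efficiency (WUE Z31, PFP
Z32), and environmental burden (soil residues of nitrate-N Z41, available
P Z42, available K Z43). Z23 and Z41–Z43 are negative indicators (smaller
is better); the rest are positive. Each year is evaluated separately: the
trial's economics are asymmetric across years (biochar is bought once,
before year one), so pooling years would blur a real difference the method
is meant to expose. A pooled two-year-average table remains available
through `average_years`.

## Derived indicators

* WUE = Y/(10·ET) with Y in kg ha⁻¹ and ET in mm, giving kg m⁻³. ET =
  P₀ + I − ΔW − D with groundwater recharge and runoff taken as zero
  (deep water table, flat terrain). Effective rainfall per event is a·P
  with a = 0 below 5 mm, a ∈ [0.8, 1.0] for 5–50 mm (default 0.9) and
  a ∈ [0.70, 0.80] above 50 mm (default 0.75); the literature prescribes
  bands, so the point value within each band is explicit configuration and
  is validated against its band. Both 5 mm and 50 mm belong to the middle
  band ("between 5 and 50" read inclusively).
* PFP = Y/FT where FT sums N, P₂O₅ and K₂O inputs; the trial's uniform
  schedule (urea 652.2 kg ha⁻¹ at 46%, superphosphate 391.3 at 46%,
  potassium sulfate 666.6 at 45%) gives FT = 780.0 kg ha⁻¹.
* Net income = gross income − water fee − fertilizer input (including
  biochar) − other inputs; may be negative.
* Soil nutrient stocks sum M·H·ρ/10 over profile layers (mg kg⁻¹, cm,
  g cm⁻³ → kg ha⁻¹).
* Percent contrasts between treatments average the years first, then take
  ratios. The printed source ranges are reproduced to ±0.01 percentage
  points under this convention for yield, vitamin C, reducing sugar and
  PFP; the starch upper endpoint recomputes to 19.36% against a printed
  19.38% (that figure is only obtained by averaging per-year ratios, a
  convention that does not reproduce the yield or vitamin C ranges — the
  source is internally inconsistent at the second decimal). The published
  net-income range (2.83–159.85%) is not recoverable from the cost table
  under any convention tried — the control's two-year mean net income
  exceeds the best treatment's — and is therefore not asserted anywhere.

## Weighting

**AHP.** Weight extraction uses the geometric-mean (root) method; the
principal-eigenvector method serves only as an independent test oracle
(the two agree exactly on consistent matrices and to well under 0.02 per
component on near-consistent matrices that pass the gate). Consistency:
CI = (λ_max − n)/(n − 1), CR = CI/RI with the standard RI table up to
order 10; CR < 0.1 passes; orders 1–2 define CR = 0 (always consistent —
this also avoids dividing by RI = 0). Entries outside the Saaty set warn
but do not fail, since elicited matrices aggregated across experts land
off-scale routinely; element-wise geometric-mean aggregation of expert
matrices is provided as an optional, clearly labeled extension. The
packaged hierarchy and matrices are illustrative defaults (economics
weighted highest, then efficiency, quality, environment; all CR < 0.012)
because the original expert matrices are not public.

**Entropy.** Computed on orientation-aware min-max standardized values,
never raw values: raw columns can be negative (net income in a year that
absorbs the full biochar cost), which would make the column distribution
P_ij invalid. Cells with G_ij = 0 contribute 0·ln 0 := 0. Constant columns
are flagged during standardization and assigned divergence d_j = 0
directly; an all-constant table is an error (no information).

**Combination.** The 2×2 Gram system can be singular (identical vectors)
or give α outside [0, 1]. Default policy: normalize α to sum 1; if a
component is still negative, fall back to α = (0.5, 0.5) and record it.
An opt-in `absolute_normalize` policy (|α|/Σ|α|) is also exposed. The
conservative default was chosen because the deviation-minimizing objective
gives no guidance once the solution leaves the simplex.

## Fuzzy evaluation

Membership functions are piecewise linear: the extreme grades saturate
beyond C1/C5 (trapezoidal), interior grades are triangular with apex at
their threshold. A value exactly at an interior threshold belongs fully to
that grade — the continuous limit of the strict-inequality formulas. The
negative-orientation family is the mirror image (implemented by negating
value and thresholds). Under this family every membership row sums to 1
exactly, so with weights summing to 1 the min{1, ·} clamp in b_j =
min{1, Σ_i a_i r_ij} is provably inactive (both facts are tested). Grade
ties resolve toward the better grade and are recorded. Scores are
B·(5,4,3,2,1) ∈ [1, 5].

Grade thresholds: the original boundaries are not public, so the default
scheme places C1..C5 at the (0.9, 0.7, 0.5, 0.3, 0.1) quantiles of the
observed values per indicator, orientation-ordered, with epsilon jitter to
break ties (warned). Quantile-anchored grading is relative to the observed
trial, which makes within-trial rankings meaningful but means absolute
grades are not comparable across trials; runs on the packaged fixture
tables are method demonstrations, not reproductions of the original
evaluation values.

Missing indicators (the fixture tables carry only the seven tabled ones;
soil residues exist only as figures in the source) are handled by
renormalizing the AHP leaf weights over the available subset, with a loud
warning in the run report.

## Response surface

The full quadratic is fitted by OLS on centered/scaled coordinates for
conditioning and the coefficients are back-transformed to raw units
(verified by exact recovery of known quadratics to 1e-8 and by affine-
invariance of the located optimum). The control is excluded from the fit
by default: it has no pyrolysis temperature, and assigning it one would
fabricate a coordinate. An option replicates the control at each
temperature level with C = 0 instead. Optimization over the factor
rectangle enumerates the interior stationary point (when the Hessian is
negative definite), the four edge-restricted 1-D maxima and the corners,
and cross-checks against a 201×201 grid; the recommendation band is the
bounding box of grid points within 1% of the maximum predicted score,
mirroring how scheme advice is stated as a range.

## Synthetic generator

Each indicator follows value = peak ∓ kT(T−T0)² ∓ kC(C−C0)² (concave for
positive, convex for negative orientation) plus independent N(0, σ) noise,
fresh per year, deterministic under the seed; negative draws clip at 0
with a warning counter. The control takes the surface value with the rate
penalty only (no biochar → no temperature effect). Net income is derived
from synthetic yield through the same accounting as the real trial
(price 1600 CNY t⁻¹ — the fixture gross income over yield; biochar at
1800 CNY t⁻¹, the fixture's fertilizer-cost increment per tonne — charged
to year one only), so accounting identities hold in synthetic data.

Defaults emulate the study conditions: 3×3 levels (300/500/700 °C ×
10/20/30 t ha⁻¹) + control, two years, crop indicators peaking at
(500 °C, 20 t ha⁻¹) with peaks and curvatures back-solved from the
two-year factorial means of the source tables, soil residues lowest at
(500, 30), (700, 10) and no-biochar respectively, and σ ≈ 2% of each
indicator's observed range. The generator emulates smooth quadratic
responses with independent Gaussian replicate noise; real trials add
year × treatment interactions, spatial autocorrelation and non-quadratic
saturation, so passing recovery tests demonstrate the pipeline's internal
correctness, not field-scale predictive validity.

`true_optimum` returns each surface's analytic optimum and an equal-weight
composite optimum from a 201×201 grid oracle over the configured ranges
(mean of orientation-aligned, grid-standardized surfaces; derived net
income enters as its across-year mean). The end-to-end check runs 100
seeded replicates at the default noise level with equal criteria weights
and quantile schemes and requires the pipeline's recommendation (mean of
the per-year surface optima) within ±50 °C and ±2.5 t ha⁻¹ of the
composite optimum in ≥ 90% of replicates; observed rates are 100%.

## Problem sizes and numerical choices

Default runs evaluate 10 treatments × ≤10 indicators per year; surface
fits use the 9 factorial points; optimizer and band grids are 201×201;
the recovery experiment uses 100 replicates (about two seconds total).
Reciprocity is validated to a relative 1e-9; weight vectors must sum to 1
within 1e-12; membership rows are checked to 1e-9; ranking ties break
lexicographically by treatment id for determinism.

## Known limitations

* The original expert matrices, grade thresholds and evaluation values
  are not public; defaults are labeled illustrative and yearly "best
  treatment" outcomes under them are not comparable to the original ones.
* The orientation of available P and K residues is configurable and
  defaults to negative (residue = leaching risk); a fertility-centered
  reading would flip Z42/Z43 to positive.
* Quantile grade schemes make scores relative to the evaluated table;
  cross-trial comparisons need fixed, externally supplied thresholds.
* The combination-weighting α is data-dependent and frequently hits the
  fallback on real tables where AHP and entropy weights disagree strongly;
  the method note in each report records which branch was taken.
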