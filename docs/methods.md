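# Methods

## Scope and data model

The package analyses thin-layer foam-mat drying experiments: a foam is
spread on a tray, weighed on a fixed cadence at constant air
temperature, and the mass series is reduced to a dimensionless drying
curve that kinetic models are fitted to.  The bundled reference dataset
(`foamdry.reference`) carries the published summary values of an
acerola-pulp study at 50, 55, 60, 65 and 70 °C — fitted logarithmic
parameters, drying times, effective diffusivities, quality-parameter
means with replicate standard deviations, CIELAB coordinates and
response equations — and anchors both the synthetic generator and the
worked examples.  The study's raw weighing curves were never deposited;
nothing in this package pretends otherwise, and every claim about raw
curves is made on synthetic data whose generating process is stated
below.

## Reduction to moisture ratio

Dry-basis moisture is `M = 100·(m_net − m_dry)/m_dry` (% d.b.) with
`m_dry` the oven-dry solids mass.  The moisture ratio
`MR = (M − Mₑ)/(M₀ − Mₑ)` uses `M₀ = M(0)` and `Mₑ` from the
equilibrium plateau, defined operationally as the first weighing from
which the mass changes by at most the balance resolution (default
0.01 g, configurable) over two further weighings — the "constant in
three consecutive weighings" stopping rule.  `Mₑ` is the mean plateau
mass converted to moisture, never a fitted parameter.  MR values pushed
marginally outside [0, 1] by noise are clipped and the clip count is
logged; a series with `M₀ ≤ Mₑ` raises a degenerate-run error.  If no
plateau exists the last observed mass is used as equilibrium, with a
warning.

Kinetic time is carried in **minutes** end to end.  The reference
drying constants (0.0021–0.0059) are only consistent with the published
300–840 min drying times on a per-minute scale; conversion to seconds
happens once, inside the diffusivity module.

## Model bank and fitting

Seven empirical forms are registered (Lewis; Page; Henderson–Pabis;
Logarithmic; Modified Midilli `e^(−ktⁿ)+bt`; Diffusion Approximation;
Two-Term Exponential).  The two-branch forms are written with the
complementary weight `(1−a)` so that MR(0) = 1; the printed sources of
such models are frequently garbled in sign, and only the complementary
form is consistent with fits in which a > 1 while the curve starts at 1.
`tⁿ` at t = 0 is taken as 0 for n > 0.

Fitting minimises squared MR residuals with `scipy.optimize.least_squares`
(trust-region reflective) under box bounds k ∈ (10⁻⁶, 1) min⁻¹,
n ∈ (0.1, 5), a ∈ (0, 5), b ∈ (−1, 1), cost tolerance 10⁻¹², at most
10⁴ evaluations.  The initial k₀ comes from the OLS slope of ln MR on
the early curve (points with MR > 0.1); a₀ = 1, n₀ = 1, b₀ = 0
(logarithmic −0.1), plus eight extra starts with seeded log-uniform
perturbations of k₀ in [0.2, 5]×k₀.  The best local optimum is
returned; non-convergence is flagged, not hidden.  A config switch fits
on the % d.b. scale instead (predictions mapped through
`M = Mₑ + MR·(M₀ − Mₑ)`), which rescales the error statistics without
moving the optimum.

Trailing MR = 0 equilibrium points are dropped from the fit by default:
they carry no kinetic information, and the mean relative error is
undefined at Y = 0.  Goodness of fit reports R² = 1 − RSS/TSS (TSS
about the mean), MRE with points |Y| < 10⁻⁶ excluded (exclusions
counted), and SDE = √(RSS/DF), DF = n − p.  Selection: keep fits with
MRE < 10 %, rank by SDE ascending with R² descending as tie-break; if
nothing survives, rank all by MRE and flag that no model meets the
criterion.

### Identifiability caveats

Two structural facts shape what parameter recovery can mean:

* In `e^(−ktⁿ)`, k carries units min⁻ⁿ, so k and n are strongly
  confounded when n is far from 1; relative k-recovery is only a
  meaningful benchmark near n ≈ 1.  Likewise a diffusion-approximation
  set with a ≈ 1 leaves its second branch nearly weightless and k
  weakly identified against b.
* Any mass-reduced curve starts at exactly MR = 1 and ends at exactly
  0.  An exactly-logarithmic reduced curve therefore has a′ + b′ = 1,
  and the diffusion approximation reproduces such a curve *exactly* in
  the limit b → 0 (its second branch degenerates to the constant
  1 − a); the modified Midilli form is a further near-equivalent.
  Model selection among these on pipeline-reduced synthetic data is a
  near-tie decided by the noise realization.  Exact recovery of the
  reference parameters (whose a + b ≈ 0.93–0.97 ≠ 1) is only possible
  on model-space curves — `synthetic.model_mr_run`, where MR *is* the
  model on the weighing schedule — and that is where the recovery and
  selection benchmarks run.  On pipeline-reduced data the drying
  constant k is still recovered exactly (it is invariant to the curve
  normalization), and a, b are recovered up to the 1/(a+b) rescaling.

## Diffusivity and activation energy

The Fick slab series is summed until the term falls below 10⁻¹² or 200
terms, then closed with the integral tail
`0.5·[e^(−s·a²)/a − √(πs)·erfc(a√s)]`, `a = 2N`, which fixes the slow
small-time convergence (at t = 0 the identity Σ1/(2n+1)² = π²/8 is
reproduced to ~10⁻⁹).

The slope method regresses ln MR on time over all points with MR > 0
(a minimum-MR cutoff is available for sensitivity analysis), converts
the slope to s⁻¹ and sets `D_eff = |slope|·4L²/π²`.  The characteristic
length defaults to **L = 0.015 m, the full foam depth**: for one-face
tray drying the equivalent-slab convention uses the full layer, and
only this value is numerically consistent with reference diffusivities
of a few 10⁻⁹ m² s⁻¹ from minute-scale slopes (half-thickness gives
values ≈ 4× smaller).  L is a required, logged parameter, never
silent.  Note that on synthetic logarithmic curves ln MR bends sharply
near the zero crossing, so pipeline slopes are steeper than the
generating k and pipeline diffusivities land above the reference
per-temperature values; the Arrhenius *trend* is preserved (seed-42
pipeline: 32.2 kJ/mol vs 30.87 from the reference table).

Arrhenius: OLS of ln D_eff on 1/T (K), `E_a = −slope·R` with
R = 8.314 J mol⁻¹ K⁻¹, `D₀ = e^intercept`; duplicate temperatures
collapse to means; identical diffusivities give E_a = 0 with r²
reported as NaN.  r² is the squared Pearson correlation, which is how
the reference correlation of 0.9604 is reproduced.

## Quality calculators and colour

All assay calculators are the standard closed forms; constants default
to citric acid (MW 192.12, n_H = 3, the dominant acerola acid), the
carotenoid absorptivity 2592 (petroleum ether, 450 nm), and vitamin-C
titre factors {8.806, 0.8806} for 0.02/0.002 M iodate.  Every
calculator is homogeneous of degree +1 in its signal and −1 in sample
mass, which the property tests assert.

Hue uses the quadrant-aware arctangent mapped to [0°, 360°); the
browning index requires a non-zero denominator `5.645L* + a* − 3.012b*`.
BI is nonlinear in (L*, a*, b*): the BI of replicate means is not the
mean of replicate BIs.  When replicates are available both are computed
and reported; tables built from published means can only provide
BI-of-means, and agreement with a published BI table is then expected
only to a few percent (the 55/60 °C reference values agree within 0.9 %,
i.e. ≈ 1–1.5 replicate standard deviations).

## Response models and the temperature choice

Quality-vs-temperature responses are OLS polynomials (`statsmodels`),
degree chosen stepwise-down from 3: reduce the degree while any
coefficient's two-sided t-test has p ≥ 0.05, stopping at degree 1; an
explicit `degree=` override bypasses selection.  With only the five
temperature means a quadratic has 2 residual degrees of freedom and its
coefficients are generally *not* significant at 5 % even when they
reproduce the published equations almost exactly (the moisture means
give 0.0122T² − 1.6698T + 74.17 vs the published
0.0122T² − 1.6715T + 74.2269); significance at 5 % requires
replicate-level data, which the generator provides.  The published L*
and a* response equations are internally inconsistent with the colour
table (the a* equation evaluates to ≈ −1277 at 50 °C) — a typographic
corruption — and are excluded from the reference equation set.

Optima are taken over the tested range [50, 70] °C from the real roots
of the derivative polynomial plus the endpoints (for "hold near the
fresh-pulp value" targets, the roots of p(T) − target as well); linear
models resolve to the favourable endpoint.  Desirability directions:
maximize vitamin C, reducing sugars, acidity, carotenoids and ash;
minimize moisture; steer colour coordinates toward the fresh-pulp
value.  The recommendation is the arithmetic mean of per-parameter
optima snapped to the nearest tested temperature (5 °C grid).  On the
reference equations this gives a mean of 61.59 °C → **60 °C**; the
exact mean depends on which parameters enter the average and how
boundary cases are treated, which published studies rarely specify, so
agreement is expected at the chosen-grid level, not in the mean's
decimals.

## Synthetic generator: what it does and does not emulate

`generate_run` produces weighing series on the real cadence (0–60 min
by 20, 90–180 by 30, hourly beyond) up to each temperature's drying
time, appends three exact equilibrium weighings at the hourly cadence,
and reconstructs masses through `M = Mₑ + MR·(M₀ − Mₑ)`,
`m_net = m_dry·(1 + M/100)`.  Defaults are the study conditions:
initial moisture 1142 % d.b. (from the 91.95 % w.b. fresh foam), per
temperature equilibrium moisture from the published final powder
moisture, dry solids 17.16 g (a 1.5 cm foam layer of density
0.14367 g cm⁻³ on a 35.5 cm tray at 8.05 % solids), tare 150 g.  The
generating curve is the reference logarithmic model normalized by its
t = 0 value (see the identifiability note above).  Noise is additive
Gaussian on MR with sd 0.01 — the residual scale implied by the
reference SDE values (0.029–0.056) — applied to scheduled points but
not to t = 0 (MR(0) ≡ 1) or the plateau; one global seed spawns a
deterministic substream per (seed, temperature).  Quality and colour
tables are Gaussian replicates (n = 3) around the published means with
the published standard deviations.

Not emulated: the initial fast-transient departure of real curves from
the fitted model, drying-air humidity and airflow, foam shrinkage and
structural collapse, balance quantisation, and replicate-level drying
curves (one averaged curve per temperature).  Passing tests on this
generator therefore demonstrate the correctness of the reduction,
fitting, selection and diffusivity machinery under the stated
statistical structure — not that the seven models would rank the same
way on any real foam's transients.

## Problem sizes and runtime choices

The Monte-Carlo benchmarks use 100 seeded replicates in the acceptance
script (the selection win-rate and median-k benchmarks) and 20–30 in
the routine suite; the Fick brute-force oracle uses 10⁵ terms; the
response grid search steps 0.001 °C.  These sizes make every
distributional claim stable at the asserted thresholds while the whole
suite stays fast enough to run habitually.

## Known limitations

* The reference diffusivities cannot be reproduced from the synthetic
  curves point-by-point (raw curves undeposited; ln-linearization of a
  logarithmic curve is slope-biased) — only the Arrhenius analysis of
  the reference table itself reproduces the published activation
  energy.
* Constant-diffusivity, constant-thickness slab assumptions are
  inherited from the method; no shrinkage correction.
* No ANOVA/Tukey replication of the published letter groupings
  (replicate-level data not published); no uncertainty propagation
  through the assay calculators.
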