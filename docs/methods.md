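# Methods

This package implements a weighted multimodal composite endpoint for
measuring retinal degeneration in early-onset Stargardt disease (STGD1), a
recessive ABCA4 macular dystrophy. The motivating problem is generic to
rare-disease trials: individual outcome measures (especially visual acuity)
progress slowly and noisily, so phase I/II trials with a dozen patients have
essentially no power. The approach here combines five biomarkers on a common
spatial scale, weights them for maximal responsiveness, and quantifies the
resulting trial power by simulation.

## Eccentricity standardization

Atrophy in STGD1 expands centrifugally from the fovea, so every biomarker is
re-expressed as the retinal eccentricity ε (degrees from the foveal center)
it corresponds to, using 1° ≈ 0.3 mm of retina:

* **BCVA** (decimal fraction): acuity decays by a factor 1/1.2 per degree of
  eccentricity, so ε_BCVA = log_{1/1.2}(BCVA). Acuity better than 1.0 (20/20)
  would give a negative extent and is clamped to ε = 0 with a warning —
  eccentricity is a nonnegative spatial quantity.
* **QDAF/DDAF areas** (mm², questionably/definitely decreased
  autofluorescence on FAF imaging): radius of the circular equivalent,
  ε = √(area/π)/0.3.
* **EZ/ELM transverse loss** (mm, ellipsoid zone and external limiting
  membrane on the foveal OCT B-scan): the loss spans a diameter, so
  ε = loss/(2·0.3).

All transforms are strictly monotone with exact algebraic inverses
(round-trips hold to 1e-9 relative error); computations are done in full
precision and rounded only for display. Note one worked value: the atrophy
area equivalent of ε = 4.22° is 5.035 mm², which prints as 5.04; the
published companion value 5.03 mm² was evidently derived from the unrounded
median eccentricity. The tests compare that pair within one unit of printed
precision.

## Grader reconciliation and agreement

Quantitative image measurements are assumed to come from two blinded
graders. Pairs are averaged arithmetically for all downstream analysis;
pairs differing by more than 1° are flagged for consensus review. Agreement
is summarized by the mean ± SD of absolute differences and by the
intraclass correlation. The ICC form is the two-way random-effects,
absolute-agreement, single-rater ICC(2,1) (computed via pingouin), chosen
because the scientific question is absolute interchangeability of graders,
not merely consistency; a consistency form (ICC(3,1)) is available by
option. A zero-total-variance input leaves the ICC undefined and raises an
explicit error.

## Composite change score

For one eye, the composite change from baseline at follow-up time Δt is the
weighted mean of the per-biomarker eccentricity changes,

    ΔC(Δt) = Σ_m w_m · [ε_m(Δt) − ε_m(0)] / Σ_m w_m,

with weights w on a fixed grid (5% steps by default). Zero weight excludes a
biomarker. When a biomarker is unmeasurable (e.g. EZ loss wider than the
scan), the composite is formed from the remaining biomarkers with their
weights renormalized; a record with no available weighted biomarker is
missing, not an error. Weights are stored as integer grid units, so each of
the C(24,4) = 10,626 five-biomarker combinations sums to exactly 100% and
enumeration order (lexicographic, first biomarker slowest) is deterministic.

The packaged default weighting is (BCVA, QDAF, DDAF, EZ, ELM) =
(0, 25, 5, 55, 15)%. The source study's summary table prints an optimal row
(15% QDAF, 5% DDAF, 55% EZ, 15% ELM) that sums to 90%; its main text states
the 100% version used here. The discrepancy is documented, not resolved.

## Progression model

Composite change is modelled with a zero-intercept linear mixed model with
two nested random slopes:

    ΔC_ij(Δt_ik) = (s + s_i + s_ij)·Δt_ik + E_ijk,

where s is the population slope (°/year), s_i ~ N(0, σ_p²) the patient's
deviation, s_ij ~ N(0, σ_e²) the eye-within-patient deviation, and
E_ijk ~ N(0, σ²) iid residuals. The intercept is identically zero because
the response is a difference from baseline. Baseline rows (Δt = 0), whose
response is deterministically zero, are excluded from fitting — including
them would deflate the residual variance. Random effects are independent
univariate normals; no covariance terms.

Estimation is REML by default (ML by option, for likelihood comparisons
across weightings). The scale σ² and the slope are profiled out, leaving a
2-dimensional optimization over the variance ratios γ_p = σ_p²/σ² and
γ_e = σ_e²/σ² on the log scale (Nelder-Mead, objective tolerance 1e-8,
deterministic start at γ = 1, ratios effectively bounded below at e⁻³⁰ ≈ 0).
A fitted ratio below 1e-8 is reported as a variance pinned at zero, with a
warning rather than an error. The marginal covariance is block-diagonal by
patient, each block a rank-≤3 update of the identity; the constituent outer
products are precomputed per block, which is what makes a fit take tens of
milliseconds. The implementation was verified against the equivalent
statsmodels MixedLM variance-components formulation (agreement to ~1e-4 on
all parameters; see tests).

The Wald 95% CI on s uses z = 1.959964; the original analysis was done in a
different statistical system whose degrees-of-freedom method is unknown,
so small CI discrepancies are expected and absorbed by test tolerances.
Conditional per-eye slopes are BLUPs, s + ŝ_i + ŝ_ij.

Responsiveness is the mean-to-standard-deviation ratio **MSDR = s/RMSE**,
with RMSE the residual SD — a unit-free sensitivity that is invariant to
rescaling the endpoint. Comparisons across weightings always use fitted,
unrounded quantities. RMSE = 0 yields an explicit infinite-MSDR flag.

The **adjusted RMSE** is the root-mean-square *conditional* residual over
follow-up records only; it is the noise scale handed to the trial
simulator. Because BLUPs absorb part of the noise, it sits somewhat below
the generating σ at 2–3 follow-ups per eye (≈20% at the development visit
density); this bias is a property of conditional residuals, not a defect of
the estimator, and the recovery test checks the quantity at a visit density
where absorption is small.

## Weight optimization

The optimizer evaluates every grid combination: form the composite column
(with renormalization), refit the model, record slope, RMSE, and MSDR. The
argmax over converged fits wins; ties break to the earlier combination in
lexicographic order, so the search is deterministic and bit-reproducible.
Combinations that fail to converge or leave too few usable records are
recorded and excluded from the argmax. Per-biomarker delta columns are
computed once; design blocks are cached per missingness pattern, and each
fit warm-starts from the previous optimum's variance ratios. The full
10,626-combination search runs in roughly 8 minutes on one CPU. The
per-biomarker MSDR *profile* reports, for each weight level of one
biomarker, the best MSDR among combinations with that weight.

## Hold-out validation and replication

For eyes of patients with ≥ 3 visits, the chronologically last visit is
withheld; the model is trained on the remainder and the withheld composite
change is predicted as (conditional slope)·Δt. Conditional (BLUP-based)
prediction is used deliberately: population-slope predictions cannot
reproduce per-eye spread, and the validation question is calibration of
individual predictions. Calibration regresses measured on predicted change
(OLS; R² = squared Pearson correlation; Wald 95% CIs on slope and
intercept). Replication freezes the development weighting and repeats the
fit and hold-out exercise on the external cohort — no re-optimization.
Both eyes of qualifying patients contribute test points.

## Trial simulation

The simulated trial treats one eye per patient and follows for x years
(default 2). Per replicate, each eye's observed x-year increment is its
conditional predicted increment plus noise, and the treated eye is further
reduced by δ = effect × (its predicted increment). The noise is
Normal(0, adjusted RMSE²) by default, consistent with the model's residual
term; a literal ±adjusted-RMSE coin-flip variant is available for
sensitivity analysis. Control eyes receive δ = 0.

* Paired design: per-patient between-eye differences, two-sided paired
  t-test. Treatment assignment is Bernoulli(½) per patient per replicate, or
  fixed to the worse eye (larger baseline composite eccentricity).
* Non-paired design: patients are randomized 1:1; one eye per patient enters
  a two-sided pooled two-sample t-test, preserving independence.

Power at each effect size (swept 0→1 by 0.05) is the rejection fraction at
α = 0.05 over 10,000 replicates, with Monte-Carlo SE √(p(1−p)/n). Replicates
with an undefined test statistic count as non-rejections and are tallied.
Randomness comes from one seed via spawned substreams per effect size, so a
seed fixes the whole curve bit-exactly and scenario curves sharing a seed
are comparable. On a homogeneous-slope fit the paired design is analytic
(noncentral t), and the simulator agrees with the closed form within
Monte-Carlo error (tested).

## Synthetic cohorts

The generator emulates the structure the analysis assumes, so the whole
pipeline is testable without clinical data: per-biomarker linear ε
trajectories with patient- and eye-level random slopes, biomarker-specific
residual noise, baselines uniform over the published cohort ranges, visit
schedules shared by both eyes (baseline plus 1–5 follow-ups, the last ≥ 1
year out), EZ set missing when its eccentricity exceeds the OCT scan
half-width, and inversion of every ε to raw clinical units so generated
tables exercise the full transform path.

Defaults are the development cohort's published conditions: 14 patients,
2–4 visits per eye over 1.1–9.7 years; univariable slopes
(BCVA, QDAF, DDAF, ELM, EZ) = (0.31, 0.32, 0.58, 0.34, 0.38) °/yr and
residual SDs (3.77, 0.14, 0.33, 0.17, 0.20)°; the validation preset has 18
patients, 2–6 visits over 1–11 years and its own baseline ranges. Values the
study does not state were fixed once at field-plausible levels: random-slope
SDs σ_p = 0.15 and σ_e = 0.05 °/yr (consistent with the width of the
published slope CI at n = 14), EZ scan half-width 9° (a typical 20°-wide
macular B-scan), and between-eye baseline correlation 0.8 (fellow eyes are
known to be highly symmetric; the exact value is not quantified), induced by
convex mixing of a shared patient draw with an independent eye draw.

Two deliberate idealizations: residual noise is added at follow-up visits
only, keeping baselines noise-free so that changes-from-baseline follow the
fitted model's iid-residual assumption exactly (this is what makes the
generator a valid parameter-recovery oracle); and trajectories are floored
at ε = 0. Consequently, passing tests demonstrate correctness of the
machinery under the model's own assumptions — they do not show robustness
to baseline measurement error, non-linear growth, informative missingness,
or grader drift, none of which the generator emulates.

## Problem sizes and numerical choices

Tests run the full pipeline on single synthetic cohorts (14–18 patients),
parameter recovery on 200 replicates, power curves at 10,000 replicates per
effect size, and grid searches at coarser steps (10–25%) where the full 5%
grid is not itself the property under test; the analysis driver runs the
full 10,626-combination search. Convergence tolerance is 1e-8 on the REML
objective; round-trip tolerances 1e-9; ties in hold-out visit times are
rejected rather than broken arbitrarily; degenerate inputs (zero variance,
all-missing composites, < 2 patients) raise explicit errors where an answer
would be meaningless and flagged sentinel values (NaN composite, infinite
MSDR) where the pipeline can continue.

## Known limitations

* The real per-visit measurements of the two cohorts are not distributed
  with the package; the numerical benchmarks tied to them (univariable
  MSDRs, the (0, 25, 5, 55, 15)% argmax, hold-out R² of 0.904/0.872) can
  only be recomputed after ingesting that spreadsheet via
  `read_cohort(..., column_map=...)`.
* The acuity–eccentricity curve is used as a fixed transform; it is not
  re-derived, and non-numeric acuity categories (counting fingers, hand
  motion) are rejected rather than imputed.
* The model is linear in time by construction and appropriate for short
  horizons only; no non-linear growth alternatives are provided.
* The trial simulator offers no sample-size inversion and no multiplicity
  adjustment across scenarios.
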