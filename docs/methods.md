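# Methods

This note records the statistical procedures `compvig` implements, the
conventions it pins for reproducibility, what the synthetic generator does
and does not emulate, and the design choices made where the design was
genuinely open.

## Case processing

FAERS cases arrive in versions (shared `CASEID`) and near-duplicate copies.
Processing runs in a fixed order: (1) per-CASEID deduplication keeping the
latest `FDA_DT` and, on ties, the highest numeric `PRIMARYID`; (2)
content-based deduplication on the key (sex, age to 1 decimal, country,
event date, sorted reaction PTs, primary-suspect drug, sorted indications),
again keeping the highest `PRIMARYID`; (3) removal of CASEIDs on FDA
quarterly deletion lists; (4) validity screening (a report must carry a
primary-suspect drug and at least one reaction PT); (5) exclusion of
reports with a systemic anti-infective started within the window
[therapy start − 14 d, therapy start) — day −14 inside, day 0 outside,
since the rule concerns treatment *prior* to initiation. Reports missing
the dates needed to establish the overlap are retained: exclusion requires
positive evidence. Every removal is logged with exactly one reason, so
kept + removed partitions the input at each stage and the chain is
idempotent and order-independent.

Partial FAERS dates: `YYYYMM` is imputed to day 01 (quarter-level
information retained without inventing sub-month precision); a bare `YYYY`
is treated as missing for interval and quarter purposes. Ages convert as
DEC×10, YR×1, MON/12, WK×7/365.25, DY/365.25, HR/8766, with values outside
[0, 120] years treated as data errors; weights convert KG×1, LBS×0.453592,
GMS/1000, valid range (0, 400) kg. Drug matching is exact (case-insensitive,
whitespace-collapsed) against a curated synonym table, applied to both
`DRUGNAME` and `PROD_AI` with union semantics; no string-distance matching,
so name coverage is fully auditable.

## Disproportionality methods

All eight methods act on the report-level 2×2 table (a, b, c, d) with
N = a+b+c+d and independence expectation E = (a+b)(a+c)/N. A report counts
in the event margin when any of its reaction PTs qualifies, and counts
once. Flags require a ≥ 3 co-reports throughout.

- **ROR** ad/bc and **PRR** [a/(a+b)]/[c/(c+d)], Woolf log-scale 95% CIs;
  flag when the lower bound exceeds 1. When any cell is zero, the
  Haldane–Anscombe +0.5 correction is applied to all four cells for the
  estimate and CI only (mirroring the stratified-analysis rule below).
- **χ²**: Yates-corrected Pearson statistic Σ(max(|O−E|−½,0))²/E; flag when
  a ≥ 3, PRR ≥ 2 and χ² ≥ 4 (the dominant pharmacovigilance convention for
  this composite rule).
- **Fisher**: two-sided by the minimum-likelihood rule (sum of
  hypergeometric probabilities ≤ the observed table's); flag at p < 0.05.
  Verified against exhaustive enumeration for every table with N ≤ 30.
- **O/E**: log2(a/E) with Wald half-width 1.96/(ln 2 · √a) from the Poisson
  delta method; flag when the lower bound exceeds 0. A ratio-scale bound
  "> 0" is vacuous, so the log scale is the only non-degenerate reading.
- **BCPNN (normal)**: closed-form posterior mean and variance of the
  information component under the standard 1998 prior (α₁=β₁=1, α=β=2,
  γ₁₁=1, γ scaled to the margins); IC025 = E[IC] − 1.96·sd; flag IC025 > 0.
- **BCPNN (Monte Carlo)**: Dirichlet(1,1,1,1) prior on the four cell
  probabilities; IC drawn from the Dirichlet(counts+1) posterior; IC025 is
  the empirical 2.5th percentile (default 100,000 draws, seeded). The two
  BCPNN variants carry different priors and agree only as counts grow: on
  database-scale tables at moderate disproportionality the IC025s agree
  within 0.15, while dense small-N tables with extreme a/E can differ by
  ~0.3 — a property of the published variants, not an implementation gap.
  The cross-method check is therefore run on the former regime.
- **MGPS/EBGM**: λ = relative reporting rate with a two-Gamma mixture prior
  whose hyperparameters (α₁, β₁, α₂, β₂, w) maximise the
  negative-binomial marginal likelihood over the whole drug×PT grid
  (Nelder–Mead on log/logit-transformed parameters from the conventional
  start 0.2, 0.1, 2.0, 4.0, 1/3; the fit must not fall below the starting
  likelihood). EBGM = exp E[ln λ | a, E] under the posterior mixture; EB05
  and EB95 are posterior percentiles found by bisection on the mixture CDF
  to 1e-6; flag EB05 > 2. The grid is unstratified (no covariate strata).

## The CIRVI composite criterion

A PT is a complement-inhibitor-related viral infection adverse event when
(1) ROR flags it in the overall exposed analysis and in each of the C3, C5
and Factor B strata, and (2) at least one of the eight methods flags it
overall and in at least two of the three strata. Clause 2 is read as
same-method-throughout by default; an any-mix reading is available
(`clause2_mode="mixed"`) because the criterion's wording admits both. ROR
itself counts as one of the eight methods. Strata are mutually exclusive by
primary-suspect class; each stratum's comparator is the rest of the
reporting universe, so the overall a-cell equals the sum of the stratum
a-cells. For the pooled viral event set, tables are also available with a
background-only comparator — the scale on which class-specific signal
strength is planted and reported. Every PT in the dataset is screened;
Monte Carlo sub-seeds derive from the master seed and the PT's rank, so
results are independent of report order.

## Time-to-onset

Onset is the calendar-day difference between the event date and the
therapy-start date of the primary-suspect drug; negative or undated
intervals are excluded and counted. There is no censoring (all reports
experienced the event), so the analysis is purely descriptive: medians and
IQRs by the type-7 quantile rule (linear interpolation between order
statistics — pinned so results are bit-reproducible), ECDF step functions,
Kruskal–Wallis across ≥3 groups or Wilcoxon rank-sum for two, and
Benjamini–Hochberg adjustment of pairwise follow-ups. Fully tied data
degenerate to p = 1 with a note rather than an error.

## Risk models

The analysis frame holds one row per complement-exposed report: fatal
indicator (outcome code DE), CIRVI indicator, age, weight, sex, drug
class, and the calendar quarter of therapy start. Categorical contrasts
follow the printed bins: age <18 (reference), 18–64, 65–74, ≥75; weight
<45 (reference), 45–80, ≥80 kg; quarter reference Q1. All regressions are
complete-case, with excluded counts reported; Wald CIs (not profile
likelihood) are pinned for ORs. Separation is reported, not repaired: a
non-converged fit or a |coefficient| > 15 raises an error naming the term.

Restricted cubic splines use Harrell's truncated-power construction with
knots at the conventional quantiles per knot count (e.g. 0.10/0.50/0.90
for k=3), columns scaled by (t_k − t₁)², giving k−1 columns including the
linear term and exact linearity beyond the boundary knots. The knot count
3–7 is selected by AIC (ties to the smaller k). The nonlinearity p-value is
a likelihood-ratio test of the *richest candidate basis* (k=7) against the
linear-in-x model with the same adjustments: a fixed-df test keeps its
nominal chi-square null distribution, whereas testing the AIC-selected
spline inflates the type-I rate (measured ≈0.13 versus the nominal 0.05 at
n = 20,000). Interaction tests compare models with and without
basis×modifier terms by LRT. Adjusted probability curves fix the remaining
covariates at a profile (cohort medians age 42 y, weight 64.2 kg by
default) and locate the minimiser by grid refinement to 0.01.

Stratified 2×2 analyses apply the Haldane–Anscombe +0.5 correction to all
four cells when any cell is zero, for the OR and its Woolf CI only;
Fisher's exact p always uses the raw counts. Crude rates and relative
risks use log-scale Wald CIs.

## The synthetic generator

The generator emulates the *structure* that the analyses rely on: a
background universe of non-complement reports (80% of the dataset, so the
c/d cells are internal), exposed classes with C5 dominant (class shares
3% C3 / 16% C5 / 1% Factor B), a 25-PT catalogue containing the four viral
PTs, FAERS outcome codes, demographics (age median ≈ 42 y, weight median
≈ 64.2 kg, 45.25% female, reporters ≈ 70% consumers / 15% physicians,
≈ 86% US), realistic missingness (age 12%, weight 30%, event date and
therapy start 15% each), and injected duplicate (2%) and
anti-infective-pretreated (1%) reports. Default cohort size is 60,000
reports, mirroring the study scale.

Planted effects and their semantics:

- **Viral signal.** The planted values are pooled class-vs-background
  reporting odds ratios for the combined viral PT set: 3.52 for C3 and
  2.62 for all exposed classes pooled. A common per-PT odds multiplier per
  class is solved by root finding at configuration time (before any data
  are drawn) so those pooled values hold in expectation. The fallback PT
  for reports drawing no reaction is sampled from non-viral PTs only,
  identically in exposed and background reports, leaving the viral margins
  untouched.
- **Fatality.** A logit with class, sex, quarter and CIRVI effects plus a
  U-shaped age term (quadratic, vertex 30 y, curvature 5e-4 per year²) and
  an L-shaped weight term (decreasing exponential). The headline ORs
  (3.55 C5-vs-C3, 0.77 female, 0.22 CIRVI, 0.88 third quarter) are planted
  as *marginal* (univariate) odds ratios: since logistic coefficients are
  non-collapsible, the conditional coefficients are calibrated by
  coordinate-wise root finding on a fixed internal covariate sample so the
  large-sample univariate estimates equal the planted values. Both the
  planted ORs and the solved conditional coefficients are recorded in the
  ground-truth ledger. Background reports die at a flat 6.34%.
- **Onset.** Lognormal onset laws parameterised by (median, σ=1.0):
  12 days for fatal and 187 days for non-fatal outcomes, rounded to the
  nearest day (median-preserving).

All randomness flows from one seed through named sub-streams
(demographics, PT assignment, outcomes, onset, missingness, injections);
the same configuration and seed reproduce the output byte-for-byte. The
ground-truth ledger records every planted quantity and per-report latent,
including the exact PRIMARYID set the processing chain must remove —
injected duplicates plus accidental content-key collisions among sparse
reports, which are genuine content duplicates under the protocol and are
recomputed from the cohort frame, not by running the pipeline.

What the generator does **not** emulate: reporting dynamics over calendar
time (stimulated reporting, the Weber effect) beyond quarter labels;
drug–drug and event–event correlation structure beyond the planted
effects (PTs are drawn independently); informative missingness (all
missingness is completely at random); geographic or reporter-type effect
modification; and the legacy pre-2012Q4 file dialect. Passing recovery
tests therefore demonstrate that the pipeline measures what was planted at
realistic scale and noise — not that real FAERS data satisfy these
simplifications.

## Problem sizes and numerical conventions

Recovery experiments use the scales at which the quantities are
identifiable: 200,000 reports for disproportionality recovery (the rarest
viral PT needs enough Factor B co-reports for its stratum CI), 50,000 for
fatality-OR recovery (20 seeded replicates; coverage assessed jointly over
the planted values), 5,000 per group for onset medians, and n = 20,000
with a uniform age design over [1, 95] and curvature 1e-3 for the
spline-vertex recovery experiment — under the cohort's own thin-tailed age
law the vertex of the shallower default U is only identifiable to ±7 y at
that n, which checks the estimator rather than the data. The acceptance
script reports univariate ORs as geometric means over 20 replicates, the
standard simulation-study aggregate for a log-scale parameter.

Ties, degenerate inputs and tolerances are pinned where they affect
results: type-7 quantiles; EB05 bisection to 1e-6; MGPS optimisation from
the standard start with an ascent guarantee; BCPNN Monte Carlo seeded with
per-table sub-seeds; Fisher two-sided by minimum likelihood; dedup
tie-breaks by numeric PRIMARYID. Empty margins yield NaN estimates with
flags false rather than exceptions wherever a screen must continue.

## Known limitations

- Content deduplication can collapse genuinely distinct but sparsely
  documented reports (missing age and event date, one common PT); the
  protocol accepts this, and at 200,000 reports it removes ≈0.8% of them,
  depressing pooled RORs by roughly 2% relative to the planted values.
- The univariate fatality ORs inherit the usual non-collapsibility and
  confounding caveats; the generator plants marginal targets, but any
  re-analysis that adjusts for covariates estimates conditional effects
  and will differ accordingly.
- EBGM hyperparameters are fitted on the unstratified grid; covariate-
  stratified shrinkage (as in regulatory MGPS deployments) is out of scope.
- The spline minimiser is a curve readout, not a parameter with a standard
  error; its printed precision should be read accordingly.
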