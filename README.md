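# compvig

Pharmacovigilance analysis of complement inhibitors in FAERS, focused on
viral-infection adverse events and their fatality risk.

Complement inhibitors — the C3 inhibitor pegcetacoplan, the C5 inhibitors
eculizumab, ravulizumab, crovalimab and pozelimab, and the Factor B
inhibitor iptacopan — are the mainstay of treatment for paroxysmal
nocturnal hemoglobinuria (PNH). Because complement is central to antiviral
defence, spontaneous-report databases such as the FDA Adverse Event
Reporting System (FAERS) are a natural place to look for viral-infection
safety signals. `compvig` implements the full analysis chain as a tested,
reusable Python package:

- **Ingestion** of the public FAERS "$"-delimited quarterly tables
  (DEMO/DRUG/REAC/OUTC/THER/INDI), with a curated drug-synonym table and a
  MedDRA-style PT→HLT→HLGT→SOC mapping (toy mapping shipped; the licensed
  dictionary is user-supplied in the same 5-column TSV format).
- **Case processing**: per-CASEID deduplication (latest `FDA_DT`, then
  highest `PRIMARYID`), content-based deduplication, FDA deletion lists,
  validity screening, and exclusion of patients on systemic anti-infectives
  in the 14 days before complement-inhibitor initiation.
- **Signal detection** with eight disproportionality methods on report-level
  2×2 tables: ROR, PRR, Yates χ², Fisher's exact test, a log2
  observed-to-expected ratio, the BCPNN information component (closed-form
  normal approximation and Monte Carlo posterior simulation), and
  MGPS/EBGM with marginal-likelihood-fitted two-gamma hyperpriors.
- **CIRVI classification**: a viral PT is a complement-inhibitor-related
  viral infection adverse event when (1) ROR flags it (lower 95% bound > 1,
  ≥3 reports) overall and in each class stratum, and (2) at least one of
  the eight methods flags it overall and in ≥2 of the 3 class strata.
- **Time-to-onset**: descriptive medians/IQRs, ECDFs and Kruskal–Wallis /
  rank-sum comparisons (no censoring: every report experienced the event).
- **Risk models**: univariate/multivariable logistic regressions (ORs with
  Wald 95% CIs), restricted cubic splines with AIC-selected knots (3–7) and
  a likelihood-ratio nonlinearity test, spline×sex interaction tests,
  adjusted probability curves, stratified 2×2 odds ratios with the
  Haldane–Anscombe correction, and crude rates / relative risks.
- **A synthetic FAERS generator** that plants every headline quantity —
  viral-signal odds multipliers (2.62 pooled, 3.52 for C3), fatality odds
  ratios (3.55 C5-vs-C3, 0.77 female, 0.22 CIRVI), lognormal onset medians
  (12 d fatal, 187 d non-fatal) — and writes a ground-truth ledger, so the
  entire pipeline is verifiable by parameter recovery without downloading
  anything.

For the core 2×2 statistics, with `a` co-reports of the drug set and event
set in a database of `N` reports and expectation `E = (a+b)(a+c)/N`:

    ROR = ad/bc            IC = log2( p11 / (p1. p.1) )
    PRR = [a/(a+b)] / [c/(c+d)]      EBGM = exp E[ln λ | a, E],  λ ~ two-Gamma mixture

## Worked example

```python
from compvig.synthetic import SyntheticConfig, simulate_cohort, cohort_to_cases
from compvig.processing import process_cases
from compvig.criteria import screen_pt_universe, pooled_event_tables
from compvig.disproportionality import ror
from compvig.risk import build_analysis_frame, univariate_logit

config = SyntheticConfig(n_reports=60_000, seed=7)
truth = simulate_cohort(config)
cases = cohort_to_cases(truth.cohort)
kept, removed = process_cases(cases)
print(f"reports: {len(cases)} raw -> {len(kept)} after processing ({len(removed)} removed)")

results = screen_pt_universe(kept, seed=7, draws=20_000)
print("CIRVI-AEs:", ", ".join(sorted(r.pt for r in results if r.cirvi)))

r = ror(pooled_event_tables(kept, comparator="background")["C3"])
print(f"C3 pooled viral ROR: {r.estimate:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f})")

frame = build_analysis_frame([c for c in kept if c.drug_class is not None])
print(univariate_logit(frame, "fatal", "cirvi", 0).summary())
```

prints:

```
reports: 61200 raw -> 59789 after processing (1411 removed)
CIRVI-AEs: Herpes zoster, Influenza, Viral infection
C3 pooled viral ROR: 3.42 (95% CI 3.02-3.87)
Logistic regression: fatal (n=12040, AIC=8464.2)
  cirvi=0: OR 1.000 (nan-nan) ref
  cirvi=1: OR 0.181 (0.135-0.242) p=5.33e-31
```

Read: of 61,200 generated report rows, the processing chain removed
injected duplicates, content-key collisions and anti-infective-pretreated
cases. Three of the four planted viral PTs clear the stratified composite
criterion at this cohort size (the rarest, viral gastroenteritis, has only
a handful of Factor B co-reports at n = 60,000 — all four are recovered at
the study-scale 200,000 used in the acceptance run). The C3 stratum's
pooled viral ROR of 3.42 recovers the planted 3.52 within sampling error,
and the univariate fatality OR for CIRVI events is far below 1: planted
protective effect, planted magnitude 0.22.

A command-line entry point mirrors the library:

```bash
compvig simulate --n-reports 60000 --seed 7 --outdir scratch/sim
compvig run-all --input-dir scratch/sim --outdir scratch/run --seed 7 --draws 20000
```

writing tidy TSVs (signal panels, CIRVI evidence, TTO summaries and ECDFs,
odds-ratio tables) plus a plain-text run manifest with stage row counts.

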