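# Methods

## Data model and ETL

A FAERS-style quarter is six dollar-delimited tables keyed by `primaryid`:
DEMO (one row per report version: demographics, `CASEID`, `FDA_DT`,
`EVENT_DT`), DRUG (one row per drug with role codes PS/SS/C/I), REAC (one
row per reported MedDRA PT), THER (therapy start/end dates per drug
sequence), OUTC (outcome codes DE/LT/HO/DS/CA/RI/OT) and INDI
(indications). RPSR is parsed when present but unused. Parsing is strict
about identity and enum fields (bad rows are rejected and tallied per
reason; accepted + rejected = raw rows for every table) and lenient about
descriptive fields (unknown sex/occupation codes normalize to `UNK`,
non-positive weights to missing). Weights convert LBS/GMS to kg; ages
normalize to months via DEC×120, YR×12, MON×1, WK×12/52.1429, DY×12/365.25,
HR×12/8766, because every subgroup definition is month-denominated.

Date tokens are total-function parsed: 8 valid digits give a full date,
6 or 4 digits a month- or year-precision partial, anything else invalid.
Partial dates are retained for non-temporal analyses but count as
"inaccurate" wherever an interval is needed.

**Deduplication** keeps, per `CASEID`, the report with the latest `FDA_DT`,
breaking ties by the numerically higher `PRIMARYID` (lexicographic
fallback, with a warning, if identifiers are non-numeric). The operation is
idempotent and its output size equals the number of distinct caseids.

## Cohort and annotation

The target drug is identified by a synonym lexicon (generic name, trade
name, R&D codes). The default match mode is case-insensitive word-boundary
containment, because FAERS drug names carry dose and formulation suffixes;
exact matching is available. A report is one statistical unit: reaction PTs
are stored as a set, so PT multiplicity within a report never inflates
counts. The target's role in a report is its most suspect role present
(PS > SS > C > I); only PS reports enter disproportionality screening,
while other roles are counted in the attrition manifest. PT → primary-SOC
and IME annotations come from user-supplied two-column files; unmapped PTs
get an explicit `UNMAPPED` SOC with a warning. MedDRA itself is licensed
and never bundled; the run manifest records the user's dictionary version
string.

## Disproportionality statistics

For a term *t*, reports are cross-classified into a (target drug, term),
b (target, other terms), c (other drugs, term), d (other, other); N is
their sum and E = (a+b)(a+c)/N the count expected under independence.

* **ROR** ad/bc with Wald 95% CI on the log scale.
* **PRR** [a/(a+b)]/[c/(c+d)]; **χ²** is Pearson's statistic without the
  Yates correction (the screening-convention choice; a flagged option adds
  nothing else).
* **IC (BCPNN)** — two dialects. *canonical*: IC = log₂[(a+½)/(E+½)] with
  IC025 = IC − 3.3(a+½)^−½ − 2(a+½)^−³ᐟ², the standard credibility-interval
  approximation of the shrunk observed/expected ratio. *fixed_offset*:
  IC = log₂(EBGM) and IC025 = IC − 1.67, matching published screening
  tables in which the IC column is exactly the base-2 log of the EBGM
  column and the printed interval gap is constant (the printed gap shows as
  1.66 or 1.67 only through rounding of each side). Both are provided
  because the two conventions coexist in the literature; *canonical* is
  the default for screening.
* **EBGM (MGPS)** — *simplified_oe*: EBGM = a/E with
  EB05 = EBGM·exp(−1.645·√(Σ 1/cell)), the log-normal approximation that
  published tables track; *mgps_em*: the full empirical-Bayes treatment
  below.

**Zero cells**: the Haldane–Anscombe +0.5 is added to all four cells, only
when some cell is zero, and only for ROR/PRR and their intervals; affected
rows carry a flag. Statistics that remain undefined (a = 0) are reported as
missing and fail their criterion instead of erroring.

**Joint signal rule** (config-overridable defaults): a ≥ 3 and ROR CI
low > 1; a ≥ 3 and PRR ≥ 2 and χ² ≥ 4; IC025 > 0; EB05 > 2. A term is a
signal only if all four pass. Screening emits one row per term with counts,
statistics, per-algorithm verdicts, IME flag and SOC, ranked by case count
(descending) then term; a post-hoc exclusion list removes named PTs from
the signal set and reports before/after counts.

**Counting units.** The default unit is the report (presence/absence). An
occurrence unit — distinct (report, PT) pairs — is provided because SOC
tables published from this kind of screening can show SOC case numbers
exceeding the report total, which is only possible when PT occurrences are
counted at SOC level. Both units share the same estimator code.

A note on monotonicity: ROR and PRR increase strictly in a (b, c, d
fixed). EBGM = a·N/((a+b)(a+c)) and the shrunk IC do not, in general —
their expectation E also grows with a, and on tiny degenerate tables the
ratio can stay flat or dip (a=1,b=1,c=1,d=6: 2.25 → 2.22). On the
screening-shaped domain (event rare in both arms, b,c > a) growth is
strict; the property suite asserts exactly that.

## MGPS empirical Bayes

Counts are modelled as a_i ~ Poisson(λ_i E_i) with λ drawn from
w·Gamma(α₁,β₁) + (1−w)·Gamma(α₂,β₂) (shape/rate). Marginally each count is
a two-component negative-binomial mixture; the hyperparameters are fitted
by EM over all screened terms — responsibilities in the E-step, per-
component weighted NB maximum likelihood (Nelder-Mead in log-parameters) in
the M-step — with convergence on the relative change of the marginal
log-likelihood and a fall-back to the simplified estimator if the
iteration cap is hit. The posterior of λ_i is again a gamma mixture;
EBGM_i = exp E[ln λ_i | a_i] (posterior geometric mean, via digamma) and
EB05 is obtained by Brent inversion of the posterior mixture CDF.

Numerical guard: log α and log β are bounded to ±15. When the null
population is exactly Poisson (rate ratio 1, as in the synthetic data) the
ML concentration of the null component diverges, and past ~1e15 the
difference Γln(α+a) − Γln(α) loses all double-precision accuracy, which
can fabricate a spurious optimum. The bound keeps the likelihood accurate
while still allowing an effectively point-mass null component.

## Stratified analyses

Subgroup screens re-run the full four-algorithm screen on a stratum of the
PS cohort against the *unchanged* background. Age bands are closed-open in
months — [0,6), [6,18), [18,∞) — to avoid double counting at the textual
band edges; cases missing the stratifier go to an explicit `missing`
stratum, so stratum sizes always sum to the cohort size.

Between-stratum contrasts (sex; weight or age about a cut such as 8.5 kg or
8 months) use the within-cohort 2×2 of (stratum × PT presence):
ROR = a₁b₂/(b₁a₂) with a Wald CI, a two-sided p from the z statistic on
ln ROR (chosen to match the ROR-CI framework; Fisher's exact test is an
option for small cells), and volcano coordinates (log₂ ROR, −log₁₀ p) that
are pure functions of the count columns. A Benjamini–Hochberg column is
emitted for reference but never gates anything, matching the raw p < 0.05
convention of this analysis style. Sex-exclusive PT sets are presence-based
by default (a signals-only variant is a flag), since the screening
convention does not pin this down.

## Time to onset

The onset interval is EVENT_DT (report-level, DEMO) minus the earliest full
START_DT of the target drug's therapy rows (flagged when several rows carry
full dates). FAERS has no per-PT event dates, so the onset unit is the
(report, PT) pair: a report with k PTs contributes k records sharing one
interval — this is what lets the onset record count exceed the report
count, and it is noted in the output metadata. Candidates are excluded and
tallied as `missing`, `partial`, `invalid` or `negative` (event before
start); records plus exclusions equal the candidate count exactly.
Profiles use 30-day bins (calendar-month binning would depend on reporter
dates that are not modelled) and a day-resolution first-month histogram
with a terminal >30 bin so every scheme conserves totals. The late-event
composition table gives SOC shares among onsets beyond a cutoff (default
365 days).

## Combination therapy

The census ranks normalized co-reported drug names over target cases at a
minimum count (default 20). Interaction screening partitions cases into
combination (target PS + partner in any role), target-monotherapy and
partner-monotherapy (partner PS/SS without the target) cohorts — partner
presence is deliberately role-insensitive to keep combo detection
sensitive, while the partner-monotherapy comparator mirrors the suspect
convention. Per PT the table reports reporting proportions, the
combination-vs-each-monotherapy RORs with CIs and p-values, an
"elevated in combination" flag (both CI lower bounds > 1), and the number
of four-algorithm criteria the PT passes on the combination cohort against
the full background, so a quorum rule (default ≥ 3 of 4 — one literal
reading of "a minimum of three screening criteria", documented as an
interpretation) can be applied.

## Synthetic data

The generator emits byte-deterministic quarters from a seed. Defaults are
the study conditions used throughout the test and acceptance suites:
50,000 reports, 5% carrying the target drug (90% of those as PS), a
100-term vocabulary with per-report background rates log-spaced over
0.005–0.05 across 8 SOCs, five planted signals at multipliers 5–12 and 95
null terms, 5% duplicated caseids with earlier FDA dates, 10% missing and
5% partial event dates, 2% negative intervals, sex ≈ 45/40/15 F/M/unknown,
age ≈ N(12, 8²) months and weight ≈ N(8.5, 2.5²) kg with 30% missingness —
magnitudes chosen to resemble an infant gene-therapy cohort — a 10%
partner-drug share with two combination-planted PTs at ×3, and an onset
mixture of a geometric early decay (p = 0.2, weight 0.8) with a uniform
tail to 730 days (an early-peaking profile with rare late events).

PT assignment is independent Bernoulli per term, with at least one PT per
report enforced by row resampling; independence is what makes the 2×2
estimators unbiased here, so parameter recovery is a fair test. The ≥1-PT
conditioning inflates all realized rates by a common factor (slightly
larger in the background, whose total rate is lower), which is why
recovered rate ratios sit a little below the planted multipliers — the
truth manifest therefore records *realized* per-PT counts at emission, and
reconciliation against the parsed, deduplicated, re-aggregated quarter is
exact, with no stochastic gap. Infeasible configs (rate × multiplier > 1)
are a hard error before anything is written.

What the generator does **not** emulate: real FAERS drug co-reporting
correlation, PT co-occurrence structure, reporting-volume trends over
quarters, or free-text drug-name noise beyond fixed synonym variants.
Passing recovery tests therefore demonstrates estimator and pipeline
correctness under the stated independence model, not robustness to the
confounding structure of real spontaneous reports.

## Orchestration and determinism

`run_all` executes parse → dedup → cohort → PT/SOC screens → exclusions →
age-band screens and sex/weight/age contrasts → onset profiles →
census/interaction → demographic summary, writing delimited tables plus
plot-ready JSON and a manifest (config snapshot, input sha256 checksums,
per-stage attrition, software and MedDRA-map versions, seed). All output
is sorted with fixed float formatting and carries no timestamps, so a
rerun with the same inputs is byte-identical. Any stage failure aborts
with the stage name and a partial manifest. The demographic table assigns
each case one outcome by severity priority (DE > LT > DS > HO > CA > RI >
OT, else Missing), so block counts conserve the total; percentages are
reported against both the cohort and the IME-subset denominators, because
published tables use each in different columns.

## Problem sizes in the distributed suites

The bundled test and acceptance runs use: 20 × 50,000-report quarters for
planted-signal recovery, 8,000–30,000-report quarters for module-level
end-to-end checks, 2,000 replicates per odds ratio for CI calibration,
1,000 random tables for oracle agreement, and 5,000 simulated terms for
EM hyperparameter recovery — sizes at which every Monte-Carlo band in the
assertions is comfortably resolved.

## Known limitations

* The fixed-offset IC dialect reproduces a printing convention, not a
  posterior; its IC025 has no coverage interpretation.
* The background comparator is "all other reports in the loaded quarters";
  same-indication comparators are out of scope.
* No multiplicity adjustment gates screening verdicts or contrasts (the
  BH column is informational), consistent with standard pharmacovigilance
  screening practice.
* Database-scale headline counts from real FAERS (millions of reports)
  are not recomputable here; the reference tables are used for algebraic
  consistency checks only.
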