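# Methods

This note documents the statistical procedures, the synthetic-data model and
the numerical conventions the package commits to, and the reasoning behind
the choices that were genuinely open.

## Data model and cleaning

FAERS quarterly extracts are `$`-delimited ASCII tables (DEMO, DRUG, REAC,
OUTC, THER) keyed by PRIMARYID; re-submissions of the same case share a
CASEID and differ in version. Cleaning follows the standard sequence:

1. **Deduplication.** Per CASEID keep the version maximizing
   (FDA_DT, PRIMARYID) lexicographically. PRIMARYID comparison is numeric
   (FAERS PRIMARYIDs are numeric strings; "highest value" presumes numeric
   order); non-numeric ids fall back to lexicographic order above all
   numeric ones. Child-table rows of dropped versions are removed.
2. **Delete lists.** Quarterly delete files exist from 2019Q1 onward and are
   applied *after* versioning, so a delete-listed retained version removes
   its case entirely rather than resurrecting an older version.
3. **Primary suspect restriction.** Only the PS-coded drug of each report is
   carried forward. Raw data can contain several PS rows per report; the
   lowest drug-sequence entry is kept (a deterministic rule is preferable to
   dropping the report; the count is logged).
4. **Normalization.** Ages are converted to years from their unit code
   (DEC ×10, YR ×1, MON ÷12, WK ÷52.18, DY ÷365.25, HR ÷8766); values
   outside [0, 150] years, or with unrecognized unit codes, become missing
   and are counted. Partial dates are completed deterministically —
   YYYYMM → the 15th, YYYY → July 1 — midpoint conventions that are unbiased
   within their period; they are used for onset only when both dates
   resolve. Therapy start for onset is the PS drug's *earliest* THER start
   date: first exposure is the pharmacologically relevant anchor.

Each stage logs input/retained counts, giving a flowchart-style funnel in
the run report.

## Cohort and signal statistics

Chemotherapy reports (any mapped ATC code beginning `L01`) are removed
before anything else, so the reference group is "all non-chemotherapy
reports". A drug with several ATC codes is excluded if *any* code is L01
(conservative), and contributes to every non-L01 level-2 class it maps to.
Unmapped drugs stay in the reference population but cannot appear in
class-level aggregation. Case status is an exact, case-insensitive match of
the target preferred term; deliberately no standardized-query expansion
(related terms like neutropenia have distinct mechanisms and would dilute
specificity).

The reporting odds ratio uses the Woolf log-normal interval with z = 1.96.
Zero cells leave the estimate undefined rather than applying a
Haldane–Anscombe 0.5 correction: the signal rule's report-count floor
(a ≥ 3) makes corrected estimates unnecessary, and the uncorrected formula
is the cited convention. The positive-signal rule is a ≥ 3 AND lower 95%
bound > 1. Rankings (by report count and by ROR) break ties by drug name so
output is deterministic.

## Onset analysis

Onset = event date − therapy start, in whole days (difference, not an
inclusive count); negative intervals are excluded and counted. Age bins are
<18, 18–44, 45–64, ≥65; unknown sex/age strata are tabulated but excluded
from tests. Quartiles use linear interpolation between order statistics
(numpy's default), so median(IQR) is invariant under record order.

* Mann–Whitney U: exact enumeration when both groups have n ≤ 8 without
  cross-group ties; otherwise the normal approximation with tie correction
  and continuity correction (small-sample accuracy; scipy implementation).
* Kruskal–Wallis: tie-corrected H, chi-square approximation with k−1 df.
  The all-values-identical case has zero rank variance and is returned as an
  explicitly flagged degenerate result (p = 1) instead of an error.
* Dunn's post-hoc test: z statistics on pooled mean ranks with the
  Σ(t³−t)/(12(N−1)) tie correction, Bonferroni-multiplied by k(k−1)/2 and
  capped at 1. (No maintained reference implementation is available in the
  dependency set, so it is implemented here and cross-checked against the
  two-group Mann–Whitney case in the tests.)

Drug- and class-specific onset summaries require ≥ 20 onset records — below
that, medians of heavy-tailed onset distributions are too unstable to
report.

## Mortality analysis

Death ⇔ outcome code DE (life-threatening, hospitalization etc. are
non-death outcomes). Period binning uses the FDA receipt year — the same
clock used for versioning — with an optional event-date alternative; the
default bins are 2004–2010, 2011–2015, 2016–2020, 2021–2024.

Convention choices here were *verified numerically* against a published
four-period summary table before being frozen as defaults:

* **Binomial intervals: Clopper–Pearson** (exact beta quantiles). This is
  the only standard method that reproduces the published intervals
  (10.59–13.34 for 262/2199; 6.31–8.35 for 188/2583) at printed precision;
  Wilson is available via `ci_method="wilson"`.
* **Omnibus trend test**: Pearson chi-square on the k×2 table, no
  continuity correction (standard for df > 1). Expected cells < 1 raise a
  warning flag.
* **Pairwise period tests**: 2×2 chi-square *with* Yates continuity
  correction, multiplied by the number of pairs (6 for four periods). This
  is the only convention reproducing the published adjusted values 0.687,
  0.028 and 0.010 — and the published uncapped 1.838, which is why adjusted
  p-values are reported both uncapped and capped at 1 (capped is the
  default in machine-readable output).
* **Gender death-vs-survival comparison**: 2×2 (death × F/M) with Yates
  correction, unknowns excluded — reproduces the published p = 0.070 (a 3×2
  including unknowns does not).
* **Gender reporting balance**: 1-df goodness-of-fit chi-square of (F, M)
  counts against 50:50, unknowns excluded, no continuity correction —
  reproduces the published p = 0.420 from the reconstructed counts
  (5011 F, 5092 M).

Per-drug mortality requires ≥ 20 deaths, again for estimate stability.
Every mortality entry point also accepts pre-aggregated counts ("fixture
mode"), because raw spontaneous-report extracts are rarely redistributable
while published summary tables are.

## Synthetic-data generator

The generator emulates the modern FAERS record structure: one DEMO row per
case version, exactly one PS drug per report, REAC rows holding MedDRA
preferred terms as text, OUTC outcome codes, THER therapy start dates, and
(from 2019Q1) per-quarter delete lists. Its generative model:

* **Event model.** Background probability p₀ of the target event (default
  0.02) defines baseline odds o₀ = p₀/(1−p₀); a drug with planted
  multiplier m produces the event with probability m·o₀/(1+m·o₀). When the
  index drug is a minority of reports against a multiplier-1 background,
  the drug-vs-rest reporting odds ratio converges to m, which is what the
  recovery tests exploit.
* **Onset** is log-normal per drug (defaults: log-mean 3.0 ≈ 20-day median,
  log-sd 1.0) — the simplest right-skewed family consistent with the
  heavy-tailed medians/IQRs typical of reported onset times. Therapy start
  is event date minus onset, so start ≤ event by construction.
* **Demographics.** Sex F/M/unknown at 0.46/0.46/0.08, age normal(57, 20)
  clipped to [0, 100] with 15% missingness — chosen once to mirror the
  demographic mix typical of agranulocytosis report series; country and
  reporter-occupation categoricals are plumbing only.
* **Duplicates and deletes.** A configurable fraction of cases gets an
  extra earlier version (and a sub-fraction an identical FDA_DT with a
  distinct PRIMARYID, exercising the tie-break); a configurable fraction of
  retained post-2019 reports is delete-listed. Missing fields are empty
  strings, per the FAERS ASCII convention; a configurable fraction of
  event/therapy dates is truncated to YYYYMM or YYYY to exercise partial
  date handling.
* **Ground truth** (per-drug multipliers, per-case event/death/onset,
  retained and deleted ids) is recorded for oracle use and written as a TSV
  beside the bundle.

What the generator does **not** emulate: free-text drug-name noise
(misspellings, salts, combination products), indication-driven channeling
bias, per-era layout changes, multi-drug reports with suspect/concomitant
interplay, or reporting-rate secular trends. Passing tests therefore show
the *computational* pipeline is correct under a known generative model, not
that signal detection on real FAERS data is free of the usual
pharmacovigilance biases.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (numpy `default_rng`);
fixed seed gives byte-identical bundles and output tables. The validation
suite recovers a planted odds multiplier of 10 within its estimated 95%
interval in ≥ 90 of 100 replicates at 50,000 reports per replicate, and
checks the null positive-signal rate (all multipliers 1) at 4,000 reports ×
200 replicates with 10 drugs — sized so each drug's expected case count
(≈ 8) clears the a ≥ 3 rule floor — against an independent brute-force
simulation of the same odds model and rule.

## Known limitations

* One report = one PS drug: concomitant-drug confounding is out of scope,
  as are shrinkage-based disproportionality statistics (PRR, EBGM).
* No MedDRA version reconciliation; the target term is matched as text.
* Onset ignores censoring (raw reported intervals only).
* The risk-tier table is an external curated input; the package validates
  and applies the rules but does not perform literature review.
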