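# Methods

`pvsignal` implements disproportionality signal mining for spontaneous
adverse-event report databases in the FAERS quarterly-file dialect, end
to end: ingestion, deduplication, drug-name mapping, event-universe
definition, reporting-odds-ratio (ROR) statistics with signal
classification, and case-series profiling, together with a synthetic
cohort generator that provides ground truth for every stage.

## The statistical model

A spontaneous-report database has no denominator: it records reports,
not patients at risk, so incidence cannot be estimated. Disproportionality
methods instead ask whether a drug–event pair is reported *more often
than expected relative to everything else in the database*. For a target
exposure E (a drug or drug class, restricted to suspect roles) and an
event term P, the deduplicated reports are cross-classified:

|            | P reported | other events only |
|------------|-----------|-------------------|
| exposed    | a         | b                 |
| unexposed  | c         | d                 |

The reporting odds ratio is the cross-product ratio ROR = ad/bc, with
the Wald 95% confidence interval exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))
and a Pearson 1-df chi-square (no continuity correction by default;
Yates available as an option) for statistical support. When any cell is
zero, the Haldane–Anscombe correction (+0.5 on all four cells) keeps the
estimate finite; such rows are flagged `corrected` in every output.

Counting is at report level: a term listed twice in one report counts
once, and a report contributes to exactly one row and one column of each
table, so a+b+c+d always equals the number of deduplicated reports.

### Signal classification

A term is a **signal** when it has at least `min_reports` exposed cases
(default 3) and its disproportionality exceeds 1. Two rules are
implemented:

* `ci_lower` (default): the CI lower bound must exceed 1. This is the
  rule that exactly reproduces the footnote flags of the published
  31-row all-PPI hepatotoxicity signal table shipped in
  `pvsignal/data/published_ppi_signal_table.tsv` — including rows such
  as "Transaminases abnormal" (ROR 1.748, CI 0.560–5.455), which a
  literal point-estimate rule would wrongly flag.
* `point_estimate`: the literal ROR > 1 screen, available by
  configuration.

A signal is **strong** when additionally ROR ≥ `strong_ror` (default 5).
A *co-owned* strong signal is a term that is strong in the per-drug
analyses of at least `coowned_min_drugs` drugs (default 2).

An ROR measures reporting disproportionality, not risk; thresholds are
screening conventions, not hypothesis tests with controlled error rates,
and no multiple-testing adjustment is applied (none is conventional in
this screening setting).

## Deduplication

Two stages, both deterministic:

1. **Latest case version.** A case (caseid) accumulates revisions, each
   a separate primaryid; only the greatest caseversion is kept, ties
   broken by greatest primaryid (numeric comparison when ids are
   numeric).
2. **Record linkage.** Reports agreeing on the complete key (receipt
   date of the first case version, age rounded to whole years, sex,
   reporter country) are collapsed to the member with the greatest
   primaryid. A key with any missing component never matches: missing
   data makes reports *less* collapsible, never more. Age is compared
   after rounding because source ages arrive in mixed units (years,
   months, days) and exact float comparison would create spurious
   mismatches.

Which member of a linkage group is "the original" is not recoverable
from the data; keeping the greatest primaryid (a proxy for the most
recently assigned identifier) is this package's deterministic choice.
An age tolerance beyond rounding is not applied.

## Drug-name normalisation and exposure

Drug entries are verbatim free text. Normalisation uppercases, trims,
collapses whitespace, strips punctuation, and repeatedly removes
trailing dose/form/salt tokens from a configurable stop-list
(`"Protonix 40 mg tablet"` → `PROTONIX`). Mapping to generic names is
exact-match against a two-column lexicon (generic, synonym); no fuzzy
matching, so every decision is auditable. The packaged lexicon covers
the seven marketed proton-pump inhibitors with common brand names; two
of them (dexlansoprazole, ilaprazole) are retained even though analyses
of real data found no reports for them — zero-report drugs produce empty
outputs, not errors.

Exposure defaults to suspect roles only (PS/SS): concomitant (C) and
interacting (I) entries do not make a report "exposed", matching
standard practice for implicating a target drug.

## Event universe and categories

Hepatotoxicity terms are defined by a double criterion on MedDRA
preferred terms: membership in at least one of two Standardized MedDRA
Queries (liver injury; acute hepatic failure) AND in the
hepatobiliary-disorders System Organ Class. MedDRA is licensed, so the
catalog is user-supplied configuration; the packaged catalog holds the
31 terms of the published signal table with their three clinical
categories (5 hepatocellular injury, 4 cholestasis, 4 liver failure,
rest uncategorized). It is a partial reconstruction — the full SMQ∩SOC
intersection in MedDRA 23.0 has 40 terms, but only the 31 published
ones are recoverable — and documents itself as such. Published tallies
of "signals among selected terms" are themselves inconsistent (31
claimed signals vs 26 unfootnoted rows); the pipeline reports both
counts in its run log and resolves nothing.

PT matching is case-insensitive exact text match (controlled
vocabulary; no lower-level-term rollup, no SMQ narrow/broad scoping).

## Case series

For one (drug, term) pair the matching reports are profiled: yearly
counts (year = FDA receipt year of the first case version, the only
date always present), sex, age bins [<18, 18–<35, 35–<60, ≥60,
unknown], concomitant-medication bins {0, 1, 2, 3, >3} counting
*distinct normalised names* other than the target (role codes on
concomitants are unreliable, and entry-level counting would double-count
respellings), top co-reported drugs, and top indications. The literal
"PRODUCT USED FOR UNKNOWN INDICATION" is kept as its own category, and
reports with no indication rows are counted under it. Percentages are
rounded half-away-from-zero to two decimals, the convention that
reproduces every published case-series percentage from its printed
counts (e.g. 19/28 → 67.86).

## Synthetic cohort generator

The generator emits DEMO/DRUG/REAC/INDI tables from an explicit model:

* demographics: receipt date uniform over the configured year range
  (default 2013–2019); age ≈ N(58, 18²) clipped to [0, 100] years;
  sex 48% male; reporter country from a small weighted pool; each field
  independently missing at configurable rates (defaults 15% age, 8%
  sex, 5% country);
* per-drug exposure: independent Bernoulli, with a role drawn from the
  drug's PS/SS/C distribution (default 0.6/0.2/0.2); names rendered as
  brands with probability 0.5 and decorated with dose/form suffixes
  with probability 0.2 to exercise normalisation;
* reactions: independent Bernoulli per term, where an injected
  (drug, term) effect multiplies the term's odds by the target ROR for
  reports exposed to the drug *in a suspect role*. Odds-scale injection
  makes the population ROR under the suspect-role exposure definition
  exactly the configured value; a report with no sampled reaction gets
  a filler term so reaction sets are never empty (which would otherwise
  condition the cohort and bias the odds);
* duplicates: per report, mutually exclusively, an extra case version
  (same caseid, caseversion 2, higher primaryid) or a cross-source
  clone (new caseid, identical linkage key) is injected; a truth
  sidecar labels exactly the rows the two dedup stages should remove.
  Accidental complete-key collisions between distinct base reports are
  removed by nudging receipt dates forward a day until keys are unique,
  so duplicate labels are exact ground truth — precision and recall
  against the sidecar are meaningful at 1.0, not approximately;
* concomitants and indications: per-report concomitant count from a
  configurable distribution, names drawn without replacement from a
  pool; indication terms attach to suspect entries and are the literal
  unknown-indication string with probability 0.5 by default.

All draws come from a single seeded NumPy generator in a fixed,
documented order (demographics → exposure/roles → reactions →
concomitant counts → name rendering → indications → concomitant picks →
duplicate assignment), so a (config, seed) pair reproduces the tables
byte for byte on any platform.

`expected_table` gives the closed-form expected 2×2 cells
(pre-duplication) by enumerating suspect-exposure patterns over the
target drug and every drug with an effect on the term; it is the
analytic oracle the convergence tests compare empirical cells against.

The default study-shaped configuration uses five PPIs with injected
per-drug effects at the reporting odds ratios the published per-drug
analyses found (e.g. cholestasis for esomeprazole at 21.556, hepatitis
cholestatic for pantoprazole at 22.611, coma hepatic for lansoprazole
at 10.424, hepatitis fulminant for rabeprazole at 40.240). Exposure
probabilities (0.4–3% per drug) are scaled up relative to a real
multi-million-report database, where PPI exposure is ~0.3% of reports,
so that cohorts of 10⁴–10⁵ reports — the problem sizes this package's
tests and acceptance script use — contain enough exposed reports for
stable cells; relative drug frequencies are preserved.

### What the generator does not emulate

Reporting-rate time trends (Weber/ripple effects), correlated
co-prescription structure, dose–response, within-report dependence
between reaction terms, free-text misspellings beyond dose/form
suffixes, and non-year age units in emitted files. Passing tests
therefore demonstrate correctness of the machinery under a known
generative model, not the clinical validity of any signal in real data.

## Numerical and degenerate-input choices

* z = 1.96 exactly (the field's conventional quantile), not
  norm.ppf(0.975); the difference is ~1e-5 relative.
* Zero cell → +0.5 on all four cells, flagged; all-zero table → error.
* Zero margin → chi-square undefined (NaN, flagged), not 0.
* Rounding of percentages: decimal half-away-from-zero on the exact
  decimal repr, immune to binary-float artifacts (2.675 → 2.68).
* Reports with no reactions are excluded at assembly (they cannot
  contribute to any cell) and counted in the run log; orphan detail
  rows are skipped and counted, never silently dropped.
* Unparseable dates become missing but keep their rows; a missing
  mandatory column is a hard, named error.
* Survivor choice in every dedup group is by greatest primaryid, making
  results invariant to input order.

## Problem sizes

Statistical checks run at sizes chosen to give the assertions power
while staying desk-scale: 500 cohorts of 20,000 reports for
parameter recovery (mean injected-ROR error and CI coverage), 300
cohorts of 10,000 for the null flag rate, 100,000 reports for
convergence of empirical cells to the analytic expectation, and 10,000
for dedup truth checks. These sizes are the package's own study
conditions and are stated so results can be reproduced exactly.

## Known limitations

* The Wald CI is anti-conservative for very sparse cells; the
  classification floor of 3 exposed cases mitigates but does not remove
  this (coverage checks in the acceptance suite run at moderate cell
  sizes).
* Exact-match name mapping misses misspellings; the stop-list is
  configuration, not ground truth.
* The record-linkage key (date, age, sex, country) can in principle
  collapse genuinely distinct reports in a real database; the
  synthetic generator side-steps this by construction, so real-data
  dedup counts should be reviewed against the run log.
* The packaged event catalog is partial (31 of 40 terms), and the
  packaged lexicon's brand lists are not exhaustive.
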