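# pvsignal

Reporting-odds-ratio (ROR) disproportionality mining for spontaneous
adverse-event reports in the FAERS quarterly-file dialect, built for
pharmacovigilance analysts and methods researchers who need the whole
chain — ingestion, deduplication, drug-name mapping, event-universe
definition, 2×2 statistics, signal classification, case-series
profiling — as auditable, testable code rather than ad-hoc SQL.

The packaged configuration targets hepatotoxicity signals of the proton
pump inhibitors (PPIs: omeprazole, esomeprazole, lansoprazole,
dexlansoprazole, rabeprazole, pantoprazole, ilaprazole), but every
piece — the drug lexicon, the MedDRA preferred-term catalog, the
thresholds — is plain configuration.

## The statistic

For a target exposure (drug or drug class, suspect roles PS/SS only)
and an event preferred term, deduplicated reports are cross-classified
into a 2×2 table (a: exposed with the event, b: exposed without,
c, d: likewise unexposed) and

```
ROR = ad / bc,   95% CI = exp( ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d) )
```

with a Pearson chi-square for support. A term is a *signal* when a ≥ 3
and the CI lower bound exceeds 1 (a literal ROR > 1 rule is available),
and a *strong signal* when additionally ROR ≥ 5. Zero cells get the
Haldane–Anscombe +0.5 correction and are flagged. Deduplication keeps
the latest version of each case, then collapses reports that agree on
the complete linkage key (first-version receipt date, age, sex,
reporter country). See `docs/methods.md` for the full model,
assumptions, and numerical choices.

## Worked example

Simulate a study-shaped cohort (five PPIs, injected drug–event effects,
duplicate reports, brand-name noise) and run the full analysis:

```python
from pvsignal.pipeline import RunConfig, run_pipeline
from pvsignal.synthetic_data import default_ppi_config

cfg = RunConfig(
    out_dir="out",
    simulate=default_ppi_config(n_reports=20_000, seed=42),
    case_series=(("pantoprazole", "Hepatic encephalopathy"),),
)
artifacts = run_pipeline(cfg)
```

`out/signals_all.tsv` then holds the pooled all-PPI signal table:

```
                     pt  a       ror   ci_low  ci_high      p_value signal_class
            Cholestasis 36 11.061000 7.096090 17.24120 2.357250e-40       strong
           Coma hepatic  2  2.643240 0.578585 12.07560 1.922490e-01         none
 Hepatic encephalopathy  1  0.439754 0.059924  3.22714 4.060980e-01         none
        Hepatitis acute  3  1.321140 0.402692  4.33435 6.448540e-01         none
  Hepatitis cholestatic  9  6.638310 2.976800 14.80360 9.079390e-08       strong
    Hepatitis fulminant  3  6.614230 1.652410 26.47530 2.041600e-03       strong
   Jaundice cholestatic  0  0.573583 0.033781  9.73902 3.612610e-01         none
           Liver injury  7  1.341290 0.615239  2.92415 4.586460e-01         none
Transaminases increased 10  1.212940 0.633278  2.32318 5.598230e-01         none
```

Cholestasis — injected with strong effects for two drugs — comes out a
strong signal (36 exposed cases, ROR 11.1, CI 7.1–17.2), while terms
with no injected effect stay non-signals: with only 2 exposed coma-
hepatic cases the table is below the 3-case floor, and "Jaundice
cholestatic" (a zero cell, hence the corrected ROR) shows how sparse
rows are kept but flagged rather than dropped. The run log records what
dedup did before any statistic was computed:

```
assemble: reports=21277
dedup: version_removed=981
dedup: linkage_removed=296
dedup: reports_remaining=20000
```

and `out/coowned_strong_signals.tsv` shows Cholestasis strong for both
drugs it was injected for, with per-drug RORs bracketing their targets
(esomeprazole 18.3 vs injected 21.6; pantoprazole 22.8 vs 15 pooled
with its cholestatic co-effects):

```
  drug_scope          pt  a     ror  ci_low  ci_high
ESOMEPRAZOLE Cholestasis 16 18.3321 10.4616  32.1237
PANTOPRAZOLE Cholestasis 23 22.7605 13.8648  37.3635
```

The same pipeline runs from the shell:

```
pvsignal simulate --n-reports 20000 --seed 42 --out raw/
pvsignal signals --input raw/ --out signals.tsv
pvsignal run-all --config run.yaml --out out/ --seed 42
```

Real quarterly ASCII files (DEMO/DRUG/REAC/INDI, `$`-delimited) drop in
via `input: {kind: quarter, path: ...}` in the YAML run configuration.

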