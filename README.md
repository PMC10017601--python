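# fcdscore

Ordinal imaging scoring of facial-canal wall integrity and a full
diagnostic-accuracy evaluation pipeline around it.

Each of the two walls (lateral, inferior) of the tympanic facial canal is
assigned an ordinal appearance score 0–3 (0 = no evident bony covering,
1 = discontinuous covering with linear deficiency, 2 = discontinuous
covering with dotted deficiency, 3 = continuous bony covering) by each of
two observers, with discrepancies resolved by consensus. The composite
score (0–6) is the sum of the two wall scores; ears scoring strictly below
a cutoff (optimally < 4) are classified as dehiscent against the surgical
gold standard.

The package provides:

- **`fcdscore.scoring`** — wall/composite score types, the strict-cutoff
  classification rule, the dehiscent (L, I) combination enumeration,
  consensus merging, and the ratings/gold-standard CSV schemas.
- **`fcdscore.agreement`** — two-observer cross-tabulation, unweighted
  Cohen's kappa with the Fleiss–Cohen–Everitt asymptotic CI, and
  strength-of-agreement bands.
- **`fcdscore.diagnostics`** — confusion tables per cutoff, sensitivity/
  specificity/Youden tables, ROC points, AUC (trapezoid and tie-corrected
  rank forms, cross-asserted), Youden-optimal cutoff selection, and
  predictive values under both positive-class orientations.
- **`fcdscore.exact_tests`** — the Freeman–Halton exact test for r×c
  tables via margin-constrained enumeration in log space, Pearson
  chi-square, and the observed-small-cell selection rule.
- **`fcdscore.fixtures`** — the published aggregate tables shipped as
  checksummed plain-text CSVs, reconstruction of the per-group
  composite-score distributions from the per-cutoff rate table, and a
  consistency report against the published summary statistics.
- **`fcdscore.simulate`** — synthetic cohorts (Bernoulli dehiscence
  status, truth-conditional wall-score draws, adjacency-weighted observer
  confusion, optional imperfect surgical probe) with closed-form kappa /
  AUC / sensitivity-specificity oracles for parameter-recovery testing.

## Command line

```sh
fcdscore simulate --n-ears 120 --seed 5 --out cohort   # cohort_ratings.csv + cohort_gold.csv
fcdscore agree cohort_ratings.csv                       # kappa per wall with CI and band
fcdscore score cohort_ratings.csv --gold cohort_gold.csv --cutoff 4 --out scored/
fcdscore report cohort_ratings.csv cohort_gold.csv --out report/
fcdscore exact counts.csv                               # headerless r×c counts
fcdscore reconstruct --out recon/                       # per-group score distributions
fcdscore reproduce                                      # fixture consistency checks
```

`fcdscore reproduce` recomputes kappa, the distribution reconstruction,
the cutoff-4 confusion table, AUC, and the rate-table round trip from the
packaged fixtures and prints a pass/fail line per check
(`--format json` for machine-readable output; `--orientation` forces the
rate-column orientation to demonstrate the infeasible alternative).

## Data formats

Ratings CSV (long format, one row per ear × observer):

```
ear_id,laterality,observer,lateral_score,inferior_score
e1,left,1,1,0
e1,left,2,1,0
e1,left,consensus,1,0
```

`observer` is `1`, `2` or `consensus`; the consensus row may be omitted
when the observers agree. Gold-standard CSV: `ear_id,surgical_finding`
with `surgical_finding` in `{dehiscent, intact, unknown}`; ears with
`unknown` findings are excluded (with a logged count) from any metric
needing the gold standard.
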