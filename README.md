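# pairedconcord

Concordance and agreement analysis for **paired bone-marrow (BM) /
peripheral-blood (PB) targeted-NGS variant calls**, plus a synthetic cohort
generator so the whole analysis can be exercised without patient data.

## The problem

In myeloid neoplasms (AML, MDS, MDS/MPN overlap, MPN), molecular
classification and monitoring rely on targeted NGS panels, and guidelines
ask for bone-marrow aspirates — an invasive draw that is frequently skipped
during follow-up. If variant calls from a blood draw agree closely enough
with the marrow, blood can serve as the monitoring sample. Quantifying that
agreement on paired samples is the job of this package:

- **Variant matching.** Per patient, BM and PB samples are paired by
  closest draw date; reportable variants (VAF ≥ 1%, population allele
  frequency ≤ 1%, non-benign) are matched across the pair on exact
  normalized `(chrom, pos, ref, alt)` keys (ordered gene pairs for fusions,
  gene+class for FLT3-ITD presence/absence calls).
- **Concordance metrics.** With BM as the reference standard, the 2×2 table
  counts mutations found in both tissues (TP), BM only (FN), PB only (FP),
  and *presumed concordant negative calls*: each mutation-negative pair
  contributes one agreed negative call per DNA gene of the panel
  (TN = negative pairs × 40). From it: concordance (TP+TN)/N, sensitivity
  TP/(TP+FN), specificity TN/(FP+TN), PPV TP/(TP+FP), NPV TN/(FN+TN), each
  carried as an exact fraction and printed half-up at one decimal.
- **VAF agreement.** Over mutations detected in both tissues: Spearman rank
  correlation (mid-rank ties; Kendall's τ-b as sensitivity analysis), OLS
  regression against the bisecting line, and Bland–Altman analysis of
  d = BM_VAF − PB_VAF with limits of agreement at d̄ ± 2σ̄, with subgroup
  strata (no circulating blasts, neutropenia ANC < 1 G/L, same-day pairs,
  VAF ≥ 5%).
- **Cohort reports.** Per-gene occurrence (once per sample per gene,
  excluding negative and fusion-only pairs), mutation-count summaries, and
  a per-mutation discordance listing joined to clinical covariates.

## Worked example

Simulate a default cohort (187 patients, ~240 pairs) and run the full
pipeline:

```bash
pairedconcord simulate --n-patients 187 --seed 1 --out cohort/
pairedconcord run --bm cohort/bm.tsv --pb cohort/pb.tsv \
    --meta cohort/metadata.csv --out results/
pairedconcord report --bundle results/report.json
```

With seed 1 this prints (abridged):

```
2x2 table: TP=566 FN=8 FP=2 TN=2440 (61 negative pairs x 40 genes)
  concordance: 99.7% (3006/3016)
  sensitivity: 98.6% (566/574)
  specificity: 99.9% (2440/2442)
  ppv: 99.6% (566/568)
  npv: 99.7% (2440/2448)
Spearman r=0.962 (very_strong, n=552)
Bland-Altman: d=3.62 sd=7.77 outliers=34/552
```

Reading: of 3016 evaluated calls (574 BM-positive mutations plus 61
mutation-negative pairs × 40 panel genes), 99.7% agree between tissues;
the BM and PB VAFs of the 552 double-detected, VAF-bearing mutations are
very strongly rank-correlated, and BM reads on average 3.6 VAF points
higher than PB with 2σ̄ limits spanning roughly −12 to +19 points. The
handful of discordant mutations sit at low VAF, where binomial sampling
noise around the 1% detection threshold dominates.

The same analysis is available as a library:

```python
from pairedconcord import (SimulationParams, simulate_cohort,
                           RunConfig, run_pipeline)

cohort = simulate_cohort(SimulationParams(n_patients=187, seed=1))
bundle = run_pipeline(RunConfig(seed=1), cohort.bm_calls,
                      cohort.pb_calls, cohort.metadata)
print(bundle["metrics"]["concordance"])   # exact fraction + rounded pct
```

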