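# Methods

This note documents the statistical conventions of the concordance
analysis, the generative model of the synthetic cohort, and the design
choices made where more than one defensible convention exists. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The concordance model

The unit of analysis is the *reported result*. A detected mutation that
appears in both tissues of a pair is one concordant positive result; a
mutation detected in exactly one tissue is one discordant result. A sample
pair in which no reportable mutation was found in either tissue is treated
as a block of **presumed concordant negative calls**: one agreed negative
per DNA gene of the panel (40 by default). The 2×2 table therefore mixes
granularities on purpose — positives are counted per mutation, negatives
per (pair × gene) — because that is how clinical concordance tables for
panel assays are constructed. `build_confusion_table(...,
gene_level_positives=True)` offers the homogeneous gene-level alternative;
it is not the default.

BM is the reference standard. Sensitivity = TP/(TP+FN) and NPV =
TN/(FN+TN) condition on the BM result; PPV = TP/(TP+FP) conditions on PB.
Any metric with a zero denominator is reported as `null`, never as 0 or
100. Every percentage retains its exact integer fraction and is displayed
rounded **half-up** to one decimal (Python's banker's rounding would
disagree with clinical tables on ties such as 99.65).

Pair categories: *negative* (no mutation either side), *complete
concordance* (≥1 mutation, none discordant), *partial concordance* (both
concordant and discordant mutations), *fully discordant* (only discordant
mutations). The headline "pairs without discordance" figure is complete +
negative.

## Reportability and matching

Filters (defaults): VAF ≥ 1% (the assay's analytic sensitivity),
population allele frequency ≤ 1% (SNP exclusion), benign/likely-benign
annotations excluded. Fusion and FLT3-ITD calls carry no VAF and are never
VAF-filtered. Germline-candidate flagging uses VAF windows 45–55% and
95–100% with **inclusive** bounds ("between 45 and 55" is read as closed);
flagged calls are only annotated, never removed.

Matching is exact. DNA-class variants are first reduced to a minimal
representation (longest common allele suffix, then prefix, trimmed with
the position shifted) so equivalent indel spellings collide; there is no
position window and no VAF tolerance. Fusions match on the ordered 5'/3'
partner pair; FLT3-ITD — a fragment-analysis presence/absence assay — on
gene + class alone. Duplicate keys within one sample are consolidated to
the highest-VAF call with a logged warning. Matching by genomic key rather
than by HGVS string is a design choice; gene-level matching would conflate
distinct co-occurring mutations in the same gene (common in TET2/ASXL1).

Sample pairing uses greedy nearest-draw-date assignment within a patient,
each sample used at most once. On the 2×2 cases that arise in practice the
greedy assignment coincides with the global minimum-total-gap assignment
(property-checked against brute force).

## Agreement statistics

* **Spearman** with mid-rank ties; p-value from the t-approximation with
  n−2 df. An exact-permutation p (`p_method="exact"`) enumerates all n!
  pairings and is intended for n ≤ 10.
* **Kendall's τ-b** (tie-corrected) as the sensitivity analysis; on any
  dataset it agrees with Spearman in sign.
* **Correlation-strength bands** on |r|, made contiguous and half-open:
  [0, 0.10) negligible, [0.10, 0.40) weak, [0.40, 0.70) moderate,
  [0.70, 0.90) strong, [0.90, 1] very strong. Published verbal scales
  often leave gaps (e.g. 0.89–0.90); the half-open convention closes them
  and puts 0.90 in "very strong".
* **Bland–Altman** on d = BM_VAF − PB_VAF: limits of agreement at
  d̄ ± **2**·σ̄ (exactly 2, not 1.96), σ̄ the *sample* SD (n−1). Outliers
  are points strictly outside the limits. For Gaussian differences the
  expected outlier mass is 2·(1−Φ(2)) ≈ 4.55%, which the tests verify on
  direct Gaussian draws.
* Only both-tissue mutations of VAF-bearing classes enter the agreement
  stage; fusions and FLT3-ITD are excluded by construction.
* **Strata**: `pb_blasts_zero`, `pb_blasts_ge1`, `anc_lt1`, `anc_ge1`,
  `same_day_only`, `min_vaf_5`. The `min_vaf_5` rule removes a VAF pair
  when *either* tissue's VAF is below 5% — a per-call rule would leave the
  pair set ill-defined. Missing covariates exclude a pair from a stratum.
* Mixed-effects modelling of repeated measures per patient is out of
  scope; serial pairs enter all statistics as independent observations,
  which mildly understates p-values but leaves point estimates unbiased.

## The synthetic cohort generator

The generator's defaults are the emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 187 | ~240 pairs once serial sampling is added |
| `serial_patient_fraction` | 30/187 | serial patients draw 2–5 pairs (weights 0.55/0.25/0.12/0.08) |
| `days_apart_probs` | 90% same-day | remainder spread out to 118 days |
| `frac_negative_pairs` | 46/240 | per-**patient** probability of carrying no clone |
| `mean_mutations_per_sample` | 2.8 | overall mean; positive patients draw from a zero-truncated Poisson capped at 10 |
| `vaf_mixture` | N(46, 15) w.p. 0.489 + Exp(6.5), truncated to (0.1, 99.7) | true BM VAF, percent; moments ≈ (25.8, 22.9) |
| `diff_mean`, `diff_sd` | 2.92, 7.71 | target mean/SD of BM−PB VAF differences |
| `depth_median`, `depth_sigma`, `depth_floor` | 6116, 0.73, 500 | floored log-normal read depth (IQR ≈ 3700–10000) |
| `detection_min_vaf` | 1.0 | emission threshold on the observed VAF |
| `fusion_rate`, `flt3_itd_rate` | 11/187, 2/187 | per-patient; emitted presence/absence with probability `fusion_detect_prob`=1 |
| `diagnosis_mix` | 46/43/15/33/50 of 187 | AML / MDS / MDS-MPN / MPN / other |
| `blast_vaf_coupling` | 0.5 | weak positive coupling of blast percentages to tumor burden |

The clonal/sub-clonal mixture parameters were moment-matched analytically:
with weight w on N(µc, σc) and mean µs for the exponential component,
E[V] = w·µc + (1−w)·µs and E[V²] = w(σc²+µc²) + (1−w)·2µs², giving
(25.8, 22.85) for the chosen values before truncation.

**BM→PB perturbation.** The PB VAF is `pb = bm·(1 − G)` with
G ~ N(g_mean, g_sd) i.i.d. per clone, and (g_mean, g_sd) solved at run time
from the drawn BM VAFs so that mean(bm−pb) = `diff_mean` and
SD(bm−pb) = `diff_sd` exactly in expectation (E[vG] = g_mean·E[v];
Var(vG) = E[v²]·g_sd² + Var(v)·g_mean²). A *level-independent additive*
difference of SD 7.7 points was rejected: it would push a sizeable share
of clones in the 5–15% VAF range below the 1% detection threshold in one
tissue, producing discordance rates orders of magnitude above what paired
myeloid cohorts show, and the censoring would bias the recovered
Bland–Altman mean far from the generator's parameter. Under the
proportional model, between-tissue noise shrinks with clone size,
discordance arises only near the threshold (discordant VAFs cluster below
~4%), and the downstream pipeline recovers `diff_mean` within ±0.5 and
`diff_sd` within ±1.0 at 500 patients (asserted in the acceptance tests).

**Observation model.** Per pair, tissue and clone: depth from the floored
log-normal, alt reads Binomial(depth, vaf/100), observed
VAF = 100·alt/depth, emitted iff ≥ `detection_min_vaf`. `read_noise=False`
with threshold 0 gives the noise-free limit in which concordance,
sensitivity and specificity are exactly 100% and (with the perturbation
disabled) Spearman r = 1 and OLS slope = 1.

**Covariates.** ANC ~ LogNormal(ln 2.3, 1.33) G/L (≈27% below 1.0), WBC ~
LogNormal(ln 4.2, 1.0). Blast percentages use diagnosis-dependent
exponential bases plus a weak additive term in the patient's largest clone
(`blast_vaf_coupling`), and the probability of *any* circulating blasts
rises mildly with burden — calibrated so the emulated VAF-vs-blast
Spearman r is weakly positive (~0.1), as in real cohorts, while both
blast strata and both ANC strata stay well populated.

What the generator does **not** emulate: read-level errors beyond binomial
sampling, clonal phylogenies or VAF dynamics across serial draws (a
clone's true VAF is constant per patient), germline contamination,
sample-swap artifacts, and gene-specific VAF distributions. Passing tests
therefore validate the *analysis machinery* and its self-consistency, not
the biological fidelity of any particular cohort.

### Known deviations of emulated summaries

Because detection censors sub-threshold clones, the *observed* negative-
pair fraction runs a few points above the latent 46/240 (a positive patient
whose only clones sit below 1% looks negative), and the observed mean
mutations per BM sample lands near 2.5–2.7 rather than 2.8. The
negative-fraction check in the tests is therefore performed at the latent
(per-patient Bernoulli) level, where the binomial interval applies; the
pair-level fraction additionally carries a serial-sampling design effect.

The discordant-mutation count is *not* monotone in the detection threshold
everywhere: below ~1% a raised threshold can delete a borderline call from
*both* tissues and remove a discordance. Above the 1% operating point the
expected behaviour — more borderline clones lost in exactly one tissue —
dominates, and the tests assert monotonicity on thresholds 1–5%.

## Numerical and edge-case conventions

* Half-up rounding for all printed percentages (1 decimal; 2 for the
  discordant-mutation share).
* Sample SD (n−1) throughout (Bland–Altman σ̄, mutation-count SD,
  discordant-VAF SD).
* Constant input vectors make correlation coefficients undefined (`None` +
  warning), as does n < 2; Bland–Altman requires n ≥ 2 and raises below.
* The discordance report's low-VAF tally uses a ≤ threshold (default 5%,
  the usual clinical-relevance cut); the descriptive statistics of
  BM-exclusive VAFs are always computed from the records themselves rather
  than taken from any printed range.
* JSON report bundles are written with sorted keys and `repr` floats, so
  identical inputs give byte-identical files.
* Seeds: all randomness flows through `numpy.random.SeedSequence(seed)`;
  the observation stage uses the child sequence `(seed, 1)` so truth and
  observation draws are independent but jointly reproducible.

## Test problem sizes

Unit and property tests run on toy inputs (≤ 10 elements, ≤ 240-pair
constructed cohorts). Simulation-backed checks use 60–800 patients: 500
for agreement parameter recovery, 400 for the mutation-count moment check,
187 (the default) for the end-to-end pipeline and threshold-monotonicity
checks. The full suite and the acceptance script each run in well under a
minute on one CPU.
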