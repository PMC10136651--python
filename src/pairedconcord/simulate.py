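"""Synthetic paired BM/PB cohort generator.

Emulates a prospective myeloid-NGS concordance cohort: ~187 patients
contributing ~240 bone-marrow/peripheral-blood sample pairs (a minority of
patients sampled serially), a mix of AML / MDS / MDS-MPN / MPN / non-myeloid
diagnoses, 0-10 reportable mutations per sample (cohort mean ~2.8), VAFs
with mean ~25.8% and SD ~22.9%, amplicon read depths with median ~6100
(floor 500), a 1% VAF detection threshold, and occasional fusion and
FLT3-ITD calls that carry no VAF.

Generative model
----------------
Each positive patient carries latent clones.  A clone has a true BM VAF
drawn from a clonal/sub-clonal mixture and a true PB VAF obtained by a
*proportional* perturbation::

    pb = bm * (1 - G),   G ~ Normal(g_mean, g_sd)   (iid per clone)

with ``g_mean``/``g_sd`` calibrated at run time from the drawn BM VAFs so
that the mean and SD of (bm - pb) over clones equal ``diff_mean`` and
``diff_sd``.  A proportional model is used rather than an additive shift
because with a level-independent additive difference of SD ~7.7 percentage
points, a large share of low-VAF clones would fall below the 1% detection
threshold in one tissue, which contradicts the near-total concordance such
cohorts actually show; under the proportional model between-tissue noise
shrinks with clone size and discordance arises only near the detection
threshold, as observed.

Observation: per sample pair, tissue and clone, a read depth is drawn from
a floored log-normal, the alt-read count is Binomial(depth, vaf/100), and a
call is emitted iff the observed VAF reaches the detection threshold.
Fusion / FLT3-ITD clones are emitted by a presence probability independent
of any VAF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
from scipy import optimize

from .datamodel import (
    AMPLISEQ_MYELOID,
    Annotation,
    Diagnosis,
    PanelDefinition,
    SamplePair,
    SampleRecord,
    Tissue,
    ValidationError,
    VarClass,
    VariantCall,
)

_BASES = "ACGT"

#: Per-gene occurrence weights (leading genes anchored to typical myeloid
#: cohort frequencies: TET2 0.254, ASXL1 0.246, DNMT3A 0.213, ...).  Used as
#: relative sampling weights when assigning mutated genes to a patient.
DEFAULT_GENE_WEIGHTS: dict[str, float] = {
    "TET2": 0.254, "ASXL1": 0.246, "DNMT3A": 0.213, "SRSF2": 0.125,
    "RUNX1": 0.113, "TP53": 0.100, "NRAS": 0.070, "JAK2": 0.060,
    "IDH2": 0.055, "NPM1": 0.050, "SF3B1": 0.050, "CBL": 0.040,
    "EZH2": 0.035, "U2AF1": 0.035, "IDH1": 0.030, "CALR": 0.030,
    "KRAS": 0.025, "PHF6": 0.025, "BCOR": 0.025, "STAG2": 0.025,
    "SETBP1": 0.020, "GATA2": 0.020, "MYD88": 0.017, "ETV6": 0.017,
    "CEBPA": 0.017, "PTPN11": 0.013, "IKZF1": 0.013, "HRAS": 0.013,
    "BRAF": 0.008, "WT1": 0.008, "KIT": 0.008, "RB1": 0.004,
    "FLT3": 0.010, "MPL": 0.008, "SH2B3": 0.006, "ZRSR2": 0.006,
    "NF1": 0.006, "PRPF8": 0.004, "ABL1": 0.0, "CSF3R": 0.0,
}

DEFAULT_DIAGNOSIS_MIX: dict[Diagnosis, float] = {
    Diagnosis.AML: 46 / 187,
    Diagnosis.MDS: 43 / 187,
    Diagnosis.MDS_MPN: 15 / 187,
    Diagnosis.MPN: 33 / 187,
    Diagnosis.OTHER: 50 / 187,
}

#: Probability that a sample pair shows a non-zero PB blast percentage,
#: by diagnosis (non-myeloid patients essentially never circulate blasts).
_P_PB_BLASTS = {
    Diagnosis.AML: 0.65, Diagnosis.MDS: 0.25, Diagnosis.MDS_MPN: 0.30,
    Diagnosis.MPN: 0.20, Diagnosis.OTHER: 0.05,
}

_VAR_CLASS_MIX = (
    (VarClass.SNV, 0.700),
    (VarClass.INSERTION, 0.143),
    (VarClass.DELETION, 0.147),
    (VarClass.MNP, 0.010),
)


@dataclass(frozen=True)
class VafMixture:
    """Clonal + sub-clonal mixture for true BM VAFs (percent scale).

    A Normal clonal component and an Exponential sub-clonal component,
    truncated to ``(low, high)`` by resampling.  The defaults were
    moment-matched to give mean ~25.8 and SD ~22.9 percent.
    """

    clonal_mean: float = 46.0
    clonal_sd: float = 15.0
    subclonal_mean: float = 6.5
    clonal_weight: float = 0.489
    low: float = 0.1
    high: float = 99.7

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        out = np.empty(size)
        todo = np.arange(size)
        while todo.size:
            clonal = rng.random(todo.size) < self.clonal_weight
            draw = np.where(
                clonal,
                rng.normal(self.clonal_mean, self.clonal_sd, todo.size),
                rng.exponential(self.subclonal_mean, todo.size),
            )
            out[todo] = draw
            todo = todo[(draw <= self.low) | (draw >= self.high)]
        return out


@dataclass(frozen=True)
class TrueClone:
    """A latent mutated clone of one patient (the truth behind observed calls)."""

    patient_id: str
    gene: str
    locus: tuple  # (chrom, pos, ref, alt)
    true_bm_vaf: float
    true_pb_vaf: float
    var_class: VarClass

    def __post_init__(self) -> None:
        for v in (self.true_bm_vaf, self.true_pb_vaf):
            if not 0.0 < v <= 100.0:
                raise ValidationError(f"true VAF {v} outside (0, 100]")


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the cohort generator; defaults are the emulated study
    conditions (see the methods note for provenance of each value)."""

    n_patients: int = 187
    seed: int = 0
    frac_negative_pairs: float = 46 / 240
    diagnosis_mix: dict = field(default_factory=lambda: dict(DEFAULT_DIAGNOSIS_MIX))
    mean_mutations_per_sample: float = 2.8
    max_mutations: int = 10
    gene_weights: dict = field(default_factory=lambda: dict(DEFAULT_GENE_WEIGHTS))
    vaf_mixture: VafMixture = field(default_factory=VafMixture)
    diff_mean: float = 2.92
    diff_sd: float = 7.71
    depth_median: float = 6116.0
    depth_sigma: float = 0.73
    depth_floor: int = 500
    detection_min_vaf: float = 1.0
    read_noise: bool = True
    fusion_rate: float = 11 / 187
    flt3_itd_rate: float = 2 / 187
    fusion_detect_prob: float = 1.0
    serial_patient_fraction: float = 30 / 187
    serial_pairs_weights: dict = field(
        default_factory=lambda: {2: 0.55, 3: 0.25, 4: 0.12, 5: 0.08}
    )
    days_apart_probs: dict = field(
        default_factory=lambda: {
            (0, 0): 0.900, (7, 7): 0.021, (8, 28): 0.042,
            (29, 56): 0.033, (57, 118): 0.004,
        }
    )
    blast_vaf_coupling: float = 0.5
    panel: PanelDefinition = field(default_factory=lambda: AMPLISEQ_MYELOID)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        if not 0.0 <= self.frac_negative_pairs <= 1.0:
            raise ValidationError("frac_negative_pairs outside [0, 1]")
        for label, probs in (
            ("diagnosis_mix", self.diagnosis_mix.values()),
            ("serial_pairs_weights", self.serial_pairs_weights.values()),
            ("days_apart_probs", self.days_apart_probs.values()),
        ):
            total = sum(probs)
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValidationError(f"{label} probabilities sum to {total}, not 1")
        if self.depth_floor < 1:
            raise ValidationError("depth_floor must be >= 1")
        for label, v in (
            ("diff_sd", self.diff_sd), ("depth_median", self.depth_median),
            ("depth_sigma", self.depth_sigma),
        ):
            if v < 0:
                raise ValidationError(f"{label} must be non-negative")


def _truncated_poisson_lambda(target_mean: float, cap: int) -> float:
    """Rate of a zero-truncated Poisson whose mean equals ``target_mean``."""
    if target_mean <= 1.0:
        return 1e-6

    def f(lam: float) -> float:
        return lam / (1.0 - math.exp(-lam)) - target_mean

    return optimize.brentq(f, 1e-9, max(10.0 * target_mean, 50.0))


def _draw_days_apart(rng: np.random.Generator, probs: dict) -> int:
    ranges = list(probs.keys())
    idx = rng.choice(len(ranges), p=np.array([probs[r] for r in ranges]))
    lo, hi = ranges[idx]
    return int(lo) if lo == hi else int(rng.integers(lo, hi + 1))


def _random_alleles(rng: np.random.Generator, var_class: VarClass) -> tuple[str, str]:
    def bases(k: int) -> str:
        return "".join(_BASES[i] for i in rng.integers(0, 4, k))

    if var_class is VarClass.SNV:
        ref = bases(1)
        alt = _BASES[(int(rng.integers(1, 4)) + _BASES.index(ref)) % 4]
        return ref, alt
    if var_class is VarClass.MNP:
        k = int(rng.integers(2, 4))
        ref = bases(k)
        alt = bases(k)
        while alt == ref:
            alt = bases(k)
        return ref, alt
    if var_class is VarClass.INSERTION:
        anchor = bases(1)
        return anchor, anchor + bases(int(rng.integers(1, 7)))
    anchor = bases(1)
    return anchor + bases(int(rng.integers(1, 7))), anchor  # deletion


@dataclass(frozen=True)
class SimulatedCohort:
    pairs: list[SamplePair]
    clones: list[TrueClone]
    bm_calls: list[VariantCall]
    pb_calls: list[VariantCall]

    @property
    def metadata(self) -> list[SampleRecord]:
        records = []
        for p in self.pairs:
            records.append(p.bm)
            records.append(p.pb)
        return records


def simulate_truth(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[list[SamplePair], list[TrueClone]]:
    """Draw the latent cohort: sample pairs with covariates, and true clones.

    Deterministic given ``params.seed``.  Negative status is imposed per
    patient first; positive patients then draw their mutation count from a
    zero-truncated Poisson capped at ``max_mutations`` whose rate is set so
    the overall per-sample mean matches ``mean_mutations_per_sample``.
    """
    params.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence(params.seed))
    if params.n_patients == 0:
        return [], []

    diagnoses = list(params.diagnosis_mix.keys())
    diag_p = np.array([params.diagnosis_mix[d] for d in diagnoses], dtype=float)
    diag_p = diag_p / diag_p.sum()

    genes = [g for g, w in params.gene_weights.items() if w > 0]
    gene_p = np.array([params.gene_weights[g] for g in genes], dtype=float)
    gene_p = gene_p / gene_p.sum()
    chrom_of = {g: f"chr{(i % 22) + 1}" for i, g in enumerate(params.panel.dna_genes)}

    pos_frac = 1.0 - params.frac_negative_pairs
    target_pos_mean = (
        params.mean_mutations_per_sample / pos_frac if pos_frac > 0 else 0.0
    )
    lam = _truncated_poisson_lambda(target_pos_mean, params.max_mutations)

    n_serial = int(round(params.serial_patient_fraction * params.n_patients))
    serial_ids = set(
        rng.choice(params.n_patients, size=min(n_serial, params.n_patients), replace=False).tolist()
    )
    serial_counts = list(params.serial_pairs_weights.keys())
    serial_p = np.array([params.serial_pairs_weights[k] for k in serial_counts], dtype=float)
    serial_p = serial_p / serial_p.sum()

    # --- latent clones -----------------------------------------------------
    patient_meta = []
    all_bm_vafs: list[float] = []
    clone_specs: list[list[dict]] = []
    for i in range(params.n_patients):
        pid = f"P{i:04d}"
        dx = diagnoses[int(rng.choice(len(diagnoses), p=diag_p))]
        negative = rng.random() < params.frac_negative_pairs
        specs: list[dict] = []
        if not negative and target_pos_mean > 0:
            k = 0
            while k < 1 or k > params.max_mutations:
                k = int(rng.poisson(lam))
            chosen = rng.choice(len(genes), size=min(k, len(genes)), replace=False, p=gene_p)
            for gi in chosen:
                gene = genes[int(gi)]
                var_class = _VAR_CLASS_MIX[
                    int(rng.choice(len(_VAR_CLASS_MIX), p=np.array([w for _, w in _VAR_CLASS_MIX])))
                ][0]
                v = float(params.vaf_mixture.sample(rng, 1)[0])
                all_bm_vafs.append(v)
                ref, alt = _random_alleles(rng, var_class)
                specs.append({
                    "gene": gene,
                    "locus": (chrom_of.get(gene, "chr1"), int(rng.integers(1_000_000, 100_000_000)), ref, alt),
                    "bm_vaf": v,
                    "var_class": var_class,
                })
            if rng.random() < params.fusion_rate:
                partners = rng.choice(len(params.panel.fusion_drivers), size=2, replace=False)
                g5, g3 = (params.panel.fusion_drivers[int(j)] for j in partners)
                specs.append({
                    "gene": f"{g5}::{g3}",
                    "locus": (chrom_of.get(g5, "chr1"), 1, "", ""),
                    "bm_vaf": 50.0, "var_class": VarClass.FUSION,
                })
            if rng.random() < params.flt3_itd_rate:
                specs.append({
                    "gene": "FLT3",
                    "locus": (chrom_of.get("FLT3", "chr13"), 28_608_000, "", ""),
                    "bm_vaf": 50.0, "var_class": VarClass.FLT3_ITD,
                })
        patient_meta.append((pid, dx, negative))
        clone_specs.append(specs)

    # Calibrate the proportional BM->PB perturbation so that bm - pb has the
    # requested mean and SD over the drawn clone population.
    if all_bm_vafs:
        v = np.array(all_bm_vafs)
        m1, m2 = float(np.mean(v)), float(np.mean(v * v))
        var_v = m2 - m1 * m1
        g_mean = params.diff_mean / m1 if m1 > 0 else 0.0
        g_var = max((params.diff_sd**2 - var_v * g_mean**2) / m2, 0.0) if m2 > 0 else 0.0
        g_sd = math.sqrt(g_var)
    else:
        g_mean = g_sd = 0.0

    clones: list[TrueClone] = []
    for (pid, dx, negative), specs in zip(patient_meta, clone_specs):
        for s in specs:
            if s["var_class"] in (VarClass.FUSION, VarClass.FLT3_ITD):
                pb_vaf = s["bm_vaf"]
            else:
                g = rng.normal(g_mean, g_sd)
                pb_vaf = float(np.clip(s["bm_vaf"] * (1.0 - g), 0.05, 99.8))
            clones.append(
                TrueClone(
                    patient_id=pid,
                    gene=s["gene"],
                    locus=s["locus"],
                    true_bm_vaf=s["bm_vaf"],
                    true_pb_vaf=pb_vaf,
                    var_class=s["var_class"],
                )
            )

    # --- sample pairs with covariates --------------------------------------
    max_vaf_of = {}
    for c in clones:
        if c.var_class in (VarClass.FUSION, VarClass.FLT3_ITD):
            continue
        max_vaf_of[c.patient_id] = max(max_vaf_of.get(c.patient_id, 0.0), c.true_bm_vaf)

    pairs: list[SamplePair] = []
    for i, (pid, dx, negative) in enumerate(patient_meta):
        n_pairs = 1
        if i in serial_ids:
            n_pairs = int(serial_counts[int(rng.choice(len(serial_counts), p=serial_p))])
        base = date(2020, 1, 1) + timedelta(days=int(rng.integers(0, 900)))
        maxvaf = max_vaf_of.get(pid, 0.0)
        for k in range(n_pairs):
            bm_date = base + timedelta(days=int(rng.integers(30, 121)) * k)
            gap = _draw_days_apart(rng, params.days_apart_probs)
            pb_date = bm_date + timedelta(days=gap)
            # circulating-blast presence and magnitude both rise weakly with
            # tumor burden, so the emulated VAF-vs-blast correlation is weak
            # but positive in both tissues
            p_pos = min(_P_PB_BLASTS[dx] + 0.003 * maxvaf, 0.95)
            if rng.random() < p_pos:
                scale = 15.0 if dx is Diagnosis.AML else 2.0
                pb_blasts = float(np.clip(
                    rng.exponential(scale) + params.blast_vaf_coupling * maxvaf * rng.random(),
                    1.0, 99.0,
                ))
                pb_blasts = round(pb_blasts, 1)
            else:
                pb_blasts = 0.0
            bm_base = {Diagnosis.AML: 25.0, Diagnosis.MDS: 5.0, Diagnosis.MDS_MPN: 6.0,
                       Diagnosis.MPN: 3.0, Diagnosis.OTHER: 2.0}[dx]
            bm_blasts = round(float(np.clip(
                rng.exponential(bm_base) + params.blast_vaf_coupling * maxvaf * rng.random(),
                0.0, 95.0,
            )), 1)
            anc = round(float(rng.lognormal(math.log(2.3), 1.33)), 2)
            wbc = round(float(rng.lognormal(math.log(4.2), 1.0)), 2)
            common = dict(patient_id=pid, diagnosis=dx, pb_blast_pct=pb_blasts,
                          bm_blast_pct=bm_blasts, anc=anc, wbc=wbc)
            bm_rec = SampleRecord(sample_id=f"{pid}-BM{k}", tissue=Tissue.BM,
                                  draw_date=bm_date, **common)
            pb_rec = SampleRecord(sample_id=f"{pid}-PB{k}", tissue=Tissue.PB,
                                  draw_date=pb_date, **common)
            pairs.append(SamplePair(
                pair_id=f"{pid}-BM{k}|{pid}-PB{k}", patient_id=pid,
                bm=bm_rec, pb=pb_rec, days_apart=gap,
            ))
    return pairs, clones


def sample_observed_calls(
    clones: list[TrueClone],
    pairs: list[SamplePair],
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Generate the observed BM and PB variant tables from the latent truth.

    For each clone, pair and tissue: draw a read depth from the floored
    log-normal, an alt-read count from Binomial(depth, vaf/100), and emit a
    call iff the observed VAF reaches ``detection_min_vaf``.  With
    ``read_noise=False`` the observed VAF equals the true VAF (depths are
    still drawn, so tables keep their shape).  Fusion and FLT3-ITD clones
    are emitted with probability ``fusion_detect_prob`` per tissue and carry
    neither VAF nor depth.  Default RNG stream is seeded from
    ``(params.seed, 1)`` so truth and observation draws are independent.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence((params.seed, 1)))
    by_patient: dict[str, list[TrueClone]] = {}
    for c in clones:
        by_patient.setdefault(c.patient_id, []).append(c)

    mu = math.log(params.depth_median)
    bm_calls: list[VariantCall] = []
    pb_calls: list[VariantCall] = []

    def draw_depth() -> int:
        return max(params.depth_floor, int(round(rng.lognormal(mu, params.depth_sigma))))

    for pair in pairs:
        for clone in by_patient.get(pair.patient_id, []):
            chrom, pos, ref, alt = clone.locus
            for tissue, sample, out in (
                (Tissue.BM, pair.bm, bm_calls),
                (Tissue.PB, pair.pb, pb_calls),
            ):
                if clone.var_class in (VarClass.FUSION, VarClass.FLT3_ITD):
                    if rng.random() < params.fusion_detect_prob:
                        out.append(VariantCall(
                            sample_id=sample.sample_id, gene=clone.gene,
                            chrom=chrom, pos=max(pos, 1), ref=ref, alt=alt,
                            var_class=clone.var_class,
                        ))
                    continue
                true_vaf = clone.true_bm_vaf if tissue is Tissue.BM else clone.true_pb_vaf
                depth = draw_depth()
                if params.read_noise:
                    alt_reads = int(rng.binomial(depth, true_vaf / 100.0))
                    obs = 100.0 * alt_reads / depth
                else:
                    obs = true_vaf
                if obs < params.detection_min_vaf or obs <= 0.0:
                    continue
                out.append(VariantCall(
                    sample_id=sample.sample_id, gene=clone.gene,
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    var_class=clone.var_class,
                    vaf=round(obs, 4), depth=depth,
                    db_entry=bool(rng.random() < 0.75),
                ))
    return bm_calls, pb_calls


def simulate_cohort(params: SimulationParams | None = None) -> SimulatedCohort:
    """Convenience wrapper: truth plus observed tables in one call."""
    params = params or SimulationParams()
    pairs, clones = simulate_truth(params)
    bm_calls, pb_calls = sample_observed_calls(clones, pairs, params)
    return SimulatedCohort(pairs=pairs, clones=clones, bm_calls=bm_calls, pb_calls=pb_calls)


def write_truth(clones: list[TrueClone], path) -> None:
    """Write the latent clones as CSV (for parameter-recovery checks)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "gene", "chrom", "pos", "ref", "alt",
                    "true_bm_vaf", "true_pb_vaf", "var_class"])
        for c in clones:
            chrom, pos, ref, alt = c.locus
            w.writerow([c.patient_id, c.gene, chrom, pos, ref, alt,
                        repr(c.true_bm_vaf), repr(c.true_pb_vaf), c.var_class.value])
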