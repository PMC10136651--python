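"""Confusion-table construction and concordance metrics with BM as reference.

The 2x2 table treats the bone-marrow result as the reference standard:

* TP = mutations detected in both tissues,
* FN = mutations detected in BM only,
* FP = mutations detected in PB only,
* TN = presumed concordant negative calls: for each sample pair in which no
  mutation was detected in either tissue, every DNA gene of the panel
  contributes one negative call agreed on by both tissues
  (TN = negative pairs x panel DNA genes).

Positive cells are counted at mutation level while TN is gene-level; this
asymmetry is the field's reporting convention and is kept as the default,
with a gene-level alternative for the positive cells behind a switch.
Every percentage carries its exact numerator/denominator and is rounded
half-up to one decimal for display.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .datamodel import (
    MatchStatus,
    MatchedVariant,
    PanelDefinition,
    SamplePair,
    VarClass,
    round_half_up,
)
from .match import PairCategory, PairClassification

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionTable:
    """Cell counts of the BM-reference 2x2 table, plus their provenance."""

    tp: int
    fn: int
    fp: int
    tn: int
    n_negative_pairs: int = 0
    panel_genes: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricValue:
    """A reported percentage with its exact fraction retained."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> float | None:
        return None if self.denominator == 0 else self.numerator / self.denominator

    @property
    def pct(self) -> float | None:
        """Percent, rounded half-up to 1 decimal; None when undefined."""
        f = self.fraction
        return None if f is None else round_half_up(100.0 * f, 1)

    def as_dict(self) -> dict:
        return {"numerator": self.numerator, "denominator": self.denominator, "pct": self.pct}


@dataclass(frozen=True)
class ConcordanceMetrics:
    concordance: MetricValue
    sensitivity: MetricValue
    specificity: MetricValue
    ppv: MetricValue
    npv: MetricValue

    def as_dict(self) -> dict:
        return {
            "concordance": self.concordance.as_dict(),
            "sensitivity": self.sensitivity.as_dict(),
            "specificity": self.specificity.as_dict(),
            "ppv": self.ppv.as_dict(),
            "npv": self.npv.as_dict(),
        }


# Functional pathway labels for the discordance report (as printed in
# clinical concordance tables); genes not listed get "other".
GENE_PATHWAYS = {
    "DNMT3A": "DNA methylation related", "TET2": "DNA methylation related",
    "IDH1": "DNA methylation related", "IDH2": "DNA methylation related",
    "ASXL1": "DNA methylation related", "EZH2": "Chromatin modification",
    "BCOR": "Chromatin modification", "STAG2": "Cohesin complex",
    "SRSF2": "Splicing factor", "SF3B1": "Splicing factor",
    "U2AF1": "Splicing factor", "ZRSR2": "Splicing factor",
    "NRAS": "RAS pathway", "KRAS": "RAS pathway", "HRAS": "RAS pathway",
    "CBL": "RAS pathway", "PTPN11": "RAS pathway", "NF1": "RAS pathway",
    "FLT3": "Signaling receptor", "KIT": "Signaling receptor",
    "MPL": "Signaling receptor", "CSF3R": "Signaling receptor",
    "JAK2": "JAK-STAT signaling", "CALR": "JAK-STAT signaling",
    "SH2B3": "JAK-STAT signaling",
    "RUNX1": "Transcription factor", "CEBPA": "Transcription factor",
    "ETV6": "Transcription factor", "GATA2": "Transcription factor",
    "IKZF1": "Transcription factor", "WT1": "Transcription factor",
    "TP53": "Tumor suppressor", "RB1": "Tumor suppressor",
    "PHF6": "Tumor suppressor", "NPM1": "Nucleolar multifunctional protein",
    "SETBP1": "DNA replication", "MYD88": "NF-kB signaling",
    "BRAF": "RAS pathway", "PRPF8": "Splicing factor", "ABL1": "Signaling kinase",
}


@dataclass(frozen=True)
class DiscordantRecord:
    """One mutation found in exactly one tissue, joined to pair covariates."""

    pair_id: str
    gene: str
    pathway: str
    tissue_found: str  # "BM" or "PB"
    vaf_found: float | None
    bm_blasts: float | None
    pb_blasts: float | None
    wbc: float | None
    n_bm_mutations: int
    n_pb_mutations: int


def build_confusion_table(
    classifications: list[PairClassification],
    matched: list[MatchedVariant],
    panel: PanelDefinition,
    gene_level_positives: bool = False,
) -> ConfusionTable:
    """Aggregate matched variants and pair categories into the 2x2 table.

    With ``gene_level_positives`` the positive cells count (pair, gene)
    combinations instead of individual mutations; the default keeps the
    mutation-level convention.
    """
    if gene_level_positives:
        keys = {(m.pair_id, m.gene, m.status) for m in matched}
        tp = len({(p, g) for (p, g, s) in keys if s is MatchStatus.BOTH})
        fn = len({(p, g) for (p, g, s) in keys if s is MatchStatus.BM_ONLY})
        fp = len({(p, g) for (p, g, s) in keys if s is MatchStatus.PB_ONLY})
    else:
        tp = sum(1 for m in matched if m.status is MatchStatus.BOTH)
        fn = sum(1 for m in matched if m.status is MatchStatus.BM_ONLY)
        fp = sum(1 for m in matched if m.status is MatchStatus.PB_ONLY)
    n_neg = sum(1 for c in classifications if c.category is PairCategory.NEGATIVE_PAIR)
    return ConfusionTable(
        tp=tp, fn=fn, fp=fp,
        tn=n_neg * panel.n_dna_genes,
        n_negative_pairs=n_neg,
        panel_genes=panel.n_dna_genes,
    )


def concordance_metrics(t: ConfusionTable) -> ConcordanceMetrics:
    """Concordance, sensitivity, specificity, PPV, NPV from the 2x2 table.

    BM is the reference: sensitivity and NPV condition on the BM result,
    PPV on the PB result.  A zero denominator yields an undefined (None)
    percentage, never 0 or 100.
    """
    return ConcordanceMetrics(
        concordance=MetricValue(t.tp + t.tn, t.total),
        sensitivity=MetricValue(t.tp, t.tp + t.fn),
        specificity=MetricValue(t.tn, t.fp + t.tn),
        ppv=MetricValue(t.tp, t.tp + t.fp),
        npv=MetricValue(t.tn, t.fn + t.tn),
    )


def pair_level_summary(
    classifications: list[PairClassification],
    matched: list[MatchedVariant],
) -> dict:
    """Reported-result and pair-category accounting.

    A "reported result" is either a mutation call (concordant when found in
    both tissues) or a negative pair (one concordant negative report).
    ``n_pairs_without_discordance`` counts pairs free of any discordant
    mutation, i.e. complete-concordance plus negative pairs.
    """
    tp = sum(1 for m in matched if m.status is MatchStatus.BOTH)
    fn = sum(1 for m in matched if m.status is MatchStatus.BM_ONLY)
    fp = sum(1 for m in matched if m.status is MatchStatus.PB_ONLY)
    cats = {cat: sum(1 for c in classifications if c.category is cat) for cat in PairCategory}
    n_neg = cats[PairCategory.NEGATIVE_PAIR]
    return {
        "tp": tp, "fn": fn, "fp": fp,
        "n_pairs": len(classifications),
        "n_negative_pairs": n_neg,
        "concordant_reported_results": tp + n_neg,
        "discordant_reported_results": fn + fp,
        "n_complete_concordance": cats[PairCategory.COMPLETE_CONCORDANCE],
        "n_partial_concordance": cats[PairCategory.PARTIAL_CONCORDANCE],
        "n_fully_discordant": cats[PairCategory.FULLY_DISCORDANT],
        "n_pairs_without_discordance": cats[PairCategory.COMPLETE_CONCORDANCE] + n_neg,
    }


def gene_occurrence(
    matched: list[MatchedVariant],
    pairs: list[SamplePair],
    group_by_diagnosis: bool = False,
) -> list[dict]:
    """Per-gene occurrence: percent of samples with >=1 mutation, by tissue.

    Denominator: pairs with at least one non-fusion mutation in either
    tissue (negative pairs and fusion-only pairs are excluded).  A sample
    with several mutations in one gene contributes once to that gene's
    numerator.  Returns a list of row dicts sorted by descending BM percent.
    """
    by_pair: dict[str, list[MatchedVariant]] = {}
    for m in matched:
        by_pair.setdefault(m.pair_id, []).append(m)
    pair_index = {p.pair_id: p for p in pairs}

    def rows_for(pair_ids: list[str], diagnosis: str | None) -> list[dict]:
        denom_ids = [
            pid for pid in pair_ids
            if any(m.var_class is not VarClass.FUSION for m in by_pair.get(pid, []))
        ]
        if not denom_ids:
            logger.warning("gene occurrence: empty denominator%s",
                           f" for {diagnosis}" if diagnosis else "")
            return []
        bm_genes: dict[str, set[str]] = {}
        pb_genes: dict[str, set[str]] = {}
        for pid in denom_ids:
            for m in by_pair.get(pid, []):
                if m.status in (MatchStatus.BOTH, MatchStatus.BM_ONLY):
                    bm_genes.setdefault(m.gene, set()).add(pid)
                if m.status in (MatchStatus.BOTH, MatchStatus.PB_ONLY):
                    pb_genes.setdefault(m.gene, set()).add(pid)
        n = len(denom_ids)
        out = []
        for gene in sorted(set(bm_genes) | set(pb_genes)):
            nb = len(bm_genes.get(gene, ()))
            np_ = len(pb_genes.get(gene, ()))
            row = {
                "gene": gene,
                "n_pairs": n,
                "bm_count": nb,
                "pb_count": np_,
                "bm_pct": round_half_up(100.0 * nb / n, 1),
                "pb_pct": round_half_up(100.0 * np_ / n, 1),
            }
            if diagnosis is not None:
                row = {"diagnosis": diagnosis, **row}
            out.append(row)
        out.sort(key=lambda r: (-r["bm_pct"], r["gene"]))
        return out

    if not group_by_diagnosis:
        return rows_for(sorted(by_pair), None)
    groups: dict[str, list[str]] = {}
    for pid in sorted(by_pair):
        pair = pair_index.get(pid)
        dx = pair.bm.diagnosis.value if pair else "unknown"
        groups.setdefault(dx, []).append(pid)
    out: list[dict] = []
    for dx in sorted(groups):
        out.extend(rows_for(groups[dx], dx))
    return out


def discordance_report(
    matched: list[MatchedVariant],
    pairs: list[SamplePair],
    low_vaf_threshold: float = 5.0,
) -> tuple[list[DiscordantRecord], dict]:
    """List every discordant mutation with pair covariates, plus a summary.

    The summary reports the discordant count as a percentage of all detected
    mutation calls (a both-tissue mutation counts twice, once per sample),
    descriptive statistics of the BM-exclusive VAFs (sample SD), and how
    many discordant mutations sit at or below ``low_vaf_threshold`` percent
    VAF, the region where sub-clonal detection noise dominates.
    """
    pair_index = {p.pair_id: p for p in pairs}
    counts: dict[str, dict[str, int]] = {}
    for m in matched:
        c = counts.setdefault(m.pair_id, {"bm": 0, "pb": 0})
        if m.status in (MatchStatus.BOTH, MatchStatus.BM_ONLY):
            c["bm"] += 1
        if m.status in (MatchStatus.BOTH, MatchStatus.PB_ONLY):
            c["pb"] += 1

    records: list[DiscordantRecord] = []
    for m in matched:
        if m.status is MatchStatus.BOTH:
            continue
        pair = pair_index.get(m.pair_id)
        found_bm = m.status is MatchStatus.BM_ONLY
        records.append(
            DiscordantRecord(
                pair_id=m.pair_id,
                gene=m.gene,
                pathway=GENE_PATHWAYS.get(m.gene, "other"),
                tissue_found="BM" if found_bm else "PB",
                vaf_found=m.bm_vaf if found_bm else m.pb_vaf,
                bm_blasts=pair.bm.bm_blast_pct if pair else None,
                pb_blasts=pair.pb.pb_blast_pct if pair else None,
                wbc=pair.pb.wbc if pair else None,
                n_bm_mutations=counts[m.pair_id]["bm"],
                n_pb_mutations=counts[m.pair_id]["pb"],
            )
        )
    records.sort(key=lambda r: (r.vaf_found if r.vaf_found is not None else math.inf, r.pair_id))

    n_both = sum(1 for m in matched if m.status is MatchStatus.BOTH)
    n_disc = len(records)
    total_calls = 2 * n_both + n_disc
    bm_vafs = [r.vaf_found for r in records if r.tissue_found == "BM" and r.vaf_found is not None]
    if bm_vafs:
        mean = sum(bm_vafs) / len(bm_vafs)
        sd = (
            math.sqrt(sum((v - mean) ** 2 for v in bm_vafs) / (len(bm_vafs) - 1))
            if len(bm_vafs) > 1 else 0.0
        )
        bm_stats = {"mean": mean, "sd": sd, "min": min(bm_vafs), "max": max(bm_vafs)}
    else:
        bm_stats = {"mean": None, "sd": None, "min": None, "max": None}
    vafs = [r.vaf_found for r in records if r.vaf_found is not None]
    summary = {
        "n_discordant": n_disc,
        "n_total_mutation_calls": total_calls,
        "pct_of_calls": round_half_up(100.0 * n_disc / total_calls, 2) if total_calls else 0.0,
        "bm_exclusive_vaf": bm_stats,
        "low_vaf_threshold": low_vaf_threshold,
        "n_at_or_below_threshold": sum(1 for v in vafs if v <= low_vaf_threshold),
    }
    return records, summary


def mutation_count_summary(
    matched: list[MatchedVariant],
    pairs: list[SamplePair],
) -> dict:
    """Mean/SD/min-max of reportable mutations per sample, by tissue.

    Every pair contributes one BM and one PB sample; negative samples
    contribute a count of zero.  SD uses the n-1 (sample) denominator.
    """
    counts = {p.pair_id: {"BM": 0, "PB": 0} for p in pairs}
    for m in matched:
        c = counts.setdefault(m.pair_id, {"BM": 0, "PB": 0})
        if m.status in (MatchStatus.BOTH, MatchStatus.BM_ONLY):
            c["BM"] += 1
        if m.status in (MatchStatus.BOTH, MatchStatus.PB_ONLY):
            c["PB"] += 1
    out = {}
    for tissue in ("BM", "PB"):
        xs = [counts[pid][tissue] for pid in counts]
        if not xs:
            out[tissue] = {"mean": None, "sd": None, "min": None, "max": None, "n": 0}
            continue
        mean = sum(xs) / len(xs)
        sd = (
            math.sqrt(sum((x - mean) ** 2 for x in xs) / (len(xs) - 1))
            if len(xs) > 1 else 0.0
        )
        out[tissue] = {"mean": mean, "sd": sd, "min": min(xs), "max": max(xs), "n": len(xs)}
    return out
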