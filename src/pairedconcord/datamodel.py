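"""Domain types and reportability filtering for paired-sample variant concordance.

The analysis compares targeted-NGS variant calls from paired bone-marrow (BM)
aspirates and peripheral-blood (PB) draws of the same patient.  This module
defines the in-memory representation of a variant call, a sample, a BM/PB
sample pair, the gene panel, and the reportability filter that decides which
raw calls enter the concordance analysis.

Conventions
-----------
* VAF (variant allele frequency) is stored as a **percent** in [0, 100],
  never as a fraction: every downstream statistic (correlation, Bland-Altman
  limits, detection threshold) operates on the percent scale.
* Absent numeric fields are explicit ``None``, never sentinel zeros, so a
  VAF of 0 can never be confused with "this assay produces no VAF"
  (fusion and FLT3-ITD calls).
* Genomic coordinates are 1-based and fully closed (VCF convention).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date
from decimal import Decimal, ROUND_HALF_UP


class PairedConcordError(Exception):
    """Base class for errors raised by this package."""


class FormatError(PairedConcordError):
    """An input file does not have the documented layout."""


class ValidationError(PairedConcordError):
    """A record violates a domain invariant."""


def round_half_up(x: float | None, ndigits: int = 1) -> float | None:
    """Round with ties away from zero, as clinical tables are printed.

    Python's builtin ``round`` uses banker's rounding (99.65 -> 99.6); report
    percentages here follow the half-up convention (99.65 -> 99.7).
    """
    if x is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class VarClass(str, enum.Enum):
    """Variant class; fusion and FLT3-ITD calls carry no VAF or depth."""

    SNV = "SNV"
    MNP = "MNP"
    INSERTION = "insertion"
    DELETION = "deletion"
    FUSION = "fusion"
    FLT3_ITD = "FLT3_ITD"


#: Classes whose assay reports a VAF and a read depth.
VAF_CLASSES = frozenset({VarClass.SNV, VarClass.MNP, VarClass.INSERTION, VarClass.DELETION})


class Annotation(str, enum.Enum):
    PATHOGENIC_OR_UNKNOWN = "pathogenic_or_unknown"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"


class Tissue(str, enum.Enum):
    BM = "BM"
    PB = "PB"


class Diagnosis(str, enum.Enum):
    AML = "AML"
    MDS = "MDS"
    MDS_MPN = "MDS_MPN"
    MPN = "MPN"
    OTHER = "other"


@dataclass(frozen=True)
class PanelDefinition:
    """A targeted myeloid panel: DNA target genes plus RNA fusion drivers.

    ``dna_genes`` is the list used for presumed-negative accounting: a sample
    pair in which no mutation was detected contributes one concordant
    negative call per DNA gene.
    """

    dna_genes: tuple[str, ...]
    fusion_drivers: tuple[str, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        for label, genes in (("dna_genes", self.dna_genes), ("fusion_drivers", self.fusion_drivers)):
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate gene symbols in {label}")

    @property
    def n_dna_genes(self) -> int:
        return len(self.dna_genes)


# 40 DNA target genes (23 hotspot + 17 full genes) and 29 RNA fusion driver
# genes of a commercial amplicon myeloid panel.
AMPLISEQ_MYELOID = PanelDefinition(
    dna_genes=(
        # hotspot genes
        "ABL1", "BRAF", "CBL", "CSF3R", "DNMT3A", "FLT3", "GATA2", "HRAS",
        "IDH1", "IDH2", "JAK2", "KIT", "KRAS", "MPL", "MYD88", "NPM1",
        "NRAS", "PTPN11", "SETBP1", "SF3B1", "SRSF2", "U2AF1", "WT1",
        # full genes
        "ASXL1", "BCOR", "CALR", "CEBPA", "ETV6", "EZH2", "IKZF1", "NF1",
        "PHF6", "PRPF8", "RB1", "RUNX1", "SH2B3", "STAG2", "TET2", "TP53",
        "ZRSR2",
    ),
    fusion_drivers=(
        "ALK", "BCL2", "BCR", "CCND1", "CREBBP", "EGFR", "ETV6F", "FGFR1",
        "FGFR2", "FUS", "HMGA2", "JAK2F", "KMT2A", "MECOM", "MET", "MLLT3",
        "MLLT10", "MYBL1", "MYH11", "NTRK3", "NUP214", "PDGFRA", "PDGFRB",
        "RARA", "RBM15", "RUNX1T1", "TCF3", "TFE3", "CBFB",
    ),
    name="myeloid-40dna-29rna",
)


@dataclass(frozen=True)
class VariantCall:
    """One observed variant in one sample.

    ``vaf`` is a percent in [0, 100] and must be present exactly for the DNA
    classes (SNV/MNP/insertion/deletion); fusion and FLT3-ITD calls are
    presence/absence calls from assays that produce no VAF.  ``population_af``
    is a general-population allele frequency (fraction in [0, 1]) used by the
    SNP exclusion filter; ``db_entry`` flags a known somatic/SNP database
    entry and is informational only.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: VarClass
    vaf: float | None = None
    depth: int | None = None
    population_af: float | None = None
    annotation: Annotation = Annotation.PATHOGENIC_OR_UNKNOWN
    db_entry: bool = False

    def __post_init__(self) -> None:
        if self.var_class in VAF_CLASSES:
            if self.vaf is None:
                raise ValidationError(
                    f"{self.var_class.value} call {self.gene} in {self.sample_id} has no VAF"
                )
        elif self.vaf is not None:
            raise ValidationError(
                f"{self.var_class.value} call {self.gene} carries a VAF; this assay produces none"
            )
        if self.vaf is not None and not 0.0 <= self.vaf <= 100.0:
            raise ValidationError(f"VAF {self.vaf} outside [0, 100]")
        if self.pos < 1:
            raise ValidationError(f"position {self.pos} is not 1-based")
        if self.var_class in (VarClass.SNV, VarClass.MNP) and self.ref == self.alt:
            raise ValidationError(f"{self.var_class.value} with ref == alt at {self.chrom}:{self.pos}")
        if self.depth is not None and self.depth < 0:
            raise ValidationError(f"negative read depth {self.depth}")
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValidationError(f"population AF {self.population_af} outside [0, 1]")


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced sample with its clinical covariates on the draw date."""

    sample_id: str
    patient_id: str
    tissue: Tissue
    draw_date: date
    diagnosis: Diagnosis
    pb_blast_pct: float | None = None
    bm_blast_pct: float | None = None
    anc: float | None = None  # absolute neutrophil count, G/L
    wbc: float | None = None  # white blood cell count, G/L

    def __post_init__(self) -> None:
        for label, v in (("pb_blast_pct", self.pb_blast_pct), ("bm_blast_pct", self.bm_blast_pct)):
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValidationError(f"{label} {v} outside [0, 100]")
        for label, v in (("anc", self.anc), ("wbc", self.wbc)):
            if v is not None and v < 0:
                raise ValidationError(f"{label} {v} is negative")


@dataclass(frozen=True)
class SamplePair:
    """A BM sample and a PB sample from one patient."""

    pair_id: str
    patient_id: str
    bm: SampleRecord
    pb: SampleRecord
    days_apart: int

    def __post_init__(self) -> None:
        if self.bm.tissue is not Tissue.BM or self.pb.tissue is not Tissue.PB:
            raise ValidationError(f"pair {self.pair_id}: tissues are not (BM, PB)")
        if self.bm.patient_id != self.pb.patient_id:
            raise ValidationError(f"pair {self.pair_id}: samples from different patients")
        expected = abs((self.bm.draw_date - self.pb.draw_date).days)
        if self.days_apart != expected:
            raise ValidationError(
                f"pair {self.pair_id}: days_apart {self.days_apart} != date difference {expected}"
            )


class MatchStatus(str, enum.Enum):
    BOTH = "both"
    BM_ONLY = "bm_only"
    PB_ONLY = "pb_only"


@dataclass(frozen=True)
class MatchedVariant:
    """A variant's joint status across one BM/PB pair."""

    pair_id: str
    gene: str
    match_key: tuple
    var_class: VarClass
    status: MatchStatus
    bm_vaf: float | None = None
    pb_vaf: float | None = None

    def __post_init__(self) -> None:
        if self.status is MatchStatus.PB_ONLY and self.bm_vaf is not None:
            raise ValidationError("pb_only variant cannot carry a BM VAF")
        if self.status is MatchStatus.BM_ONLY and self.pb_vaf is not None:
            raise ValidationError("bm_only variant cannot carry a PB VAF")


@dataclass(frozen=True)
class FilterConfig:
    """Reportability filter settings.

    Defaults mirror routine clinical practice for a myeloid panel: analytic
    sensitivity at 1% VAF, exclusion of variants present in >1% of the
    general population (SNPs), and exclusion of (likely) benign annotations.
    ``germline_windows`` are the VAF intervals that trigger a germline-origin
    follow-up (heterozygous ~50%, homozygous ~100%); bounds are inclusive.
    """

    min_vaf: float = 1.0
    max_population_af: float = 0.01
    exclude_benign: bool = True
    germline_windows: tuple[tuple[float, float], ...] = ((45.0, 55.0), (95.0, 100.0))

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_vaf <= 100.0:
            raise ValidationError(f"min_vaf {self.min_vaf} outside [0, 100]")
        if not 0.0 <= self.max_population_af <= 1.0:
            raise ValidationError("max_population_af outside [0, 1]")
        for lo, hi in self.germline_windows:
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValidationError(f"germline window ({lo}, {hi}) outside [0, 100]")

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        windows = d.get("germline_windows")
        return cls(
            min_vaf=float(d.get("min_vaf", 1.0)),
            max_population_af=float(d.get("max_population_af", 0.01)),
            exclude_benign=bool(d.get("exclude_benign", True)),
            germline_windows=tuple(tuple(map(float, w)) for w in windows)
            if windows is not None
            else ((45.0, 55.0), (95.0, 100.0)),
        )

    def to_dict(self) -> dict:
        return {
            "min_vaf": self.min_vaf,
            "max_population_af": self.max_population_af,
            "exclude_benign": self.exclude_benign,
            "germline_windows": [list(w) for w in self.germline_windows],
        }


@dataclass(frozen=True)
class FilterRemoval:
    """A call removed by :func:`filter_reportable`, with the first reason that fired."""

    call: VariantCall
    reason: str


REASON_BELOW_VAF = "below VAF threshold"
REASON_POPULATION_SNP = "population SNP"
REASON_BENIGN = "benign or likely benign annotation"


def filter_reportable(
    calls: list[VariantCall], cfg: FilterConfig | None = None
) -> tuple[list[VariantCall], list[FilterRemoval]]:
    """Apply the reportability filter; returns (kept, removed-with-reasons).

    A call is kept iff all of:

    * its VAF is absent (fusion/FLT3-ITD) or >= ``cfg.min_vaf``;
    * its population allele frequency is absent or <= ``cfg.max_population_af``;
    * its annotation is not benign/likely-benign (when ``exclude_benign``).

    The filter is pure, order-preserving, and idempotent.
    """
    cfg = cfg or FilterConfig()
    kept: list[VariantCall] = []
    removed: list[FilterRemoval] = []
    for call in calls:
        if call.vaf is not None and call.vaf < cfg.min_vaf:
            removed.append(FilterRemoval(call, REASON_BELOW_VAF))
        elif call.population_af is not None and call.population_af > cfg.max_population_af:
            removed.append(FilterRemoval(call, REASON_POPULATION_SNP))
        elif cfg.exclude_benign and call.annotation in (Annotation.BENIGN, Annotation.LIKELY_BENIGN):
            removed.append(FilterRemoval(call, REASON_BENIGN))
        else:
            kept.append(call)
    return kept, removed


def flag_germline_candidates(
    calls: list[VariantCall], cfg: FilterConfig | None = None
) -> list[tuple[VariantCall, bool]]:
    """Flag calls whose VAF falls in a germline-candidate window.

    Windows are inclusive at both ends (a VAF of exactly 45 or 55 is
    flagged).  No call is removed; flagged calls would be routed to a
    germline-control sequencing (e.g., buccal swab) in practice.
    """
    cfg = cfg or FilterConfig()
    out = []
    for call in calls:
        flagged = call.vaf is not None and any(
            lo <= call.vaf <= hi for lo, hi in cfg.germline_windows
        )
        out.append((call, flagged))
    return out
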