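"""End-to-end orchestration: filter -> pair -> match -> classify -> report.

``run_pipeline`` takes the two variant tables and the cohort metadata
(in-memory lists or file paths), runs every analysis stage, and returns a
single JSON-serialisable report bundle in which every percentage carries
its exact numerator/denominator.  Re-running on identical inputs produces a
byte-identical JSON file (stable key order, ``repr`` float formatting).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import io as pcio
from .agreement import (
    bland_altman,
    blast_vaf_correlation,
    collect_vaf_pairs,
    kendall_tau,
    regression_line,
    spearman,
    stratify,
)
from .concordance import (
    build_confusion_table,
    concordance_metrics,
    discordance_report,
    gene_occurrence,
    mutation_count_summary,
    pair_level_summary,
)
from .datamodel import (
    AMPLISEQ_MYELOID,
    FilterConfig,
    PanelDefinition,
    SampleRecord,
    ValidationError,
    VariantCall,
)
from .match import classify_pair, match_variants, pair_samples

logger = logging.getLogger(__name__)

DEFAULT_STRATA = ("pb_blasts_zero", "pb_blasts_ge1", "anc_lt1", "anc_ge1",
                  "same_day_only", "min_vaf_5")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; ``seed`` is recorded in every output bundle."""

    filter: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    panel: PanelDefinition = dataclasses.field(default_factory=lambda: AMPLISEQ_MYELOID)
    strata: tuple[str, ...] = DEFAULT_STRATA
    seed: int = 0
    low_vaf_threshold: float = 5.0
    gene_level_positives: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        panel = AMPLISEQ_MYELOID
        if "panel" in data:
            panel = PanelDefinition(
                dna_genes=tuple(data["panel"]["dna_genes"]),
                fusion_drivers=tuple(data["panel"].get("fusion_drivers", ())),
                name=data["panel"].get("name", "custom"),
            )
        return cls(
            filter=FilterConfig.from_dict(data.get("filter", {})),
            panel=panel,
            strata=tuple(data.get("strata", DEFAULT_STRATA)),
            seed=int(data.get("seed", 0)),
            low_vaf_threshold=float(data.get("low_vaf_threshold", 5.0)),
            gene_level_positives=bool(data.get("gene_level_positives", False)),
        )


def _load_calls(src) -> list[VariantCall]:
    if isinstance(src, (str, Path)):
        return pcio.read_variant_table(src)
    return list(src)


def _load_metadata(src) -> list[SampleRecord]:
    if isinstance(src, (str, Path)):
        return pcio.read_cohort_metadata(src)
    return list(src)


def _correlation_block(vaf_pairs) -> dict:
    x = [p.bm_vaf for p in vaf_pairs]
    y = [p.pb_vaf for p in vaf_pairs]
    block: dict = {"n": len(vaf_pairs)}
    if len(vaf_pairs) < 2:
        block.update({"spearman": None, "kendall": None, "regression": None,
                      "bland_altman": None, "warning": "fewer than 2 VAF pairs"})
        return block
    block["spearman"] = spearman(x, y).as_dict()
    block["kendall"] = kendall_tau(x, y).as_dict()
    slope, intercept = regression_line(x, y)
    block["regression"] = {"slope": slope, "intercept": intercept,
                           "bisecting_line": {"slope": 1.0, "intercept": 0.0}}
    block["bland_altman"] = bland_altman(vaf_pairs).as_dict()
    return block


def run_pipeline(
    config: RunConfig,
    bm_table,
    pb_table,
    metadata,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the full concordance analysis and return the report bundle.

    Stage errors propagate as :class:`ValidationError` annotated with the
    stage name.  When ``out_dir`` is given, writes ``report.json`` plus the
    CSV report tables there.
    """
    stages: list[tuple[str, callable]] = []

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # annotate with the failing stage
                raise ValidationError(f"stage '{name}': {exc}") from exc
        return wrap

    bm_calls = stage("read BM table")(lambda: _load_calls(bm_table))
    pb_calls = stage("read PB table")(lambda: _load_calls(pb_table))
    records = stage("read metadata")(lambda: _load_metadata(metadata))

    from .datamodel import filter_reportable

    bm_kept, bm_removed = filter_reportable(bm_calls, config.filter)
    pb_kept, pb_removed = filter_reportable(pb_calls, config.filter)
    logger.info("filter: BM %d kept / %d removed; PB %d kept / %d removed",
                len(bm_kept), len(bm_removed), len(pb_kept), len(pb_removed))

    pairs, unpaired = stage("pair samples")(lambda: pair_samples(records))
    logger.info("pairing: %d pairs, %d unpaired samples", len(pairs), len(unpaired))

    bm_by_sample: dict[str, list[VariantCall]] = {}
    for c in bm_kept:
        bm_by_sample.setdefault(c.sample_id, []).append(c)
    pb_by_sample: dict[str, list[VariantCall]] = {}
    for c in pb_kept:
        pb_by_sample.setdefault(c.sample_id, []).append(c)

    matched = []
    classifications = []
    for p in pairs:
        m = match_variants(bm_by_sample.get(p.bm.sample_id, []),
                           pb_by_sample.get(p.pb.sample_id, []), pair_id=p.pair_id)
        matched.extend(m)
        classifications.append(classify_pair(m, pair_id=p.pair_id))

    table = build_confusion_table(classifications, matched, config.panel,
                                  gene_level_positives=config.gene_level_positives)
    metrics = concordance_metrics(table)
    summary = pair_level_summary(classifications, matched)
    occurrence = gene_occurrence(matched, pairs)
    disc_records, disc_summary = discordance_report(
        matched, pairs, low_vaf_threshold=config.low_vaf_threshold)
    counts = mutation_count_summary(matched, pairs)

    vaf_pairs = collect_vaf_pairs(matched, pairs)
    agreement_block = {"overall": _correlation_block(vaf_pairs), "strata": {}}
    if config.strata:
        for name, subset in stratify(vaf_pairs, *config.strata).items():
            agreement_block["strata"][name] = _correlation_block(subset)
    agreement_block["blast_vaf_correlation"] = {
        "BM": blast_vaf_correlation(matched, pairs, "BM").as_dict(),
        "PB": blast_vaf_correlation(matched, pairs, "PB").as_dict(),
    }

    bundle = {
        "seed": config.seed,
        "filter": {
            "config": config.filter.to_dict(),
            "bm_removed": len(bm_removed),
            "pb_removed": len(pb_removed),
        },
        "pairing": {
            "n_pairs": len(pairs),
            "n_unpaired_samples": len(unpaired),
            "n_same_day": sum(1 for p in pairs if p.days_apart == 0),
        },
        "confusion": {
            "tp": table.tp, "fn": table.fn, "fp": table.fp, "tn": table.tn,
            "n_negative_pairs": table.n_negative_pairs,
            "panel_genes": table.panel_genes,
        },
        "metrics": metrics.as_dict(),
        "pair_summary": summary,
        "pair_classifications": [dataclasses.asdict(c) | {"category": c.category.value}
                                  for c in classifications],
        "mutation_counts": counts,
        "occurrence": occurrence,
        "discordance": {
            "records": [dataclasses.asdict(r) for r in disc_records],
            "summary": disc_summary,
        },
        "agreement": agreement_block,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
            fh.write("\n")
        pcio.write_report_tables(bundle, out_dir)
    return bundle
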