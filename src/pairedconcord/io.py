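"""Readers and writers for variant tables, cohort metadata, and minimal VCF.

Variant table (TSV or CSV, header required)::

    sample_id,gene,chrom,pos,ref,alt,var_class,vaf,depth,population_af,annotation,db_entry

Cohort metadata (CSV, header required)::

    sample_id,patient_id,tissue,draw_date,diagnosis,pb_blast_pct,bm_blast_pct,anc,wbc

Empty cells are explicit nulls.  Writing then reading any table reproduces
all fields bit-identically (floats are serialised with ``repr``, which is
the shortest round-tripping decimal form).
"""

from __future__ import annotations

import csv
from datetime import date
from pathlib import Path

from .datamodel import (
    Annotation,
    Diagnosis,
    FilterConfig,
    FormatError,
    SampleRecord,
    Tissue,
    ValidationError,
    VarClass,
    VariantCall,
)

VARIANT_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "var_class",
    "vaf", "depth", "population_af", "annotation", "db_entry",
]

METADATA_COLUMNS = [
    "sample_id", "patient_id", "tissue", "draw_date", "diagnosis",
    "pb_blast_pct", "bm_blast_pct", "anc", "wbc",
]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _delimiter(path: Path, sample_line: str) -> str:
    if path.suffix.lower() == ".tsv":
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    return "\t" if "\t" in sample_line else ","


def _opt_float(cell: str) -> float | None:
    return None if cell == "" else float(cell)


def _opt_int(cell: str) -> int | None:
    return None if cell == "" else int(cell)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def read_variant_table(path: str | Path) -> list[VariantCall]:
    """Read a variant-call table; raises :class:`FormatError` on a missing
    column and :class:`ValidationError` (with the 1-based data row number)
    on invalid values.  Row order is preserved."""
    path = Path(path)
    with open(path, newline="") as fh:
        first = fh.readline()
        if first == "":
            raise FormatError(f"{path}: empty file, expected a header")
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=_delimiter(path, first))
        header = reader.fieldnames or []
        for col in VARIANT_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column: {col}")
        calls: list[VariantCall] = []
        for i, row in enumerate(reader, start=1):
            try:
                vaf = _opt_float(row["vaf"])
                if vaf is not None and not 0.0 <= vaf <= 100.0:
                    raise ValidationError(f"VAF {vaf} outside [0, 100]")
                calls.append(
                    VariantCall(
                        sample_id=row["sample_id"],
                        gene=row["gene"],
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        ref=row["ref"],
                        alt=row["alt"],
                        var_class=VarClass(row["var_class"]),
                        vaf=vaf,
                        depth=_opt_int(row["depth"]),
                        population_af=_opt_float(row["population_af"]),
                        annotation=Annotation(row["annotation"]),
                        db_entry=row["db_entry"].strip().lower() in _TRUE,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return calls


def write_variant_table(calls: list[VariantCall], path: str | Path) -> None:
    path = Path(path)
    delim = "\t" if path.suffix.lower() != ".csv" else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(VARIANT_COLUMNS)
        for c in calls:
            writer.writerow([
                c.sample_id, c.gene, c.chrom, c.pos, c.ref, c.alt,
                c.var_class.value, _fmt(c.vaf), _fmt(c.depth),
                _fmt(c.population_af), c.annotation.value, _fmt(c.db_entry),
            ])


def read_cohort_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the cohort metadata CSV; duplicate sample IDs are rejected."""
    path = Path(path)
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in METADATA_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column: {col}")
        for i, row in enumerate(reader, start=1):
            sid = row["sample_id"]
            if sid in seen:
                raise ValidationError(f"{path}: row {i}: duplicate sample_id {sid}")
            seen.add(sid)
            try:
                records.append(
                    SampleRecord(
                        sample_id=sid,
                        patient_id=row["patient_id"],
                        tissue=Tissue(row["tissue"]),
                        draw_date=date.fromisoformat(row["draw_date"]),
                        diagnosis=Diagnosis(row["diagnosis"]),
                        pb_blast_pct=_opt_float(row["pb_blast_pct"]),
                        bm_blast_pct=_opt_float(row["bm_blast_pct"]),
                        anc=_opt_float(row["anc"]),
                        wbc=_opt_float(row["wbc"]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_cohort_metadata(records: list[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_COLUMNS)
        for r in records:
            writer.writerow([
                r.sample_id, r.patient_id, r.tissue.value, r.draw_date.isoformat(),
                r.diagnosis.value, _fmt(r.pb_blast_pct), _fmt(r.bm_blast_pct),
                _fmt(r.anc), _fmt(r.wbc),
            ])


def read_vcf(path: str | Path, sample_id: str | None = None, gene_info_key: str = "GENE") -> list[VariantCall]:
    """Read a minimal single-sample VCF into variant calls.

    Uses CHROM/POS/REF/ALT plus a ``VAF`` (percent, 0-100) and ``DP`` field
    from INFO or the first sample's FORMAT.  The gene symbol is taken from
    the INFO key ``gene_info_key`` when present.  The variant class is
    inferred from the allele lengths; fusion and FLT3-ITD calls are not
    representable in this minimal reader.  Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF  # optional dependency

    path = str(path)
    vcf = VCF(path)
    sid = sample_id or (vcf.samples[0] if vcf.samples else Path(path).stem)
    calls: list[VariantCall] = []
    for v in vcf:
        ref, alt = v.REF, v.ALT[0] if v.ALT else ""
        if len(ref) == 1 and len(alt) == 1:
            var_class = VarClass.SNV
        elif len(ref) == len(alt):
            var_class = VarClass.MNP
        elif len(alt) > len(ref):
            var_class = VarClass.INSERTION
        else:
            var_class = VarClass.DELETION
        vaf = v.INFO.get("VAF")
        if vaf is None:
            try:
                arr = v.format("VAF")
                if arr is not None:
                    vaf = float(arr[0][0])
            except KeyError:
                vaf = None
        depth = v.INFO.get("DP")
        if depth is None:
            try:
                arr = v.format("DP")
                if arr is not None:
                    depth = int(arr[0][0])
            except KeyError:
                depth = None
        calls.append(
            VariantCall(
                sample_id=sid,
                gene=str(v.INFO.get(gene_info_key) or ""),
                chrom=v.CHROM,
                pos=v.POS,
                ref=ref,
                alt=alt,
                var_class=var_class,
                vaf=float(vaf) if vaf is not None else None,
                depth=int(depth) if depth is not None else None,
            )
        )
    return calls


def read_filter_config(path: str | Path) -> FilterConfig:
    """Load a :class:`FilterConfig` from a YAML file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return FilterConfig.from_dict(data)


def write_report_tables(bundle: dict, out_dir: str | Path) -> list[Path]:
    """Write the report bundle's tabular sections as CSV files.

    Emits the 2x2 confusion table with its derived metrics, the discordant
    mutation listing, and the per-gene occurrence table, mirroring how a
    clinical concordance report is laid out.  Returns the written paths.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    conf = bundle.get("confusion")
    metrics = bundle.get("metrics")
    if conf and metrics:
        rows = [
            {"cell": "both_positive (TP)", "count": conf["tp"]},
            {"cell": "bm_only (FN)", "count": conf["fn"]},
            {"cell": "pb_only (FP)", "count": conf["fp"]},
            {"cell": "presumed_negative (TN)", "count": conf["tn"]},
        ]
        for name, m in metrics.items():
            rows.append({
                "cell": name,
                "count": "" if m["pct"] is None else m["pct"],
                "fraction": f"{m['numerator']}/{m['denominator']}",
            })
        p = out_dir / "confusion_metrics.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)

    if "discordance" in bundle and bundle["discordance"].get("records"):
        p = out_dir / "discordant.csv"
        pd.DataFrame(bundle["discordance"]["records"]).to_csv(p, index=False)
        written.append(p)

    if "occurrence" in bundle and bundle["occurrence"]:
        p = out_dir / "occurrence.csv"
        pd.DataFrame(bundle["occurrence"]).to_csv(p, index=False)
        written.append(p)

    if "pair_classifications" in bundle and bundle["pair_classifications"]:
        p = out_dir / "pair_classification.csv"
        pd.DataFrame(bundle["pair_classifications"]).to_csv(p, index=False)
        written.append(p)

    return written
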