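"""Sample pairing and variant matching across paired BM/PB samples.

Pairing: within a patient, each BM sample is paired with the yet-unused PB
sample drawn closest in time (greedy nearest-date assignment).  Matching:
DNA-class variants match on exact normalized (chrom, pos, ref, alt); fusion
calls match on the ordered 5'/3' partner pair; FLT3-ITD calls (a separate
fragment-analysis assay producing presence/absence only) match on gene and
class.  There is no VAF tolerance and no positional fuzziness: two calls
either denote the same event or they do not.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

from .datamodel import (
    MatchStatus,
    MatchedVariant,
    SamplePair,
    SampleRecord,
    Tissue,
    VAF_CLASSES,
    VarClass,
    VariantCall,
)

logger = logging.getLogger(__name__)


class PairCategory(str, enum.Enum):
    NEGATIVE_PAIR = "negative_pair"
    COMPLETE_CONCORDANCE = "complete_concordance"
    PARTIAL_CONCORDANCE = "partial_concordance"
    FULLY_DISCORDANT = "fully_discordant"


@dataclass(frozen=True)
class PairClassification:
    """Per-pair mutation counts and the concordance category they imply.

    * negative_pair: no mutation in either tissue
    * complete_concordance: >=1 mutation, all found in both tissues
    * partial_concordance: mutations in both tissues plus >=1 discordant
    * fully_discordant: only discordant mutations
    """

    pair_id: str
    n_both: int
    n_bm_only: int
    n_pb_only: int
    category: PairCategory


def pair_samples(
    records: list[SampleRecord],
) -> tuple[list[SamplePair], list[SampleRecord]]:
    """Pair BM with PB samples per patient by closest draw date.

    Each sample is used in at most one pair.  Samples that cannot be paired
    (patient has BM but no remaining PB, or vice versa) are returned in the
    exclusion list and logged as warnings.
    """
    by_patient: dict[str, dict[Tissue, list[SampleRecord]]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, {Tissue.BM: [], Tissue.PB: []})[r.tissue].append(r)

    pairs: list[SamplePair] = []
    unpaired: list[SampleRecord] = []
    for patient_id in sorted(by_patient):
        bms = by_patient[patient_id][Tissue.BM]
        pbs = by_patient[patient_id][Tissue.PB]
        candidates = sorted(
            ((abs((b.draw_date - p.draw_date).days), b.draw_date, p.draw_date,
              b.sample_id, p.sample_id, b, p)
             for b in bms for p in pbs),
            key=lambda t: t[:5],
        )
        used_bm: set[str] = set()
        used_pb: set[str] = set()
        for gap, _, _, _, _, b, p in candidates:
            if b.sample_id in used_bm or p.sample_id in used_pb:
                continue
            used_bm.add(b.sample_id)
            used_pb.add(p.sample_id)
            pairs.append(
                SamplePair(
                    pair_id=f"{b.sample_id}|{p.sample_id}",
                    patient_id=patient_id,
                    bm=b,
                    pb=p,
                    days_apart=gap,
                )
            )
        for r in bms + pbs:
            if r.sample_id not in used_bm and r.sample_id not in used_pb:
                logger.warning(
                    "patient %s: %s sample %s has no counterpart and was excluded",
                    patient_id, r.tissue.value, r.sample_id,
                )
                unpaired.append(r)
    return pairs, unpaired


def minimal_representation(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared allele context so that equivalent indel spellings match.

    Removes the longest common suffix, then the longest common prefix
    (always leaving at least one base on each allele), shifting ``pos`` past
    the trimmed prefix.  This is parsimony-based normalization; left-shifting
    across repeat tracts would additionally need the reference sequence.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def match_key(call: VariantCall) -> tuple:
    """The identity key used to match a call across the two tissues."""
    if call.var_class is VarClass.FUSION:
        return ("fusion", call.gene)
    if call.var_class is VarClass.FLT3_ITD:
        return ("itd", call.gene)
    pos, ref, alt = minimal_representation(call.pos, call.ref, call.alt)
    return ("dna", call.chrom, pos, ref, alt)


def _consolidate(calls: list[VariantCall]) -> dict[tuple, VariantCall]:
    """Collapse duplicate keys within one sample, keeping the highest VAF."""
    out: dict[tuple, VariantCall] = {}
    for c in calls:
        k = match_key(c)
        if k in out:
            logger.warning(
                "sample %s: duplicate call for %s; keeping highest VAF", c.sample_id, k
            )
            prev = out[k]
            if (c.vaf or 0.0) > (prev.vaf or 0.0):
                out[k] = c
        else:
            out[k] = c
    return out


def match_variants(
    bm_calls: list[VariantCall],
    pb_calls: list[VariantCall],
    pair_id: str = "",
) -> list[MatchedVariant]:
    """Classify every variant of one pair as both / bm_only / pb_only.

    Inputs must already be reportability-filtered and belong to a single
    sample pair.  Every input call appears in exactly one matched variant;
    duplicate identical keys within a sample are consolidated first (highest
    VAF wins, with a logged warning).
    """
    bm = _consolidate(bm_calls)
    pb = _consolidate(pb_calls)
    matched: list[MatchedVariant] = []
    for k in sorted(set(bm) | set(pb), key=str):
        in_bm, in_pb = k in bm, k in pb
        call = bm.get(k) or pb[k]
        if in_bm and in_pb:
            status = MatchStatus.BOTH
        elif in_bm:
            status = MatchStatus.BM_ONLY
        else:
            status = MatchStatus.PB_ONLY
        matched.append(
            MatchedVariant(
                pair_id=pair_id,
                gene=call.gene,
                match_key=k,
                var_class=call.var_class,
                status=status,
                bm_vaf=bm[k].vaf if in_bm else None,
                pb_vaf=pb[k].vaf if in_pb else None,
            )
        )
    return matched


def classify_pair(matched: list[MatchedVariant], pair_id: str | None = None) -> PairClassification:
    """Derive the pair-level concordance category from its matched variants."""
    if pair_id is None:
        pair_id = matched[0].pair_id if matched else ""
    n_both = sum(1 for m in matched if m.status is MatchStatus.BOTH)
    n_bm_only = sum(1 for m in matched if m.status is MatchStatus.BM_ONLY)
    n_pb_only = sum(1 for m in matched if m.status is MatchStatus.PB_ONLY)
    n_disc = n_bm_only + n_pb_only
    if n_both == 0 and n_disc == 0:
        category = PairCategory.NEGATIVE_PAIR
    elif n_both > 0 and n_disc == 0:
        category = PairCategory.COMPLETE_CONCORDANCE
    elif n_both > 0:
        category = PairCategory.PARTIAL_CONCORDANCE
    else:
        category = PairCategory.FULLY_DISCORDANT
    return PairClassification(pair_id, n_both, n_bm_only, n_pb_only, category)
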