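"""Confusion table, concordance metrics, occurrence, and discordance report."""

from __future__ import annotations

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_call, make_pair
from oracles import confusion_brute
from pairedconcord import (
    AMPLISEQ_MYELOID,
    ConfusionTable,
    MatchStatus,
    MatchedVariant,
    PanelDefinition,
    VarClass,
    build_confusion_table,
    concordance_metrics,
    discordance_report,
    gene_occurrence,
    mutation_count_summary,
    pair_level_summary,
)
from pairedconcord.match import classify_pair, match_variants

TOY_PANEL = PanelDefinition(dna_genes=("A", "B", "C", "D", "E"), fusion_drivers=())


def mv(pair_id, gene="TET2", status=MatchStatus.BOTH, bm_vaf=30.0, pb_vaf=28.0,
       var_class=VarClass.SNV, key=None):
    if status is MatchStatus.BM_ONLY:
        pb_vaf = None
    if status is MatchStatus.PB_ONLY:
        bm_vaf = None
    if var_class in (VarClass.FUSION, VarClass.FLT3_ITD):
        bm_vaf = pb_vaf = None
    return MatchedVariant(pair_id=pair_id, gene=gene,
                          match_key=key or ("dna", "chr1", 1, "C", "T"),
                          var_class=var_class, status=status,
                          bm_vaf=bm_vaf, pb_vaf=pb_vaf)


def study_scale_inputs():
    """A cohort with the canonical counts: 656 both, 8 BM-only, 1 PB-only,
    46 negative pairs, 240 pairs in total (185 complete, 7 partial, 2 fully
    discordant).  The 9 discordant VAFs follow the canonical listing."""
    matched = []
    classifications = []
    bm_only_vafs = [0.6, 1.1, 1.3, 1.9, 2.2, 2.5, 3.7, 9.1]
    pb_only_vafs = [1.0]
    # 46 negative pairs
    for i in range(46):
        classifications.append(classify_pair([], pair_id=f"neg{i}"))
    # 7 partial pairs carry the first 7 discordant mutations plus some both
    disc = [("BM", v) for v in bm_only_vafs] + [("PB", v) for v in pb_only_vafs]
    n_both = 0
    for i in range(7):
        pid = f"partial{i}"
        tissue, vaf = disc[i]
        status = MatchStatus.BM_ONLY if tissue == "BM" else MatchStatus.PB_ONLY
        items = [mv(pid, status=status, bm_vaf=vaf, pb_vaf=vaf)]
        for j in range(3):
            items.append(mv(pid, key=("dna", "chr1", 10 + j, "C", "T")))
            n_both += 1
        matched.extend(items)
        classifications.append(classify_pair(items, pair_id=pid))
    # 2 fully discordant pairs carry the last 2
    for i in range(2):
        pid = f"fulldisc{i}"
        tissue, vaf = disc[7 + i]
        status = MatchStatus.BM_ONLY if tissue == "BM" else MatchStatus.PB_ONLY
        items = [mv(pid, status=status, bm_vaf=vaf, pb_vaf=vaf)]
        matched.extend(items)
        classifications.append(classify_pair(items, pair_id=pid))
    # 185 complete-concordance pairs absorb the remaining both-calls
    remaining = 656 - n_both
    for i in range(185):
        pid = f"complete{i}"
        k = remaining // (185 - i)
        remaining -= k
        items = [mv(pid, key=("dna", "chr1", 100 + j, "C", "T")) for j in range(k)]
        matched.extend(items)
        classifications.append(classify_pair(items, pair_id=pid))
    assert remaining == 0
    return classifications, matched


class TestConfusionTable:
    def test_study_scale_counts_give_1840_presumed_negatives(self):
        classifications, matched = study_scale_inputs()
        t = build_confusion_table(classifications, matched, AMPLISEQ_MYELOID)
        assert (t.tp, t.fn, t.fp, t.tn) == (656, 8, 1, 1840)
        assert t.n_negative_pairs == 46 and t.panel_genes == 40

    def test_zero_pairs_all_cells_zero(self):
        t = build_confusion_table([], [], AMPLISEQ_MYELOID)
        assert (t.tp, t.fn, t.fp, t.tn) == (0, 0, 0, 0)

    def test_toy_negative_pairs_times_panel_genes(self):
        classifications = [classify_pair([], pair_id=f"n{i}") for i in range(3)]
        t = build_confusion_table(classifications, [], TOY_PANEL)
        assert t.tn == 15  # 3 pairs x 5 genes

    def test_doubling_panel_grows_negative_denominators(self):
        classifications, matched = study_scale_inputs()
        small = build_confusion_table(classifications, matched, AMPLISEQ_MYELOID)
        big_panel = PanelDefinition(
            dna_genes=AMPLISEQ_MYELOID.dna_genes
            + tuple(f"X{i}" for i in range(40)),
            fusion_drivers=(),
        )
        big = build_confusion_table(classifications, matched, big_panel)
        ms, mb = concordance_metrics(small), concordance_metrics(big)
        assert mb.specificity.denominator > ms.specificity.denominator
        assert mb.npv.denominator > ms.npv.denominator

    def test_gene_level_positives_collapse_same_gene_mutations(self):
        items = [mv("p", key=("dna", "chr1", i, "C", "T")) for i in range(3)]
        cls = [classify_pair(items, pair_id="p")]
        t_mut = build_confusion_table(cls, items, TOY_PANEL)
        t_gene = build_confusion_table(cls, items, TOY_PANEL, gene_level_positives=True)
        assert t_mut.tp == 3 and t_gene.tp == 1


class TestConcordanceMetrics:
    def test_canonical_2x2_percentages(self):
        m = concordance_metrics(ConfusionTable(656, 8, 1, 1840))
        assert m.concordance.pct == 99.6
        assert m.sensitivity.pct == 98.8
        assert m.specificity.pct == 99.9
        assert m.ppv.pct == 99.8
        assert m.npv.pct == 99.6

    def test_no_positives_leaves_sensitivity_undefined(self):
        m = concordance_metrics(ConfusionTable(0, 0, 0, 100))
        assert m.concordance.pct == 100.0
        assert m.sensitivity.pct is None and m.ppv.pct is None

    def test_no_negatives_leaves_specificity_undefined(self):
        m = concordance_metrics(ConfusionTable(10, 0, 0, 0))
        assert m.sensitivity.pct == 100.0
        assert m.specificity.pct is None and m.npv.pct is None

    @given(st.integers(0, 500), st.integers(0, 50), st.integers(0, 50), st.integers(0, 2000))
    def test_percentages_equal_their_carried_fractions(self, tp, fn, fp, tn):
        m = concordance_metrics(ConfusionTable(tp, fn, fp, tn))
        for metric in (m.concordance, m.sensitivity, m.specificity, m.ppv, m.npv):
            if metric.denominator == 0:
                assert metric.pct is None
            else:
                from pairedconcord import round_half_up

                assert metric.pct == round_half_up(
                    100.0 * metric.numerator / metric.denominator, 1)
                assert metric.numerator <= metric.denominator

    def test_matches_brute_force_enumeration_on_tiny_cohort(self):
        # <= 6 pairs, <= 3 genes: enumerate every (pair, variant) cell by hand
        bm_sets = {
            "p1": {("A", 1), ("B", 2)},
            "p2": {("A", 1)},
            "p3": set(),
            "p4": {("C", 9)},
        }
        pb_sets = {
            "p1": {("A", 1)},
            "p2": {("A", 1), ("B", 5)},
            "p3": set(),
            "p4": {("C", 9)},
        }
        panel = PanelDefinition(dna_genes=("A", "B", "C"), fusion_drivers=())
        matched, classifications = [], []
        for pid in sorted(bm_sets):
            bm = [make_call(sample_id=f"{pid}b", gene=g, pos=1000 + p, vaf=10.0)
                  for g, p in sorted(bm_sets[pid])]
            pb = [make_call(sample_id=f"{pid}p", gene=g, pos=1000 + p, vaf=10.0)
                  for g, p in sorted(pb_sets[pid])]
            m = match_variants(bm, pb, pair_id=pid)
            matched.extend(m)
            classifications.append(classify_pair(m, pair_id=pid))
        t = build_confusion_table(classifications, matched, panel)
        assert (t.tp, t.fn, t.fp, t.tn) == confusion_brute(bm_sets, pb_sets, 3)


class TestPairLevelSummary:
    def test_study_scale_accounting(self):
        classifications, matched = study_scale_inputs()
        s = pair_level_summary(classifications, matched)
        assert s["concordant_reported_results"] == 702
        assert s["discordant_reported_results"] == 9
        assert s["n_pairs"] == 240
        assert s["n_pairs_without_discordance"] == 231
        assert s["n_partial_concordance"] == 7
        assert s["n_fully_discordant"] == 2

    def test_all_negative_cohort(self):
        classifications = [classify_pair([], pair_id=f"n{i}") for i in range(5)]
        s = pair_level_summary(classifications, [])
        assert s["concordant_reported_results"] == 5
        assert s["discordant_reported_results"] == 0


class TestGeneOccurrence:
    def test_denominator_excludes_negative_and_fusion_only_pairs(self):
        matched = [mv("pos1"), mv("fus1", gene="CBFB::MYH11", var_class=VarClass.FUSION)]
        pairs = [make_pair("pos1"), make_pair("fus1"), make_pair("neg1")]
        rows = gene_occurrence(matched, pairs)
        assert all(r["n_pairs"] == 1 for r in rows)

    def test_multiple_mutations_in_one_gene_count_once(self):
        matched = [
            mv("p1", gene="TET2", key=("dna", "chr4", 1, "C", "T")),
            mv("p1", gene="TET2", key=("dna", "chr4", 2, "G", "A")),
        ]
        rows = gene_occurrence(matched, [make_pair("p1")])
        [tet2] = [r for r in rows if r["gene"] == "TET2"]
        assert tet2["bm_count"] == 1 and tet2["bm_pct"] == 100.0

    def test_hand_counted_toy_percentages(self):
        # gene X mutated in 2 of 4 BM samples and 1 of 4 PB samples
        matched = [
            mv("p1", gene="X"),
            mv("p2", gene="X", status=MatchStatus.BM_ONLY, bm_vaf=5.0),
            mv("p1", gene="Y"), mv("p2", gene="Y", key=("dna", "chr1", 7, "A", "G")),
            mv("p3", gene="Y"), mv("p4", gene="Y", key=("dna", "chr1", 8, "A", "G")),
        ]
        pairs = [make_pair(p) for p in ("p1", "p2", "p3", "p4")]
        rows = {r["gene"]: r for r in gene_occurrence(matched, pairs)}
        assert rows["X"]["bm_pct"] == 50.0 and rows["X"]["pb_pct"] == 25.0

    def test_grouped_by_diagnosis_splits_denominators(self):
        from pairedconcord import Diagnosis

        matched = [mv("aml1"), mv("mds1")]
        pairs = [make_pair("aml1", diagnosis=Diagnosis.AML),
                 make_pair("mds1", diagnosis=Diagnosis.MDS)]
        rows = gene_occurrence(matched, pairs, group_by_diagnosis=True)
        assert {r["diagnosis"] for r in rows} == {"AML", "MDS"}
        assert all(r["n_pairs"] == 1 for r in rows)


class TestDiscordanceReport:
    def test_study_scale_discordance_summary(self):
        classifications, matched = study_scale_inputs()
        pairs = [make_pair(c.pair_id) for c in classifications]
        records, summary = discordance_report(matched, pairs, low_vaf_threshold=3.7)
        assert summary["n_discordant"] == 9
        assert summary["n_total_mutation_calls"] == 1321
        assert summary["pct_of_calls"] == 0.68
        assert summary["n_at_or_below_threshold"] == 8
        bm_stats = summary["bm_exclusive_vaf"]
        assert bm_stats["min"] == 0.6 and bm_stats["max"] == 9.1
        assert math.isclose(bm_stats["mean"], 2.8)

    def test_records_join_pair_covariates(self):
        matched = [mv("p1", status=MatchStatus.BM_ONLY, bm_vaf=2.2, gene="SRSF2"), mv("p1")]
        pairs = [make_pair("p1", pb_blast_pct=2.0, bm_blast_pct=2.5, wbc=3.6)]
        [rec], _ = discordance_report(matched, pairs)
        assert rec.tissue_found == "BM" and rec.vaf_found == 2.2
        assert rec.pathway == "Splicing factor"
        assert rec.wbc == 3.6
        assert (rec.n_bm_mutations, rec.n_pb_mutations) == (2, 1)

    def test_no_discordance_yields_empty_report(self):
        records, summary = discordance_report([mv("p1")], [make_pair("p1")])
        assert records == [] and summary["pct_of_calls"] == 0.0


class TestMutationCountSummary:
    def test_hand_counts(self):
        matched = (
            [mv("p2", key=("dna", "chr1", i, "C", "T")) for i in range(2)]
            + [mv("p3", key=("dna", "chr1", i, "C", "T")) for i in range(4)]
        )
        pairs = [make_pair(p) for p in ("p1", "p2", "p3")]
        s = mutation_count_summary(matched, pairs)
        assert s["BM"]["mean"] == 2.0 and s["BM"]["min"] == 0 and s["BM"]["max"] == 4

    def test_all_negative_cohort_means_zero(self):
        pairs = [make_pair(p) for p in ("p1", "p2")]
        s = mutation_count_summary([], pairs)
        assert s["BM"]["mean"] == 0 and s["PB"]["mean"] == 0

    def test_simulated_default_cohort_bm_mean_near_target(self):
        from pairedconcord import RunConfig, SimulationParams, run_pipeline, simulate_cohort

        c = simulate_cohort(SimulationParams(n_patients=400, seed=13))
        b = run_pipeline(RunConfig(), c.bm_calls, c.pb_calls, c.metadata)
        assert abs(b["mutation_counts"]["BM"]["mean"] - 2.8) <= 0.3
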