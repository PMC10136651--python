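from __future__ import annotations

from datetime import date

import pytest
from hypothesis import HealthCheck, settings

from pairedconcord import (
    Diagnosis,
    SamplePair,
    SampleRecord,
    Tissue,
    VarClass,
    VariantCall,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_call(
    sample_id="S1",
    gene="TET2",
    chrom="chr4",
    pos=106_155_100,
    ref="C",
    alt="T",
    var_class=VarClass.SNV,
    vaf=25.4,
    depth=6116,
    **kw,
) -> VariantCall:
    if var_class in (VarClass.FUSION, VarClass.FLT3_ITD):
        vaf, depth = None, None
    return VariantCall(
        sample_id=sample_id, gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
        var_class=var_class, vaf=vaf, depth=depth, **kw,
    )


def make_record(
    sample_id,
    patient_id="P1",
    tissue=Tissue.BM,
    draw_date=date(2021, 3, 1),
    diagnosis=Diagnosis.MDS,
    **kw,
) -> SampleRecord:
    return SampleRecord(
        sample_id=sample_id, patient_id=patient_id, tissue=tissue,
        draw_date=draw_date, diagnosis=diagnosis, **kw,
    )


def make_pair(pair_id="PR1", patient_id="P1", days_apart=0, **record_kw) -> SamplePair:
    bm = make_record(f"{pair_id}-bm", patient_id, Tissue.BM, **record_kw)
    pb_kw = dict(record_kw)
    pb_date = bm.draw_date
    if days_apart:
        from datetime import timedelta

        pb_date = bm.draw_date + timedelta(days=days_apart)
    pb_kw["draw_date"] = pb_date
    pb = make_record(f"{pair_id}-pb", patient_id, Tissue.PB, **pb_kw)
    return SamplePair(pair_id=pair_id, patient_id=patient_id, bm=bm, pb=pb,
                      days_apart=days_apart)


@pytest.fixture
def helpers():
    class H:
        call = staticmethod(make_call)
        record = staticmethod(make_record)
        pair = staticmethod(make_pair)

    return H


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient simulated cohort shared by pipeline-level tests."""
    from pairedconcord import SimulationParams, simulate_cohort

    return simulate_cohort(SimulationParams(n_patients=60, seed=11))
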