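"""Shared fixtures.

The heavy fixture is ``cohort_bundle``: ten independent default-condition
cohorts (simulation + consensus + decomposition), shared by the ordering,
duplicate-intersection and truth-audit tests so the expensive Monte-Carlo
work happens once per session.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from ccfnoise.consensus import collapse, filter_by_family_size
from ccfnoise.decompose import DecompositionResult, run_decomposition
from ccfnoise.errors import build_pileup, parse_positions
from ccfnoise.pipeline import simulate_cohort_libraries
from ccfnoise.records import AlignedRead, NraRecord
from ccfnoise.simulate import CohortTruth, SimConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

BUNDLE_SEEDS = tuple(range(101, 111))


def make_read(
    start: int = 0,
    seq: str = "ACGT",
    umi: str = "AAAAAAAA",
    qual: int = 37,
    mate: int | None = None,
    sample: str = "S1",
    replicate: str = "R1",
    strand: str = "top",
    mq: int = 60,
    tags=frozenset(),
) -> AlignedRead:
    if mate is None:
        mate = start + len(seq) - 1
    return AlignedRead(
        sample_id=sample,
        replicate_id=replicate,
        chrom="ref",
        unclipped_start=start,
        mate_unclipped_start=mate,
        strand_of_origin=strand,
        umi=umi,
        sequence=seq,
        base_qualities=np.full(len(seq), qual, dtype=np.uint8),
        mapping_quality=mq,
        truth_tags=frozenset(tags),
    )


@pytest.fixture
def read_factory():
    return make_read


@dataclass
class CohortRun:
    """One seed's full decomposition run on the default study conditions."""

    config: SimConfig
    truth: CohortTruth
    result: DecompositionResult                 # corrections {C,P,D}, fs (1,2,3)
    result_seqdup: DecompositionResult          # corrections {D} vs sequencing duplicate
    nras_r1: dict[str, list[NraRecord]]         # per-sample fs>=2 NRA tracks, replicate 1
    nras_r2: dict[str, list[NraRecord]]         # replicate 2


def build_cohort_run(seed: int, family_sizes=(1, 2, 3)) -> CohortRun:
    cfg = SimConfig(seed=seed)
    regions = cfg.target_regions()
    cohort = simulate_cohort_libraries(cfg, include_seqdup=True)
    ccf1 = {s: collapse(r, "duplex") for s, r in cohort.ccf_r1.items()}
    ccf2 = {s: collapse(r, "duplex") for s, r in cohort.ccf_r2.items()}
    buffy = {s: collapse(r, "duplex") for s, r in cohort.buffy.items()}
    seqdup = {s: collapse(r, "duplex") for s, r in cohort.seqdup.items()}
    result = run_decomposition(
        ccf1,
        cohort.truth.reference,
        duplicate_consensus=ccf2,
        buffy_consensus=buffy,
        regions=regions,
        family_sizes=family_sizes,
    )
    result_seqdup = run_decomposition(
        ccf1,
        cohort.truth.reference,
        duplicate_consensus=seqdup,
        regions=regions,
        corrections=frozenset("D"),
        family_sizes=(2,),
    )
    nras = {}
    for label, cons in (("r1", ccf1), ("r2", ccf2)):
        nras[label] = {
            s: parse_positions(
                build_pileup(
                    filter_by_family_size(c, 2), cohort.truth.reference, regions
                )
            )
            for s, c in cons.items()
        }
    return CohortRun(
        config=cfg,
        truth=cohort.truth,
        result=result,
        result_seqdup=result_seqdup,
        nras_r1=nras["r1"],
        nras_r2=nras["r2"],
    )


@pytest.fixture(scope="session")
def cohort_bundle() -> list[CohortRun]:
    return [build_cohort_run(seed) for seed in BUNDLE_SEEDS]
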