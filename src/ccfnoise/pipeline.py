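"""End-to-end reproduction driver.

One invocation regenerates the full synthetic-cohort result set: simulate the
cohort (ccfDNA libraries, full sample duplicates, sequencing duplicates,
matched buffy coat), collapse UMI families, estimate error per family-size
threshold and correction subset, and summarise substitution spectra and
allele-frequency bins. Every output table is plain text and carries a
manifest recording the seed and a hash of the configuration, so a rerun with
the same seed is byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import io as cio
from .consensus import collapse
from .decompose import (
    DecompositionResult,
    af_bins,
    run_decomposition,
    spectrum,
    truth_label_audit,
)
from .records import AlignedRead, NraRecord
from .simulate import CohortTruth, SimConfig, generate_cohort, simulate_library

__all__ = ["RunConfig", "PipelineResult", "simulate_cohort_libraries", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    family_sizes: tuple[int, ...] = (1, 2, 3)
    corrections: str = "CPD"
    relatedness_k: int | None = None
    duplex_step: int = 1
    include_seqdup: bool = False
    out_dir: str | Path = "ccfnoise_run"

    def __post_init__(self) -> None:
        if any(fs < 1 for fs in self.family_sizes):
            raise ValueError("family-size sweep values must be >= 1")
        if self.duplex_step not in (1, 2):
            raise ValueError("duplex_step must be 1 or 2")

    def config_hash(self) -> str:
        blob = yaml.safe_dump(
            {
                "sim": self.sim.to_dict(),
                "family_sizes": list(self.family_sizes),
                "corrections": self.corrections,
                "relatedness_k": self.relatedness_k,
                "duplex_step": self.duplex_step,
                "include_seqdup": self.include_seqdup,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Cohort:
    """Simulated cohort: truth plus per-sample raw read sets."""

    truth: CohortTruth
    ccf_r1: Mapping[str, list[AlignedRead]]
    ccf_r2: Mapping[str, list[AlignedRead]]
    buffy: Mapping[str, list[AlignedRead]]
    seqdup: Mapping[str, list[AlignedRead]] | None = None


def simulate_cohort_libraries(
    config: SimConfig, *, include_seqdup: bool = False
) -> Cohort:
    """Simulate every library the decomposition needs.

    Per sample: two independently prepared ccfDNA libraries (R1 and the full
    sample duplicate R2), a matched buffy-coat library, and optionally a
    sequencing duplicate of R1 (same post-PCR pool, fresh read sampling).
    """
    truth = generate_cohort(config)
    ccf_r1: dict[str, list[AlignedRead]] = {}
    ccf_r2: dict[str, list[AlignedRead]] = {}
    buffy: dict[str, list[AlignedRead]] = {}
    seqdup: dict[str, list[AlignedRead]] = {}
    for s in truth.sample_ids:
        ccf_r1[s] = simulate_library(truth, s, "R1", config, kind="ccf")
        ccf_r2[s] = simulate_library(truth, s, "R2", config, kind="ccf")
        buffy[s] = simulate_library(truth, s, "B1", config, kind="buffy")
        if include_seqdup:
            seqdup[s] = simulate_library(
                truth, s, "R1SD", config, kind="ccf",
                mode="seqdup", base_replicate_id="R1",
            )
    return Cohort(
        truth=truth,
        ccf_r1=ccf_r1,
        ccf_r2=ccf_r2,
        buffy=buffy,
        seqdup=seqdup if include_seqdup else None,
    )


@dataclass
class PipelineResult:
    """Everything one pipeline invocation computed, plus where it was written."""

    cohort: Cohort
    decomposition: DecompositionResult
    baseline_nras: dict[str, list[NraRecord]]
    out_dir: Path
    manifest: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run simulate -> consensus -> error estimation -> decomposition -> spectra."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    scheme = sim.adapter_scheme

    logger.info("simulating cohort (%d samples)", sim.n_samples)
    cohort = simulate_cohort_libraries(sim, include_seqdup=config.include_seqdup)
    reference = cohort.truth.reference

    def _collapse(reads_by_sample):
        return {
            s: collapse(reads, scheme, duplex_step=config.duplex_step)
            for s, reads in reads_by_sample.items()
        }

    logger.info("collapsing UMI families")
    ccf1 = _collapse(cohort.ccf_r1)
    ccf2 = _collapse(cohort.ccf_r2)
    bf = _collapse(cohort.buffy)

    logger.info("running decomposition (corrections=%s)", config.corrections)
    result = run_decomposition(
        ccf1,
        reference,
        duplicate_consensus=ccf2 if "D" in config.corrections else None,
        buffy_consensus=bf if "C" in config.corrections else None,
        regions=sim.target_regions(),
        corrections=frozenset(config.corrections),
        family_sizes=config.family_sizes,
        relatedness_k=config.relatedness_k,
    )

    # Baseline per-sample NRA tracks at family size >= 2 for spectra / AF bins.
    fs_ref = 2 if 2 in config.family_sizes else config.family_sizes[0]
    baseline_nras = {
        s: [
            NraRecord(
                chrom=rec.chrom, position=rec.position, ref_base=rec.ref_base,
                alt_base=rec.alt_base, alt_count=rec.alt_count, depth=rec.depth,
                tags=rec.tags,
            )
            for rec in result.survivors[(fs_ref, frozenset())]
            if rec.sample_id == s
        ]
        for s in result.sample_ids
    }

    # --- write the artifact bundle
    cio.write_fasta(reference, out_dir / "reference.fa")
    cio.save_config(sim, out_dir / "sim_config.yaml")
    ledger = result.to_frame()
    ledger.to_csv(out_dir / "error_ledger.tsv", sep="\t", index=False,
                  float_format="%.6e")
    all_baseline = [r for recs in baseline_nras.values() for r in recs]
    spectrum(all_baseline).to_csv(out_dir / "spectrum_baseline.tsv", sep="\t",
                                  index=False, float_format="%.4f")
    af_bins(all_baseline).to_csv(out_dir / "af_bins_baseline.tsv", sep="\t",
                                 header=True, float_format="%.6f")
    for s, recs in baseline_nras.items():
        cio.write_nra_bed(recs, out_dir / f"nra_{s}.bed")
    if result.patterned is not None:
        with open(out_dir / "patterned_positions.bed", "w") as fh:
            for chrom, pos in sorted(result.patterned.positions):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\tpatterned\t0\n")
    if result.chip is not None:
        with open(out_dir / "chip_catalog.tsv", "w") as fh:
            fh.write("sample\tchrom\tposition\talt\n")
            for s, chrom, pos, alt in sorted(result.chip.variants):
                fh.write(f"{s}\t{chrom}\t{pos}\t{alt}\n")

    full = frozenset(config.corrections)
    audit = truth_label_audit(result.survivors.get((fs_ref, full), []))
    manifest = {
        "seed": sim.seed,
        "config_hash": config.config_hash(),
        "n_samples": sim.n_samples,
        "family_sizes": list(config.family_sizes),
        "corrections": config.corrections,
        "truth_audit_fraction": None if audit != audit else round(audit, 6),
        "outputs": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        cohort=cohort,
        decomposition=result,
        baseline_nras=baseline_nras,
        out_dir=out_dir,
        manifest=manifest,
    )
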