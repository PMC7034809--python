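"""Plain-text interchange formats.

All intermediate artifacts are text (FASTA, SAM, BED, TSV, YAML) so pipeline
outputs diff cleanly. Simulated read pairs are exported as single fused SAM
records spanning the template fragment: POS is the leftmost covered base
(1-based in SAM, 0-based internally), the UMI rides as the last
colon-delimited read-name field (with an ``RX`` tag mirror), and the
simulator's bookkeeping — unclipped starts, strand of origin, sample,
replicate, truth tags — rides in optional tags so a write/read round trip is
lossless.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pysam
import yaml
from pyfaidx import Fasta

from .records import (
    AlignedRead,
    ConsensusRead,
    ErrorReport,
    NraRecord,
    decode_tags,
    encode_tags,
)
from .simulate import SimConfig

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_alignments",
    "read_alignments",
    "write_consensus",
    "write_nra_bed",
    "read_nra_bed",
    "write_error_reports",
    "save_config",
    "load_config",
]

logger = logging.getLogger(__name__)

_FASTA_WIDTH = 70


def write_fasta(reference: str, path: str | Path, name: str = "ref") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(reference), _FASTA_WIDTH):
            fh.write(reference[i:i + _FASTA_WIDTH] + "\n")
    return path


def read_fasta(path: str | Path, name: str | None = None) -> str:
    fa = Fasta(str(path))
    key = name if name is not None else list(fa.keys())[0]
    return str(fa[key][:])


def _header(reference_length: int, chrom: str) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": int(reference_length)}],
    }


def write_alignments(
    reads: list[AlignedRead],
    path: str | Path,
    reference_length: int,
    chrom: str = "ref",
) -> Path:
    """Write simulated reads as a coordinate-sorted SAM file."""
    path = Path(path)
    ordered = sorted(
        enumerate(reads), key=lambda iv: (iv[1].ref_start, iv[0])
    )
    with pysam.AlignmentFile(str(path), "wh", header=_header(reference_length, chrom)) as out:
        for i, r in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{r.sample_id}:{r.replicate_id}:{i}:{r.umi}"
            a.flag = 0
            a.reference_id = 0
            a.reference_start = r.ref_start
            a.mapping_quality = r.mapping_quality
            a.cigarstring = f"{len(r.sequence)}M"
            a.query_sequence = r.sequence
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.base_qualities)
            )
            a.set_tag("RX", r.umi)
            a.set_tag("us", r.unclipped_start)
            a.set_tag("ms", r.mate_unclipped_start)
            a.set_tag("so", "T" if r.strand_of_origin == "top" else "B")
            a.set_tag("sm", r.sample_id)
            a.set_tag("rp", r.replicate_id)
            if r.truth_tags:
                a.set_tag("tt", encode_tags(r.truth_tags))
            out.write(a)
    return path


def read_alignments(path: str | Path, umi_tag: str | None = None) -> list[AlignedRead]:
    """Read a coordinate-sorted SAM back into aligned-read records.

    The UMI is parsed from the last colon-delimited read-name field, or from
    ``umi_tag`` when given. Malformed records are skipped and reported with
    their line numbers (header lines included in the numbering).
    """
    reads: list[AlignedRead] = []
    bad: list[int] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        n_header = str(fh.header).count("\n")
        for i, a in enumerate(fh):
            line_no = n_header + i + 1
            try:
                if umi_tag is not None and a.has_tag(umi_tag):
                    umi = str(a.get_tag(umi_tag))
                else:
                    umi = a.query_name.rsplit(":", 1)[-1]
                us = int(a.get_tag("us")) if a.has_tag("us") else a.reference_start
                ms = int(a.get_tag("ms")) if a.has_tag("ms") else (
                    a.next_reference_start if a.next_reference_start >= 0 else us
                )
                strand = "top"
                if a.has_tag("so"):
                    strand = "top" if a.get_tag("so") == "T" else "bottom"
                tags = frozenset()
                if a.has_tag("tt"):
                    tags = decode_tags(str(a.get_tag("tt")))
                reads.append(
                    AlignedRead(
                        sample_id=str(a.get_tag("sm")) if a.has_tag("sm") else "",
                        replicate_id=str(a.get_tag("rp")) if a.has_tag("rp") else "",
                        chrom=a.reference_name or "ref",
                        unclipped_start=us,
                        mate_unclipped_start=ms,
                        strand_of_origin=strand,
                        umi=umi,
                        sequence=a.query_sequence or "",
                        base_qualities=np.array(a.query_qualities or [], dtype=np.uint8),
                        mapping_quality=a.mapping_quality,
                        truth_tags=tags,
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                bad.append(line_no)
                logger.warning("skipping malformed SAM record at line %d: %s", line_no, exc)
    if bad:
        logger.warning("%d malformed records skipped (lines %s)", len(bad), bad)
    return reads


def write_consensus(
    reads: list[ConsensusRead],
    path: str | Path,
    reference_length: int,
    chrom: str = "ref",
) -> Path:
    """Write consensus reads as SAM with the family size in the ``fs`` tag."""
    path = Path(path)
    ordered = sorted(enumerate(reads), key=lambda iv: (iv[1].ref_start, iv[0]))
    with pysam.AlignmentFile(str(path), "wh", header=_header(reference_length, chrom)) as out:
        for i, r in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{r.sample_id}:{r.replicate_id}:consensus:{i}:{r.umi}"
            a.flag = 0
            a.reference_id = 0
            a.reference_start = r.ref_start
            a.mapping_quality = r.mapping_quality
            a.cigarstring = f"{len(r.sequence)}M"
            a.query_sequence = r.sequence
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.base_qualities)
            )
            a.set_tag("RX", r.umi)
            a.set_tag("fs", r.family_size)
            a.set_tag("ds", r.duplex_step)
            a.set_tag("us", r.unclipped_start)
            a.set_tag("ms", r.mate_unclipped_start)
            out.write(a)
    return path


def write_nra_bed(records: list[NraRecord], path: str | Path) -> Path:
    """Write NRA records as 5-column BED: chrom, start, end, name(AF), score(depth).

    Coordinates are 0-based half-open, one base per record.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda x: (x.chrom, x.position, x.alt_base)):
            fh.write(
                f"{r.chrom}\t{r.position}\t{r.position + 1}\t{r.af:.6g}\t{r.depth}\n"
            )
    return path


def read_nra_bed(path: str | Path) -> list[tuple[str, int, float, int]]:
    """Read the 5-column NRA BED back as (chrom, position, af, depth) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, af, depth = line.rstrip("\n").split("\t")
            out.append((chrom, int(start), float(af), int(depth)))
    return out


def write_error_reports(
    reports: dict[str, ErrorReport], path: str | Path
) -> Path:
    """Write a set of labelled error reports as a TSV table."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "label\tfamily_size\tcorrections\tnra_observations\t"
            "quality_bases\tpassing_positions\terror_rate\n"
        )
        for label, r in sorted(reports.items()):
            rate = "nan" if r.total_quality_bases == 0 else f"{r.error_rate:.6e}"
            fh.write(
                f"{label}\t{r.family_size_threshold}\t"
                f"{''.join(sorted(r.correction_labels)) or '-'}\t"
                f"{r.total_nra_observations}\t{r.total_quality_bases}\t"
                f"{r.n_passing_positions}\t{rate}\n"
            )
    return path


def save_config(config: SimConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path


def load_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh))
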