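"""Base-level error estimation from consensus alignments.

Two estimators operate on a quality-filtered pileup (bases >= Q20 from reads
with mapping quality >= MQ20, restricted to target regions):

* :func:`estimate_error_rates` — the region-gated global estimator. It slides
  over every run of seven adjacent covered positions; a window passes only if
  all seven columns have depth >= 100, no indel evidence, and every
  nonreference allele frequency <= 0.4 (which excludes heterozygous and
  homozygous germline variants). Only the centre base of each passing window
  is tabulated, and the error rate is nonreference centre observations over
  all centre observations.
* :func:`parse_positions` — the per-position track. Every position with
  depth >= 100 and no allele above AF 0.4 emits one record per observed
  nonreference allele, suitable for BED export and for all the set algebra in
  the decomposition module.

Windows overlap (they slide by one position), so each interior position
serves as the centre of exactly one window — maximising tabulated centres and
matching per-exonic-base reporting.
"""
from __future__ import annotations

import numpy as np

from .records import (
    ASCII_TO_CODE,
    BASES,
    ConsensusRead,
    ErrorReport,
    NraRecord,
    PileupColumn,
    seq_to_bytes,
)

__all__ = [
    "build_pileup",
    "estimate_error_rates",
    "parse_positions",
    "gc_context",
    "passing_center_indices",
]

MIN_BASE_QUALITY = 20
MIN_MAPPING_QUALITY = 20
DEFAULT_MIN_DEPTH = 100
DEFAULT_MAX_AF = 0.4
DEFAULT_WINDOW = 7
GC_FLANK = 10


def build_pileup(
    reads: list[ConsensusRead],
    reference: str,
    regions: list[tuple[int, int]] | None = None,
    *,
    min_base_quality: int = MIN_BASE_QUALITY,
    min_mapping_quality: int = MIN_MAPPING_QUALITY,
) -> list[PileupColumn]:
    """Stack quality-filtered base observations per reference position.

    ``regions`` are 0-based half-open target intervals (the exon analogue);
    ``None`` means the whole reference. N bases carry quality zero and are
    excluded by the quality gate. Columns are emitted, sorted by position,
    only where at least one observation survives. Truth-tag provenance is
    accumulated per (position, alt): a tag kind is attributed only when the
    contributing read actually shows the tagged alt at that position.
    """
    L = len(reference)
    if regions is None:
        regions = [(0, L)]
    in_region = np.zeros(L, dtype=bool)
    for start, end in regions:
        if not (0 <= start < end <= L):
            raise ValueError(f"region ({start}, {end}) outside reference [0, {L})")
        in_region[start:end] = True

    counts = np.zeros((4, L), dtype=np.int64)
    tag_map: dict[int, dict[str, set[str]]] = {}
    for r in reads:
        if r.mapping_quality < min_mapping_quality:
            continue
        rs = r.ref_start
        codes = ASCII_TO_CODE[seq_to_bytes(r.sequence)]
        pos = np.arange(rs, rs + codes.size)
        ok = (codes < 4) & (r.base_qualities >= min_base_quality) & in_region[pos]
        np.add.at(counts, (codes[ok], pos[ok]), 1)
        for kind, p, alt in r.truth_tags:
            off = p - rs
            if 0 <= off < codes.size and ok[off] and r.sequence[off] == alt:
                tag_map.setdefault(p, {}).setdefault(alt, set()).add(kind)

    chrom = reads[0].chrom if reads else "ref"
    columns: list[PileupColumn] = []
    covered = np.flatnonzero(counts.sum(axis=0) > 0)
    for p in covered:
        p = int(p)
        base_counts = {
            BASES[b]: int(counts[b, p]) for b in range(4) if counts[b, p] > 0
        }
        alt_tags = {
            alt: frozenset(kinds)
            for alt, kinds in tag_map.get(p, {}).items()
            if alt in base_counts
        }
        columns.append(
            PileupColumn(
                chrom=chrom,
                position=p,
                ref_base=reference[p],
                base_counts=base_counts,
                alt_tags=alt_tags,
            )
        )
    return columns


def _column_passes(col: PileupColumn, min_depth: int, max_af: float) -> bool:
    d = col.depth
    if d < min_depth or col.indel_evidence:
        return False
    for base, count in col.base_counts.items():
        if base != col.ref_base and count / d > max_af:
            return False
    return True


def passing_center_indices(
    pileup: list[PileupColumn],
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_af: float = DEFAULT_MAX_AF,
    window: int = DEFAULT_WINDOW,
) -> list[int]:
    """Indices into ``pileup`` of centre columns of passing 7-base regions.

    A region is ``window`` columns at consecutive reference positions, all of
    which pass the depth / indel / allele-frequency gates.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd number")
    ok = np.array([_column_passes(c, min_depth, max_af) for c in pileup], dtype=bool)
    pos = np.array([c.position for c in pileup])
    chroms = [c.chrom for c in pileup]
    half = window // 2
    centers = []
    n = len(pileup)
    for i in range(n - window + 1):
        j = i + window - 1
        if chroms[i] != chroms[j] or pos[j] - pos[i] != window - 1:
            continue
        if ok[i:j + 1].all():
            centers.append(i + half)
    return centers


def estimate_error_rates(
    pileup: list[PileupColumn],
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_af: float = DEFAULT_MAX_AF,
    window: int = DEFAULT_WINDOW,
    *,
    family_size_threshold: int = 1,
    correction_labels: frozenset[str] = frozenset(),
) -> ErrorReport:
    """Region-gated global error rate over passing-window centre bases.

    An empty or fully gated pileup yields a report with zero denominators,
    whose ``error_rate`` is NaN.
    """
    centers = passing_center_indices(pileup, min_depth, max_af, window)
    nra = 0
    total = 0
    for i in centers:
        col = pileup[i]
        d = col.depth
        total += d
        nra += d - col.base_counts.get(col.ref_base, 0)
    return ErrorReport(
        total_nra_observations=nra,
        total_quality_bases=total,
        n_passing_positions=len(centers),
        family_size_threshold=family_size_threshold,
        correction_labels=correction_labels,
    )


def gc_context(reference: str, position: int, flank: int = GC_FLANK) -> float:
    """G+C fraction of the +/- ``flank`` bp window around ``position``.

    The window is truncated at contig ends; use :func:`gc_context_window` to
    learn whether truncation occurred.
    """
    frac, _ = gc_context_window(reference, position, flank)
    return frac


def gc_context_window(
    reference: str, position: int, flank: int = GC_FLANK
) -> tuple[float, bool]:
    """As :func:`gc_context`, additionally flagging end truncation."""
    if not 0 <= position < len(reference):
        raise ValueError(f"position {position} outside reference")
    lo = max(0, position - flank)
    hi = min(len(reference), position + flank + 1)
    window = reference[lo:hi]
    gc = sum(1 for b in window if b in "GC")
    return gc / len(window), len(window) < 2 * flank + 1


def parse_positions(
    pileup: list[PileupColumn],
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_af: float = DEFAULT_MAX_AF,
    *,
    reference: str | None = None,
    gc_flank: int = GC_FLANK,
) -> list[NraRecord]:
    """Per-position nonreference-allele records (the BED track contents).

    One record per observed alt allele at each position with depth >=
    ``min_depth``; positions showing any allele above ``max_af`` (heterozygous
    or homozygous variants) are ignored entirely. When ``reference`` is given,
    each record carries the local GC fraction of the +/- ``gc_flank`` window.
    """
    records: list[NraRecord] = []
    for col in pileup:
        d = col.depth
        if d < min_depth:
            continue
        alts = [(b, c) for b, c in col.base_counts.items() if b != col.ref_base]
        if any(c / d > max_af for _, c in alts):
            continue
        for base, count in sorted(alts):
            records.append(
                NraRecord(
                    chrom=col.chrom,
                    position=col.position,
                    ref_base=col.ref_base,
                    alt_base=base,
                    alt_count=count,
                    depth=d,
                    gc_context=(
                        gc_context(reference, col.position, gc_flank)
                        if reference is not None else None
                    ),
                    tags=col.alt_tags.get(base, frozenset()),
                )
            )
    return records
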