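"""UMI family grouping and consensus calling.

Reads are grouped into families by exact identity of
(chrom, unclipped start, mate unclipped start, UMI) — no UMI mismatch
tolerance, so single-base UMI read errors split families, deliberately
mirroring the exact-matching workflow this package models. Each family is
collapsed column-by-column: a base with concordance strictly greater than
0.66 becomes the consensus base carrying the maximum quality observed for it
among the members that have it; anything else (ties, sub-threshold
majorities) becomes N with quality zero, which the downstream Q20 gate then
excludes from pileups.

For duplex adapters, consensus is a two-step process. Step 1 collapses each
strand family separately (the rotated 3+3 UMIs keep the two strands of one
molecule apart). Step 2 finds strand pairs — reads whose UMI halves are
mutual rotations at swapped start/mate coordinates — and collapses the pair
with the same rule, so any disagreement between the strands yields N. This is
what removes first-cycle PCR errors, which by construction reach only one
strand family.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .records import (
    STEP1,
    STEP2,
    AlignedRead,
    ConsensusRead,
    Family,
    seq_to_bytes,
)

__all__ = [
    "group_families",
    "call_consensus",
    "pair_duplex_strands",
    "filter_by_family_size",
    "DuplexPairingResult",
]

logger = logging.getLogger(__name__)

CONCORDANCE_THRESHOLD = 0.66


def group_families(
    reads: list[AlignedRead],
    scheme: str | None = None,
    *,
    drop_missing_umi: bool = False,
) -> list[Family]:
    """Partition reads into families keyed by coordinates + exact UMI.

    Every read lands in exactly one family (partition property). Reads with a
    missing UMI are rejected: a ``ValueError`` reporting the count by default,
    or dropped with a logged count when ``drop_missing_umi`` is set.
    """
    if scheme is not None and scheme not in ("singleton", "duplex"):
        raise ValueError(f"unknown scheme {scheme!r}")
    missing = sum(1 for r in reads if not r.umi)
    if missing:
        if not drop_missing_umi:
            raise ValueError(f"{missing} reads have no UMI")
        logger.warning("dropping %d reads with no UMI", missing)
    buckets: dict[tuple, list[AlignedRead]] = {}
    for r in reads:
        if not r.umi:
            continue
        buckets.setdefault(r.family_key, []).append(r)
    return [Family(key=k, members=v) for k, v in buckets.items()]


def _column_consensus(bases: list[str], quals: list[int], threshold: float):
    """Apply the >threshold concordance rule to one column of observations."""
    counts = Counter(bases)
    base, count = counts.most_common(1)[0]
    if count / len(bases) > threshold:
        q = max(q for b, q in zip(bases, quals) if b == base)
        return base, (0 if base == "N" else q)
    return "N", 0


def call_consensus(
    family: Family,
    concordance_threshold: float = CONCORDANCE_THRESHOLD,
) -> ConsensusRead:
    """Collapse one family to a consensus read.

    Members may span unequal lengths (clipping differences in real data): a
    column's denominator is the number of members covering it, and positions
    covered by no member are clipped. The simulator always emits equal spans,
    so that path is exercised only by hand-built fixtures.
    """
    if not family.members:
        raise ValueError("cannot call consensus on an empty family")
    members = family.members
    n = len(members)
    span = max(len(m.sequence) for m in members)
    first = members[0]

    lens = [len(m.sequence) for m in members]
    if min(lens) == span:
        # Equal spans: vectorised fast path.
        seqs = np.stack([seq_to_bytes(m.sequence) for m in members])
        quals = np.stack([m.base_qualities for m in members])
        out_seq = seqs[0].copy()
        out_qual = np.max(quals, axis=0)           # valid where all members agree
        diff_cols = np.flatnonzero((seqs != seqs[0]).any(axis=0))
        for c in diff_cols:
            base, q = _column_consensus(
                [chr(b) for b in seqs[:, c]], list(quals[:, c]), concordance_threshold
            )
            out_seq[c] = ord(base)
            out_qual[c] = q
        # N observations never carry quality.
        out_qual[out_seq == ord("N")] = 0
        sequence = out_seq.tobytes().decode("ascii")
        qual = out_qual.astype(np.uint8)
    else:
        chars = []
        qvals = []
        for c in range(span):
            bases = [m.sequence[c] for m in members if len(m.sequence) > c]
            qs = [int(m.base_qualities[c]) for m in members if len(m.sequence) > c]
            base, q = _column_consensus(bases, qs, concordance_threshold)
            chars.append(base)
            qvals.append(q)
        sequence = "".join(chars)
        qual = np.array(qvals, dtype=np.uint8)

    tags = frozenset().union(*(m.truth_tags for m in members))
    return ConsensusRead(
        chrom=first.chrom,
        unclipped_start=first.unclipped_start,
        mate_unclipped_start=first.mate_unclipped_start,
        umi=first.umi,
        ref_start=first.ref_start,
        sequence=sequence,
        base_qualities=qual,
        family_size=n,
        duplex_step=STEP1,
        sample_id=first.sample_id,
        replicate_id=first.replicate_id,
        mapping_quality=max(m.mapping_quality for m in members),
        truth_tags=tags,
    )


@dataclass
class DuplexPairingResult:
    """Step-2 output plus the strand-pairing bookkeeping the assay reports."""

    reads: list[ConsensusRead]
    n_input: int
    n_paired: int          # step-1 reads that found their rotated partner

    @property
    def fraction_paired(self) -> float:
        return self.n_paired / self.n_input if self.n_input else 0.0


def _rotate(umi: str) -> str:
    half = len(umi) // 2
    return umi[half:] + umi[:half]


def pair_duplex_strands(
    step1: list[ConsensusRead],
    concordance_threshold: float = CONCORDANCE_THRESHOLD,
) -> DuplexPairingResult:
    """Collapse mutually rotated strand pairs into step-2 duplex consensus reads.

    A pair is two step-1 reads whose UMI halves are rotations of each other
    ("abc-def" vs "def-abc") at swapped start/mate coordinates. The two
    sequences are combined with the same >0.66 rule, so two disagreeing base
    calls always give N; an N on one strand is a no-call, letting the other
    strand's base stand. Unpaired reads pass through unchanged. Pairing is
    best-effort and reports the fraction of step-1 reads that found a partner.
    """
    index: dict[tuple, ConsensusRead] = {}
    for r in step1:
        if r.family_key in index:
            raise ValueError(f"duplicate step-1 family key {r.family_key}")
        index[r.family_key] = r
    consumed: set[tuple] = set()
    out: list[ConsensusRead] = []
    n_paired = 0

    for r in sorted(step1, key=lambda x: (x.ref_start, x.umi)):
        key = r.family_key
        if key in consumed:
            continue
        partner_key = (r.chrom, r.mate_unclipped_start, r.unclipped_start,
                       _rotate(r.umi))
        partner = index.get(partner_key)
        if partner is None or partner_key == key or partner_key in consumed:
            consumed.add(key)
            out.append(r)
            continue
        consumed.add(key)
        consumed.add(partner_key)
        n_paired += 2
        a, b = r, partner
        span = max(len(a.sequence), len(b.sequence))
        chars = []
        quals = []
        for c in range(span):
            obs = [
                (m.sequence[c], int(m.base_qualities[c]))
                for m in (a, b)
                if len(m.sequence) > c and m.sequence[c] != "N"
            ]
            if not obs:
                chars.append("N")
                quals.append(0)
                continue
            bases = [o[0] for o in obs]
            qs = [o[1] for o in obs]
            base, count = Counter(bases).most_common(1)[0]
            if count / len(bases) > concordance_threshold:
                chars.append(base)
                quals.append(max(q for bb, q in zip(bases, qs) if bb == base))
            else:
                chars.append("N")
                quals.append(0)
        out.append(
            ConsensusRead(
                chrom=a.chrom,
                unclipped_start=a.unclipped_start,
                mate_unclipped_start=a.mate_unclipped_start,
                umi=min(a.umi, _rotate(a.umi)),
                ref_start=a.ref_start,
                sequence="".join(chars),
                base_qualities=np.array(quals, dtype=np.uint8),
                family_size=a.family_size + b.family_size,
                duplex_step=STEP2,
                sample_id=a.sample_id,
                replicate_id=a.replicate_id,
                mapping_quality=max(a.mapping_quality, b.mapping_quality),
                truth_tags=a.truth_tags | b.truth_tags,
            )
        )
    return DuplexPairingResult(reads=out, n_input=len(step1), n_paired=n_paired)


def filter_by_family_size(
    consensus: list[ConsensusRead], min_size: int
) -> list[ConsensusRead]:
    """Keep consensus reads built from at least ``min_size`` PCR duplicates."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [c for c in consensus if c.family_size >= min_size]


def collapse(
    reads: list[AlignedRead],
    scheme: str,
    *,
    duplex_step: int = 1,
    concordance_threshold: float = CONCORDANCE_THRESHOLD,
    drop_missing_umi: bool = False,
) -> list[ConsensusRead]:
    """Convenience: group + call consensus (+ optional duplex step 2).

    Duplex results default to the step-1 consensus of each strand — strand
    pairing is rare in sparsely sampled real libraries — with step 2 available
    via ``duplex_step=2``.
    """
    families = group_families(reads, scheme, drop_missing_umi=drop_missing_umi)
    step1 = [call_consensus(f, concordance_threshold) for f in families]
    if scheme == "duplex" and duplex_step == 2:
        return pair_duplex_strands(step1, concordance_threshold).reads
    return step1
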