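"""Core record types shared by the simulator, the consensus caller and the estimators.

The unit of analysis throughout is the *base observation*: one quality-filtered
base from one (consensus) read stacked on a reference position. Noise is any
observation that disagrees with the reference (a nonreference allele, NRA).
Reads carry *truth tags* so every NRA seen downstream can be traced back to the
generative event that produced it (an early PCR error, a late PCR error, a
sequencing error, a clonal-hematopoiesis variant, a patterned artifact, or a
spiked true variant).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

BASES = "ACGT"
BASE_SET = frozenset(BASES)

#: The 12 ordered single-base substitution categories (ref>alt).
SUBSTITUTION_TYPES: tuple[str, ...] = tuple(
    f"{r}>{a}" for r in BASES for a in BASES if r != a
)

#: Recognised truth-tag kinds, in provenance order.
TAG_KINDS = (
    "first_cycle_error",   # PCR error during the first copy event of an original strand
    "late_pcr_error",      # PCR error in any later copy event
    "seq_error",           # sequencing-layer substitution
    "true_variant",        # spiked somatic variant (the ctDNA analogue)
    "chip_variant",        # clonal-hematopoiesis variant shared with buffy coat
    "patterned_error",     # recurrent position-specific artifact
)

#: A truth tag: (kind, 0-based reference position, alt base).
TruthTag = tuple[str, int, str]

# ASCII lookup: base byte -> 0..3, everything else (incl. N) -> 255.
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
ASCII_TO_CODE = _LUT
CODE_TO_ASCII = np.frombuffer(BASES.encode(), dtype=np.uint8)


def seq_to_bytes(seq: str) -> np.ndarray:
    """View a base string as a uint8 ASCII array (zero-copy on the encoded bytes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def bytes_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def encode_tags(tags: Iterable[TruthTag]) -> str:
    """Serialise truth tags as 'kind@pos>alt;...' (stable order) for SAM export."""
    return ";".join(f"{k}@{p}>{a}" for k, p, a in sorted(tags))


def decode_tags(text: str) -> frozenset[TruthTag]:
    out = []
    for item in text.split(";"):
        if not item:
            continue
        kind, rest = item.split("@", 1)
        pos, alt = rest.split(">", 1)
        out.append((kind, int(pos), alt))
    return frozenset(out)


@dataclass(eq=False)
class AlignedRead:
    """One placed read-pair member with UMI, sample/replicate and truth annotations.

    Read pairs are represented as a single fused record spanning the whole
    template fragment; ``unclipped_start``/``mate_unclipped_start`` hold the
    unclipped 5' start of the read and of its mate (0-based), which is all the
    family grouping needs. The leftmost covered reference position is
    ``ref_start``.
    """

    sample_id: str
    replicate_id: str
    chrom: str
    unclipped_start: int
    mate_unclipped_start: int
    strand_of_origin: str          # 'top' | 'bottom'
    umi: str
    sequence: str
    base_qualities: np.ndarray     # uint8 Phred scores, same length as sequence
    mapping_quality: int = 60
    truth_tags: frozenset[TruthTag] = frozenset()

    def __post_init__(self) -> None:
        self.base_qualities = np.asarray(self.base_qualities, dtype=np.uint8)
        if len(self.sequence) != len(self.base_qualities):
            raise ValueError("sequence and base_qualities lengths differ")
        if self.strand_of_origin not in ("top", "bottom"):
            raise ValueError(f"bad strand_of_origin {self.strand_of_origin!r}")

    @property
    def ref_start(self) -> int:
        return min(self.unclipped_start, self.mate_unclipped_start)

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.sequence)

    @property
    def family_key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.unclipped_start, self.mate_unclipped_start, self.umi)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignedRead):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.replicate_id == other.replicate_id
            and self.chrom == other.chrom
            and self.unclipped_start == other.unclipped_start
            and self.mate_unclipped_start == other.mate_unclipped_start
            and self.strand_of_origin == other.strand_of_origin
            and self.umi == other.umi
            and self.sequence == other.sequence
            and np.array_equal(self.base_qualities, other.base_qualities)
            and self.mapping_quality == other.mapping_quality
            and self.truth_tags == other.truth_tags
        )


@dataclass
class Family:
    """A group of PCR duplicates sharing (chrom, starts, UMI) exactly."""

    key: tuple[str, int, int, str]
    members: list[AlignedRead]

    @property
    def size(self) -> int:
        return len(self.members)


STEP1 = "step1_single_strand"
STEP2 = "step2_paired"


@dataclass(eq=False)
class ConsensusRead:
    """A collapsed family: per-column majority base or N (quality 0)."""

    chrom: str
    unclipped_start: int
    mate_unclipped_start: int
    umi: str
    ref_start: int
    sequence: str
    base_qualities: np.ndarray
    family_size: int
    duplex_step: str = STEP1
    sample_id: str = ""
    replicate_id: str = ""
    mapping_quality: int = 60
    truth_tags: frozenset[TruthTag] = frozenset()

    def __post_init__(self) -> None:
        self.base_qualities = np.asarray(self.base_qualities, dtype=np.uint8)
        if len(self.sequence) != len(self.base_qualities):
            raise ValueError("sequence and base_qualities lengths differ")
        if self.duplex_step not in (STEP1, STEP2):
            raise ValueError(f"bad duplex_step {self.duplex_step!r}")

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.sequence)

    @property
    def family_key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.unclipped_start, self.mate_unclipped_start, self.umi)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConsensusRead):
            return NotImplemented
        return (
            self.family_key == other.family_key
            and self.ref_start == other.ref_start
            and self.sequence == other.sequence
            and np.array_equal(self.base_qualities, other.base_qualities)
            and self.family_size == other.family_size
            and self.duplex_step == other.duplex_step
        )


@dataclass
class PileupColumn:
    """Per-position stack of quality-filtered base observations.

    ``alt_tags`` carries truth provenance: for every observed base it records
    the set of truth-tag kinds attached, by contributing reads, to that base at
    this position. The simulator never sets ``indel_evidence``; it exists so
    the indel gate of the region-based estimator is a real, testable branch.
    """

    chrom: str
    position: int                  # 0-based
    ref_base: str
    base_counts: dict[str, int]
    indel_evidence: bool = False
    alt_tags: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())

    def alt_af(self, base: str) -> float:
        d = self.depth
        return self.base_counts.get(base, 0) / d if d else 0.0


@dataclass(frozen=True)
class NraRecord:
    """One position's nonreference-allele observation: the unit of all
    downstream set algebra (CHIP filtering, patterning, duplicate intersection).
    """

    chrom: str
    position: int
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int
    gc_context: float | None = None
    tags: frozenset[str] = frozenset()   # truth-tag *kinds* explaining this NRA

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alt equals ref")
        if not (0 < self.alt_count <= self.depth):
            raise ValueError("alt_count must be in (0, depth]")

    @property
    def af(self) -> float:
        return self.alt_count / self.depth

    @property
    def substitution_type(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"

    @property
    def position_key(self) -> tuple[str, int]:
        return (self.chrom, self.position)

    @property
    def allele_key(self) -> tuple[str, int, str]:
        return (self.chrom, self.position, self.alt_base)


@dataclass
class ErrorReport:
    """Error rate plus bookkeeping at one family-size threshold / correction set.

    Correction labels follow the ledger convention used throughout:
    X = duplex adapters, C = CHIP subtraction, P = patterned-position removal,
    D = sample-duplicate intersection.
    """

    total_nra_observations: int
    total_quality_bases: int
    n_passing_positions: int
    family_size_threshold: int = 1
    correction_labels: frozenset[str] = frozenset()

    @property
    def error_rate(self) -> float:
        if self.total_quality_bases == 0:
            return float("nan")     # zero denominator flagged as NaN
        return self.total_nra_observations / self.total_quality_bases


def merge_reports(reports: Iterable[ErrorReport]) -> ErrorReport:
    """Pool several reports (same threshold/labels) into one cohort-level report."""
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to merge")
    first = reports[0]
    return ErrorReport(
        total_nra_observations=sum(r.total_nra_observations for r in reports),
        total_quality_bases=sum(r.total_quality_bases for r in reports),
        n_passing_positions=sum(r.n_passing_positions for r in reports),
        family_size_threshold=first.family_size_threshold,
        correction_labels=first.correction_labels,
    )
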