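"""Stepwise decomposition of residual sequencing noise.

After UMI consensus calling, the remaining nonreference alleles (NRAs) in
ccfDNA come from several channels that can be accounted for one by one:

* **C** — CHIP artifacts: real somatic variants of blood cells, detected in
  matched buffy-coat DNA within the 2-30% allele-frequency window. They are
  sample-specific biology, so the correction subtracts the matching
  (position, alt) observations from that sample's ccfDNA only. Buffy-coat
  NRAs recurring in most samples are reclassified as patterned error, not
  CHIP.
* **P** — patterned error: recurrent position-specific artifacts shared
  across unrelated samples. Positions where at least ``relatedness_k``
  samples show any NRA are removed from the analyzable footprint entirely
  (``relatedness_k = n_samples`` reproduces the "highly patterned" catalog).
* **D** — sample-duplicate intersection: an NRA counts as error only if the
  same position (and by default the same alt allele) also shows an NRA in an
  independently prepared duplicate library. This is what removes stochastic
  early-PCR errors, which never recur across independent library
  preparations.

The corrections commute where they act on disjoint axes (C removes alleles,
P removes positions); D is applied last by construction since it confirms
whatever survives.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DEFAULT_MAX_AF,
    DEFAULT_MIN_DEPTH,
    DEFAULT_WINDOW,
    build_pileup,
    parse_positions,
    passing_center_indices,
)
from .records import (
    SUBSTITUTION_TYPES,
    ConsensusRead,
    ErrorReport,
    NraRecord,
    PileupColumn,
)
from .consensus import filter_by_family_size

__all__ = [
    "ChipVariantSet",
    "PatternedPositionSet",
    "DecompositionResult",
    "detect_chip",
    "patterned_positions",
    "intersect_duplicates",
    "error_reduction",
    "spectrum",
    "af_bins",
    "run_decomposition",
    "truth_label_audit",
]

CHIP_AF_LOW = 0.02
CHIP_AF_HIGH = 0.30
CHIP_RECURRENCE_CUTOFF = 6
CATALOG_FAMILY_SIZE = 2    # CHIP and patterned catalogs are built at family size >= 2


@dataclass
class ChipVariantSet:
    """Per-sample CHIP candidates from buffy coat, after recurrence exclusion."""

    variants: frozenset[tuple[str, str, int, str]]   # (sample, chrom, pos, alt)
    af_low: float = CHIP_AF_LOW
    af_high: float = CHIP_AF_HIGH
    recurrence_cutoff: int = CHIP_RECURRENCE_CUTOFF
    excluded_recurrent: frozenset[tuple[str, int]] = frozenset()   # (chrom, pos)

    def for_sample(self, sample_id: str) -> set[tuple[str, int, str]]:
        return {(c, p, a) for s, c, p, a in self.variants if s == sample_id}


@dataclass
class PatternedPositionSet:
    """Positions whose NRAs recur in at least ``relatedness_k`` samples."""

    positions: frozenset[tuple[str, int]]
    relatedness_k: int

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.positions


def detect_chip(
    buffy_nras: Mapping[str, Sequence[NraRecord]],
    af_low: float = CHIP_AF_LOW,
    af_high: float = CHIP_AF_HIGH,
    recurrence_cutoff: int = CHIP_RECURRENCE_CUTOFF,
) -> ChipVariantSet:
    """Identify CHIP candidates: buffy-coat NRAs within the AF window.

    Positions whose windowed NRAs recur in at least ``recurrence_cutoff``
    samples are excluded from the CHIP set — recurrence across unrelated
    individuals marks a region that is hard to sequence or align (patterned
    error), not clonal hematopoiesis. Recurrence is counted at position level.
    """
    if af_low >= af_high:
        raise ValueError("af_low must be below af_high")
    candidates: dict[str, set[tuple[str, int, str]]] = {}
    position_hits: dict[tuple[str, int], set[str]] = {}
    for sample, records in buffy_nras.items():
        for rec in records:
            if af_low <= rec.af <= af_high:
                candidates.setdefault(sample, set()).add(rec.allele_key)
                position_hits.setdefault(rec.position_key, set()).add(sample)
    recurrent = {
        pos for pos, samples in position_hits.items()
        if len(samples) >= recurrence_cutoff
    }
    variants = frozenset(
        (sample, chrom, pos, alt)
        for sample, keys in candidates.items()
        for chrom, pos, alt in keys
        if (chrom, pos) not in recurrent
    )
    return ChipVariantSet(
        variants=variants,
        af_low=af_low,
        af_high=af_high,
        recurrence_cutoff=recurrence_cutoff,
        excluded_recurrent=frozenset(recurrent),
    )


def patterned_positions(
    ccf_nras: Mapping[str, Sequence[NraRecord]],
    relatedness_k: int,
) -> PatternedPositionSet:
    """Positions with any NRA in at least ``relatedness_k`` samples.

    Presence is position-level (the alt allele identity is ignored): patterned
    error is a property of the locus, not of a particular substitution.
    """
    n_samples = len(ccf_nras)
    if not 1 <= relatedness_k <= max(n_samples, 1):
        raise ValueError(
            f"relatedness_k={relatedness_k} outside [1, {n_samples}]"
        )
    hits: dict[tuple[str, int], set[str]] = {}
    for sample, records in ccf_nras.items():
        for rec in records:
            hits.setdefault(rec.position_key, set()).add(sample)
    return PatternedPositionSet(
        positions=frozenset(
            pos for pos, samples in hits.items() if len(samples) >= relatedness_k
        ),
        relatedness_k=relatedness_k,
    )


def intersect_duplicates(
    nras_a: Sequence[NraRecord],
    nras_b: Sequence[NraRecord],
    match_on_alt: bool = True,
) -> list[NraRecord]:
    """NRAs of replicate A confirmed by replicate B.

    With ``match_on_alt`` (default) confirmation requires the identical alt
    allele at the position; otherwise any NRA at the position confirms.
    """
    if match_on_alt:
        keys_b = {r.allele_key for r in nras_b}
        return [r for r in nras_a if r.allele_key in keys_b]
    keys_b = {r.position_key for r in nras_b}
    return [r for r in nras_a if r.position_key in keys_b]


def error_reduction(baseline: ErrorReport | float, corrected: ErrorReport | float) -> float:
    """Percent error reduction, 100 * (1 - corrected / baseline).

    A zero baseline with nonzero corrected error is undefined and returns NaN;
    zero over zero counts as no change (0%).
    """
    b = baseline.error_rate if isinstance(baseline, ErrorReport) else float(baseline)
    c = corrected.error_rate if isinstance(corrected, ErrorReport) else float(corrected)
    if b == 0:
        return 0.0 if c == 0 else float("nan")
    return 100.0 * (1.0 - c / b)


def spectrum(nras: Sequence[NraRecord], weight: str = "observations") -> pd.DataFrame:
    """Counts and percentages over the 12 ordered substitution types.

    ``weight='observations'`` sums alt read counts (the assay's count axis);
    ``weight='records'`` counts distinct position/allele records.
    """
    if weight not in ("observations", "records"):
        raise ValueError("weight must be 'observations' or 'records'")
    counts = dict.fromkeys(SUBSTITUTION_TYPES, 0)
    for rec in nras:
        counts[rec.substitution_type] += rec.alt_count if weight == "observations" else 1
    total = sum(counts.values())
    df = pd.DataFrame(
        {
            "substitution": list(SUBSTITUTION_TYPES),
            "count": [counts[t] for t in SUBSTITUTION_TYPES],
        }
    )
    df["percent"] = 100.0 * df["count"] / total if total else 0.0
    return df


def af_bins(
    nras: Sequence[NraRecord],
    edges: Sequence[float] = (0.001, 0.01),
) -> pd.Series:
    """Fraction of NRA records per allele-frequency bin.

    Default bins: AF <= 0.1%, 0.1-1%, and above 1% — the axes on which ~90%
    of post-consensus errors fall below 0.1% AF at production sequencing
    depth. Fractions sum to 1 for nonempty input.
    """
    edges = sorted(edges)
    bounds = [0.0] + list(edges) + [np.inf]
    labels = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        labels.append(f"({lo:g}, {hi:g}]" if np.isfinite(hi) else f"> {lo:g}")
    counts = np.zeros(len(labels), dtype=np.int64)
    for rec in nras:
        for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            if lo < rec.af <= hi:
                counts[i] += 1
                break
    total = counts.sum()
    fractions = counts / total if total else counts.astype(float)
    return pd.Series(fractions, index=labels, name="fraction")


# --------------------------------------------------------------------------
# full decomposition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivorRecord:
    """One NRA that survived a correction set, with its truth provenance."""

    sample_id: str
    chrom: str
    position: int
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int
    tags: frozenset[str]


@dataclass
class DecompositionResult:
    """Error ledger over family-size thresholds and correction subsets."""

    family_sizes: tuple[int, ...]
    corrections: frozenset[str]
    sample_ids: tuple[str, ...]
    reports: dict[tuple[int, frozenset[str]], dict[str, ErrorReport]]
    survivors: dict[tuple[int, frozenset[str]], list[SurvivorRecord]]
    chip: ChipVariantSet | None = None
    patterned: PatternedPositionSet | None = None

    def report(self, family_size: int, labels: Sequence[str] = ()) -> ErrorReport:
        """Cohort-pooled report for one cell of the ledger."""
        cell = self.reports[(family_size, frozenset(labels))]
        from .records import merge_reports
        return merge_reports(list(cell.values()))

    def mean_error(self, family_size: int, labels: Sequence[str] = ()) -> float:
        cell = self.reports[(family_size, frozenset(labels))]
        rates = [r.error_rate for r in cell.values()]
        return float(np.nanmean(rates)) if rates else float("nan")

    def reduction(
        self, family_size: int, labels: Sequence[str]
    ) -> tuple[float, float]:
        """Per-sample percent reduction vs the uncorrected baseline: mean, SD."""
        base = self.reports[(family_size, frozenset())]
        corr = self.reports[(family_size, frozenset(labels))]
        vals = [
            error_reduction(base[s], corr[s])
            for s in self.sample_ids
            if s in base and s in corr
        ]
        arr = np.array(vals, dtype=float)
        mean = float(np.nanmean(arr)) if arr.size else float("nan")
        sd = float(np.nanstd(arr, ddof=1)) if arr.size > 1 else float("nan")
        return mean, sd

    def footprint(self, family_size: int, labels: Sequence[str] = ()) -> float:
        """Mean analyzable positions per sample for one ledger cell."""
        cell = self.reports[(family_size, frozenset(labels))]
        return float(np.mean([r.n_passing_positions for r in cell.values()]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (fs, labels), cell in sorted(
            self.reports.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]))
        ):
            for sample, rep in sorted(cell.items()):
                rows.append(
                    {
                        "sample": sample,
                        "family_size": fs,
                        "corrections": "".join(sorted(labels)) or "-",
                        "nra_observations": rep.total_nra_observations,
                        "quality_bases": rep.total_quality_bases,
                        "error_rate": rep.error_rate,
                        "footprint": rep.n_passing_positions,
                    }
                )
        return pd.DataFrame(rows)


def _powerset(labels: frozenset[str]):
    items = sorted(labels)
    return chain.from_iterable(combinations(items, k) for k in range(len(items) + 1))


@dataclass
class _CenterStats:
    position: int
    depth: int
    ref_base: str
    alt_counts: dict[str, int]
    alt_tags: dict[str, frozenset[str]]


def _center_stats(
    pileup: list[PileupColumn], min_depth: int, max_af: float, window: int
) -> list[_CenterStats]:
    out = []
    for i in passing_center_indices(pileup, min_depth, max_af, window):
        col = pileup[i]
        alts = {b: c for b, c in col.base_counts.items() if b != col.ref_base}
        out.append(
            _CenterStats(
                position=col.position,
                depth=col.depth,
                ref_base=col.ref_base,
                alt_counts=alts,
                alt_tags=col.alt_tags,
            )
        )
    return out


def run_decomposition(
    ccf_consensus: Mapping[str, Sequence[ConsensusRead]],
    reference: str,
    *,
    duplicate_consensus: Mapping[str, Sequence[ConsensusRead]] | None = None,
    buffy_consensus: Mapping[str, Sequence[ConsensusRead]] | None = None,
    regions: list[tuple[int, int]] | None = None,
    corrections: frozenset[str] | str = frozenset({"C", "P", "D"}),
    family_sizes: Sequence[int] = (1, 2, 3),
    relatedness_k: int | None = None,
    chip_af_low: float = CHIP_AF_LOW,
    chip_af_high: float = CHIP_AF_HIGH,
    chip_recurrence_cutoff: int = CHIP_RECURRENCE_CUTOFF,
    match_on_alt: bool = True,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_af: float = DEFAULT_MAX_AF,
    window: int = DEFAULT_WINDOW,
) -> DecompositionResult:
    """Compute the full error ledger over family sizes and correction subsets.

    Inputs are uncollapsed-threshold consensus reads (family size >= 1) per
    sample: the primary ccfDNA libraries, optionally their independent
    duplicates (required for D) and matched buffy-coat libraries (required
    for C). For every family-size threshold and every subset of the requested
    corrections, the estimator tabulates passing-window centre bases and
    applies, in order: C (subtract that sample's CHIP alleles), P (drop
    patterned positions from the footprint), D (keep only alleles confirmed
    in the duplicate at the same threshold).

    The CHIP and patterned catalogs are built once, at family size >= 2, and
    applied across all thresholds.
    """
    corrections = frozenset(corrections)
    unknown = corrections - {"C", "P", "D"}
    if unknown:
        raise ValueError(f"unknown correction labels {sorted(unknown)}")
    if "C" in corrections and buffy_consensus is None:
        raise ValueError("correction C requires buffy_consensus")
    if "D" in corrections and duplicate_consensus is None:
        raise ValueError("correction D requires duplicate_consensus")
    samples = tuple(sorted(ccf_consensus))
    if relatedness_k is None:
        relatedness_k = len(samples)

    def _pileup(reads, fs):
        return build_pileup(
            filter_by_family_size(list(reads), fs), reference, regions
        )

    # --- catalogs at family size >= 2
    chip = None
    if "C" in corrections:
        buffy_nras = {
            s: parse_positions(_pileup(buffy_consensus[s], CATALOG_FAMILY_SIZE),
                               min_depth, max_af)
            for s in samples
        }
        chip = detect_chip(buffy_nras, chip_af_low, chip_af_high,
                           chip_recurrence_cutoff)
    patterned = None
    if "P" in corrections:
        ccf_nras_fs2 = {
            s: parse_positions(_pileup(ccf_consensus[s], CATALOG_FAMILY_SIZE),
                               min_depth, max_af)
            for s in samples
        }
        patterned = patterned_positions(ccf_nras_fs2, relatedness_k)

    reports: dict[tuple[int, frozenset[str]], dict[str, ErrorReport]] = {}
    survivors: dict[tuple[int, frozenset[str]], list[SurvivorRecord]] = {}
    subsets = [frozenset(s) for s in _powerset(corrections)]
    for key in ((fs, sub) for fs in family_sizes for sub in subsets):
        reports[key] = {}
        survivors[key] = []

    for fs in family_sizes:
        for s in samples:
            centers = _center_stats(
                _pileup(ccf_consensus[s], fs), min_depth, max_af, window
            )
            confirmed: set | None = None
            if "D" in corrections:
                dup_records = parse_positions(
                    _pileup(duplicate_consensus[s], fs), min_depth, max_af
                )
                confirmed = (
                    {r.allele_key for r in dup_records}
                    if match_on_alt
                    else {r.position_key for r in dup_records}
                )
            chip_alleles = chip.for_sample(s) if chip is not None else set()
            chrom = "ref"
            for sub in subsets:
                nra = 0
                total = 0
                n_pos = 0
                survs = survivors[(fs, sub)]
                for c in centers:
                    if "P" in sub and (chrom, c.position) in patterned.positions:
                        continue
                    n_pos += 1
                    total += c.depth
                    for alt, count in c.alt_counts.items():
                        if "C" in sub and (chrom, c.position, alt) in chip_alleles:
                            continue
                        if "D" in sub and confirmed is not None:
                            key = (
                                (chrom, c.position, alt)
                                if match_on_alt else (chrom, c.position)
                            )
                            if key not in confirmed:
                                continue
                        nra += count
                        survs.append(
                            SurvivorRecord(
                                sample_id=s,
                                chrom=chrom,
                                position=c.position,
                                ref_base=c.ref_base,
                                alt_base=alt,
                                alt_count=count,
                                depth=c.depth,
                                tags=c.alt_tags.get(alt, frozenset()),
                            )
                        )
                reports[(fs, sub)][s] = ErrorReport(
                    total_nra_observations=nra,
                    total_quality_bases=total,
                    n_passing_positions=n_pos,
                    family_size_threshold=fs,
                    correction_labels=sub,
                )

    return DecompositionResult(
        family_sizes=tuple(family_sizes),
        corrections=corrections,
        sample_ids=samples,
        reports=reports,
        survivors=survivors,
        chip=chip,
        patterned=patterned,
    )


def truth_label_audit(
    survivors: Sequence[SurvivorRecord],
    accepted_kinds: frozenset[str] = frozenset({"first_cycle_error", "true_variant"}),
    weight: str = "observations",
) -> float:
    """Fraction of surviving NRAs explained by the accepted truth kinds.

    The computable analogue of attributing residual post-correction error to
    very early, random PCR errors (plus genuine variants). Weighted by alt
    observations by default — the same unit in which error rates are measured
    — with ``weight='records'`` counting distinct position/allele records
    instead. Returns NaN for an empty survivor list.
    """
    if weight not in ("observations", "records"):
        raise ValueError("weight must be 'observations' or 'records'")
    if not survivors:
        return float("nan")
    if weight == "records":
        return sum(1 for s in survivors if s.tags & accepted_kinds) / len(survivors)
    total = sum(s.alt_count for s in survivors)
    ok = sum(s.alt_count for s in survivors if s.tags & accepted_kinds)
    return ok / total if total else float("nan")
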