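"""Stand-alone assay-level calculators.

Index hopping from unique-dual-index (UDI) demultiplexing count tables,
ligation efficiency from densitometry regions or droplet-digital PCR copy
counts, and the theoretical consensus-depth ceiling set by library input
mass. These are pure arithmetic on count/region tables — the lab instruments
and the demultiplexer that produce those tables are upstream of this package.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from .simulate import UdiPairCounts

__all__ = [
    "DensitometryRegion",
    "DdPcrCounts",
    "UdiRates",
    "index_hopping_rate",
    "udi_rates",
    "ligation_efficiency_densitometry",
    "ligation_efficiency_ddpcr",
    "theoretical_depth",
    "theoretical_depth_rounded",
]

AVOGADRO = 6.02214076e23
BP_WEIGHT_DA = 650.0          # average molecular weight per base pair
HUMAN_GENOME_BP = 3.3e9

REGION_LABELS = ("unligated", "single_end", "dual_end")


@dataclass(frozen=True)
class DensitometryRegion:
    """One electropherogram region: a ligation product class.

    ``concentration`` is mass per volume (any unit — the efficiency is
    invariant to rescaling); ``average_size`` is the region's mean fragment
    length in bp.
    """

    label: str
    concentration: float
    average_size: float

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"label must be one of {REGION_LABELS}")
        if self.average_size <= 0:
            raise ValueError("average_size must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")

    @property
    def molarity(self) -> float:
        return self.concentration / (self.average_size * BP_WEIGHT_DA)


@dataclass(frozen=True)
class DdPcrCounts:
    """Absolute copy counts from the two ddPCR reactions.

    ``internal_copies`` uses insert-specific primers (total template);
    ``flanking_copies`` uses adapter-flanking primers (dual-end ligated
    template only). Flanking above internal is physically unexpected and is
    flagged with a warning, not an error.
    """

    internal_copies: float
    flanking_copies: float

    def __post_init__(self) -> None:
        if self.internal_copies < 0 or self.flanking_copies < 0:
            raise ValueError("copy counts must be >= 0")
        if self.flanking_copies > self.internal_copies:
            warnings.warn(
                "flanking copies exceed internal copies; ligation efficiency "
                "above 100% is physically unexpected",
                stacklevel=2,
            )


@dataclass(frozen=True)
class UdiRates:
    """Lane-level read-fate rates from a UDI count table."""

    hopping: float             # mixed-sample pairs / all lane reads
    sample_associated: float   # correct (diagonal) pairs / all lane reads
    unaffiliated: float        # undetermined / all lane reads


def udi_rates(counts: UdiPairCounts) -> UdiRates:
    """Hopping, sample-associated and unaffiliated rates for one lane.

    The denominator is the total number of reads in the lane: diagonal +
    mixed + undetermined.
    """
    if len(counts.samples) < 2:
        raise ValueError("index hopping needs at least 2 samples in the lane")
    diagonal = set(counts.samples)
    diag = sum(c for pair, c in counts.counts.items() if pair in diagonal)
    mixed = sum(c for pair, c in counts.counts.items() if pair not in diagonal)
    total = diag + mixed + counts.undetermined
    if total == 0:
        raise ValueError("count table holds zero reads")
    return UdiRates(
        hopping=mixed / total,
        sample_associated=diag / total,
        unaffiliated=counts.undetermined / total,
    )


def index_hopping_rate(counts: UdiPairCounts) -> float:
    """Reads mapping unambiguously to mixed-sample UDI pairs over lane total."""
    return udi_rates(counts).hopping


def ligation_efficiency_densitometry(regions: list[DensitometryRegion]) -> float:
    """Percent dual-end ligated product among all ligation products.

    Region molarity is concentration / (average size x 650 Da per bp); the
    efficiency is the dual-end region's molar share of the three regions.
    Requires exactly one region per label.
    """
    by_label = {r.label: r for r in regions}
    if sorted(by_label) != sorted(REGION_LABELS) or len(regions) != 3:
        raise ValueError(f"need exactly one region per label {REGION_LABELS}")
    total = sum(r.molarity for r in regions)
    if total == 0:
        raise ValueError("total molarity is zero")
    return 100.0 * by_label["dual_end"].molarity / total


def ligation_efficiency_ddpcr(counts: DdPcrCounts) -> float:
    """Percent dual-end ligated copies (flanking) among total copies (internal)."""
    if counts.internal_copies == 0:
        raise ValueError("internal copy count is zero")
    return 100.0 * counts.flanking_copies / counts.internal_copies


def theoretical_depth(
    input_mass_ng: float,
    genome_length_bp: float = HUMAN_GENOME_BP,
    bp_weight_da: float = BP_WEIGHT_DA,
) -> float:
    """Theoretical consensus read-depth ceiling for a given library input.

    With lossless ligation and capture, consensus depth cannot exceed the
    number of haploid genome copies in the input:
    mass x N_A / (bp weight x genome length). 10 ng of human DNA gives ~2,800
    copies, which is why consensus depth saturates near 2,800X regardless of
    raw read count.
    """
    if input_mass_ng <= 0 or genome_length_bp <= 0 or bp_weight_da <= 0:
        raise ValueError("all inputs must be positive")
    mass_g = input_mass_ng * 1e-9
    return mass_g * AVOGADRO / (bp_weight_da * genome_length_bp)


def theoretical_depth_rounded(
    input_mass_ng: float,
    genome_length_bp: float = HUMAN_GENOME_BP,
    bp_weight_da: float = BP_WEIGHT_DA,
) -> int:
    """Convenience rounding of :func:`theoretical_depth` to the nearest 100."""
    return int(round(theoretical_depth(input_mass_ng, genome_length_bp, bp_weight_da) / 100.0) * 100)
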