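"""Assay-level calculators: index hopping and ligation efficiency."""
from ccfnoise import (
    DdPcrCounts,
    DensitometryRegion,
    index_hopping_rate,
    ligation_efficiency_ddpcr,
    ligation_efficiency_densitometry,
    simulate_udi_counts,
    udi_rates,
)

# Unique-dual-index demultiplexing: reads landing on mixed-sample UDI pairs.
table = simulate_udi_counts(n_samples=7, reads_per_sample=200_000,
                            hop_rate=2e-4, seed=11)
rates = udi_rates(table)
print(f"simulated lane: {table.total} reads, "
      f"index hopping {100 * rates.hopping:.4f}% "
      f"(sample-associated {100 * rates.sample_associated:.2f}%)")

# Ligation efficiency from densitometry: molar share of dual-end product.
regions = [
    DensitometryRegion("unligated", concentration=2.1, average_size=165),
    DensitometryRegion("single_end", concentration=1.4, average_size=330),
    DensitometryRegion("dual_end", concentration=6.8, average_size=500),
]
print(f"densitometry ligation efficiency: "
      f"{ligation_efficiency_densitometry(regions):.1f}% dual-end product")

# Orthogonal ddPCR estimate: adapter-flanking vs insert-internal copies.
print(f"ddPCR ligation efficiency: "
      f"{ligation_efficiency_ddpcr(DdPcrCounts(internal_copies=1000, flanking_copies=740)):.1f}%")

print(
    "\nHopping rates well below 0.1% mean index misassignment cannot explain "
    "the consensus-level error floor; ligation efficiency sets how much of a "
    "low-input sample ever becomes sequenceable library."
)
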