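"""One library end to end: simulate, collapse UMI families, estimate error.

Shows the error rate before consensus calling and at increasing family-size
thresholds, with the analyzable footprint that survives the depth gates.
"""
from ccfnoise import (
    SimConfig, generate_cohort, simulate_library,
    build_pileup, estimate_error_rates,
)
from ccfnoise.consensus import collapse, filter_by_family_size

cfg = SimConfig(seed=42)
truth = generate_cohort(cfg)
reads = simulate_library(truth, "S1", "R1", cfg)
regions = cfg.target_regions()

raw = estimate_error_rates(build_pileup(reads, truth.reference, regions))
print(f"raw reads        error {100 * raw.error_rate:.4f}%  "
      f"({raw.total_nra_observations} NRA obs / {raw.total_quality_bases} bases)")

consensus = collapse(reads, cfg.adapter_scheme)
for fs in (1, 2, 3):
    kept = filter_by_family_size(consensus, fs)
    rep = estimate_error_rates(
        build_pileup(kept, truth.reference, regions),
        family_size_threshold=fs,
    )
    print(f"family size >={fs}  error {100 * rep.error_rate:.4f}%  "
          f"footprint {rep.n_passing_positions} positions, "
          f"{len(kept)} consensus reads")

print(
    "\nConsensus calling removes the sequencing-error layer almost entirely; "
    "the residual plateau is PCR-borne and patterned noise, which family "
    "size alone cannot eliminate."
)
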