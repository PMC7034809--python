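"""The full noise-decomposition ledger on a seven-sample synthetic cohort.

C = subtract CHIP variants detected in matched buffy coat (2-30% AF window,
    recurrent positions excluded), P = remove positions with NRAs in all
    seven samples (highly patterned error), D = keep only NRAs confirmed in
    an independent library duplicate.
"""
from ccfnoise import SimConfig, run_decomposition, truth_label_audit
from ccfnoise.consensus import collapse
from ccfnoise.pipeline import simulate_cohort_libraries

cfg = SimConfig(seed=7)
cohort = simulate_cohort_libraries(cfg)
ccf1 = {s: collapse(r, "duplex") for s, r in cohort.ccf_r1.items()}
ccf2 = {s: collapse(r, "duplex") for s, r in cohort.ccf_r2.items()}
buffy = {s: collapse(r, "duplex") for s, r in cohort.buffy.items()}

result = run_decomposition(
    ccf1, cohort.truth.reference,
    duplicate_consensus=ccf2, buffy_consensus=buffy,
    regions=cfg.target_regions(), family_sizes=(2,),
)

print("corrections  error(FS>=2)   reduction vs baseline (mean +/- SD)")
for labels in ((), ("C",), ("P",), ("D",), ("C", "P"), ("C", "P", "D")):
    err = result.mean_error(2, labels)
    name = "".join(labels) or "none"
    if labels:
        mean, sd = result.reduction(2, labels)
        print(f"{name:>10}   {100 * err:9.5f}%   {mean:5.1f} +/- {sd:4.1f} %")
    else:
        print(f"{name:>10}   {100 * err:9.5f}%   (baseline)")

survivors = result.survivors[(2, frozenset("CPD"))]
audit = truth_label_audit(survivors)
print(f"\nchip catalog: {len(result.chip.variants)} variants; "
      f"patterned catalog: {len(result.patterned.positions)} positions")
print(f"residual NRAs after C+P+D: {len(survivors)} records, "
      f"{100 * audit:.1f}% of observations tagged early-PCR or true variant")
print(
    "\nDuplicates remove the stochastic early-PCR channel that consensus, "
    "CHIP filtering and patterned-error removal all leave behind; what "
    "survives everything is (by construction) real signal plus rare "
    "coincidental errors."
)
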