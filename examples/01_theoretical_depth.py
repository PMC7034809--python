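"""Consensus read-depth ceiling set by library input mass.

However many raw reads you sequence, consensus depth cannot exceed the
number of template genome copies that went into the library.
"""
from ccfnoise import theoretical_depth, theoretical_depth_rounded

for mass_ng in (1, 10, 30):
    exact = theoretical_depth(mass_ng)
    print(f"{mass_ng:>4} ng input -> {exact:8.1f} haploid genome copies "
          f"(~{theoretical_depth_rounded(mass_ng)}X consensus depth ceiling)")

print(
    "\nA 10 ng ccfDNA input therefore saturates near 2,800X no matter how "
    "deeply the library is sequenced; extra reads only enlarge UMI families."
)
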