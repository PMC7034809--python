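# Methods

## Scope and intent

`ccfnoise` reimplements, at desk scale, the analysis chain used to dissect
the noise floor of deep targeted sequencing of circulating cell-free DNA:
UMI family grouping and consensus calling (singleton and duplex adapter
designs), region-gated base-level error estimation, and a stepwise
decomposition of residual error into clonal-hematopoiesis (CHIP) artifacts,
recurrent patterned error, and stochastic PCR errors removable only with
sample duplicates. All inputs are synthetic: the generator is first-class
code whose defaults define the package's study conditions, and every
simulated error carries a truth label so downstream claims are auditable.

## The generative model

**Molecules and cohort truth.** A cohort is `n_samples` individuals (default
7, matching the emulated study design) sharing one random reference contig
(default 1,500 bp, GC 0.45). Each library draws `molecules_per_sample`
double-stranded fragments (default 800) of fixed length (150 bp,
approximating the ccfDNA mononucleosome peak) with uniform start positions.
Cohort truth comprises:

* **CHIP variants** (default 6 per cohort): sample-private somatic variants
  of blood cells, present in both the buffy-coat and ccfDNA libraries of
  their carrier at an AF drawn from `chip_af_range` (default 0.08–0.20).
  The clinical detection window is 2–30 %; the default draw range sits
  inside it with margins so that binomial AF noise at ~160× consensus depth
  does not push observed AFs out of the window. The window itself is not
  narrowed.
* **Patterned positions** (default 3): platform/alignment artifacts that
  convert each covering molecule with probability
  `patterned_molecule_rate` (default 0.12) in affected samples, in both
  ccfDNA and buffy coat. Affected samples are independent Bernoulli draws
  with `patterned_hit_probability`; the default of 1.0 models fully
  recurrent artifacts (the "present in all samples" class); lower values
  produce mixed relatedness levels.
* **Spiked true variants** (default 12 at AF 0.05–0.08): the ctDNA
  analogue, injected into a single index-case sample's ccfDNA only. A
  cohort-wide spike would be indistinguishable from patterned error by the
  relatedness filter, which is a property of the filter worth preserving,
  not a bug to paper over. The AFs are the desk-scale transliteration of
  "low frequency": at ~160× consensus depth they yield ≥ 8 expected carrier
  families, the same detection head-room that 0.5 % AF enjoys at a
  production depth of ~2,800×.

**PCR.** Amplification is a per-strand branching process: over
`pcr_cycles` (default 10) every existing single-stranded amplicon spawns a
copy with probability `pcr_efficiency`, and each copied base substitutes
with probability `pcr_error_rate`. The *first copy event* of each original
strand founds the bulk of its UMI family, so an error occurring there is
carried by roughly half of the family — the precise, queryable meaning of
"early PCR error" here (`first_cycle_error` tag; everything later is
`late_pcr_error`). Measured over the default conditions, first-copy errors
have mean carrier fraction ≈ 0.5 versus ≈ 0.04 for later errors.

Efficiency and polymerase error rate are not published quantities for the
emulated workflow; the defaults (0.55, 1×10⁻³ per base per copy event) were
chosen once so that (a) the expected pool of 2·(1+0.55)¹⁰ ≈ 160 amplicons
per molecule keeps a 7-sample × 3-library cohort simulatable in seconds,
and (b) the stochastic PCR channel dominates the residual error budget, as
it does in the real data this models. They are parameters, not claims.

**UMIs and sequencing.** Singleton adapters give each strand an independent
8-mer (two families per molecule); duplex adapters give the molecule a
3+3-mer pair read in opposite rotations from the two strands. Reads are
drawn without replacement from the amplicon pool (`reads_sampled`, default
14,000 per library → mean family size ≈ 9), then pass through an
independent per-base sequencing-error layer (default 1×10⁻³) and a
two-point quality model: Q37 with probability 1−`q_low`, Q11 otherwise
(default `q_low` = 0.02), which exercises the ≥ Q20 gates without a full
quality model. Optional per-base UMI read errors reproduce family-splitting
inflation; they default to off. Read pairs are fused single records
spanning the fragment — the analyses are per-base over the fragment, and
pairing matters only to family keying, which keeps the mate's unclipped
start.

**Replicates.** A *full sample duplicate* re-runs library formation from
fresh molecule sampling; a *sequencing duplicate* resamples reads from the
same post-PCR pool. The two modes share nothing and everything,
respectively, of the PCR error history — which is exactly the contrast the
duplicate-intersection analysis measures.

**Determinism.** All randomness flows from `SimConfig.seed` through named
`SeedSequence` spawn keys (per sample, replicate, material, stage), so any
library is byte-reproducible in isolation and replicates draw from
independent streams.

## Consensus calling

Families are exact-match groups on (chromosome, unclipped start, mate
unclipped start, UMI); there is no UMI mismatch tolerance, so single-base
UMI errors found spurious families (visible as depth inflation at family
size 1). Each column with strictly more than 0.66 concordance yields the
predominant base with the maximum quality observed among its carriers;
otherwise N at quality 0, which the Q20 pileup gate silently removes —
N-as-exclusion is the mechanism, not a special case. Members of unequal
span (real-data clipping) use per-column covering denominators; the
simulator always emits equal spans.

Duplex step 2 pairs step-1 strand consensi whose UMI halves are mutual
rotations at swapped coordinates and recollapses with the same rule, so a
strand disagreement — e.g. a first-copy error present on one strand only —
becomes N. An N on one strand is treated as a no-call rather than a
disagreement: the informative strand stands. Results default to step-1
consensus (strand pairing is rare under sparse production sampling); step 2
is a flag away.

A structural property worth knowing: because 2/3 > 0.66, two-of-three
agreement passes the rule, which makes size-3 families *more* permissive to
moderate-carrier-fraction errors than size-2 families (P(≥2 of 3 carriers)
= 3f²−2f³ ≥ f² for every f). Error therefore declines with the family-size
threshold only when the family-size mix is dominated by larger families,
where the binomial tail P(X > 0.66k) shrinks; the default read depth is
chosen in that regime. At very small mean family sizes the decline between
thresholds 2 and 3 can vanish or invert — a real property of the rule, not
a simulator artifact.

## Error estimation

`build_pileup` counts bases ≥ Q20 from reads ≥ MQ20 inside target regions.
The default analysis target is the flat-coverage core of the contig (one
fragment length in from each end) — the analogue of restricting error
analysis to capture-target exons — because the coverage ramps at the ends
otherwise shift the footprint's composition as family-size thresholds rise.

`estimate_error_rates` slides a 7-position window (overlapping, step 1);
windows pass if all columns have depth ≥ 100, no indel evidence, and every
alt AF ≤ 0.4; only centre bases are tabulated. `parse_positions` emits one
NRA record per observed alt at positions with depth ≥ 100 and no allele
above 0.4, with local GC content over ± 10 bp when a reference is supplied.
Indel evidence exists as a column flag so the gate is a real branch; the
simulator never sets it (indels are out of scope), fixtures do.

## Decomposition

The CHIP and patterned catalogs are built once, from family-size ≥ 2 NRA
tracks, and applied across all thresholds. CHIP detection takes buffy-coat
NRAs in the 2–30 % AF window and excludes positions recurring in ≥ 6
samples (position-level recurrence) — recurrence across unrelated
individuals marks patterned error, not biology; in the default simulation
the patterned positions are exactly what this exclusion catches. C
subtraction removes matching (position, alt) observations from the carrier
sample only. P removes catalog positions from the analyzable footprint
entirely. D keeps only (position, alt) pairs confirmed in the duplicate at
the same threshold; position-only matching is available
(`match_on_alt=False`) since the emulated workflow's choice is not
documented. C and P commute (alleles vs positions); D is applied last.

Reduction percentages are computed per sample and summarised as mean ± SD
over the cohort. The truth audit reports the fraction of surviving NRAs
explained by `first_cycle_error` or `true_variant` tags, weighted by alt
observations — the same unit in which error rates are measured; a
record-level weighting is available.

## What the generator does and does not emulate

It emulates: UMI family structure from branching PCR with realistic family
size overdispersion, early-versus-late PCR error carrier fractions, an
independent sequencing-error layer with quality gates, CHIP visible in
matched buffy coat, cross-sample patterned artifacts, index hopping in UDI
count tables, and full vs sequencing duplicates.

It does not emulate: indels, polymerase-specific substitution spectra
(mutations are uniform over the three alts, so observed spectra are flat by
construction), GC-dependent amplification, capture-enrichment bias,
alignment ambiguity (reads are placed where they belong), or per-mate
sequencing of read pairs. Passing tests therefore demonstrate the *logic*
of the corrections — what each channel removes and what survives — not
quantitative agreement with any particular instrument's error profile, and
cohort-level percentages from real data (tens of kilobases of footprint,
~2,800× depth) are reproduced in ordering, not magnitude.

## Numerical and design choices

* Coordinates are 0-based half-open internally; SAM export is 1-based; the
  NRA BED dialect is 5 columns (chrom, start, end, AF, depth).
* Exact threshold semantics: concordance strictly greater than 0.66
  (2/3 passes at 0.6667); AF gates are inclusive (≤ 0.4, 2 % ≤ AF ≤ 30 %).
* The depth margin (≈ 160× at threshold 2 vs the 100× gate) keeps
  position dropout from the depth gate below ~0.1 % per sample so the
  relatedness-`n` patterned catalog is reliable; at thresholds ≥ 4 the
  margin narrows and footprint loss becomes visible, as it should.
* Empty denominators yield NaN error rates, never silent zeros; a zero
  baseline makes reduction percentages NaN ("flagged undefined").
* `error_reduction` and the ledger treat 0/0 as "no change".
* Degenerate inputs (empty families, zero-length fragments with positive
  error rates, oversampled pools, missing UMIs) raise with counts in the
  message rather than being repaired.

## Known limitations

The contig is a single 1.5 kb target, so absolute footprints are ~1,200
positions and rare-event statistics (duplicate-coincidence rates, spectrum
tails) carry visible Monte-Carlo noise; the acceptance checks therefore
pool ten independent cohorts. The branching process tracks single-strand
amplicons without primer asymmetries or partial products, and "first copy
event" is the model's operational definition of early PCR error — close
to, but simpler than, the chemistry it abstracts.
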