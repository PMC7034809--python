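"""Synthetic ccfDNA cohort generator.

Generates every input the analysis pipeline consumes: a reference contig,
cohort truth (CHIP variants, patterned-error positions, spiked true variants),
UMI-tagged reads produced by a branching-process PCR with per-cycle
substitution errors plus a sequencing-error layer, and unique-dual-index (UDI)
read-count tables with index hopping.

The PCR model works at single-strand amplicon granularity. Each input molecule
contributes two original strands (top/bottom, both tracked in reference
orientation). Every cycle, each existing amplicon spawns one copy with
probability ``efficiency``; every copied base substitutes independently with
probability ``error_rate``. The *first copy event* of an original strand is
the moment a single-primer extension creates the founding copy of its family
lineage, so errors introduced there are carried by roughly half of the final
family — the mechanism by which stochastic early PCR errors survive consensus
calling. Such errors are labelled ``first_cycle_error``; all later PCR errors
are ``late_pcr_error``.

UMI schemes:

* ``singleton`` — each original strand founds its own family under an
  independent 8-mer UMI (two families per molecule).
* ``duplex`` — the molecule receives one (alpha, beta) pair of 3-mers; reads
  from the top strand report ``alpha+beta`` and reads from the bottom strand
  the rotation ``beta+alpha``, which keeps the two strand families separate at
  step 1 while letting the duplex pairing step find them again.

All randomness is derived from ``SimConfig.seed`` through named
``numpy.random.SeedSequence`` spawn keys, so every generator is byte
reproducible and independent libraries draw from independent streams.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .records import (
    ASCII_TO_CODE,
    BASES,
    CODE_TO_ASCII,
    AlignedRead,
    TruthTag,
    bytes_to_seq,
    seq_to_bytes,
)

__all__ = [
    "SimConfig",
    "CohortTruth",
    "UdiPairCounts",
    "Mutation",
    "Amplicon",
    "SimulatedPool",
    "generate_cohort",
    "simulate_pcr",
    "simulate_library",
    "simulate_udi_counts",
]

# The clinically accepted allele-frequency window for CHIP in white blood cells.
CHIP_AF_WINDOW = (0.02, 0.30)


def _spawn_key(parts: Sequence) -> tuple[int, ...]:
    out = []
    for p in parts:
        if isinstance(p, str):
            out.append(zlib.crc32(p.encode()) & 0x7FFFFFFF)
        else:
            out.append(int(p) & 0x7FFFFFFF)
    return tuple(out)


def _rng(seed: int, *parts) -> np.random.Generator:
    """A named, reproducible random stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=_spawn_key(parts)))


def _draw_umi(rng: np.random.Generator, length: int) -> str:
    return bytes_to_seq(CODE_TO_ASCII[rng.integers(0, 4, length)])


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the reference study's design at desk scale: seven healthy
    controls, 10 cycles of PCR on low-input ccfDNA, duplex (3+3) or singleton
    (8-mer) UMI adapters, CHIP variants visible in matched buffy coat within
    the 2-30% allele-frequency window, recurrent patterned-error positions
    shared across samples, and spiked low-frequency true variants confined to
    a single index case. ``molecules_per_sample`` is the desk-scale analogue
    of the genome-equivalents in a 10 ng input.
    """

    reference_length: int = 1500
    gc_fraction: float = 0.45
    n_samples: int = 7
    molecules_per_sample: int = 800
    fragment_length: int = 150
    pcr_cycles: int = 10
    pcr_efficiency: float = 0.55
    pcr_error_rate: float = 1e-3           # substitutions per base per copy event
    seq_error_rate: float = 1e-3           # substitutions per base per read
    q_low: float = 0.02                    # fraction of bases emitted at Q11 (rest Q37)
    reads_sampled: int = 14000             # reads per library
    adapter_scheme: str = "duplex"         # 'singleton' | 'duplex'
    umi_length: int | None = None          # 8 for singleton, 6 (3+3) for duplex
    umi_error_rate: float = 0.0            # per-base UMI read error (family splitting)
    chip_variants: int = 6
    chip_af_range: tuple[float, float] = (0.08, 0.20)
    patterned_positions: int = 3
    patterned_hit_probability: float = 1.0
    patterned_molecule_rate: float = 0.12  # per covering molecule conversion probability
    spike_variants: list[tuple[int | None, str | None, float]] = field(
        default_factory=lambda: [
            (None, None, af) for af in (0.05, 0.06, 0.07, 0.08) for _ in range(3)
        ]
    )
    spike_sample_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adapter_scheme not in ("singleton", "duplex"):
            raise ValueError(f"unknown adapter_scheme {self.adapter_scheme!r}")
        expected_umi = 8 if self.adapter_scheme == "singleton" else 6
        if self.umi_length is None:
            self.umi_length = expected_umi
        elif self.umi_length != expected_umi:
            raise ValueError(
                f"umi_length {self.umi_length} does not match scheme "
                f"{self.adapter_scheme!r} (expected {expected_umi})"
            )
        for name in ("pcr_efficiency", "pcr_error_rate", "seq_error_rate",
                     "q_low", "umi_error_rate", "gc_fraction",
                     "patterned_hit_probability", "patterned_molecule_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.pcr_cycles < 1:
            raise ValueError("pcr_cycles must be >= 1")
        if self.fragment_length > self.reference_length:
            raise ValueError("fragment_length exceeds reference_length")
        lo, hi = self.chip_af_range
        if not (CHIP_AF_WINDOW[0] <= lo < hi <= CHIP_AF_WINDOW[1]):
            raise ValueError(
                f"chip_af_range {self.chip_af_range} must sit inside "
                f"[{CHIP_AF_WINDOW[0]}, {CHIP_AF_WINDOW[1]}] with lo < hi"
            )
        for pos, alt, af in self.spike_variants:
            if pos is not None and not 0 <= pos < self.reference_length:
                raise ValueError(f"spike position {pos} outside reference")
            if alt is not None and alt not in BASES:
                raise ValueError(f"spike alt {alt!r} is not a base")
            if not 0.0 < af <= 1.0:
                raise ValueError(f"spike AF {af} outside (0, 1]")
        if not 0 <= self.spike_sample_index < self.n_samples:
            raise ValueError("spike_sample_index out of range")

    def target_regions(self) -> list[tuple[int, int]]:
        """Default analysis target: the flat-coverage core of the contig.

        Fragment starts are uniform, so coverage ramps up over the first and
        last fragment length of the reference. Restricting error analysis to
        the core mirrors restricting real analyses to capture-target exons,
        away from off-target coverage shoulders, and keeps the analyzable
        footprint homogeneous across family-size thresholds.
        """
        return [(self.fragment_length, self.reference_length - self.fragment_length)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chip_af_range"] = list(self.chip_af_range)
        d["spike_variants"] = [list(v) for v in self.spike_variants]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "chip_af_range" in d:
            d["chip_af_range"] = tuple(d["chip_af_range"])
        if "spike_variants" in d:
            d["spike_variants"] = [tuple(v) for v in d["spike_variants"]]
        return cls(**d)


# --------------------------------------------------------------------------
# cohort truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortTruth:
    """Ground truth for one synthetic cohort.

    ``chip_set`` entries are (sample_id, position, alt, allele_frequency);
    ``patterned_set`` entries are (position, alt, affected_sample_ids);
    ``spike_set`` entries are (position, alt, allele_frequency) and apply to
    the single designated index-case sample's ccfDNA only.
    """

    reference: str
    sample_ids: tuple[str, ...]
    chip_set: tuple[tuple[str, int, str, float], ...]
    patterned_set: tuple[tuple[int, str, tuple[str, ...]], ...]
    spike_set: tuple[tuple[int, str, float], ...]
    spike_sample_id: str = ""


def generate_cohort(config: SimConfig) -> CohortTruth:
    """Draw the cohort-level truth: reference sequence and variant catalogs.

    Special positions (CHIP, patterned, spikes) are mutually distinct and kept
    one fragment length away from the contig ends so they receive full,
    uniform molecule coverage. Patterned positions are assigned to samples by
    independent Bernoulli draws with ``patterned_hit_probability``, so any
    relatedness level from 1 to ``n_samples`` can arise when the probability
    is below one.
    """
    rng = _rng(config.seed, "cohort")
    L = config.reference_length
    probs = [(1 - config.gc_fraction) / 2, config.gc_fraction / 2,
             config.gc_fraction / 2, (1 - config.gc_fraction) / 2]
    ref_codes = rng.choice(4, size=L, p=probs).astype(np.uint8)
    reference = bytes_to_seq(CODE_TO_ASCII[ref_codes])
    sample_ids = tuple(f"S{i + 1}" for i in range(config.n_samples))

    explicit_spikes = [(p, a, af) for p, a, af in config.spike_variants if p is not None]
    n_auto_spikes = len(config.spike_variants) - len(explicit_spikes)
    n_special = config.chip_variants + config.patterned_positions + n_auto_spikes

    lo, hi = config.fragment_length, L - config.fragment_length
    if hi - lo < n_special:
        raise ValueError("reference too short for the requested variant catalog")
    taken = {p for p, _, _ in explicit_spikes}
    pool = np.array([p for p in range(lo, hi) if p not in taken])
    special = rng.choice(pool, size=n_special, replace=False) if n_special else np.array([], int)

    def _alt(pos: int, rng: np.random.Generator) -> str:
        ref_code = ASCII_TO_CODE[ord(reference[pos])]
        return BASES[(ref_code + rng.integers(1, 4)) % 4]

    cursor = 0
    chip = []
    for _ in range(config.chip_variants):
        pos = int(special[cursor]); cursor += 1
        sample = sample_ids[rng.integers(config.n_samples)]
        af = float(rng.uniform(*config.chip_af_range))
        chip.append((sample, pos, _alt(pos, rng), af))

    patterned = []
    for _ in range(config.patterned_positions):
        pos = int(special[cursor]); cursor += 1
        affected = tuple(
            s for s in sample_ids if rng.random() < config.patterned_hit_probability
        )
        patterned.append((pos, _alt(pos, rng), affected))

    spikes = []
    for pos, alt, af in config.spike_variants:
        if pos is None:
            pos = int(special[cursor]); cursor += 1
        if alt is None:
            alt = _alt(pos, rng)
        if alt == reference[pos]:
            raise ValueError(f"spike alt at {pos} equals the reference base")
        spikes.append((int(pos), alt, float(af)))

    return CohortTruth(
        reference=reference,
        sample_ids=sample_ids,
        chip_set=tuple(chip),
        patterned_set=tuple(patterned),
        spike_set=tuple(spikes),
        spike_sample_id=sample_ids[config.spike_sample_index],
    )


# --------------------------------------------------------------------------
# branching PCR
# --------------------------------------------------------------------------

# Internal raw mutation: (position, code offset 1..3, cycle, first_copy_event)
_RawMut = tuple[int, int, int, bool]


@dataclass
class _Pool:
    """Post-PCR amplicon pool for a whole library, in flat-array form."""

    mol: np.ndarray                 # molecule index per amplicon
    strand: np.ndarray              # 0 = top, 1 = bottom
    born: np.ndarray                # cycle of origin (0 for input strands)
    muts: dict[int, tuple[_RawMut, ...]]   # amplicon index -> inherited mutations
    n_original: int

    @property
    def size(self) -> int:
        return int(self.mol.size)

    def equals(self, other: "_Pool") -> bool:
        return (
            np.array_equal(self.mol, other.mol)
            and np.array_equal(self.strand, other.strand)
            and np.array_equal(self.born, other.born)
            and self.muts == other.muts
            and self.n_original == other.n_original
        )


def _branching_pool(
    n_molecules: int,
    fragment_length: int,
    cycles: int,
    efficiency: float,
    error_rate: float,
    rng: np.random.Generator,
) -> _Pool:
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if error_rate > 0 and fragment_length == 0:
        raise ValueError("cannot apply a positive error rate to a zero-length fragment")

    n0 = 2 * n_molecules
    mol = np.repeat(np.arange(n_molecules, dtype=np.int64), 2)
    strand = np.tile(np.array([0, 1], dtype=np.uint8), n_molecules)
    born = np.zeros(n0, dtype=np.int16)
    first_copied = np.zeros(n0, dtype=bool)
    muts: dict[int, tuple[_RawMut, ...]] = {}
    mut_keys: list[int] = []

    for cycle in range(1, cycles + 1):
        n = mol.size
        if efficiency >= 1.0:
            parents = np.arange(n)
        else:
            parents = np.flatnonzero(rng.random(n) < efficiency)
        k = parents.size
        if k == 0:
            continue
        if error_rate > 0:
            nmut = rng.binomial(fragment_length, error_rate, k)
        else:
            nmut = np.zeros(k, dtype=np.int64)
        if mut_keys:
            keys_arr = np.asarray(mut_keys)
            parent_has = np.isin(parents, keys_arr)
        else:
            parent_has = np.zeros(k, dtype=bool)
        todo = np.flatnonzero((nmut > 0) | parent_has)
        for j in todo:
            p = int(parents[j])
            inherited = muts.get(p, ())
            new = inherited
            if nmut[j]:
                first = p < n0 and not first_copied[p]
                positions = rng.integers(0, fragment_length, int(nmut[j]))
                offsets = rng.integers(1, 4, int(nmut[j]))
                new = inherited + tuple(
                    (int(pp), int(oo), cycle, bool(first))
                    for pp, oo in zip(positions, offsets)
                )
            child = n + int(j)
            muts[child] = new
            mut_keys.append(child)
        originals = parents[parents < n0]
        if originals.size:
            first_copied[originals] = True
        mol = np.concatenate([mol, mol[parents]])
        strand = np.concatenate([strand, strand[parents]])
        born = np.concatenate([born, np.full(k, cycle, dtype=np.int16)])

    return _Pool(mol=mol, strand=strand, born=born, muts=muts, n_original=n0)


@dataclass(frozen=True)
class Mutation:
    """One inherited PCR substitution with its provenance."""

    position: int
    alt: str
    cycle: int
    first_cycle: bool


@dataclass
class Amplicon:
    """One single-stranded amplicon with lineage tags (unit-scale interface)."""

    molecule_index: int
    strand_of_origin: str
    cycle_born: int
    umi: str
    sequence: str
    mutations: tuple[Mutation, ...]


def _apply_raw_muts(codes: np.ndarray, raw: tuple[_RawMut, ...]):
    """Apply raw mutations in inheritance order; return list of resolved tags."""
    tags = []
    for pos, off, cycle, first in raw:
        codes[pos] = (codes[pos] + off) % 4
        kind = "first_cycle_error" if first else "late_pcr_error"
        tags.append((kind, pos, cycle, BASES[int(codes[pos])]))
    return tags


def simulate_pcr(
    fragment: str,
    scheme: str,
    cycles: int,
    efficiency: float,
    error_rate: float,
    rng: np.random.Generator,
) -> list[Amplicon]:
    """Amplify one double-stranded fragment and return the full amplicon pool.

    ``fragment`` is the top-strand sequence in reference orientation; the
    bottom strand is tracked by label (all sequences are reported in reference
    orientation, which is what the aligned-read model downstream consumes).
    Singleton scheme: the two strand lineages receive independent 8-mer UMIs.
    Duplex scheme: one (alpha, beta) 3-mer pair, read as alpha+beta from the
    top strand and beta+alpha from the bottom strand.
    """
    if scheme not in ("singleton", "duplex"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if not 0.0 <= efficiency <= 1.0 or not 0.0 <= error_rate <= 1.0:
        raise ValueError("efficiency and error_rate must be in [0, 1]")
    pool = _branching_pool(1, len(fragment), cycles, efficiency, error_rate, rng)

    if scheme == "singleton":
        strand_umis = (_draw_umi(rng, 8), _draw_umi(rng, 8))
    else:
        alpha, beta = _draw_umi(rng, 3), _draw_umi(rng, 3)
        strand_umis = (alpha + beta, beta + alpha)

    template = ASCII_TO_CODE[seq_to_bytes(fragment)].copy()
    out = []
    for i in range(pool.size):
        codes = template.copy()
        resolved = _apply_raw_muts(codes, pool.muts.get(i, ()))
        out.append(
            Amplicon(
                molecule_index=int(pool.mol[i]),
                strand_of_origin="top" if pool.strand[i] == 0 else "bottom",
                cycle_born=int(pool.born[i]),
                umi=strand_umis[int(pool.strand[i])],
                sequence=bytes_to_seq(CODE_TO_ASCII[codes]),
                mutations=tuple(
                    Mutation(p, alt, cyc, kind == "first_cycle_error")
                    for kind, p, cyc, alt in resolved
                ),
            )
        )
    return out


# --------------------------------------------------------------------------
# library simulation
# --------------------------------------------------------------------------

@dataclass
class SimulatedPool:
    """Opaque record of a library's pre-sequencing state (for mode contracts)."""

    starts: np.ndarray
    templates: np.ndarray
    umi_codes: np.ndarray
    pool: _Pool

    def equals(self, other: "SimulatedPool") -> bool:
        return (
            np.array_equal(self.starts, other.starts)
            and np.array_equal(self.templates, other.templates)
            and np.array_equal(self.umi_codes, other.umi_codes)
            and self.pool.equals(other.pool)
        )


def simulate_library(
    truth: CohortTruth,
    sample_id: str,
    replicate_id: str,
    config: SimConfig,
    *,
    kind: str = "ccf",
    mode: str = "full",
    base_replicate_id: str | None = None,
    return_pool: bool = False,
):
    """Simulate one sequencing library and return its aligned reads.

    ``kind`` selects the material: ``'ccf'`` (plasma, carries CHIP + patterned
    + spiked variants) or ``'buffy'`` (white-blood-cell DNA, carries CHIP +
    patterned but no spikes). ``mode='full'`` re-runs library formation from
    fresh molecule sampling — an independent full sample duplicate.
    ``mode='seqdup'`` resamples reads from the *same* post-PCR pool as
    ``base_replicate_id`` — a sequencing duplicate sharing all PCR errors.
    """
    if kind not in ("ccf", "buffy"):
        raise ValueError(f"unknown library kind {kind!r}")
    if mode not in ("full", "seqdup"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "seqdup" and base_replicate_id is None:
        raise ValueError("sequencing-duplicate mode requires base_replicate_id")
    try:
        si = truth.sample_ids.index(sample_id)
    except ValueError:
        raise ValueError(f"sample {sample_id!r} not in cohort") from None

    L = len(truth.reference)
    flen = config.fragment_length
    n_mol = config.molecules_per_sample
    pool_rep = base_replicate_id if mode == "seqdup" else replicate_id

    # --- molecule formation and PCR: one stream, shared by sequencing duplicates
    rng_pool = _rng(config.seed, "pool", si, pool_rep, kind)
    starts = rng_pool.integers(0, L - flen + 1, n_mol)
    ref_codes = ASCII_TO_CODE[seq_to_bytes(truth.reference)]
    templates = ref_codes[starts[:, None] + np.arange(flen)[None, :]]

    molecule_events: dict[int, list[TruthTag]] = {}

    def _inject(pos: int, alt: str, prob: float, tag_kind: str) -> None:
        covering = np.flatnonzero((starts <= pos) & (pos < starts + flen))
        if covering.size == 0:
            return
        carriers = covering[rng_pool.random(covering.size) < prob]
        for m in carriers:
            templates[m, pos - starts[m]] = ASCII_TO_CODE[ord(alt)]
            molecule_events.setdefault(int(m), []).append((tag_kind, pos, alt))

    for sample, pos, alt, af in truth.chip_set:
        if sample == sample_id:
            _inject(pos, alt, af, "chip_variant")
    if kind == "ccf" and sample_id == truth.spike_sample_id:
        for pos, alt, af in truth.spike_set:
            _inject(pos, alt, af, "true_variant")
    for pos, alt, affected in truth.patterned_set:
        if sample_id in affected:
            _inject(pos, alt, config.patterned_molecule_rate, "patterned_error")

    if config.adapter_scheme == "singleton":
        umi_codes = rng_pool.integers(0, 4, (n_mol, 2, 8)).astype(np.uint8)
    else:
        ab = rng_pool.integers(0, 4, (n_mol, 2, 3)).astype(np.uint8)
        umi_codes = np.empty((n_mol, 2, 6), dtype=np.uint8)
        umi_codes[:, 0, :3] = ab[:, 0]; umi_codes[:, 0, 3:] = ab[:, 1]
        umi_codes[:, 1, :3] = ab[:, 1]; umi_codes[:, 1, 3:] = ab[:, 0]

    pool = _branching_pool(
        n_mol, flen, config.pcr_cycles, config.pcr_efficiency,
        config.pcr_error_rate, rng_pool,
    )

    # --- read sampling and the sequencing-error layer: a separate stream
    rng_reads = _rng(config.seed, "reads", si, replicate_id, kind, mode)
    if config.reads_sampled > pool.size:
        raise ValueError(
            f"reads_sampled={config.reads_sampled} exceeds the post-PCR pool "
            f"({pool.size} amplicons; short by {config.reads_sampled - pool.size})"
        )
    chosen = np.sort(rng_reads.choice(pool.size, config.reads_sampled, replace=False))
    n_reads = chosen.size
    if config.seq_error_rate > 0:
        n_seq_err = rng_reads.binomial(flen, config.seq_error_rate, n_reads)
    else:
        n_seq_err = np.zeros(n_reads, dtype=np.int64)
    quals_all = np.where(
        rng_reads.random((n_reads, flen)) < config.q_low, 11, 37
    ).astype(np.uint8)

    umi_cache: dict[tuple[int, int], str] = {}
    reads: list[AlignedRead] = []
    for i, idx in enumerate(chosen):
        idx = int(idx)
        m = int(pool.mol[idx])
        st = int(pool.strand[idx])
        codes = templates[m].copy()
        tags: list[TruthTag] = list(molecule_events.get(m, ()))
        for kind_, p, _cyc, alt in _apply_raw_muts(codes, pool.muts.get(idx, ())):
            tags.append((kind_, int(starts[m]) + p, alt))
        if n_seq_err[i]:
            for p in rng_reads.integers(0, flen, int(n_seq_err[i])):
                codes[p] = (codes[p] + rng_reads.integers(1, 4)) % 4
                tags.append(("seq_error", int(starts[m]) + int(p), BASES[int(codes[p])]))
        umi = umi_cache.get((m, st))
        if umi is None:
            umi = bytes_to_seq(CODE_TO_ASCII[umi_codes[m, st]])
            umi_cache[(m, st)] = umi
        if config.umi_error_rate > 0:
            k = rng_reads.binomial(len(umi), config.umi_error_rate)
            if k:
                ucodes = ASCII_TO_CODE[seq_to_bytes(umi)].copy()
                for p in rng_reads.integers(0, len(umi), int(k)):
                    ucodes[p] = (ucodes[p] + rng_reads.integers(1, 4)) % 4
                umi = bytes_to_seq(CODE_TO_ASCII[ucodes])
        s = int(starts[m])
        e = s + flen - 1
        reads.append(
            AlignedRead(
                sample_id=sample_id,
                replicate_id=replicate_id,
                chrom="ref",
                unclipped_start=s if st == 0 else e,
                mate_unclipped_start=e if st == 0 else s,
                strand_of_origin="top" if st == 0 else "bottom",
                umi=umi,
                sequence=bytes_to_seq(CODE_TO_ASCII[codes]),
                base_qualities=quals_all[i],
                mapping_quality=60,
                truth_tags=frozenset(tags),
            )
        )

    if return_pool:
        return reads, SimulatedPool(starts=starts, templates=templates,
                                    umi_codes=umi_codes, pool=pool)
    return reads


# --------------------------------------------------------------------------
# UDI count tables with index hopping
# --------------------------------------------------------------------------

@dataclass
class UdiPairCounts:
    """Read counts per (i7, i5) unique-dual-index pair for one lane.

    Correct sample assignments sit on the diagonal (sample k's own i7 with its
    own i5); mixed pairs are index-hopping events; ``undetermined`` counts
    reads matching no configured pair.
    """

    samples: list[tuple[str, str]]
    counts: dict[tuple[str, str], int]
    undetermined: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.undetermined


def simulate_udi_counts(
    n_samples: int,
    reads_per_sample: int,
    hop_rate: float,
    seed: int,
) -> UdiPairCounts:
    """Simulate a demultiplexing count table with index hopping.

    Each read independently hops exactly one of its two indices to another
    sample's with probability ``hop_rate``; the hop lands uniformly on the
    2*(n_samples-1) eligible mixed pairs that retain one of the read's own
    indices.
    """
    if not 0.0 <= hop_rate < 1.0:
        raise ValueError("hop_rate must be in [0, 1)")
    if n_samples < 2 and hop_rate > 0:
        raise ValueError("index hopping requires at least 2 samples")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = _rng(seed, "udi")
    codes = rng.choice(4 ** 8, size=2 * n_samples, replace=False)

    def _barcode(c: int) -> str:
        return "".join(BASES[(c >> (2 * j)) & 3] for j in range(8))

    samples = [(_barcode(int(codes[2 * k])), _barcode(int(codes[2 * k + 1])))
               for k in range(n_samples)]
    counts: dict[tuple[str, str], int] = {}
    for k, (i7, i5) in enumerate(samples):
        counts[(i7, i5)] = 0
    for k, (i7, i5) in enumerate(samples):
        hops = int(rng.binomial(reads_per_sample, hop_rate)) if hop_rate > 0 else 0
        counts[(i7, i5)] += reads_per_sample - hops
        if hops:
            others = [j for j in range(n_samples) if j != k]
            targets = []
            for j in others:
                targets.append((i7, samples[j][1]))        # own i7, hopped i5
                targets.append((samples[j][0], i5))        # hopped i7, own i5
            split = rng.multinomial(hops, np.full(len(targets), 1 / len(targets)))
            for pair, c in zip(targets, split):
                if c:
                    counts[pair] = counts.get(pair, 0) + int(c)
    return UdiPairCounts(samples=samples, counts=counts, undetermined=0)
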