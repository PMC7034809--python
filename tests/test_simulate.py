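"""Generator contracts: truth catalogs, branching PCR, libraries, UDI tables."""
import numpy as np
import pytest

import ccfnoise as cn
from ccfnoise.consensus import collapse, filter_by_family_size
from ccfnoise.errors import build_pileup, estimate_error_rates
from ccfnoise.simulate import SimConfig, _branching_pool, _rng


def _clean_config(**kw):
    base = dict(
        chip_variants=0,
        patterned_positions=0,
        spike_variants=[],
        pcr_error_rate=0.0,
        seq_error_rate=0.0,
        q_low=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenerateCohort:
    def test_null_cohort_has_empty_truth_sets(self):
        cfg = _clean_config(seed=5)
        truth = cn.generate_cohort(cfg)
        assert truth.chip_set == () and truth.patterned_set == () and truth.spike_set == ()
        assert len(truth.reference) == cfg.reference_length
        assert set(truth.reference) <= set("ACGT")

    def test_seed_determinism(self):
        cfg = SimConfig(seed=1)
        assert cn.generate_cohort(cfg) == cn.generate_cohort(cfg)
        assert cn.generate_cohort(SimConfig(seed=2)) != cn.generate_cohort(cfg)

    def test_degenerate_bernoulli_hits_all_samples(self):
        cfg = _clean_config(patterned_positions=50, patterned_hit_probability=1.0, seed=3)
        truth = cn.generate_cohort(cfg)
        assert len(truth.patterned_set) == 50
        assert all(affected == truth.sample_ids for _, _, affected in truth.patterned_set)

    def test_zero_hit_probability_affects_nobody(self):
        cfg = _clean_config(patterned_positions=10, patterned_hit_probability=0.0, seed=3)
        truth = cn.generate_cohort(cfg)
        assert all(affected == () for _, _, affected in truth.patterned_set)

    def test_truth_alts_differ_from_reference(self):
        truth = cn.generate_cohort(SimConfig(seed=7))
        for _, pos, alt, af in truth.chip_set:
            assert truth.reference[pos] != alt
            assert 0.02 <= af <= 0.30
        for pos, alt, _ in truth.patterned_set:
            assert truth.reference[pos] != alt
        for pos, alt, _ in truth.spike_set:
            assert truth.reference[pos] != alt

    def test_explicit_spike_copied_verbatim(self):
        cfg = _clean_config(spike_variants=[(400, None, 0.1)], seed=11)
        truth = cn.generate_cohort(cfg)
        assert truth.spike_set[0][0] == 400 and truth.spike_set[0][2] == 0.1


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(adapter_scheme="triplex"),
            dict(adapter_scheme="singleton", umi_length=6),
            dict(pcr_cycles=0),
            dict(pcr_efficiency=1.5),
            dict(chip_af_range=(0.01, 0.2)),      # below the CHIP window
            dict(chip_af_range=(0.2, 0.4)),       # above the CHIP window
            dict(spike_variants=[(10_000, None, 0.05)]),
            dict(spike_variants=[(None, "X", 0.05)]),
            dict(fragment_length=5000),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)

    def test_umi_length_follows_scheme(self):
        assert SimConfig(adapter_scheme="singleton").umi_length == 8
        assert SimConfig(adapter_scheme="duplex").umi_length == 6


class TestSimulatePcr:
    def test_error_free_full_efficiency_doubles(self):
        rng = _rng(0, "t")
        pool = cn.simulate_pcr("ACGTACGT", "singleton", cycles=3,
                               efficiency=1.0, error_rate=0.0, rng=rng)
        assert len(pool) == 2 * 2 ** 3
        assert all(a.sequence == "ACGTACGT" for a in pool)
        umis = {a.umi for a in pool}
        assert len(umis) == 2 and all(len(u) == 8 for u in umis)

    def test_duplex_umis_are_rotations(self):
        rng = _rng(1, "t")
        pool = cn.simulate_pcr("ACGT", "duplex", 2, 1.0, 0.0, rng)
        top = {a.umi for a in pool if a.strand_of_origin == "top"}
        bottom = {a.umi for a in pool if a.strand_of_origin == "bottom"}
        (u_top,), (u_bot,) = top, bottom
        assert len(u_top) == 6 and u_bot == u_top[3:] + u_top[:3]

    def test_first_cycle_error_carried_by_half_the_lineage(self):
        # At efficiency 1 the first copy's descendants are exactly half of the
        # strand lineage at every later cycle.
        rng = _rng(42, "fc")
        found = 0
        for _ in range(80):
            pool = cn.simulate_pcr("A" * 40, "singleton", cycles=5,
                                   efficiency=1.0, error_rate=0.004, rng=rng)
            by_strand = {}
            for a in pool:
                by_strand.setdefault(a.strand_of_origin, []).append(a)
            for members in by_strand.values():
                fc = [
                    m for a in members for m in a.mutations if m.first_cycle
                ]
                if not fc:
                    continue
                mut = fc[0]
                others = [
                    m for a in members for m in a.mutations
                    if m.position == mut.position and not m.first_cycle
                ]
                if others:
                    continue          # confounded by a late hit at the same site
                carriers = sum(
                    any(m.position == mut.position and m.first_cycle
                        for m in a.mutations)
                    for a in members
                )
                assert carriers / len(members) == 0.5
                found += 1
        assert found > 5

    def test_branching_process_expectation(self):
        rng = _rng(9, "bp")
        pool = _branching_pool(1000, 10, cycles=8, efficiency=0.5,
                               error_rate=0.0, rng=rng)
        expected = 1000 * 2 * 1.5 ** 8
        assert abs(pool.size - expected) / expected < 0.05

    def test_zero_length_fragment_with_errors_rejected(self):
        with pytest.raises(ValueError):
            cn.simulate_pcr("", "singleton", 2, 1.0, 0.01, _rng(0, "z"))

    def test_cycle_of_origin_recorded(self):
        rng = _rng(4, "cyc")
        pool = cn.simulate_pcr("A" * 60, "duplex", 4, 1.0, 0.01, rng)
        cycles = {m.cycle for a in pool for m in a.mutations}
        assert cycles and cycles <= {1, 2, 3, 4}


class TestSimulateLibrary:
    def test_clean_library_measures_zero_error(self):
        cfg = _clean_config(
            n_samples=2, molecules_per_sample=300, reads_sampled=2500,
            reference_length=900, pcr_cycles=6, pcr_efficiency=0.8, seed=21,
        )
        truth = cn.generate_cohort(cfg)
        reads = cn.simulate_library(truth, "S1", "R1", cfg)
        cons = collapse(reads, "duplex")
        pile = build_pileup(cons, truth.reference, cfg.target_regions())
        report = estimate_error_rates(pile, min_depth=50)
        assert report.n_passing_positions > 0
        assert report.total_nra_observations == 0

    def test_spike_carrier_fraction_within_binomial_ci(self):
        cfg = _clean_config(
            n_samples=1, molecules_per_sample=2000, reads_sampled=4000,
            pcr_cycles=1, pcr_efficiency=0.0,
            spike_variants=[(750, None, 0.10)], seed=8,
        )
        truth = cn.generate_cohort(cfg)
        pos, alt, af = truth.spike_set[0]
        reads, pool = cn.simulate_library(truth, "S1", "R1", cfg, return_pool=True)
        covering = np.flatnonzero(
            (pool.starts <= pos) & (pos < pool.starts + cfg.fragment_length)
        )
        carriers = sum(
            truth.reference[pos] != chr(b"ACGT"[pool.templates[m, pos - pool.starts[m]]])
            for m in covering
        )
        n = covering.size
        sd = np.sqrt(n * af * (1 - af))
        assert abs(carriers - n * af) < 2.58 * sd    # 99% CI

    def test_sequencing_duplicate_shares_pool_not_reads(self):
        cfg = _clean_config(
            n_samples=1, molecules_per_sample=100, reads_sampled=800,
            reference_length=600, pcr_cycles=5, pcr_efficiency=0.8,
            seq_error_rate=1e-3, seed=13,
        )
        truth = cn.generate_cohort(cfg)
        r1, p1 = cn.simulate_library(truth, "S1", "R1", cfg, return_pool=True)
        d1, pd1 = cn.simulate_library(
            truth, "S1", "SD1", cfg, mode="seqdup", base_replicate_id="R1",
            return_pool=True,
        )
        d1b, _ = cn.simulate_library(
            truth, "S1", "SD1", cfg, mode="seqdup", base_replicate_id="R1",
            return_pool=True,
        )
        assert p1.equals(pd1)                  # identical post-PCR pool
        assert d1 == d1b                       # deterministic under same ids
        assert r1 != d1                        # fresh read sampling

    def test_full_replicates_draw_independent_molecules(self):
        cfg = _clean_config(n_samples=1, molecules_per_sample=50,
                            reads_sampled=200, pcr_cycles=4,
                            pcr_efficiency=1.0, seed=3)
        truth = cn.generate_cohort(cfg)
        _, p1 = cn.simulate_library(truth, "S1", "R1", cfg, return_pool=True)
        _, p2 = cn.simulate_library(truth, "S1", "R2", cfg, return_pool=True)
        assert not np.array_equal(p1.starts, p2.starts)

    def test_oversampling_reports_shortfall(self):
        cfg = _clean_config(n_samples=1, molecules_per_sample=10,
                            reads_sampled=1000, pcr_cycles=1,
                            pcr_efficiency=0.0, seed=0)
        truth = cn.generate_cohort(cfg)
        with pytest.raises(ValueError, match="short by 980"):
            cn.simulate_library(truth, "S1", "R1", cfg)

    def test_unknown_sample_rejected(self):
        cfg = _clean_config(seed=0)
        truth = cn.generate_cohort(cfg)
        with pytest.raises(ValueError, match="not in cohort"):
            cn.simulate_library(truth, "S99", "R1", cfg)

    def test_truth_tags_fall_inside_read_span(self):
        cfg = SimConfig(n_samples=2, molecules_per_sample=150,
                        reads_sampled=1200, reference_length=800,
                        pcr_cycles=5, pcr_efficiency=0.8,
                        chip_variants=2, patterned_positions=2,
                        spike_variants=[(None, None, 0.1)], seed=17)
        truth = cn.generate_cohort(cfg)
        reads = cn.simulate_library(truth, "S1", "R1", cfg)
        tagged = 0
        for r in reads:
            for kind, pos, alt in r.truth_tags:
                tagged += 1
                assert r.ref_start <= pos < r.ref_end
                assert alt in "ACGT"
        assert tagged > 0

    def test_umi_errors_split_families(self):
        base = dict(n_samples=1, molecules_per_sample=200, reads_sampled=1600,
                    reference_length=800, pcr_cycles=5, pcr_efficiency=0.8,
                    seed=19)
        cfg0 = _clean_config(**base)
        cfg1 = _clean_config(umi_error_rate=0.02, **base)
        truth = cn.generate_cohort(cfg0)
        n0 = len(collapse(cn.simulate_library(truth, "S1", "R1", cfg0), "duplex"))
        n1 = len(collapse(cn.simulate_library(truth, "S1", "R1", cfg1), "duplex"))
        assert n1 > n0    # single-base UMI errors become spurious new molecules


class TestUdiCounts:
    def test_zero_hop_rate_is_diagonal(self):
        t = cn.simulate_udi_counts(4, 1000, 0.0, seed=2)
        diagonal = set(t.samples)
        assert all(pair in diagonal for pair, c in t.counts.items() if c > 0)

    @pytest.mark.parametrize("seed", [1, 7])
    def test_total_conservation(self, seed):
        n, reads = 5, 20_000
        t = cn.simulate_udi_counts(n, reads, 0.013, seed=seed)
        assert t.total == n * reads

    def test_hop_requires_two_samples(self):
        with pytest.raises(ValueError):
            cn.simulate_udi_counts(1, 100, 0.01, seed=0)
        with pytest.raises(ValueError):
            cn.simulate_udi_counts(3, 100, 1.0, seed=0)
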