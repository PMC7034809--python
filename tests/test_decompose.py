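"""CHIP filtering, patterned positions, duplicate intersection, spectra,
and the full decomposition ledger on simulated cohorts."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ccfnoise.decompose import (
    af_bins,
    detect_chip,
    error_reduction,
    intersect_duplicates,
    patterned_positions,
    run_decomposition,
    spectrum,
    truth_label_audit,
)
from ccfnoise.records import ErrorReport, NraRecord, SUBSTITUTION_TYPES

STOCHASTIC = {"first_cycle_error", "late_pcr_error", "seq_error"}


def rec(pos, alt="G", ref="A", count=5, depth=100, tags=()):
    return NraRecord(chrom="ref", position=pos, ref_base=ref, alt_base=alt,
                     alt_count=count, depth=depth, tags=frozenset(tags))


class TestDetectChip:
    def test_af_window(self):
        buffy = {"S1": [rec(10, count=1, depth=100),      # AF 0.01: below
                        rec(20, count=10, depth=100),     # AF 0.10: in
                        rec(30, count=50, depth=125)]}    # AF 0.40: above
        chip = detect_chip(buffy)
        assert chip.for_sample("S1") == {("ref", 20, "G")}

    def test_recurrent_positions_reclassified_as_patterned(self):
        buffy = {f"S{i}": [rec(40, count=10, depth=100)] for i in range(1, 7)}
        buffy["S7"] = [rec(50, count=10, depth=100)]
        chip = detect_chip(buffy, recurrence_cutoff=6)
        assert ("ref", 40) in chip.excluded_recurrent
        assert all(("ref", 40, "G") not in chip.for_sample(s) for s in buffy)
        assert chip.for_sample("S7") == {("ref", 50, "G")}

    def test_private_variant_included_for_its_sample_only(self):
        buffy = {"S1": [rec(10, count=10, depth=100)], "S2": []}
        chip = detect_chip(buffy)
        assert chip.for_sample("S1") == {("ref", 10, "G")}
        assert chip.for_sample("S2") == set()

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            detect_chip({}, af_low=0.3, af_high=0.3)


class TestPatternedPositions:
    def test_k1_collects_every_position(self):
        nras = {"S1": [rec(1)], "S2": [rec(2)], "S3": []}
        assert patterned_positions(nras, 1).positions == {("ref", 1), ("ref", 2)}

    def test_threshold_boundary(self):
        nras = {f"S{i}": [rec(5)] for i in (1, 2, 3)}
        nras.update({f"S{i}": [] for i in (4, 5, 6, 7)})
        assert ("ref", 5) in patterned_positions(nras, 3)
        assert ("ref", 5) not in patterned_positions(nras, 4)

    def test_position_level_ignores_alt_identity(self):
        nras = {"S1": [rec(5, alt="G")], "S2": [rec(5, alt="T")]}
        assert ("ref", 5) in patterned_positions(nras, 2)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            patterned_positions({"S1": []}, 0)

    @given(st.data())
    def test_set_sizes_non_increasing_in_k(self, data):
        n_samples = data.draw(st.integers(2, 6))
        nras = {
            f"S{i}": [rec(p) for p in data.draw(
                st.sets(st.integers(0, 15), max_size=10)
            )]
            for i in range(n_samples)
        }
        sizes = [len(patterned_positions(nras, k).positions)
                 for k in range(1, n_samples + 1)]
        assert sizes == sorted(sizes, reverse=True)


class TestIntersectDuplicates:
    def test_disjoint_sets_empty(self):
        assert intersect_duplicates([rec(1)], [rec(2)]) == []

    def test_identical_sets_identity(self):
        a = [rec(1), rec(2, alt="T")]
        assert intersect_duplicates(a, a) == a

    def test_alt_matching_mode(self):
        a, b = [rec(1, alt="G")], [rec(1, alt="T")]
        assert intersect_duplicates(a, b, match_on_alt=True) == []
        assert intersect_duplicates(a, b, match_on_alt=False) == a


class TestErrorReduction:
    def test_arithmetic(self):
        assert error_reduction(0.0004, 0.0001) == pytest.approx(75.0)
        assert error_reduction(0.0004, 0.0004) == 0.0
        assert error_reduction(0.0004, 0.0) == 100.0

    def test_zero_baseline_flagged_undefined(self):
        assert np.isnan(error_reduction(0.0, 0.1))
        assert error_reduction(0.0, 0.0) == 0.0

    def test_accepts_reports(self):
        base = ErrorReport(4, 10_000, 10)
        corr = ErrorReport(1, 10_000, 10)
        assert error_reduction(base, corr) == pytest.approx(75.0)


class TestSpectrum:
    def test_single_type(self):
        df = spectrum([rec(1, ref="G", alt="A", count=7)])
        row = df.set_index("substitution").loc["G>A"]
        assert row["count"] == 7 and row["percent"] == 100.0

    def test_empty_is_all_zero(self):
        df = spectrum([])
        assert df["count"].sum() == 0 and df["percent"].sum() == 0.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        recs = [rec(i, ref="A", alt=rng.choice(list("CGT")), count=int(c))
                for i, c in enumerate(rng.integers(1, 9, 40))]
        assert spectrum(recs)["percent"].sum() == pytest.approx(100.0)

    def test_uniform_substitution_model_fills_bins_uniformly(self):
        rng = np.random.default_rng(1)
        refs = rng.choice(list("ACGT"), 6000)
        recs = []
        for i, r in enumerate(refs):
            alt = rng.choice([b for b in "ACGT" if b != r])
            recs.append(rec(i, ref=r, alt=alt, count=1))
        counts = spectrum(recs)["count"].to_numpy()
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=11)


class TestAfBins:
    def test_all_low(self):
        s = af_bins([rec(1, count=1, depth=2000)])
        assert s.iloc[0] == 1.0

    def test_one_record_per_bin(self):
        recs = [rec(1, count=1, depth=2000),    # 0.0005
                rec(2, count=1, depth=200),     # 0.005
                rec(3, count=10, depth=200)]    # 0.05
        assert list(af_bins(recs)) == [pytest.approx(1 / 3)] * 3

    @given(st.lists(st.tuples(st.integers(1, 40), st.integers(100, 4000)),
                    min_size=1, max_size=30))
    def test_fractions_sum_to_one(self, pairs):
        recs = [rec(i, count=c, depth=d) for i, (c, d) in enumerate(pairs)]
        assert af_bins(recs).sum() == pytest.approx(1.0)


class TestRunDecompositionContracts:
    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError, match="buffy"):
            run_decomposition({}, "A" * 10, corrections={"C"})
        with pytest.raises(ValueError, match="duplicate"):
            run_decomposition({}, "A" * 10, corrections={"D"})
        with pytest.raises(ValueError, match="unknown correction"):
            run_decomposition({}, "A" * 10, corrections={"Z"})

    def test_chip_subtraction_and_position_removal_commute(self):
        # C removes alleles, P removes positions: disjoint axes.
        records = [rec(1, alt="G"), rec(2, alt="T"), rec(3, alt="G")]
        chip = {("ref", 1, "G")}
        patterned = {("ref", 2)}

        def apply_c(rs):
            return [r for r in rs if r.allele_key not in chip]

        def apply_p(rs):
            return [r for r in rs if r.position_key not in patterned]

        assert apply_c(apply_p(records)) == apply_p(apply_c(records))


class TestCohortDecomposition:
    """Monte-Carlo properties on the shared default-condition cohorts."""

    def test_empty_corrections_yield_baseline_only(self, cohort_bundle):
        run = cohort_bundle[0]
        assert (2, frozenset()) in run.result.reports
        base = run.result.report(2)
        assert base.total_quality_bases > 0

    def test_adding_corrections_never_increases_error(self, cohort_bundle):
        subsets = [frozenset(), {"C"}, {"P"}, {"D"}, {"C", "P"},
                   {"C", "D"}, {"P", "D"}, {"C", "P", "D"}]
        for run in cohort_bundle:
            for fs in (1, 2, 3):
                err = {frozenset(s): run.result.report(fs, s).error_rate
                       for s in subsets}
                for small in subsets:
                    for big in subsets:
                        if frozenset(small) < frozenset(big):
                            assert err[frozenset(big)] <= err[frozenset(small)] + 1e-12

    def test_duplicate_intersection_suppresses_stochastic_errors_tenfold(
        self, cohort_bundle
    ):
        before = after = 0
        for run in cohort_bundle:
            for s in run.truth.sample_ids:
                stoch = [r for r in run.nras_r1[s]
                         if r.tags and r.tags <= STOCHASTIC]
                confirmed = intersect_duplicates(stoch, run.nras_r2[s])
                before += len(stoch)
                after += len(confirmed)
        assert before > 200          # the channel is populated
        assert after < before / 10   # and the intersection crushes it

    def test_confirmed_spikes_survive_all_corrections(self, cohort_bundle):
        for run in cohort_bundle:
            s = run.truth.spike_sample_id
            surviving = {
                (r.position, r.alt_base)
                for r in run.result.survivors[(2, frozenset("CPD"))]
                if r.sample_id == s
            }
            baseline = {
                (r.position, r.alt_base)
                for r in run.result.survivors[(2, frozenset())]
                if r.sample_id == s
            }
            keys_r2 = {(r.position, r.alt_base) for r in run.nras_r2[s]}
            for pos, alt, af in run.truth.spike_set:
                if af >= 0.005 and (pos, alt) in baseline and (pos, alt) in keys_r2:
                    assert (pos, alt) in surviving

    def test_footprint_with_stricter_patterning_is_larger(self, cohort_bundle):
        for run in cohort_bundle:
            k7 = patterned_positions(run.nras_r1, 7)
            k2 = patterned_positions(run.nras_r1, 2)
            assert k2.positions >= k7.positions

    def test_chip_catalog_recovers_planted_variants(self, cohort_bundle):
        found = planted = 0
        for run in cohort_bundle:
            chip = run.result.chip
            planted_set = {(s, "ref", pos, alt)
                           for s, pos, alt, _ in run.truth.chip_set}
            planted += len(planted_set)
            found += len(planted_set & set(chip.variants))
        assert found / planted > 0.9

    def test_patterned_catalog_recovers_planted_positions(self, cohort_bundle):
        for run in cohort_bundle:
            truth_positions = {("ref", p) for p, _, _ in run.truth.patterned_set}
            assert truth_positions <= run.result.patterned.positions
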