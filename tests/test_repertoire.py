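"""Clone grouping, filters and CDR/FWR contrasts for BCR repertoires."""

import numpy as np
import pytest
from scipy.stats import binom

from sercodon.repertoire import (
    Clone,
    ReceptorRecord,
    RegionMask,
    cross_individual_test,
    filter_records,
    germline_region_contrast,
    group_clones,
    position_coverage_filter,
    run_repertoire_analysis,
    somatic_region_contrast,
)
from sercodon.simulate import RepertoireSimSpec, simulate_repertoire

MASK = RegionMask()
N_POSITIONS = 106


def make_record(individual="I0", germ=None, seq=None, v="IGHV1-1", j="IGHJ1",
                cdr3=15, fill="GCT"):
    """A full-length record built from the fill codon plus overrides."""
    germ_codons = [fill] * N_POSITIONS
    for pos, codon in (germ or {}).items():
        germ_codons[pos - 1] = codon
    seq_codons = list(germ_codons)
    for pos, codon in (seq or {}).items():
        seq_codons[pos - 1] = codon
    return ReceptorRecord(individual, "".join(seq_codons), "".join(germ_codons),
                          v, j, cdr3)


class TestRegionMask:
    @pytest.mark.parametrize("pos,region", [
        (1, "FWR"), (24, "FWR"), (25, "CDR"), (40, "CDR"), (41, "FWR"),
        (53, "FWR"), (54, None), (56, "CDR"), (65, "CDR"), (66, "FWR"),
        (104, "FWR"), (105, "CDR"), (106, "CDR"), (107, None),
    ])
    def test_imgt_bounds(self, pos, region):
        assert MASK.region_of(pos) == region

    def test_analyzed_positions(self):
        assert 25 in MASK.analyzed and 31 not in MASK.analyzed
        assert 34 not in MASK.analyzed and 35 in MASK.analyzed
        assert 73 not in MASK.analyzed and 74 in MASK.analyzed
        assert 106 in MASK.analyzed and 107 not in MASK.analyzed


class TestFilters:
    def test_over_thirty_percent_mutated_dropped(self):
        # 31 mismatches over exactly 100 aligned nt (trailing gap padding)
        rec = ReceptorRecord("I0", "C" * 31 + "A" * 69 + "..",
                             "A" * 100 + "..", "V", "J", 10)
        assert rec.mutated_fraction() == pytest.approx(0.31)
        kept, report = filter_records([rec])
        assert kept == [] and report.dropped_mutation == 1

    def test_exactly_thirty_percent_kept(self):
        rec = ReceptorRecord("I0", "C" * 30 + "A" * 70 + "..",
                             "A" * 100 + "..", "V", "J", 10)
        others = [make_record("I0") for _ in range(2)]
        kept, report = filter_records([rec] + others)
        assert rec in kept and report.dropped_mutation == 0

    def test_individual_with_two_sequences_removed(self):
        records = [make_record("I0"), make_record("I0"),
                   make_record("I1"), make_record("I1"), make_record("I1")]
        kept, report = filter_records(records)
        assert {r.individual for r in kept} == {"I1"}
        assert report.dropped_individuals == ["I0"]
        assert report.dropped_few_sequences == 2

    def test_pristine_input_unchanged(self):
        records = [make_record("I0") for _ in range(3)]
        kept, report = filter_records(records)
        assert kept == records
        assert report.dropped_mutation == 0 and report.dropped_few_sequences == 0


class TestClones:
    def test_shared_key_one_clone(self):
        records = [make_record("I0") for _ in range(5)]
        clones = group_clones(records)
        assert len(clones) == 1 and len(clones[0].members) == 5

    def test_cdr3_length_separates_clones(self):
        records = [make_record("I0", cdr3=15), make_record("I0", cdr3=16)]
        assert len(group_clones(records)) == 2

    def test_partition_covers_every_record(self):
        spec = RepertoireSimSpec(n_individuals=3, clones_per_individual=5,
                                 members_per_clone=2, seed=4)
        records = simulate_repertoire(spec)
        clones = group_clones(records)
        assert sum(len(c.members) for c in clones) == len(records)

    def test_mutational_event_counted_once_per_clone(self):
        germ = {50: "TCT"}
        members = [make_record("I0", germ=germ, seq={50: "AGT" if i < 3 else "TCT"})
                   for i in range(5)]
        clone = Clone("I0", ("V", "J", 15), members)
        events = clone.events(range(1, N_POSITIONS + 1))
        assert events == {(50, "TCT", "AGT")}

    def test_event_count_bounded(self):
        spec = RepertoireSimSpec(n_individuals=2, clones_per_individual=4,
                                 members_per_clone=3, mutation_rate=0.1, seed=5)
        for clone in group_clones(simulate_repertoire(spec)):
            events = clone.events(range(1, N_POSITIONS + 1))
            assert len(events) <= len(clone.members) * N_POSITIONS


class TestCoverage:
    def test_boundary_at_threshold(self):
        records = [make_record("I0") for _ in range(30)]
        assert position_coverage_filter(records, MASK, 30) == MASK.analyzed
        assert position_coverage_filter(records[:29], MASK, 30) == frozenset()

    def test_gapped_position_not_covered(self):
        gapped = [ReceptorRecord("I0", "..." + "GCT" * 105, "..." + "GCT" * 105,
                                 "V", "J", 10) for _ in range(30)]
        covered = position_coverage_filter(gapped, MASK, 30)
        assert 25 in covered  # position 1 is not analyzed anyway; 25 intact

    def test_empty_input_empty_set(self):
        assert position_coverage_filter([], MASK, 30) == frozenset()


class TestGermlineContrast:
    def test_extreme_planted_split(self):
        """CDR germline serines AGY and FWR germline serines TCN maximise
        the GS2N difference and minimise the S1PA one."""
        clones = []
        for i in range(6):
            germ = {}
            for pos in sorted(MASK.analyzed):
                region = MASK.region_of(pos)
                germ[pos] = "AGT" if region == "CDR" else "TCT"
            clones.append(Clone("I0", ("V", "J", i),
                                [make_record("I0", germ=germ, cdr3=i)]))
        summary = germline_region_contrast(clones, MASK.analyzed, MASK)
        assert summary.germline_difference["GS2N"] > 0
        assert summary.germline_difference["S1PA"] < 0

    def test_identical_usage_zero_difference(self):
        clones = [Clone("I0", ("V", "J", i),
                        [make_record("I0", germ={p: "AGT" for p in MASK.analyzed},
                                     cdr3=i)])
                  for i in range(4)]
        summary = germline_region_contrast(clones, MASK.analyzed, MASK)
        assert summary.germline_difference["GS2N"] == pytest.approx(0.0)

    def test_planted_bias_recovered_from_simulation(self):
        spec = RepertoireSimSpec(n_individuals=4, clones_per_individual=20,
                                 members_per_clone=2, beta_cdr=0.9, beta_fwr=0.1,
                                 seed=6)
        result = run_repertoire_analysis(simulate_repertoire(spec))
        diffs = [s.germline_difference["GS2N"] for s in result.summaries]
        assert all(d > 0 for d in diffs)


class TestSomaticContrast:
    def test_extreme_substitution_split_gives_difference_one(self):
        clones = []
        for i in range(4):
            germ = {p: "AGT" if MASK.region_of(p) == "CDR" else "TCT"
                    for p in MASK.analyzed}
            seq = {}
            for pos in sorted(MASK.analyzed):
                # CDR substitutions to glycine, FWR substitutions to proline
                seq[pos] = "GGT" if MASK.region_of(pos) == "CDR" else "CCT"
            clones.append(Clone("I0", ("V", "J", i),
                                [make_record("I0", germ=germ, seq=seq, cdr3=i)]))
        summary = somatic_region_contrast(clones, MASK.analyzed, MASK)
        assert summary.somatic_difference == pytest.approx(1.0)

    def test_no_substitutions_excludes_individual(self):
        clones = [Clone("I0", ("V", "J", i),
                        [make_record("I0", germ={p: "TCT" for p in MASK.analyzed},
                                     cdr3=i)])
                  for i in range(4)]
        assert somatic_region_contrast(clones, MASK.analyzed, MASK) is None

    def test_balanced_substitutions_near_zero(self):
        clones = []
        for i in range(4):
            germ = {p: "TCT" for p in MASK.analyzed}
            # every position carries one G and one P substitution, so the
            # GS2N share is 0.5 everywhere in both regions
            members = [make_record("I0", germ=germ,
                                   seq={p: "GGT" for p in MASK.analyzed}, cdr3=i),
                       make_record("I0", germ=germ,
                                   seq={p: "CCT" for p in MASK.analyzed}, cdr3=i)]
            clones.append(Clone("I0", ("V", "J", i), members))
        summary = somatic_region_contrast(clones, MASK.analyzed, MASK)
        assert summary.somatic_difference == pytest.approx(0.0)


class TestCohortTest:
    def test_all_positive_hits_exact_minimal_p(self):
        n = 20
        result = cross_individual_test([0.1 * (i + 1) for i in range(n)])
        assert result.successes == n and result.total == n
        # exact oracle: two-sided P(W- <= 0) under sign flips = 2 / 2^n
        assert result.p_value == pytest.approx(2 / 2 ** n)

    def test_symmetric_null_not_significant(self):
        rng = np.random.default_rng(8)
        diffs = rng.normal(0, 1, 20)
        assert cross_individual_test(diffs).p_value > 0.01

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError):
            cross_individual_test([0.5])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cross_individual_test([0.0, 0.0, 0.0])


class TestOrderInvariance:
    def test_statistics_invariant_to_record_order(self):
        spec = RepertoireSimSpec(n_individuals=3, clones_per_individual=8,
                                 members_per_clone=2, beta_cdr=0.8, beta_fwr=0.2,
                                 seed=9)
        records = simulate_repertoire(spec)
        rng = np.random.default_rng(0)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        r1 = run_repertoire_analysis(records)
        r2 = run_repertoire_analysis(shuffled)
        d1 = [s.germline_difference for s in r1.summaries]
        d2 = [s.germline_difference for s in r2.summaries]
        assert d1 == d2


def test_null_success_proportion_is_calibrated():
    """At equal CDR/FWR serine bias the sign of the per-individual
    difference is a fair coin (checked over 40 small cohorts)."""
    pos = neg = 0
    for seed in range(40):
        spec = RepertoireSimSpec(n_individuals=5, clones_per_individual=10,
                                 members_per_clone=2, beta_cdr=0.5,
                                 beta_fwr=0.5, seed=1000 + seed)
        result = run_repertoire_analysis(simulate_repertoire(spec))
        for s in result.summaries:
            d = s.germline_difference.get("GS2N")
            if d:
                pos += d > 0
                neg += d < 0
    total = pos + neg
    # two-sided binomial band at ~4 sigma
    low, high = binom.ppf([0.00005, 0.99995], total, 0.5)
    assert low <= pos <= high
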