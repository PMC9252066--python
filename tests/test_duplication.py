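import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_differences, oracle_kaks, oracle_sites
from genefam.cli_report import classify_named_pairs
from genefam.core_model import GeneLocus, PipelineConfig, ValidationError
from genefam.duplication_evolution import (
    classify_pair,
    compute_ratio,
    divergence_time,
    jukes_cantor,
    kaks,
    ng86_differences,
    ng86_sites,
    selection_regime,
    truncate,
)
from genefam.synthetic_data import simulate_duplication_set

SENSE_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - {"TAA", "TAG", "TGA"}
)


class TestSites:
    @pytest.mark.parametrize(
        "codon,expected_syn",
        [("TTT", 1 / 3), ("GGG", 1.0), ("ATG", 0.0)],
    )
    def test_hand_enumerated_codons(self, codon, expected_syn):
        syn, nonsyn = ng86_sites(codon)
        assert syn == pytest.approx(expected_syn)
        assert syn + nonsyn == pytest.approx(3.0)

    def test_sites_sum_to_three_for_every_sense_codon(self):
        for codon in SENSE_CODONS:
            syn, nonsyn = ng86_sites(codon)
            assert syn + nonsyn == pytest.approx(3.0)
            assert syn >= 0 and nonsyn >= 0

    def test_oracle_equivalence_all_codons(self):
        for codon in SENSE_CODONS:
            assert ng86_sites(codon) == pytest.approx(oracle_sites(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValidationError):
            ng86_sites("TAA")
        with pytest.raises(ValidationError):
            ng86_sites("ANA")


class TestDifferences:
    def test_single_synonymous_change(self):
        assert ng86_differences("TTG", "TTA") == (1.0, 0.0)

    def test_two_pathway_average(self):
        # TTT->GTA via GTT: syn+nonsyn 1+1; via TTA: 0+2; average (0.5, 1.5)
        assert ng86_differences("TTT", "GTA") == pytest.approx((0.5, 1.5))

    def test_identical_codons(self):
        assert ng86_differences("AAA", "AAA") == (0.0, 0.0)

    def test_difference_count_conserved_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b = rng.choice(SENSE_CODONS, size=2)
            nd = sum(x != y for x, y in zip(a, b))
            ds, dn = ng86_differences(a, b)
            assert ds + dn == pytest.approx(nd)

    def test_oracle_equivalence_random_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            a, b = rng.choice(SENSE_CODONS, size=2)
            assert ng86_differences(a, b) == pytest.approx(oracle_differences(a, b))


class TestJukesCantor:
    def test_known_values(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.5) == pytest.approx(0.8239, abs=1e-4)

    def test_monotone_increasing(self):
        ps = np.linspace(0, 0.74, 50)
        ds = [jukes_cantor(p) for p in ps]
        assert all(x < y for x, y in zip(ds, ds[1:]))

    def test_saturation(self):
        assert math.isnan(jukes_cantor(0.75))


class TestKaks:
    def test_identical_pair(self):
        cds = "".join(["ATG", "GGG", "TTT", "AAA"] * 30)
        ka, ks, ratio = kaks(cds, cds)
        assert (ka, ks) == (0.0, 0.0)
        assert math.isnan(ratio)

    def test_synonymous_only_pair(self):
        pairs, _, _ = simulate_duplication_set(1, 300, syn_subs=5, nonsyn_subs=0, seed=9)
        _, ca, _, cb = pairs[0]
        ka, ks, ratio = kaks(ca, cb)
        assert ka == 0.0 and ks > 0 and ratio == 0.0

    def test_oracle_equivalence_planted_pair(self):
        pairs, _, _ = simulate_duplication_set(
            1, 300, syn_subs=10, nonsyn_subs=10, seed=10
        )
        _, ca, _, cb = pairs[0]
        ka, ks, _ = kaks(ca, cb)
        oka, oks = oracle_kaks(ca, cb)
        assert ka == pytest.approx(oka, rel=1e-9)
        assert ks == pytest.approx(oks, rel=1e-9)

    def test_symmetric(self):
        pairs, _, _ = simulate_duplication_set(1, 100, syn_subs=5, nonsyn_subs=5, seed=11)
        _, ca, _, cb = pairs[0]
        assert kaks(ca, cb)[:2] == pytest.approx(kaks(cb, ca)[:2])

    def test_gapped_protein_alignment_backthreading(self):
        # one codon deleted in b: alignment restores the comparable columns
        ca = "ATGGGGTTTAAACCC"
        cb = "ATGGGGAAACCC"
        pa, pb = ("MGFKP", "MG-KP")
        ka, ks, _ = kaks(ca + "TAA", cb + "TAA", (pa, pb))
        assert (ka, ks) == (0.0, 0.0)

    def test_parameter_recovery_over_replicates(self):
        # ~5% planted divergence over 300 codons, 20 seeded replicates
        for seed in range(20):
            pairs, _, _ = simulate_duplication_set(
                1, 300, syn_subs=10, nonsyn_subs=10, seed=100 + seed
            )
            _, ca, _, cb = pairs[0]
            ka, ks, ratio = kaks(ca, cb)
            oka, oks = oracle_kaks(ca, cb)
            assert abs(ka - oka) <= 0.25 * max(oka, 1e-12)
            assert abs(ks - oks) <= 0.25 * max(oks, 1e-12)


class TestRatioAndTime:
    @pytest.mark.parametrize(
        "ka,ks,expected",
        [(0.1664, 2.5295, 0.0657), (0.2294, 1.5649, 0.1465), (0.228, 0.7719, 0.2953),
         (0.1584, 1.0913, 0.1451), (0.1399, 1.0607, 0.1318)],
    )
    def test_reported_ratios_truncated_to_4dp(self, ka, ks, expected):
        assert truncate(compute_ratio(ka, ks), 4) == pytest.approx(expected)

    def test_zero_over_zero_undefined(self):
        assert math.isnan(compute_ratio(0.0, 0.0))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            compute_ratio(-0.1, 0.5)

    @pytest.mark.parametrize(
        "ks,rate,expected",
        [(0.7719, 1.5e-8, 25.73), (2.5295, 1.5e-8, 84.31), (1.0913, 1.5e-8, 36.37),
         (0.7719, 6.1e-9, 63.27), (0.0, 1.5e-8, 0.0)],
    )
    def test_divergence_times(self, ks, rate, expected):
        assert truncate(divergence_time(ks, rate), 2) == pytest.approx(expected)

    def test_undefined_ks_not_determinable(self):
        assert math.isnan(divergence_time(float("nan"), 1.5e-8))

    @pytest.mark.parametrize(
        "ratio,regime",
        [(0.0657, "purifying"), (2.0, "positive"), (1.0, "neutral"),
         (float("nan"), "undetermined")],
    )
    def test_selection_regime(self, ratio, regime):
        assert selection_regime(ratio) == regime


class TestClassification:
    def test_tandem_within_window(self):
        a = GeneLocus("Sobic.003G203500", "Chr03", "+", 53_331_225, 53_339_384)
        b = GeneLocus("Sobic.003G203600", "Chr03", "+", 53_368_965, 53_376_625)
        assert b.start - a.end == 29_581
        assert classify_pair(a, b) == "tandem"

    def test_cross_chromosome_segmental(self):
        a = GeneLocus("Sobic.003G356000", "Chr03", "+", 67_427_644, 67_434_548)
        b = GeneLocus("Sobic.009G160100", "Chr09", "+", 51_779_375, 51_800_133)
        assert classify_pair(a, b) == "segmental"

    def test_same_chromosome_beyond_window_segmental(self):
        a = GeneLocus("g1", "Chr01", "+", 1_000, 2_000)
        b = GeneLocus("g2", "Chr01", "+", 152_001, 153_000)
        assert classify_pair(a, b) == "segmental"

    def test_overlapping_spans_gap_zero(self):
        a = GeneLocus("g1", "Chr01", "+", 1_000, 5_000)
        b = GeneLocus("g2", "Chr01", "+", 4_000, 9_000)
        assert classify_pair(a, b) == "tandem"

    def test_self_comparison_rejected(self):
        a = GeneLocus("g1", "Chr01", "+", 1_000, 5_000)
        with pytest.raises(ValidationError):
            classify_pair(a, a)

    def test_fixture_pairs_one_tandem_five_segmental(self, table1, table2):
        pairs = classify_named_pairs(table1, table2)
        classes = [p.dup_class for p in pairs]
        assert classes.count("tandem") == 1
        assert classes.count("segmental") == 5
        tandem = next(p for p in pairs if p.dup_class == "tandem")
        assert {tandem.locus_a, tandem.locus_b} == {"SbALDH2C1", "SbALDH2C2"}
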