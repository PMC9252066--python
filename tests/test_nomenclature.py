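import numpy as np
import pytest

from _oracles import brute_force_global_score
from genefam.agnc_nomenclature import (
    FamilyAssignment,
    ReferenceEntry,
    assign_family,
    build_symbol,
    global_align,
    make_aligner,
    percent_identity,
)
from genefam.core_model import GeneLocus, PipelineConfig, ValidationError
from genefam.synthetic_data import simulate_family_panel


class TestGlobalAlign:
    def test_identical_sequences_ungapped(self):
        ga, gb, score = global_align("ACD", "ACD")
        assert ga == gb == "ACD"

    def test_simple_scoring_matches_brute_force(self):
        al = make_aligner(matrix=None, gap_open=1.0, gap_extend=1.0)
        ga, gb, score = global_align("ACD", "AD", al)
        assert (ga, gb) == ("ACD", "A-D")
        assert score == brute_force_global_score("ACD", "AD") == 1.0

    @pytest.mark.parametrize("a,b", [("AC", "GT"), ("ACDE", "AE"), ("A", "ACC")])
    def test_brute_force_score_equivalence(self, a, b):
        al = make_aligner(matrix=None, gap_open=1.0, gap_extend=1.0)
        _, _, score = global_align(a, b, al)
        assert score == brute_force_global_score(a, b)

    def test_single_mismatch_column(self):
        al = make_aligner(matrix=None, gap_open=1.0, gap_extend=1.0)
        ga, gb, _ = global_align("A", "G", al)
        assert (ga, gb) == ("A", "G")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            global_align("", "ACD")

    def test_score_symmetric(self):
        rng = np.random.default_rng(7)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(aas, size=rng.integers(5, 30)))
            b = "".join(rng.choice(aas, size=rng.integers(5, 30)))
            _, _, s1 = global_align(a, b)
            _, _, s2 = global_align(b, a)
            assert s1 == s2


class TestPercentIdentity:
    def test_identity(self):
        assert percent_identity("ABCDEFGHIJ", "ABCDEFGHIJ") == 100.0

    def test_gap_columns_count_in_denominator(self):
        assert percent_identity("ACD", "A-D") == pytest.approx(200 / 3)

    def test_no_identical_columns(self):
        assert percent_identity("AAAA", "GGGG") == 0.0

    def test_symmetric(self):
        assert percent_identity("AC-D", "A-CD") == percent_identity("A-CD", "AC-D")


class TestAssignFamily:
    @pytest.fixture()
    def panel(self):
        rng = np.random.default_rng(11)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        return [
            ReferenceEntry(f"REF{f}", "".join(rng.choice(aas, size=300)), f, "B")
            for f in (1, 2)
        ]

    @staticmethod
    def _mutate(seq, frac, seed):
        rng = np.random.default_rng(seed)
        k = round(frac * len(seq))
        pos = rng.choice(len(seq), size=k, replace=False)
        out = list(seq)
        for p in pos:
            out[p] = rng.choice([a for a in "ACDEFGHIKLMNPQRSTVWY" if a != out[p]])
        return "".join(out)

    def test_above_subfamily_threshold_inherits_both(self, panel):
        q = self._mutate(panel[1].sequence, 0.15, 1)
        a = assign_family("q", q, panel)
        assert (a.family, a.subfamily) == (2, "B")
        assert a.best_reference == "REF2"

    def test_between_thresholds_new_subfamily(self, panel):
        q = self._mutate(panel[0].sequence, 0.50, 2)
        a = assign_family("q", q, panel)
        assert a.family == 1
        assert a.subfamily == "A"  # next unused letter, B taken by the reference

    def test_below_family_threshold_novel(self, panel):
        q = self._mutate(panel[0].sequence, 0.75, 3)
        a = assign_family("q", q, panel)
        assert a.family == "novel" and a.subfamily == "new"

    def test_empty_panel_rejected(self):
        with pytest.raises(ValidationError):
            assign_family("q", "ACDEF", [])

    def test_threshold_equality_falls_to_lower_tier(self, panel):
        # identity exactly 60.0 must NOT inherit the subfamily
        cfg = PipelineConfig()
        q = self._mutate(panel[0].sequence, 0.40, 4)
        a = assign_family("q", q, panel)
        if a.identity == 60.0:
            assert a.subfamily != panel[0].subfamily


class TestBuildSymbol:
    def test_fixture_like_symbols(self):
        loci = {
            "L1": GeneLocus("Sobic.004G250900", "Chr04", "+", 59_720_135, 59_725_595),
            "L2": GeneLocus("Sobic.002G426100", "Chr02", "+", 77_251_658, 77_257_367),
        }
        assignments = {
            "L1": FamilyAssignment("L1", "r", 80.0, 2, "B"),
            "L2": FamilyAssignment("L2", "r", 80.0, 22, "A"),
        }
        variants = {"L1": ["L1.1", "L1.2"], "L2": ["L2.1"]}
        symbols = build_symbol("Sb", "ALDH", assignments, loci, variants)
        assert symbols["L1.1"] == "SbALDH2B1a"
        assert symbols["L1.2"] == "SbALDH2B1b"
        assert symbols["L2.1"] == "SbALDH22A1"  # sole transcript: no variant letter

    def test_numbering_by_chromosome_then_start(self):
        # one subfamily spread over Chr3 (53.3 Mb) and Chr10 (51.6 Mb):
        # chromosome order outranks coordinate
        loci = {
            "A": GeneLocus("Sobic.010G178300", "Chr10", "+", 51_625_698, 51_631_645),
            "B": GeneLocus("Sobic.003G203500", "Chr03", "+", 53_331_225, 53_339_384),
        }
        assignments = {k: FamilyAssignment(k, "r", 80.0, 2, "C") for k in loci}
        variants = {"A": ["A.1"], "B": ["B.1"]}
        symbols = build_symbol("Sb", "ALDH", assignments, loci, variants)
        assert symbols["B.1"] == "SbALDH2C1"
        assert symbols["A.1"] == "SbALDH2C2"

    def test_symbols_unique(self):
        loci = {
            f"L{i}": GeneLocus(f"Sobic.00{1 + i % 3}G{i:06d}", f"Chr0{1 + i % 3}", "+", i * 1000 + 1, i * 1000 + 500)
            for i in range(6)
        }
        assignments = {
            lid: FamilyAssignment(lid, "r", 80.0, 1 + i % 2, "A")
            for i, lid in enumerate(loci)
        }
        variants = {lid: [f"{lid}.1", f"{lid}.2"] for lid in loci}
        symbols = build_symbol("Sb", "ALDH", assignments, loci, variants)
        assert len(set(symbols.values())) == len(symbols)

    def test_too_many_variants_rejected(self):
        loci = {"L": GeneLocus("Sobic.001G000100", "Chr01", "+", 1, 10)}
        assignments = {"L": FamilyAssignment("L", "r", 80.0, 1, "A")}
        variants = {"L": [f"L.{i}" for i in range(27)]}
        with pytest.raises(ValidationError):
            build_symbol("Sb", "ALDH", assignments, loci, variants)


class TestPlantedRecovery:
    def test_planted_identity_levels_recovered(self):
        queries, panel, manifest = simulate_family_panel(
            2, 3, [85.0, 50.0, 25.0], seed=42
        )
        for qid, seq in queries:
            truth = manifest.entries[qid]
            a = assign_family(qid, seq, panel)
            if truth["identity_level"] > 60:
                assert a.family == truth["family"]
                assert a.subfamily == "A"
            elif truth["identity_level"] > 40:
                assert a.family == truth["family"]
                assert a.subfamily != "A"
            else:
                assert a.family == "novel"
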