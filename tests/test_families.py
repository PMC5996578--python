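"""Family rulebook: motif matching, copy counting, frequency matrices."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuropep.families import (
    FamilyRule,
    c_terminal_pad,
    classify_peptide,
    count_family_copies,
    frequency_matrix,
    load_rulebook,
    measure_cys_spacing,
    measure_trp_spacing,
    save_rulebook,
)


class TestClassification:
    def test_luqin_peptide_is_both_rfamide_and_luqin(self, family_rules):
        fams = classify_peptide(("APQWRPQGRF", True), family_rules)
        assert {"luqin", "RFamide"} <= set(fams)
        assert fams.index("luqin") < fams.index("RFamide")  # priority order

    def test_allatostatin_c_by_cys_spacing(self, family_rules):
        fams = classify_peptide(("GHIQCLVNLVACY", True), family_rules)
        assert "allatostatin_C" in fams

    def test_myomodulin_motif(self, family_rules):
        assert "myomodulin" in classify_peptide(("GMNMLRL", True), family_rules)

    def test_wwamide_is_allatostatin_b(self, family_rules):
        assert "allatostatin_B" in classify_peptide(("GWKDMGTW", True), family_rules)

    def test_amidation_requirement_gates_matches(self, family_rules):
        assert classify_peptide(("APQWRPQGRF", False), family_rules) == []

    def test_npf_and_cck_motifs(self, family_rules):
        npf = "QEAMLEPPDRPHSFRTPDQLRSYLRALNEYYSIVGRPRF"
        assert "NPF" in classify_peptide((npf, True), family_rules)
        assert "CCK/SK" in classify_peptide(("QGRWDLDYGLGGGRF", True), family_rules)

    def test_pgwamide_tetrapeptides(self, family_rules):
        for seq in ("APGW", "TPGW", "SPGW"):
            assert "PGWamide" in classify_peptide((seq, True), family_rules)
        assert "PGWamide" not in classify_peptide(("APGWA", True), family_rules)


class TestTrpSpacing:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("WAAAAW", True),  # 4 between: molluscan spacing
            ("WAAAAAW", True),  # 5 between
            ("WAAAAAAW", False),  # 6 between: insect spacing, rejected
            ("WAAAAAAAW", False),  # 7 between
        ],
    )
    def test_molluscan_spacings_only(self, family_rules, seq, expected):
        fams = classify_peptide((seq, True), family_rules)
        assert ("allatostatin_B" in fams) is expected


class TestNaiveScanAgreement:
    def test_rule_engine_matches_naive_per_rule_scan(self, family_rules):
        """1000 random peptides against a re-implementation of each rule."""

        def naive_match(rule, seq, amid):
            if rule.amidation_required and not amid:
                return False
            if rule.kind == "c_terminal_motif":
                pat = rule.pattern
                if len(seq) < len(pat):
                    return False
                tail = seq[-len(pat):]
                return all(p == "x" or p == c for p, c in zip(pat, tail))
            if rule.kind == "pattern":
                pat = rule.pattern
                # expand single residue-class bracket by trying all members
                if "[" in pat:
                    start, end = pat.index("["), pat.index("]")
                    return any(
                        naive_match(
                            FamilyRule(rule.name, "pattern",
                                       pat[:start] + ch + pat[end + 1:], False),
                            seq, amid)
                        for ch in pat[start + 1 : end]
                    )
                if len(seq) != len(pat):
                    return False
                return all(p == "x" or p == c for p, c in zip(pat, seq))
            if rule.kind == "cys_spacing":
                pos = [i for i, c in enumerate(seq) if c == "C"]
                return any(
                    q - p - 1 in rule.spacings()
                    for i, p in enumerate(pos) for q in pos[i + 1:]
                )
            if rule.kind == "trp_spacing":
                pos = [i for i, c in enumerate(seq) if c == "W"]
                return (
                    len(pos) >= 2
                    and pos[0] <= 1
                    and pos[-1] == len(seq) - 1
                    and (pos[-1] - pos[0] - 1) in rule.spacings()
                )
            raise AssertionError(rule.kind)

        rng = random.Random(40)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(1000):
            seq = "".join(rng.choice(alphabet) for _ in range(rng.randrange(3, 16)))
            amid = rng.random() < 0.5
            got = set(classify_peptide((seq, amid), family_rules))
            want = {r.name for r in family_rules if naive_match(r, seq, amid)}
            assert got == want, (seq, amid)


class TestCopyCounting:
    def test_fmrf_domain_counts_24(self, benchmark, family_rules):
        fmrf_tx = next(
            r["id"]
            for r in benchmark["manifest"]["transcripts"]
            if r["template"] == "fmrfamide"
        )
        peps = benchmark["peptides"][fmrf_tx]
        assert count_family_copies(peps, "FMRFamide", family_rules) == 24

    def test_luqin_single_copy(self, benchmark, family_rules):
        luqin_tx = next(
            r["id"]
            for r in benchmark["manifest"]["transcripts"]
            if r["template"] == "luqin"
        )
        assert count_family_copies(benchmark["peptides"][luqin_tx], "luqin", family_rules) == 1

    def test_no_rfamide_units_counts_zero(self, family_rules):
        assert count_family_copies([("GWKDMGTW", True)], "RFamide", family_rules) == 0

    def test_unknown_family_raises(self, family_rules):
        with pytest.raises(KeyError):
            count_family_copies([], "nonexistent", family_rules)


class TestFrequencyMatrix:
    def test_identical_sequences_give_unit_columns(self):
        m = frequency_matrix(["FMRF", "FMRF"])
        for j, res in enumerate("FMRF"):
            assert m.loc[res, j] == 1.0
        assert np.allclose(m.sum(axis=0), 1.0)

    def test_mixed_column_frequencies(self):
        m = frequency_matrix(["AR", "GR"])
        assert m.loc["A", 0] == 0.5 and m.loc["G", 0] == 0.5
        assert m.loc["R", 1] == 1.0

    def test_columns_sum_to_one_on_random_input(self):
        rng = random.Random(41)
        seqs = [
            "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(12))
            for _ in range(100)
        ]
        m = frequency_matrix(seqs)
        assert np.all(np.abs(m.sum(axis=0) - 1.0) < 1e-9)

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ACDEFGHIKLMNPQRSTVWY-", min_size=8, max_size=8),
            min_size=1,
            max_size=20,
        )
    )
    def test_columns_always_sum_to_one(self, seqs):
        m = frequency_matrix(seqs)
        assert np.all(np.abs(m.sum(axis=0) - 1.0) < 1e-9)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            frequency_matrix(["AA", "AAA"])

    def test_c_terminal_padding(self):
        assert c_terminal_pad(["FMRF", "RF"]) == ["FMRF", "--RF"]


class TestSpacingMeasures:
    def test_allatostatin_c_cys_spacing(self):
        assert measure_cys_spacing("GHIQCLVNLVACY") == 6

    def test_allatostatin_b_trp_spacing(self):
        assert measure_trp_spacing("GWKDMGTW") == 5


class TestRulebookIO:
    def test_round_trip(self, tmp_path, family_rules):
        path = tmp_path / "rules.tsv"
        save_rulebook(family_rules, path)
        assert load_rulebook(path) == family_rules
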