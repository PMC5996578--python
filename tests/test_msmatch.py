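"""MS confirmation: score filter, monoisotopic masses, matching."""

import pandas as pd
import pytest

from neuropep.msmatch import (
    ConfirmationReport,
    ObservedPeptide,
    filter_observations,
    match_observations,
    monoisotopic_mass,
)
from neuropep.processing import MaturePeptide

# Frozen residue monoisotopic masses (independent oracle table).
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.01056


def oracle_mass(seq: str) -> float:
    return sum(RESIDUE_MASS[c] for c in seq) + WATER


def mature(seq: str, precursor="p1", start=0, amidated=True, pyroglu="none") -> MaturePeptide:
    return MaturePeptide(
        sequence=seq,
        precursor_id=precursor,
        start=start,
        end=start + len(seq),
        amidated=amidated,
        pyroglu=pyroglu,
        disulfide_candidates=(),
        unpaired_cys=None,
        copy_index=1,
    )


class TestScoreFilter:
    def test_boundary_score_20_excluded(self):
        df = pd.DataFrame({"peptide": ["A", "B", "C"], "modifications": ["", "", ""],
                           "score": [20.0, 20.5, 19.9]})
        kept = filter_observations(df)
        assert list(kept["score"]) == [20.5]

    def test_empty_table_stays_empty(self):
        df = pd.DataFrame({"peptide": [], "modifications": [], "score": []})
        assert filter_observations(df).empty


class TestMass:
    def test_glycine(self):
        assert monoisotopic_mass("G") == pytest.approx(75.03203, abs=1e-4)

    def test_amidated_fmrf_vs_residue_table_oracle(self):
        expected = oracle_mass("FMRF") - 0.98402
        assert monoisotopic_mass("FMRF", ["amidated"]) == pytest.approx(expected, abs=1e-3)

    def test_composition_symmetry(self):
        assert monoisotopic_mass("AG") == pytest.approx(monoisotopic_mass("GA"), abs=1e-9)

    def test_modification_deltas_vs_oracle(self):
        base = oracle_mass("QGMW")
        cases = {
            "pyroglu_fromQ": -17.02655,
            "met_oxidation": +15.99491,
            "met_dioxidation": +31.98983,
            "acetyl_nterm": +42.01057,
        }
        for mod, delta in cases.items():
            assert monoisotopic_mass("QGMW", [mod]) == pytest.approx(base + delta, abs=1e-3)

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            monoisotopic_mass("GGZG")


class TestObservedValidation:
    def test_pyroglu_requires_matching_n_terminus(self):
        with pytest.raises(ValueError):
            ObservedPeptide("AGF", frozenset({"pyroglu_fromQ"}), 30.0)

    def test_oxidation_requires_met(self):
        with pytest.raises(ValueError):
            ObservedPeptide("AGF", frozenset({"met_oxidation"}), 30.0)


class TestMatching:
    def test_allatostatin_b_peptide_matches(self):
        obs = [ObservedPeptide("GWKDMGTW", frozenset({"amidated"}), 45.0)]
        rep = match_observations(obs, [mature("GWKDMGTW")])
        assert rep.confirmed == {"p1": True}
        assert rep.percentage == 100.0

    def test_unknown_sequence_goes_to_orphans(self):
        obs = [ObservedPeptide("YYYYYY", frozenset(), 45.0)]
        rep = match_observations(obs, [mature("GWKDMGTW")])
        assert rep.confirmed == {"p1": False}
        assert len(rep.orphans) == 1

    def test_pyroglu_potential_matches_with_and_without(self):
        pred = [mature("QGRWDLDYGLGGGRF", pyroglu="fromQ")]
        with_mod = ObservedPeptide(
            "QGRWDLDYGLGGGRF", frozenset({"amidated", "pyroglu_fromQ"}), 50.0
        )
        without = ObservedPeptide("QGRWDLDYGLGGGRF", frozenset({"amidated"}), 50.0)
        assert match_observations([with_mod], pred).confirmed["p1"]
        assert match_observations([without], pred).confirmed["p1"]

    def test_observed_pyroglu_needs_predicted_license(self):
        pred = [mature("QGRF", pyroglu="none")]
        obs = ObservedPeptide("QGRF", frozenset({"amidated", "pyroglu_fromQ"}), 50.0)
        assert not match_observations([obs], pred).confirmed["p1"]

    def test_amidation_state_must_agree(self):
        pred = [mature("FMRF", amidated=True)]
        obs = ObservedPeptide("FMRF", frozenset(), 50.0)  # not amidated
        assert not match_observations([obs], pred).confirmed["p1"]

    def test_mass_tolerance_rejects_discrepant_observations(self):
        good_mass = monoisotopic_mass("FMRF", ["amidated"])
        pred = [mature("FMRF")]
        ok = ObservedPeptide("FMRF", frozenset({"amidated"}), 50.0, good_mass * (1 + 5e-6))
        bad = ObservedPeptide("FMRF", frozenset({"amidated"}), 50.0, good_mass * (1 + 5e-5))
        assert match_observations([ok], pred).confirmed["p1"]
        assert not match_observations([bad], pred).confirmed["p1"]

    def test_injective_assignment_prefers_first_position(self):
        preds = [
            mature("FMRF", precursor="p2", start=40),
            mature("FMRF", precursor="p1", start=10),
            mature("FMRF", precursor="p1", start=90),
        ]
        obs = [ObservedPeptide("FMRF", frozenset({"amidated"}), 50.0)]
        rep = match_observations(obs, preds)
        assert rep.confirmed == {"p1": True, "p2": False}
        matched = rep.per_precursor["p1"]
        assert len(matched) == 1 and matched[0][1].start == 10

    def test_leu_ile_distinct_by_default_collapsible(self):
        pred = [mature("FLRF")]
        obs = [ObservedPeptide("FIRF", frozenset({"amidated"}), 50.0)]
        assert not match_observations(obs, pred).confirmed["p1"]
        assert match_observations(obs, pred, collapse_leu_ile=True).confirmed["p1"]


class TestReportArithmetic:
    def test_percentage_rounding_convention(self):
        assert ConfirmationReport.compute_percentage(31, 63) == 49.21

    def test_percentage_matches_recomputation(self):
        preds = [mature("FMRF", precursor=f"p{i}") for i in range(7)]
        obs = [ObservedPeptide("FMRF", frozenset({"amidated"}), 50.0)]
        rep = match_observations(obs, preds)
        assert rep.percentage == ConfirmationReport.compute_percentage(
            rep.confirmed_count, rep.total_count
        )
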