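"""Signal heuristic, cleavage-site grammar, repeat detection, criteria."""

import random

import pytest

from neuropep.discovery import (
    CleavageSite,
    classify_candidate,
    detect_repeats,
    evaluate_orf,
    find_cleavage_sites,
    predict_signal,
)
from neuropep.orf import OpenReadingFrame

HYDROPHILIC_TAIL = "DQNERDSTNQESNDGEDQNERDSTNQESNDGE"


def orf_of(protein: str) -> OpenReadingFrame:
    return OpenReadingFrame("t", "+", 0, 0, 3 * (len(protein) + 1), protein)


class TestSignalPrediction:
    def test_hydrophobic_core_with_small_cleavage_site(self):
        sig = predict_signal("MKTLLLLLLLLLALAS" + HYDROPHILIC_TAIL)
        assert sig.has_signal
        assert sig.cleavage_after == 15  # earliest small -1/-3 point

    def test_acidic_n_terminus_fails_hydropathy_floor(self):
        sig = predict_signal("M" + "DEDEDEDEDEDEDE" + HYDROPHILIC_TAIL)
        assert not sig.has_signal

    def test_short_protein_gets_no_signal(self):
        assert not predict_signal("MKTLLLLLLLLLALAS").has_signal

    def test_missing_initiator_met_fails(self):
        assert not predict_signal("KTLLLLLLLLLALASA" + HYDROPHILIC_TAIL).has_signal

    def test_anchor_like_hydrophobic_mature_region_fails(self):
        # hydrophobic character continues past the putative cleavage point
        protein = "MKTLLLLLLLLLALAS" + "LVLFLVLFLVLFLVLFLVLFLVLFLVLF"
        assert not predict_signal(protein).has_signal

    def test_synthetic_precursor_signals_recovered(self, benchmark):
        called = 0
        precursors = [
            r for r in benchmark["manifest"]["transcripts"] if r["label"] == "precursor"
        ]
        for rec in precursors:
            sig = predict_signal(rec["protein"])
            if sig.has_signal and sig.cleavage_after == rec["signal_length"]:
                called += 1
        assert called / len(precursors) >= 0.95


def brute_force_sites(protein: str) -> list[tuple]:
    """Rule-by-rule scan written independently of the run-based scanner."""
    claimed = [False] * len(protein)
    found = []

    def is_basic(c):
        return c in "KR"

    # tetrabasic first (longest rule)
    i = 0
    while i + 4 <= len(protein):
        window = protein[i : i + 4]
        if all(is_basic(c) for c in window) and not any(claimed[i : i + 4]):
            left_ok = i == 0 or not is_basic(protein[i - 1])
            if left_ok:
                found.append((i, "tetrabasic", window))
                for k in range(i, i + 4):
                    claimed[k] = True
                # consume the whole basic run
                j = i + 4
                while j < len(protein) and is_basic(protein[j]):
                    claimed[j] = True
                    j += 1
                i = j
                continue
        i += 1
    # dibasic
    i = 0
    while i + 2 <= len(protein):
        if (
            is_basic(protein[i])
            and is_basic(protein[i + 1])
            and not claimed[i]
            and not claimed[i + 1]
            and (i == 0 or not is_basic(protein[i - 1]))
        ):
            found.append((i, "dibasic", protein[i : i + 2]))
            claimed[i] = claimed[i + 1] = True
            i += 2
            continue
        i += 1
    # monobasic R with a basic at -3/-5/-7 (2, 4 or 6 positions N-terminal)
    for i, c in enumerate(protein):
        if c == "R" and not claimed[i]:
            if any(i - d >= 0 and is_basic(protein[i - d]) for d in (2, 4, 6)):
                found.append((i, "monobasic", "R"))
    return sorted(found)


class TestCleavageSites:
    def test_dibasic_example(self):
        sites = find_cleavage_sites("AAKRAA")
        assert [(s.position, s.site_type, s.motif) for s in sites] == [(2, "dibasic", "KR")]

    def test_tetrabasic_furin_site(self):
        sites = find_cleavage_sites("AARKRRAA")
        assert [(s.position, s.site_type, s.motif) for s in sites] == [
            (2, "tetrabasic", "RKRR")
        ]

    def test_monobasic_needs_upstream_basic_context(self):
        assert [
            (s.position, s.site_type) for s in find_cleavage_sites("AKARAA")
        ] == [(3, "monobasic")]
        assert find_cleavage_sites("AAARAA") == []
        # lysine alone is never a monobasic site, even with context
        assert find_cleavage_sites("AKAKAA") == []

    def test_matches_brute_force_rulebook(self):
        rng = random.Random(20)
        residues = "AKRGSDE"
        for _ in range(200):
            protein = "".join(rng.choice(residues) for _ in range(rng.randrange(5, 60)))
            got = sorted(
                (s.position, s.site_type, s.motif) for s in find_cleavage_sites(protein)
            )
            assert got == brute_force_sites(protein), protein


class TestRepeats:
    def test_fmrf_domain_counts_24_copies(self):
        protein = "FMRFGKR" * 24
        sites = [
            s for s in find_cleavage_sites(protein) if s.site_type != "monobasic"
        ]
        assert detect_repeats(protein, sites) == 24

    def test_distinct_fragments_count_one(self):
        protein = "AADDWWKRGGSSYYKRDWDWDW"
        sites = find_cleavage_sites(protein)
        frags_distinct = detect_repeats(protein, sites, min_identity=0.9)
        assert frags_distinct == 1

    def test_two_identical_one_unrelated(self):
        protein = "AAADDDKRAAADDDKRWWWYYY"
        sites = find_cleavage_sites(protein)
        assert detect_repeats(protein, sites) == 2

    def test_fewer_than_two_fragments_returns_fragment_count(self):
        assert detect_repeats("AAAA", []) == 1

    def test_permutation_invariance(self):
        # same fragments in shuffled order give the same count
        frags = ["FMRFG", "FMRFG", "WWYYD", "FMRFG", "SSTTA"]
        rng = random.Random(21)
        counts = set()
        for _ in range(5):
            rng.shuffle(frags)
            protein, sites, pos = "", [], 0
            for f in frags[:-1]:
                protein += f + "KR"
                sites.append(CleavageSite(pos + len(f), "dibasic", "KR"))
                pos += len(f) + 2
            protein += frags[-1]
            counts.add(detect_repeats(protein, sites))
        assert counts == {3}


class TestClassification:
    def test_decoy_with_repeats_but_no_signal_rejected(self, benchmark):
        rejected = [
            r
            for r in benchmark["manifest"]["transcripts"]
            if r["template"] == "decoy_repeats_no_signal"
        ]
        assert rejected  # the benchmark contains such decoys
        accepted_ids = {c.orf.transcript_id for c in benchmark["candidates"]}
        assert not accepted_ids & {r["id"] for r in rejected}

    def test_luqin_style_precursor_accepted_with_amidation(self):
        from neuropep.synthetic import build_signal

        protein = build_signal(23) + "APQWRPQGRF" + "G" + "KR" + "SDPETDSNANLFDPNQSAVE"
        cand = evaluate_orf(orf_of(protein))
        assert cand.accepted
        assert cand.criteria_flags["amidation_gly"]

    def test_homology_only_candidate_flagged_partial(self):
        protein = "M" + "DENQ" * 20  # no architecture at all
        cand = evaluate_orf(orf_of(protein), homology_flag=True)
        assert not cand.accepted
        assert cand.partial
        assert cand.evidence == "homology"

    def test_acceptance_invariant_over_benchmark(self, benchmark):
        for c in benchmark["candidates"]:
            f = c.criteria_flags
            assert f["signal"] and f["cleavage"]
            assert f["amidation_gly"] or c.repeat_count >= 2 or f["cys_pattern"]
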