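"""Pairwise Ka/Ks estimation with the Nei-Gojobori (NG86) counting method.

For each codon the number of synonymous sites is the fraction of possible
single-nucleotide changes that preserve the encoded amino acid (changes
creating stop codons are excluded from the denominator), summed over the
three positions and averaged between the two sequences. Substitutions in
codons differing at more than one position are counted by averaging the
synonymous/non-synonymous steps over all mutational pathways, skipping
pathways that pass through a stop codon. Both raw proportions receive the
Jukes-Cantor multiple-hit correction; a proportion >= 3/4 makes the
correction undefined and flags the result as saturated.

Selection classes follow the conventional thresholds: Ka/Ks > 1 strong
positive selection, 0.5 < Ka/Ks <= 1 a moderate-positive candidate,
Ka/Ks <= 0.5 purifying; the ratio (and hence the class) is undefined when
Ks is zero or saturated.

Input alignments are caller-provided; gap codons (any codon containing
``-`` in either sequence) are stripped pairwise before counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = set(_TABLE.stop_codons)
NUCS = "ACGT"

SelectionClass = Literal[
    "strong_positive", "moderate_positive_candidate", "purifying", "undefined"
]


@dataclass(frozen=True)
class KaKsResult:
    pair_id: str
    ka: float
    ks: float
    ratio: float | None
    selection_class: SelectionClass
    saturated: bool
    syn_sites: float
    nonsyn_sites: float
    syn_subs: float
    nonsyn_subs: float
    n_codons: int


@lru_cache(maxsize=None)
def _syn_site_fraction(codon: str) -> float:
    """Synonymous sites of one codon (sum of per-position fractions)."""
    if codon in STOP_CODONS:
        return 0.0
    aa = CODON_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        considered = 0
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            considered += 1
            if CODON_AA[mutant] == aa:
                syn += 1
        if considered:
            total += syn / considered
    return total


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) substitutions between two codons,
    averaged over stop-free mutational pathways.

    Recursion over the first substituted position; a step is skipped when
    the intermediate codon is a stop. If every pathway is blocked by stops
    the average falls back to all pathways (stops allowed as intermediates).
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return (0.0, 0.0)

    def walk(cur: str, allow_stops: bool) -> tuple[float, float, int]:
        """Sum of (syn, nonsyn) over complete pathways from `cur`, plus the
        number of complete pathways."""
        rem = [i for i in range(3) if cur[i] != c2[i]]
        if not rem:
            return (0.0, 0.0, 1)
        syn_total = nonsyn_total = 0.0
        n_paths = 0
        for pos in rem:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops and nxt != c2:
                continue
            s_rest, n_rest, k = walk(nxt, allow_stops)
            if k == 0:
                continue
            step_syn = (
                1.0
                if nxt not in STOP_CODONS
                and cur not in STOP_CODONS
                and CODON_AA.get(nxt) == CODON_AA.get(cur)
                else 0.0
            )
            syn_total += k * step_syn + s_rest
            nonsyn_total += k * (1.0 - step_syn) + n_rest
            n_paths += k
        return syn_total, nonsyn_total, n_paths

    syn, nonsyn, n_paths = walk(c1, allow_stops=False)
    if n_paths == 0:
        syn, nonsyn, n_paths = walk(c1, allow_stops=True)
    return (syn / n_paths, nonsyn / n_paths)


def _codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def strip_gap_codons(a: str, b: str) -> tuple[str, str]:
    """Remove codon columns containing a gap in either sequence."""
    kept_a, kept_b = [], []
    for ca, cb in zip(_codons(a), _codons(b)):
        if "-" in ca or "-" in cb:
            continue
        kept_a.append(ca)
        kept_b.append(cb)
    return "".join(kept_a), "".join(kept_b)


def jukes_cantor(p: float) -> float:
    """JC69 distance; raises ValueError at saturation (p >= 3/4)."""
    if p >= 0.75:
        raise ValueError("proportion >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0


def ng86_kaks(cds_a: str, cds_b: str, pair_id: str = "pair") -> KaKsResult:
    """NG86 Ka, Ks and selection class for one aligned CDS pair."""
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned coding sequences must have equal length")
    if len(a) % 3:
        raise ValueError("aligned length must be a multiple of 3")
    a, b = strip_gap_codons(a, b)
    if not a:
        raise ValueError("no ungapped codons to compare")
    bad = (set(a) | set(b)) - set(NUCS)
    if bad:
        raise ValueError(f"non-ACGT characters in coding sequence: {sorted(bad)}")
    codons_a, codons_b = _codons(a), _codons(b)
    internal_a, internal_b = codons_a[:-1], codons_b[:-1]
    if any(c in STOP_CODONS for c in internal_a + internal_b):
        raise ValueError("internal stop codon in coding sequence")
    # A terminal stop pair is permitted and dropped from counting.
    if codons_a[-1] in STOP_CODONS or codons_b[-1] in STOP_CODONS:
        codons_a, codons_b = codons_a[:-1], codons_b[:-1]
        if not codons_a:
            raise ValueError("no sense codons to compare")

    S = sum((_syn_site_fraction(ca) + _syn_site_fraction(cb)) / 2.0
            for ca, cb in zip(codons_a, codons_b))
    n_codons = len(codons_a)
    N = 3.0 * n_codons - S

    Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        s, n = _pathway_counts(ca, cb)
        Sd += s
        Nd += n

    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    saturated = False
    try:
        ks = jukes_cantor(ps)
    except ValueError:
        ks, saturated = float("nan"), True
    try:
        ka = jukes_cantor(pn)
    except ValueError:
        ka, saturated = float("nan"), True

    if saturated or math.isnan(ks) or ks == 0.0:
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(
        pair_id=pair_id,
        ka=ka,
        ks=ks,
        ratio=ratio,
        selection_class=classify_selection(ratio),
        saturated=saturated,
        syn_sites=S,
        nonsyn_sites=N,
        syn_subs=Sd,
        nonsyn_subs=Nd,
        n_codons=n_codons,
    )


def classify_selection(ratio: float | None) -> SelectionClass:
    """Thresholds applied exactly as conventionally printed: > 1 strong
    positive; 0.5 < ratio <= 1 moderate-positive candidate; otherwise
    purifying. Undefined ratios stay undefined."""
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        return "undefined"
    if ratio < 0:
        raise ValueError("Ka/Ks ratio cannot be negative")
    if ratio > 1.0:
        return "strong_positive"
    if ratio > 0.5:
        return "moderate_positive_candidate"
    return "purifying"


def kaks_table(pairs: Sequence[tuple[str, str, str]]) -> list[KaKsResult]:
    """Run NG86 over (pair_id, cds_a, cds_b) triples."""
    return [ng86_kaks(a, b, pair_id=pid) for pid, a, b in pairs]


def write_kaks_tsv(results: Sequence[KaKsResult], path) -> None:
    import pandas as pd

    rows = [
        {
            "pair": r.pair_id,
            "ka": r.ka,
            "ks": r.ks,
            "ratio": "" if r.ratio is None else r.ratio,
            "class": r.selection_class,
            "saturated": r.saturated,
            "n_codons": r.n_codons,
        }
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["pair", "ka", "ks", "ratio", "class", "saturated", "n_codons"]
    ).to_csv(path, sep="\t", index=False)
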