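"""De novo recognition of neuropeptide precursor candidates.

An ORF is promoted to a precursor candidate when it shows the canonical
prepropeptide architecture: (i) an N-terminal signal peptide, (ii) mono-,
di- or tetrabasic convertase cleavage sites, and at least one of (iii) a
glycine amidation substrate immediately N-terminal to a cleavage site,
repeated inter-site peptides, or (iv) a cysteine pattern consistent with
disulfide bridging.

Signal peptides are called with a two-feature heuristic (best hydrophobic
window + small residues at the -1/-3 positions of the candidate cleavage
point); externally computed signal predictions can be supplied instead via
a 3-column table (id, has_signal, cleavage_after).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from neuropep.orf import OpenReadingFrame

logger = logging.getLogger(__name__)

BASIC = set("KR")
SMALL = set("AGSCT")  # accepted at the -1/-3 positions of a signal cleavage
STRONG_HYDROPHOBIC = set("CFILV")  # Kyte-Doolittle >= 2.5

# Signal heuristic defaults: hydrophobic core window within the first 30
# residues, cleavage point scanned over residues 15..40.
HYDRO_WINDOW = 8
HYDRO_MIN = 2.0
CLEAVE_RANGE = (15, 40)

SiteType = Literal["monobasic", "dibasic", "tetrabasic"]


@dataclass(frozen=True)
class SignalPrediction:
    has_signal: bool
    cleavage_after: int | None  # 1-based position of the last signal residue
    score: float

    def __post_init__(self) -> None:
        if self.has_signal and not (10 <= (self.cleavage_after or 0) <= 40):
            raise ValueError("signal cleavage_after must lie in [10, 40]")


@dataclass(frozen=True)
class CleavageSite:
    position: int  # 0-based index of the first basic residue of the motif
    site_type: SiteType
    motif: str

    def __post_init__(self) -> None:
        if set(self.motif) - BASIC:
            raise ValueError(f"cleavage motif must be K/R only: {self.motif!r}")
        expected = {"monobasic": 1, "dibasic": 2, "tetrabasic": 4}[self.site_type]
        if len(self.motif) != expected:
            raise ValueError(f"{self.site_type} motif must have {expected} residues")

    @property
    def end(self) -> int:
        return self.position + len(self.motif)


@dataclass
class PrecursorCandidate:
    orf: OpenReadingFrame
    signal: SignalPrediction
    sites: list[CleavageSite]
    criteria_flags: dict[str, bool]
    evidence: Literal["homology", "de_novo", "both"]
    repeat_count: int
    score: float
    accepted: bool
    partial: bool = False  # homology evidence without the de novo architecture


def predict_signal(
    protein: str,
    hydro_min: float = HYDRO_MIN,
    window: int = HYDRO_WINDOW,
    cleave_range: tuple[int, int] = CLEAVE_RANGE,
) -> SignalPrediction:
    """Heuristic signal-peptide call.

    Requires the initiator methionine, (a) the best ``window``-residue mean
    Kyte-Doolittle hydropathy within residues 1-30 to exceed ``hydro_min``,
    (b) a small residue (A/G/S/C/T) at both the -1 and -3 positions of
    some cleavage point in residues 15-40, and (c) that the 30 residues
    following the cleavage point are predominantly hydrophilic (< 50%
    strongly hydrophobic residues), i.e. the protein is a cleaved secretory
    protein rather than a signal-anchor / membrane protein whose
    hydrophobic character simply continues. The earliest cleavage point
    satisfying (b) and (c) is reported. The Met requirement reflects that a
    signal peptide is an N-terminal feature of the translated protein, not
    of an arbitrary read-through fragment.
    """
    if len(protein) < 30:
        logger.warning("protein of %d residues too short for a signal call", len(protein))
        return SignalPrediction(False, None, 0.0)
    if not protein.startswith("M"):
        return SignalPrediction(False, None, 0.0)
    head = protein[:30]
    best = max(
        (
            sum(KYTE_DOOLITTLE.get(c, -4.5) for c in head[i : i + window]) / window
            for i in range(len(head) - window + 1)
        ),
    )
    if best <= hydro_min:
        return SignalPrediction(False, None, float(best))
    lo, hi = cleave_range
    for c in range(lo, min(hi, len(protein)) + 1):
        if protein[c - 1] not in SMALL or protein[c - 3] not in SMALL:
            continue
        mature_head = protein[c : c + 30]
        if not mature_head:
            continue
        hydrophobic = sum(1 for r in mature_head if r in STRONG_HYDROPHOBIC)
        if hydrophobic / len(mature_head) >= 0.5:
            continue
        return SignalPrediction(True, c, float(best))
    return SignalPrediction(False, None, float(best))


def read_signal_table(path: str | Path) -> dict[str, SignalPrediction]:
    """Ingest external signal predictions: id <TAB> has_signal <TAB> cleavage_after."""
    out: dict[str, SignalPrediction] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("id\t"):
                continue
            name, has, cleave = line.split("\t")[:3]
            flag = has.strip().lower() in {"1", "true", "yes"}
            out[name] = SignalPrediction(
                flag, int(cleave) if flag else None, score=float("nan")
            )
    return out


def find_cleavage_sites(protein: str) -> list[CleavageSite]:
    """Scan for prohormone-convertase cleavage sites.

    Maximal K/R runs are resolved longest-first, left-to-right: runs of
    four or more report a single tetrabasic (furin-type) site; runs of two
    or three report a dibasic site at the run start; an isolated (or
    leftover) R is a monobasic site only when another basic residue lies
    2, 4 or 6 positions N-terminal (the -3/-5/-7 rule).
    """
    sites: list[CleavageSite] = []
    n = len(protein)
    i = 0
    while i < n:
        if protein[i] not in BASIC:
            i += 1
            continue
        j = i
        while j < n and protein[j] in BASIC:
            j += 1
        run_len = j - i
        if run_len >= 4:
            sites.append(CleavageSite(i, "tetrabasic", protein[i : i + 4]))
        elif run_len >= 2:
            sites.append(CleavageSite(i, "dibasic", protein[i : i + 2]))
            if run_len == 3 and protein[i + 2] == "R":
                p = i + 2
                if any(p - d >= 0 and protein[p - d] in BASIC for d in (2, 4, 6)):
                    sites.append(CleavageSite(p, "monobasic", "R"))
        else:
            if protein[i] == "R" and any(
                i - d >= 0 and protein[i - d] in BASIC for d in (2, 4, 6)
            ):
                sites.append(CleavageSite(i, "monobasic", "R"))
        i = j
    return sites


def _lcs_len(a: str, b: str) -> int:
    """Length of the longest common subsequence (gap-free match count of the
    best global alignment under match=1, mismatch/gap=0)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def fragment_identity(a: str, b: str) -> float:
    """Global alignment identity normalised by the longer fragment."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return _lcs_len(a, b) / max(len(a), len(b))


def inter_site_fragments(protein: str, sites: Sequence[CleavageSite]) -> list[str]:
    """Protein segments between consecutive cleavage-site motifs."""
    frags = []
    prev = 0
    for s in sorted(sites, key=lambda s: s.position):
        frags.append(protein[prev : s.position])
        prev = s.end
    frags.append(protein[prev:])
    return [f for f in frags if f]


def detect_repeats(
    protein: str,
    sites: Sequence[CleavageSite],
    min_identity: float = 0.5,
) -> int:
    """Size of the largest cluster of mutually similar inter-site fragments.

    Fragments are compared pairwise with length-normalised global identity;
    clusters are connected components of the >= ``min_identity`` graph.
    """
    frags = inter_site_fragments(protein, sites)
    if len(frags) < 2:
        return len(frags)
    n = len(frags)
    parent = list(range(n))

    def root(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if fragment_identity(frags[i], frags[j]) >= min_identity:
                parent[root(i)] = root(j)
    sizes: dict[int, int] = {}
    for i in range(n):
        r = root(i)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values())


def classify_candidate(
    orf: OpenReadingFrame,
    signal: SignalPrediction,
    sites: Sequence[CleavageSite],
    repeat_count: int,
    homology_flag: bool = False,
) -> PrecursorCandidate:
    """Apply the four precursor criteria and assemble the candidate record.

    Acceptance requires signal AND cleavage AND (amidation glycine OR
    repeat_count >= 2 OR cysteine pattern). A transcript with homology
    evidence but without the de novo architecture is reported as a partial,
    homology-only candidate.
    """
    protein = orf.protein
    start = signal.cleavage_after or 0
    mature_sites = [s for s in sites if s.position >= start]
    has_cleavage = bool(mature_sites)
    amidation_gly = any(
        s.position > 0 and protein[s.position - 1] == "G" for s in mature_sites
    )
    cys_pattern = protein[start:].count("C") >= 2
    flags = {
        "signal": signal.has_signal,
        "cleavage": has_cleavage,
        "amidation_gly": amidation_gly,
        "cys_pattern": cys_pattern,
    }
    de_novo_ok = (
        signal.has_signal
        and has_cleavage
        and (amidation_gly or repeat_count >= 2 or cys_pattern)
    )
    if de_novo_ok and homology_flag:
        evidence = "both"
    elif de_novo_ok:
        evidence = "de_novo"
    else:
        evidence = "homology"
    score = (
        1.0 * flags["signal"]
        + 1.0 * flags["cleavage"]
        + 1.0 * flags["amidation_gly"]
        + 0.5 * flags["cys_pattern"]
        + 0.5 * (repeat_count >= 3)
    )
    accepted = de_novo_ok
    partial = (not de_novo_ok) and homology_flag
    return PrecursorCandidate(
        orf=orf,
        signal=signal,
        sites=list(mature_sites),
        criteria_flags=flags,
        evidence=evidence,
        repeat_count=repeat_count,
        score=score,
        accepted=accepted,
        partial=partial,
    )


def evaluate_orf(
    orf: OpenReadingFrame,
    homology_flag: bool = False,
    min_identity: float = 0.5,
    signal_override: SignalPrediction | None = None,
    hydro_min: float = HYDRO_MIN,
) -> PrecursorCandidate:
    """Run the full de novo assessment for one ORF."""
    protein = orf.protein
    signal = signal_override or predict_signal(protein, hydro_min=hydro_min)
    sites = find_cleavage_sites(protein)
    start = signal.cleavage_after or 0
    mature_sites = [s for s in sites if s.position >= start]
    # Repeat units are delimited by the sites that are actually cleaved;
    # putative monobasic sites stay inside their fragments.
    shifted = [
        CleavageSite(s.position - start, s.site_type, s.motif)
        for s in mature_sites
        if s.site_type != "monobasic"
    ]
    repeat_count = detect_repeats(protein[start:], shifted, min_identity=min_identity)
    return classify_candidate(orf, signal, sites, repeat_count, homology_flag)


def _overlap_fraction(a: OpenReadingFrame, b: OpenReadingFrame) -> float:
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return ov / max(1, min(a.end - a.start, b.end - b.start))


def merge_candidates(candidates: Sequence[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """Union of the homology and de novo evidence streams.

    Candidates are deduplicated per transcript when their ORF coordinate
    spans overlap by more than 50% (the higher-scoring candidate is kept).
    """
    kept: list[PrecursorCandidate] = []
    for cand in sorted(
        candidates, key=lambda c: (-c.score, c.orf.transcript_id, c.orf.start)
    ):
        dup = any(
            k.orf.transcript_id == cand.orf.transcript_id
            and _overlap_fraction(k.orf, cand.orf) > 0.5
            for k in kept
        )
        if not dup:
            kept.append(cand)
    kept.sort(key=lambda c: (c.orf.transcript_id, c.orf.start))
    return kept
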