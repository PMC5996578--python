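"""Translated local-alignment homology stage.

A panel of known neuropeptide precursor proteins is aligned against all six
frame translations of each transcript with affine-gap Smith-Waterman
(BLOSUM62, gap open 11 / extend 1, the classic protein-search defaults).
This plays the role a translated BLAST search plays in transcriptome
annotation, without word seeding or E-value statistics: hits are filtered
on raw score, with the default threshold sitting above the score
distribution of shuffled (composition-matched) queries.

A gap of length k costs ``gap_open + k * gap_extend``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from neuropep.orf import Transcript, six_frame_translate

logger = logging.getLogger(__name__)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
# Raw-score threshold: sits above both shuffled-composition nulls and the
# chained-repeat noise that tandem-repeat queries produce against
# repeat-bearing non-homologs, while staying well below genuine full-length
# precursor matches. calibrate_min_score() recalibrates for a given panel.
DEFAULT_MIN_SCORE = 170.0


@dataclass(frozen=True)
class Alignment:
    score: float
    a_interval: tuple[int, int]  # 0-based half-open on sequence a
    b_interval: tuple[int, int]
    a_aligned: str
    b_aligned: str


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    transcript_id: str
    strand: str
    frame: int
    score: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]  # residue coords within the frame translation
    expect: float | None = None


def _matrix_lookup(matrix) -> tuple[dict[tuple[str, str], float], float]:
    alpha = matrix.alphabet
    lut = {}
    floor = float("inf")
    for i, x in enumerate(alpha):
        for j, y in enumerate(alpha):
            v = float(matrix[i, j])
            lut[(x, y)] = v
            floor = min(floor, v)
    return lut, floor


def smith_waterman(
    a: str,
    b: str,
    matrix=BLOSUM62,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Optimal local alignment under affine gaps (Gotoh).

    Traceback is deterministic: on ties prefer the diagonal move, then the
    vertical (gap in ``b``), then the horizontal. Residues outside the
    substitution matrix alphabet score the matrix floor against everything
    (with a warning), so unknowns can never anchor an alignment.
    """
    if not a or not b:
        raise ValueError("smith_waterman requires non-empty sequences")
    if not (gap_open >= gap_extend >= 0):
        raise ValueError("require gap_open >= gap_extend >= 0")
    lut, floor = _matrix_lookup(matrix)
    alphabet = set(matrix.alphabet)
    unknown = (set(a) | set(b)) - alphabet
    if unknown:
        logger.warning("unknown residues scored at matrix floor: %s", sorted(unknown))

    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    best, best_pos = 0.0, (0, 0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = lut.get((ai, b[j - 1]), floor)
            E[i, j] = max(H[i, j - 1] - gap_open - gap_extend, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_extend, F[i - 1, j] - gap_extend)
            h = max(0.0, H[i - 1, j - 1] + sub, F[i, j], E[i, j])
            H[i, j] = h
            if h > best:
                best, best_pos = h, (i, j)
    if best <= 0:
        return Alignment(0.0, (0, 0), (0, 0), "", "")

    # Traceback from the best cell down to the first zero.
    i, j = best_pos
    a_out: list[str] = []
    b_out: list[str] = []
    state = "H"
    while H[i, j] > 0 or state != "H":
        if state == "H":
            sub = lut.get((a[i - 1], b[j - 1]), floor)
            if H[i, j] == H[i - 1, j - 1] + sub:
                a_out.append(a[i - 1])
                b_out.append(b[j - 1])
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            a_out.append(a[i - 1])
            b_out.append("-")
            if F[i, j] == F[i - 1, j] - gap_extend:
                i -= 1
            else:  # opened here
                i -= 1
                state = "H"
        else:  # E
            a_out.append("-")
            b_out.append(b[j - 1])
            if E[i, j] == E[i, j - 1] - gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
    return Alignment(
        score=float(best),
        a_interval=(i, best_pos[0]),
        b_interval=(j, best_pos[1]),
        a_aligned="".join(reversed(a_out)),
        b_aligned="".join(reversed(b_out)),
    )


def mask_low_complexity(seq: str, max_run: int = 5) -> str:
    """Mask homopolymer runs longer than ``max_run`` to X.

    Plays the role of the low-complexity query filter in translated
    database searches: without it, shared low-complexity features such as
    poly-Leu signal-peptide cores dominate the hit list.
    """
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        out.append(seq[i:j] if j - i <= max_run else "X" * (j - i))
        i = j
    return "".join(out)


def _fast_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def search_panel(
    queries: Mapping[str, str],
    transcripts: Sequence[Transcript],
    min_score: float = DEFAULT_MIN_SCORE,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    mask_queries: bool = True,
) -> list[HomologyHit]:
    """Best hit per (query, transcript) pair with score >= ``min_score``.

    Queries are low-complexity masked by default (see
    :func:`mask_low_complexity`). Scores are screened with Biopython's C
    aligner (identical scoring scheme, hence identical optimal scores);
    alignment intervals for reported hits come from
    :func:`smith_waterman`.
    """
    if not queries:
        raise ValueError("query panel is empty")
    if mask_queries:
        queries = {qid: mask_low_complexity(q) for qid, q in queries.items()}
    aligner = _fast_aligner(gap_open, gap_extend)
    hits: list[HomologyHit] = []
    for t in transcripts:
        frames = six_frame_translate(t)
        for qid, qseq in queries.items():
            best = None  # (score, strand, frame, frame_aa)
            for (strand, frame), aa in frames.items():
                if not aa:
                    continue
                score = float(aligner.score(qseq, aa))
                if best is None or score > best[0]:
                    best = (score, strand, frame, aa)
            if best is None or best[0] < min_score:
                continue
            score, strand, frame, aa = best
            aln = smith_waterman(qseq, aa, gap_open=gap_open, gap_extend=gap_extend)
            hits.append(
                HomologyHit(
                    query_id=qid,
                    transcript_id=t.id,
                    strand=strand,
                    frame=frame,
                    score=aln.score,
                    query_interval=aln.a_interval,
                    subject_interval=aln.b_interval,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.query_id, h.transcript_id))
    return hits


def flagged_transcripts(hits: Sequence[HomologyHit]) -> set[str]:
    """Transcripts carrying at least one hit (homology evidence)."""
    return {h.transcript_id for h in hits}


def calibrate_min_score(
    queries: Mapping[str, str],
    transcripts: Sequence[Transcript],
    n_shuffles: int = 1000,
    quantile: float = 1.0,
    margin: float = 5.0,
    seed: int = 0,
) -> float:
    """Empirical-null score threshold from shuffled queries.

    Each shuffle permutes a query's residues (composition preserved) and
    records its best score over the transcript set; the returned threshold
    is the given quantile of that null plus ``margin``.
    """
    rng = np.random.default_rng(seed)
    aligner = _fast_aligner(DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND)
    qlist = list(queries.values())
    frame_cache = [list(six_frame_translate(t).values()) for t in transcripts]
    null_scores = []
    for k in range(n_shuffles):
        q = qlist[k % len(qlist)]
        shuffled = "".join(rng.permutation(list(q)))
        best = 0.0
        for frames in frame_cache:
            for aa in frames:
                if aa:
                    best = max(best, float(aligner.score(shuffled, aa)))
        null_scores.append(best)
    return float(np.quantile(null_scores, quantile) + margin)


def write_hits_tsv(hits: Sequence[HomologyHit], path) -> None:
    import pandas as pd

    rows = [
        {
            "query": h.query_id,
            "transcript": h.transcript_id,
            "strand": h.strand,
            "frame": h.frame,
            "score": h.score,
            "query_start": h.query_interval[0],
            "query_end": h.query_interval[1],
            "subject_start": h.subject_interval[0],
            "subject_end": h.subject_interval[1],
            "expect": "" if h.expect is None else h.expect,
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=[
            "query",
            "transcript",
            "strand",
            "frame",
            "score",
            "query_start",
            "query_end",
            "subject_start",
            "subject_end",
            "expect",
        ],
    ).to_csv(path, sep="\t", index=False)
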