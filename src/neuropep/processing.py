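"""In-silico prohormone processing.

An accepted precursor is segmented into signal peptide, cleavage-site
motifs and intervening fragments; fragments become mature peptides after
basic-residue trimming, glycine-to-amide conversion and N-terminal
pyroglutamate annotation. The segmentation is a strict partition of the
precursor, so concatenating all segments reconstructs it exactly — the
invariant the conservation tests rely on.

Peptides are rendered in the conventional notation: the amidation
substrate glycine is dropped and the sequence gains an ``amide`` suffix
(e.g. ``APQWRPQGRFGKR`` -> ``APQWRPQGRFamide``). Pyroglutamate from an
N-terminal Gln/Glu is annotated as a potential modification rather than
applied, matching how variable modifications are treated in MS searches.

Monobasic sites are putative: many single-arginine contexts sit inside
genuine bioactive peptides (the NPF and luqin C-termini are classic
examples), so by default the engine cleaves only di- and tetrabasic sites
and leaves monobasic sites annotated but uncut; pass
``cleave_monobasic=True`` to cut everything the site scanner reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

from neuropep.discovery import BASIC, CleavageSite, PrecursorCandidate

logger = logging.getLogger(__name__)

MIN_PEPTIDE_LEN = 3
MAX_BASIC_TRIM = 4  # at most a tetrabasic run per terminus

PyroGlu = Literal["none", "fromQ", "fromE"]


@dataclass(frozen=True)
class MaturePeptide:
    sequence: str
    precursor_id: str
    start: int  # 0-based half-open span of `sequence` on the precursor
    end: int
    amidated: bool
    pyroglu: PyroGlu
    disulfide_candidates: tuple[tuple[int, int], ...]  # 1-based Cys positions
    unpaired_cys: int | None
    copy_index: int
    uncleaved: bool = False

    def render(self, apply_pyroglu: bool = False) -> str:
        return render_peptide(self.sequence, self.amidated, self.pyroglu, apply_pyroglu)


@dataclass(frozen=True)
class Segment:
    """One piece of the precursor partition."""

    kind: Literal["signal", "peptide", "amide_gly", "basic", "discarded"]
    start: int
    end: int
    text: str


def render_peptide(
    sequence: str,
    amidated: bool,
    pyroglu: PyroGlu = "none",
    apply_pyroglu: bool = False,
) -> str:
    seq = sequence
    prefix = ""
    if pyroglu != "none" and apply_pyroglu:
        prefix = "pyroGlu-"
        seq = seq[1:] if seq else seq
    return prefix + seq + ("amide" if amidated else "")


def assign_amidation(fragment: str, following_context: str) -> tuple[str, bool]:
    """Strip the amidation-substrate glycine when it abuts a basic site.

    The flag is set iff the fragment ends in Gly and the residue that
    followed it on the precursor was the first basic of a cleavage site.
    """
    if fragment.endswith("G") and following_context[:1] in BASIC:
        return fragment[:-1], True
    return fragment, False


def annotate_disulfides(sequence: str) -> tuple[tuple[tuple[int, int], ...], int | None]:
    """Pair consecutive cysteines (1-2, 3-4, ...); positions are 1-based.

    An odd cysteine count leaves the last one unpaired (returned separately).
    """
    cys = [i + 1 for i, c in enumerate(sequence) if c == "C"]
    pairs = tuple((cys[i], cys[i + 1]) for i in range(0, len(cys) - 1, 2))
    unpaired = cys[-1] if len(cys) % 2 else None
    return pairs, unpaired


def pyroglu_potential(sequence: str) -> PyroGlu:
    if sequence.startswith("Q"):
        return "fromQ"
    if sequence.startswith("E"):
        return "fromE"
    return "none"


def segment_precursor(
    protein: str,
    signal_cleavage: int,
    sites: Sequence[CleavageSite],
    min_len: int = MIN_PEPTIDE_LEN,
) -> list[Segment]:
    """Partition a precursor into labelled, non-overlapping segments.

    ``signal_cleavage`` is the 1-based position of the last signal residue
    (0 for none). Cleavage sites upstream of the signal boundary are
    ignored. Fragments shorter than ``min_len`` after trimming are labelled
    ``discarded`` but kept in the partition.
    """
    segments: list[Segment] = []
    if signal_cleavage:
        segments.append(Segment("signal", 0, signal_cleavage, protein[:signal_cleavage]))
    cursor = signal_cleavage
    mature_sites = sorted(
        (s for s in sites if s.position >= signal_cleavage), key=lambda s: s.position
    )
    bounds = [(s.position, s.end) for s in mature_sites] + [(len(protein), len(protein))]
    for site_start, site_end in bounds:
        frag_start, frag_end = cursor, site_start
        frag = protein[frag_start:frag_end]
        # basic-residue trimming, at most a tetrabasic run per terminus
        lead = 0
        while lead < min(MAX_BASIC_TRIM, len(frag)) and frag[lead] in BASIC:
            lead += 1
        trail = 0
        while (
            trail < min(MAX_BASIC_TRIM, len(frag) - lead)
            and frag[len(frag) - 1 - trail] in BASIC
        ):
            trail += 1
        if lead:
            segments.append(
                Segment("basic", frag_start, frag_start + lead, frag[:lead])
            )
        core_start, core_end = frag_start + lead, frag_end - trail
        core = protein[core_start:core_end]
        followed_by_site = site_start < len(protein)
        if followed_by_site and trail == 0 and core.endswith("G"):
            peptide, amid = core[:-1], True
        else:
            peptide, amid = core, False
        if peptide:
            pep_end = core_end - (1 if amid else 0)
            kind = "peptide" if len(peptide) >= min_len else "discarded"
            segments.append(Segment(kind, core_start, pep_end, peptide))
            if amid:
                segments.append(Segment("amide_gly", pep_end, core_end, "G"))
        elif amid:  # lone glycine fragment
            segments.append(Segment("amide_gly", core_start, core_end, "G"))
        if trail:
            segments.append(Segment("basic", core_end, frag_end, protein[core_end:frag_end]))
        if followed_by_site:
            segments.append(
                Segment("basic", site_start, site_end, protein[site_start:site_end])
            )
        cursor = site_end
    return segments


def release_peptides(
    precursor: PrecursorCandidate | None = None,
    *,
    protein: str | None = None,
    signal_cleavage: int | None = None,
    sites: Sequence[CleavageSite] | None = None,
    precursor_id: str = "precursor",
    min_len: int = MIN_PEPTIDE_LEN,
    cleave_monobasic: bool = False,
) -> list[MaturePeptide]:
    """Release mature peptides from an accepted precursor.

    Accepts either a :class:`PrecursorCandidate` or the raw
    (protein, signal_cleavage, sites) triple. With zero cleavage sites the
    whole pro-region is returned as a single peptide flagged uncleaved.
    """
    if precursor is not None:
        protein = precursor.orf.protein
        signal_cleavage = precursor.signal.cleavage_after or 0
        sites = precursor.sites
        precursor_id = precursor.orf.orf_id
    assert protein is not None and signal_cleavage is not None and sites is not None

    mature_sites = [
        s
        for s in sites
        if s.position >= signal_cleavage
        and (cleave_monobasic or s.site_type != "monobasic")
    ]
    uncleaved = not mature_sites
    segments = segment_precursor(protein, signal_cleavage, mature_sites, min_len=min_len)

    peptides: list[MaturePeptide] = []
    seen_counts: dict[str, int] = {}
    for idx, seg in enumerate(segments):
        if seg.kind != "peptide":
            continue
        amidated = idx + 1 < len(segments) and segments[idx + 1].kind == "amide_gly"
        seq = seg.text
        pairs, unpaired = annotate_disulfides(seq)
        seen_counts[seq] = seen_counts.get(seq, 0) + 1
        peptides.append(
            MaturePeptide(
                sequence=seq,
                precursor_id=precursor_id,
                start=seg.start,
                end=seg.end,
                amidated=amidated,
                pyroglu=pyroglu_potential(seq),
                disulfide_candidates=pairs,
                unpaired_cys=unpaired,
                copy_index=seen_counts[seq],
                uncleaved=uncleaved,
            )
        )
    return peptides


def reconstruct(segments: Sequence[Segment]) -> str:
    """Concatenate a segment partition back into the precursor sequence."""
    ordered = sorted(segments, key=lambda s: s.start)
    return "".join(s.text for s in ordered)


def write_peptides_tsv(peptides: Sequence[MaturePeptide], path) -> None:
    import pandas as pd

    rows = [
        {
            "precursor": p.precursor_id,
            "start": p.start,
            "end": p.end,
            "sequence": p.sequence,
            "amidated": p.amidated,
            "pyroglu": p.pyroglu,
            "copy_index": p.copy_index,
            "uncleaved": p.uncleaved,
            "rendered": p.render(),
        }
        for p in peptides
    ]
    pd.DataFrame(
        rows,
        columns=[
            "precursor",
            "start",
            "end",
            "sequence",
            "amidated",
            "pyroglu",
            "copy_index",
            "uncleaved",
            "rendered",
        ],
    ).to_csv(path, sep="\t", index=False)
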