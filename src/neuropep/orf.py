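"""Transcript ingest, six-frame translation and ORF extraction.

Coordinates are 0-based half-open on the forward strand of the transcript
throughout; 1-based inclusive conversion happens only in report writers.
When an ORF is terminated by a stop codon the coordinate span includes the
stop codon, so ``end - start`` is always a multiple of 3 and equals
``3 * (len(protein) + 1)`` for stop-terminated ORFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

STOP = "*"
_VALID_NT = set("ACGTN")

# Standard genetic code as an explicit lookup so that the translation
# contract is simple: any codon containing N renders as X, full stop.
_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = STOP

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Dialect = Literal["stop_to_stop", "atg_to_stop"]


@dataclass(frozen=True)
class Transcript:
    """A nucleotide record (A/C/G/T/N, uppercased on ingest)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(seq) - _VALID_NT
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: characters outside ACGTN: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OpenReadingFrame:
    transcript_id: str
    strand: str  # "+" or "-"
    frame: int  # 0..2, offset on the reading strand
    start: int  # forward-strand coords, 0-based half-open
    end: int
    protein: str

    @property
    def orf_id(self) -> str:
        return f"{self.transcript_id}|{self.strand}|{self.frame}|{self.start}-{self.end}"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_frame(nt: str) -> str:
    """Translate one reading frame codon by codon.

    Codons containing N translate to X; stop codons render as ``*``.
    Trailing bases short of a full codon are ignored.
    """
    out = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        out.append("X" if "N" in codon else CODON_TO_AA[codon])
    return "".join(out)


def six_frame_translate(t: Transcript) -> dict[tuple[str, int], str]:
    """All six frame translations keyed by (strand, frame offset)."""
    fwd, rev = t.sequence, revcomp(t.sequence)
    return {
        **{("+", f): translate_frame(fwd[f:]) for f in range(3)},
        **{("-", f): translate_frame(rev[f:]) for f in range(3)},
    }


def _frame_orfs(
    aa: str, min_len: int, dialect: Dialect
) -> Iterator[tuple[int, int, str]]:
    """Yield (start_codon_idx, end_codon_idx_exclusive, protein) in frame codon
    units; end index includes the terminating stop codon when present."""
    n = len(aa)
    seg_start = 0
    i = 0
    while i <= n:
        if i == n or aa[i] == STOP:
            seg_end = i  # codon index of the stop (or n if ran off the end)
            if dialect == "atg_to_stop":
                m = aa.find("M", seg_start, seg_end)
                start = m if m != -1 else None
            else:
                start = seg_start if seg_end > seg_start else None
            if start is not None:
                protein = aa[start:seg_end]
                if len(protein) >= min_len:
                    span_end = seg_end + 1 if i < n else seg_end
                    yield start, span_end, protein
            seg_start = i + 1
        i += 1


def find_orfs(
    t: Transcript, min_len: int = 60, dialect: Dialect = "stop_to_stop"
) -> list[OpenReadingFrame]:
    """Extract maximal ORFs on both strands.

    ``stop_to_stop`` keeps leading residues after the previous stop (the
    behaviour of classical getorf-style extractors); ``atg_to_stop`` starts
    at the first Met of each stop-free segment. Coordinates are reported on
    the forward strand, half-open, and include the terminating stop codon.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    L = len(t)
    orfs: list[OpenReadingFrame] = []
    frames = six_frame_translate(t)
    for (strand, frame), aa in frames.items():
        for c_start, c_end, protein in _frame_orfs(aa, min_len, dialect):
            s = frame + 3 * c_start
            e = frame + 3 * c_end
            if strand == "-":
                s, e = L - e, L - s
            orfs.append(
                OpenReadingFrame(
                    transcript_id=t.id,
                    strand=strand,
                    frame=frame,
                    start=s,
                    end=e,
                    protein=protein,
                )
            )
    orfs.sort(key=lambda o: (o.strand, o.start, o.end, o.frame))
    return orfs


def orf_protein_from_coords(t: Transcript, orf: OpenReadingFrame) -> str:
    """Re-translate an ORF from its coordinates (trailing stop stripped)."""
    nt = t.sequence[orf.start : orf.end]
    if orf.strand == "-":
        nt = revcomp(nt)
    return translate_frame(nt).rstrip(STOP)


# ---------------------------------------------------------------- FASTA IO


def read_fasta(path: str | Path) -> list[Transcript]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        try:
            out.append(Transcript(id=rec.id, sequence=str(rec.seq)))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return out


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA as an ordered id -> sequence mapping."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return {rec.id: str(rec.seq).upper() for rec in records}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_orf_fasta(orfs: Iterable[OpenReadingFrame], path: str | Path) -> None:
    write_fasta(((o.orf_id, o.protein) for o in orfs), path)
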