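"""Peptide-family annotation via a declarative motif rulebook.

Family definitions follow the motifs used in molluscan neuropeptidomics:
C-terminal amidated motifs (RFamide, luqin's WRPQGRFamide, NPF's
GRPRFamide, myomodulin's xxxMLRLamide, ...), whole-peptide patterns
(the xPGWamide tetrapeptides), cysteine spacing (allatostatin C: two Cys
with six residues between) and tryptophan spacing (molluscan
allatostatin B / WWamide: N-terminal Trp and C-terminal Trp-amide
separated by four or five residues).

Pattern language: uppercase residues match themselves, ``x`` matches any
residue, ``[ABC]`` matches a residue class. ``c_terminal_motif`` patterns
are anchored at the C-terminus, ``pattern`` rules must match the whole
peptide. ``cys_spacing``/``trp_spacing`` patterns are integer spacings
(comma-separated alternatives).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

RuleKind = ("c_terminal_motif", "cys_spacing", "trp_spacing", "pattern")

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilyRule:
    name: str
    kind: str
    pattern: str
    amidation_required: bool
    priority: int = 100

    def __post_init__(self) -> None:
        if self.kind not in RuleKind:
            raise ValueError(f"unknown rule kind: {self.kind}")
        if self.kind in ("cys_spacing", "trp_spacing"):
            spacings = self.spacings()
            if not spacings or any(s < 0 for s in spacings):
                raise ValueError(f"bad spacing pattern: {self.pattern}")

    def spacings(self) -> tuple[int, ...]:
        return tuple(int(s) for s in self.pattern.split(",") if s.strip())


def _wildcard_to_regex(pattern: str) -> str:
    out = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "x":
            out.append("[A-Z]")
            i += 1
        elif c == "[":
            j = pattern.index("]", i)
            out.append(pattern[i : j + 1])
            i = j + 1
        else:
            out.append(re.escape(c))
            i += 1
    return "".join(out)


def _match_rule(rule: FamilyRule, sequence: str, amidated: bool) -> bool:
    if rule.amidation_required and not amidated:
        return False
    if rule.kind == "c_terminal_motif":
        return re.search(_wildcard_to_regex(rule.pattern) + r"$", sequence) is not None
    if rule.kind == "pattern":
        return re.fullmatch(_wildcard_to_regex(rule.pattern), sequence) is not None
    if rule.kind == "cys_spacing":
        positions = [i for i, c in enumerate(sequence) if c == "C"]
        return any(
            q - p - 1 in rule.spacings()
            for i, p in enumerate(positions)
            for q in positions[i + 1 :]
        )
    if rule.kind == "trp_spacing":
        # N-terminal Trp (within the first two residues) and C-terminal
        # Trp (last residue, the amidated one), spacing counted between.
        positions = [i for i, c in enumerate(sequence) if c == "W"]
        if len(positions) < 2 or positions[0] > 1 or positions[-1] != len(sequence) - 1:
            return False
        return positions[-1] - positions[0] - 1 in rule.spacings()
    raise AssertionError(rule.kind)


def classify_peptide(peptide, rules: Sequence[FamilyRule]) -> list[str]:
    """All families a peptide matches, ordered by rule priority then name.

    ``peptide`` is a MaturePeptide-like object with ``sequence`` and
    ``amidated`` attributes, or a (sequence, amidated) tuple.
    """
    if isinstance(peptide, tuple):
        sequence, amidated = peptide
    else:
        sequence, amidated = peptide.sequence, peptide.amidated
    matched = [r for r in rules if _match_rule(r, sequence, amidated)]
    matched.sort(key=lambda r: (r.priority, r.name))
    return [r.name for r in matched]


def count_family_copies(peptides: Iterable, family: str, rules: Sequence[FamilyRule]) -> int:
    """Number of released peptides from one precursor matching a family."""
    rule_map = {r.name: r for r in rules}
    if family not in rule_map:
        raise KeyError(f"unknown family: {family}")
    rule = rule_map[family]
    count = 0
    for p in peptides:
        seq, amid = (p if isinstance(p, tuple) else (p.sequence, p.amidated))
        if _match_rule(rule, seq, amid):
            count += 1
    return count


# -------------------------------------------------------------- rulebook IO

_DEFAULT_RULEBOOK = "family_rules.tsv"


def load_rulebook(path: str | Path) -> list[FamilyRule]:
    """One rule per line: name, kind, pattern, amidation_required, priority."""
    rules = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, kind, pattern, amid, priority = line.split("\t")
            rules.append(
                FamilyRule(
                    name=name,
                    kind=kind,
                    pattern=pattern,
                    amidation_required=amid.lower() in {"1", "true", "yes"},
                    priority=int(priority),
                )
            )
    return rules


def save_rulebook(rules: Sequence[FamilyRule], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# name\tkind\tpattern\tamidation_required\tpriority\n")
        for r in rules:
            fh.write(
                f"{r.name}\t{r.kind}\t{r.pattern}\t{int(r.amidation_required)}\t{r.priority}\n"
            )


def default_rules() -> list[FamilyRule]:
    """The shipped molluscan neuropeptide family rulebook."""
    ref = resources.files("neuropep.data").joinpath(_DEFAULT_RULEBOOK)
    with resources.as_file(ref) as path:
        return load_rulebook(path)


# ----------------------------------------------------- frequency matrices


def c_terminal_pad(sequences: Sequence[str], gap: str = "-") -> list[str]:
    """Right-align sequences by padding on the left (C-terminal anchoring)."""
    width = max(len(s) for s in sequences)
    return [gap * (width - len(s)) + s for s in sequences]


def frequency_matrix(aligned: Sequence[str], gap: str = "-") -> pd.DataFrame:
    """Per-column relative residue frequencies of equal-length sequences.

    Rows are residues (20-letter alphabet plus gap), columns alignment
    positions; every column sums to 1.
    """
    if not aligned:
        raise ValueError("need at least one sequence")
    width = len(aligned[0])
    if any(len(s) != width for s in aligned):
        raise ValueError("aligned sequences must all have the same length")
    alphabet = list(AA20) + [gap]
    allowed = set(alphabet)
    counts = pd.DataFrame(0.0, index=alphabet, columns=range(width))
    for s in aligned:
        for j, c in enumerate(s):
            if c not in allowed:
                raise ValueError(f"residue {c!r} outside the alphabet")
            counts.loc[c, j] += 1
    return counts / len(aligned)


def measure_cys_spacing(sequence: str) -> int | None:
    """Residues between the first two cysteines (None if fewer than two)."""
    positions = [i for i, c in enumerate(sequence) if c == "C"]
    if len(positions) < 2:
        return None
    return positions[1] - positions[0] - 1


def measure_trp_spacing(sequence: str) -> int | None:
    """Residues between the first and last tryptophan (None if fewer than two)."""
    positions = [i for i, c in enumerate(sequence) if c == "W"]
    if len(positions) < 2:
        return None
    return positions[-1] - positions[0] - 1


def write_classification_tsv(rows: Sequence[dict], path) -> None:
    pd.DataFrame(
        rows, columns=["precursor", "sequence", "rendered", "families"]
    ).to_csv(path, sep="\t", index=False)
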