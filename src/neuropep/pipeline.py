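"""End-to-end orchestration of the discovery pipeline.

Stages consume only the declared artifacts of earlier stages; every stage
writes a tab-separated report into the run directory and the run ends
with a ``summary.json`` of headline counts (precursors by evidence
stream, released peptides, MS confirmation percentage, Ka/Ks classes).
Rerunning with the same configuration reproduces the run directory
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from neuropep import discovery, families, homology, kaks, msmatch, orf, processing

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    transcripts: str  # FASTA path
    out_dir: str
    query_panel: str | None = None  # protein FASTA
    observed_peptides: str | None = None  # TSV
    cds_pairs: str | None = None  # FASTA with 2N records, consecutive pairs
    signal_table: str | None = None  # external signal predictions
    rulebook: str | None = None
    orf_min_len: int = 60
    orf_dialect: str = "stop_to_stop"
    homology_min_score: float = homology.DEFAULT_MIN_SCORE
    signal_hydro_min: float = discovery.HYDRO_MIN
    repeat_min_identity: float = 0.5
    ms_min_score: float = msmatch.DEFAULT_MIN_SCORE
    ppm_tol: float = msmatch.DEFAULT_PPM_TOL
    min_peptide_len: int = processing.MIN_PEPTIDE_LEN
    cleave_monobasic: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.orf_min_len < 1:
            raise ValueError("orf_min_len must be >= 1")
        if self.orf_dialect not in ("stop_to_stop", "atg_to_stop"):
            raise ValueError(f"unknown ORF dialect: {self.orf_dialect}")
        if not (0.0 < self.repeat_min_identity <= 1.0):
            raise ValueError("repeat_min_identity must lie in (0, 1]")
        if self.ppm_tol <= 0:
            raise ValueError("ppm_tol must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _candidate_row(c: discovery.PrecursorCandidate) -> dict:
    return {
        "orf": c.orf.orf_id,
        "transcript": c.orf.transcript_id,
        "accepted": c.accepted,
        "partial": c.partial,
        "evidence": c.evidence,
        "signal": c.criteria_flags["signal"],
        "cleavage": c.criteria_flags["cleavage"],
        "amidation_gly": c.criteria_flags["amidation_gly"],
        "cys_pattern": c.criteria_flags["cys_pattern"],
        "cleavage_after": c.signal.cleavage_after or "",
        "n_sites": len(c.sites),
        "repeat_count": c.repeat_count,
        "score": c.score,
    }


def read_cds_pairs(path: str | Path) -> list[tuple[str, str, str]]:
    """Consecutive record pairs of an aligned-CDS FASTA."""
    seqs = orf.read_protein_fasta(path)  # generic FASTA reader (id -> seq)
    items = list(seqs.items())
    if len(items) % 2:
        raise ValueError("paired CDS FASTA must contain an even record count")
    pairs = []
    for i in range(0, len(items), 2):
        (id_a, a), (id_b, b) = items[i], items[i + 1]
        pairs.append((f"{id_a}|{id_b}", a, b))
    return pairs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    transcripts = orf.read_fasta(config.transcripts)
    summary["n_transcripts"] = len(transcripts)

    # Stage: ORF extraction
    all_orfs: list[orf.OpenReadingFrame] = []
    for t in transcripts:
        all_orfs.extend(orf.find_orfs(t, min_len=config.orf_min_len, dialect=config.orf_dialect))
    orf.write_orf_fasta(all_orfs, out / "orfs.fasta")
    summary["n_orfs"] = len(all_orfs)

    # Stage: translated homology search
    homology_flags: set[str] = set()
    hits: list[homology.HomologyHit] = []
    if config.query_panel:
        queries = orf.read_protein_fasta(config.query_panel)
        hits = homology.search_panel(
            queries, transcripts, min_score=config.homology_min_score
        )
        homology_flags = homology.flagged_transcripts(hits)
        homology.write_hits_tsv(hits, out / "hits.tsv")
    summary["n_hits"] = len(hits)
    summary["n_homology_transcripts"] = len(homology_flags)

    # Stage: de novo discovery + evidence merge
    signal_overrides = (
        discovery.read_signal_table(config.signal_table) if config.signal_table else {}
    )
    candidates = []
    for o in all_orfs:
        cand = discovery.evaluate_orf(
            o,
            homology_flag=o.transcript_id in homology_flags,
            min_identity=config.repeat_min_identity,
            signal_override=signal_overrides.get(o.orf_id),
            hydro_min=config.signal_hydro_min,
        )
        if cand.accepted or cand.partial:
            candidates.append(cand)
        else:
            logger.debug(
                "rejected %s: flags=%s repeats=%d",
                o.orf_id,
                cand.criteria_flags,
                cand.repeat_count,
            )
    merged = discovery.merge_candidates(candidates)
    pd.DataFrame(
        [_candidate_row(c) for c in merged],
        columns=list(_candidate_row(merged[0]).keys()) if merged else None,
    ).to_csv(out / "candidates.tsv", sep="\t", index=False)
    accepted = [c for c in merged if c.accepted]
    summary["n_candidates"] = len(merged)
    summary["n_accepted"] = len(accepted)
    summary["n_precursors_union"] = len({c.orf.transcript_id for c in merged})
    summary["evidence_counts"] = {
        kind: sum(1 for c in merged if c.evidence == kind)
        for kind in ("homology", "de_novo", "both")
    }

    # Stage: prohormone processing
    peptides: list[processing.MaturePeptide] = []
    for c in accepted:
        peptides.extend(
            processing.release_peptides(
                c,
                min_len=config.min_peptide_len,
                cleave_monobasic=config.cleave_monobasic,
            )
        )
    processing.write_peptides_tsv(peptides, out / "peptides.tsv")
    summary["n_mature_peptides"] = len(peptides)

    # Stage: family classification
    rules = (
        families.load_rulebook(config.rulebook)
        if config.rulebook
        else families.default_rules()
    )
    fam_rows = [
        {
            "precursor": p.precursor_id,
            "sequence": p.sequence,
            "rendered": p.render(),
            "families": ";".join(families.classify_peptide(p, rules)) or "unclassified",
        }
        for p in peptides
    ]
    families.write_classification_tsv(fam_rows, out / "families.tsv")
    summary["n_classified_peptides"] = sum(
        1 for r in fam_rows if r["families"] != "unclassified"
    )

    # Stage: MS confirmation
    if config.observed_peptides:
        table = msmatch.read_observed_table(config.observed_peptides)
        filtered = msmatch.filter_observations(table, min_score=config.ms_min_score)
        report = msmatch.match_observations(
            filtered, peptides, ppm_tol=config.ppm_tol
        )
        msmatch.write_report_tsv(report, out / "confirmation.tsv")
        summary["confirmation"] = msmatch.report_summary(report)

    # Stage: selection pressure
    if config.cds_pairs:
        pairs = read_cds_pairs(config.cds_pairs)
        results = kaks.kaks_table(pairs)
        kaks.write_kaks_tsv(results, out / "kaks.tsv")
        summary["kaks_classes"] = {
            cls: sum(1 for r in results if r.selection_class == cls)
            for cls in (
                "strong_positive",
                "moderate_positive_candidate",
                "purifying",
                "undefined",
            )
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def benchmark_metrics(manifest: dict, accepted_transcripts: set[str]) -> dict:
    """Transcript-level recall/precision against a ground-truth manifest."""
    truth = {rec["id"] for rec in manifest["transcripts"] if rec["label"] == "precursor"}
    tp = len(truth & accepted_transcripts)
    fp = len(accepted_transcripts - truth)
    return {
        "recall": tp / len(truth) if truth else float("nan"),
        "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
        "tp": tp,
        "fp": fp,
        "n_true": len(truth),
    }
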