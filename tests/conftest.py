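"""Shared fixtures: the default synthetic benchmark, run once per session."""

from __future__ import annotations

import pytest

from neuropep.discovery import evaluate_orf, merge_candidates
from neuropep.orf import find_orfs
from neuropep.processing import release_peptides
from neuropep.synthetic import default_templates, generate_transcriptome

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark (20 precursors, 200 decoys, noise 0)
    carried through de novo discovery and prohormone processing."""
    templates = default_templates()
    transcripts, manifest = generate_transcriptome(
        templates, n_decoys=200, noise=0.0, seed=BENCHMARK_SEED
    )
    candidates = []
    for t in transcripts:
        for o in find_orfs(t):
            c = evaluate_orf(o)
            if c.accepted:
                candidates.append(c)
    merged = merge_candidates(candidates)
    peptides = {c.orf.transcript_id: release_peptides(c) for c in merged}
    return {
        "templates": templates,
        "transcripts": transcripts,
        "manifest": manifest,
        "records": {r["id"]: r for r in manifest["transcripts"]},
        "candidates": merged,
        "peptides": peptides,
    }


@pytest.fixture(scope="session")
def family_rules():
    from neuropep.families import default_rules

    return default_rules()
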