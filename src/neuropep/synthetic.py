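"""Seeded synthetic transcriptomes with embedded neuropeptide precursors.

Each precursor template describes a prepropeptide architecture of the kind
seen in molluscan nerve ganglia: an N-terminal signal peptide, an ordered
series of peptide units (optionally amidated, i.e. emitted with a trailing
glycine), and a basic cleavage site after every unit (dibasic by default,
tetrabasic for furin-type domain boundaries). Templates are
reverse-translated with a fixed codon choice, wrapped in random UTRs, and
mixed with decoy transcripts; a ground-truth manifest records every
embedded ORF and the mature peptides processing should release.

Decoys stress the precursor criteria one at a time: class (a) carries a
signal peptide but a mature region free of basic residues (no cleavage
architecture), class (b) carries repeats and cleavage sites but a
hydrophilic N-terminus (no signal peptide).

The expected-peptide lists are computed from the template grammar alone,
independently of the prohormone-processing engine, so round-trip tests
compare two separate code paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from neuropep.kaks import CODON_AA, STOP_CODONS
from neuropep.msmatch import monoisotopic_mass
from neuropep.orf import Transcript, write_fasta
from neuropep.processing import pyroglu_potential

SITE_MOTIFS = {"monobasic": "R", "dibasic": "KR", "tetrabasic": "RKRR"}

# Fixed reverse-translation choice, so nucleotide output is byte-stable:
# the alphabetically first codon of each amino acid, except that Ser uses
# TCA (Leu's alphabetically-first CTA is kept). Both read as stop codons on
# the reverse strand, which keeps the antisense strand stop-dense — as
# natural codon usage does — and damps spurious minus-strand ORFs.
AA_TO_CODON: dict[str, str] = {}
for _codon in sorted(CODON_AA):
    AA_TO_CODON.setdefault(CODON_AA[_codon], _codon)
AA_TO_CODON["S"] = "TCA"

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_HYDROPHILIC = "DENQSTHP"  # decoy class (b) N-terminus
_NONBASIC = "ADEFGHILMNPQSTVWY"  # decoy mature regions: no K/R (no C for class a)


@dataclass(frozen=True)
class PeptideUnit:
    core: str
    copies: int = 1
    amidated: bool = True
    site: Literal["monobasic", "dibasic", "tetrabasic"] = "dibasic"

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copy counts must be >= 1")
        if not self.core:
            raise ValueError("empty peptide core")


@dataclass(frozen=True)
class PrecursorTemplate:
    name: str
    signal_length: int
    peptide_units: tuple[PeptideUnit, ...]
    linker: str = ""  # spacer emitted (with its own dibasic site) after each unit

    def __post_init__(self) -> None:
        if self.signal_length < 10:
            raise ValueError("signal_length must be >= 10")
        if not self.peptide_units:
            raise ValueError("template needs at least one peptide unit")


def build_signal(length: int) -> str:
    """Canonical synthetic signal peptide: Met-Lys, a poly-Leu hydrophobic
    core, and a V-A-S-A cleavage region (small residues at -1/-3)."""
    if length < 10:
        raise ValueError("signal_length must be >= 10")
    return "MK" + "L" * (length - 6) + "VASA"


def build_precursor(template: PrecursorTemplate) -> tuple[str, list[dict]]:
    """Protein sequence and expected mature peptides for a template."""
    parts = [build_signal(template.signal_length)]
    expected: list[dict] = []
    counts: dict[str, int] = {}
    for unit in template.peptide_units:
        for _ in range(unit.copies):
            parts.append(unit.core)
            if unit.amidated:
                parts.append("G")
            parts.append(SITE_MOTIFS[unit.site])
            if template.linker:
                parts.append(template.linker)
                parts.append(SITE_MOTIFS["dibasic"])
            counts[unit.core] = counts.get(unit.core, 0) + 1
            expected.append(
                {
                    "sequence": unit.core,
                    "amidated": unit.amidated,
                    "pyroglu": pyroglu_potential(unit.core),
                    "copy_index": counts[unit.core],
                }
            )
            if len(template.linker) >= 3:
                counts[template.linker] = counts.get(template.linker, 0) + 1
                expected.append(
                    {
                        "sequence": template.linker,
                        "amidated": False,
                        "pyroglu": pyroglu_potential(template.linker),
                        "copy_index": counts[template.linker],
                    }
                )
    return "".join(parts), expected


def reverse_translate(protein: str) -> str:
    return "".join(AA_TO_CODON[aa] for aa in protein)


def default_templates() -> list[PrecursorTemplate]:
    """Twenty precursor templates spanning the canonical architectures:
    tetrabasic-split FMRFamide-type repeats, single-copy amidated peptides
    (luqin-, GnRH-, NPF-style), pyroglutamate candidates (CCK/SK-style),
    cysteine-bridged peptides, and non-amidated repeat domains."""
    T, U = PrecursorTemplate, PeptideUnit

    def filler(seq: str) -> PeptideUnit:
        # Non-amidated pro-region domain, K/R/G-free so it adds no cleavage
        # architecture of its own; pads short precursors to realistic length.
        return PeptideUnit(seq, amidated=False)

    return [
        T("fmrfamide", 22, (
            U("TFLRF"), U("ALSGDAFFRF"), U("FLRF", site="tetrabasic"),
            U("FMRF", copies=24),
        )),
        T("luqin", 23, (
            U("APQWRPQGRF"),
            filler("SDPETDSNANLFDPNQSAVCMSDTECNIE"),
        )),
        T("cck_sk", 21, (
            U("QGRWDLDYGLGGGRF"), U("EYDDYRLGGGRF"),
            filler("NSDLEAPQTTSFDMNE"),
        )),
        T("fcap", 19, (
            U("SLDRLGGAFIHGY", copies=2, amidated=False),
            U("ALDPLGGVYLHGY", copies=2, amidated=False),
            U("SLDPLGGMWIHGY", copies=2, amidated=False),
        )),
        T("fxriamide", 16, (
            U("MSSFMRI", copies=7), U("LSSFMRI", copies=6),
            U("GLSSFVRI"), U("IPTSSFMRI"),
        )),
        T("allatostatin_b", 25, (
            U("GWKDMGTW", copies=3),
            filler("DSAENQLPFDTMSNIE"),
        )),
        T("allatostatin_c", 28, (
            U("GHIQCLVNLVACY"),
            filler("EDPSLNAQTFDMNSHPVE"),
        )),
        T("apgwamide", 20, (U("TPGW", copies=6), U("APGW", copies=2), U("SPGW"))),
        T("myomodulin", 19, (
            U("GGLSMLRL"), U("GMNMLRL"), U("PMSMLRL"),
            filler("TDSAENQLPFDMNE"),
        )),
        T("npf", 22, (U("QEAMLEPPDRPHSFRTPDQLRSYLRALNEYYSIVGRPRF"),)),
        T("gnrh", 24, (
            U("QNFHYSNGWQP"),
            filler("DAENSLQPTFDMSNHDLVPTQIE"),
        )),
        T("conopressin", 22, (
            U("CFIRNCPPG"),
            # neurophysin-style cysteine-rich carrier domain
            filler("ESDPETASCFSSNAPCMAFDTNSECQMAE"),
        )),
        T("buccalin", 23, (
            U("MPFFGSL"), U("FKQQFFGTL"), U("LRPSFYGSL"),
            filler("DSENAQLPFDTMIE"),
        )),
        T("scap", 21, (
            U("APNFLAYPRG"), U("AMFSYPRL"),
            filler("CSDNETCAPQFDMCLNSECAE"),
        )),
        T("tachykinin", 22, (U("PSSFVGMF", copies=5),)),
        T("elh", 25, (U("AISNDLDHFTSREMSNDISE", copies=2, amidated=False),)),
        T("pedal_peptide", 20, (U("PLDSVYGTHGMSGF", copies=3, amidated=False),)),
        T("lfrfamide", 23, (U("GSLLRF", copies=3), U("GGLFRF"), U("PHTPFRF"))),
        T("wx3yamide", 21, (
            U("SNKWSIAY"), U("LRQGWNIAY"), U("QQGWHIAY"),
            filler("DTENSALPQFDMIE"),
        )),
        T("insulin_like", 24, (
            U("GVDQCCNNACSMDELLSYC", amidated=False),
            U("SGSSCALTHLDLMQYCE", amidated=False),
        )),
    ]


def _random_utr(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list("ACGT"), size=length))


def _decoy_protein(rng: np.random.Generator, kind: str) -> str:
    if kind == "decoy_signal_no_sites":
        # class (a): signal peptide, mature region free of K/R/C
        length = int(rng.integers(60, 121))
        mature = "".join(rng.choice(list(_NONBASIC.replace("C", ""))) for _ in range(length))
        return build_signal(22) + mature
    # class (b): repeats + cleavage sites, hydrophilic N-terminus
    head = "M" + "".join(rng.choice(list(_HYDROPHILIC)) for _ in range(30))
    core_len = int(rng.integers(5, 9))
    core = "".join(rng.choice(list(_NONBASIC)) for _ in range(core_len))
    return head + "".join(core + "G" + "KR" for _ in range(6))


def _apply_noise(rng: np.random.Generator, seq: str, noise: float) -> str:
    if noise <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < noise
    for i in np.flatnonzero(hit):
        choices = [c for c in "ACGT" if c != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def generate_transcriptome(
    templates: Sequence[PrecursorTemplate] | None = None,
    n_decoys: int = 200,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[Transcript], dict]:
    """Build a synthetic transcriptome and its ground-truth manifest.

    Every template becomes one transcript: random 5'UTR (ending in an
    in-frame stop immediately before the start codon, as upstream ORF
    stops do in real 5'UTRs), the reverse-translated precursor CDS with a
    terminal stop, and a random 3'UTR. ``noise`` applies per-base random
    substitutions to the finished transcript. Identical inputs and seed
    give byte-identical output.
    """
    if not (0.0 <= noise <= 0.2):
        raise ValueError("noise must lie in [0, 0.2]")
    if templates is None:
        templates = default_templates()
    if not templates:
        raise ValueError("templates must be non-empty")
    rng = np.random.default_rng(seed)
    transcripts: list[Transcript] = []
    records: list[dict] = []

    def emit(name: str, label: str, template_name: str, protein: str, expected: list[dict]) -> None:
        utr5 = _random_utr(rng, 15, 60)
        utr5 = utr5[: len(utr5) - len(utr5) % 3] + "TAA"
        cds = reverse_translate(protein) + "TAA"
        utr3 = _random_utr(rng, 20, 60)
        nt = _apply_noise(rng, utr5 + cds + utr3, noise)
        transcripts.append(Transcript(id=name, sequence=nt))
        records.append(
            {
                "id": name,
                "label": label,
                "template": template_name,
                "orf_start": len(utr5),
                "orf_end": len(utr5) + len(cds),
                "strand": "+",
                "protein": protein,
                "signal_length": None,
                "expected_peptides": expected,
            }
        )

    for i, template in enumerate(templates):
        protein, expected = build_precursor(template)
        rec_name = f"precursor_{i:03d}_{template.name}"
        emit(rec_name, "precursor", template.name, protein, expected)
        records[-1]["signal_length"] = template.signal_length
    for j in range(n_decoys):
        kind = "decoy_signal_no_sites" if j % 2 == 0 else "decoy_repeats_no_signal"
        protein = _decoy_protein(rng, kind)
        emit(f"decoy_{j:03d}", "decoy", kind, protein, [])

    manifest = {
        "params": {
            "n_templates": len(templates),
            "n_decoys": n_decoys,
            "noise": noise,
            "seed": seed,
        },
        "transcripts": records,
    }
    return transcripts, manifest


def write_transcriptome(transcripts: Sequence[Transcript], path: str | Path) -> None:
    write_fasta(((t.id, t.sequence) for t in transcripts), path)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


OBSERVED_COLUMNS = ["peptide", "modifications", "score", "observed_mass"]


def generate_observed_peptides(
    manifest: dict,
    detection_rate: float = 0.3,
    decoy_peptide_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulated MS search output for a generated transcriptome.

    Each expected mature peptide is detected independently with
    ``detection_rate``; detected peptides carry their true modifications
    (potential pyroglutamate applied half the time), a significance score
    above the 20 threshold, and a monoisotopic mass jittered within 5 ppm.
    Decoy rows (random sequences, scores straddling the threshold) are
    added at ``decoy_peptide_rate`` per true peptide.
    """
    if not (0.0 <= detection_rate <= 1.0 and 0.0 <= decoy_peptide_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    true_rows = [
        pep
        for rec in manifest["transcripts"]
        if rec["label"] == "precursor"
        for pep in rec["expected_peptides"]
    ]
    for pep in true_rows:
        if rng.random() >= detection_rate:
            continue
        mods = []
        if pep["amidated"]:
            mods.append("amidated")
        if pep["pyroglu"] != "none" and rng.random() < 0.5:
            mods.append(f"pyroglu_{pep['pyroglu']}")
        mass = monoisotopic_mass(pep["sequence"], mods)
        mass *= 1.0 + rng.uniform(-5e-6, 5e-6)
        rows.append(
            {
                "peptide": pep["sequence"],
                "modifications": ";".join(mods),
                "score": round(float(rng.uniform(20.5, 120.0)), 2),
                "observed_mass": round(mass, 5),
            }
        )
    n_decoy = int(rng.binomial(len(true_rows), decoy_peptide_rate)) if true_rows else 0
    for _ in range(n_decoy):
        length = int(rng.integers(8, 16))
        seq = "".join(rng.choice(list(AA20)) for _ in range(length))
        rows.append(
            {
                "peptide": seq,
                "modifications": "",
                "score": round(float(rng.uniform(10.0, 40.0)), 2),
                "observed_mass": round(monoisotopic_mass(seq), 5),
            }
        )
    return pd.DataFrame(rows, columns=OBSERVED_COLUMNS)


def write_observed_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------- ortholog simulation


def simulate_ortholog(
    cds: str, n_synonymous: int, n_nonsynonymous: int, seed: int = 0
) -> str:
    """Mutate a coding sequence with controlled numbers of synonymous and
    non-synonymous single-codon changes (for selection-pressure demos)."""
    rng = np.random.default_rng(seed)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    order = rng.permutation(len(codons))
    syn_left, nonsyn_left = n_synonymous, n_nonsynonymous
    for idx in order:
        codon = codons[idx]
        if codon in STOP_CODONS:
            continue
        aa = CODON_AA[codon]
        neighbours = []
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                mut = codon[:pos] + nt + codon[pos + 1 :]
                if mut in STOP_CODONS:
                    continue
                neighbours.append((mut, CODON_AA[mut] == aa))
        syn_opts = [m for m, is_syn in neighbours if is_syn]
        nonsyn_opts = [m for m, is_syn in neighbours if not is_syn]
        if syn_left > 0 and syn_opts:
            codons[idx] = syn_opts[int(rng.integers(0, len(syn_opts)))]
            syn_left -= 1
        elif nonsyn_left > 0 and nonsyn_opts:
            codons[idx] = nonsyn_opts[int(rng.integers(0, len(nonsyn_opts)))]
            nonsyn_left -= 1
        if syn_left == 0 and nonsyn_left == 0:
            break
    return "".join(codons)
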