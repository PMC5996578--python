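"""Mass-spectrometry confirmation of predicted mature peptides.

The interface is a search-engine result table (peptide, modifications,
score, optional observed mass), not raw spectra: any engine's filtered
output can be fed in. Matching requires exact sequence equality and
modification compatibility; when an observed mass is present the computed
monoisotopic mass must agree within the precursor-ion tolerance
(10 ppm by default). Rows are retained only with score strictly above the
significance threshold (default 20). The fragment-ion tolerance (0.05 Da)
is carried as report metadata only — no fragment matching is performed.

Leucine and isoleucine are treated as distinct by default (identifications
are database-driven, not de novo); pass ``collapse_leu_ile=True`` to fold
them together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from pyteomics import mass as _pmass

from neuropep.processing import MaturePeptide

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 20.0
DEFAULT_PPM_TOL = 10.0
FRAGMENT_TOL_DA = 0.05  # metadata only

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

# Monoisotopic mass shifts (Da) of the supported variable modifications.
MOD_DELTAS = {
    "amidated": -0.98402,
    "pyroglu_fromQ": -17.02655,
    "pyroglu_fromE": -18.01056,
    "met_oxidation": +15.99491,
    "met_dioxidation": +31.98983,
    "acetyl_nterm": +42.01057,
}


@dataclass(frozen=True)
class ObservedPeptide:
    sequence: str
    modifications: frozenset[str]
    score: float
    observed_mass: float | None = None

    def __post_init__(self) -> None:
        unknown = self.modifications - set(MOD_DELTAS)
        if unknown:
            raise ValueError(f"unknown modifications: {sorted(unknown)}")
        if "pyroglu_fromQ" in self.modifications and not self.sequence.startswith("Q"):
            raise ValueError("pyroglu_fromQ requires an N-terminal Q")
        if "pyroglu_fromE" in self.modifications and not self.sequence.startswith("E"):
            raise ValueError("pyroglu_fromE requires an N-terminal E")
        if (
            self.modifications & {"met_oxidation", "met_dioxidation"}
            and "M" not in self.sequence
        ):
            raise ValueError("Met oxidation requires a methionine")


@dataclass
class ConfirmationReport:
    per_precursor: dict[str, list[tuple[ObservedPeptide, MaturePeptide]]]
    confirmed: dict[str, bool]
    orphans: list[ObservedPeptide]
    confirmed_count: int
    total_count: int
    percentage: float
    ppm_tol: float = DEFAULT_PPM_TOL
    fragment_tol_da: float = FRAGMENT_TOL_DA

    @staticmethod
    def compute_percentage(confirmed: int, total: int) -> float:
        return round(100.0 * confirmed / total, 2) if total else 0.0


def monoisotopic_mass(sequence: str, modifications: Sequence[str] | frozenset[str] = ()) -> float:
    """Monoisotopic mass in Da: residue sum + water, adjusted per modification."""
    for i, c in enumerate(sequence):
        if c not in AA20:
            raise ValueError(f"unknown residue {c!r} at position {i + 1}")
    m = _pmass.fast_mass(sequence)
    for mod in modifications:
        if mod not in MOD_DELTAS:
            raise ValueError(f"unknown modification: {mod}")
        m += MOD_DELTAS[mod]
    return m


def read_observed_table(path: str | Path) -> pd.DataFrame:
    """Tab-separated observed-peptide table: peptide, modifications
    (semicolon-joined), score, optional observed_mass."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str})
    required = {"peptide", "modifications", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observed table missing columns: {sorted(missing)}")
    df["modifications"] = df["modifications"].fillna("")
    return df


def observations_from_frame(df: pd.DataFrame) -> list[ObservedPeptide]:
    obs = []
    for row in df.itertuples(index=False):
        mods = frozenset(m for m in str(row.modifications).split(";") if m)
        mass = getattr(row, "observed_mass", None)
        if mass is not None and pd.isna(mass):
            mass = None
        obs.append(
            ObservedPeptide(
                sequence=row.peptide,
                modifications=mods,
                score=float(row.score),
                observed_mass=None if mass is None else float(mass),
            )
        )
    return obs


def filter_observations(df: pd.DataFrame, min_score: float = DEFAULT_MIN_SCORE) -> pd.DataFrame:
    """Strictly-greater-than significance filter on the score column."""
    return df[df["score"] > min_score].reset_index(drop=True)


def _mods_compatible(obs: ObservedPeptide, pred: MaturePeptide) -> bool:
    # Amidation state must agree exactly.
    if ("amidated" in obs.modifications) != pred.amidated:
        return False
    # Predicted potential pyroGlu matches with or without the modification;
    # an observed pyroGlu must be licensed by the predicted N-terminus.
    if "pyroglu_fromQ" in obs.modifications and pred.pyroglu != "fromQ":
        return False
    if "pyroglu_fromE" in obs.modifications and pred.pyroglu != "fromE":
        return False
    # Side-chain / N-term artifacts (Met ox, acetyl) are free variable mods;
    # sequence consistency is enforced by ObservedPeptide validation.
    return True


def match_observations(
    observations: Sequence[ObservedPeptide] | pd.DataFrame,
    predicted: Sequence[MaturePeptide],
    ppm_tol: float = DEFAULT_PPM_TOL,
    collapse_leu_ile: bool = False,
) -> ConfirmationReport:
    """Match observed peptides to predicted mature peptides per precursor.

    Matching is injective per observation: each observation confirms at
    most one predicted peptide position, ties broken by precursor id then
    start coordinate (and logged). The per-precursor summary counts a
    precursor confirmed when at least one of its peptides is matched.
    """
    if isinstance(observations, pd.DataFrame):
        observations = observations_from_frame(observations)

    def key(seq: str) -> str:
        return seq.replace("I", "L") if collapse_leu_ile else seq

    by_seq: dict[str, list[MaturePeptide]] = {}
    for p in predicted:
        by_seq.setdefault(key(p.sequence), []).append(p)
    for plist in by_seq.values():
        plist.sort(key=lambda p: (p.precursor_id, p.start))

    precursors = sorted({p.precursor_id for p in predicted})
    per_precursor: dict[str, list[tuple[ObservedPeptide, MaturePeptide]]] = {
        pid: [] for pid in precursors
    }
    orphans: list[ObservedPeptide] = []
    for obs in observations:
        candidates = [
            p for p in by_seq.get(key(obs.sequence), []) if _mods_compatible(obs, p)
        ]
        if candidates and obs.observed_mass is not None:
            computed = monoisotopic_mass(obs.sequence, obs.modifications)
            ppm = abs(computed - obs.observed_mass) / computed * 1e6
            if ppm > ppm_tol:
                candidates = []
        if not candidates:
            orphans.append(obs)
            continue
        if len(candidates) > 1:
            logger.info(
                "observation %s matches %d positions; keeping %s:%d",
                obs.sequence,
                len(candidates),
                candidates[0].precursor_id,
                candidates[0].start,
            )
        chosen = candidates[0]
        per_precursor[chosen.precursor_id].append((obs, chosen))

    confirmed = {pid: bool(matches) for pid, matches in per_precursor.items()}
    n_confirmed = sum(confirmed.values())
    total = len(precursors)
    return ConfirmationReport(
        per_precursor=per_precursor,
        confirmed=confirmed,
        orphans=orphans,
        confirmed_count=n_confirmed,
        total_count=total,
        percentage=ConfirmationReport.compute_percentage(n_confirmed, total),
        ppm_tol=ppm_tol,
    )


def write_report_tsv(report: ConfirmationReport, path) -> None:
    rows = []
    for pid in sorted(report.per_precursor):
        matches = report.per_precursor[pid]
        rows.append(
            {
                "precursor": pid,
                "confirmed": report.confirmed[pid],
                "n_matches": len(matches),
                "matched_peptides": ";".join(m[0].sequence for m in matches),
            }
        )
    pd.DataFrame(
        rows, columns=["precursor", "confirmed", "n_matches", "matched_peptides"]
    ).to_csv(path, sep="\t", index=False)


def report_summary(report: ConfirmationReport) -> dict:
    return {
        "confirmed_count": report.confirmed_count,
        "total_count": report.total_count,
        "percentage": report.percentage,
        "n_orphans": len(report.orphans),
        "ppm_tol": report.ppm_tol,
        "fragment_tol_da": report.fragment_tol_da,
    }
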