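"""Deduplication and filtering cascade: raw correlations -> distinct gene symbols.

The same MS/MS spectrum is typically correlated to several candidate
peptides, at more than one charge state, and to every protein accession that
contains the winning peptide. Re-use of a spectrum inflates identification
counts, so the cascade enforces, in order: an intensity floor on the
precursor, one charge state per spectrum, one peptide per spectrum, one
accession per spectrum (RANK1), a minimum number of independent correlations
per accession, and finally a rollup to one representative accession per gene
symbol.

Tie-breaking is deterministic throughout: lower charge, then lower p-value,
then lexicographically smaller peptide, then lexicographically smaller
accession.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "STAGES",
    "CascadeConfig",
    "CascadeReport",
    "CascadeResult",
    "complex_key",
    "intensity_filter",
    "best_charge_state",
    "best_peptide",
    "rank1_collapse",
    "min_peptide_count_filter",
    "gene_rollup",
    "run_cascade",
]

#: Fixed stage order. Counts at all stages up to GENE_ROLLUP are surviving
#: correlation (row) counts; DISTINCT_GENES is the number of gene symbols.
STAGES = [
    "RAW",
    "INTENSITY_GE_1000",
    "BEST_CHARGE",
    "BEST_PEPTIDE",
    "RANK1_PEPTIDES",
    "ACCESSION_GE_K",
    "GENE_ROLLUP",
    "DISTINCT_GENES",
]

_CORRELATION_STAGES = STAGES[:-1]


def complex_key(spectrum_id: str, charge: int, peptide: str, accession: str) -> str:
    """SHA1 digest over (spectrum, charge, peptide, accession).

    Identifies one candidate correlation; equal keys iff equal 4-tuples.
    """
    payload = "\x1f".join((spectrum_id, str(int(charge)), peptide, accession))
    return hashlib.sha1(payload.encode("utf-8")).hexdigest()


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and mode flags for one cascade run.

    min_intensity: precursor detector-count floor (default 1000, inclusive).
    strict_intensity: if True the floor is exclusive (> instead of >=).
    min_peptides: minimum independent RANK1 correlations per accession.
    count_distinct_sequences: count distinct peptide sequences rather than
        correlations toward ``min_peptides``.
    proline_rule unused here; tryptic checks happen upstream of the table.
    """

    min_intensity: float = 1000.0
    strict_intensity: bool = False
    min_peptides: int = 5
    count_distinct_sequences: bool = False


@dataclass
class CascadeReport:
    """Ordered (stage, surviving count) pairs — the filter-count table."""

    counts: list[tuple[str, int]] = field(default_factory=list)

    def record(self, stage: str, count: int) -> None:
        self.counts.append((stage, int(count)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=["stage", "surviving_count"])

    def validate(self) -> None:
        names = [s for s, _ in self.counts]
        if names != STAGES:
            raise ValueError(f"stage names/order wrong: {names}")
        corr = [c for s, c in self.counts if s in _CORRELATION_STAGES]
        if any(a < b for a, b in zip(corr, corr[1:])):
            raise ValueError(f"correlation-level counts increased: {corr}")


@dataclass
class CascadeResult:
    summaries: pd.DataFrame
    report: CascadeReport
    rank1: pd.DataFrame
    rollup_rows: pd.DataFrame
    n_no_symbol: int


def intensity_filter(
    psms: pd.DataFrame, min_counts: float = 1000.0, strict: bool = False
) -> pd.DataFrame:
    """Keep correlations whose precursor intensity meets the floor.

    "At least" semantics by default: the boundary value is kept.
    """
    if min_counts < 0:
        raise ValueError("min_counts must be >= 0")
    mask = psms["intensity"] > min_counts if strict else psms["intensity"] >= min_counts
    return psms.loc[mask]


def _stable_sort(df: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    return df.sort_values(by, kind="mergesort")


def best_charge_state(psms: pd.DataFrame) -> pd.DataFrame:
    """Per spectrum, keep only rows at the charge whose best p-value is lowest.

    Ties between charges go to the lower charge.
    """
    if psms.empty:
        return psms
    best = (
        psms.groupby(["spectrum_id", "charge"], sort=False)["p_value"]
        .min()
        .reset_index()
    )
    best = _stable_sort(best, ["p_value", "charge"])
    winner = best.drop_duplicates("spectrum_id")[["spectrum_id", "charge"]]
    return psms.merge(winner, on=["spectrum_id", "charge"])


def best_peptide(psms: pd.DataFrame) -> pd.DataFrame:
    """Per spectrum, keep only rows for the single lowest-p peptide sequence.

    Rows correlating that peptide to multiple accessions all remain; no
    spectrum is assigned to more than one peptide. Ties go to the
    lexicographically smaller peptide.
    """
    if psms.empty:
        return psms
    best = (
        psms.groupby(["spectrum_id", "peptide"], sort=False)["p_value"]
        .min()
        .reset_index()
    )
    best = _stable_sort(best, ["p_value", "peptide"])
    winner = best.drop_duplicates("spectrum_id")[["spectrum_id", "peptide"]]
    return psms.merge(winner, on=["spectrum_id", "peptide"])


def rank1_collapse(psms: pd.DataFrame) -> pd.DataFrame:
    """Collapse shared-accession redundancy: one (peptide, accession) per spectrum.

    Among the accessions sharing a spectrum's peptide, the row kept is the
    one whose accession carries the highest total number of correlations in
    the table (the same rule that later picks the gene-symbol
    representative); ties go to the lexicographically smaller accession.
    """
    if psms.empty:
        return psms
    counts = psms.groupby("accession").size()
    df = psms.assign(_acc_n=psms["accession"].map(counts))
    df = _stable_sort(df, ["accession"])
    df = df.sort_values("_acc_n", kind="mergesort", ascending=False)
    out = df.drop_duplicates("spectrum_id").drop(columns="_acc_n")
    return _stable_sort(out, ["spectrum_id"])


def min_peptide_count_filter(
    psms: pd.DataFrame, k: int = 5, distinct_sequences: bool = False
) -> pd.DataFrame:
    """Keep rows whose accession has >= k independent RANK1 correlations.

    By default "independent peptides" counts correlations (one per
    spectrum); ``distinct_sequences=True`` counts distinct peptide
    sequences instead.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if psms.empty:
        return psms
    if distinct_sequences:
        counts = psms.groupby("accession")["peptide"].nunique()
    else:
        counts = psms.groupby("accession").size()
    keep = counts.index[counts >= k]
    return psms[psms["accession"].isin(keep)]


def gene_rollup(psms: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """One representative accession per gene symbol: the one with most correlations.

    Returns (summaries, surviving rows, number of empty-symbol rows).
    Rows without a gene symbol are excluded from the rollup and counted
    separately. Count ties go to the lexicographically smaller accession.
    """
    no_symbol = int((psms["gene_symbol"] == "").sum()) if len(psms) else 0
    named = psms[psms["gene_symbol"] != ""] if len(psms) else psms
    if named.empty:
        summaries = pd.DataFrame(columns=["gene_symbol", "accession", "peptide_count"])
        return summaries, named, no_symbol
    counts = (
        named.groupby(["gene_symbol", "accession"], sort=False)
        .size()
        .reset_index(name="peptide_count")
    )
    counts = _stable_sort(counts, ["accession"])
    counts = counts.sort_values("peptide_count", kind="mergesort", ascending=False)
    reps = counts.drop_duplicates("gene_symbol")
    reps = _stable_sort(reps, ["gene_symbol"]).reset_index(drop=True)
    rows = named.merge(reps[["gene_symbol", "accession"]], on=["gene_symbol", "accession"])
    return reps[["gene_symbol", "accession", "peptide_count"]], rows, no_symbol


def run_cascade(
    psms: pd.DataFrame, config: CascadeConfig = CascadeConfig()
) -> CascadeResult:
    """Apply all stages in the fixed order and record survivor counts."""
    report = CascadeReport()
    report.record("RAW", len(psms))
    df = intensity_filter(psms, config.min_intensity, config.strict_intensity)
    report.record("INTENSITY_GE_1000", len(df))
    df = best_charge_state(df)
    report.record("BEST_CHARGE", len(df))
    df = best_peptide(df)
    report.record("BEST_PEPTIDE", len(df))
    rank1 = rank1_collapse(df)
    report.record("RANK1_PEPTIDES", len(rank1))
    df = min_peptide_count_filter(
        rank1, config.min_peptides, config.count_distinct_sequences
    )
    report.record("ACCESSION_GE_K", len(df))
    summaries, rollup_rows, n_no_symbol = gene_rollup(df)
    report.record("GENE_ROLLUP", len(rollup_rows))
    report.record("DISTINCT_GENES", len(summaries))
    report.validate()
    return CascadeResult(
        summaries=summaries,
        report=report,
        rank1=rank1,
        rollup_rows=rollup_rows,
        n_no_symbol=n_no_symbol,
    )
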