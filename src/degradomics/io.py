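"""Readers and writers for PSM tables, protein libraries, manifests and summaries.

One strict dialect everywhere: tab-separated UTF-8 text with a single header
row and '.' as the decimal mark. Metadata lines beginning with '#' may
precede the header and are ignored on read. FASTA headers are
``>accession description``.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PSM_COLUMNS",
    "PsmRecord",
    "PsmReadResult",
    "ProteinLibrary",
    "read_psm_table",
    "write_psm_table",
    "read_fasta_library",
    "write_fasta_library",
    "read_manifest",
    "write_manifest",
    "read_annotation_table",
    "write_gene_summaries",
    "records_to_frame",
    "frame_to_records",
]

#: Required PSM-table columns, in canonical order. ``mod_mass`` is optional
#: on read (defaults to 0) but always written.
PSM_COLUMNS = [
    "spectrum_id",
    "precursor_mz",
    "charge",
    "intensity",
    "peptide",
    "prev_aa",
    "next_aa",
    "accession",
    "gene_symbol",
    "p_value",
    "algorithm",
    "sample_id",
    "treatment",
    "time_h",
    "mod_mass",
]

_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")
_FLANK_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY\-]$")
_ALGORITHMS = frozenset({"XTANDEM", "SEQUEST"})
_TREATMENTS = frozenset({"ICE", "RT"})


@dataclass(frozen=True)
class PsmRecord:
    """One MS/MS-to-peptide correlation with its spectrum, protein and sample context."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    intensity: float
    peptide: str
    prev_aa: str
    next_aa: str
    accession: str
    gene_symbol: str
    p_value: float
    algorithm: str
    sample_id: str
    treatment: str
    time_h: float
    mod_mass: float = 0.0


@dataclass
class PsmReadResult:
    """Validated PSM frame plus per-row rejections (line number, reason)."""

    frame: pd.DataFrame
    rejects: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


def records_to_frame(records: Iterable[PsmRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records], columns=PSM_COLUMNS)
    return _coerce_psm_dtypes(df)


def frame_to_records(frame: pd.DataFrame) -> list[PsmRecord]:
    return [PsmRecord(**row) for row in frame[PSM_COLUMNS].to_dict("records")]


def _coerce_psm_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if len(df):
        df["charge"] = df["charge"].astype(np.int64)
        for col in ("precursor_mz", "intensity", "p_value", "time_h", "mod_mass"):
            df[col] = df[col].astype(float)
        for col in (
            "spectrum_id", "peptide", "prev_aa", "next_aa", "accession",
            "gene_symbol", "algorithm", "sample_id", "treatment",
        ):
            df[col] = df[col].astype(str)
    return df


def _validate_psm_frame(raw: pd.DataFrame, first_data_line: int) -> PsmReadResult:
    rejects: list[tuple[int, str]] = []
    n = len(raw)
    ok = np.ones(n, dtype=bool)

    def flag(bad: np.ndarray, reason: str) -> None:
        for pos in np.nonzero(bad & ok)[0]:
            rejects.append((first_data_line + int(pos), reason))
        ok[bad] = False

    charge = pd.to_numeric(raw["charge"], errors="coerce")
    flag(charge.isna().to_numpy() | (charge % 1 != 0).to_numpy(), "unparseable charge")
    flag((charge < 1).to_numpy(), "charge < 1")
    for col, low, high in (
        ("intensity", 0.0, None),
        ("p_value", None, None),
        ("time_h", 0.0, 72.0),
        ("precursor_mz", 0.0, None),
    ):
        vals = pd.to_numeric(raw[col], errors="coerce")
        flag(vals.isna().to_numpy(), f"unparseable {col}")
        if low is not None:
            flag((vals < low).to_numpy(), f"{col} out of range")
        if high is not None:
            flag((vals > high).to_numpy(), f"{col} out of range")
    p = pd.to_numeric(raw["p_value"], errors="coerce")
    flag(((p <= 0) | (p > 1)).to_numpy(), "p_value outside (0,1]")
    if "mod_mass" in raw.columns:
        mm = pd.to_numeric(raw["mod_mass"], errors="coerce")
        flag(mm.isna().to_numpy() | (mm < 0).to_numpy(), "invalid mod_mass")
    flag(~raw["peptide"].astype(str).str.match(_PEPTIDE_RE).to_numpy(), "invalid peptide")
    for col in ("prev_aa", "next_aa"):
        flag(~raw[col].astype(str).str.match(_FLANK_RE).to_numpy(), f"invalid {col}")
    flag(~raw["algorithm"].astype(str).isin(_ALGORITHMS).to_numpy(), "unknown algorithm")
    flag(~raw["treatment"].astype(str).isin(_TREATMENTS).to_numpy(), "unknown treatment")

    good = raw.loc[ok].copy()
    if "mod_mass" not in good.columns:
        good["mod_mass"] = 0.0
    # astype(float), unlike to_numeric, parses to the nearest double exactly,
    # which the write/read round-trip guarantee relies on
    good["charge"] = good["charge"].astype(float)
    for col in ("precursor_mz", "intensity", "p_value", "time_h", "mod_mass"):
        good[col] = good[col].astype(float)
    good = _coerce_psm_dtypes(good[PSM_COLUMNS])
    return PsmReadResult(frame=good.reset_index(drop=True), rejects=rejects)


def read_psm_table(path: str | Path) -> PsmReadResult:
    """Read and validate a PSM table.

    Malformed rows are counted and reported with their file line number in
    ``PsmReadResult.rejects`` rather than silently dropped. A missing
    required column is a hard error naming the column.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    n_meta = 0
    while n_meta < len(lines) and lines[n_meta].startswith("#"):
        n_meta += 1
    body = "\n".join(lines[n_meta:])
    if not body.strip():
        raise ValueError(f"{path}: no header row found")
    raw = pd.read_csv(
        _io.StringIO(body), sep="\t", dtype=str, keep_default_na=False,
        float_precision="round_trip",
    )
    required = [c for c in PSM_COLUMNS if c != "mod_mass"]
    for col in required:
        if col not in raw.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    # file line of the first data row: metadata lines + header, 1-based
    return _validate_psm_frame(raw, first_data_line=n_meta + 2)


def _metadata_lines(metadata: Mapping[str, object] | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in metadata.items())


def write_psm_table(
    frame: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    """Write a PSM table in the canonical dialect (round-trips exactly)."""
    path = Path(path)
    df = frame[PSM_COLUMNS]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(metadata))
        # default float repr is shortest-round-trip, so read(write(x)) == x
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class ProteinLibrary:
    """Accession -> (gene symbol, sequence) map allowing shared-peptide redundancy.

    Gene symbols may be empty: only a fraction of accessions in large
    federated protein libraries carry a defined symbol.
    """

    accessions: list[str]
    gene_symbols: dict[str, str]
    sequences: dict[str, str]

    def __len__(self) -> int:
        return len(self.accessions)

    def sequence(self, accession: str) -> str:
        return self.sequences[accession]

    def gene_symbol(self, accession: str) -> str:
        return self.gene_symbols.get(accession, "")

    @property
    def symbol_fraction(self) -> float:
        """Fraction of accessions with a non-empty gene symbol."""
        if not self.accessions:
            return 0.0
        with_symbol = sum(1 for a in self.accessions if self.gene_symbols.get(a, ""))
        return with_symbol / len(self.accessions)

    def genes(self) -> dict[str, list[str]]:
        """Gene symbol -> accessions carrying it (empty symbols excluded)."""
        out: dict[str, list[str]] = {}
        for acc in self.accessions:
            sym = self.gene_symbols.get(acc, "")
            if sym:
                out.setdefault(sym, []).append(acc)
        return out


def read_fasta_library(
    path: str | Path, symbol_map: Mapping[str, str] | str | Path | None = None
) -> ProteinLibrary:
    """Build a protein library from FASTA plus an optional accession->symbol map.

    ``symbol_map`` may be a mapping or a path to a two-column TSV
    (accession, gene_symbol). Entries absent from the map carry an empty
    gene symbol. Duplicate accessions and empty sequences are errors.
    """
    if symbol_map is None:
        mapping: Mapping[str, str] = {}
    elif isinstance(symbol_map, (str, Path)):
        tbl = pd.read_csv(symbol_map, sep="\t", dtype=str, keep_default_na=False, comment="#")
        mapping = dict(zip(tbl.iloc[:, 0], tbl.iloc[:, 1]))
    else:
        mapping = symbol_map
    accessions: list[str] = []
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = record.id
        if acc in sequences:
            raise ValueError(f"duplicate accession '{acc}' in {path}")
        seq = str(record.seq)
        if not seq:
            raise ValueError(f"empty sequence for accession '{acc}' in {path}")
        accessions.append(acc)
        sequences[acc] = seq
    symbols = {acc: mapping.get(acc, "") for acc in accessions}
    return ProteinLibrary(accessions=accessions, gene_symbols=symbols, sequences=sequences)


def write_fasta_library(library: ProteinLibrary, path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(library.sequences[acc]),
            id=acc,
            description=library.gene_symbols.get(acc, ""),
        )
        for acc in library.accessions
    ]
    SeqIO.write(records, str(path), "fasta")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Sample manifest: sample_id, treatment, time_h, preservation."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in ("sample_id", "treatment", "time_h", "preservation"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing manifest column '{col}'")
    df["time_h"] = df["time_h"].astype(float)
    return df


def write_manifest(
    manifest: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(metadata))
        manifest.to_csv(fh, sep="\t", index=False)


def check_manifest_covers(psms: pd.DataFrame, manifest: pd.DataFrame) -> None:
    """Every sample_id in the PSM table must appear in the manifest."""
    missing = set(psms["sample_id"]) - set(manifest["sample_id"])
    if missing:
        raise ValueError(f"sample_ids absent from manifest: {sorted(missing)[:10]}")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Category annotation: term_id, description, gene_symbol (one gene per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in ("term_id", "description", "gene_symbol"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing annotation column '{col}'")
    return df


GENE_SUMMARY_COLUMNS = [
    "gene_symbol",
    "accession",
    "peptide_count",
    "n_ice",
    "n_rt",
    "mean_p",
    "cumulative_p",
    "log10_cumulative_p",
    "q_value",
]


def write_gene_summaries(
    summaries: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    """Write gene summaries sorted by q-value ascending, ties by gene symbol."""
    cols = [c for c in GENE_SUMMARY_COLUMNS if c in summaries.columns]
    df = summaries[cols]
    if "q_value" in df.columns:
        df = df.sort_values(["q_value", "gene_symbol"], kind="mergesort")
    else:
        df = df.sort_values("gene_symbol", kind="mergesort")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(metadata))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_gene_summaries(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    df["gene_symbol"] = df["gene_symbol"].astype(str)
    return df
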