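"""Treatment comparisons: RT/ICE enrichment ratios, contaminant flags, consensus.

Random mis-correlations (giant proteins), electrospray source noise and
laboratory-dust contamination are expected to hit room-temperature and
ice-preserved samples about equally, so the ratio of correlation counts in
room-temperature over ice-preserved samples — normalised by the number of
LC-ESI-MS/MS runs per group — separates genuinely degradation-released
proteins (high ratio) from those artefacts (ratio near 1). A fivefold excess
is the default enrichment call. Known-contaminant gene lists and a
two-algorithm consensus rule provide further orthogonal controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContaminantCatalog",
    "DEFAULT_CATALOG",
    "treatment_ratio",
    "rt_enriched",
    "flag_contaminants",
    "consensus_filter",
]

# Gene symbols repeatedly identified from random-spectra controls: giant
# proteins (titin, nebulin, ...) accumulate chance correlations in
# proportion to their tryptic-peptide count.
_RANDOM_MISCORRELATION = (
    "TTN", "NEB", "CCDC168", "SYNE1", "OBSCN", "TROPH", "SYNE2", "MACF1",
    "AHNAK", "DST", "LRP1", "XIRP2", "MUC16", "FSIP2", "LRP1B", "PLEC",
)
# Correlated from noise spectra collected on blank solvent-gradient runs.
_SOURCE_NOISE = (
    "ZNF503", "VWCE", "API5", "TMEM199", "SYT7", "TPSG1", "USP9X", "DACT3",
    "SUGP2", "CXorf31", "MYO3A", "KLRC4", "CYCS", "RGP1", "SYN1", "DSPP",
    "IMMP1L", "CAMK1", "ASPM", "AHNAK", "TTN",
)
# Typical constituents of a tryptic digest of laboratory dust.
_DUST = (
    "keratins", "POTEI", "POTEE", "POTEF", "ACTA2", "ACTB", "ACTG2", "GFAP",
    "POTEM", "MUC5AC",
)


@dataclass(frozen=True)
class ContaminantCatalog:
    """Named gene-symbol sets of known false-positive sources.

    The literal entry ``keratins`` in the dust set expands to a prefix rule:
    any gene symbol starting with ``KRT`` is treated as a keratin.
    """

    random_miscorrelation: frozenset[str] = frozenset(_RANDOM_MISCORRELATION)
    source_noise: frozenset[str] = frozenset(_SOURCE_NOISE)
    dust: frozenset[str] = frozenset(_DUST)

    def sets(self) -> dict[str, frozenset[str]]:
        return {
            "random_miscorrelation": self.random_miscorrelation,
            "source_noise": self.source_noise,
            "dust": self.dust,
        }

    def all_genes(self) -> set[str]:
        out = set().union(*self.sets().values())
        out.discard("keratins")
        return out

    def tags_for(self, gene: str) -> list[str]:
        tags = []
        for name, genes in self.sets().items():
            if gene in genes:
                tags.append(name)
            elif name == "dust" and "keratins" in genes and gene.startswith("KRT"):
                tags.append(name)
        return tags


DEFAULT_CATALOG = ContaminantCatalog()


def _run_counts(manifest: pd.DataFrame) -> tuple[int, int]:
    rt = manifest.loc[manifest["treatment"] == "RT", "sample_id"].nunique()
    ice = manifest.loc[manifest["treatment"] == "ICE", "sample_id"].nunique()
    return int(rt), int(ice)


def treatment_ratio(
    psms: pd.DataFrame,
    manifest: pd.DataFrame,
    pseudocount: float = 1.0,
    normalize_by_runs: bool = True,
    fold: float = 5.0,
) -> pd.DataFrame:
    """Per-gene RT/ICE correlation-count ratio.

    ``ratio = ((count_rt + pseudocount)/runs_rt) / ((count_ice + pseudocount)/runs_ice)``
    with runs taken from the manifest (both normalisers 1 when
    ``normalize_by_runs`` is off). One record per gene symbol observed in
    either group; the pseudocount keeps genes absent from one group finite.
    Input rows should be post-cascade (RANK1) correlations.
    """
    runs_rt, runs_ice = _run_counts(manifest)
    if normalize_by_runs and (runs_rt == 0 or runs_ice == 0):
        raise ValueError("a treatment group has zero runs in the manifest")
    if not normalize_by_runs:
        runs_rt = runs_ice = 1
    named = psms[psms["gene_symbol"] != ""]
    counts = (
        named.groupby(["gene_symbol", "treatment"]).size().unstack(fill_value=0)
    )
    for col in ("RT", "ICE"):
        if col not in counts.columns:
            counts[col] = 0
    out = pd.DataFrame(
        {
            "gene_symbol": counts.index,
            "count_rt": counts["RT"].to_numpy(),
            "count_ice": counts["ICE"].to_numpy(),
            "runs_rt": runs_rt,
            "runs_ice": runs_ice,
        }
    ).reset_index(drop=True)
    num = (out["count_rt"] + pseudocount) / runs_rt
    den = (out["count_ice"] + pseudocount) / runs_ice
    with np.errstate(divide="ignore"):
        out["ratio"] = num / den
    out["enriched"] = out["ratio"] >= fold
    return out.sort_values("gene_symbol", kind="mergesort").reset_index(drop=True)


def rt_enriched(ratios: pd.DataFrame, fold: float = 5.0) -> list[str]:
    """Gene symbols with RT/ICE ratio >= fold, sorted by ratio descending.

    Inclusive at the boundary; ties broken by gene symbol for determinism.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    hit = ratios[ratios["ratio"] >= fold]
    hit = hit.sort_values(["gene_symbol"], kind="mergesort")
    hit = hit.sort_values("ratio", kind="mergesort", ascending=False)
    return list(hit["gene_symbol"])


def flag_contaminants(
    genes: list[str], catalog: ContaminantCatalog = DEFAULT_CATALOG
) -> pd.DataFrame:
    """Tag each gene with the contaminant set(s) containing it (may be none)."""
    rows = [
        {"gene_symbol": g, "contaminant_tags": ";".join(catalog.tags_for(g))}
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene_symbol", "contaminant_tags"])


def consensus_filter(
    sequest_summaries: pd.DataFrame,
    xtandem_summaries: pd.DataFrame,
    k_sequest: int = 5,
    m_xtandem: int = 1,
) -> list[str]:
    """Genes identified by SEQUEST with >= k peptides and by X!TANDEM >= m times.

    With both thresholds at 0 this degenerates to the union of gene symbols.
    """
    seq = dict(zip(sequest_summaries["gene_symbol"], sequest_summaries["peptide_count"]))
    xt = dict(zip(xtandem_summaries["gene_symbol"], xtandem_summaries["peptide_count"]))
    genes = set(seq) | set(xt)
    kept = [
        g for g in sorted(genes)
        if seq.get(g, 0) >= k_sequest and xt.get(g, 0) >= m_xtandem
    ]
    return kept
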