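"""Synthetic protein libraries, PSM tables and null tables with exported truth.

The generator emulates the statistical structure the downstream analysis
assumes: a redundant protein library whose isoforms share tryptic peptides
within a gene symbol; fully tryptic peptides with up to three missed
cleavages; a mixture of genuine correlations (small p-values, Beta(a,1)
with a < 1) and mis-correlations (uniform p-values) hitting large proteins
in proportion to their tryptic-peptide count; log-normal precursor
intensities; Gaussian precursor delta masses truncated to +/- 2 Da;
ice-preserved versus room-temperature sample designs in which a chosen
fraction of genes yields a fold more correlations at room temperature; and
contaminant correlations injected equally into both treatment groups.

All randomness flows from the single mandatory seed in the design, so a
given design reproduces its tables byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import masses
from .io import PSM_COLUMNS, ProteinLibrary

__all__ = [
    "SimulationDesign",
    "SyntheticTruth",
    "make_library",
    "in_silico_digest",
    "simulate_psm_tables",
    "simulate_null_table",
    "make_manifest",
]

# sequences are drawn without P so every K/R is an unconditional cleavage
# site, and without K/R inside a fragment body
_BODY_ALPHABET = np.array(list("ACDEFGHILMNQSTVWY"))


@dataclass(frozen=True)
class SimulationDesign:
    """All knobs of one synthetic study; the seed is mandatory.

    Run counts default to the ice/room-temperature design of the emulated
    experiment (82 preserved, 88 room-temperature LC-ESI-MS/MS runs).
    Per-gene expected ice-preserved correlation counts are log-normal around
    ``mean_psms_per_gene_ice`` with a floor of ``min_gene_rate_ice`` so that
    every gene is quantifiable in the preserved group; room-temperature
    rates are multiplied by the degradation fold for degraded genes and by
    the run-count ratio for all genes.
    """

    seed: int
    n_genes: int = 200
    isoform_choices: tuple[int, ...] = (1, 2, 3)
    isoform_probs: tuple[float, ...] = (0.5, 0.3, 0.2)
    units_per_protein_mean: int = 40
    symbol_fraction: float = 0.74
    n_ice_runs: int = 82
    n_rt_runs: int = 88
    mean_psms_per_gene_ice: float = 30.0
    gene_rate_sigma: float = 0.4
    min_gene_rate_ice: float = 20.0
    degraded_gene_fraction: float = 0.15
    degradation_fold: float = 10.0
    true_p_alpha: float = 0.05
    false_psm_rate: float = 0.02
    log10_intensity_mean_ice: float = 3.5
    log10_intensity_mean_rt: float = 3.6
    log10_intensity_sd: float = 0.5
    delta_mass_sd: float = 0.4
    phospho_rate: float = 0.05
    extra_charge_rate: float = 0.15
    extra_peptide_rate: float = 0.10
    contaminant_genes: tuple[str, ...] = ("TTN", "NEB", "ACTB", "KRT10", "CYCS")
    contaminant_units: tuple[int, ...] = (300, 120, 40, 40, 30)
    contaminant_mean_psms: float = 25.0
    shared_peptide_fraction: float = 0.6
    max_missed: int = 3
    min_peptide_length: int = 5
    false_enrichment_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("symbol_fraction", "degraded_gene_fraction", "false_psm_rate",
                     "extra_charge_rate", "extra_peptide_rate", "phospho_rate",
                     "shared_peptide_fraction", "false_enrichment_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationDesign":
        data = json.loads(text)
        for key in ("isoform_choices", "isoform_probs", "contaminant_genes",
                    "contaminant_units"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class SyntheticTruth:
    """Ground truth: per-gene degradation status and per-PSM labels."""

    genes: pd.DataFrame  # gene_symbol, degraded, fold, contaminant
    psm_labels: pd.DataFrame  # algorithm, spectrum_id, is_true, is_contaminant
    design: SimulationDesign

    def degraded_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes["degraded"], "gene_symbol"])

    def recoverable_degraded_genes(self) -> set[str]:
        """Degraded genes with at least one symbol-bearing accession.

        A gene none of whose accessions carries a defined symbol cannot be
        reported by any gene-symbol-level analysis, so recovery metrics are
        computed over this set.
        """
        mask = self.genes["degraded"] & self.genes["symbol_visible"]
        return set(self.genes.loc[mask, "gene_symbol"])

    def contaminant_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes["contaminant"], "gene_symbol"])


def _random_unit(rng: np.random.Generator) -> str:
    """One tryptic fragment: 5-14 non-K/R residues ending in K or R."""
    length = int(rng.integers(5, 15))
    body = "".join(rng.choice(_BODY_ALPHABET, size=length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def make_library(design: SimulationDesign) -> tuple[ProteinLibrary, pd.DataFrame]:
    """Redundant protein library: isoforms within a gene share >= 50% of peptides.

    Each gene's first isoform is a concatenation of tryptic fragments;
    further isoforms keep a shared prefix of at least
    ``shared_peptide_fraction`` of those fragments and append fresh ones.
    A ``1 - symbol_fraction`` share of accessions has its gene symbol
    blanked, mimicking accessions without a defined symbol. Contaminant
    genes (one accession each, the first being the giant) are appended with
    their catalog symbols. Returns the library and a gene-truth frame.
    """
    rng = np.random.default_rng(design.seed)
    accessions: list[str] = []
    symbols: dict[str, str] = {}
    sequences: dict[str, str] = {}
    gene_rows = []
    n_degraded = int(round(design.n_genes * design.degraded_gene_fraction))
    degraded_idx = set(rng.choice(design.n_genes, size=n_degraded, replace=False).tolist())
    for g in range(design.n_genes):
        gene = f"GS{g + 1:04d}"
        n_iso = int(rng.choice(design.isoform_choices, p=design.isoform_probs))
        n_units = max(5, int(rng.poisson(design.units_per_protein_mean)))
        base_units = [_random_unit(rng) for _ in range(n_units)]
        visible = False
        for iso in range(n_iso):
            acc = f"{gene}_I{iso + 1}"
            if iso == 0:
                units = base_units
            else:
                n_shared = max(1, int(np.ceil(design.shared_peptide_fraction * n_units)))
                n_new = n_units - n_shared
                units = base_units[:n_shared] + [_random_unit(rng) for _ in range(n_new)]
            accessions.append(acc)
            sequences[acc] = "".join(units)
            blanked = rng.random() > design.symbol_fraction
            symbols[acc] = "" if blanked else gene
            visible = visible or not blanked
        gene_rows.append(
            {
                "gene_symbol": gene,
                "degraded": g in degraded_idx,
                "fold": design.degradation_fold if g in degraded_idx else 1.0,
                "contaminant": False,
                "symbol_visible": visible,
            }
        )
    for gene, n_units in zip(design.contaminant_genes, design.contaminant_units):
        acc = f"{gene}_I1"
        accessions.append(acc)
        sequences[acc] = "".join(_random_unit(rng) for _ in range(n_units))
        symbols[acc] = gene
        gene_rows.append(
            {
                "gene_symbol": gene,
                "degraded": False,
                "fold": 1.0,
                "contaminant": True,
                "symbol_visible": True,
            }
        )
    library = ProteinLibrary(
        accessions=accessions, gene_symbols=symbols, sequences=sequences
    )
    return library, pd.DataFrame(gene_rows)


def in_silico_digest(
    library: ProteinLibrary,
    max_missed: int = 3,
    min_length: int = 1,
    proline_rule: bool = True,
) -> pd.DataFrame:
    """All fully tryptic peptides with 0..max_missed missed cleavages.

    One row per (accession, peptide occurrence) with flanking residues
    ('-' at protein termini) and the missed-cleavage count.
    """
    rows = []
    for acc in library.accessions:
        seq = library.sequence(acc)
        cuts = [0]
        for i, res in enumerate(seq[:-1]):
            if res in "KR" and not (proline_rule and seq[i + 1] == "P"):
                cuts.append(i + 1)
        cuts.append(len(seq))
        n_frag = len(cuts) - 1
        for start in range(n_frag):
            for end in range(start + 1, min(start + max_missed + 2, n_frag + 1)):
                pep = seq[cuts[start]:cuts[end]]
                if len(pep) < min_length:
                    continue
                prev_aa = seq[cuts[start] - 1] if cuts[start] > 0 else "-"
                next_aa = seq[cuts[end]] if cuts[end] < len(seq) else "-"
                rows.append(
                    {
                        "accession": acc,
                        "peptide": pep,
                        "prev_aa": prev_aa,
                        "next_aa": next_aa,
                        "missed_cleavages": end - start - 1,
                    }
                )
    return pd.DataFrame(
        rows, columns=["accession", "peptide", "prev_aa", "next_aa", "missed_cleavages"]
    )


def make_manifest(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    preservations = np.array(["ICE", "LN2", "MINUS80"])
    for i in range(design.n_ice_runs):
        rows.append(
            {
                "sample_id": f"ICE{i + 1:03d}",
                "treatment": "ICE",
                "time_h": float(rng.integers(0, 73)),
                "preservation": str(rng.choice(preservations)),
            }
        )
    for i in range(design.n_rt_runs):
        rows.append(
            {
                "sample_id": f"RT{i + 1:03d}",
                "treatment": "RT",
                "time_h": float(rng.integers(0, 73)),
                "preservation": "RT",
            }
        )
    return pd.DataFrame(rows)


class _PeptidePools:
    """Digest-derived sampling pools shared by both algorithm tables."""

    def __init__(self, library: ProteinLibrary, design: SimulationDesign):
        digest = in_silico_digest(
            library, max_missed=design.max_missed, min_length=design.min_peptide_length
        )
        acc_symbol = digest["accession"].map(library.gene_symbols)
        digest = digest.assign(gene_symbol=acc_symbol)
        # gene pools keyed by the true gene (symbol may be blanked per accession)
        true_gene = digest["accession"].str.rsplit("_I", n=1).str[0]
        digest = digest.assign(true_gene=true_gene)
        self.digest = digest
        self.by_gene: dict[str, pd.DataFrame] = {
            g: sub.drop_duplicates(["peptide"]) for g, sub in digest.groupby("true_gene")
        }
        # peptide -> all accessions containing it, with flanks/symbols per row
        self.by_peptide = digest.groupby("peptide")
        self.global_pool = digest.reset_index(drop=True)

    def rows_for(self, peptide: str) -> pd.DataFrame:
        return self.by_peptide.get_group(peptide)


def _emit_rows(
    out: list[dict],
    labels: list[dict],
    pools: _PeptidePools,
    peptide_row: pd.Series,
    spectrum_id: str,
    sample_id: str,
    treatment: str,
    time_h: float,
    p_value: float,
    algorithm: str,
    is_true: bool,
    is_contaminant: bool,
    design: SimulationDesign,
    rng: np.random.Generator,
) -> None:
    peptide = peptide_row["peptide"]
    charge = 2 if rng.random() < 0.6 else 3
    mod = masses.PHOSPHO_MASS if rng.random() < design.phospho_rate else 0.0
    mu = (
        design.log10_intensity_mean_rt
        if treatment == "RT"
        else design.log10_intensity_mean_ice
    )
    intensity = float(10 ** rng.normal(mu, design.log10_intensity_sd))
    delta = float(np.clip(rng.normal(0.0, design.delta_mass_sd), -2.0, 2.0))
    theo = masses.peptide_mass(peptide, mod)
    mz = masses.mz_from_mass(theo + delta, charge)
    carriers = pools.rows_for(peptide)
    for _, crow in carriers.iterrows():
        out.append(
            {
                "spectrum_id": spectrum_id,
                "precursor_mz": mz,
                "charge": charge,
                "intensity": intensity,
                "peptide": peptide,
                "prev_aa": crow["prev_aa"],
                "next_aa": crow["next_aa"],
                "accession": crow["accession"],
                "gene_symbol": crow["gene_symbol"],
                "p_value": p_value,
                "algorithm": algorithm,
                "sample_id": sample_id,
                "treatment": treatment,
                "time_h": time_h,
                "mod_mass": mod,
            }
        )
        labels.append(
            {
                "algorithm": algorithm,
                "spectrum_id": spectrum_id,
                "accession": crow["accession"],
                "is_true": is_true,
                "is_contaminant": is_contaminant,
            }
        )
    # decoy extra candidates the cascade must strip: same spectrum at the
    # other charge, or a second peptide, always with a worse p-value
    if rng.random() < design.extra_charge_rate:
        worse = min(1.0, p_value * float(rng.uniform(2.0, 20.0)) + 1e-12)
        first = carriers.iloc[0]
        out.append(out[-len(carriers)] | {"charge": 5 - charge, "p_value": worse})
        labels.append(
            {
                "algorithm": algorithm,
                "spectrum_id": spectrum_id,
                "accession": first["accession"],
                "is_true": False,
                "is_contaminant": is_contaminant,
            }
        )
    if rng.random() < design.extra_peptide_rate:
        alt = pools.global_pool.iloc[int(rng.integers(len(pools.global_pool)))]
        worse = min(1.0, p_value * float(rng.uniform(2.0, 20.0)) + 1e-12)
        out.append(
            out[-1]
            | {
                "charge": charge,
                "peptide": alt["peptide"],
                "prev_aa": alt["prev_aa"],
                "next_aa": alt["next_aa"],
                "accession": alt["accession"],
                "gene_symbol": alt["gene_symbol"],
                "p_value": worse,
            }
        )
        labels.append(
            {
                "algorithm": algorithm,
                "spectrum_id": spectrum_id,
                "accession": alt["accession"],
                "is_true": False,
                "is_contaminant": False,
            }
        )


def simulate_psm_tables(
    library: ProteinLibrary,
    design: SimulationDesign,
    gene_truth: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth, pd.DataFrame]:
    """Emit X!TANDEM and SEQUEST PSM tables plus ground truth and a manifest.

    Per-gene correlation counts are Poisson with room-temperature rates
    scaled by the degradation fold and the run-count ratio; contaminant
    genes are injected at equal normalised rates in both groups; a
    ``false_psm_rate`` share of events are mis-correlations drawn from the
    whole digest in proportion to tryptic-peptide counts, with uniform
    p-values. Both algorithm tables are drawn over the same genes with
    overlapping but non-identical assignments.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    manifest = make_manifest(design, rng)
    pools = _PeptidePools(library, design)
    ice_samples = manifest.loc[manifest["treatment"] == "ICE"]
    rt_samples = manifest.loc[manifest["treatment"] == "RT"]
    run_ratio = design.n_rt_runs / design.n_ice_runs

    gene_rates = {}
    for _, row in gene_truth.iterrows():
        gene = row["gene_symbol"]
        if row["contaminant"]:
            base = design.contaminant_mean_psms
        else:
            base = max(
                design.min_gene_rate_ice,
                design.mean_psms_per_gene_ice
                * float(np.exp(rng.normal(0.0, design.gene_rate_sigma))),
            )
        gene_rates[gene] = base

    tables: dict[str, pd.DataFrame] = {}
    all_labels: list[dict] = []
    for algorithm in ("XTANDEM", "SEQUEST"):
        out: list[dict] = []
        labels: list[dict] = []
        counter = 0
        for _, row in gene_truth.iterrows():
            gene = row["gene_symbol"]
            pool = pools.by_gene[gene]
            rate_ice = gene_rates[gene]
            rate_rt = rate_ice * row["fold"] * run_ratio
            for treatment, rate, samples in (
                ("ICE", rate_ice, ice_samples),
                ("RT", rate_rt, rt_samples),
            ):
                n_events = int(rng.poisson(rate))
                for _ in range(n_events):
                    counter += 1
                    spectrum_id = f"{algorithm[:2]}{counter:08d}"
                    srow = samples.iloc[int(rng.integers(len(samples)))]
                    if rng.random() < design.false_psm_rate:
                        prow = pools.global_pool.iloc[
                            int(rng.integers(len(pools.global_pool)))
                        ]
                        p_value = float(rng.uniform(np.nextafter(0, 1), 1.0))
                        is_true = False
                    else:
                        prow = pool.iloc[int(rng.integers(len(pool)))]
                        p_value = float(
                            max(rng.beta(design.true_p_alpha, 1.0), 1e-300)
                        )
                        is_true = True
                    _emit_rows(
                        out, labels, pools, prow, spectrum_id,
                        str(srow["sample_id"]), treatment, float(srow["time_h"]),
                        p_value, algorithm, is_true, bool(row["contaminant"]),
                        design, rng,
                    )
        tables[algorithm] = pd.DataFrame(out, columns=PSM_COLUMNS)
        all_labels.extend(labels)

    truth = SyntheticTruth(
        genes=gene_truth.copy(),
        psm_labels=pd.DataFrame(all_labels),
        design=design,
    )
    return tables["XTANDEM"], tables["SEQUEST"], truth, manifest


def simulate_study(design: SimulationDesign):
    """Convenience wrapper: library + both PSM tables + truth + manifest."""
    library, gene_truth = make_library(design)
    xt, seq, truth, manifest = simulate_psm_tables(library, design, gene_truth)
    return library, xt, seq, truth, manifest


def simulate_null_table(
    library: ProteinLibrary,
    n_correlations: int,
    design: SimulationDesign,
) -> pd.DataFrame:
    """Random-assignment null: peptides drawn with probability proportional
    to each accession's tryptic-peptide count, uniform p-values.

    Giant proteins accumulate hits in proportion to their digest size,
    reproducing the random mis-correlation artefact without a search engine.
    """
    if n_correlations < 1:
        raise ValueError("n_correlations must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 2]))
    digest = in_silico_digest(
        library, max_missed=design.max_missed, min_length=design.min_peptide_length
    )
    idx = rng.integers(0, len(digest), size=n_correlations)
    rows = []
    for i, j in enumerate(idx):
        prow = digest.iloc[int(j)]
        peptide = prow["peptide"]
        charge = 2 if rng.random() < 0.6 else 3
        theo = masses.peptide_mass(peptide, 0.0)
        delta = float(rng.uniform(-3.0, 3.0))
        rows.append(
            {
                "spectrum_id": f"NULL{i + 1:08d}",
                "precursor_mz": masses.mz_from_mass(theo + delta, charge),
                "charge": charge,
                "intensity": float(10 ** rng.normal(3.5, 0.5)),
                "peptide": peptide,
                "prev_aa": prow["prev_aa"],
                "next_aa": prow["next_aa"],
                "accession": prow["accession"],
                "gene_symbol": library.gene_symbol(prow["accession"]),
                "p_value": float(rng.uniform(np.nextafter(0, 1), 1.0)),
                "algorithm": "XTANDEM",
                "sample_id": "NULL001",
                "treatment": "ICE",
                "time_h": 0.0,
                "mod_mass": 0.0,
            }
        )
    return pd.DataFrame(rows, columns=PSM_COLUMNS)
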