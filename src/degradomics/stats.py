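"""Gene-level significance and distributional summaries.

Per-gene significance combines the retained peptides' p-values into a
cumulative value (raw product by default, Fisher's method as the
chi-square-calibrated alternative) and adjusts across gene symbols with the
Benjamini-Hochberg step-up. Distribution summaries mirror the standard
quality-control views of a peptidomics run: peptide counts per gene symbol,
log10 precursor-intensity histograms per treatment, and the normal-quantile
pairing of precursor delta masses. A Pearson chi-square goodness-of-fit test
compares an observed count distribution against a null (e.g. random-spectra)
distribution to bound the experiment-wide type I error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import masses
from .io import ProteinLibrary

__all__ = [
    "cumulative_p",
    "bh_fdr",
    "gene_significance",
    "peptide_count_distribution",
    "intensity_histogram",
    "delta_mass_quantiles",
    "DeltaMassSummary",
    "goodness_of_fit",
]


def cumulative_p(p_values: Sequence[float], method: str = "product") -> float:
    """Combine per-peptide p-values into one gene-level value.

    ``product`` is the raw product of the p-values (not itself a calibrated
    p-value, but spans many orders of magnitude and preserves ranking);
    ``fisher`` evaluates -2*sum(ln p) against chi-square with 2k degrees of
    freedom.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0):
        raise ValueError("p-value of 0 signals upstream underflow")
    if np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "product":
        value = float(np.prod(p))
        # many-peptide genes underflow double precision; floor at the
        # smallest subnormal so the value stays in (0, 1] for BH. The exact
        # magnitude is available as log10_cumulative_p in gene summaries.
        return value if value > 0 else float(np.nextafter(0, 1))
    if method == "fisher":
        statistic = -2.0 * float(np.sum(np.log(p)))
        return float(sps.chi2.sf(statistic, df=2 * p.size))
    raise ValueError(f"unknown method {method!r}")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_significance(
    rollup_rows: pd.DataFrame, method: str = "product"
) -> pd.DataFrame:
    """Per-gene summary from the cascade's surviving rows.

    One row per gene symbol with its representative accession, correlation
    count, per-treatment counts, mean p, cumulative p and BH q-value
    (adjusted across gene symbols).
    """
    if rollup_rows.empty:
        return pd.DataFrame(
            columns=[
                "gene_symbol", "accession", "peptide_count", "n_ice", "n_rt",
                "mean_p", "cumulative_p", "q_value",
            ]
        )
    grouped = rollup_rows.groupby(["gene_symbol", "accession"], sort=True)
    rows = []
    for (gene, acc), sub in grouped:
        p = sub["p_value"].to_numpy()
        combined = cumulative_p(p, method=method)
        if method == "product":
            log10_combined = float(np.sum(np.log10(p)))
        else:
            log10_combined = float(np.log10(combined))
        rows.append(
            {
                "gene_symbol": gene,
                "accession": acc,
                "peptide_count": len(sub),
                "n_ice": int((sub["treatment"] == "ICE").sum()),
                "n_rt": int((sub["treatment"] == "RT").sum()),
                "mean_p": float(p.mean()),
                "cumulative_p": combined,
                "log10_cumulative_p": log10_combined,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["cumulative_p"].to_numpy())
    return out


def peptide_count_distribution(summaries: pd.DataFrame) -> pd.Series:
    """Histogram of peptide (correlation) counts per gene symbol."""
    if summaries.empty:
        return pd.Series(dtype=int)
    return summaries["peptide_count"].value_counts().sort_index()


def intensity_histogram(
    psms: pd.DataFrame, bin_width: float = 0.25
) -> dict[str, pd.Series]:
    """log10-intensity histograms per treatment group.

    Bins are [k*w, (k+1)*w) on the log10 scale, keyed by their left edge.
    Zero or negative intensities cannot be log-transformed; they are
    excluded with a warning.
    """
    bad = psms["intensity"] <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} non-positive intensities")
    df = psms.loc[~bad]
    out: dict[str, pd.Series] = {}
    for treatment, sub in df.groupby("treatment"):
        bins = np.floor(np.log10(sub["intensity"].to_numpy()) / bin_width) * bin_width
        series = pd.Series(bins).round(10).value_counts().sort_index()
        out[str(treatment)] = series
    return out


@dataclass(frozen=True)
class DeltaMassSummary:
    mean: float
    sd: float
    fraction_within_2da: float
    degenerate: bool


def delta_mass_quantiles(
    psms: pd.DataFrame,
    table: masses.ResidueMassTable = masses.MONOISOTOPIC,
) -> tuple[np.ndarray, np.ndarray, DeltaMassSummary]:
    """Paired vectors for a normal Q-Q plot of precursor delta masses.

    The delta for each row is the observed neutral mass (from precursor m/z
    and charge) minus the theoretical peptide mass including any
    modification. Returns (sorted deltas, matching standard-normal
    quantiles, summary). A spread of ~zero is flagged degenerate.
    """
    deltas = np.array(
        [
            masses.delta_mass(
                row.precursor_mz,
                int(row.charge),
                masses.peptide_mass(row.peptide, row.mod_mass, table),
            )
            for row in psms.itertuples()
        ]
    )
    n = deltas.size
    if n == 0:
        return deltas, deltas, DeltaMassSummary(np.nan, np.nan, np.nan, True)
    order = np.sort(deltas)
    quantiles = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    sd = float(order.std(ddof=1)) if n > 1 else 0.0
    summary = DeltaMassSummary(
        mean=float(order.mean()),
        sd=sd,
        fraction_within_2da=float(np.mean(np.abs(order) <= 2.0)),
        degenerate=bool(sd == 0.0),
    )
    return order, quantiles, summary


def _align_histograms(
    observed: Mapping[int, float] | pd.Series, null: Mapping[int, float] | pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    obs = pd.Series(dict(observed) if not isinstance(observed, pd.Series) else observed)
    nul = pd.Series(dict(null) if not isinstance(null, pd.Series) else null)
    keys = sorted(set(obs.index) | set(nul.index))
    o = np.array([obs.get(k, 0.0) for k in keys], dtype=float)
    e = np.array([nul.get(k, 0.0) for k in keys], dtype=float)
    return np.asarray(keys, dtype=float), o, e


def goodness_of_fit(
    observed: Mapping[int, float] | pd.Series,
    null: Mapping[int, float] | pd.Series,
    min_expected: float = 5.0,
) -> tuple[float, float, str]:
    """Pearson chi-square test of an observed count histogram against a null.

    The null histogram is scaled to the observed total; bins with expected
    count below ``min_expected`` are pooled into the tail (from the right).
    Returns (statistic, p, direction), where direction summarises whether
    the observed distribution has the heavier right tail (an excess of
    multi-peptide proteins over random expectation).
    """
    keys, o, e = _align_histograms(observed, null)
    if e.sum() <= 0:
        raise ValueError("null histogram has zero total")
    if o.sum() <= 0:
        raise ValueError("observed histogram has zero total")
    e = e * (o.sum() / e.sum())
    # pool any low-expectation bin into its right neighbour (the tail bin
    # folds left); every merge shrinks the list, so this terminates
    o_pool, e_pool = list(o), list(e)
    i = 0
    while i < len(e_pool):
        if e_pool[i] < min_expected and len(e_pool) > 1:
            j = i + 1 if i + 1 < len(e_pool) else i - 1
            e_pool[j] += e_pool[i]
            o_pool[j] += o_pool[i]
            del e_pool[i]
            del o_pool[i]
        else:
            i += 1
    o_arr, e_arr = np.array(o_pool), np.array(e_pool)
    if len(o_arr) < 2:
        return 0.0, 1.0, "indistinguishable"
    statistic = float(np.sum((o_arr - e_arr) ** 2 / e_arr))
    p = float(sps.chi2.sf(statistic, df=len(o_arr) - 1))
    mean_obs = float(np.sum(keys * o) / o.sum())
    mean_null = float(np.sum(keys * e) / e.sum())
    if mean_obs > mean_null:
        direction = "observed right-shifted (excess multi-peptide proteins)"
    elif mean_obs < mean_null:
        direction = "observed left-shifted"
    else:
        direction = "indistinguishable"
    return statistic, p, direction
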