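"""Category-distribution enrichment over a user-supplied annotation table.

Given a gene set and an annotation mapping terms to gene sets over a fixed
background, each term is tested with the hypergeometric upper tail (the
"random expectation" model: probability of drawing at least the observed
number of annotated genes when sampling the gene set uniformly from the
background), then corrected by Bonferroni and by Benjamini-Hochberg. This is
a generic reimplementation of the category test performed by network
databases; results carry a ``method`` metadata field saying so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .stats import bh_fdr

__all__ = ["AnnotationTable", "enrich"]

METHOD_LABEL = "hypergeometric upper tail (generic category test)"


@dataclass
class AnnotationTable:
    """term_id -> (description, gene set) plus the background gene universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            stray = genes - self.background
            if stray:
                raise ValueError(
                    f"term {term!r} annotates genes outside the background: "
                    f"{sorted(stray)[:5]}"
                )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, background: Iterable[str] | None = None
    ) -> "AnnotationTable":
        """Build from a (term_id, description, gene_symbol) long table.

        If no explicit background is given, the union of annotated genes is
        used.
        """
        terms: dict[str, tuple[str, frozenset[str]]] = {}
        for term, sub in frame.groupby("term_id", sort=True):
            desc = str(sub["description"].iloc[0])
            terms[str(term)] = (desc, frozenset(sub["gene_symbol"].astype(str)))
        if background is None:
            bg = frozenset().union(*(g for _, g in terms.values()))
        else:
            bg = frozenset(str(g) for g in background)
        return cls(terms=terms, background=bg)


def enrich(
    gene_set: Iterable[str],
    annotation: AnnotationTable,
    universe: str = "observed",
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``gene_set`` over every annotation term.

    Genes outside the background are dropped with a warning. The
    multiple-testing universe is the number of terms with at least one gene
    from the set (``universe='observed'``, default) or all terms
    (``'all'``). Results are sorted by p ascending; invariants
    p <= p_bonferroni <= 1 and p <= p_fdr <= 1 hold row-wise.
    """
    genes = set(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    if not annotation.terms:
        raise ValueError("empty annotation")
    stray = genes - annotation.background
    if stray:
        warnings.warn(f"dropping {len(stray)} genes outside the background")
        genes -= stray
    if not genes:
        raise ValueError("no gene-set members in the background")
    if universe not in ("observed", "all"):
        raise ValueError("universe must be 'observed' or 'all'")

    M = len(annotation.background)
    N = len(genes)
    rows = []
    for term_id, (description, term_genes) in annotation.terms.items():
        k = len(genes & term_genes)
        K = len(term_genes)
        # P(X >= k) when drawing N genes from a background of M with K marked
        p = float(hypergeom.sf(k - 1, M, K, N)) if k > 0 else 1.0
        rows.append(
            {
                "term_id": term_id,
                "description": description,
                "count_in_set": k,
                "term_size": K,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if universe == "observed":
        tested = out["count_in_set"] >= 1
    else:
        tested = pd.Series(True, index=out.index)
    n_tests = max(int(tested.sum()), 1)
    out["p_bonferroni"] = 1.0
    out.loc[tested, "p_bonferroni"] = (out.loc[tested, "p_value"] * n_tests).clip(upper=1.0)
    out["p_fdr"] = 1.0
    if tested.any():
        out.loc[tested, "p_fdr"] = bh_fdr(out.loc[tested, "p_value"].to_numpy())
    out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    out.attrs["method"] = METHOD_LABEL
    return out
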