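"""Independent brute-force oracles used by the tests.

These deliberately re-derive every rule literally and inefficiently from
the definitions (exhaustive enumeration, explicit loops over dict rows),
sharing no code with the package implementation.
"""

from __future__ import annotations

import math


def digest_positions(sequence: str, proline_rule: bool = True) -> set[int]:
    """All positions where trypsin cuts: 0, len, and after each K/R site."""
    cuts = {0, len(sequence)}
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            cuts.add(i + 1)
    return cuts


def tryptic_oracle(peptide: str, prev_aa: str, next_aa: str, proline_rule: bool = True):
    """Classify via exhaustive digestion of the reconstructed local context."""
    left = "" if prev_aa == "-" else prev_aa
    right = "" if next_aa == "-" else next_aa
    context = left + peptide + right
    start, end = len(left), len(left) + len(peptide)
    cuts = digest_positions(context, proline_rule)
    fully = start in cuts and end in cuts
    missed = sum(1 for c in cuts if start < c < end)
    return fully, missed


def bh_oracle(p_values):
    """Literal step-up: q_i = min over j with p_(j) >= p_(i) of p_(j) * n / j."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    q = [0.0] * n
    running = math.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


def cascade_oracle(rows, min_intensity=1000.0, k=5):
    """Apply every cascade rule literally to a list of row dicts.

    Returns a dict of stage name -> set of surviving
    (spectrum_id, charge, peptide, accession) keys, plus the rollup
    summaries as {gene: (accession, count)}.
    """

    def keys(rs):
        return {(r["spectrum_id"], r["charge"], r["peptide"], r["accession"]) for r in rs}

    stages = {"RAW": keys(rows)}
    rows = [r for r in rows if r["intensity"] >= min_intensity]
    stages["INTENSITY_GE_1000"] = keys(rows)

    out = []
    for sid in {r["spectrum_id"] for r in rows}:
        cand = [r for r in rows if r["spectrum_id"] == sid]
        best_charge = min((r["p_value"], r["charge"]) for r in cand)[1]
        out.extend(r for r in cand if r["charge"] == best_charge)
    rows = out
    stages["BEST_CHARGE"] = keys(rows)

    out = []
    for sid in {r["spectrum_id"] for r in rows}:
        cand = [r for r in rows if r["spectrum_id"] == sid]
        best_pep = min((r["p_value"], r["peptide"]) for r in cand)[1]
        out.extend(r for r in cand if r["peptide"] == best_pep)
    rows = out
    stages["BEST_PEPTIDE"] = keys(rows)

    acc_counts = {}
    for r in rows:
        acc_counts[r["accession"]] = acc_counts.get(r["accession"], 0) + 1
    out = []
    for sid in {r["spectrum_id"] for r in rows}:
        cand = [r for r in rows if r["spectrum_id"] == sid]
        winner = min(cand, key=lambda r: (-acc_counts[r["accession"]], r["accession"]))
        out.append(winner)
    rows = out
    stages["RANK1_PEPTIDES"] = keys(rows)

    acc_counts = {}
    for r in rows:
        acc_counts[r["accession"]] = acc_counts.get(r["accession"], 0) + 1
    rows = [r for r in rows if acc_counts[r["accession"]] >= k]
    stages["ACCESSION_GE_K"] = keys(rows)

    named = [r for r in rows if r["gene_symbol"]]
    per_gene_acc = {}
    for r in named:
        per_gene_acc.setdefault(r["gene_symbol"], {})
        d = per_gene_acc[r["gene_symbol"]]
        d[r["accession"]] = d.get(r["accession"], 0) + 1
    summaries = {}
    for gene, d in per_gene_acc.items():
        rep = min(d, key=lambda a: (-d[a], a))
        summaries[gene] = (rep, d[rep])
    survivors = [
        r for r in named if summaries[r["gene_symbol"]][0] == r["accession"]
    ]
    stages["GENE_ROLLUP"] = keys(survivors)
    stages["DISTINCT_GENES"] = set(summaries)
    return stages, summaries


def random_psm_table(rng, n_rows):
    """A random small PSM table exercising every grouping dimension."""
    rows = []
    for i in range(n_rows):
        rows.append(
            {
                "spectrum_id": f"S{rng.integers(1, max(2, n_rows // 3))}",
                "precursor_mz": float(rng.uniform(300, 1500)),
                "charge": int(rng.integers(1, 5)),
                "intensity": float(rng.uniform(0, 3000)),
                "peptide": "".join(
                    rng.choice(list("ACDK"), size=rng.integers(3, 7))
                ),
                "prev_aa": "R",
                "next_aa": "G",
                "accession": f"A{rng.integers(1, 8)}",
                "gene_symbol": ["", "G1", "G2", "G3"][rng.integers(0, 4)],
                "p_value": float(rng.uniform(1e-6, 1.0)),
                "algorithm": "XTANDEM",
                "sample_id": "ICE001",
                "treatment": ["ICE", "RT"][rng.integers(0, 2)],
                "time_h": 0.0,
                "mod_mass": 0.0,
            }
        )
    return rows
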