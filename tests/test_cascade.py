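import numpy as np
import pandas as pd
import pytest

from degradomics import cascade
from conftest import make_psm, psm_frame
from oracles import cascade_oracle, random_psm_table


class TestIntensityFilter:
    def test_at_least_semantics_keeps_boundary(self):
        df = psm_frame(
            [make_psm(spectrum_id=f"S{i}", intensity=v) for i, v in enumerate([999, 1000, 1001])]
        )
        assert len(cascade.intensity_filter(df, 1000)) == 2

    def test_strict_mode_drops_boundary(self):
        df = psm_frame(
            [make_psm(spectrum_id=f"S{i}", intensity=v) for i, v in enumerate([999, 1000, 1001])]
        )
        assert len(cascade.intensity_filter(df, 1000, strict=True)) == 1

    def test_zero_threshold_is_identity(self):
        df = psm_frame([make_psm(intensity=0.0), make_psm(spectrum_id="S2")])
        assert len(cascade.intensity_filter(df, 0)) == 2

    def test_all_below_threshold_gives_empty(self):
        df = psm_frame([make_psm(intensity=5.0)])
        assert cascade.intensity_filter(df, 1000).empty


class TestBestChargeState:
    def test_keeps_lowest_p_charge(self):
        df = psm_frame(
            [make_psm(charge=2, p_value=0.01), make_psm(charge=3, p_value=0.05)]
        )
        out = cascade.best_charge_state(df)
        assert set(out["charge"]) == {2}

    def test_single_charge_unchanged(self):
        df = psm_frame([make_psm(charge=3)])
        assert len(cascade.best_charge_state(df)) == 1

    def test_tie_goes_to_lower_charge(self):
        df = psm_frame(
            [make_psm(charge=3, p_value=0.01), make_psm(charge=2, p_value=0.01)]
        )
        out = cascade.best_charge_state(df)
        assert set(out["charge"]) == {2}


class TestBestPeptide:
    def test_keeps_lowest_p_peptide(self):
        df = psm_frame(
            [make_psm(peptide="AAAK", p_value=0.001), make_psm(peptide="CCCK", p_value=0.01)]
        )
        out = cascade.best_peptide(df)
        assert set(out["peptide"]) == {"AAAK"}

    def test_shared_peptide_keeps_all_accessions(self):
        df = psm_frame(
            [make_psm(accession=a, p_value=0.001) for a in ("A1", "A2", "A3")]
        )
        out = cascade.best_peptide(df)
        assert len(out) == 3
        assert out["spectrum_id"].nunique() == 1
        assert out["peptide"].nunique() == 1

    def test_p_tie_goes_to_lexicographically_smaller_peptide(self):
        df = psm_frame(
            [make_psm(peptide="CCCK", p_value=0.01), make_psm(peptide="AAAK", p_value=0.01)]
        )
        out = cascade.best_peptide(df)
        assert set(out["peptide"]) == {"AAAK"}


class TestRank1Collapse:
    def test_assigned_to_accession_with_most_correlations(self):
        rows = [make_psm(spectrum_id=f"X{i}", accession="A1", peptide="CCCK") for i in range(9)]
        rows += [make_psm(spectrum_id=f"Y{i}", accession="A2", peptide="DDDK") for i in range(3)]
        rows += [make_psm(spectrum_id="S0", accession="A1"), make_psm(spectrum_id="S0", accession="A2")]
        out = cascade.rank1_collapse(psm_frame(rows))
        assert out.loc[out["spectrum_id"] == "S0", "accession"].item() == "A1"

    def test_unshared_peptide_unchanged(self):
        df = psm_frame([make_psm()])
        pd.testing.assert_frame_equal(
            cascade.rank1_collapse(df).reset_index(drop=True), df
        )

    def test_count_tie_goes_to_lexicographically_smaller_accession(self):
        df = psm_frame(
            [make_psm(accession="B9"), make_psm(accession="A1")]
        )
        out = cascade.rank1_collapse(df)
        assert list(out["accession"]) == ["A1"]


class TestMinPeptideCountFilter:
    def test_boundary_inclusive(self):
        rows = [make_psm(spectrum_id=f"S{i}") for i in range(5)]
        assert len(cascade.min_peptide_count_filter(psm_frame(rows), 5)) == 5

    def test_below_threshold_dropped(self):
        rows = [make_psm(spectrum_id=f"S{i}") for i in range(4)]
        assert cascade.min_peptide_count_filter(psm_frame(rows), 5).empty

    def test_k_one_is_identity(self):
        rows = [make_psm(spectrum_id=f"S{i}") for i in range(3)]
        assert len(cascade.min_peptide_count_filter(psm_frame(rows), 1)) == 3

    def test_distinct_sequence_mode(self):
        rows = [make_psm(spectrum_id=f"S{i}", peptide="AAAK") for i in range(5)]
        assert cascade.min_peptide_count_filter(
            psm_frame(rows), 2, distinct_sequences=True
        ).empty


class TestGeneRollup:
    def test_representative_is_argmax_accession(self):
        rows = [make_psm(spectrum_id=f"S{i}", accession="A1") for i in range(7)]
        rows += [make_psm(spectrum_id=f"T{i}", accession="A2") for i in range(5)]
        summaries, survivors, n_empty = cascade.gene_rollup(psm_frame(rows))
        assert summaries.iloc[0]["accession"] == "A1"
        assert summaries.iloc[0]["peptide_count"] == 7
        assert len(survivors) == 7
        assert n_empty == 0

    def test_count_tie_lexicographic(self):
        rows = [make_psm(spectrum_id="S1", accession="B2"), make_psm(spectrum_id="S2", accession="A1")]
        summaries, _, _ = cascade.gene_rollup(psm_frame(rows))
        assert summaries.iloc[0]["accession"] == "A1"

    def test_empty_symbols_counted_separately(self):
        rows = [make_psm(), make_psm(spectrum_id="S2", gene_symbol="")]
        summaries, survivors, n_empty = cascade.gene_rollup(psm_frame(rows))
        assert n_empty == 1
        assert len(summaries) == 1


class TestRunCascade:
    def test_empty_input_all_zero(self):
        result = cascade.run_cascade(psm_frame([]))
        assert all(count == 0 for _, count in result.report.counts)

    def test_already_filtered_input_is_idempotent(self, study):
        first = cascade.run_cascade(study["xtandem"])
        again = cascade.run_cascade(first.rollup_rows)
        assert again.report.as_dict()["RAW"] == len(first.rollup_rows)
        assert again.report.as_dict()["GENE_ROLLUP"] == len(first.rollup_rows)
        pd.testing.assert_frame_equal(
            again.summaries.reset_index(drop=True),
            first.summaries.reset_index(drop=True),
        )

    def test_counts_monotone_non_increasing(self, study):
        result = cascade.run_cascade(study["xtandem"])
        corr = [c for s, c in result.report.counts if s != "DISTINCT_GENES"]
        assert all(a >= b for a, b in zip(corr, corr[1:]))

    def test_no_spectrum_has_two_peptides_or_charges(self, study):
        result = cascade.run_cascade(study["xtandem"])
        post = cascade.best_peptide(
            cascade.best_charge_state(
                cascade.intensity_filter(study["xtandem"], 1000)
            )
        )
        per_spectrum = post.groupby("spectrum_id").agg(
            n_pep=("peptide", "nunique"), n_charge=("charge", "nunique")
        )
        assert (per_spectrum["n_pep"] == 1).all()
        assert (per_spectrum["n_charge"] == 1).all()
        assert result.rank1["spectrum_id"].is_unique

    def test_matches_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            rows = random_psm_table(rng, int(rng.integers(5, 120)))
            stages, oracle_summaries = cascade_oracle(rows, min_intensity=1000, k=3)
            result = cascade.run_cascade(
                psm_frame(rows), cascade.CascadeConfig(min_intensity=1000, min_peptides=3)
            )

            def key_set(df):
                return set(zip(df["spectrum_id"], df["charge"], df["peptide"], df["accession"]))

            assert key_set(result.rank1) == stages["RANK1_PEPTIDES"]
            assert key_set(result.rollup_rows) == stages["GENE_ROLLUP"]
            got = {
                row["gene_symbol"]: (row["accession"], row["peptide_count"])
                for _, row in result.summaries.iterrows()
            }
            assert got == oracle_summaries


def test_complex_key_identifies_four_tuple():
    a = cascade.complex_key("S1", 2, "AAAK", "P1")
    assert a == cascade.complex_key("S1", 2, "AAAK", "P1")
    assert a != cascade.complex_key("S1", 3, "AAAK", "P1")
    assert len(a) == 40  # SHA1 hex digest
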