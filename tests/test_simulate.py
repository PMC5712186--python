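import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from degradomics import io as dio, masses
from degradomics.simulate import (
    SimulationDesign,
    in_silico_digest,
    make_library,
    simulate_null_table,
    simulate_psm_tables,
    simulate_study,
)


def small_design(**overrides) -> SimulationDesign:
    base = dict(
        seed=3,
        n_genes=20,
        n_ice_runs=8,
        n_rt_runs=8,
        units_per_protein_mean=20,
        mean_psms_per_gene_ice=25.0,
        min_gene_rate_ice=20.0,
    )
    base.update(overrides)
    return SimulationDesign(**base)


class TestMakeLibrary:
    def test_accession_and_symbol_counting(self):
        design = small_design(
            n_genes=10, isoform_choices=(2,), isoform_probs=(1.0,),
            symbol_fraction=1.0, contaminant_genes=(), contaminant_units=(),
        )
        library, truth = make_library(design)
        assert len(library) == 20
        assert len(library.genes()) == 10
        assert library.symbol_fraction == 1.0
        assert len(truth) == 10

    def test_same_seed_gives_identical_fasta(self, tmp_path):
        design = small_design()
        a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        dio.write_fasta_library(make_library(design)[0], a)
        dio.write_fasta_library(make_library(design)[0], b)
        assert a.read_bytes() == b.read_bytes()

    def test_symbol_coverage_near_design_fraction(self):
        design = small_design(n_genes=500, contaminant_genes=(), contaminant_units=())
        library, _ = make_library(design)
        assert library.symbol_fraction == pytest.approx(0.74, abs=0.05)

    def test_isoforms_share_half_their_peptides(self):
        design = small_design(
            n_genes=5, isoform_choices=(2,), isoform_probs=(1.0,),
            contaminant_genes=(), contaminant_units=(),
        )
        library, _ = make_library(design)
        digest = in_silico_digest(library, max_missed=0)
        for gene, accs in library.genes().items():
            if len(accs) < 2:
                continue
            sets = [
                set(digest.loc[digest["accession"] == a, "peptide"]) for a in accs
            ]
            shared = len(sets[0] & sets[1]) / min(len(sets[0]), len(sets[1]))
            assert shared >= 0.5


class TestInSilicoDigest:
    def test_manual_enumeration_with_missed_cleavages(self, tmp_path):
        fasta = tmp_path / "t.fasta"
        fasta.write_text(">P1\nAAKGGRCC\n")
        library = dio.read_fasta_library(fasta)
        digest = in_silico_digest(library, max_missed=1)
        expected = {"AAK", "AAKGGR", "GGR", "GGRCC", "CC"}
        assert set(digest["peptide"]) == expected
        row = digest[digest["peptide"] == "GGRCC"].iloc[0]
        assert row["prev_aa"] == "K" and row["next_aa"] == "-"
        assert row["missed_cleavages"] == 1

    def test_zero_missed_on_lysine_run(self, tmp_path):
        fasta = tmp_path / "t.fasta"
        fasta.write_text(">P1\nKKKK\n")
        library = dio.read_fasta_library(fasta)
        digest = in_silico_digest(library, max_missed=0)
        assert list(digest["peptide"]) == ["K"] * 4

    def test_every_peptide_is_fully_tryptic(self):
        library, _ = make_library(small_design(n_genes=5))
        digest = in_silico_digest(library, max_missed=3, min_length=1)
        for row in digest.itertuples():
            status = masses.tryptic_status(row.peptide, row.prev_aa, row.next_aa)
            assert status.is_fully_tryptic
            assert status.missed_cleavages == row.missed_cleavages
            assert status.missed_cleavages <= 3


class TestSimulatePsmTables:
    def test_same_seed_gives_identical_tables(self):
        design = small_design(n_genes=8)
        lib1, truth1 = make_library(design)
        xt1, seq1, _, _ = simulate_psm_tables(lib1, design, truth1)
        lib2, truth2 = make_library(design)
        xt2, seq2, _, _ = simulate_psm_tables(lib2, design, truth2)
        pd.testing.assert_frame_equal(xt1, xt2)
        pd.testing.assert_frame_equal(seq1, seq2)

    def test_no_degradation_means_balanced_counts(self):
        design = small_design(
            n_genes=30, degraded_gene_fraction=0.0,
            mean_psms_per_gene_ice=170.0, min_gene_rate_ice=150.0,
            contaminant_genes=(), contaminant_units=(),
            false_psm_rate=0.0,
        )
        library, truth = make_library(design)
        xt, _, _, _ = simulate_psm_tables(library, design, truth)
        # gene x treatment contingency over unique spectra
        dedup = xt.drop_duplicates("spectrum_id")
        gene_of = dedup["accession"].str.rsplit("_I", n=1).str[0]
        table = pd.crosstab(gene_of, dedup["treatment"])
        _, p, _, _ = sps.chi2_contingency(table)
        assert p > 0.01

    def test_designed_fold_recovered_within_sampling_envelope(self):
        design = small_design(
            n_genes=30, degraded_gene_fraction=0.3, degradation_fold=10.0,
            mean_psms_per_gene_ice=40.0, min_gene_rate_ice=20.0,
        )
        library, truth = make_library(design)
        xt, _, synth, manifest = simulate_psm_tables(library, design, truth)
        dedup = xt.drop_duplicates("spectrum_id")
        gene_of = dedup["accession"].str.rsplit("_I", n=1).str[0]
        counts = pd.crosstab(gene_of, dedup["treatment"])
        run_ratio = design.n_rt_runs / design.n_ice_runs
        for gene in synth.degraded_genes():
            if gene in counts.index and counts.loc[gene, "ICE"] >= 10:
                ratio = (counts.loc[gene, "RT"] / run_ratio) / counts.loc[gene, "ICE"]
                assert 5 <= ratio <= 20, gene

    def test_truth_labels_align_with_tables(self):
        design = small_design(n_genes=6)
        library, gene_truth = make_library(design)
        xt, seq, truth, _ = simulate_psm_tables(library, design, gene_truth)
        labels = truth.psm_labels
        assert len(labels) == len(xt) + len(seq)
        xt_labels = labels[labels["algorithm"] == "XTANDEM"].reset_index(drop=True)
        assert (xt_labels["spectrum_id"].to_numpy() == xt["spectrum_id"].to_numpy()).all()
        assert (xt_labels["accession"].to_numpy() == xt["accession"].to_numpy()).all()

    def test_contaminants_injected_in_both_groups(self):
        design = small_design(n_genes=6, contaminant_mean_psms=50.0)
        library, gene_truth = make_library(design)
        xt, _, truth, _ = simulate_psm_tables(library, design, gene_truth)
        cont = xt[xt["gene_symbol"].isin(truth.contaminant_genes())]
        assert set(cont["treatment"]) == {"ICE", "RT"}


class TestSimulateNullTable:
    def test_hits_proportional_to_digest_size(self, tmp_path):
        rng = np.random.default_rng(0)

        def protein(n_units):
            return "".join(
                "".join(rng.choice(list("ACDEFGHILMNQSTVWY"), size=7)) + "K"
                for _ in range(n_units)
            )

        fasta = tmp_path / "two.fasta"
        fasta.write_text(f">BIG\n{protein(100)}\n>SMALL\n{protein(10)}\n")
        library = dio.read_fasta_library(fasta, {"BIG": "BIG", "SMALL": "SMALL"})
        design = small_design(max_missed=0, min_peptide_length=1)
        null = simulate_null_table(library, 10000, design)
        counts = null.groupby("accession").size()
        p_big = 100 / 110
        se = np.sqrt(p_big * (1 - p_big) / 10000)
        assert counts["BIG"] / 10000 == pytest.approx(p_big, abs=4 * se)

    def test_single_row_table(self):
        library, _ = make_library(small_design(n_genes=3))
        null = simulate_null_table(library, 1, small_design(n_genes=3))
        assert len(null) == 1

    def test_giant_protein_gets_most_hits(self, study):
        null = simulate_null_table(study["library"], 20000, study["design"])
        top = null.groupby("accession").size().idxmax()
        digest = in_silico_digest(
            study["library"], study["design"].max_missed,
            study["design"].min_peptide_length,
        )
        assert top == digest.groupby("accession").size().idxmax()
        assert top.startswith("TTN")


class TestDesignSerialization:
    def test_json_round_trip(self):
        design = small_design(degradation_fold=7.5)
        assert SimulationDesign.from_json(design.to_json()) == design

    def test_seed_required(self):
        with pytest.raises(TypeError):
            SimulationDesign()  # type: ignore[call-arg]

    def test_probability_bounds_validated(self):
        with pytest.raises(ValueError, match="degraded_gene_fraction"):
            small_design(degraded_gene_fraction=1.5)
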