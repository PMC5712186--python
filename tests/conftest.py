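import pandas as pd
import pytest

from degradomics.io import PSM_COLUMNS
from degradomics.simulate import SimulationDesign, simulate_study


def make_psm(**overrides) -> dict:
    """One well-formed PSM row; keyword arguments override defaults."""
    row = {
        "spectrum_id": "S1",
        "precursor_mz": 500.0,
        "charge": 2,
        "intensity": 5000.0,
        "peptide": "AAAK",
        "prev_aa": "R",
        "next_aa": "G",
        "accession": "A1",
        "gene_symbol": "GENE1",
        "p_value": 0.01,
        "algorithm": "XTANDEM",
        "sample_id": "ICE001",
        "treatment": "ICE",
        "time_h": 0.0,
        "mod_mass": 0.0,
    }
    row.update(overrides)
    return row


def psm_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


@pytest.fixture(scope="session")
def study():
    """One seeded synthetic study at the suite's working scale.

    200 genes, the full 82 ice + 88 room-temperature run design, fold-10
    degradation on 15% of genes with at least 20 expected ice-preserved
    correlations per gene.
    """
    design = SimulationDesign(seed=11)
    library, xt, seq, truth, manifest = simulate_study(design)
    return {
        "design": design,
        "library": library,
        "xtandem": xt,
        "sequest": seq,
        "truth": truth,
        "manifest": manifest,
    }
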