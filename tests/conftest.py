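import pandas as pd
import pytest

from psmstack import generate_decoys, simulate_psm_tables, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small two-dataset synthetic study with decoys and PSM tables."""
    db, truth, predictions = simulate_study(
        n_proteins=150, n_datasets=2, present_fraction=0.7, seed=7
    )
    db = generate_decoys(db, "trypsin", seed=7)
    psms = simulate_psm_tables(db, truth, n_true=2500, n_false=300, seed=7)
    return db, truth, predictions, psms


def make_psm_row(
    spectrum_id,
    peptide,
    pep,
    engine="msgfplus",
    is_decoy=False,
    dataset_id="DS0",
    accessions="P1",
    specificity="full",
    modifications="",
):
    return {
        "spectrum_id": spectrum_id,
        "dataset_id": dataset_id,
        "raw_file": f"{dataset_id}_run0",
        "engine": engine,
        "peptide": peptide,
        "modifications": modifications,
        "charge": 2,
        "is_decoy": is_decoy,
        "accessions": accessions,
        "enzyme": "trypsin",
        "specificity": specificity,
        "pep": pep,
    }


@pytest.fixture
def psm_frame():
    def build(rows):
        return pd.DataFrame([make_psm_row(**r) for r in rows])

    return build
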