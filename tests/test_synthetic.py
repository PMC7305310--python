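"""Generator contracts: exact allocation, determinism, truth round-trips,
target/decoy exchangeability of false matches."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from psmstack import generate_decoys, simulate_psm_tables, simulate_study
from psmstack.synthetic import (
    SyntheticTruth,
    empirical_fdr,
    peptide_truth,
    plant_signal_peptide_evidence,
    write_study,
)


def test_exact_presence_allocation():
    db, truth, _ = simulate_study(
        n_proteins=100, n_datasets=3, present_fraction=0.6,
        duplicate_fraction=0.0, spurious_fraction=0.0, seed=1,
    )
    assert db.counted_size == 100
    for ds, present in truth.protein_presence.items():
        assert len(present) == 60


def test_exact_spurious_and_duplicate_allocation():
    db, truth, _ = simulate_study(
        n_proteins=120, n_datasets=1, n_spurious=7, n_duplicates=9, seed=2
    )
    assert db.counted_size == 120 - 7 - 9
    assert sum(e.is_spurious for e in db.targets) == 7
    extra = sum(len(e.duplicate_members) - 1 for e in db.counted)
    assert extra == 9


def test_infeasible_allocation_rejected():
    with pytest.raises(ValueError):
        simulate_study(n_proteins=60, n_datasets=1, n_spurious=30, n_duplicates=40, seed=0)


def test_planted_island_recorded_and_absent():
    db, truth, _ = simulate_study(
        n_proteins=210, n_datasets=2, planted_islands=[(0, 40, 30)], seed=3
    )
    assert truth.planted_islands == [("rep0", 40, 30)]
    order = db.replicon_order("rep0")
    island_accs = {order[(40 + k) % len(order)] for k in range(30)}
    for present in truth.protein_presence.values():
        assert not island_accs & set(present)


def test_same_seed_reproduces_identical_study(tmp_path):
    outputs = []
    for run in range(2):
        db, truth, pred = simulate_study(n_proteins=80, n_datasets=2, seed=9)
        out = tmp_path / f"run{run}"
        write_study(db, truth, pred, out)
        outputs.append((out / "proteome.fasta").read_bytes())
        if run:
            assert truth.protein_presence == first_truth.protein_presence
        else:
            first_truth = truth
    assert outputs[0] == outputs[1]


def test_truth_round_trips_through_json(tmp_path):
    db, truth, _ = simulate_study(n_proteins=80, n_datasets=2, seed=4)
    db = generate_decoys(db, "trypsin", seed=4)
    simulate_psm_tables(db, truth, n_true=300, n_false=50, seed=4)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    loaded = SyntheticTruth.from_json(path)
    assert loaded.psm_labels == truth.psm_labels
    assert loaded.protein_presence == truth.protein_presence
    assert loaded.planted_cs == truth.planted_cs
    assert loaded.generator_params == truth.generator_params


def test_false_matches_split_evenly_and_exchangeably(small_study):
    db, truth, _, psms = small_study
    false_ids = {s for s, label in truth.psm_labels.items() if label == "false_match"}
    false_psms = psms[psms["spectrum_id"].isin(false_ids)].drop_duplicates("spectrum_id")
    n_decoy = int(false_psms["is_decoy"].sum())
    # decoy fraction of false matches is a fair-coin binomial draw
    assert stats.binomtest(n_decoy, len(false_psms), 0.5).pvalue > 1e-4
    # exchangeability: false-target and decoy PEPs from one distribution
    target_peps = psms[psms["spectrum_id"].isin(false_ids) & ~psms["is_decoy"]]["pep"]
    decoy_peps = psms[psms["spectrum_id"].isin(false_ids) & psms["is_decoy"]]["pep"]
    assert stats.ks_2samp(target_peps, decoy_peps).pvalue > 0.01


def test_true_matches_hit_present_proteins(small_study):
    db, truth, _, psms = small_study
    true_ids = {s for s, label in truth.psm_labels.items() if label == "true_match"}
    sub = psms[psms["spectrum_id"].isin(true_ids)]
    for ds, block in sub.groupby("dataset_id"):
        present = set(truth.protein_presence[ds])
        for accs in block["accessions"]:
            assert any(a in present for a in accs.split(";"))


def test_unfiltered_fdr_computable_from_labels(small_study):
    db, truth, _, psms = small_study
    labels = peptide_truth(psms, truth)
    targets = psms[~psms["is_decoy"]].drop_duplicates("peptide")
    fdr = empirical_fdr(targets["peptide"], labels)
    n_false = sum(1 for p in targets["peptide"] if not labels[p])
    assert fdr == pytest.approx(n_false / len(targets))
    assert 0 < fdr < 0.5


def test_overlap_bias_raises_engine_count_of_true_matches(small_study):
    db, truth, _, psms = small_study
    per_psm = psms.groupby("spectrum_id").agg(
        n_engines=("engine", "nunique"),
    )
    per_psm["label"] = [truth.psm_labels[s] for s in per_psm.index]
    mean_true = per_psm.loc[per_psm["label"] == "true_match", "n_engines"].mean()
    mean_false = per_psm.loc[per_psm["label"] == "false_match", "n_engines"].mean()
    assert mean_true > mean_false


def test_oversampling_the_peptide_pool_rejected(small_study):
    db, truth, *_ = small_study
    with pytest.raises(ValueError, match="exceeds"):
        simulate_psm_tables(db, truth, n_true=10_000_000, n_false=0, seed=0)


def test_planted_sparse_case_emits_exactly_four_psms():
    db, truth, _ = simulate_study(n_proteins=120, n_datasets=1, predicted_fraction=0.6, seed=6)
    db = generate_decoys(db, "trypsin", seed=6)
    spi = [a for a, (p, _) in sorted(truth.planted_cs.items()) if p.endswith("(SPI)")]
    planted = plant_signal_peptide_evidence(db, truth, {"sparse": spi[:1]}, seed=6)
    semi = planted[planted["specificity"] == "semi_n"]
    assert semi["spectrum_id"].nunique() == 4


def test_refined_offset_moves_peptide_start():
    db, truth, _ = simulate_study(n_proteins=120, n_datasets=1, predicted_fraction=0.6, seed=8)
    db = generate_decoys(db, "trypsin", seed=8)
    spi = [a for a, (p, _) in sorted(truth.planted_cs.items()) if p.endswith("(SPI)")]
    acc = spi[0]
    cs = truth.planted_cs[acc][1]
    planted = plant_signal_peptide_evidence(db, truth, {"refined": {acc: 2}}, seed=8)
    semi = planted[planted["specificity"] == "semi_n"]
    starts = {db[acc].sequence.find(p) + 1 for p in semi["peptide"]}
    assert starts == {cs + 2}
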