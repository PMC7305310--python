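"""Peptide collapse, q-values, protein inference, picked protein FDR."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psmstack.fdr import (
    apply_confidence_filters,
    apply_length_bounds,
    collapse_to_peptides,
    compute_classical_protein_qvalues,
    compute_peptide_qvalues,
    compute_picked_protein_qvalues,
    identification_summary,
    infer_proteins,
    score_proteins,
    two_traversal_qvalues,
)
from psmstack.model import ProteinDB, ProteinEntry


def brute_force_qvalues(is_decoy):
    """Independent oracle: cumulative decoy/target ratio + min-so-far."""
    raw, d, t = [], 0, 0
    for flag in is_decoy:
        d += bool(flag)
        t += not flag
        raw.append(math.inf if t == 0 else d / t)
    out, best = [], math.inf
    for v in reversed(raw):
        best = min(best, v)
        out.append(best)
    return out[::-1]


def combined_frame(rows):
    defaults = {
        "dataset_id": "DS0",
        "modifications": "",
        "is_decoy": False,
        "accessions": "P1",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


# ---------------------------------------------------------------- collapse


def test_collapse_takes_min_pep_and_counts_psms():
    psms = combined_frame(
        [
            {"spectrum_id": "s1", "peptide": "AAAK", "combined_pep": 0.01},
            {"spectrum_id": "s2", "peptide": "AAAK", "combined_pep": 0.001, "dataset_id": "DS1"},
            {"spectrum_id": "s3", "peptide": "AAAK", "combined_pep": 0.1},
        ]
    )
    out = collapse_to_peptides(psms)
    assert len(out) == 1
    row = out.iloc[0]
    assert row["best_pep"] == pytest.approx(0.001)
    assert row["psm_count"] == 3
    assert row["dataset_ids"] == "DS0;DS1"


def test_collapse_target_decoy_collision_labeled_target():
    psms = combined_frame(
        [
            {"spectrum_id": "s1", "peptide": "AAAK", "combined_pep": 0.01},
            {"spectrum_id": "s2", "peptide": "AAAK", "combined_pep": 0.001, "is_decoy": True},
        ]
    )
    out = collapse_to_peptides(psms)
    assert len(out) == 1
    assert not out.iloc[0]["is_decoy"]
    assert out.iloc[0]["psm_count"] == 1  # the decoy occurrence is discarded


def test_length_bounds_drop_short_and_long():
    peps = pd.DataFrame(
        {"peptide": ["AAAAA", "A" * 6, "A" * 50, "A" * 51], "length": [5, 6, 50, 51]}
    )
    out = apply_length_bounds(peps)
    assert list(out["length"]) == [6, 50]


# ---------------------------------------------------------------- q-values


def test_qvalue_hand_example_ten_targets_one_decoy():
    is_decoy = [False] * 10 + [True]
    q = two_traversal_qvalues(np.array(is_decoy))
    assert np.allclose(q[:10], 0.0)
    assert q[10] == pytest.approx(0.1)


def test_no_decoys_gives_zero_q():
    q = two_traversal_qvalues(np.zeros(5, dtype=bool))
    assert np.allclose(q, 0.0)


def test_second_traversal_monotonizes():
    # raw top-down sequence ends (..., 0.1, 0.05); min-so-far makes both 0.05
    is_decoy = [False] * 10 + [True] + [False] * 10  # raw: 0.1 at decoy, 0.05 at end
    q = two_traversal_qvalues(np.array(is_decoy))
    assert q[10] == pytest.approx(1 / 20)
    assert (np.diff(q) >= -1e-15).all()


@settings(derandomize=True, max_examples=300)
@given(st.lists(st.booleans(), min_size=1, max_size=50))
def test_qvalues_match_brute_force_oracle(flags):
    got = two_traversal_qvalues(np.array(flags))
    expected = brute_force_qvalues(flags)
    for g, e in zip(got, expected):
        assert g == pytest.approx(e) or (math.isinf(g) and math.isinf(e))


def test_grouped_qvalues_rank_decoys_first_on_ties():
    peps = pd.DataFrame(
        {
            "peptide": ["AAAAAA", "CCCCCC", "DDDDDD"],
            "length": [6, 6, 6],
            "is_decoy": [False, True, False],
            "best_pep": [0.01, 0.01, 0.001],
            "psm_count": 2,
            "dataset_ids": "DS0",
            "accessions": "P1",
        }
    )
    out = compute_peptide_qvalues(peps, group_by_length=False)
    # ranking: DDDDDD, then decoy CCCCCC (tie broken conservatively), then AAAAAA
    by_pep = out.set_index("peptide")["q_value"]
    assert by_pep["DDDDDD"] == pytest.approx(0.0)
    assert by_pep["CCCCCC"] == pytest.approx(0.5)
    assert by_pep["AAAAAA"] == pytest.approx(0.5)


def test_all_decoy_group_flagged_undefined():
    peps = pd.DataFrame(
        {
            "peptide": ["AAAAAA"],
            "length": [6],
            "is_decoy": [True],
            "best_pep": [0.5],
            "psm_count": 1,
            "dataset_ids": "DS0",
            "accessions": "decoy_P1",
        }
    )
    out = compute_peptide_qvalues(peps, group_by_length=False)
    assert out["q_undefined"].all()
    assert out["q_value"].isna().all()


def test_sparse_length_bins_merge():
    rng = np.random.default_rng(1)
    lengths = [7] * 150 + [8] * 150 + [30] * 3  # the 30-mers merge into a neighbor
    peps = pd.DataFrame(
        {
            "peptide": [f"{'A' * (l - 1)}K{i}"[:l] for i, l in enumerate(lengths)],
            "length": lengths,
            "is_decoy": rng.random(len(lengths)) < 0.3,
            "best_pep": rng.uniform(0, 1, len(lengths)),
            "psm_count": 1,
            "dataset_ids": "DS0",
            "accessions": "P1",
        }
    )
    out = compute_peptide_qvalues(peps, group_by_length=True, min_group_size=100)
    assert out["q_value"].notna().sum() + out["q_undefined"].sum() == len(out)


# ---------------------------------------------------------------- inference


def make_db(seqs):
    db = ProteinDB()
    for acc, seq in seqs.items():
        db.add(ProteinEntry(accession=acc, sequence=seq))
    return db


def peptide_table(rows):
    defaults = {"is_decoy": False, "psm_count": 2, "q_value": 0.0, "dataset_ids": "DS0"}
    df = pd.DataFrame([{**defaults, **r} for r in rows])
    df["length"] = df["peptide"].str.len()
    df["best_pep"] = df.get("best_pep", pd.Series([0.001] * len(df)))
    return df


SHARED_DB = make_db(
    {"P1": "MAAAKCCCK", "P2": "MAAAKDDDK", "P3": "WWWKAAAK"}
)


def test_shared_peptide_assigned_to_uniquely_evidenced_protein():
    peps = peptide_table(
        [
            {"peptide": "CCCK", "accessions": "P1"},  # proteotypic for P1
            {"peptide": "MAAAK", "accessions": "P1;P2"},  # shared
        ]
    )
    groups = infer_proteins(peps, SHARED_DB)
    assert list(groups["representative"]) == ["P1"]
    assert sorted(groups.iloc[0]["peptides"]) == ["CCCK", "MAAAK"]


def test_shared_peptide_with_two_evidenced_carriers_discarded():
    peps = peptide_table(
        [
            {"peptide": "CCCK", "accessions": "P1"},
            {"peptide": "DDDK", "accessions": "P2"},
            {"peptide": "MAAAK", "accessions": "P1;P2"},
        ]
    )
    groups = infer_proteins(peps, SHARED_DB)
    by_status = groups.set_index("status")
    assert "discarded_ambiguous" in groups["status"].values
    assert by_status.loc["discarded_ambiguous", "members"] == "P1;P2"


def test_shared_peptide_with_no_evidenced_carrier_counts_once():
    peps = peptide_table([{"peptide": "MAAAK", "accessions": "P1;P2"}])
    groups = infer_proteins(peps, SHARED_DB)
    assert len(groups) == 1
    assert groups.iloc[0]["status"] == "group"
    assert groups.iloc[0]["members"] == "P1;P2"


def test_unknown_accession_is_a_database_mismatch():
    peps = peptide_table([{"peptide": "MAAAK", "accessions": "NOPE"}])
    with pytest.raises(ValueError, match="unknown accession"):
        infer_proteins(peps, SHARED_DB)


# ---------------------------------------------------------------- scoring


def test_protein_score_sums_neglog_peps():
    peps = peptide_table(
        [
            {"peptide": "CCCK", "accessions": "P1", "best_pep": 0.01},
            {"peptide": "MAAAK", "accessions": "P1", "best_pep": 0.001},
        ]
    )
    groups = score_proteins(infer_proteins(peps, SHARED_DB), peps)
    assert groups.iloc[0]["score"] == pytest.approx(5.0)


def test_peptides_above_q_threshold_do_not_score():
    peps = peptide_table(
        [
            {"peptide": "CCCK", "accessions": "P1", "best_pep": 0.01},
            {"peptide": "MAAAK", "accessions": "P1", "best_pep": 0.001, "q_value": 0.02},
        ]
    )
    groups = score_proteins(infer_proteins(peps, SHARED_DB), peps)
    assert groups.iloc[0]["score"] == pytest.approx(2.0)


def test_group_with_no_qualifying_peptides_dropped():
    peps = peptide_table([{"peptide": "CCCK", "accessions": "P1", "q_value": 0.5}])
    groups = score_proteins(infer_proteins(peps, SHARED_DB), peps)
    assert len(groups) == 0


# ------------------------------------------------------------- picked FDR


def group_frame(scores, prefix=""):
    return pd.DataFrame(
        {
            "representative": [f"{prefix}P{i}" for i in range(len(scores))],
            "members": [f"{prefix}P{i}" for i in range(len(scores))],
            "status": "single",
            "peptides": [[f"pep{i}"] for i in range(len(scores))],
            "n_peptides": 1,
            "psm_count": 2,
            "score": scores,
            "scope": "combined",
        }
    )


def test_picked_competition_discards_pair_losers():
    t = group_frame([5.0, 2.0])
    d = group_frame([2.0, 5.0], prefix="decoy_")
    out = compute_picked_protein_qvalues(t, d)
    survivors = set(out["representative"])
    assert survivors == {"P0", "decoy_P1"}  # each pair keeps its higher scorer


def test_picked_tie_keeps_target():
    t = group_frame([3.0])
    d = group_frame([3.0], prefix="decoy_")
    out = compute_picked_protein_qvalues(t, d)
    assert list(out["representative"]) == ["P0"]


def test_picked_qvalues_match_oracle_on_survivor_ranking():
    # survivors by rank: T T D T T D
    t = group_frame([10.0, 9.0, 7.0, 6.0])
    d = group_frame([1.0, 1.0, 1.0, 1.0], prefix="decoy_")
    d.loc[4] = {**d.iloc[0].to_dict(), "representative": "decoy_P9", "members": "decoy_P9", "score": 8.0}
    d.loc[5] = {**d.iloc[0].to_dict(), "representative": "decoy_P8", "members": "decoy_P8", "score": 5.0}
    out = compute_picked_protein_qvalues(t, d)
    ranked = out.sort_values("score", ascending=False)
    expected = brute_force_qvalues(ranked["is_decoy"].tolist())
    assert np.allclose(ranked["q_value"], expected)


def test_unpaired_decoy_prefix_rejected():
    t = group_frame([1.0])
    d = group_frame([1.0], prefix="bogus_")
    with pytest.raises(ValueError, match="prefix"):
        compute_picked_protein_qvalues(t, d)


def test_picked_never_exceeds_classical_with_high_scoring_decoys():
    rng = np.random.default_rng(0)
    t = group_frame(sorted(rng.uniform(5, 15, 40), reverse=True))
    # decoys slightly below their targets: lose every pair but outrank
    # later targets in the classical joint ranking
    d = t.copy()
    d["representative"] = "decoy_" + d["representative"]
    d["members"] = d["representative"]
    d["score"] = t["score"] - 0.2
    picked = compute_picked_protein_qvalues(t, d)
    classical = compute_classical_protein_qvalues(t, d)
    pq = picked[~picked["is_decoy"]].set_index("representative")["q_value"]
    cq = classical[~classical["is_decoy"]].set_index("representative")["q_value"]
    assert (pq <= cq.loc[pq.index] + 1e-12).all()
    assert (cq.loc[pq.index] > pq).any()  # classical is strictly more conservative somewhere


# ---------------------------------------------------------------- filters


def test_confidence_filters_and_summary():
    peptides = pd.DataFrame(
        {
            "peptide": ["A", "B", "C", "D"],
            "is_decoy": [False, False, False, True],
            "q_value": [0.001, 0.001, 0.02, 0.001],
            "psm_count": [1, 2, 5, 9],
        }
    )
    groups = pd.DataFrame(
        {
            "representative": ["P1", "P2", "P3"],
            "status": ["single", "single", "discarded_ambiguous"],
            "q_value": [0.004, 0.006, 0.001],
            "psm_count": [3, 3, 3],
            "is_decoy": [False, False, False],
        }
    )
    peps, prots, summary = apply_confidence_filters(peptides, groups, counted_size=10)
    # 1-PSM peptide excluded despite excellent q; q>1% excluded; decoy excluded
    assert list(peps["peptide"]) == ["B"]
    # q=0.006 > 0.5% excluded; ambiguous group excluded
    assert list(prots["representative"]) == ["P1"]
    assert summary["n_proteins"] == 1 and summary["identified_fraction_pct"] == 10


def test_identified_fraction_rounding():
    assert identification_summary(0, 2930, 4074)["identified_fraction_pct"] == 72


def test_min_psms_filter_removes_singleton_decoys():
    """Requiring two PSMs can eliminate every decoy peptide (theoretical FDR 0)."""
    rng = np.random.default_rng(2)
    n_t, n_d = 200, 20
    peptides = pd.DataFrame(
        {
            "peptide": [f"T{i}" for i in range(n_t)] + [f"D{i}" for i in range(n_d)],
            "is_decoy": [False] * n_t + [True] * n_d,
            "q_value": np.concatenate([rng.uniform(0, 0.01, n_t), rng.uniform(0, 0.01, n_d)]),
            "psm_count": [3] * n_t + [1] * n_d,  # decoys are singleton hits
        }
    )
    groups = pd.DataFrame(
        {"representative": [], "status": [], "q_value": [], "psm_count": [], "is_decoy": []}
    )
    peps, _, _ = apply_confidence_filters(peptides, groups, counted_size=n_t)
    assert len(peps) == n_t
    decoy_like = peptides[peptides["is_decoy"] & (peptides["psm_count"] >= 2)]
    assert len(decoy_like) == 0
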