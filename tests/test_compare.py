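"""Dataset overlap, arCOG enrichment, low-identification islands."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from psmstack.compare import (
    arcog_enrichment,
    dataset_overlap,
    overlap_bins,
    percent,
    scan_low_identification_islands,
)
from psmstack.model import ProteinDB, ProteinEntry


def small_db(n=10, classes=None):
    db = ProteinDB()
    for i in range(n):
        db.add(
            ProteinEntry(
                accession=f"P{i}",
                sequence="MAKR",
                replicon_id="rep0",
                gene_index=i,
                arcog_class=(classes or {}).get(i),
            )
        )
    db.circular["rep0"] = True
    return db


# ----------------------------------------------------------------- overlap


def test_overlap_counts_and_partition():
    db = small_db(5)
    sets = {
        "DS0": {"P0", "P1", "P2"},
        "DS1": {"P0", "P1"},
        "DS2": {"P0"},
    }
    profile = dataset_overlap(sets, db)
    k = profile.set_index("accession")["k"]
    assert k["P0"] == 3 and k["P1"] == 2 and k["P2"] == 1 and k["P4"] == 0
    bins = overlap_bins(profile, 3)
    assert bins.sum() == db.counted_size
    assert list(bins) == [2, 1, 1, 1]


# -------------------------------------------------------------- enrichment


def fisher_oracle(table):
    """Exhaustive two-sided Fisher p: sum of hypergeometric probabilities of
    all tables with the observed margins that are no more probable."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


def test_fisher_p_matches_enumeration_oracle():
    table = [[8, 2], [10, 40]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    assert p == pytest.approx(fisher_oracle(table), rel=1e-9)


def test_no_association_gives_p_one():
    db = small_db(8, classes={i: "J" if i < 4 else "K" for i in range(8)})
    out = arcog_enrichment({"P0", "P1", "P4", "P5"}, db)  # same 50/50 split
    assert np.allclose(out["p_value"], 1.0)


def test_bonferroni_multiplies_by_class_count():
    db = small_db(9, classes={0: "J", 1: "J", 2: "K", 3: "K", 4: "L", 5: "L"})
    out = arcog_enrichment({"P0", "P1"}, db)
    assert len(out) == 3
    assert np.allclose(out["p_bonferroni"], np.minimum(1.0, out["p_value"] * 3))
    assert ((out["p_value"] > 0) & (out["p_value"] <= 1)).all()


def test_empty_group_rejected():
    with pytest.raises(ValueError, match="empty"):
        arcog_enrichment(set(), small_db(5))


def test_planted_enrichment_detected_at_scale():
    """A class planted at ~3x background odds is significant at n=2000."""
    rng = np.random.default_rng(42)
    db = ProteinDB()
    classes = ["J"] * 200 + ["K"] * 1800
    rng.shuffle(classes)
    for i, cls in enumerate(classes):
        db.add(ProteinEntry(accession=f"P{i}", sequence="MAKR", gene_index=i, arcog_class=cls))
    group = {
        f"P{i}"
        for i, cls in enumerate(classes)
        if rng.random() < (0.6 if cls == "J" else 0.2)
    }
    out = arcog_enrichment(group, db).set_index("arcog_class")
    assert out.loc["J", "p_bonferroni"] < 0.05
    assert out.loc["J", "odds_ratio"] > 1


# ----------------------------------------------------------------- islands


def brute_force_window_counts(flags, half):
    n = len(flags)
    return [
        sum(flags[(i + o) % n] for o in range(-half, half + 1)) for i in range(n)
    ]


def test_window_rate_percentages():
    assert percent(20, 51) == 39.2
    assert percent(14, 51) == 27.5
    assert percent(48, 51) == 94.1


def test_window_counts_match_brute_force_on_random_circular_layout():
    rng = np.random.default_rng(3)
    flags = rng.random(120) < 0.6
    report = scan_low_identification_islands(flags)
    assert list(report.counts) == brute_force_window_counts(list(flags), 25)
    assert report.window_size == 51


def test_window_counts_rotation_invariant():
    rng = np.random.default_rng(4)
    flags = rng.random(100) < 0.5
    base = scan_low_identification_islands(flags).counts
    for shift in (1, 17, 50):
        rolled = scan_low_identification_islands(np.roll(flags, shift)).counts
        assert (np.roll(base, shift) == rolled).all()


def test_all_identified_yields_no_islands():
    report = scan_low_identification_islands(np.ones(100, dtype=bool))
    assert report.islands == []


def test_planted_absent_run_recovered_as_single_island():
    rng = np.random.default_rng(5)
    flags = rng.random(200) < 0.7
    flags[60:90] = False  # 30-gene absent run
    report = scan_low_identification_islands(flags)
    assert len(report.islands) == 1
    start, end = report.islands[0]
    assert start <= 60 and end >= 85  # island covers the run's core


def test_planted_run_across_origin_recovered_with_wraparound():
    rng = np.random.default_rng(5)
    flags = rng.random(200) < 0.7
    for i in range(185, 215):
        flags[i % 200] = False  # wraps the origin
    report = scan_low_identification_islands(flags)
    assert len(report.islands) == 1
    start, end = report.islands[0]
    assert start > end  # the reported run itself wraps
    frame = report.islands_frame()
    assert frame.loc[0, "n_genes"] >= 25


def test_short_linear_replicon_rejected():
    with pytest.raises(ValueError, match="shorter than"):
        scan_low_identification_islands(np.ones(30, dtype=bool), circular=False)
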