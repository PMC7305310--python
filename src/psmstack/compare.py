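"""Cross-dataset comparison: overlap, functional enrichment, genomic islands.

* ``dataset_overlap`` counts, for every protein of the counted proteome, the
  number of whole-proteome datasets in which it was confidently identified.
* ``arcog_enrichment`` tests each arCOG functional class for over/under-
  representation in a protein group against the whole-proteome background
  with a two-sided Fisher exact test and Bonferroni correction.
* ``scan_low_identification_islands`` slides a 51-gene window (25 genes on
  each side) along each replicon's gene order, respecting circularity, and
  reports maximal runs of genes whose window identification count falls at
  or below a threshold (default 20 of 51, i.e. 39.2 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .model import ProteinDB


def percent(count: int, total: int, digits: int = 1) -> float:
    """Percentage rounded half-up to ``digits`` decimals (report convention)."""
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP))


def dataset_overlap(
    protein_sets: dict[str, set[str]], db: ProteinDB
) -> pd.DataFrame:
    """Per-protein presence count over whole-proteome datasets.

    Returns one row per counted protein with ``k`` (number of datasets the
    protein was identified in; 0 for proteins never identified).  The bin
    sizes over k = 0..n partition the counted proteome.
    """
    counted = [e.accession for e in db.counted]
    k = {acc: 0 for acc in counted}
    for _, accs in protein_sets.items():
        for acc in accs:
            if acc in k:
                k[acc] += 1
    return pd.DataFrame({"accession": counted, "k": [k[a] for a in counted]})


def overlap_bins(profile: pd.DataFrame, n_datasets: int) -> np.ndarray:
    """Histogram of the overlap profile over k = 0..n_datasets."""
    return np.bincount(profile["k"], minlength=n_datasets + 1)


def arcog_enrichment(group: set[str], db: ProteinDB) -> pd.DataFrame:
    """Fisher exact enrichment of arCOG classes in a group vs the proteome.

    For each class the 2x2 table compares in-group membership against the
    whole counted proteome background; proteins without a class count
    outside every class.  ``p_bonferroni = min(1, m * p)`` with m the number
    of classes tested.
    """
    if not group:
        raise ValueError("empty protein group")
    background = {e.accession: e.arcog_class for e in db.counted}
    classes = sorted({c for c in background.values() if c})
    n_bg = len(background)
    n_group = len(group & set(background))
    rows = []
    for cls in classes:
        bg_in = sum(1 for c in background.values() if c == cls)
        grp_in = sum(1 for a in group if background.get(a) == cls)
        table = [
            [grp_in, n_group - grp_in],
            [bg_in, n_bg - bg_in],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "arcog_class": cls,
                "group_in": grp_in,
                "group_out": n_group - grp_in,
                "background_in": bg_in,
                "background_out": n_bg - bg_in,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p_value"] * len(classes))
    return out


@dataclass
class IslandReport:
    replicon_id: str
    window_size: int
    counts: np.ndarray  # per-gene identified count within the window
    rates_pct: list[float]
    low_threshold: int
    islands: list[tuple[int, int]] = field(default_factory=list)  # inclusive gene-index runs

    @property
    def low_mask(self) -> np.ndarray:
        return self.counts <= self.low_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_index": np.arange(len(self.counts)),
                "window_count": self.counts,
                "rate_pct": self.rates_pct,
                "low": self.low_mask,
            }
        )

    def islands_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.counts)
        for start, end in self.islands:
            span = [(start + k) % n for k in range(((end - start) % n) + 1)]
            rows.append(
                {
                    "replicon_id": self.replicon_id,
                    "start_gene": start,
                    "end_gene": end,
                    "n_genes": len(span),
                    "min_count": int(self.counts[span].min()),
                    "min_rate_pct": min(self.rates_pct[i] for i in span),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["replicon_id", "start_gene", "end_gene", "n_genes", "min_count", "min_rate_pct"],
        )


def scan_low_identification_islands(
    identified: np.ndarray,
    *,
    replicon_id: str = "rep0",
    circular: bool = True,
    half_window: int = 25,
    low_threshold: int = 20,
) -> IslandReport:
    """Sliding-window identification rates and low-identification islands.

    ``identified`` is the per-gene boolean identification flag in gene order
    (genes ordered by coding-region start).  Each gene's window covers
    itself plus ``half_window`` genes on each side, wrapping around on
    circular replicons.  Genes whose window contains at most
    ``low_threshold`` identified proteins are low; maximal consecutive runs
    of low genes are reported as islands (runs may wrap the origin).
    """
    flags = np.asarray(identified, dtype=bool)
    n = len(flags)
    window = 2 * half_window + 1
    if n < window:
        if not circular:
            raise ValueError(
                f"replicon of {n} genes is shorter than the {window}-gene window"
            )
        # on a short circular replicon every window sees the whole replicon
    if circular:
        idx = np.arange(n)
        counts = np.empty(n, dtype=int)
        offsets = np.arange(-half_window, half_window + 1)
        # each window position wraps modulo n; duplicate coverage of a gene
        # on very short replicons counts once per window slot
        for i in range(n):
            counts[i] = int(flags[(i + offsets) % n].sum())
    else:
        counts = np.empty(n, dtype=int)
        for i in range(n):
            lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
            counts[i] = int(flags[lo:hi].sum())
    rates = [percent(int(c), window) for c in counts]
    low = counts <= low_threshold

    islands: list[tuple[int, int]] = []
    if low.any():
        if low.all():
            islands.append((0, n - 1))
        else:
            runs = []
            start = None
            for i in range(n):
                if low[i] and start is None:
                    start = i
                elif not low[i] and start is not None:
                    runs.append((start, i - 1))
                    start = None
            if start is not None:
                runs.append((start, n - 1))
            if circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == n - 1:
                first = runs.pop(0)
                runs[-1] = (runs[-1][0], first[1])  # wrap-around merge
            islands = runs
    return IslandReport(
        replicon_id=replicon_id,
        window_size=window,
        counts=counts,
        rates_pct=rates,
        low_threshold=low_threshold,
        islands=islands,
    )


def scan_db_islands(
    db: ProteinDB,
    identified_accessions: set[str],
    *,
    half_window: int = 25,
    low_threshold: int = 20,
) -> dict[str, IslandReport]:
    """Run the island scan per replicon of a protein database."""
    reports = {}
    for replicon_id in db.replicons:
        order = db.replicon_order(replicon_id)
        flags = np.array([acc in identified_accessions for acc in order])
        reports[replicon_id] = scan_low_identification_islands(
            flags,
            replicon_id=replicon_id,
            circular=db.circular.get(replicon_id, True),
            half_window=half_window,
            low_threshold=low_threshold,
        )
    return reports
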