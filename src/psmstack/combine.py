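"""Multi-engine PSM combination, spectrum sanitization, parameter selection.

``combine_pep`` rescores PSMs according to their overlap between search
engines: PSMs matched by the same set of engines form a group; within each
group PSMs are ranked by their joint score (sum of -log10 engine PEPs) and a
combined posterior error probability is estimated from the local decoy
density in a centered sliding window (decoy count doubled, as decoys
estimate only the incorrect-target half of the mixture).  Sharing a match
between engines therefore raises confidence exactly when the multi-engine
groups are decoy-poor.

The estimator is windowed decoy-density within engine-set groups: windows
are truncated at group edges, groups smaller than the window fall back to
the whole-group ratio, estimates are clipped to ``[PEP_FLOOR, 1]`` and
monotonized along each group's ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import COMBINED_PSM_COLUMNS, PEP_FLOOR

PSM_KEY = ["dataset_id", "spectrum_id", "peptide", "modifications"]


def combine_pep(
    psms: pd.DataFrame,
    window_size: int = 249,
    epsilon: float = PEP_FLOOR,
) -> pd.DataFrame:
    """Combine long-format (one row per engine) PSMs into combined PEPs.

    Returns one row per matched PSM with ``engines`` (sorted, ``;``-joined),
    ``joint_score`` and ``combined_pep`` columns.  Output is invariant to
    input row order.
    """
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be an odd integer >= 3")
    if len(psms) == 0:
        return pd.DataFrame(columns=COMBINED_PSM_COLUMNS)

    df = psms.copy()
    df["neglog_pep"] = -np.log10(np.clip(df["pep"].to_numpy(float), epsilon, 1.0))
    carried = [c for c in df.columns if c not in PSM_KEY + ["engine", "pep", "neglog_pep"]]
    kwargs = {c: (c, "first") for c in carried}
    kwargs["engines"] = ("engine", lambda e: ";".join(sorted(e)))
    kwargs["joint_score"] = ("neglog_pep", "sum")
    grouped = (
        df.sort_values(PSM_KEY + ["engine"], kind="mergesort")
        .groupby(PSM_KEY, as_index=False, sort=True)
        .agg(**kwargs)
    )

    # canonical order inside each engine-set group: best first; on ties decoys
    # first (conservative), then lexicographic for determinism
    grouped = grouped.sort_values(
        ["engines", "joint_score", "is_decoy", "peptide", "spectrum_id"],
        ascending=[True, False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)

    combined = np.empty(len(grouped))
    half = window_size // 2
    for _, idx in grouped.groupby("engines", sort=False).groups.items():
        pos = np.asarray(idx)
        is_decoy = grouped.loc[pos, "is_decoy"].to_numpy(bool)
        n = len(pos)
        if n < window_size:
            pep = np.full(n, 2.0 * is_decoy.sum() / n)
        else:
            cs = np.concatenate([[0], np.cumsum(is_decoy)])
            i = np.arange(n)
            lo = np.maximum(0, i - half)
            hi = np.minimum(n, i + half + 1)
            pep = 2.0 * (cs[hi] - cs[lo]) / (hi - lo)
        pep = np.clip(pep, epsilon, 1.0)
        combined[pos] = np.maximum.accumulate(pep)  # monotone along ranking
    grouped["combined_pep"] = combined
    return grouped[COMBINED_PSM_COLUMNS].reset_index(drop=True)


def sanitize_psms(psms: pd.DataFrame, ratio: float = 0.1) -> pd.DataFrame:
    """Resolve conflicting identifications of the same spectrum.

    Per spectrum: if all PSMs agree on peptide + modifications, the
    best-scoring record is kept; otherwise the best PSM is kept only when its
    combined PEP is at least an order of magnitude (``ratio``) better than
    the runner-up identification, else every PSM of the spectrum is dropped.
    """
    if len(psms) == 0:
        return psms.copy()
    df = psms.sort_values(
        ["dataset_id", "spectrum_id", "combined_pep", "peptide", "modifications"],
        kind="mergesort",
    )
    keep_rows = []
    for _, block in df.groupby(["dataset_id", "spectrum_id"], sort=False):
        idents = block.drop_duplicates(["peptide", "modifications"])
        if len(idents) == 1:
            keep_rows.append(block.index[0])
            continue
        best, runner = idents["combined_pep"].iloc[0], idents["combined_pep"].iloc[1]
        if best <= ratio * runner:
            keep_rows.append(block.index[0])
    return psms.loc[keep_rows].reset_index(drop=True)


def select_optimal_parameters(
    grid: pd.DataFrame,
) -> tuple[tuple[float, float], dict[str, float]]:
    """Select global mass tolerances and per-file instrument offsets.

    ``grid`` must be a full cross of ``precursor_tol`` x ``fragment_tol`` x
    ``offset`` x ``raw_file`` with an ``n_peptides`` count per cell.  The
    tolerance pair maximizing the total peptide yield (summing each file's
    best offset) wins; ties go to the smaller precursor then fragment
    tolerance.  With the pair fixed, each file gets its argmax offset (ties:
    offset closest to zero, then the smaller).
    """
    required = {"precursor_tol", "fragment_tol", "offset", "raw_file", "n_peptides"}
    missing_cols = required - set(grid.columns)
    if missing_cols:
        raise ValueError(f"grid is missing columns {sorted(missing_cols)}")
    precs = sorted(grid["precursor_tol"].unique())
    frags = sorted(grid["fragment_tol"].unique())
    offsets = sorted(grid["offset"].unique())
    files = sorted(grid["raw_file"].unique())
    have = set(zip(grid["precursor_tol"], grid["fragment_tol"], grid["offset"], grid["raw_file"]))
    missing = [
        (p, f, o, r)
        for p in precs
        for f in frags
        for o in offsets
        for r in files
        if (p, f, o, r) not in have
    ]
    if missing:
        raise ValueError(f"ragged parameter grid; missing cells: {missing}")

    per_file_best = (
        grid.groupby(["precursor_tol", "fragment_tol", "raw_file"])["n_peptides"]
        .max()
        .groupby(["precursor_tol", "fragment_tol"])
        .sum()
    )
    best_total = per_file_best.max()
    candidates = sorted(per_file_best[per_file_best == best_total].index)
    pair = candidates[0]  # smaller precursor, then smaller fragment

    sub = grid[(grid["precursor_tol"] == pair[0]) & (grid["fragment_tol"] == pair[1])]
    offset_map: dict[str, float] = {}
    for raw_file, block in sub.groupby("raw_file"):
        best_n = block["n_peptides"].max()
        tied = sorted(block.loc[block["n_peptides"] == best_n, "offset"], key=lambda o: (abs(o), o))
        offset_map[raw_file] = tied[0]
    return (pair[0], pair[1]), offset_map
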