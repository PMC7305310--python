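"""Peptide collapse, target-decoy q-values, protein inference, picked FDR.

q-values follow the classical two-traversal scheme: identifications are
ranked best-first, the cumulative decoy count is divided by the cumulative
target count (the raw empirical q), and a second bottom-up traversal
replaces each raw value with the minimum seen so far, enforcing monotone
non-decreasing q along the ranking.  Peptide q-values are computed within
groups of equal peptide length (sparse lengths merged), which removes the
length bias of the decoy model for very short and very long peptides.

Protein-level control uses the picked strategy: every target competes only
against its own paired decoy (same sequence, peptide-shuffled); the loser of
each pair is discarded before ranking, giving sharper target/decoy
separation than classical joint ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .model import DECOY_PREFIX, PEP_FLOOR, PEPTIDE_COLUMNS, ProteinDB


def collapse_to_peptides(psms: pd.DataFrame) -> pd.DataFrame:
    """Collapse sanitized PSMs to one row per peptide sequence.

    Modifications are ignored at this level (the peptide sequence is the
    statistical unit); ``best_pep`` is the minimum combined PEP over the
    peptide's PSMs.  A sequence occurring in both the target and the decoy
    database is labeled target and its decoy occurrences are discarded.
    """
    if len(psms) == 0:
        return pd.DataFrame(columns=PEPTIDE_COLUMNS)
    df = psms.copy()
    both = df.groupby("peptide")["is_decoy"].agg(["min", "max"])
    collided = set(both.index[(~both["min"].astype(bool)) & both["max"].astype(bool)])
    if collided:
        df = df[~(df["peptide"].isin(collided) & df["is_decoy"])]

    def union_join(values) -> str:
        items: set[str] = set()
        for v in values:
            if v:
                items.update(str(v).split(";"))
        return ";".join(sorted(items))

    out = (
        df.groupby("peptide", as_index=False, sort=True)
        .agg(
            is_decoy=("is_decoy", "first"),
            best_pep=("combined_pep", "min"),
            psm_count=("combined_pep", "size"),
            dataset_ids=("dataset_id", union_join),
            accessions=("accessions", union_join),
        )
        .assign(length=lambda d: d["peptide"].str.len(), q_value=np.nan)
    )
    return out[PEPTIDE_COLUMNS]


def apply_length_bounds(
    peptides: pd.DataFrame, bounds: tuple[int, int] = (6, 50)
) -> pd.DataFrame:
    """Drop peptides outside the inclusive length bounds (default 6-50)."""
    keep = (peptides["length"] >= bounds[0]) & (peptides["length"] <= bounds[1])
    return peptides[keep].reset_index(drop=True)


def two_traversal_qvalues(is_decoy: np.ndarray) -> np.ndarray:
    """Raw cumulative decoy/target ratio plus bottom-up min-monotonization.

    ``is_decoy`` must already be in ranked order (best identification
    first).  Positions ranked before any target get ``inf`` raw values that
    the second traversal resolves; an all-decoy input stays ``inf``.
    """
    is_decoy = np.asarray(is_decoy, dtype=bool)
    cum_d = np.cumsum(is_decoy)
    cum_t = np.cumsum(~is_decoy)
    raw = np.divide(
        cum_d.astype(float),
        cum_t,
        out=np.full(len(is_decoy), np.inf),
        where=cum_t > 0,
    )
    return np.minimum.accumulate(raw[::-1])[::-1]


def _merge_length_bins(counts: pd.Series, min_group_size: int) -> dict[int, int]:
    """Map each peptide length to a bin label, merging bins below size.

    Bins smaller than ``min_group_size`` are iteratively merged with the
    nearest neighboring length bin (ties: the smaller neighbor count, then
    the lower lengths), so every group is large enough for a stable decoy
    estimate.
    """
    bins: list[list[int]] = [[int(length)] for length in sorted(counts.index)]
    sizes = [int(counts[b[0]]) for b in bins]
    while len(bins) > 1 and min(sizes) < min_group_size:
        i = int(np.argmin(sizes))
        neighbors = [j for j in (i - 1, i + 1) if 0 <= j < len(bins)]
        j = min(neighbors, key=lambda j: (sizes[j], bins[j][0]))
        lo, hi = sorted((i, j))
        bins[lo] = bins[lo] + bins[hi]
        sizes[lo] = sizes[lo] + sizes[hi]
        del bins[hi], sizes[hi]
    return {length: b[0] for b in bins for length in b}


def compute_peptide_qvalues(
    peptides: pd.DataFrame,
    group_by_length: bool = True,
    min_group_size: int = 100,
) -> pd.DataFrame:
    """Assign q-values per length group (or globally).

    Within a group, peptides are ranked by ascending ``best_pep`` with
    decoys preceding targets on ties (conservative).  Groups with zero
    targets get ``NaN`` q-values and ``q_undefined=True``.
    """
    df = peptides.copy().reset_index(drop=True)
    if len(df) == 0:
        df["q_value"] = pd.Series(dtype=float)
        df["q_undefined"] = pd.Series(dtype=bool)
        return df
    if group_by_length:
        bin_of = _merge_length_bins(df["length"].value_counts(), min_group_size)
        df["_bin"] = df["length"].map(bin_of)
    else:
        df["_bin"] = 0
    df["q_value"] = np.nan
    df["q_undefined"] = False
    for _, idx in df.groupby("_bin").groups.items():
        block = df.loc[idx]
        order = np.lexsort(
            (block["peptide"].to_numpy(), ~block["is_decoy"].to_numpy(bool), block["best_pep"].to_numpy(float))
        )
        ranked = block.index.to_numpy()[order]
        q = two_traversal_qvalues(df.loc[ranked, "is_decoy"].to_numpy(bool))
        if np.isinf(q).all():
            df.loc[ranked, "q_undefined"] = True
        else:
            df.loc[ranked, "q_value"] = q
    return df.drop(columns="_bin")


@dataclass
class InferenceResult:
    groups: pd.DataFrame
    peptide_assignment: dict[str, tuple[str, ...]] = field(default_factory=dict)


def infer_proteins(
    peptides: pd.DataFrame, db: ProteinDB, scope: str | None = None
) -> pd.DataFrame:
    """Assign peptides to proteins with the simple shared-peptide rule.

    Proteotypic peptides evidence their protein directly.  A shared peptide
    is assigned to the single otherwise-evidenced protein among its carriers
    if exactly one exists; with several otherwise-evidenced carriers the
    identification is discarded as ambiguous; with none, the carriers form
    one group counted as a single protein.

    ``scope`` names the sample the evidence comes from (a dataset id, or
    ``None`` for the combined analysis); it is recorded on the output.
    """
    if len(peptides) == 0:
        return pd.DataFrame(
            columns=["representative", "members", "status", "peptides", "n_peptides", "psm_count", "scope"]
        )
    pep_accs: dict[str, tuple[str, ...]] = {}
    for pep, accs in zip(peptides["peptide"], peptides["accessions"]):
        named = [a for a in str(accs).split(";") if a]
        if not named:
            raise ValueError(f"peptide {pep!r} maps to no database entry")
        carriers = set()
        for a in named:
            resolved = db.resolve(a)
            if resolved is None:
                raise ValueError(f"peptide {pep!r} names unknown accession {a!r}")
            carriers.add(resolved)
        pep_accs[pep] = tuple(sorted(carriers))

    evidenced = {accs[0] for accs in pep_accs.values() if len(accs) == 1}
    assignment: dict[tuple[str, ...], dict] = {}

    def add(key: tuple[str, ...], status: str, pep: str, psms: int) -> None:
        rec = assignment.setdefault(
            key, {"members": key, "status": status, "peptides": [], "psm_count": 0}
        )
        rec["peptides"].append(pep)
        rec["psm_count"] += psms

    psm_counts = dict(zip(peptides["peptide"], peptides["psm_count"]))
    for pep, accs in pep_accs.items():
        n_psms = int(psm_counts.get(pep, 1))
        if len(accs) == 1:
            add(accs, "single", pep, n_psms)
            continue
        hits = [a for a in accs if a in evidenced]
        if len(hits) == 1:
            add((hits[0],), "single", pep, n_psms)
        elif len(hits) >= 2:
            add(accs, "discarded_ambiguous", pep, n_psms)
        else:
            add(accs, "group", pep, n_psms)
    rows = []
    for key, rec in sorted(assignment.items()):
        rows.append(
            {
                "representative": key[0],
                "members": ";".join(key),
                "status": rec["status"],
                "peptides": sorted(rec["peptides"]),
                "n_peptides": len(rec["peptides"]),
                "psm_count": rec["psm_count"],
                "scope": scope if scope is not None else "combined",
            }
        )
    return pd.DataFrame(rows)


def score_proteins(
    groups: pd.DataFrame,
    peptides: pd.DataFrame,
    peptide_q_threshold: float = 0.01,
    epsilon: float = PEP_FLOOR,
) -> pd.DataFrame:
    """Score protein groups as the sum of -log10 best peptide PEPs.

    Only peptides at or below the peptide q-value threshold contribute;
    groups left without any qualifying peptide are dropped.
    """
    qualifying = peptides[
        peptides["q_value"].notna() & (peptides["q_value"] <= peptide_q_threshold)
    ]
    pep_score = {
        p: -np.log10(max(bp, epsilon))
        for p, bp in zip(qualifying["peptide"], qualifying["best_pep"])
    }
    pep_psms = dict(zip(qualifying["peptide"], qualifying["psm_count"]))
    out = groups.copy()
    scores, n_quals, psms = [], [], []
    for peps in out["peptides"]:
        used = [p for p in peps if p in pep_score]
        scores.append(sum(pep_score[p] for p in used))
        n_quals.append(len(used))
        psms.append(int(sum(pep_psms[p] for p in used)))
    out["score"] = scores
    out["n_peptides"] = n_quals
    out["psm_count"] = psms
    return out[out["n_peptides"] > 0].reset_index(drop=True)


def _ranked_qvalues(groups: pd.DataFrame) -> pd.DataFrame:
    out = groups.copy().reset_index(drop=True)
    order = np.lexsort(
        (
            out["representative"].to_numpy(),
            ~out["is_decoy"].to_numpy(bool),  # decoys first on score ties
            -out["score"].to_numpy(float),
        )
    )
    ranked = out.index.to_numpy()[order]
    out.loc[ranked, "q_value"] = two_traversal_qvalues(
        out.loc[ranked, "is_decoy"].to_numpy(bool)
    )
    return out


def compute_picked_protein_qvalues(
    target_groups: pd.DataFrame,
    decoy_groups: pd.DataFrame,
    decoy_prefix: str = DECOY_PREFIX,
) -> pd.DataFrame:
    """Picked protein FDR: pairwise target/decoy competition, then q-values.

    Each decoy group is paired with its target via the accession prefix; the
    higher-scoring member of each pair enters the ranking (ties keep the
    target).  Survivors are ranked by descending score and q-values follow
    the same two-traversal scheme as peptides.
    """
    t = target_groups.copy()
    t["is_decoy"] = False
    d = decoy_groups.copy()
    d["is_decoy"] = True
    for rep in d["representative"]:
        if not str(rep).startswith(decoy_prefix):
            raise ValueError(f"decoy group {rep!r} lacks the {decoy_prefix!r} prefix")
    d["partner"] = d["representative"].str[len(decoy_prefix) :]

    t_scores = dict(zip(t["representative"], t["score"]))
    d_scores = dict(zip(d["partner"], d["score"]))
    keep_t = t[t["score"] >= t["representative"].map(lambda a: d_scores.get(a, -np.inf))]
    keep_d = d[d["score"] > d["partner"].map(lambda a: t_scores.get(a, -np.inf))]
    survivors = pd.concat(
        [keep_t, keep_d.drop(columns="partner")], ignore_index=True, sort=False
    )
    return _ranked_qvalues(survivors)


def compute_classical_protein_qvalues(
    target_groups: pd.DataFrame, decoy_groups: pd.DataFrame
) -> pd.DataFrame:
    """Joint target+decoy ranking without pairwise competition (reference)."""
    t = target_groups.copy()
    t["is_decoy"] = False
    d = decoy_groups.copy()
    d["is_decoy"] = True
    return _ranked_qvalues(pd.concat([t, d], ignore_index=True, sort=False))


def _round_half_up(x: float, digits: int = 0) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def identification_summary(n_peptides: int, n_proteins: int, counted_size: int) -> dict:
    frac = n_proteins / counted_size if counted_size else float("nan")
    return {
        "n_peptides": int(n_peptides),
        "n_proteins": int(n_proteins),
        "counted_size": int(counted_size),
        "identified_fraction": frac,
        "identified_fraction_pct": _round_half_up(100.0 * frac, 0),
    }


def apply_confidence_filters(
    peptides: pd.DataFrame,
    groups: pd.DataFrame,
    counted_size: int,
    peptide_q: float = 0.01,
    protein_q: float = 0.005,
    min_psms: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply the headline confidence filters and summarize.

    Peptides: target, q <= 1 %, >= 2 PSMs.  Proteins: target, not discarded
    as ambiguous, q <= 0.5 %, >= 2 PSMs.  The summary reports counts and the
    identified fraction of the counted proteome size.
    """
    pep_ok = peptides[
        (~peptides["is_decoy"].astype(bool))
        & peptides["q_value"].notna()
        & (peptides["q_value"] <= peptide_q)
        & (peptides["psm_count"] >= min_psms)
    ].reset_index(drop=True)
    prot = groups[~groups["is_decoy"].astype(bool)] if "is_decoy" in groups else groups
    prot_ok = prot[
        (prot["status"] != "discarded_ambiguous")
        & prot["q_value"].notna()
        & (prot["q_value"] <= protein_q)
        & (prot["psm_count"] >= min_psms)
    ].reset_index(drop=True)
    summary = identification_summary(len(pep_ok), len(prot_ok), counted_size)
    return pep_ok, prot_ok, summary
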