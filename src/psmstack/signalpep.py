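"""Grouped validation of semi-enzymatic searches and cleavage-site calls.

Semi-enzymatic searches inflate the search space, so their PSMs are
validated separately from fully enzymatic ones: the engine-combination and
FDR machinery runs independently on each specificity group and the results
are merged with group provenance retained.  Semi-enzymatic identifications
never contribute to headline identification counts; they serve only to test
predicted signal-peptide cleavage sites (CS) against observed peptides.

A prediction is *correct* when a qualifying semi-tryptic peptide starts
exactly at the predicted first mature residue; *refined* when one starts
within +/-3 residues; *incorrect* when a fully tryptic peptide starts at
least three residues N-terminal of the site; *unclassifiable* when no
theoretical 5-50 aa tryptic peptide could start at the site or an
N-terminal lipid modification is predicted (lipobox pathways).  Semi
evidence qualifies only with at least five supporting PSMs.
"""

from __future__ import annotations

import pandas as pd

from .combine import combine_pep, sanitize_psms
from .digestion import cleavage_sites
from .fdr import collapse_to_peptides, compute_peptide_qvalues
from .model import CleavageSiteCall, ProteinEntry

LIPOBOX_PATHWAYS = {"Tat(lipobox)", "Sec(lipobox)"}


def validate_semi_enzymatic(
    psms: pd.DataFrame,
    window_size: int = 249,
    peptide_q_threshold: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run combination, sanitization and peptide q-values per enzyme group.

    Returns ``(kept_psms, peptides)``; both carry an ``enzyme_group`` column
    with values ``full`` / ``semi``.
    """
    df = psms.copy()
    df["enzyme_group"] = df["specificity"].map(
        lambda s: "full" if s == "full" else "semi"
    )
    kept_parts, peptide_parts = [], []
    for group in ("full", "semi"):
        part = df[df["enzyme_group"] == group].drop(columns="enzyme_group")
        if len(part) == 0:
            continue
        combined = combine_pep(part, window_size=window_size)
        kept = sanitize_psms(combined)
        peptides = compute_peptide_qvalues(collapse_to_peptides(kept))
        kept["enzyme_group"] = group
        peptides["enzyme_group"] = group
        kept_parts.append(kept)
        peptide_parts.append(peptides)
    empty = pd.DataFrame()
    kept_all = pd.concat(kept_parts, ignore_index=True) if kept_parts else empty
    peps_all = pd.concat(peptide_parts, ignore_index=True) if peptide_parts else empty
    return kept_all, peps_all


def theoretical_cs_peptide_possible(
    sequence: str,
    cs: int,
    enzyme: str = "trypsin",
    max_missed: int = 2,
    length_bounds: tuple[int, int] = (5, 50),
) -> bool:
    """Can a semi-enzymatic peptide of allowed length start at the site?

    The peptide's C terminus must be an enzymatic cleavage site (or the
    protein end) reachable with at most ``max_missed`` internal sites.
    """
    cuts = cleavage_sites(sequence, enzyme)
    ends = sorted(c + 1 for c in cuts if c + 1 >= cs) + (
        [len(sequence)] if not cuts or cuts[-1] + 1 < len(sequence) else []
    )
    for missed, end in enumerate(ends):
        if missed > max_missed:
            break
        if length_bounds[0] <= end - cs + 1 <= length_bounds[1]:
            return True
    return False


def classify_cleavage_sites(
    protein: ProteinEntry,
    predicted_cs: int,
    pathway: str,
    semi_evidence: list[tuple[str, int, int]],
    full_evidence: list[tuple[str, int, int]],
    *,
    enzyme: str = "trypsin",
    min_semi_psms: int = 5,
    max_missed: int = 2,
    length_bounds: tuple[int, int] = (5, 50),
) -> CleavageSiteCall:
    """Classify one predicted cleavage site against peptide evidence.

    ``semi_evidence`` and ``full_evidence`` are lists of
    ``(peptide, 1-based start, psm_count)`` restricted to this protein.
    Verdict precedence: correct > refined > incorrect > unclassifiable; a
    refined site takes the smallest absolute offset (upstream on ties).
    """
    if not 1 <= predicted_cs <= protein.length:
        raise ValueError(
            f"predicted site {predicted_cs} outside protein of length {protein.length}"
        )
    semi_ok = [(p, s, n) for p, s, n in semi_evidence if n >= min_semi_psms]
    exact = [(p, s, n) for p, s, n in semi_ok if s == predicted_cs]
    if exact:
        return CleavageSiteCall(
            accession=protein.accession,
            pathway=pathway,
            predicted_cs=predicted_cs,
            verdict="correct",
            evidence_peptides=[p for p, _, _ in exact],
            n_psms=sum(n for _, _, n in exact),
        )
    near = [(p, s, n) for p, s, n in semi_ok if 1 <= abs(s - predicted_cs) <= 3]
    if near:
        near.sort(key=lambda t: (abs(t[1] - predicted_cs), t[1] - predicted_cs))
        refined_cs = near[0][1]
        chosen = [t for t in near if t[1] == refined_cs]
        return CleavageSiteCall(
            accession=protein.accession,
            pathway=pathway,
            predicted_cs=predicted_cs,
            verdict="refined",
            refined_cs=refined_cs,
            evidence_peptides=[p for p, _, _ in chosen],
            n_psms=sum(n for _, _, n in chosen),
        )
    upstream = [(p, s, n) for p, s, n in full_evidence if s <= predicted_cs - 3]
    if upstream:
        return CleavageSiteCall(
            accession=protein.accession,
            pathway=pathway,
            predicted_cs=predicted_cs,
            verdict="incorrect",
            evidence_peptides=[p for p, _, _ in upstream],
            n_psms=sum(n for _, _, n in upstream),
        )
    if pathway in LIPOBOX_PATHWAYS or not theoretical_cs_peptide_possible(
        protein.sequence, predicted_cs, enzyme, max_missed, length_bounds
    ):
        return CleavageSiteCall(
            accession=protein.accession,
            pathway=pathway,
            predicted_cs=predicted_cs,
            verdict="unclassifiable",
        )
    return CleavageSiteCall(
        accession=protein.accession,
        pathway=pathway,
        predicted_cs=predicted_cs,
        verdict="no_call",
    )


def classify_all_cleavage_sites(
    db,
    predictions: dict[str, tuple[str, int]],
    peptides: pd.DataFrame,
    *,
    enzyme: str = "trypsin",
    peptide_q_threshold: float = 0.01,
    min_semi_psms: int = 5,
    excluded_accessions: set[str] | None = None,
) -> pd.DataFrame:
    """Classify every predicted site from merged grouped-validation output.

    ``predictions`` maps accession -> (pathway, predicted CS); entries whose
    pathway is Tat(SPI) are assumed to already carry any TatLipo override.
    ``peptides`` is the merged output of :func:`validate_semi_enzymatic`
    (with ``enzyme_group`` column).  Proteins with more semi- than
    fully-tryptic peptides are excluded (diffuse proteolysis rather than a
    defined processing site), as are explicitly excluded accessions
    (e.g. enrichment-based datasets).
    """
    excluded = excluded_accessions or set()
    confident = peptides[
        (~peptides["is_decoy"].astype(bool))
        & peptides["q_value"].notna()
        & (peptides["q_value"] <= peptide_q_threshold)
    ]

    def evidence_for(acc: str, group: str) -> list[tuple[str, int, int]]:
        seq = db[acc].sequence
        rows = confident[
            (confident["enzyme_group"] == group)
            & confident["accessions"].str.split(";").map(lambda a: acc in a)
        ]
        out = []
        for pep, n in zip(rows["peptide"], rows["psm_count"]):
            start = seq.find(pep)
            if start >= 0:
                out.append((pep, start + 1, int(n)))
        return out

    calls = []
    for acc in sorted(predictions):
        pathway, cs = predictions[acc]
        if acc in excluded:
            continue
        semi_ev = evidence_for(acc, "semi")
        full_ev = evidence_for(acc, "full")
        if len(semi_ev) > len(full_ev):
            continue  # more semi than fully tryptic peptides: not assessed
        call = classify_cleavage_sites(
            db[acc], cs, pathway, semi_ev, full_ev,
            enzyme=enzyme, min_semi_psms=min_semi_psms,
        )
        calls.append(
            {
                "accession": call.accession,
                "pathway": call.pathway,
                "predicted_cs": call.predicted_cs,
                "verdict": call.verdict,
                "refined_cs": call.refined_cs,
                "n_psms": call.n_psms,
            }
        )
    return pd.DataFrame(
        calls,
        columns=["accession", "pathway", "predicted_cs", "verdict", "refined_cs", "n_psms"],
    )
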