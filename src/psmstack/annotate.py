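"""Per-protein annotation: physicochemistry, coverage, localization, termini.

Molecular weight is monoisotopic (residue masses summed plus one water).
The isoelectric point is the pH at which the net charge of the Henderson-
Hasselbalch model crosses zero, found by bisection; the default pK set is
the EMBOSS table, which distinguishes N-terminal, C-terminal and side-chain
groups and can be swapped for any other table.  Hydrophobicity is the GRAVY
index, the mean Kyte-Doolittle hydropathy per residue.

Localization is decided from the supplied outputs of six prediction engines
by a fixed sequential decision tree: the first positive predictor in the
order TatLipo > LipoP > TatFind > FlaFind > SignalP decides the secretion
category; otherwise transmembrane-segment counts split membrane proteins
from cytosolic ones.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from pyteomics import mass as _pt_mass

from .model import LocalizationPrediction, ProteinEntry, TerminusCall, validate_sequence

logger = logging.getLogger(__name__)

#: Kyte-Doolittle hydropathy index
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: EMBOSS pK set; "nterm"/"cterm" are the terminal amine/carboxyl groups
PK_EMBOSS = {
    "nterm": 8.6, "cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}
_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")

LOCALIZATION_CATEGORIES = [
    "Tat(lipobox)",
    "Sec(lipobox)",
    "Tat(SPI)",
    "Pil(SPIII)",
    "Sec(SPI)",
    "integral_membrane",
    "TM_N_term",
    "TM_C_term",
    "Cyt",
]

SECRETED_CATEGORIES = LOCALIZATION_CATEGORIES[:5]


def monoisotopic_mw(sequence: str) -> float:
    """Monoisotopic molecular weight in Da (residues + water)."""
    validate_sequence(sequence)
    return float(_pt_mass.calculate_mass(sequence=sequence, monoisotopic=True))


def net_charge(sequence: str, ph: float, pk: dict | None = None) -> float:
    """Net charge of the peptide at the given pH (Henderson-Hasselbalch)."""
    pk = pk or PK_EMBOSS
    counts = {aa: sequence.count(aa) for aa in set(sequence)}
    charge = 1.0 / (1.0 + 10 ** (ph - pk["nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pk["cterm"] - ph))
    for aa in _POSITIVE:
        if aa in pk and counts.get(aa):
            charge += counts[aa] / (1.0 + 10 ** (ph - pk[aa]))
    for aa in _NEGATIVE:
        if aa in pk and counts.get(aa):
            charge -= counts[aa] / (1.0 + 10 ** (pk[aa] - ph))
    return charge


def isoelectric_point(
    sequence: str, pk: dict | None = None, tol: float = 1e-4
) -> float:
    """pH at which the net charge crosses zero, by bisection.

    The charge model is strictly decreasing in pH, so the root is unique.
    """
    validate_sequence(sequence)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(sequence, mid, pk)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(sequence: str, table: dict | None = None) -> float:
    """Grand average of hydropathy; positive values indicate hydrophobic."""
    validate_sequence(sequence)
    table = table or HYDROPATHY
    return float(np.mean([table[aa] for aa in sequence]))


def compute_physicochemical(sequence: str) -> tuple[float, float, float]:
    """Return (monoisotopic MW in Da, pI, GRAVY)."""
    return monoisotopic_mw(sequence), isoelectric_point(sequence), gravy(sequence)


def compute_sequence_coverage(
    protein_length: int, peptides: list[tuple[str, int]]
) -> float:
    """Fraction of residues covered by the union of peptide intervals.

    ``peptides`` is a list of (sequence, 1-based start).
    """
    covered = np.zeros(protein_length, dtype=bool)
    for seq, start in peptides:
        end = start + len(seq) - 1
        if start < 1 or end > protein_length:
            raise ValueError(
                f"peptide {seq!r} at {start} out of bounds for length {protein_length}"
            )
        covered[start - 1 : end] = True
    return float(covered.mean()) if protein_length else 0.0


def classify_localization(
    pred: LocalizationPrediction | None,
    protein_length: int,
    terminal_span: int = 50,
    single_tm_internal: str = "integral_membrane",
) -> str:
    """Assign one localization category from the prediction row.

    Secretion predictors take precedence in a fixed order; otherwise >= 2 TM
    segments mean an integral membrane protein, a single TM segment within
    the first or last ``terminal_span`` residues gives ``TM_N_term`` /
    ``TM_C_term`` (a single internal TM falls into ``single_tm_internal``),
    and everything else is cytosolic.
    """
    if pred is None:
        warnings.warn("no localization prediction row; defaulting to Cyt", stacklevel=2)
        return "Cyt"
    for cs, category in (
        (pred.tatlipo_cs, "Tat(lipobox)"),
        (pred.lipop_cs, "Sec(lipobox)"),
        (pred.tatfind_cs, "Tat(SPI)"),
        (pred.flafind_cs, "Pil(SPIII)"),
        (pred.signalp_cs, "Sec(SPI)"),
    ):
        if cs is not None:
            return category
    n_tm = len(pred.tm_segments)
    if n_tm >= 2:
        return "integral_membrane"
    if n_tm == 1:
        start, end = pred.tm_segments[0]
        if end <= terminal_span:
            return "TM_N_term"
        if start >= protein_length - terminal_span + 1:
            return "TM_C_term"
        return single_tm_internal
    return "Cyt"


def classify_terminus(
    protein: ProteinEntry,
    peptide: str,
    start: int,
    modifications: str = "",
    psm_count: int = 1,
) -> TerminusCall | None:
    """Classify an N-/C-terminal peptide into a maturation call.

    A peptide starting at position 1 on an initiator methionine reports a
    retained Met; a start at position 2 reports a cleaved N terminus (at
    most one residue removed).  An acetyl modification on the peptide
    N-terminus (position 0) or its first residue flags Nt-acetylation.  A
    peptide ending on the final residue marks an identified C terminus.
    Non-terminal peptides yield ``None``.
    """
    end = start + len(peptide) - 1
    n_class = None
    if start == 1 and protein.sequence[:1] == "M" and peptide[:1] == "M":
        n_class = "met_retained"
    elif start == 2:
        n_class = "cleaved"
    c_term = end == protein.length
    if n_class is None and not c_term:
        return None
    acetylated = False
    if n_class is not None and modifications:
        for item in str(modifications).split(";"):
            if not item:
                continue
            name, _, pos = item.partition(":")
            if "acetyl" in name.lower() and pos in ("0", "1"):
                acetylated = True
    return TerminusCall(
        accession=protein.accession,
        n_term_class=n_class,
        acetylated=acetylated,
        c_term_identified=c_term,
        peptide=peptide,
        psm_count=psm_count,
    )
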