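"""In-silico proteolytic digestion.

Trypsin cleaves C-terminal to K/R but not before proline; GluC cleaves after
E by default ("gluc"), or after E and D ("gluc_de").  Peptides are reported
with their 1-based start position.  ``mode="semi"`` additionally yields
peptides with exactly one non-enzymatic terminus (``semi_n``: the N terminus
is internal; ``semi_c``: the C terminus is internal), the signature of
proteolytic processing events such as signal-peptide removal.
"""

from __future__ import annotations

from dataclasses import dataclass

ENZYMES = {
    "trypsin": ("KR", "P"),
    "gluc": ("E", ""),
    "gluc_de": ("ED", ""),
}


@dataclass(frozen=True)
class Peptide:
    sequence: str
    start: int  # 1-based position of first residue in the protein
    specificity: str  # full | semi_n | semi_c
    missed: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1


def cleavage_sites(sequence: str, enzyme: str) -> list[int]:
    """0-based indices i such that the bond after residue i is cleaved."""
    try:
        residues, blocker = ENZYMES[enzyme]
    except KeyError:
        raise ValueError(f"unknown enzyme {enzyme!r}; choose from {sorted(ENZYMES)}")
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in residues and (not blocker or sequence[i + 1] not in blocker):
            sites.append(i)
    return sites


def digest(
    sequence: str,
    enzyme: str,
    max_missed: int = 0,
    mode: str = "full",
    length_bounds: tuple[int, int] | None = None,
) -> list[Peptide]:
    """Enumerate enzymatic (and optionally semi-enzymatic) peptides.

    Parameters
    ----------
    max_missed:
        Maximum number of uncleaved internal sites per peptide.
    mode:
        ``"full"`` for fully enzymatic peptides only, ``"semi"`` to add
        peptides with exactly one non-enzymatic terminus.
    length_bounds:
        Inclusive ``(min, max)`` peptide length filter; ``None`` keeps all.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if mode not in ("full", "semi"):
        raise ValueError(f"unknown digestion mode {mode!r}")
    if length_bounds is not None and length_bounds[0] > length_bounds[1]:
        raise ValueError(f"invalid length bounds {length_bounds}")

    sites = cleavage_sites(sequence, enzyme)
    n = len(sequence)
    # segment boundaries: starts of fully cleaved units (0-based)
    starts = [0] + [s + 1 for s in sites]
    ends = [s for s in sites] + [n - 1]  # inclusive 0-based segment ends

    def keep(length: int) -> bool:
        if length_bounds is None:
            return True
        return length_bounds[0] <= length <= length_bounds[1]

    peptides: list[Peptide] = []
    nseg = len(starts)
    for i in range(nseg):
        for j in range(i, min(i + max_missed + 1, nseg)):
            a, b = starts[i], ends[j]
            missed = j - i
            if keep(b - a + 1):
                peptides.append(Peptide(sequence[a : b + 1], a + 1, "full", missed))
            if mode == "semi":
                # one internal terminus inside the fully enzymatic span
                for a2 in range(a + 1, b + 1):  # internal N terminus
                    if a2 in starts:
                        continue
                    if keep(b - a2 + 1):
                        peptides.append(
                            Peptide(sequence[a2 : b + 1], a2 + 1, "semi_n", missed)
                        )
                for b2 in range(a, b):  # internal C terminus
                    if b2 in ends:
                        continue
                    if keep(b2 - a + 1):
                        peptides.append(
                            Peptide(sequence[a : b2 + 1], a + 1, "semi_c", missed)
                        )
    if mode == "semi":
        # a semi peptide reachable with fewer missed cleavages is the same
        # molecule; keep the lowest-missed instance of each (seq, start, spec)
        best: dict[tuple[str, int, str], Peptide] = {}
        for p in peptides:
            key = (p.sequence, p.start, p.specificity)
            if key not in best or p.missed < best[key].missed:
                best[key] = p
        peptides = sorted(
            best.values(), key=lambda p: (p.start, len(p.sequence), p.specificity)
        )
    return peptides
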