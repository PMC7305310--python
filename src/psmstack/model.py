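"""Domain types and table schemas.

Two in-memory representations coexist:

* small, structured objects (proteins, truth records, classification calls)
  are dataclasses;
* high-volume evidence (PSMs, peptides, protein groups) lives in pandas
  DataFrames with the fixed column sets declared here, which are also the
  columns of the tab-separated files the package reads and writes.

Conventions: protein coordinates are 1-based inclusive; a peptide's ``start``
is the position of its first residue in the protein.  Modification positions
are 1-based residue positions, position 0 meaning the peptide N-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: accession prefix that pairs a decoy protein with its target
DECOY_PREFIX = "decoy_"

#: floor applied to posterior error probabilities before -log10 transforms
PEP_FLOOR = 1e-6

# Long-format PSM table: one row per (engine, spectrum, peptide) match.
PSM_COLUMNS = [
    "spectrum_id",
    "dataset_id",
    "raw_file",
    "engine",
    "peptide",
    "modifications",
    "charge",
    "is_decoy",
    "accessions",
    "enzyme",
    "specificity",
    "pep",
]

# After engine combination: one row per matched PSM.
COMBINED_PSM_COLUMNS = [
    "spectrum_id",
    "dataset_id",
    "raw_file",
    "engines",
    "peptide",
    "modifications",
    "charge",
    "is_decoy",
    "accessions",
    "enzyme",
    "specificity",
    "joint_score",
    "combined_pep",
]

PEPTIDE_COLUMNS = [
    "peptide",
    "length",
    "is_decoy",
    "best_pep",
    "psm_count",
    "dataset_ids",
    "accessions",
    "q_value",
]

PROTEIN_GROUP_COLUMNS = [
    "representative",
    "members",
    "status",
    "n_peptides",
    "psm_count",
    "score",
    "q_value",
]


@dataclass
class ProteinEntry:
    """One entry of the (merged, decoy-augmented) protein database."""

    accession: str
    sequence: str
    is_spurious: bool = False
    duplicate_members: list[str] = field(default_factory=list)
    replicon_id: str = "chr"
    gene_index: int = -1
    strand: str = "+"
    arcog_class: str | None = None
    is_decoy: bool = False
    partner_accession: str | None = None

    def __post_init__(self) -> None:
        if not self.duplicate_members:
            self.duplicate_members = [self.accession]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinDB:
    """Merged, spurious-flagged protein database.

    ``counted_size`` is the number of non-spurious, duplicate-merged target
    entries: the denominator for every "identified fraction" in reports.
    """

    entries: dict[str, ProteinEntry] = field(default_factory=dict)
    circular: dict[str, bool] = field(default_factory=dict)

    def add(self, entry: ProteinEntry) -> None:
        if entry.accession in self.entries:
            raise ValueError(f"duplicate accession {entry.accession!r}")
        self.entries[entry.accession] = entry

    def __getitem__(self, accession: str) -> ProteinEntry:
        return self.entries[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def targets(self) -> list[ProteinEntry]:
        return [e for e in self.entries.values() if not e.is_decoy]

    @property
    def decoys(self) -> list[ProteinEntry]:
        return [e for e in self.entries.values() if e.is_decoy]

    @property
    def counted(self) -> list[ProteinEntry]:
        return [e for e in self.targets if not e.is_spurious]

    @property
    def counted_size(self) -> int:
        return len(self.counted)

    def resolve(self, accession: str) -> str | None:
        """Map any accession (including merged duplicate members) to its entry.

        Returns the representative accession, or ``None`` if unknown.
        """
        if accession in self.entries:
            return accession
        member_map = getattr(self, "_member_map", None)
        if member_map is None or getattr(self, "_member_map_size", -1) != len(self.entries):
            member_map = {}
            for e in self.entries.values():
                for m in e.duplicate_members:
                    member_map[m] = e.accession
            self._member_map = member_map
            self._member_map_size = len(self.entries)
        return member_map.get(accession)

    def replicon_order(self, replicon_id: str) -> list[str]:
        """Accessions of counted proteins on a replicon, in gene order."""
        on = [e for e in self.counted if e.replicon_id == replicon_id]
        on.sort(key=lambda e: e.gene_index)
        return [e.accession for e in on]

    @property
    def replicons(self) -> list[str]:
        return sorted({e.replicon_id for e in self.counted})


@dataclass
class LocalizationPrediction:
    """Summarized output of the six localization prediction engines.

    Each cleavage-site field is the 1-based position of the first mature
    residue; ``None`` means the predictor was negative for this protein.
    """

    accession: str
    tm_segments: list[tuple[int, int]] = field(default_factory=list)
    tatlipo_cs: int | None = None
    lipop_cs: int | None = None
    tatfind_cs: int | None = None
    flafind_cs: int | None = None
    signalp_cs: int | None = None


@dataclass
class TerminusCall:
    accession: str
    n_term_class: str | None = None  # "met_retained" | "cleaved"
    acetylated: bool = False
    c_term_identified: bool = False
    peptide: str = ""
    psm_count: int = 0


@dataclass
class CleavageSiteCall:
    accession: str
    pathway: str
    predicted_cs: int
    verdict: str  # correct | refined | incorrect | unclassifiable | no_call
    refined_cs: int | None = None
    evidence_peptides: list[str] = field(default_factory=list)
    n_psms: int = 0


def validate_sequence(sequence: str) -> None:
    """Raise ``ValueError`` listing positions of non-standard residues."""
    bad = [i + 1 for i, aa in enumerate(sequence) if aa not in AMINO_ACIDS]
    if bad:
        raise ValueError(
            f"non-standard residues at positions {bad} in sequence "
            f"of length {len(sequence)}"
        )
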