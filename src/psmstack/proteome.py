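"""Protein database construction: loading, duplicate merging, decoys.

The database is read from a FASTA file plus a tab-separated annotation table
keyed by accession (columns: ``accession``, ``is_spurious``, ``replicon_id``,
``gene_index``, ``strand``, ``arcog_class``).  Entries with identical
sequences are merged into one representative entry (chosen by a seeded RNG)
whose ``duplicate_members`` records all merged accessions.  Spurious entries
are kept but flagged and excluded from ``counted_size``.

Decoy proteins are built per target by shuffling residues within each fully
enzymatic peptide while the enzymatic C-terminal residue of each peptide
stays fixed, so the decoy database preserves residue composition and the
enzyme's cleavage-site structure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digestion import digest
from .model import DECOY_PREFIX, ProteinDB, ProteinEntry, validate_sequence

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "accession",
    "is_spurious",
    "replicon_id",
    "gene_index",
    "strand",
    "arcog_class",
]


def load_proteome(
    fasta_path,
    annotations: pd.DataFrame | None = None,
    *,
    seed: int = 0,
    circular: dict[str, bool] | None = None,
) -> ProteinDB:
    """Load a FASTA proteome, merge duplicates, and flag spurious entries.

    Raises on duplicate accessions with differing sequences.  Entries missing
    an annotation row are kept with defaults and a logged warning.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        validate_sequence(seq)
        if rec.id in records:
            if records[rec.id] != seq:
                raise ValueError(
                    f"accession {rec.id!r} appears twice with different sequences"
                )
            continue
        records[rec.id] = seq

    ann: dict[str, dict] = {}
    if annotations is not None:
        for row in annotations.to_dict("records"):
            ann[str(row["accession"])] = row

    def entry_for(acc: str) -> ProteinEntry:
        row = ann.get(acc)
        if row is None:
            if annotations is not None:
                logger.warning("no annotation row for %s; using defaults", acc)
            return ProteinEntry(accession=acc, sequence=records[acc])
        arcog = row.get("arcog_class")
        if pd.isna(arcog) or arcog in ("", "-", None):
            arcog = None
        members = row.get("duplicate_members")
        members = (
            str(members).split(";")
            if members is not None and not pd.isna(members) and str(members)
            else []
        )
        return ProteinEntry(
            accession=acc,
            sequence=records[acc],
            is_spurious=bool(row.get("is_spurious", False)),
            replicon_id=str(row.get("replicon_id", "chr")),
            gene_index=int(row.get("gene_index", -1)),
            strand=str(row.get("strand", "+")),
            arcog_class=arcog,
            duplicate_members=members,
        )

    entries = {acc: entry_for(acc) for acc in records}

    # merge identical sequences among non-spurious targets
    by_seq: dict[str, list[str]] = {}
    for acc, e in entries.items():
        if not e.is_spurious:
            by_seq.setdefault(e.sequence, []).append(acc)

    rng = np.random.default_rng(seed)
    db = ProteinDB(circular=dict(circular or {}))
    merged_away: set[str] = set()
    for seq in sorted(by_seq):
        members = sorted(by_seq[seq])
        if len(members) > 1:
            rep = members[int(rng.integers(len(members)))]
            entries[rep].duplicate_members = members
            merged_away.update(m for m in members if m != rep)
    for acc in records:  # preserve file order
        if acc not in merged_away:
            db.add(entries[acc])
    for e in db.counted:
        db.circular.setdefault(e.replicon_id, True)
    logger.info(
        "loaded %d entries -> %d counted (%d spurious, %d duplicate members merged)",
        len(records),
        db.counted_size,
        sum(e.is_spurious for e in db.targets),
        len(merged_away),
    )
    return db


def generate_decoys(db: ProteinDB, enzyme: str, seed: int) -> ProteinDB:
    """Add one shuffled-peptide decoy per non-spurious target.

    Each target is digested fully (no missed cleavages, no length bounds);
    within every peptide the residues are shuffled, keeping the C-terminal
    residue fixed when it is an enzymatic cleavage residue.  Deterministic
    under ``seed``.
    """
    from .digestion import ENZYMES

    residues, _ = ENZYMES[enzyme]
    rng = np.random.default_rng(seed)
    for target in list(db.counted):
        parts = []
        for pep in digest(target.sequence, enzyme, max_missed=0, mode="full"):
            s = pep.sequence
            if s[-1] in residues:
                head = np.array(list(s[:-1]))
                rng.shuffle(head)
                parts.append("".join(head) + s[-1])
            else:
                arr = np.array(list(s))
                rng.shuffle(arr)
                parts.append("".join(arr))
        decoy_acc = DECOY_PREFIX + target.accession
        db.add(
            ProteinEntry(
                accession=decoy_acc,
                sequence="".join(parts),
                is_decoy=True,
                partner_accession=target.accession,
                replicon_id=target.replicon_id,
                gene_index=target.gene_index,
                strand=target.strand,
            )
        )
        target.partner_accession = decoy_acc
    return db


def write_fasta(db: ProteinDB, path, *, include_decoys: bool = True) -> None:
    recs = []
    for e in db.entries.values():
        if e.is_decoy and not include_decoys:
            continue
        recs.append(SeqRecord(Seq(e.sequence), id=e.accession, description=""))
    SeqIO.write(recs, str(path), "fasta")


def annotations_frame(db: ProteinDB) -> pd.DataFrame:
    rows = [
        {
            "accession": e.accession,
            "is_spurious": e.is_spurious,
            "replicon_id": e.replicon_id,
            "gene_index": e.gene_index,
            "strand": e.strand,
            "arcog_class": e.arcog_class or "-",
            "duplicate_members": ";".join(e.duplicate_members),
        }
        for e in db.targets
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + ["duplicate_members"])


def write_annotations(db: ProteinDB, path) -> None:
    annotations_frame(db).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
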