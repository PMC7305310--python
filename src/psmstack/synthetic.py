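"""Ground-truthed synthetic studies for end-to-end testing and calibration.

The generator emulates the statistical structure of a multi-dataset,
multi-engine proteomics reanalysis at desk scale: a proteome of random
sequences laid out in gene order on circular replicons (with exact-count
spurious annotations, identical-sequence duplicates, and optional planted
runs of never-identified genes), per-dataset protein presence, and PSM
tables that mix correct matches to present proteins with incorrect matches
that hit target and decoy sequences with equal probability and
exchangeable error probabilities — the symmetry assumption under which
decoy counting estimates the false discovery rate.  Signal-peptide
processing is emulated by planting semi-enzymatic evidence around predicted
cleavage sites.

True-match PEPs follow a Beta(1, 150) (sharply concentrated near zero);
false-match PEPs are uniform on [0, 1] for targets and decoys alike.  What
the generator does not model: spectra, retention times, intensities,
modification-level errors, or homology structure between proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digestion import cleavage_sites, digest
from .model import AMINO_ACIDS, PSM_COLUMNS, ProteinDB, ProteinEntry
from .proteome import write_annotations, write_fasta

#: roughly proteome-like residue frequencies (normalized at use)
AA_WEIGHTS = {
    "A": 8.0, "R": 5.5, "N": 4.0, "D": 5.4, "C": 1.4,
    "Q": 3.9, "E": 6.0, "G": 7.0, "H": 2.2, "I": 5.9,
    "L": 9.6, "K": 5.8, "M": 2.4, "F": 3.9, "P": 4.7,
    "S": 6.6, "T": 5.3, "W": 1.1, "Y": 2.9, "V": 6.8,
}

ENGINES = ("msfragger", "msgfplus", "xtandem")

PATHWAYS = ("Sec(SPI)", "Tat(SPI)", "Tat(lipobox)", "Sec(lipobox)", "Pil(SPIII)")


@dataclass
class SyntheticTruth:
    """Per-PSM and per-protein ground truth plus generator parameters."""

    psm_labels: dict[str, str] = field(default_factory=dict)
    protein_presence: dict[str, list[str]] = field(default_factory=dict)
    planted_cs: dict[str, tuple[str, int]] = field(default_factory=dict)
    planted_islands: list[tuple[str, int, int]] = field(default_factory=list)
    generator_params: dict = field(default_factory=dict)

    def is_present(self, dataset_id: str, accession: str) -> bool:
        return accession in self._presence_sets.setdefault(
            dataset_id, set(self.protein_presence.get(dataset_id, ()))
        )

    def __post_init__(self) -> None:
        self._presence_sets: dict[str, set[str]] = {}

    def to_json(self, path) -> None:
        payload = {
            "psm_labels": self.psm_labels,
            "protein_presence": self.protein_presence,
            "planted_cs": {a: list(v) for a, v in self.planted_cs.items()},
            "planted_islands": [list(i) for i in self.planted_islands],
            "generator_params": self.generator_params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            psm_labels=payload["psm_labels"],
            protein_presence=payload["protein_presence"],
            planted_cs={a: (v[0], int(v[1])) for a, v in payload["planted_cs"].items()},
            planted_islands=[tuple(i) for i in payload["planted_islands"]],
            generator_params=payload["generator_params"],
        )


def _random_sequence(rng: np.random.Generator, length: int, alphabet: str | None = None) -> str:
    letters = list(alphabet or AMINO_ACIDS)
    w = np.array([AA_WEIGHTS[a] for a in letters])
    return "".join(rng.choice(letters, size=length, p=w / w.sum()))


def _exact_count(fraction: float, n: int, what: str) -> int:
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"{what} fraction {fraction} outside [0, 1]")
    return int(round(fraction * n))


def simulate_study(
    n_proteins: int = 400,
    n_datasets: int = 3,
    present_fraction: float = 0.7,
    duplicate_fraction: float = 0.02,
    spurious_fraction: float = 0.02,
    seed: int = 0,
    *,
    n_replicons: int = 1,
    length_range: tuple[int, int] = (80, 400),
    predicted_fraction: float = 0.25,
    planted_islands: list[tuple[int, int, int]] | None = None,
    min_replicon_size: int = 51,
    n_spurious: int | None = None,
    n_duplicates: int | None = None,
) -> tuple[ProteinDB, SyntheticTruth, pd.DataFrame]:
    """Generate a merged proteome, its ground truth, and a prediction table.

    ``n_proteins`` counts database entries including spurious annotations
    and redundant duplicate copies, whose exact numbers default to rounded
    fractions of the total.  Unique, non-spurious proteins are laid out in
    gene order on circular replicons; per dataset an exact-count present set
    is drawn, avoiding genes inside ``planted_islands`` (triples of replicon
    index, start gene, run length), which are absent everywhere.  A fraction
    of proteins receives localization predictions, including signal-peptide
    cleavage sites recorded in the truth.
    """
    rng = np.random.default_rng(seed)
    n_spur = n_spurious if n_spurious is not None else _exact_count(spurious_fraction, n_proteins, "spurious")
    n_dup = n_duplicates if n_duplicates is not None else _exact_count(duplicate_fraction, n_proteins, "duplicate")
    n_unique = n_proteins - n_spur - n_dup
    if n_unique <= 0:
        raise ValueError("spurious + duplicate allocation exceeds n_proteins")
    per_replicon = [n_unique // n_replicons] * n_replicons
    for i in range(n_unique % n_replicons):
        per_replicon[i] += 1
    if min(per_replicon) < min_replicon_size:
        raise ValueError(
            f"each replicon needs >= {min_replicon_size} proteins; got {per_replicon}"
        )

    # which unique proteins get localization predictions (exact count)
    n_pred = _exact_count(predicted_fraction, n_unique, "predicted")
    pred_idx = set(rng.choice(n_unique, size=n_pred, replace=False).tolist())

    db = ProteinDB()
    truth = SyntheticTruth(
        generator_params={
            "n_proteins": n_proteins,
            "n_datasets": n_datasets,
            "present_fraction": present_fraction,
            "n_spurious": n_spur,
            "n_duplicates": n_dup,
            "n_replicons": n_replicons,
            "predicted_fraction": predicted_fraction,
            "seed": int(seed),
        }
    )
    predictions: list[dict] = []
    arcog_letters = list("CDEFGHIJKLMNOPQRSTUVX")

    entry_no = 0
    unique_entries: list[ProteinEntry] = []
    for r in range(n_replicons):
        replicon_id = f"rep{r}"
        db.circular[replicon_id] = True
        for g in range(per_replicon[r]):
            i = entry_no
            entry_no += 1
            acc = f"SYN{i:05d}"
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = _random_sequence(rng, length)
            pathway = None
            cs = None
            tm_segments: list[tuple[int, int]] = []
            if i in pred_idx:
                roll = rng.random()
                if roll < 0.55:
                    pathway = PATHWAYS[int(rng.integers(len(PATHWAYS)))]
                    cs = int(rng.integers(18, 33))
                    seq = _plant_cleavage_region(seq, cs, rng)
                    truth.planted_cs[acc] = (pathway, cs)
                else:
                    n_tm = int(rng.integers(1, 4))
                    pos = 5
                    for _ in range(n_tm):
                        start = pos + int(rng.integers(0, 30))
                        end = start + 20
                        if end > length - 5:
                            break
                        tm_segments.append((start, end))
                        pos = end + 10
            entry = ProteinEntry(
                accession=acc,
                sequence=seq,
                replicon_id=replicon_id,
                gene_index=g,
                strand="+" if rng.random() < 0.5 else "-",
                arcog_class=(
                    arcog_letters[int(rng.integers(len(arcog_letters)))]
                    if rng.random() < 0.85
                    else None
                ),
            )
            db.add(entry)
            unique_entries.append(entry)
            if i in pred_idx:
                predictions.append(
                    _prediction_row(acc, pathway, cs, tm_segments)
                )

    # redundant duplicate copies: identical sequence, own accession, merged
    # into the representative entry (the copy accession is only a member)
    dup_of = rng.choice(len(unique_entries), size=n_dup, replace=False)
    for j, k in enumerate(sorted(dup_of.tolist())):
        rep = unique_entries[k]
        copy_acc = f"SYNDUP{j:04d}"
        rep.duplicate_members = sorted(set(rep.duplicate_members) | {copy_acc})
    for j in range(n_spur):
        acc = f"SYNSPUR{j:04d}"
        db.add(
            ProteinEntry(
                accession=acc,
                sequence=_random_sequence(rng, int(rng.integers(*length_range))),
                is_spurious=True,
            )
        )

    # planted islands: absent in every dataset
    island_accs: set[str] = set()
    for rep_idx, start, run in planted_islands or []:
        replicon_id = f"rep{rep_idx}"
        order = db.replicon_order(replicon_id)
        m = len(order)
        accs = [order[(start + k) % m] for k in range(run)]
        island_accs.update(accs)
        truth.planted_islands.append((replicon_id, int(start), int(run)))

    eligible = [e.accession for e in unique_entries if e.accession not in island_accs]
    n_present = _exact_count(present_fraction, n_unique, "present")
    if n_present > len(eligible):
        raise ValueError(
            f"cannot mark {n_present} proteins present with only {len(eligible)} "
            "outside planted islands"
        )
    for d in range(n_datasets):
        chosen = rng.choice(len(eligible), size=n_present, replace=False)
        truth.protein_presence[f"DS{d}"] = sorted(eligible[c] for c in chosen)

    pred_df = pd.DataFrame(
        predictions,
        columns=["accession", "tm_segments", "tatlipo_cs", "lipop_cs", "tatfind_cs", "flafind_cs", "signalp_cs"],
    )
    return db, truth, pred_df


def _plant_cleavage_region(seq: str, cs: int, rng: np.random.Generator) -> str:
    """Rewrite a sequence so the planted cleavage site is testable.

    The signal region (before ``cs``) carries no tryptic site, the residues
    flanking the site are non-K/R/P (so peptides starting near the site are
    genuinely semi-tryptic), and a guaranteed K..A tryptic stop sits
    downstream so semi peptides of allowed length exist.
    """
    no_krp = "".join(a for a in AMINO_ACIDS if a not in "KRP")
    seq = list(seq)
    n = len(seq)
    for i in range(0, min(cs + 3, n)):  # signal region + flank, 0-based cs-1 is CS
        if seq[i] in "KRP":
            seq[i] = no_krp[int(rng.integers(len(no_krp)))]
    stop = cs + 11  # 0-based position of the guaranteed C-terminal K
    if stop + 1 < n:
        seq[stop] = "K"
        seq[stop + 1] = "A"
    return "".join(seq)


def _prediction_row(acc, pathway, cs, tm_segments) -> dict:
    row = {
        "accession": acc,
        "tm_segments": ";".join(f"{s}-{e}" for s, e in tm_segments),
        "tatlipo_cs": "",
        "lipop_cs": "",
        "tatfind_cs": "",
        "flafind_cs": "",
        "signalp_cs": "",
    }
    column = {
        "Tat(lipobox)": "tatlipo_cs",
        "Sec(lipobox)": "lipop_cs",
        "Tat(SPI)": "tatfind_cs",
        "Pil(SPIII)": "flafind_cs",
        "Sec(SPI)": "signalp_cs",
    }
    if pathway is not None:
        row[column[pathway]] = str(cs)
    return row


def _peptide_pool(
    entries,
    enzyme: str,
    max_missed: int,
    length_bounds: tuple[int, int],
    mature_start: dict[str, int] | None = None,
) -> tuple[list[str], dict[str, list[str]]]:
    # proteins with a planted cleavage site are observed in their mature
    # form: peptides starting inside the signal region do not exist
    mature_start = mature_start or {}
    carriers: dict[str, list[str]] = {}
    for e in entries:
        first = mature_start.get(e.accession, 1)
        for pep in digest(e.sequence, enzyme, max_missed=max_missed, mode="full", length_bounds=length_bounds):
            if pep.start < first:
                continue
            carriers.setdefault(pep.sequence, []).append(e.accession)
    return sorted(carriers), carriers


def simulate_psm_tables(
    db: ProteinDB,
    truth: SyntheticTruth,
    n_true: int = 9000,
    n_false: int = 1000,
    engines: tuple[str, ...] = ENGINES,
    overlap_bias: float = 0.5,
    seed: int = 0,
    *,
    enzyme: str = "trypsin",
    max_missed: int = 2,
    length_bounds: tuple[int, int] = (6, 50),
    pep_true: tuple[float, float] = (1.0, 150.0),
    pep_false: tuple[float, float] = (1.0, 1.0),
    engine_noise_sd: float = 0.15,
    exact_decoy_split: bool = False,
) -> pd.DataFrame:
    """Draw true and false PSMs and return a long-format PSM table.

    True matches sample fully enzymatic peptides of proteins present in the
    drawn dataset, with Beta(``pep_true``) error probabilities and an
    engine-inclusion probability raised by ``overlap_bias``.  False matches
    hit target and decoy peptides with equal probability (a fair-coin draw
    per PSM, or an exact half-and-half allocation when
    ``exact_decoy_split``) and share one Beta(``pep_false``) error model,
    making false targets and decoys exchangeable.  Labels are recorded in
    ``truth.psm_labels``.
    """
    if not db.decoys:
        raise ValueError("database has no decoys; run generate_decoys first")
    rng = np.random.default_rng(seed)
    datasets = sorted(truth.protein_presence) or ["DS0"]
    mature = {acc: cs for acc, (_, cs) in truth.planted_cs.items()}
    target_pool, target_carriers = _peptide_pool(
        db.counted, enzyme, max_missed, length_bounds, mature_start=mature
    )
    decoy_pool, decoy_carriers = _peptide_pool(db.decoys, enzyme, max_missed, length_bounds)
    if n_true > len(target_pool):
        raise ValueError(
            f"n_true={n_true} exceeds the {len(target_pool)} available target peptides"
        )
    # per-dataset pool of peptides of present proteins
    present_peps: dict[str, list[str]] = {}
    for ds in datasets:
        present = set(truth.protein_presence.get(ds, ()))
        present_peps[ds] = [p for p in target_pool if any(a in present for a in target_carriers[p])]

    p_engine_true = min(0.95, 0.5 + 0.45 * overlap_bias)
    p_engine_false = 0.45

    def engine_set(p_inc: float) -> list[str]:
        chosen = [e for e in engines if rng.random() < p_inc]
        if not chosen:
            chosen = [engines[int(rng.integers(len(engines)))]]
        return chosen

    rows: list[dict] = []
    counter = 0

    def emit(ds: str, peptide: str, is_decoy: bool, carriers: list[str], base_pep: float, p_inc: float, label: str) -> None:
        nonlocal counter
        sid = f"{ds}.scan{counter:06d}"
        counter += 1
        truth.psm_labels[sid] = label
        for eng in engine_set(p_inc):
            pep_val = float(np.clip(base_pep * 10 ** rng.normal(0.0, engine_noise_sd), 1e-8, 1.0))
            rows.append(
                {
                    "spectrum_id": sid,
                    "dataset_id": ds,
                    "raw_file": f"{ds}_run0",
                    "engine": eng,
                    "peptide": peptide,
                    "modifications": "",
                    "charge": 2,
                    "is_decoy": is_decoy,
                    "accessions": ";".join(sorted(carriers)),
                    "enzyme": enzyme,
                    "specificity": "full",
                    "pep": pep_val,
                }
            )

    for i in range(n_true):
        ds = datasets[i % len(datasets)]
        pool = present_peps[ds]
        if not pool:
            raise ValueError(f"dataset {ds} has no present-protein peptides")
        peptide = pool[int(rng.integers(len(pool)))]
        emit(ds, peptide, False, target_carriers[peptide], float(rng.beta(*pep_true)), p_engine_true, "true_match")
    if exact_decoy_split:
        to_decoy = np.zeros(n_false, dtype=bool)
        to_decoy[rng.permutation(n_false)[: n_false // 2]] = True
    else:
        to_decoy = rng.random(n_false) < 0.5
    for i in range(n_false):
        ds = datasets[i % len(datasets)]
        if to_decoy[i]:
            peptide = decoy_pool[int(rng.integers(len(decoy_pool)))]
            emit(ds, peptide, True, decoy_carriers[peptide], float(rng.beta(*pep_false)), p_engine_false, "false_match")
        else:
            peptide = target_pool[int(rng.integers(len(target_pool)))]
            emit(ds, peptide, False, target_carriers[peptide], float(rng.beta(*pep_false)), p_engine_false, "false_match")
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def plant_signal_peptide_evidence(
    db: ProteinDB,
    truth: SyntheticTruth,
    cases: dict,
    seed: int = 0,
    *,
    dataset_id: str = "DS0",
    n_psms: int = 6,
    engines: tuple[str, ...] = ENGINES,
    enzyme: str = "trypsin",
) -> pd.DataFrame:
    """Emit semi-/fully-tryptic PSMs realizing planted cleavage-site cases.

    ``cases`` maps case kinds to accessions: ``correct`` / ``incorrect`` /
    ``sparse`` are lists, ``refined`` maps accession -> offset in
    ``[-3, 3] \\ {0}``.  Correct and refined cases receive ``n_psms`` (>= 5)
    semi-tryptic PSMs starting at (or offset from) the predicted site;
    incorrect cases receive a fully tryptic peptide starting at the protein
    N terminus (upstream of the site); sparse cases get exactly 4 PSMs.
    """
    if n_psms < 5:
        raise ValueError("n_psms must be >= 5 so planted evidence qualifies")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    counter = 0

    def semi_peptide(seq: str, start: int) -> str:
        for c in cleavage_sites(seq, enzyme):
            length = (c + 1) - start + 1
            if 5 <= length <= 50:
                return seq[start - 1 : c + 1]
        raise ValueError(f"no admissible semi-tryptic peptide at position {start}")

    def emit(acc: str, peptide: str, start: int, specificity: str, count: int) -> None:
        nonlocal counter
        for _ in range(count):
            sid = f"{dataset_id}.sp{counter:05d}"
            counter += 1
            truth.psm_labels[sid] = "true_match"
            base = float(rng.beta(1.0, 150.0))
            for eng in engines:
                rows.append(
                    {
                        "spectrum_id": sid,
                        "dataset_id": dataset_id,
                        "raw_file": f"{dataset_id}_run0",
                        "engine": eng,
                        "peptide": peptide,
                        "modifications": "",
                        "charge": 2,
                        "is_decoy": False,
                        "accessions": acc,
                        "enzyme": enzyme,
                        "specificity": specificity,
                        "pep": float(np.clip(base * 10 ** rng.normal(0, 0.15), 1e-8, 1.0)),
                    }
                )

    def cs_of(acc: str) -> int:
        if acc not in truth.planted_cs:
            raise ValueError(f"{acc} has no planted cleavage site")
        cs = truth.planted_cs[acc][1]
        if cs < 2 or cs > db[acc].length:
            raise ValueError(f"planted site {cs} incompatible with {acc}")
        return cs

    def emit_mature_full(acc: str, cs: int, count: int = 2) -> None:
        # fully tryptic peptides from the mature region, so proteins with a
        # genuine processing site keep at least as many full as semi peptides
        full = digest(db[acc].sequence, enzyme, max_missed=0, mode="full", length_bounds=(5, 50))
        mature = [p for p in full if p.start > cs][:count]
        for p in mature:
            emit(acc, p.sequence, p.start, "full", n_psms)

    for acc in cases.get("correct", []):
        cs = cs_of(acc)
        emit(acc, semi_peptide(db[acc].sequence, cs), cs, "semi_n", n_psms)
        emit_mature_full(acc, cs)
    for acc, delta in cases.get("refined", {}).items():
        if not 1 <= abs(int(delta)) <= 3:
            raise ValueError("refined offsets must be within +/-3 and nonzero")
        cs = cs_of(acc) + int(delta)
        emit(acc, semi_peptide(db[acc].sequence, cs), cs, "semi_n", n_psms)
        emit_mature_full(acc, cs)
    for acc in cases.get("incorrect", []):
        cs = cs_of(acc)
        full = digest(db[acc].sequence, enzyme, max_missed=0, mode="full", length_bounds=(5, 50))
        starters = [p for p in full if p.start <= cs - 3]
        if not starters:
            raise ValueError(f"no fully tryptic peptide upstream of site in {acc}")
        p = starters[0]
        emit(acc, p.sequence, p.start, "full", n_psms)
    for acc in cases.get("sparse", []):
        cs = cs_of(acc)
        emit(acc, semi_peptide(db[acc].sequence, cs), cs, "semi_n", 4)
        emit_mature_full(acc, cs)
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def peptide_truth(psms: pd.DataFrame, truth: SyntheticTruth) -> dict[str, bool]:
    """Map each target peptide sequence to whether any true PSM supports it."""
    labels: dict[str, bool] = {}
    for sid, pep, dec in zip(psms["spectrum_id"], psms["peptide"], psms["is_decoy"]):
        if dec:
            continue
        is_true = truth.psm_labels.get(sid) == "true_match"
        labels[pep] = labels.get(pep, False) or is_true
    return labels


def empirical_fdr(accepted_peptides, labels: dict[str, bool]) -> float:
    """Fraction of accepted target peptides not supported by any true PSM."""
    accepted = list(accepted_peptides)
    if not accepted:
        return 0.0
    false = sum(1 for p in accepted if not labels.get(p, False))
    return false / len(accepted)


def write_study(
    db: ProteinDB,
    truth: SyntheticTruth,
    predictions: pd.DataFrame,
    out_dir,
) -> None:
    """Serialize the study in the formats the pipeline consumes."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # write the unmerged view: duplicate members reappear as identical copies
    expanded = ProteinDB()
    for e in db.targets:
        expanded.add(
            ProteinEntry(
                accession=e.accession,
                sequence=e.sequence,
                is_spurious=e.is_spurious,
                duplicate_members=list(e.duplicate_members),
                replicon_id=e.replicon_id,
                gene_index=e.gene_index,
                strand=e.strand,
                arcog_class=e.arcog_class,
            )
        )
        for m in e.duplicate_members:
            if m != e.accession:
                expanded.add(ProteinEntry(accession=m, sequence=e.sequence))
    write_fasta(expanded, out / "proteome.fasta", include_decoys=False)
    write_annotations(expanded, out / "annotations.tsv")
    predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
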