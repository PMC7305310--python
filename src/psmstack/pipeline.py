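"""End-to-end orchestration: configuration, staging, reports.

``run_pipeline`` executes the full post-search aggregation chain

    combine -> sanitize -> collapse -> peptide q -> infer -> score ->
    picked protein q -> confidence filters -> annotation -> comparative

for each dataset separately, for the combination of all datasets, or both.
Per-dataset and combined analyses may legitimately disagree on marginal
identifications; in ``mode="both"`` the discrepancy sets are reported
explicitly rather than merged.  Every output table carries the hash of the
configuration that produced it; identical configuration implies identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import classify_localization, compute_physicochemical, compute_sequence_coverage
from .combine import combine_pep, sanitize_psms
from .compare import arcog_enrichment, dataset_overlap, overlap_bins, scan_db_islands
from .fdr import (
    apply_confidence_filters,
    apply_length_bounds,
    collapse_to_peptides,
    compute_peptide_qvalues,
    compute_picked_protein_qvalues,
    infer_proteins,
    score_proteins,
)
from .io import read_psms, write_json, write_table
from .model import LocalizationPrediction, ProteinDB
from .proteome import generate_decoys, load_proteome, read_annotations

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative run configuration; thresholds default to study practice."""

    proteome_fasta: str = ""
    annotations: str = ""
    psm_tables: list[str] = field(default_factory=list)
    prediction_table: str = ""
    output_dir: str = "results"
    enzyme: str = "trypsin"
    mode: str = "both"  # per-dataset | combined | both
    peptide_q: float = 0.01
    protein_q: float = 0.005
    min_psms: int = 2
    semi_min_psms: int = 5
    combined_pep_threshold: float = 0.01
    length_bounds: tuple[int, int] = (6, 50)
    window_size: int = 249
    group_by_length: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("peptide_q", "protein_q", "combined_pep_threshold"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.mode not in ("per-dataset", "combined", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.length_bounds = tuple(self.length_bounds)  # type: ignore[assignment]

    def validate_paths(self) -> None:
        paths = [self.proteome_fasta, self.annotations, *self.psm_tables]
        if self.prediction_table:
            paths.append(self.prediction_table)
        missing = [p for p in paths if p and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def analyze_scope(
    psms: pd.DataFrame, db: ProteinDB, config: RunConfig, scope: str | None = None
) -> dict:
    """Run the statistical chain on one evidence scope (dataset or combined)."""
    label = scope if scope is not None else "combined"
    counts = {"psms_in": int(psms["spectrum_id"].nunique())}
    combined = combine_pep(psms, window_size=config.window_size)
    combined = combined[combined["combined_pep"] <= config.combined_pep_threshold]
    kept = sanitize_psms(combined)
    counts["psms_kept"] = len(kept)
    peptides = apply_length_bounds(collapse_to_peptides(kept), config.length_bounds)
    peptides = compute_peptide_qvalues(peptides, group_by_length=config.group_by_length)
    counts["peptides"] = int((~peptides["is_decoy"]).sum())

    target_peps = peptides[~peptides["is_decoy"]]
    decoy_peps = peptides[peptides["is_decoy"]]
    t_groups = score_proteins(
        infer_proteins(target_peps, db, scope=label), peptides, config.peptide_q
    )
    d_groups = score_proteins(
        infer_proteins(decoy_peps, db, scope=label), peptides, config.peptide_q
    )
    groups = compute_picked_protein_qvalues(t_groups, d_groups)
    pep_ok, prot_ok, summary = apply_confidence_filters(
        peptides,
        groups,
        db.counted_size,
        peptide_q=config.peptide_q,
        protein_q=config.protein_q,
        min_psms=config.min_psms,
    )
    counts.update({"confident_peptides": len(pep_ok), "confident_proteins": len(prot_ok)})
    logger.info("scope %s: %s", label, counts)
    return {
        "scope": label,
        "psms": kept,
        "peptides": peptides,
        "groups": groups,
        "confident_peptides": pep_ok,
        "confident_proteins": prot_ok,
        "summary": summary,
        "counts": counts,
    }


def _prediction_lookup(path: str) -> dict[str, LocalizationPrediction]:
    if not path:
        return {}
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.to_dict("records"):
        segments = []
        if isinstance(row.get("tm_segments"), str) and row["tm_segments"]:
            for part in row["tm_segments"].split(";"):
                s, _, e = part.partition("-")
                segments.append((int(s), int(e)))

        def cs(key):
            v = row.get(key)
            if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
                return None
            return int(v)

        out[str(row["accession"])] = LocalizationPrediction(
            accession=str(row["accession"]),
            tm_segments=segments,
            tatlipo_cs=cs("tatlipo_cs"),
            lipop_cs=cs("lipop_cs"),
            tatfind_cs=cs("tatfind_cs"),
            flafind_cs=cs("flafind_cs"),
            signalp_cs=cs("signalp_cs"),
        )
    return out


def annotate_proteins(
    db: ProteinDB,
    confident: pd.DataFrame,
    confident_peptides: pd.DataFrame,
    predictions: dict[str, LocalizationPrediction],
) -> pd.DataFrame:
    """Physicochemistry, coverage and localization for confident proteins."""
    pep_by_acc: dict[str, list[tuple[str, int]]] = {}
    for pep, accs in zip(confident_peptides["peptide"], confident_peptides["accessions"]):
        for acc in str(accs).split(";"):
            if acc in db:
                start = db[acc].sequence.find(pep)
                if start >= 0:
                    pep_by_acc.setdefault(acc, []).append((pep, start + 1))
    rows = []
    for acc in confident["representative"]:
        entry = db[acc]
        mw, pi, gr = compute_physicochemical(entry.sequence)
        rows.append(
            {
                "accession": acc,
                "length": entry.length,
                "mw_da": mw,
                "pi": pi,
                "gravy": gr,
                "coverage": compute_sequence_coverage(entry.length, pep_by_acc.get(acc, [])),
                "category": classify_localization(predictions.get(acc), entry.length)
                if predictions
                else None,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the result bundle.

    Returns a dict with per-scope results, the annotation and comparative
    tables, and the JSON-serializable summary.  A stage failure aborts with
    the failing stage named.
    """
    config.validate_paths()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = {"config_hash": config.config_hash, "psmstack_version": __version__}
    stage = "load-proteome"
    try:
        annotations = read_annotations(config.annotations) if config.annotations else None
        db = load_proteome(config.proteome_fasta, annotations, seed=config.seed)
        if not db.decoys:
            db = generate_decoys(db, config.enzyme, seed=config.seed)

        stage = "read-psms"
        psms = pd.concat([read_psms(p) for p in config.psm_tables], ignore_index=True)

        stage = "analyze"
        scopes: dict[str, dict] = {}
        if config.mode in ("combined", "both"):
            scopes["combined"] = analyze_scope(psms, db, config, None)
        if config.mode in ("per-dataset", "both"):
            for ds, block in psms.groupby("dataset_id"):
                scopes[str(ds)] = analyze_scope(block.reset_index(drop=True), db, config, str(ds))

        stage = "annotate"
        predictions = _prediction_lookup(config.prediction_table)
        reference = scopes.get("combined") or next(iter(scopes.values()))
        annotation = annotate_proteins(
            db, reference["confident_proteins"], reference["confident_peptides"], predictions
        )

        stage = "comparative"
        per_ds = {k: v for k, v in scopes.items() if k != "combined"}
        comparative: dict = {}
        if per_ds:
            sets = {
                ds: set(res["confident_proteins"]["representative"]) for ds, res in per_ds.items()
            }
            profile = dataset_overlap(sets, db)
            comparative["overlap"] = profile
            comparative["overlap_bins"] = overlap_bins(profile, len(sets)).tolist()
        identified = set(reference["confident_proteins"]["representative"])
        comparative["islands"] = scan_db_islands(db, identified)
        if any(e.arcog_class for e in db.counted):
            comparative["enrichment"] = arcog_enrichment(identified, db)

        stage = "report"
        summary = {
            "config_hash": config.config_hash,
            "version": __version__,
            "seed": config.seed,
            "thresholds": {
                "peptide_q": config.peptide_q,
                "protein_q": config.protein_q,
                "min_psms": config.min_psms,
                "combined_pep": config.combined_pep_threshold,
                "length_bounds": list(config.length_bounds),
            },
            "scopes": {k: v["summary"] | v["counts"] for k, v in scopes.items()},
        }
        if "combined" in scopes and per_ds:
            combined_set = set(scopes["combined"]["confident_proteins"]["representative"])
            any_ds = set().union(*(set(r["confident_proteins"]["representative"]) for r in per_ds.values()))
            summary["discrepancy"] = {
                "combined_only": sorted(combined_set - any_ds),
                "per_dataset_only": sorted(any_ds - combined_set),
            }
        for name, res in scopes.items():
            write_table(res["peptides"], out_dir / f"peptides_{name}.tsv", header)
            groups = res["groups"].copy()
            groups["peptides"] = groups["peptides"].map(lambda ps: ";".join(ps))
            write_table(groups, out_dir / f"proteins_{name}.tsv", header)
        write_table(annotation, out_dir / "annotation.tsv", header)
        if "enrichment" in comparative:
            write_table(comparative["enrichment"], out_dir / "arcog_enrichment.tsv", header)
        if "overlap" in comparative:
            write_table(comparative["overlap"], out_dir / "dataset_overlap.tsv", header)
        islands_frames = [r.islands_frame() for r in comparative["islands"].values()]
        if islands_frames:
            write_table(pd.concat(islands_frames, ignore_index=True), out_dir / "islands.tsv", header)
        write_json(summary, out_dir / "summary.json")
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {
        "db": db,
        "scopes": scopes,
        "annotation": annotation,
        "comparative": comparative,
        "summary": summary,
    }
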