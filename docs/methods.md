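# Methods

This note documents the statistical model, the default parameters, the
synthetic-data generator, and the numerical and design choices behind
psmstack. Nothing here reports an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

The input is a set of per-dataset, per-engine PSM tables (delimited text:
spectrum id, peptide, modifications, target/decoy flag, accessions, enzyme,
terminal specificity, per-engine PEP) searched against a merged
target/decoy protein database, plus a table of localization-predictor
outputs. The task is to aggregate this evidence across engines and
datasets into peptide- and protein-level identifications with strictly
controlled error rates, and to derive downstream biology from the result.
Raw spectra, quantification, and running the search or prediction engines
are out of scope: upstream scores are data.

## Protein database

FASTA entries are merged when their sequences are identical; the
representative is drawn with a seeded RNG and all member accessions are
recorded, so reloading a serialized database reproduces the same counted
set. Entries flagged spurious in the annotation table are retained but
excluded from the `counted_size` denominator used for identified-fraction
reports. Decoys are generated per target by shuffling residues within each
fully cleaved peptide, holding the enzymatic C-terminal residue fixed; this
preserves residue composition and the enzyme's cleavage-site structure.
Decoy accessions take the `decoy_` prefix, which also implements the
pairing needed for the picked protein FDR.

Digestion rules: trypsin cleaves after K/R except before P; GluC after E
(after E and D with the `gluc_de` variant). Coordinates are 1-based
inclusive throughout; I and L are distinct residues. Default missed
cleavages follow practice for the two proteases (2 for trypsin, 3 for
GluC); peptide length bounds 6–50 are applied before FDR computation.

## Engine combination

The upstream references for combined-PEP rescoring do not pin down one
estimator, so psmstack specifies one precisely: PSMs are grouped by the
exact set of engines that produced them (spectrum + peptide +
modifications as the match key, so the same peptide with different
modifications counts as a conflict); within a group, PSMs are ordered by
descending joint score Σ −log₁₀ PEPᵉ and the combined PEP at rank *i* is

    PEP_combined(i) = 2 · #decoys in window(i) / |window(i)|

with a centered window of 249 PSMs truncated at the group edges, a
whole-group fallback for groups smaller than the window, clipping to
[ε, 1] with ε = 10⁻⁶ (avoids zero PEPs breaking −log₁₀ sums), and a
running-maximum pass so the estimate is monotone along the ranking. The
factor 2 reflects symmetric target/decoy competition: decoys estimate only
the incorrect-target half of the mixture. The estimator is deliberately
simple, monotone, and order-invariant (a canonical sort precedes
windowing); 249 is large enough for stable decoy counts yet small relative
to the toy-scale groups the generator produces.

Spectrum sanitization: when engines disagree on a spectrum, the best PSM
is kept only if its combined PEP is at least 10× better than the
runner-up identification, otherwise all PSMs of that spectrum are dropped.

Parameter-sweep selection consumes grid summaries (tolerances × offsets ×
raw files, with peptide yields) only: the tolerance pair maximizing the
total yield — summing each file's best offset — wins, ties going to the
smaller precursor then fragment tolerance; offsets are then chosen per
file (ties: closest to zero).

## FDR control

Peptide level: one record per peptide sequence, `best_pep` = minimum
combined PEP (modifications are kept for downstream tables but ignored for
FDR). Ranked by ascending best PEP with decoys placed before targets on
ties (conservative), raw q = cumulative decoys / cumulative targets, then
a bottom-up minimum-so-far traversal enforces monotonicity. Raw q may
exceed 1 deep in the ranking; it is reported as computed, since decisions
are taken at thresholds far below 1. Ranking is per length group, because
the decoy model is biased for very short and very long peptides; groups
with fewer than 100 peptides are merged with the nearest length bin, and a
rare sequence occurring in both databases is labeled target.

Protein level: the inference rule is intentionally simple (shared peptides
are rare in a small-genome proteome). Proteotypic peptides evidence their
protein; a shared peptide joins the unique otherwise-evidenced carrier if
exactly one exists, is discarded as ambiguous if several are evidenced,
and otherwise forms a group counted as a single protein. Scores are
Σ −log₁₀ best PEP over peptides with q ≤ 1 %. The picked competition
discards the lower-scoring member of every target/decoy pair (ties keep
the target) before the same two-traversal q-value computation; a classical
joint-ranking variant is provided as a reference for comparison, never as
the default. Protein scoring can be run per dataset or on the combined
evidence; both modes are exposed and the pipeline reports per-dataset and
combined results side by side with their discrepancy sets, because marginal
identifications legitimately differ between the two.

Confidence filters: peptide q ≤ 1 %, protein q ≤ 0.5 %, and at least two
supporting PSMs at both levels. Reported percentages round half-up.

## Annotation

Monoisotopic molecular weight sums residue masses plus one water
(pyteomics mass tables). The isoelectric point is the unique root of the
strictly decreasing Henderson–Hasselbalch net-charge model, found by
bisection on pH ∈ [0, 14] to |charge| < 10⁻⁴; the default pK set is the
EMBOSS table (distinct N-terminal, C-terminal and side-chain values) and
is swappable per call. GRAVY is the mean Kyte–Doolittle hydropathy.
Coverage is the length of the union of peptide intervals over the protein
length.

Localization: the first positive predictor in the fixed order TatLipo
(Tat lipobox) → LipoP (Sec lipobox) → TatFind (Tat SPI) → FlaFind (Pil
SPIII) → SignalP (Sec SPI) decides; otherwise ≥ 2 TM segments mean an
integral membrane protein, one TM segment within the first/last 50
residues gives TM-N-term/TM-C-term, and the remainder is cytosolic. A
single TM segment in neither terminal region is not named by the upstream
categorization; it is assigned to the integral-membrane bucket
(configurable) so the categories stay exhaustive and mutually exclusive.
A missing prediction row falls back to cytosolic with a warning.

N-terminal maturation: a peptide at position 1 with the initiator Met
reports a retained methionine; a start at position 2 reports a cleaved N
terminus (cleavage of at most one residue; a start at position 3 is not
accepted as "cleaved"). Nt-acetylation is recognized by an acetyl
modification at peptide position 0 or residue 1. A peptide ending on the
final residue marks the C terminus as identified. One protein may
contribute several peptidoform calls; counts are per category.

## Signal-peptide cleavage sites

Semi-enzymatic searches inflate the search space, so fully and
semi-enzymatic PSMs are validated in separate groups (combination,
sanitization and peptide q-values run independently per group) and semi
results never enter headline identification counts. For each predicted
cleavage site (TatLipo overriding Tat SPI predictions where both exist):
*correct* if a qualifying semi-tryptic peptide (global 1 % peptide
q-threshold, ≥ 5 PSMs) starts exactly at the site; *refined* if one starts
within ±3 residues (smallest |offset| wins, upstream on ties); otherwise
*incorrect* if a fully tryptic peptide starts at least three residues
N-terminal of the site (boundary start = site−3 also satisfies the
refinement window, and refinement wins by precedence); otherwise
*unclassifiable* when no theoretical 5–50-residue tryptic peptide can
start at the site or an N-terminal lipid anchor is predicted (lipobox
pathways). Proteins with more semi- than fully-tryptic peptides are not
assessed (diffuse proteolysis), GluC-digested and enrichment-based
datasets are excluded via flags, and SPIII (pilin) sites are out of scope.

## Cross-dataset comparison

Overlap profiles count, per counted protein, the number of whole-proteome
datasets containing it (bin 0 is the never-identified remainder, so bins
partition the proteome). arCOG enrichment uses the two-sided Fisher exact
test (scipy's hypergeometric enumeration) on in-group/in-class tables
against the whole-proteome background, Bonferroni-corrected by the number
of classes tested. Island detection orders genes by coding-region start,
counts identified proteins in a 51-gene window per gene (25 each side,
indices wrapping on circular replicons), flags windows at or below 20
identified (39.2 %), and reports maximal consecutive runs of flagged genes
as islands — "closely spaced" is operationalized as consecutive, with no
minimum run length, and a run may wrap the origin. The focal gene itself
is not required to be unidentified.

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes,
at desk scale. Defaults: one circular replicon; protein lengths uniform
80–400 over proteome-like residue frequencies; exact-count (not
Bernoulli) allocation of present, spurious and duplicate entries so tests
are deterministic given a seed; per-dataset presence 70 %; a quarter of
proteins carry localization predictions. True PSMs sample fully tryptic
peptides (6–50 residues, ≤ 2 missed cleavages) of present proteins with
Beta(1, 150) PEPs (mean ≈ 0.7 %) and an engine-inclusion probability
raised by the overlap bias (default 0.5 → ~73 % per engine); false PSMs
hit target and decoy peptides with equal probability — a fair coin per
PSM, or an exact half/half allocation for calibration studies — with
uniform (Beta(1, 1)) PEPs and ~45 % engine inclusion, making false
targets and decoys exchangeable, the premise under which decoy counting
estimates the FDR. Proteins carrying a planted cleavage site are treated
as observed in mature form: peptides starting inside the signal region
are excluded from the true-match pool, and their sequences are locally
rewritten so the site is testable (no tryptic site in the signal region,
non-K/R/P flanks, a guaranteed downstream tryptic stop).

What the generator does not model: spectra, retention time, intensity,
modification-level errors, homology between proteins, or engine-specific
score idiosyncrasies. Passing tests therefore demonstrate the statistical
correctness of the aggregation machinery under the stated mixture
assumptions, not performance on real spectra.

Problem sizes used by the test suite and acceptance script — 150–620
proteins, 2 000–10 000 PSMs per study, 20 calibration seeds, 200-gene
replicons, 10 000 random prediction rows — were chosen as the smallest
scales at which the tested properties are statistically meaningful
(e.g. ≈ 80 expected decoys at the 1 % cutoff of a 9 000/1 000 study).

## Known limitations

* The combined-PEP estimator is a windowed stand-in for the upstream
  implementation, which is not fully specified by its references; its
  outputs are used as rankings plus a thresholding score, for which any
  monotone calibrated transform is equivalent.
* The cumulative D/T estimator without a +1 correction, selected at the
  last q-crossing, is mildly anti-conservative at small decoy counts;
  the calibration study quantifies this (empirical FDR ≈ 1.03 % at a
  nominal 1 % across 20 seeds).
* Protein inference is the simple single-evidence rule, not a global
  parsimony model; deliberately so.
* pI values depend on the chosen pK set; only the EMBOSS table ships.
* The island scan reports smoothed windows: island borders can extend a
  few genes beyond a planted absent run because neighboring windows also
  fall below the threshold.
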