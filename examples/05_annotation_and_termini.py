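"""Per-protein annotation: mass, pI, GRAVY, coverage, localization, termini.

Computes physicochemical properties and sequence coverage for a small
protein, classifies localization from prediction-engine outputs, and calls
N-terminal maturation states from terminal peptides.
"""

from psmstack import (
    classify_localization,
    classify_terminus,
    compute_physicochemical,
    compute_sequence_coverage,
)
from psmstack.model import LocalizationPrediction, ProteinEntry

protein = ProteinEntry(accession="demo", sequence="MAKTEILNVKGGDHWESTNVKAVNDHESTGKLMWQAVR")
mw, pi, gravy = compute_physicochemical(protein.sequence)
print(f"{protein.accession}: {protein.length} aa, {mw / 1000:.2f} kDa (monoisotopic), "
      f"pI {pi:.2f}, GRAVY {gravy:+.2f}")

peptides = [("MAKTEILNVK", 1), ("GGDHWESTNVK", 11), ("LMWQAVR", 32)]
coverage = compute_sequence_coverage(protein.length, peptides)
print(f"sequence coverage from {len(peptides)} peptides: {100 * coverage:.0f}%")

pred = LocalizationPrediction(accession="demo", tm_segments=[(8, 30)])
print("localization:", classify_localization(pred, protein.length))
# one TM segment ending within the first 50 residues -> TM_N_term

call = classify_terminus(protein, "MAKTEILNVK", 1, modifications="Acetyl:0")
print(f"N terminus: {call.n_term_class}, acetylated: {call.acetylated}")
call = classify_terminus(protein, "AKTEILNVK", 2)
print(f"start at position 2 -> {call.n_term_class} initiator methionine")
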