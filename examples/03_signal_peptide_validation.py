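"""Validate predicted signal-peptide cleavage sites with semi-tryptic peptides.

Plants four kinds of evidence for predicted cleavage sites (CS) — exact
support, support shifted by up to three residues, contradicting fully
tryptic peptides, and under-supported (4-PSM) evidence — runs the grouped
semi-enzymatic validation, and classifies each prediction.
"""

import pandas as pd

from psmstack import generate_decoys, simulate_psm_tables, simulate_study
from psmstack.signalpep import classify_all_cleavage_sites, validate_semi_enzymatic
from psmstack.synthetic import plant_signal_peptide_evidence

db, truth, _ = simulate_study(n_proteins=150, n_datasets=1, predicted_fraction=0.6, seed=5)
db = generate_decoys(db, "trypsin", seed=5)

spi = [a for a, (p, _) in sorted(truth.planted_cs.items()) if p.endswith("(SPI)")]
cases = {
    "correct": spi[0:3],
    "refined": {spi[3]: 2, spi[4]: -3},
    "incorrect": spi[5:7],
    "sparse": spi[7:9],
}
background = simulate_psm_tables(db, truth, n_true=1500, n_false=150, seed=5)
planted = plant_signal_peptide_evidence(db, truth, cases, seed=5, dataset_id="DS0")

# fully- and semi-enzymatic PSMs are validated in separate groups
_, peptides = validate_semi_enzymatic(pd.concat([background, planted], ignore_index=True))
predictions = {
    acc: truth.planted_cs[acc]
    for acc in cases["correct"] + list(cases["refined"]) + cases["incorrect"] + cases["sparse"]
}
calls = classify_all_cleavage_sites(db, predictions, peptides)
print(calls.to_string(index=False))
# "correct": a >= 5-PSM semi-tryptic peptide starts exactly at the predicted
# CS; "refined": the best start lies within +/-3 residues (refined_cs);
# "incorrect": a fully tryptic peptide covers the supposed signal region;
# "no_call": the 4-PSM sparse case fails the evidence threshold.
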