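"""Curate a small compound table: salts, metals, routes.

Builds a handful of raw SMILES, standardizes them, and applies the
administration-route filter, printing what survives and why the rest
was removed.
"""

from cholepk.curation import (CompoundRecord, Rejection,
                              apply_dataset_filters, compute_descriptors,
                              standardize_structure)

RAW = [
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "oral"),
    ("ethanol HCl salt", "CCO.Cl", "oral"),
    ("cisplatin-like", "[Pt](Cl)(Cl)", "intravenous"),
    ("water", "O", "oral"),
    ("benzocaine", "CCOC(=O)c1ccc(N)cc1", "other"),
]

records = []
for name, smiles, route in RAW:
    out = standardize_structure(smiles, compound_id=name, route=route)
    if isinstance(out, Rejection):
        print(f"{name:18s} rejected ({out.reason})")
    else:
        print(f"{name:18s} -> {out.smiles}  (MolWt {out.molwt:.1f})")
        records.append(out)

kept, report = apply_dataset_filters(records)
print(f"\nroute filter kept {len(kept)}/{len(records)}; "
      f"removed per stage: {report.stages}")

d = compute_descriptors(kept[0])
print(f"\n{kept[0].compound_id} Lipinski block: "
      f"ExactMolWt={d['ExactMolWt']:.2f}, MolLogP={d['MolLogP']:.2f}, "
      f"donors={d['NumHDonors']:.0f}, acceptors={d['NumHAcceptors']:.0f}")
# Rejections mirror common curation practice: inorganic (no carbon) and
# metal-containing structures cannot be modelled by the fingerprints the
# transporter QSARs use; non-oral/-iv routes lack a meaningful oral dose.
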