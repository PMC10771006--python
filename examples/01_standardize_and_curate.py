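"""Standardize raw SMILES and assemble a balanced training set.

Salts are stripped to the parent structure, mixtures and inorganics are
rejected with a reason, canonical duplicates are merged, and the non-drug
pool is down-sampled to match the drug count.
"""

from dbpp import chemprep

raw = [
    ("CCO", "already standard"),
    ("OCC", "same molecule, different SMILES"),
    ("CCO.Cl", "hydrochloride salt"),
    ("CC(=O)[O-].[Na+]", "sodium acetate -> acetic acid"),
    ("CCO.CCN", "two organic fragments: a mixture"),
    ("[Na+].[Cl-]", "no carbon: inorganic"),
    ("this-is-not-smiles", "unparseable"),
]

print("standardization:")
for smiles, note in raw:
    out = chemprep.standardize(smiles)
    if isinstance(out, chemprep.StandardizedMolecule):
        fixes = ",".join(out.applied_fixes) or "-"
        print(f"  {smiles:22s} -> accepted {out.canonical_smiles:12s} fixes={fixes}  ({note})")
    else:
        print(f"  {smiles:22s} -> rejected [{out.reason}]  ({note})")

# curate a toy pool: duplicates collapse to the first canonical occurrence
accepted = [
    chemprep.standardize(s, label)
    for s, label in [("CCO", 1), ("OCC", 1), ("CCN", 0), ("CCC", 0), ("CCCC", 0)]
]
unique = chemprep.deduplicate(accepted)
print(f"\ndeduplicate: {len(accepted)} records -> {len(unique)} unique structures")

positives = [r for r in unique if r.label == 1]
negatives = [r for r in unique if r.label == 0]
dataset = chemprep.assemble_dataset(positives, negatives, n_negative=1, seed=7)
print(f"balanced dataset: {len(dataset)} records, "
      f"{dataset.labels.sum()} drugs / {(dataset.labels == 0).sum()} non-drugs")
# The same seed + replicate_id always reproduces the same negative draw.
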