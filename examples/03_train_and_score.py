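"""Train a DBPP model end to end and score molecules.

The 20-endpoint ADMET panel is fitted on synthetic endpoint tables (stand-ins
for real endpoint training data), the drug-likeness classifier is trained on
the packaged 40-molecule drug/non-drug panel, and new molecules are scored.
A DBPP score is the probability that a molecule's 26-value property profile
belongs to the drug class; scores above the threshold flag the molecule as
druggable.
"""

from dbpp import chemprep, model, synthetic

panel = synthetic.train_synthetic_panel(n=240, effect=3.0, algo="lr", seed=0)
print(f"panel: {len(panel)} endpoints, hash {panel.manifest_hash()}")

mols = synthetic.fixture_molecules()
records = [
    chemprep.standardize(row["smiles"], int(row["label"]), row["name"])
    for _, row in mols.iterrows()
]
dataset = chemprep.LabeledDataset(records=records, seed=0)
dbpp_model = model.train_dbpp(dataset, panel, algo="lgbm", gamma=0.6,
                              seed=0, tune=False)
print(f"model: algo={dbpp_model.algo} gamma={dbpp_model.gamma} "
      f"threshold={dbpp_model.threshold}")

for name, smiles in [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("sertraline", "CN[C@H]1CC[C@@H](c2ccc(Cl)c(Cl)c2)c2ccccc21"),
    ("hexane", "CCCCCC"),
    ("triethylamine", "CCN(CC)CC"),
]:
    score = dbpp_model.score_mol(chemprep.standardize(smiles))
    call = "druggable" if model.classify(score, dbpp_model.threshold) else "not druggable"
    print(f"  {name:14s} DBPP = {score:.3f}  -> {call}")

# The threshold can be re-derived as the mean score of a reference drug set:
drugs = [r for r in records if r.label == 1]
print(f"reference-drug mean score (re-derived threshold): "
      f"{model.derive_threshold(dbpp_model, drugs):.3f}")
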