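"""Molecular representations: physicochemical profile, descriptors,
fingerprints, QED, and dataset-diversity statistics.
"""

import numpy as np

from dbpp import featurize, qed, synthetic

aspirin = "CC(=O)Oc1ccccc1C(=O)O"

pc = featurize.physchem_profile(aspirin)
print(f"aspirin physchem: MW={pc.mw:.1f} g/mol  logP={pc.logp:.2f}  "
      f"TPSA={pc.tpsa:.1f} A^2  HBA={pc.hba} HBD={pc.hbd} nROT={pc.nrot}")

desc = featurize.descriptor_vector(aspirin)
print(f"descriptor vector: {desc.values.shape[0]} values "
      f"(first 3: {np.round(desc.values[:3], 3)})")

for kind in featurize.FINGERPRINT_KINDS:
    fp = featurize.fingerprint(aspirin, kind)
    print(f"  {kind:15s} {fp.nbits:4d} bits, {int(fp.bits.sum())} set")

print(f"QED (weighted) = {qed.qed_score(aspirin):.3f} "
      "(0 = nothing like a drug, 1 = ideal oral-drug properties)")

# diversity of the packaged 40-molecule panel
mols = synthetic.fixture_molecules()
sim, mean_sim = featurize.tanimoto_stats(list(mols["smiles"]))
scaffolds = featurize.murcko_summary(list(mols["smiles"]))
print(f"\npanel diversity: mean off-diagonal MACCS Tanimoto = {mean_sim:.3f}")
print(f"Murcko scaffolds: {scaffolds.n_scaffolds} among "
      f"{scaffolds.n_molecules} molecules "
      f"({scaffolds.acyclic_count} acyclic); most frequent: "
      f"{scaffolds.top_scaffolds(1)[0]}")
# A low mean similarity (~0.3-0.4) indicates a structurally diverse set.
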