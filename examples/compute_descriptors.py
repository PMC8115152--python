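"""Compute the three model descriptors for a few compounds and predict
their skin permeability with the frozen three-descriptor equation.

The printed log Kp is the base-10 log of the permeability coefficient in
cm/h; more negative means slower penetration through human skin.
"""

from skinperm import descriptor_vector, predict_published

compounds = {
    "ethanol": "CCO",
    "phenol": "Oc1ccccc1",
    "testosterone": "CC12CCC3C(C1CCC2O)CCC4=CC(=O)CCC34C",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
}

print(f"{'compound':<14} {'AlogP':>7} {'cos2':>6} {'X3v':>6} {'Neo80':>5} {'logKp':>7}")
for name, smiles in compounds.items():
    vec = descriptor_vector(smiles)
    logkp = predict_published("three_descriptor_full", vec.as_dict())
    print(f"{name:<14} {vec.alogp:7.2f} {vec.cos2_alogp:6.3f} "
          f"{vec.x3v:6.3f} {vec.neoplastic80:5d} {logkp:7.2f}")

print("\nA more hydrophobic, compact molecule (higher AlogP, lower X3v) "
      "permeates faster; the drug-likeness flag Neo80 lowers predicted log Kp.")
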