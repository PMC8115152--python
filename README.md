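# skinperm

Three-descriptor QSAR modeling of human skin permeability.

Estimating how fast a chemical crosses human skin matters to drug delivery,
cosmetics and occupational risk assessment, and measuring it is slow,
expensive and ethically fraught. `skinperm` predicts the permeability
coefficient — as log Kp, the base-10 log of Kp in cm/h — from molecular
structure alone, for chemists and toxicologists who have nothing but a
SMILES string.

## The model

Three cheap 2D descriptors carry the signal:

* **cos²[(4.31 + AlogP)/8.66]** — a bounded transform of the
  atom-contribution octanol/water partition coefficient AlogP
  (hydrophobicity). Over the chemistry of interest the transform is
  monotone in AlogP and linearizes its relationship to log Kp.
* **X3v** — the third-order valence molecular connectivity index
  Σ(δᵥᵢ·δᵥⱼ·δᵥₖ·δᵥₗ)^(-1/2) over all 4-vertex paths of the H-depleted
  graph, where δᵥ is the Kier–Hall valence vertex degree. It encodes
  molecular size and branching.
* **Neoplastic-80** — a 0/1 drug-likeness indicator: 1 iff the molecule
  carries a qualifying functional group (benzene or heterocyclic ring,
  aliphatic amine, carboxamide, alcoholic hydroxyl, carboxy ester or keto
  group) and AlogP ∈ [−1.5, 4.7], molar refractivity ∈ [43, 128],
  MW ∈ [180, 470], total atom count ∈ [21, 63].

On top of the descriptors the package provides:

* the frozen published linear equations, e.g. the full-set model
  log Kp = 2.209 − 6.698·cos²[(4.31 + AlogP)/8.66] − 0.174·X3v
  − 0.704·Neoplastic-80;
* fresh OLS fits with the usual QSAR diagnostics (se, t, P, VIF, F) and
  classical stepwise selection;
* deterministic Kennard–Stone max–min train/test splitting;
* ε-SVR with RBF kernel, solved by an SMO-style ascent on the dual, with
  real-coded genetic-algorithm tuning of (C, γ) by 5-fold CV;
* leave-one-out / m-fold cross-validation and the Golbraikh–Tropsha
  external-validation battery (q²_ext, through-origin slopes k and k′,
  R0², R0′² and their relative differences).

## Worked example

```python
from skinperm import descriptor_vector, predict_published

vec = descriptor_vector("CC12CCC3C(C1CCC2O)CCC4=CC(=O)CCC34C")  # testosterone
print(vec.alogp, vec.x3v, vec.neoplastic80)
print(predict_published("three_descriptor_full", vec.as_dict()))
```

prints

```
3.8792000000000035 7.911977548938119 1
-2.1668009588273615
```

AlogP ≈ 3.88 (hydrophobic), X3v ≈ 7.91 (four fused rings), and the molecule
qualifies as drug-like, giving a predicted log Kp ≈ −2.17 — i.e. a
permeability coefficient of about 7 × 10⁻³ cm/h, a readily permeating
steroid. The scripts under `examples/` walk through each capability
(descriptors, splitting, MLR, SVR, GA tuning, external validation) and
print a line explaining every number; there is also a `skinperm` CLI with
`descriptors`, `synth`, `split`, `fit-mlr`, `fit-svm`, `tune`, `validate`,
`predict` and `run` subcommands.

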