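# Methods

This note records the scientific and numerical choices behind `skinperm`:
what is computed, under which conventions, and what the tests do and do not
demonstrate.

## Endpoint and model form

The endpoint is log Kp, the base-10 logarithm of the skin permeability
coefficient in cm/h; experimental values for the chemistry the model serves
span roughly −6.1 to −0.8. The core model is linear in three 2D
descriptors — cos²[(4.31 + AlogP)/8.66], X3v and Neoplastic-80 — either as
frozen published equations or refit by OLS; a nonlinear alternative maps the
same descriptors through ε-SVR with an RBF kernel. Both operate per
compound and assume the query chemistry resembles the neutral organics the
model was built on: parsing rejects net-charged species and organometallics
outright rather than extrapolating.

## Descriptors

**AlogP and molar refractivity** are atom-contribution sums. The package
delegates atom typing and constants to the Wildman–Crippen parameterization
shipped with RDKit, the maintained successor of the Ghose–Crippen–
Viswanadhan scheme; the provenance string travels with the
`AtomContributionTable`, and element-keyed custom tables can be substituted
(used in tests). Hydrogens are typed explicitly, so contributions are summed
over the hydrogen-added structure.

**cos² transform.** The argument (4.31 + AlogP)/8.66 is in radians. Over
AlogP ∈ [−4.3, 4.4] it spans ≈ [0, 1] rad, so the transform is monotone
decreasing there — a bounded re-expression of hydrophobicity, not an
oscillation. Values map into [0, 1] for any input by construction.

**Connectivity indices.** The H-depleted graph keeps heavy atoms only.
Simple degree δ is the count of bonded heavy atoms; the valence degree
follows Kier–Hall: δᵥ = Zᵥ − h for second-row atoms and
(Zᵥ − h)/(Z − Zᵥ − 1) for heavier ones (Zᵥ = valence electrons, h =
attached hydrogens). This is the convention the original descriptor
software implements, and the choice is validated against RDKit's
independent Chi3v implementation in the tests. Order-k indices sum
(Π δ)^(−1/2) over all simple paths of k edges, each undirected path counted
once; k is limited to 0–5. Degree-zero vertices are skipped in the order-0
sum (1/√0 is undefined; an isolated atom contributes nothing). Aromaticity
enters only through hydrogen counts — path enumeration uses the skeleton.

**Neoplastic-80.** Functional groups are detected by SMARTS patterns
(documented in `descriptors.NEOPLASTIC_GROUP_SMARTS`, one positive and one
negative example each in the tests). All four property gates are treated as
closed intervals, and the total atom count includes hydrogens, matching the
total-atom convention of the drug-likeness index family. These two
conventions are the genuinely open choices here; both are recorded in code
and exercised by tests, and both can be revisited against tabulated
reference values if a user supplies them.

## Dataset handling

Tables are UTF-8 CSV with header (`id,smiles,logkp`, optional name/split/
descriptor columns). Duplicates are detected by canonical SMILES — stricter
and cheaper than molecular-weight grouping plus inspection — keeping the
first occurrence and warning when duplicate records disagree in log Kp by
more than 0.01. The descriptor pre-filter drops constant columns, then
scans in column order dropping any column with |r| > 0.90 against an
already-kept one.

The Kennard–Stone split operates on the three model descriptors,
standardized to zero mean and unit variance (the feature space is
configurable; the original study did not state it). Selection is the
classical max–min rule; every tie breaks toward the lowest row index, so
splits are bit-reproducible across platforms. Because the original split's
feature space is unknowable, statistics that depend on the reconstructed
partition carry wider tolerances in the acceptance checks than split-free
ones.

## Regression and diagnostics

OLS stands on statsmodels; reported diagnostics are the QSAR-customary set
(coefficient se, t, two-sided P, VIF = 1/(1 − R²ⱼ), multiple R, R²,
adjusted R², standard error of estimate, F reconstructed from R²). Stepwise
selection is classical forward-with-backward on partial-F significance,
defaults p-enter = 0.05 / p-remove = 0.10 (the common defaults of the
statistics packages this procedure originates from); candidates that would
make the design rank-deficient are ineligible, which also blocks duplicate
columns. The four published equations are frozen verbatim — including the
X3v/Neoplastic-80 coefficient pattern that differs between the full-set
equation (−0.174/−0.704) and the training-set equation (−0.722/−0.168);
no "correction" is applied, and the training-set values match the printed
coefficient table.

## ε-SVR

The dual is solved by an SMO-style maximal-violating-pair method on the 2n
box-constrained variables (aᵢ, aᵢ*) with the single equality constraint
Σ(aᵢ − aᵢ*) = 0: at each step the most violating pair under the Karush–
Kuhn–Tucker conditions is updated analytically with clipping to the box.
Stopping is a KKT gap below 1e−3 by default (tightened in oracle-comparison
tests); the bias b averages the KKT value over free support vectors and
falls back to the midpoint of the feasible interval when none is free.
Inputs are standardized inside training — deliberately self-contained,
where the usual library practice leaves scaling to the caller — and the
standardization is serialized with the model. Correctness is anchored two
independent ways: a general-purpose QP solve of the same dual (SLSQP) must
agree in objective to 1e−6 and in predictions to 1e−4 on ≥ 20 random small
instances, and scikit-learn's SVR serves as a second external cross-check.

The GA is real-coded over (C, γ) ∈ [0, 1000] × [0, 10] with tournament
selection (size 2), blend crossover, Gaussian mutation (σ = 5% of each
range), elitism of one, population 20 and up to 200 generations; fitness is
5-fold cross-validated MSE with a seed-deterministic fold assignment. The
study-scale budget is the default; tests and examples pass explicitly
smaller budgets. C = 0 lies on the printed search boundary but is
degenerate, so evaluated candidates clamp C ≥ 1e−6. The original study's
GA internals (fitness definition, folds, seed) are not recoverable, so its
tuned optimum (C = 7.2906, γ = 1.7200) is treated as a frozen input to the
SVR, never as a reproduction target.

## Validation

rms is √(mean squared residual); R² is the squared Pearson correlation of
observed and predicted. The leave-one-out "correlation coefficient" is
Pearson R of held-out predictions versus observations (not q²_LOO) — the
reading most consistent with the quantity's reported magnitude. The
Golbraikh–Tropsha battery computes q²_ext with the denominator centered on
the *training* mean, through-origin slopes k = Σyỹ/Σỹ² and k′ = Σyỹ/Σy²,
and R0²/R0′² exactly as conventionally printed (residuals of ỹ about k·ỹ
over scatter of ỹ about its mean, and symmetrically); the relative
differences compare both against the test-set R². Pass thresholds:
q²_ext > 0.5, slopes in (0.85, 1.15), relative differences < 0.1.

## Synthetic data

The generator emulates the study conditions: 274 compounds, cos² uniform on
[0, 1], X3v uniform on [0, 8], Neoplastic-80 Bernoulli(0.25), log Kp from
the frozen full-set equation plus Gaussian noise of 0.324 log units (the
published fit's standard error of estimate — the natural residual scale for
realistic data). The Bernoulli rate and the X3v range are one-time choices:
a quarter of compounds drug-like and X3v spanning small solvents to fused
polycyclics. Descriptors are sampled independently, which real data do not
satisfy (hydrophobicity and size correlate), and no SMILES are attached to
synthetic records. Passing tests on synthetic data therefore demonstrate
coefficient recovery, split determinism, solver correctness and pipeline
integrity — not that the package reproduces the real data's headline
statistics, which require the original 274-compound table (see README).

## Problem sizes and tolerances

Oracle equivalence runs at n ≤ 25 (SVR/QP), n ≤ 50 (Kennard–Stone,
OLS) and ≤ 12 heavy atoms (path enumeration) — sizes where brute force is
exact and fast. Monte-Carlo checks (noise-calibrated R², stepwise false
entry) use 20–50 seeded replicates and assert within ~4 standard errors.
The acceptance script runs the full 274-compound workflow, including 139
leave-one-out SVR refits, in under a minute on one core.

## Known limitations

Stereochemistry, 3D geometry and charged species are out of scope; the
descriptor trio was selected on one skin-permeability dataset and carries
that domain with it; the Kennard–Stone reconstruction of the original
partition is approximate by necessity; and Wildman–Crippen constants are a
successor, not a byte-identical copy, of the AlogP table the original
descriptor software used, so per-compound AlogP can drift at the second
decimal.
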