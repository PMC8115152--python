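"""Tune (C, gamma) with the genetic algorithm on a small problem.

The GA minimizes 5-fold cross-validated squared error over the box
C in [0, 1000] x gamma in [0, 10].  A short budget (8 generations,
population 10) is enough to show the monotone improvement of the
best-so-far fitness; the study-scale defaults are 200 generations with a
population of 20.
"""

from skinperm import GaConfig, SynthConfig, generate_dataset, ga_optimize

ds = generate_dataset(SynthConfig(n=40, seed=3))
cfg = GaConfig(generations=8, population=10, folds=5, seed=3)
c_best, g_best, history = ga_optimize(ds.descriptor_matrix(), ds.endpoint(), cfg)

print(f"best C = {c_best:.4f}, gamma = {g_best:.4f}")
print("best CV MSE by generation:")
for gen, fit in enumerate(history):
    print(f"  gen {gen:2d}: {fit:.4f}")
print("The trace never increases: elitism keeps the best candidate alive.")
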