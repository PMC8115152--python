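"""Run the Golbraikh-Tropsha external-validation battery on predictions.

A model passes when q2_ext > 0.5, the through-origin slopes k and k' lie in
(0.85, 1.15), and the through-origin determination coefficients stay within
10% (relative) of the test-set R2.  Here the battery is shown on accurate
predictions and then on predictions with a constant systematic offset,
which correlate perfectly yet fail every criterion.
"""

import numpy as np

from skinperm import golbraikh_tropsha

rng = np.random.default_rng(0)
y = rng.uniform(-6.0, -1.0, size=40)

for label, pred in [
    ("accurate model", y + rng.normal(0, 0.3, size=40)),
    ("offset model  ", y + 1.2),
]:
    rep = golbraikh_tropsha(y, pred, y_train_mean=-3.5)
    print(f"{label}: q2_ext {rep.q2_ext:6.3f}  k {rep.k:5.3f}  "
          f"k' {rep.k_prime:5.3f}  rel_diff {rep.rel_diff:5.3f}  "
          f"pass: {rep.all_pass}")

print("\nThe offset model correlates perfectly (R2 = 1) yet fails the "
      "battery: external validity needs accuracy, not just correlation.")
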