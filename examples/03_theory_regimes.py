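"""When does taking the minimum beat averaging? The Gaussian answer.

Class-conditional model: each of N scorers draws a variant's LLR from a
Gaussian whose mean/sd depend on the true class. The table prints analytic
AUCs for both aggregators across separations and class-sd ratios: averaging
wins when the classes disperse equally, while the minimum wins when
pathogenic scores are much more dispersed — exactly what complementary
blind spots produce.
"""

import numpy as np

from minvep import regime_map

grid = regime_map(
    separations=np.array([0.5, 1.0, 2.0]),
    sigma_ratios=np.array([1.0, 2.0, 4.0]),
    n_models=10,
)
print(grid.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
n_min = (grid["winner"] == "min").sum()
print(f"\nmin aggregation wins {n_min}/{len(grid)} cells, all at sd ratio >= 2;")
print("at equal sds averaging is never beaten (its AUC gains the full sqrt(N)).")
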