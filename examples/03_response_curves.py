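"""Negative-binomial trait-response curve with backward model selection.

The bundled scenario generates scraper counts whose log-mean rises with flow
velocity (true centred slope 1.2).  Backward elimination tests the quadratic
term first, then the linear term, each at the 5% level.
"""

import numpy as np

from traitseg import (
    backward_select,
    build_trait_abundance_matrix,
    paperlike_scenario,
    response_curve,
    simulate_dataset,
)

scenario = paperlike_scenario()
taxa, affinity, env = simulate_dataset(scenario, seed=0)
matrix = build_trait_abundance_matrix(taxa, affinity)

y = matrix.data[("feeding_style", "scraper")].to_numpy()
x = env["velocity"].to_numpy()
fit = backward_select(y, x, "negative-binomial", response="scraper", predictor="velocity")

print(f"selected form: {fit.form}")
print(f"centred-scale coefficients: {np.round(fit.coefficients, 3)}  (truth: [2.6, 1.2])")
print(f"overdispersion k: {fit.k:.2f}  (truth: 2)")
for step in fit.trace:
    print(f"  tested {step['term']}: LR p = {step['p_value']:.3g} -> "
          f"{'kept' if step['kept'] else 'dropped'}")
grid = np.linspace(x.min(), x.max(), 5)
mean, _ = response_curve(fit, grid)
for g, m in zip(grid, mean):
    print(f"  velocity {g:4.2f} m/s -> expected scraper abundance {m:6.1f}")
print("\nThe fitted mean abundance rises roughly e^1.2 ~ 3.3-fold per m/s.")
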