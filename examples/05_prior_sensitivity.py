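"""How the drift-scale prior shapes severity trajectories on sparse data.

Under a sparse 2-rater link design, a strongly skewed prior (mu_sigma=-5)
flattens the estimated severity trajectories, a flat-ish prior (0) lets
them wander, and the i.i.d.-severity ablation wanders the most; mu_sigma=-2
is the recommended default.
"""

import raterdrift as rd
from raterdrift.experiments import mean_adjacent_change, prior_sensitivity_sweep

J, R, T = 80, 5, 4
truth = rd.draw_parameters(J, R, T, seed=21)
design = rd.systematic_link_design(J, R, 2, T, seed=22)
data = rd.simulate_scores(truth, design, seed=23)
print(f"{data.n_obs} ratings under the 2-rater link design")

entries = prior_sensitivity_sweep(
    data,
    mu_values=(-5.0, -2.0, 0.0),
    config=rd.SamplerConfig(chains=2, iterations=1200, warmup=600, seed=24),
)

print("\nsetting        mean per-rater total |severity change|")
for e in entries:
    print(f"{e.label:<14} {mean_adjacent_change(e.beta_hat):.3f}")
print(f"{'truth':<14} {mean_adjacent_change(truth.beta):.3f}")
print(
    "\nSmaller values mean flatter estimated trajectories: the skewed\n"
    "prior shrinks severity changes, the ablation does not smooth at all."
)
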