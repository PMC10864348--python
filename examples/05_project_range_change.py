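"""Project the model onto future climates and account for range change.

Futures are built by shifting the favourable layer downward (a warming-like
degradation), the suitability maps are binarized at the evaluation
threshold, and gains/losses are counted relative to the current suitable
area — so change % = gain % − loss % exactly.
"""

import sdmax
from sdmax import EvalConfig, ScenarioSet, ScenarioShift

stack = sdmax.generate_landscape(4, (100, 100), smooth_radius=2.5, seed=1)
truth = sdmax.TrueModel(linear={"env1": 2.0, "env2": -1.5})
suit = sdmax.true_suitability(stack, truth)
presences = sdmax.extract_values(stack, sdmax.sample_presences(suit, stack, 1000, seed=2))
background = sdmax.sample_background(stack, 5000, seed=3)

report = sdmax.kfold_cv(presences, background,
                        {"classes": ("linear",), "beta0": 0.05},
                        EvalConfig(k_folds=5, seed=4))
spec = sdmax.FeatureSpec.from_background(background, classes=("linear",))
model, _ = sdmax.fit_maxent(spec.build(presences), spec.build(background),
                            spec, beta0=0.05)

scenarios = []
for label, horizon, delta in [("RCP4.5", "2050", -0.5), ("RCP4.5", "2070", -0.8),
                              ("RCP8.5", "2050", -1.0), ("RCP8.5", "2070", -1.6)]:
    future = sdmax.apply_shift(stack, ScenarioShift(f"{label}-{horizon}",
                                                    delta={"env1": delta}))
    scenarios.append(ScenarioSet(label, horizon, [future]))

table = sdmax.run_scenarios(model, stack, scenarios, report.threshold,
                            species="virtual")
print(table.round(2).to_string(index=False))
print("\nnegative change % = net contraction of suitable habitat relative "
      "to the current range; loss can never exceed 100 %.")
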