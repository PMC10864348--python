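"""Screen predictors for collinearity before fitting.

Two predictors correlated beyond |r| = 0.70 carry near-duplicate
information; the filter drops one member of each offending pair (the more
redundant one, unless a priority list says otherwise) and documents every
decision.
"""

import sdmax

stack = sdmax.generate_landscape(
    5, (100, 100), smooth_radius=3.0, corr_spec={(0, 1): 0.9}, seed=21)
background = sdmax.sample_background(stack, 5000, seed=22)

matrix = sdmax.pearson_matrix(background)
print("correlation matrix:")
print(matrix.round(2).to_string())

report = sdmax.greedy_collinearity_filter(matrix, sdmax.FilterConfig(threshold=0.70))
print(f"\nkept: {report.kept}")
for d in report.dropped:
    print(f"dropped {d['variable']} (r = {d['r']:.2f} with {d['partner']})")

# an expert can force the other member to be kept instead
report2 = sdmax.greedy_collinearity_filter(
    matrix, sdmax.FilterConfig(threshold=0.70, priority=["env1"]))
print(f"with priority on env1, kept: {report2.kept}")
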