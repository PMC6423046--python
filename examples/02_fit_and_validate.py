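"""Fit an OPLS-DA class model and validate it on a blinded holdout third.

Normalizes each spectrum to the TSP reference, bins at 0.0092 ppm with the
water region excluded, Pareto-scales, fits one predictive plus three
orthogonal components, and evaluates class predictions at the a-priori
0.5 cut-off on a stratified one-third holdout.
"""

import numpy as np

from urimet import (
    SimConfig, CohortDesign, simulate_cohort, normalize_to_reference,
    SpectrumSet, build_matrix, pareto_scale, fit_opls, cross_validate_q2,
    holdout_validate, confusion, accuracy_panel, ConfusionCounts,
)

sset, labels = simulate_cohort(
    CohortDesign(n_control=45, n_case=30, fold_change=2.0), SimConfig(seed=2)
)
norm = np.vstack([normalize_to_reference(sset.spectrum(i)).intensity
                  for i in range(len(sset))])
matrix = build_matrix(SpectrumSet(sset.ppm, norm, sset.sample_ids, labels))
print(f"binned matrix: {matrix.values.shape[0]} samples x {matrix.values.shape[1]} bins")

X, params = pareto_scale(matrix)
model = fit_opls(X, labels, n_orth=3)
q2 = cross_validate_q2(X, labels, n_orth=3, n_folds=7, seed=2)
print(f"R2Y = {model.r2y:.3f} (training fit)   Q2 = {q2:.3f} (7-fold cross-validation)")

model, counts = holdout_validate(matrix.values, labels, holdout_fraction=1/3,
                                 n_orth=3, seed=2)
print(f"blinded holdout: controls {counts['control_correct']}/{counts['control_total']}"
      f"  cases {counts['case_correct']}/{counts['case_total']}")
cc = ConfusionCounts(tp=counts["case_correct"],
                     fn=counts["case_total"] - counts["case_correct"],
                     tn=counts["control_correct"],
                     fp=counts["control_total"] - counts["control_correct"])
panel = accuracy_panel(cc)
print("accuracy panel:", panel.formatted())
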