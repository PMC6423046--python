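"""Rank marker metabolites by ROC AUC.

Estimates per-sample metabolite levels by window integration around each
signature line (after TSP normalization), then ranks the metabolites by
oriented AUC: the probability that a random case level is more extreme
than a random control level in the marker's direction.
"""

from urimet import (
    SimConfig, CohortDesign, simulate_cohort, build_signature_library,
    metabolite_levels, multi_roc_ranking,
)

sset, labels = simulate_cohort(
    CohortDesign(n_control=50, n_case=50, fold_change=2.0), SimConfig(seed=4)
)
levels = metabolite_levels(sset, build_signature_library())
ranking = multi_roc_ranking(levels, labels)

print("oriented AUC ranking (0.5 = useless, 1.0 = perfect discriminator):")
print(ranking.to_string(index=False,
                        formatters={"auc": lambda a: f"{a:.3f}"}))
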