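"""Run the benchmarking suite at demonstration scale.

Tenfold cross-validation of edge prediction, regulon-perturbation
robustness of the activity estimate, imputation sensitivity, and the KSEA
z-score baseline.
"""

import numpy as np
import pandas as pd

import sphinks as sp

spec = sp.default_specs()["standard"]
proteome, phospho, labels, truth = sp.generate_cohort(spec)

cv = sp.crossvalidate(truth.revealed_prior, proteome, phospho,
                      proteome.features, k_folds=10, n_bags=12, seed=11)
print("tenfold CV AUC per fold:", [f"{r.auc:.2f}" for r in cv])
print(f"mean {np.mean([r.auc for r in cv]):.3f} "
      "(how well held-out validated pairs outrank random unlabeled pairs)")

res = sp.run_pipeline(proteome, phospho, truth.revealed_prior,
                      proteome.features, n_bags=12, seed=11)
print("\nregulon perturbation (replace bottom-P of each SOPS):")
for pct in (0.05, 0.20, 0.50):
    pert = sp.perturb_interactome(res.network, res.scores, pct, seed=5)
    cp = sp.draw_controls(pert, res.bins, seed=11)
    act_p = sp.activity_matrix(pert, phospho, cp, res.scores)
    shared = res.activities.index.intersection(act_p.index)
    d = sp.delta_activity(res.activities.loc[shared], act_p.loc[shared],
                          percentage=pct)
    print(f"  P={pct:.0%}: median |dAct/Act| = {d.median_over_kinases:.3f}")
print("small values mean the activity estimate is robust to replacing its "
      "weakest predicted substrates")

aucs = sp.imputation_benchmark(phospho, proteome, truth.revealed_prior,
                               proteome.features, ratios=(0.10, 0.25),
                               seed=11, n_bags=12)
print("\nimputation robustness (network AUC vs un-degraded gold):")
print(aucs.round(4).to_string())

# KSEA baseline on the subtype contrast of the first subtype
st = sorted(labels.unique())[0]
contrast = (phospho.data.loc[:, labels[labels == st].index].mean(axis=1)
            - phospho.data.loc[:, labels[labels != st].index].mean(axis=1))
sets = {k: set(res.network.sops(k)["phosphosite"]) for k in res.network.kinases}
z = sp.ksea_zscore(contrast, {k: v for k, v in sets.items() if v})
print(f"\nKSEA z-score baseline, top 3 kinases for subtype {st}:")
print(z.sort_values(ascending=False).head(3).round(2).to_string())
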