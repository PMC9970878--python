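"""Preprocessing and single-sample set enrichment on a toy matrix.

Filters and imputes a phospho matrix with missing values, quantile/log2
normalizes it, residualizes sites against their parent proteins, and runs
single-sample MWW-GST on a signature.
"""

import numpy as np
import pandas as pd

import sphinks as sp

rng = np.random.default_rng(0)
samples = [f"s{i}" for i in range(8)]
genes = [f"G{i}" for i in range(12)]
prot = sp.AbundanceMatrix(pd.DataFrame(rng.normal(5, 1, (12, 8)),
                                       index=genes, columns=samples))
site_vals = 1.2 * prot.data.to_numpy() + rng.normal(0, 0.4, (12, 8))
site_vals[rng.random((12, 8)) < 0.15] = np.nan
phospho = sp.AbundanceMatrix(pd.DataFrame(site_vals,
                                          index=[f"{g}_S10" for g in genes],
                                          columns=samples))

print(f"input: {phospho.n_missing} missing cells")
imputed = sp.filter_and_impute(phospho, max_missing_fraction=0.5, method="knn")
norm = sp.log2_quantile_normalize(imputed)
print(f"after filter+impute: {imputed.data.shape[0]} sites, 0 missing; "
      "after quantile normalization all samples share the same sorted values:",
      np.allclose(np.sort(norm.data.to_numpy(), axis=0).std(axis=1), 0))

resid, model = sp.residualize_phosphosites(norm, prot)
print(f"residualized {int(model.coefficients['has_parent'].sum())} sites "
      f"against their parent proteins; residual row sums ~ 0: "
      f"{np.allclose(resid.data.sum(axis=1), 0, atol=1e-8)}")

sig = {"program": set(resid.features[:5])}
enr = sp.ss_mww_gst(resid, sig, min_set_size=5)
print("\nper-sample NES of a 5-site signature (0.5 = no enrichment):")
print(enr["nes"].round(3).T.to_string())
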