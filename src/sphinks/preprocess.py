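"""Matrix preprocessing: missingness filtering, imputation, quantile/log2
normalization and protein-residualized phosphosite abundance.

The pipeline mirrors standard TMT proteomics practice: phosphosites
quantified in fewer than half the cohort are dropped, the remainder are
imputed (k-nearest-neighbour over features, Euclidean distance on shared
observed samples), and every sample column is mapped onto the cohort-mean
distribution of order statistics (quantile normalization) on the log2
scale. Residualization regresses each site's abundance on its parent
protein's abundance and keeps the residual — the phosphorylation signal not
explained by protein level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.impute import KNNImputer

from .io import AbundanceMatrix

logger = logging.getLogger("sphinks")


@dataclass
class ResidualModel:
    """Per-site OLS fit of site abundance on parent-protein abundance.

    ``coefficients`` has one row per site with columns beta0 (intercept,
    log2 units), beta1 (slope) and has_parent (whether the site's gene was
    quantified in the proteome; sites without a parent pass through
    unchanged and carry NaN coefficients).
    """

    coefficients: pd.DataFrame


def filter_and_impute(
    m: AbundanceMatrix,
    max_missing_fraction: float = 0.5,
    method: str = "knn",
    k: int = 5,
    seed: int = 0,
) -> AbundanceMatrix:
    """Drop features missing in >= ``max_missing_fraction`` of samples and
    impute the rest.

    ``knn`` fills a feature's missing entries from its ``k`` nearest
    features (Euclidean on shared observed samples, distance-weighted);
    ``feature_mean`` uses the feature's own observed mean. Observed values
    are never altered. The output carries no missing values.
    """
    if not (0 < max_missing_fraction <= 1):
        raise ValueError("max_missing_fraction must be in (0, 1]")
    if method not in ("knn", "feature_mean"):
        raise ValueError(f"unknown imputation method: {method!r}")
    frac = m.data.isna().mean(axis=1)
    keep = frac < max_missing_fraction
    dropped = m.data.index[~keep].tolist()
    if dropped:
        logger.info("filter_and_impute: dropped %d features over %.0f%% missing",
                    len(dropped), 100 * max_missing_fraction)
    data = m.data.loc[keep].copy()
    if data.empty:
        raise ValueError("all features dropped by missingness filter")
    if data.isna().to_numpy().any():
        if method == "feature_mean":
            row_means = data.mean(axis=1)
            filled = data.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
        else:
            imputer = KNNImputer(n_neighbors=min(k, len(data) - 1), weights="distance")
            # features as rows: each feature is imputed from its nearest
            # feature profiles over the shared observed samples
            filled = pd.DataFrame(
                imputer.fit_transform(data.to_numpy()),
                index=data.index, columns=data.columns,
            )
        observed = ~data.isna()
        filled = filled.where(~observed, data)
        data = filled
    return AbundanceMatrix(data, scale=m.scale, normalized=m.normalized)


def log2_quantile_normalize(m: AbundanceMatrix, pseudocount: float = 1.0) -> AbundanceMatrix:
    """Quantile-normalize sample columns on the log2 scale.

    Raw-scale input is first transformed as log2(x + pseudocount). After
    normalization every sample shares the same sorted values — the
    across-sample mean of order statistics. Ties within a column receive
    the mean of the normalized values at their tied ranks, which makes the
    operation idempotent.
    """
    if m.data.isna().to_numpy().any():
        raise ValueError("quantile normalization requires a complete matrix; impute first")
    vals = m.data.to_numpy(dtype=float)
    if m.scale == "raw":
        if (vals + pseudocount <= 0).any():
            raise ValueError("nonpositive values after pseudocount; cannot log2-transform")
        vals = np.log2(vals + pseudocount)
    n, p = vals.shape
    mean_sorted = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    positions = np.arange(1, n + 1)
    for j in range(p):
        ranks = rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, mean_sorted)
    df = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return AbundanceMatrix(df, scale="log2", normalized=True)


def residualize_phosphosites(
    phospho: AbundanceMatrix, proteome: AbundanceMatrix
) -> tuple[AbundanceMatrix, ResidualModel]:
    """Regress each phosphosite on its parent protein; return residuals.

    The parent protein of site ``GENE_Rpos`` is the proteome row ``GENE``.
    Sites without a quantified parent pass through unchanged (flagged in
    the model table). A constant parent is treated as an unidentifiable
    regressor: beta1 = 0 and the residual is the centered site profile.
    """
    shared = [s for s in phospho.samples if s in set(proteome.samples)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, found {len(shared)}")
    ph = phospho.data[shared]
    pr = proteome.data[shared]
    if ph.isna().to_numpy().any() or pr.isna().to_numpy().any():
        raise ValueError("residualization requires complete matrices; impute first")
    out = ph.copy()
    rows = []
    prot_index = set(pr.index)
    for site in ph.index:
        gene = site.split("_", 1)[0]
        if gene not in prot_index:
            rows.append((site, np.nan, np.nan, False))
            continue
        y = ph.loc[site].to_numpy(dtype=float)
        x = pr.loc[gene].to_numpy(dtype=float)
        xc = x - x.mean()
        ssx = float(xc @ xc)
        if ssx <= 1e-12 * len(x):
            beta1 = 0.0
            beta0 = float(y.mean())
        else:
            beta1 = float(xc @ (y - y.mean()) / ssx)
            beta0 = float(y.mean() - beta1 * x.mean())
        out.loc[site] = y - (beta0 + beta1 * x)
        rows.append((site, beta0, beta1, True))
    model = ResidualModel(
        pd.DataFrame(rows, columns=["site", "beta0", "beta1", "has_parent"]).set_index("site")
    )
    return AbundanceMatrix(out, scale="log2", normalized=phospho.normalized), model
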