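"""Mann-Whitney-Wilcoxon machinery: two-sample test, rank-based gene-set
test (MWW-GST) and its single-sample variant (ssMWW-GST).

Conventions used throughout the package:

* ``prob_superiority`` = U / (n1*n2), the probability that a value drawn
  from the first group exceeds one drawn from the second (ties count 1/2).
* ``mww_score`` = logit(prob_superiority), clamped away from 0/1 so it
  stays finite at full separation.
* ``effect_size`` = 2*|prob_superiority - 1/2|, the common-language effect
  size rescaled to [0, 1].
* For set enrichment, NES is the prob_superiority of in-set over
  out-of-set values; ``logit_nes`` = logit(NES) after the same clamp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceMatrix

logger = logging.getLogger("sphinks")


@dataclass(frozen=True)
class MwwResult:
    U: float
    prob_superiority: float
    mww_score: float
    effect_size: float
    p_value: float
    log2_fc: float


@dataclass(frozen=True)
class EnrichmentResult:
    nes: float
    logit_nes: float
    p_value: float
    set_size: int


def _clamp_logit(p: float, n_pairs: int) -> float:
    lo = 1.0 / (n_pairs + 1.0)
    p = min(max(p, lo), 1.0 - lo)
    return float(np.log(p / (1.0 - p)))


def mww_test(x, y) -> MwwResult:
    """Two-sided MWW test of ``x`` versus ``y``.

    U uses the midrank convention. The p-value is the exact null when
    n1*n2 <= 400 and there are no ties, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mww_test requires nonempty groups")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (n1 * n2 <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    ps = u / (n1 * n2)
    return MwwResult(
        U=u,
        prob_superiority=ps,
        mww_score=_clamp_logit(ps, n1 * n2),
        effect_size=2.0 * abs(ps - 0.5),
        p_value=float(min(res.pvalue, 1.0)),
        log2_fc=float(x.mean() - y.mean()),
    )


def mww_gst(ranked_values: pd.Series | dict, feature_set) -> EnrichmentResult:
    """Rank-based set enrichment of ``feature_set`` within ``ranked_values``.

    NES is the probability that an in-set value outranks an out-of-set
    value; the p-value comes from the two-sided MWW test of in-set versus
    out-of-set values.
    """
    values = pd.Series(ranked_values, dtype=float)
    in_set = values.index.isin(set(feature_set))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("feature set has no overlap with the ranked universe")
    if n_in == len(values):
        raise ValueError("feature set covers the whole universe; no background left")
    res = mww_test(values[in_set].to_numpy(), values[~in_set].to_numpy())
    return EnrichmentResult(
        nes=res.prob_superiority,
        logit_nes=res.mww_score,
        p_value=res.p_value,
        set_size=n_in,
    )


def ss_mww_gst(
    m: AbundanceMatrix,
    signatures: dict[str, set[str]],
    min_set_size: int = 5,
) -> dict[str, pd.DataFrame]:
    """Single-sample MWW-GST: per-sample set enrichment of each signature.

    For each sample, features are ranked by that sample's abundance and
    each signature is tested against the rest of the features. Returns
    ``{"nes", "logit_nes", "p_value", "fdr"}`` -> sample x signature
    DataFrames; FDR is Benjamini-Hochberg across samples per signature.
    Signatures with fewer than ``min_set_size`` quantified features are
    skipped with a warning.
    """
    if m.data.isna().to_numpy().any():
        raise ValueError("ssMWW-GST requires a complete matrix; impute first")
    universe = set(m.features)
    usable = {}
    for name, members in signatures.items():
        present = members & universe
        if len(present) < min_set_size:
            logger.warning("ss_mww_gst: signature %s has %d/%d quantified features; skipped",
                           name, len(present), min_set_size)
            continue
        usable[name] = present
    if not usable:
        raise ValueError("no signature meets the minimum quantified size")
    names = sorted(usable)
    out = {k: pd.DataFrame(index=m.samples, columns=names, dtype=float)
           for k in ("nes", "logit_nes", "p_value", "fdr")}
    for sample in m.samples:
        col = m.data[sample]
        for name in names:
            r = mww_gst(col, usable[name])
            out["nes"].loc[sample, name] = r.nes
            out["logit_nes"].loc[sample, name] = r.logit_nes
            out["p_value"].loc[sample, name] = r.p_value
    for name in names:
        out["fdr"][name] = multipletests(out["p_value"][name].to_numpy(), method="fdr_bh")[1]
    return out
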