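"""Benchmarking of the network and activity estimates.

Four procedures:

* **Imputation robustness** — degrade a complete phospho matrix at fixed
  missingness ratios, impute, rebuild the network and score the recovered
  edge ranking against the network built from the pristine matrix (ROC AUC).
* **Tenfold cross-validation** — split the validated prior into folds,
  train the bagged classifier on nine folds plus sampled negatives, and
  measure per-fold AUC on held-out positives versus fresh unlabeled pairs
  disjoint from every training negative.
* **Regulon perturbation** — replace the bottom-scoring fraction of each
  kinase's substrate set with random phosphosites and measure the relative
  activity change |(Act^u - Act^p) / Act^u|.
* **Method comparison** — a mean-based KSEA z-score baseline, top-k-hit
  over perturbation experiments, and rank differences between methods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import AbundanceMatrix, Interactome, ValidatedInteractionSet
from .network import ScoreMatrix, build_pair_universe, derive_sops, train_sphinks
from .preprocess import filter_and_impute

logger = logging.getLogger("sphinks")


@dataclass
class CvResult:
    fold: int
    auc: float
    n_pos_test: int
    n_neg_test: int


def simulate_missingness(phospho: AbundanceMatrix, ratio: float, seed: int = 0) -> AbundanceMatrix:
    """Mask entries in ``ceil(ratio * n_sites)`` randomly chosen sites.

    Each hit site receives a per-site missing fraction drawn uniformly in
    (0, 0.5) applied to a random subset of its samples. Deterministic given
    the seed; a ratio of 0 returns the matrix unchanged.
    """
    if ratio == 0:
        return phospho.copy()
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    if phospho.data.isna().to_numpy().any():
        raise ValueError("simulate_missingness expects a complete matrix")
    rng = np.random.default_rng(seed)
    n_sites, n_samples = phospho.data.shape
    n_hit = math.ceil(ratio * n_sites)
    hit = rng.choice(n_sites, size=n_hit, replace=False)
    data = phospho.data.copy()
    vals = data.to_numpy()
    for i in hit:
        frac = rng.uniform(0.0, 0.5)
        n_mask = max(1, int(round(frac * n_samples)))
        n_mask = min(n_mask, n_samples - 1)  # keep every site partially observed
        cols = rng.choice(n_samples, size=n_mask, replace=False)
        vals[i, cols] = np.nan
    return AbundanceMatrix(pd.DataFrame(vals, index=data.index, columns=data.columns),
                           scale=phospho.scale, normalized=phospho.normalized)


def imputation_benchmark(
    phospho_complete: AbundanceMatrix,
    proteome: AbundanceMatrix,
    prior: ValidatedInteractionSet,
    kinase_list,
    ratios=(0.10, 0.25, 0.50),
    seed: int = 0,
    n_bags: int = 25,
    impute_method: str = "knn",
    spearman_filter: bool = True,
) -> pd.Series:
    """AUC of the degraded-then-imputed network against the pristine one.

    The gold standard is SOPS edge membership from the complete matrix;
    each ratio's degraded matrix is imputed, rescored and its scores ranked
    against gold membership over the shared pair universe.
    """
    pairs_gold = build_pair_universe(proteome, phospho_complete, kinase_list, prior)
    scores_gold = train_sphinks(pairs_gold, n_bags=n_bags, seed=seed)
    net_gold = derive_sops(scores_gold, prior, proteome, phospho_complete,
                           spearman_filter=spearman_filter)
    gold_edges = set(zip(net_gold.edges["kinase"], net_gold.edges["phosphosite"]))
    aucs = {}
    for r_i, r in enumerate(ratios):
        degraded = simulate_missingness(phospho_complete, r, seed=seed + 1000 + r_i)
        imputed = filter_and_impute(degraded, max_missing_fraction=0.5,
                                    method=impute_method, seed=seed)
        pairs_r = build_pair_universe(proteome, imputed, kinase_list, prior)
        scores_r = train_sphinks(pairs_r, n_bags=n_bags, seed=seed)
        flat = scores_r.scores.stack()
        y_true = np.array([(k, s) in gold_edges for k, s in flat.index])
        if y_true.all() or not y_true.any():
            raise ValueError("degenerate gold standard: all or no pairs are edges")
        aucs[r] = float(roc_auc_score(y_true, flat.to_numpy()))
        logger.info("imputation_benchmark: r=%.2f AUC=%.4f", r, aucs[r])
    return pd.Series(aucs, name="auc")


def crossvalidate(
    prior: ValidatedInteractionSet,
    proteome: AbundanceMatrix,
    phospho: AbundanceMatrix,
    kinase_list,
    k_folds: int = 10,
    n_bags: int = 100,
    seed: int = 0,
    kernel: str = "rbf",
) -> list[CvResult]:
    """Tenfold CV of edge prediction on the validated prior.

    Validated pairs are split into folds; per fold the bagged classifier is
    trained on the other folds' positives plus sampled negatives, and
    tested on the held-out positives against an equal number of unlabeled
    pairs kept disjoint from every training negative.
    """
    pairs = build_pair_universe(proteome, phospho, kinase_list, prior)
    pos_idx = np.flatnonzero(pairs.positive)
    unl_idx = np.flatnonzero(~pairs.positive)
    if pos_idx.size < 2 * k_folds:
        raise ValueError(f"need >= {2 * k_folds} quantified validated pairs, "
                         f"found {pos_idx.size}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pos_idx)
    folds = np.array_split(perm, k_folds)
    results: list[CvResult] = []
    from .network import _fit_one_bag

    for f, test_pos in enumerate(folds):
        if test_pos.size == 0:
            raise ValueError(f"fold {f + 1} has no positives")
        train_pos = np.setdiff1d(pos_idx, test_pos)
        frng = np.random.default_rng(seed + 10_000 + f)
        test_neg = frng.choice(unl_idx, size=test_pos.size, replace=False)
        trainable_unl = np.setdiff1d(unl_idx, test_neg)  # test negatives never train
        test_idx = np.concatenate([test_pos, test_neg])
        y_test = np.concatenate([np.ones(test_pos.size), np.zeros(test_neg.size)])
        total = np.zeros(test_idx.size)
        for b in range(n_bags):
            brng = np.random.default_rng(seed + 10_000 + f * 1000 + b + 1)
            n_neg = min(train_pos.size, trainable_unl.size)
            neg = brng.choice(trainable_unl, size=n_neg, replace=False)
            train_idx = np.concatenate([train_pos, neg])
            y_train = np.concatenate([np.ones(train_pos.size), np.zeros(neg.size)])
            clf = _fit_one_bag(pairs.X[train_idx], y_train, kernel)
            total += clf.predict_proba_positive(pairs.X[test_idx])
        auc = float(roc_auc_score(y_test, total / n_bags))
        results.append(CvResult(f + 1, auc, int(test_pos.size), int(test_neg.size)))
        logger.info("crossvalidate: fold %d AUC=%.4f", f + 1, auc)
    return results


def perturb_interactome(
    net: Interactome,
    scores: ScoreMatrix,
    percentage: float,
    seed: int = 0,
    pooled: bool = False,
) -> Interactome:
    """Replace each kinase's bottom-scoring substrates with random sites.

    The ``floor(percentage * |SOPS|)`` lowest-score members (at least one
    when the percentage is positive) are swapped for uniformly drawn
    non-SOPS phosphosites, which inherit the score matrix's value for the
    new pair; SOPS sizes are preserved. ``pooled`` applies the bottom
    fraction over the pooled edge list instead of per kinase.
    """
    if percentage == 0:
        return Interactome(net.edges.copy(), tau=net.tau)
    if not (0 < percentage < 1):
        raise ValueError("percentage must be in (0, 1)")
    if len(net) == 0:
        raise ValueError("cannot perturb an empty interactome")
    rng = np.random.default_rng(seed)
    all_sites = list(scores.scores.columns)
    edges = net.edges.copy()
    if pooled:
        n_repl = max(1, math.floor(percentage * len(edges)))
        to_replace = edges.nsmallest(n_repl, "sphinks_score").index
    else:
        to_replace = []
        for kinase, grp in edges.groupby("kinase"):
            n_repl = max(1, math.floor(percentage * len(grp)))
            to_replace.extend(grp.nsmallest(n_repl, "sphinks_score").index)
        to_replace = pd.Index(to_replace)
    # replacements are drawn outside the kinase's original SOPS and are
    # distinct from each other, so exactly |to_replace| members change
    for kinase, grp_idx in pd.Series(to_replace).groupby(
            edges.loc[to_replace, "kinase"].to_numpy()):
        original = set(net.edges.loc[net.edges["kinase"] == kinase, "phosphosite"])
        pool = [s for s in all_sites if s not in original]
        if len(pool) < len(grp_idx):
            raise ValueError(f"no replacement phosphosites available for {kinase}")
        new_sites = rng.choice(pool, size=len(grp_idx), replace=False)
        for idx, new_site in zip(grp_idx, new_sites):
            new_site = str(new_site)
            edges.at[idx, "phosphosite"] = new_site
            edges.at[idx, "sphinks_score"] = scores.score(kinase, new_site)
            edges.at[idx, "spearman_rho"] = np.nan
            edges.at[idx, "validated"] = 0
    return Interactome(edges, tau=net.tau)


@dataclass
class PerturbationResult:
    percentage: float
    per_kinase: pd.Series  # kinase -> ΔAct (median over samples)
    median_over_kinases: float
    n_excluded: int


def delta_activity(
    act_u: pd.DataFrame,
    act_p: pd.DataFrame,
    percentage: float = float("nan"),
    epsilon: float | None = None,
) -> PerturbationResult:
    """Relative activity change |(Act^u - Act^p) / Act^u| per kinase.

    The ratio is taken per kinase per sample and summarized as the median
    over samples, then the median over kinases. Entries with
    |Act^u| < epsilon are excluded (the ratio is undefined near zero);
    epsilon defaults to 1e-3 of the unperturbed matrix's interquartile
    range.
    """
    if act_u.shape != act_p.shape or list(act_u.index) != list(act_p.index) \
            or list(act_u.columns) != list(act_p.columns):
        raise ValueError("activity matrices must share kinases and samples")
    u = act_u.to_numpy(dtype=float)
    p = act_p.to_numpy(dtype=float)
    if epsilon is None:
        q75, q25 = np.nanpercentile(u, [75, 25])
        epsilon = 1e-3 * max(q75 - q25, 1e-12)
    valid = np.abs(u) >= epsilon
    rel = np.full_like(u, np.nan)
    rel[valid] = np.abs((u[valid] - p[valid]) / u[valid])
    per_kinase = pd.Series(np.nanmedian(rel, axis=1), index=act_u.index, name="delta_act")
    return PerturbationResult(
        percentage=percentage,
        per_kinase=per_kinase,
        median_over_kinases=float(np.nanmedian(per_kinase.to_numpy())),
        n_excluded=int((~valid).sum()),
    )


def ksea_zscore(phospho_contrast: pd.Series, substrate_sets: dict[str, set]) -> pd.Series:
    """Mean-based KSEA z-score per kinase.

    z = (mean_set - mean_all) * sqrt(m) / sd_all over the site-level
    contrast values (e.g. mean log2 differences), with m the number of the
    kinase's substrates quantified in the contrast.
    """
    vals = phospho_contrast.astype(float)
    mean_all = float(vals.mean())
    sd_all = float(vals.std(ddof=1))
    if sd_all == 0 or not np.isfinite(sd_all):
        raise ValueError("contrast has zero variance; z-score undefined")
    out = {}
    for kinase, sites in substrate_sets.items():
        present = [s for s in sites if s in vals.index]
        if not present:
            continue
        m = len(present)
        out[kinase] = (float(vals.loc[present].mean()) - mean_all) * math.sqrt(m) / sd_all
    if not out:
        raise ValueError("no substrate set overlaps the contrast universe")
    return pd.Series(out, name="ksea_z")


def top_k_hit(experiments: list[tuple[pd.Series, str]], k: int = 10) -> float:
    """Fraction of perturbation experiments whose true kinase ranks <= k.

    Each experiment is (kinase -> rank, perturbed kinase); experiments
    whose perturbed kinase is absent from the ranking are skipped with a
    warning.
    """
    hits, n = 0, 0
    for ranking, perturbed in experiments:
        if perturbed not in ranking.index:
            logger.warning("top_k_hit: %s absent from ranking; experiment skipped", perturbed)
            continue
        n += 1
        if ranking.loc[perturbed] <= k:
            hits += 1
    if n == 0:
        raise ValueError("no usable experiments")
    return hits / n


def delta_rank(rank_a: pd.Series, rank_b: pd.Series) -> pd.Series:
    """Per-kinase rank difference (method A minus method B) on the shared set.

    Negative values mean method A ranks the kinase higher (more active)."""
    shared = rank_a.index.intersection(rank_b.index)
    if shared.empty:
        raise ValueError("no shared kinases between rankings")
    return (rank_a.loc[shared] - rank_b.loc[shared]).astype(int).rename("delta_rank")
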