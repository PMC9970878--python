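"""The SPHINKS core: positive-unlabeled, bagged max-margin scoring of
kinase-phosphosite pairs and derivation of each kinase's substrate set.

Every candidate pair (kinase, phosphosite) is described by the kinase's
protein abundance profile concatenated with the site's phospho abundance
profile across the cohort. Pairs present in the validated prior are the
positive class; everything else is unlabeled. Training follows the
easyensemble principle for extreme class imbalance: each bag keeps the full
positive set and draws a fresh balanced sample of "negatives" from the
unlabeled pool, fits an SVM with Platt-calibrated probabilities, and scores
the whole universe; the SPHINKS score of a pair is the mean calibrated
probability across bags — the estimated probability that the phosphosite is
a substrate of the kinase.

The interactome keeps, per kinase, the pairs whose score clears a global
threshold chosen so that at least half of the validated interactions are
retained, and whose kinase-site Spearman correlation is positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .io import AbundanceMatrix, Interactome, ValidatedInteractionSet

logger = logging.getLogger("sphinks")


@dataclass
class PairFeatureMatrix:
    """Feature rows for every candidate kinase-phosphosite pair.

    ``X`` has one row per pair and ``2 * n_samples`` columns (kinase
    protein profile, then site phospho profile), z-scored per column over
    the whole universe. ``positive`` marks pairs found in the validated
    prior; the rest are unlabeled.
    """

    pair_ids: list[tuple[str, str]]
    X: np.ndarray
    positive: np.ndarray  # bool per pair
    kinases: list[str]
    phosphosites: list[str]
    sample_ids: list[str]
    column_means: np.ndarray = field(repr=False, default=None)
    column_sds: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.pair_ids)

    @property
    def n_positive(self) -> int:
        return int(self.positive.sum())


@dataclass
class ScoreMatrix:
    """Kinase x phosphosite matrix of SPHINKS scores in [0, 1]."""

    scores: pd.DataFrame
    n_bags: int
    seed: int

    def __post_init__(self) -> None:
        v = self.scores.to_numpy()
        if len(v) and (np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12):
            raise ValueError("SPHINKS scores must lie in [0, 1]")

    def score(self, kinase: str, site: str) -> float:
        return float(self.scores.at[kinase, site])


def build_pair_universe(
    proteome: AbundanceMatrix,
    phospho: AbundanceMatrix,
    kinase_list,
    prior: ValidatedInteractionSet,
) -> PairFeatureMatrix:
    """Assemble the universe of all kinase x phosphosite candidate pairs.

    Kinases must be quantified in the proteome; all phosphosites in the
    phospho matrix enter the universe. Prior pairs not quantified in the
    data are dropped from the positive set and counted in a coverage log
    line. Feature columns are z-scored once over the full universe so all
    pairs live on one scale.
    """
    kinases = sorted(set(kinase_list))
    missing_k = [k for k in kinases if k not in set(proteome.features)]
    if missing_k:
        raise ValueError(f"kinases absent from proteome: {missing_k}")
    shared = [s for s in proteome.samples if s in set(phospho.samples)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples between proteome and phospho")
    if proteome.data[shared].isna().to_numpy().any() or phospho.data[shared].isna().to_numpy().any():
        raise ValueError("pair universe requires complete matrices; impute first")
    sites = list(phospho.features)
    kin_mat = proteome.data.loc[kinases, shared].to_numpy(dtype=float)
    site_mat = phospho.data.loc[sites, shared].to_numpy(dtype=float)
    n_k, n_s, n_c = len(kinases), len(sites), len(shared)

    pair_ids = [(k, s) for k in kinases for s in sites]
    X = np.empty((n_k * n_s, 2 * n_c), dtype=float)
    X[:, :n_c] = np.repeat(kin_mat, n_s, axis=0)
    X[:, n_c:] = np.tile(site_mat, (n_k, 1))

    site_set = set(sites)
    quantified = {(k, s) for k, s in prior.pairs if k in set(kinases) and s in site_set}
    unquantified = len(prior.pairs) - len(quantified)
    if unquantified:
        logger.info("build_pair_universe: %d/%d prior pairs not quantified in the data",
                    unquantified, len(prior.pairs))
    positive = np.array([pid in quantified for pid in pair_ids], dtype=bool)
    kin_with_pos = {k for k, _ in quantified}
    if len(kin_with_pos) < 2:
        raise ValueError("insufficient positive training data: prior covers "
                         f"{len(kin_with_pos)} kinase(s) with quantified positives")

    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds_safe = np.where(sds > 1e-12, sds, 1.0)
    X = (X - means) / sds_safe
    logger.info("build_pair_universe: %d pairs (%d positive, %d unlabeled)",
                len(pair_ids), int(positive.sum()), int((~positive).sum()))
    return PairFeatureMatrix(pair_ids, X, positive, kinases, sites, shared, means, sds)


class _CalibratedSvm:
    """Max-margin classifier with Platt-style sigmoid calibration.

    An SVC is fit on the bag's training set and a logistic model maps its
    decision values to probabilities (calibration fit on the same training
    data). Deterministic given the inputs.
    """

    def __init__(self, kernel: str = "rbf", C: float = 1.5):
        self.svm = SVC(kernel=kernel, C=C)
        self.platt = LogisticRegression(C=1e3)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_CalibratedSvm":
        self.svm.fit(X, y)
        d = self.svm.decision_function(X).reshape(-1, 1)
        self.platt.fit(d, y)
        return self

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        d = self.svm.decision_function(X).reshape(-1, 1)
        pos_col = int(np.flatnonzero(self.platt.classes_ == 1.0)[0])
        return self.platt.predict_proba(d)[:, pos_col]


def _fit_one_bag(X_train: np.ndarray, y_train: np.ndarray, kernel: str,
                 C: float = 1.5) -> _CalibratedSvm:
    return _CalibratedSvm(kernel, C).fit(X_train, y_train)


def train_sphinks(
    pairs: PairFeatureMatrix,
    n_bags: int = 100,
    neg_per_pos: float = 1.0,
    seed: int = 0,
    kernel: str = "rbf",
    svm_c: float = 1.5,
) -> ScoreMatrix:
    """Score every candidate pair by a bagged PU ensemble of calibrated SVMs.

    Each bag keeps all positives and draws ``ceil(neg_per_pos * n_pos)``
    unlabeled pairs without replacement as that bag's negatives (seeded by
    ``seed + bag``); a max-margin classifier with sigmoid probability
    calibration is fit and the whole universe scored. The SPHINKS score is
    the across-bag mean calibrated probability, in [0, 1]. Deterministic
    given inputs and seed.
    """
    if n_bags < 1:
        raise ValueError("n_bags must be >= 1")
    n_pos = pairs.n_positive
    if n_pos < 10:
        raise ValueError(f"need >= 10 positive pairs, found {n_pos}")
    pos_idx = np.flatnonzero(pairs.positive)
    unl_idx = np.flatnonzero(~pairs.positive)
    n_neg = math.ceil(neg_per_pos * n_pos)
    if n_neg > unl_idx.size:
        logger.warning("train_sphinks: only %d unlabeled pairs for %d requested negatives",
                       unl_idx.size, n_neg)
        n_neg = unl_idx.size
    total = np.zeros(len(pairs))
    informative = pairs.X.std(axis=0).max() > 1e-12
    for b in range(n_bags):
        rng = np.random.default_rng(seed + b)
        neg = rng.choice(unl_idx, size=n_neg, replace=False)
        train_idx = np.concatenate([pos_idx, neg])
        y = np.concatenate([np.ones(pos_idx.size), np.zeros(neg.size)])
        if not informative:
            # degenerate constant features: every pair gets the training prevalence
            total += pos_idx.size / train_idx.size
            continue
        clf = _fit_one_bag(pairs.X[train_idx], y, kernel, svm_c)
        total += clf.predict_proba_positive(pairs.X)
    mean_scores = np.clip(total / n_bags, 0.0, 1.0)
    mat = pd.DataFrame(
        mean_scores.reshape(len(pairs.kinases), len(pairs.phosphosites)),
        index=pairs.kinases,
        columns=pairs.phosphosites,
    )
    return ScoreMatrix(mat, n_bags=n_bags, seed=seed)


def retention_threshold(validated_scores: np.ndarray, min_retained: float = 0.5) -> float:
    """Largest candidate threshold keeping >= ``min_retained`` of validated scores.

    Candidates are the validated scores themselves (retention uses score >=
    threshold, so ties at the threshold are retained).
    """
    v = np.asarray(validated_scores, dtype=float)
    if v.size == 0:
        raise ValueError("no validated pairs scored; cannot set a threshold")
    for tau in np.sort(np.unique(v))[::-1]:
        if np.mean(v >= tau) >= min_retained:
            return float(tau)
    return float(v.min())  # unreachable: the minimum always retains all


def _spearman_matrix(kin: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlations between kinase and site profiles."""
    kr = np.apply_along_axis(rankdata, 1, kin)
    sr = np.apply_along_axis(rankdata, 1, sites)
    kr = kr - kr.mean(axis=1, keepdims=True)
    sr = sr - sr.mean(axis=1, keepdims=True)
    kn = np.linalg.norm(kr, axis=1)
    sn = np.linalg.norm(sr, axis=1)
    kn[kn == 0] = np.inf  # constant profile: correlation treated as 0
    sn[sn == 0] = np.inf
    return (kr / kn[:, None]) @ (sr / sn[:, None]).T


def derive_sops(
    scores: ScoreMatrix,
    prior: ValidatedInteractionSet,
    proteome: AbundanceMatrix,
    phospho: AbundanceMatrix,
    min_retained: float = 0.5,
    per_kinase_threshold: bool = False,
    spearman_filter: bool = True,
) -> Interactome:
    """Threshold scores into per-kinase substrate sets (SOPS).

    The global threshold tau is the highest score retaining at least
    ``min_retained`` of the validated pairs quantified in the score matrix;
    edges additionally require a positive Spearman correlation between the
    kinase's protein profile and the site's phospho profile (disable with
    ``spearman_filter=False``). A per-kinase threshold variant is available
    behind ``per_kinase_threshold``.
    """
    kinases = list(scores.scores.index)
    sites = list(scores.scores.columns)
    site_pos = {s: j for j, s in enumerate(sites)}
    kin_pos = {k: i for i, k in enumerate(kinases)}
    validated = [(k, s) for k, s in prior.pairs if k in kin_pos and s in site_pos]
    if not validated:
        raise ValueError("no validated pairs scored; cannot derive SOPS")
    smat = scores.scores.to_numpy()
    vscores = np.array([smat[kin_pos[k], site_pos[s]] for k, s in validated])
    tau = retention_threshold(vscores, min_retained)

    shared = [s for s in proteome.samples if s in set(phospho.samples)]
    rho = _spearman_matrix(
        proteome.data.loc[kinases, shared].to_numpy(dtype=float),
        phospho.data.loc[sites, shared].to_numpy(dtype=float),
    )
    validated_set = set(validated)
    records = []
    for k in kinases:
        i = kin_pos[k]
        if per_kinase_threshold:
            vk = np.array([smat[i, site_pos[s]] for kk, s in validated if kk == k])
            tau_k = retention_threshold(vk, min_retained) if vk.size else tau
        else:
            tau_k = tau
        keep = smat[i] >= tau_k
        if spearman_filter:
            keep &= rho[i] > 0
        for j in np.flatnonzero(keep):
            records.append((k, sites[j], smat[i, j], rho[i, j],
                            int((k, sites[j]) in validated_set)))
    edges = pd.DataFrame(records, columns=Interactome._COLS)
    net = Interactome(edges, tau=tau)
    logger.info("derive_sops: tau=%.4f, %d edges across %d kinases",
                tau, len(net), len(net.kinases))
    return net
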