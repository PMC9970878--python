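"""Single-sample master-kinase activity and subtype-specific kinase tables.

A kinase's activity in a sample contrasts the score-weighted mean abundance
of its predicted substrates (SOPS) against the score-weighted mean of
abundance-matched control phosphosites:

    Act(X_i, K) = sum_k(w_sk * t_sk,i) / sum_k(w_sk)
                - sum_j(w_cj * t_cj,i) / sum_j(w_cj)

where w are SPHINKS scores and t log2 abundances. Controls are drawn from
the substrate's abundance bin (25 quantile bins on the per-site mean across
samples, 100 controls per substrate), so the control set matches the SOPS
abundance distribution while being 100-fold larger. Positive Act means the
substrate program is elevated over its abundance-matched background —
the kinase is active in that sample.

Master kinases of a subtype are kinases whose activity is significantly
higher in that subtype than in the rest of the cohort (MWW test, effect
size and p-value thresholds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, Interactome
from .mww import mww_test
from .network import ScoreMatrix

logger = logging.getLogger("sphinks")


@dataclass
class BinAssignment:
    """Quantile bin of every phosphosite on mean abundance across samples."""

    bins: pd.Series  # site -> bin index (1-based)
    boundaries: np.ndarray  # (n_bins, 2) [min_mean, max_mean] per bin

    @property
    def n_bins(self) -> int:
        return int(self.bins.max())

    def members(self, bin_index: int) -> list[str]:
        return list(self.bins.index[self.bins == bin_index])


@dataclass
class ControlAssignment:
    """Per (kinase, substrate): the drawn control phosphosites.

    ``controls[(kinase, substrate)]`` is the list of control site ids
    (length ``n_controls``); ``with_replacement`` flags substrates whose
    eligible pool was smaller than ``n_controls``.
    """

    controls: dict[tuple[str, str], list[str]]
    n_controls: int
    seed: int
    with_replacement: set[tuple[str, str]]


def bin_substrates(phospho: AbundanceMatrix, n_bins: int = 25) -> BinAssignment:
    """Quantile (equal-count) binning of sites on mean abundance.

    Bin sizes differ by at most one; ties and the within-bin split are
    broken stably by feature order.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if phospho.data.isna().to_numpy().any():
        raise ValueError("binning requires a complete matrix; impute first")
    means = phospho.data.mean(axis=1)
    n_bins = min(n_bins, len(means))
    order = np.argsort(means.to_numpy(), kind="stable")
    assignment = np.empty(len(means), dtype=int)
    chunks = np.array_split(order, n_bins)
    bounds = np.empty((n_bins, 2))
    for b, chunk in enumerate(chunks, start=1):
        assignment[chunk] = b
        bounds[b - 1] = (means.iloc[chunk].min(), means.iloc[chunk].max())
    return BinAssignment(pd.Series(assignment, index=means.index, name="bin"), bounds)


def draw_controls(
    net: Interactome,
    bins: BinAssignment,
    n_controls: int = 100,
    seed: int = 0,
    exclude_own_sops: bool = True,
) -> ControlAssignment:
    """Draw abundance-matched control sites for every SOPS substrate.

    Controls come from the substrate's bin; the kinase's own SOPS members
    are excluded from the pool (so the contrast is not diluted by the
    program itself). If the eligible pool is smaller than ``n_controls``
    the draw falls back to with-replacement and the substrate is flagged.
    One draw is made per cohort and reused across samples. Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    controls: dict[tuple[str, str], list[str]] = {}
    flagged: set[tuple[str, str]] = set()
    binned = set(bins.bins.index)
    for kinase in net.kinases:
        sops_sites = list(net.sops(kinase)["phosphosite"])
        sops_set = set(sops_sites) if exclude_own_sops else set()
        for site in sops_sites:
            if site not in binned:
                raise ValueError(f"SOPS site {site} has no abundance bin")
            pool = [c for c in bins.members(int(bins.bins[site])) if c not in sops_set]
            if not pool:
                raise ValueError(
                    f"empty control pool in bin {int(bins.bins[site])} for {kinase}/{site}"
                )
            if len(pool) >= n_controls:
                drawn = rng.choice(pool, size=n_controls, replace=False)
            else:
                drawn = rng.choice(pool, size=n_controls, replace=True)
                flagged.add((kinase, site))
            controls[(kinase, site)] = [str(c) for c in drawn]
    if flagged:
        logger.warning("draw_controls: %d substrates used with-replacement pools", len(flagged))
    return ControlAssignment(controls, n_controls, seed, flagged)


def mk_activity(
    sample: str,
    kinase: str,
    net: Interactome,
    phospho: AbundanceMatrix,
    controls: ControlAssignment,
    scores: ScoreMatrix,
    min_sops: int = 3,
) -> float:
    """Activity of one kinase in one sample: weighted substrate mean minus
    weighted control mean (weights = SPHINKS scores)."""
    sops = net.sops(kinase)
    if len(sops) < min_sops:
        raise ValueError(f"{kinase}: |SOPS|={len(sops)} below minimum {min_sops}")
    col = phospho.data[sample]
    w_s = sops["sphinks_score"].to_numpy(dtype=float)
    t_s = col.loc[sops["phosphosite"]].to_numpy(dtype=float)
    if w_s.sum() <= 0:
        raise ValueError(f"{kinase}: zero total substrate weight")
    c_sites: list[str] = []
    for site in sops["phosphosite"]:
        c_sites.extend(controls.controls[(kinase, site)])
    w_c = scores.scores.loc[kinase, c_sites].to_numpy(dtype=float)
    t_c = col.loc[c_sites].to_numpy(dtype=float)
    if w_c.sum() <= 0:
        raise ValueError(f"{kinase}: zero total control weight")
    return float((w_s @ t_s) / w_s.sum() - (w_c @ t_c) / w_c.sum())


def activity_matrix(
    net: Interactome,
    phospho: AbundanceMatrix,
    controls: ControlAssignment,
    scores: ScoreMatrix,
    min_sops: int = 3,
) -> pd.DataFrame:
    """Kinase x sample activity matrix; kinases with |SOPS| below
    ``min_sops`` are skipped with a warning."""
    if len(net) == 0:
        logger.warning("activity_matrix: empty interactome")
        return pd.DataFrame(columns=phospho.samples)
    rows = {}
    for kinase in net.kinases:
        sops = net.sops(kinase)
        if len(sops) < min_sops:
            logger.warning("activity_matrix: %s skipped (|SOPS|=%d < %d)",
                           kinase, len(sops), min_sops)
            continue
        # vectorized over samples: same weights, per-sample abundances
        w_s = sops["sphinks_score"].to_numpy(dtype=float)
        t_s = phospho.data.loc[sops["phosphosite"]].to_numpy(dtype=float)
        c_sites: list[str] = []
        for site in sops["phosphosite"]:
            c_sites.extend(controls.controls[(kinase, site)])
        w_c = scores.scores.loc[kinase, c_sites].to_numpy(dtype=float)
        t_c = phospho.data.loc[c_sites].to_numpy(dtype=float)
        rows[kinase] = (w_s @ t_s) / w_s.sum() - (w_c @ t_c) / w_c.sum()
    return pd.DataFrame(rows, index=phospho.samples).T


def subtype_master_kinases(
    act: pd.DataFrame,
    labels: pd.Series,
    effect_min: float = 0.3,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Kinases with significantly elevated activity in one subtype vs the rest.

    For each (kinase, subtype), the subtype's activities are tested against
    all other samples with the two-sided MWW test; rows passing
    ``effect_size > effect_min`` and ``p < p_max`` with positive shift are
    kept and ranked per subtype by mww_score descending (ties broken by
    p ascending, then kinase name).
    """
    labeled = [s for s in act.columns if s in labels.index]
    dropped = set(act.columns) - set(labeled)
    if dropped:
        logger.warning("subtype_master_kinases: %d unlabeled samples excluded", len(dropped))
    lab = labels.loc[labeled]
    subtypes = sorted(lab.unique())
    if len(subtypes) < 2:
        raise ValueError("need >= 2 subtypes")
    counts = lab.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"subtypes with < 3 samples: {list(small.index)}")
    rows = []
    for subtype in subtypes:
        in_s = [s for s in labeled if lab[s] == subtype]
        out_s = [s for s in labeled if lab[s] != subtype]
        for kinase in act.index:
            r = mww_test(act.loc[kinase, in_s].to_numpy(), act.loc[kinase, out_s].to_numpy())
            if r.effect_size > effect_min and r.p_value < p_max and r.prob_superiority > 0.5:
                rows.append((kinase, subtype, r.effect_size, r.p_value, r.mww_score,
                             float(np.mean(act.loc[kinase, in_s]) - np.mean(act.loc[kinase, out_s]))))
    table = pd.DataFrame(
        rows, columns=["kinase", "subtype", "effect_size", "p_value", "mww_score", "mean_diff"]
    )
    if table.empty:
        table["rank"] = pd.Series(dtype=int)
        return table
    table = table.sort_values(
        ["subtype", "mww_score", "p_value", "kinase"],
        ascending=[True, False, True, True],
    ).reset_index(drop=True)
    table["rank"] = table.groupby("subtype").cumcount() + 1
    return table
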