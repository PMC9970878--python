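"""End-to-end convenience pipeline: matrices + prior -> network ->
activities -> subtype master-kinase table."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .activity import (
    BinAssignment,
    ControlAssignment,
    activity_matrix,
    bin_substrates,
    draw_controls,
    subtype_master_kinases,
)
from .io import AbundanceMatrix, Interactome, ValidatedInteractionSet
from .network import ScoreMatrix, build_pair_universe, derive_sops, train_sphinks


@dataclass
class PipelineResult:
    scores: ScoreMatrix
    network: Interactome
    bins: BinAssignment
    controls: ControlAssignment
    activities: pd.DataFrame
    master_kinases: pd.DataFrame | None


def run_pipeline(
    proteome: AbundanceMatrix,
    phospho: AbundanceMatrix,
    prior: ValidatedInteractionSet,
    kinase_list,
    labels: pd.Series | None = None,
    n_bags: int = 100,
    n_controls: int = 100,
    n_bins: int = 25,
    min_sops: int = 3,
    effect_min: float = 0.3,
    p_max: float = 0.01,
    seed: int = 0,
) -> PipelineResult:
    """Run scoring, SOPS derivation, activity estimation and (when labels
    are given) master-kinase selection in one seeded pass."""
    pairs = build_pair_universe(proteome, phospho, kinase_list, prior)
    scores = train_sphinks(pairs, n_bags=n_bags, seed=seed)
    net = derive_sops(scores, prior, proteome, phospho)
    bins = bin_substrates(phospho, n_bins=n_bins)
    controls = draw_controls(net, bins, n_controls=n_controls, seed=seed)
    act = activity_matrix(net, phospho, controls, scores, min_sops=min_sops)
    mk = None
    if labels is not None and not act.empty:
        mk = subtype_master_kinases(act, labels, effect_min=effect_min, p_max=p_max)
    return PipelineResult(scores, net, bins, controls, act, mk)
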