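"""Seeded synthetic proteome/phospho-proteome cohorts with planted truth.

The generator emulates the statistical structure the network-inference
method relies on: kinase protein abundance varies across samples; each
planted substrate's phospho abundance tracks its kinase linearly on the
log2 scale (slope ``edge_effect``) plus Gaussian noise; non-substrate sites
are independent noise of comparable variance. A shared per-sample offset
induces sample-to-sample correlation, as in label-based proteomics. One
kinase per subtype carries a planted program: its substrates gain
``subtype_shift`` log2 units in that subtype's samples. A fraction of the
planted edges is revealed as the "validated" prior; the rest stay hidden
and must be recovered. Missing values, when requested, are introduced
preferentially at low abundance (logistic in abundance), mimicking
mass-spectrometry left-censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, PhosphositeID, ValidatedInteractionSet


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of one synthetic cohort.

    Abundances are on the log2 scale throughout; ``edge_effect`` is the
    log2/log2 slope of a substrate on its kinase, ``noise_sd`` the residual
    site noise, ``subtype_shift`` the log2 activation added to a planted
    kinase's substrate program in its own subtype.
    """

    n_samples: int = 60
    n_kinases: int = 20
    n_phosphosites: int = 800
    n_subtypes: int = 4
    substrates_per_kinase: int = 20
    edge_effect: float = 0.8
    noise_sd: float = 0.5
    subtype_shift: float = 1.5
    prior_reveal_fraction: float = 0.5
    missing_rate: float = 0.0
    sample_effect_sd: float = 0.3
    heavy_tailed_noise: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_kinases", "n_phosphosites", "n_subtypes",
                     "substrates_per_kinase"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.prior_reveal_fraction <= 1):
            raise ValueError("prior_reveal_fraction must be in (0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.substrates_per_kinase * self.n_kinases > self.n_phosphosites:
            raise ValueError("substrates_per_kinase * n_kinases exceeds n_phosphosites")
        if self.n_subtypes > self.n_samples // 3:
            raise ValueError("need >= 3 samples per subtype")
        if self.n_subtypes > self.n_kinases:
            raise ValueError("need at least one kinase per subtype")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    planted_edges: frozenset[tuple[str, str]]
    planted_subtype_kinases: dict[str, str]  # kinase -> subtype
    revealed_prior: ValidatedInteractionSet
    spec: CohortSpec = field(repr=False, default=None)


def _noise(rng: np.random.Generator, sd: float, size, heavy: bool) -> np.ndarray:
    if heavy:
        # Student-t (df=4) scaled to the requested sd
        return rng.standard_t(4, size=size) * sd / np.sqrt(2.0)
    return rng.normal(0.0, sd, size=size)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[AbundanceMatrix, AbundanceMatrix, pd.Series, SyntheticTruth]:
    """Generate (proteome, phospho, subtype labels, truth) for one cohort.

    Fully determined by ``spec.seed``: repeated calls with the same spec
    return bit-identical matrices.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    samples = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    kinases = [f"KIN{i + 1:02d}" for i in range(spec.n_kinases)]
    genes = rng.permutation([f"G{i + 1:04d}" for i in range(spec.n_phosphosites)])
    residues = rng.choice(list("STY"), size=spec.n_phosphosites)
    positions = rng.integers(1, 1000, size=spec.n_phosphosites)
    sites = [str(PhosphositeID(g, r, int(p))) for g, r, p in zip(genes, residues, positions)]

    # subtype blocks, as even as possible
    block = np.array_split(np.arange(spec.n_samples), spec.n_subtypes)
    subtypes = [f"ST{j + 1}" for j in range(spec.n_subtypes)]
    label_arr = np.empty(spec.n_samples, dtype=object)
    for j, idx in enumerate(block):
        label_arr[idx] = subtypes[j]
    labels = pd.Series(label_arr, index=samples, name="subtype")

    sample_offset = rng.normal(0.0, spec.sample_effect_sd, size=spec.n_samples)
    kin_base = rng.normal(0.0, 1.0, size=spec.n_kinases)
    kin_mat = (kin_base[:, None] + sample_offset[None, :]
               + rng.normal(0.0, 1.0, size=(spec.n_kinases, spec.n_samples)))

    # planted subtype programs are kinase-mediated: the kinase is elevated in
    # its subtype and its substrates inherit exactly `subtype_shift` log2
    # units through the regulatory slope
    planted_subtype = {kinases[j]: subtypes[j] for j in range(spec.n_subtypes)}
    in_subtype = {kinases[j]: labels.to_numpy() == subtypes[j]
                  for j in range(spec.n_subtypes)}
    if spec.subtype_shift != 0 and spec.edge_effect > 0:
        for j in range(spec.n_subtypes):
            kin_mat[j] += (spec.subtype_shift / spec.edge_effect) * in_subtype[kinases[j]]

    # plant edges: disjoint substrate blocks per kinase
    chosen = rng.choice(spec.n_phosphosites,
                        size=spec.substrates_per_kinase * spec.n_kinases, replace=False)
    edge_of_site = {}  # site index -> kinase index
    planted = set()
    for ki, start in enumerate(range(0, chosen.size, spec.substrates_per_kinase)):
        for si in chosen[start:start + spec.substrates_per_kinase]:
            edge_of_site[int(si)] = ki
            planted.add((kinases[ki], sites[int(si)]))

    site_base = rng.normal(0.0, 1.0, size=spec.n_phosphosites)
    null_sd = float(np.hypot(spec.edge_effect, spec.noise_sd))
    phospho_mat = np.empty((spec.n_phosphosites, spec.n_samples))
    for si in range(spec.n_phosphosites):
        if si in edge_of_site:
            ki = edge_of_site[si]
            row = (site_base[si] + spec.edge_effect * kin_mat[ki]
                   + _noise(rng, spec.noise_sd, spec.n_samples, spec.heavy_tailed_noise))
            k_name = kinases[ki]
            if spec.edge_effect <= 0 and k_name in planted_subtype:
                # degenerate slope: apply the program shift to the sites directly
                row = row + spec.subtype_shift * in_subtype[k_name]
        else:
            row = (site_base[si] + sample_offset
                   + _noise(rng, null_sd, spec.n_samples, spec.heavy_tailed_noise))
        phospho_mat[si] = row

    if spec.missing_rate > 0:
        z = (phospho_mat - phospho_mat.mean()) / phospho_mat.std()
        w = 1.0 / (1.0 + np.exp(z))  # low abundance -> high weight
        p_miss = np.clip(spec.missing_rate * w / w.mean(), 0.0, 0.95)
        mask = rng.random(phospho_mat.shape) < p_miss
        # never censor a site completely
        full = mask.all(axis=1)
        mask[full, 0] = False
        phospho_mat = np.where(mask, np.nan, phospho_mat)

    # reveal a fixed fraction of each kinase's edges (stratified), emulating
    # a prior that covers every analysed kinase — studies restrict to
    # kinases with adequate validated substrate coverage
    revealed_list: list[tuple[str, str]] = []
    by_kinase: dict[str, list[tuple[str, str]]] = {}
    for edge in sorted(planted):
        by_kinase.setdefault(edge[0], []).append(edge)
    for k_name in sorted(by_kinase):
        k_edges = by_kinase[k_name]
        n_k = max(1, int(round(spec.prior_reveal_fraction * len(k_edges))))
        idx = rng.choice(len(k_edges), size=n_k, replace=False)
        revealed_list.extend(k_edges[i] for i in idx)
    revealed = frozenset(revealed_list)
    prior = ValidatedInteractionSet(revealed, source_tag=f"synthetic(seed={spec.seed})")

    proteome = AbundanceMatrix(pd.DataFrame(kin_mat, index=kinases, columns=samples),
                               scale="log2")
    phospho = AbundanceMatrix(pd.DataFrame(phospho_mat, index=sites, columns=samples),
                              scale="log2")
    truth = SyntheticTruth(frozenset(planted), planted_subtype, prior, spec)
    return proteome, phospho, labels, truth


def default_specs() -> dict[str, CohortSpec]:
    """Named presets: ``smoke`` (seconds, full pipeline), ``standard`` (the
    reference benchmark conditions) and ``hard`` (high noise, sparse prior)."""
    standard = CohortSpec()
    return {
        "smoke": replace(standard, n_samples=20, n_kinases=5, n_phosphosites=100,
                         n_subtypes=2, substrates_per_kinase=8),
        "standard": standard,
        "hard": replace(standard, noise_sd=1.5, prior_reveal_fraction=0.2),
    }
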