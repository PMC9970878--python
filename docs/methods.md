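# Methods

## Problem

Kinases drive signalling by phosphorylating specific residues on substrate
proteins, but which kinase phosphorylates which site is context-dependent
and only sparsely catalogued. Given a paired cohort — a proteome matrix
(kinase/protein × sample, log2 abundance) and a phospho-proteome matrix
(phosphosite × sample) — together with a curated set of validated
kinase–substrate pairs, the package infers a cohort-specific weighted
kinase–phosphosite interactome, derives each kinase's predicted substrate
set, scores per-sample kinase activity, and extracts the kinases whose
activity marks each tumor (or sample) subtype.

## Network inference (positive–unlabeled bagged SVMs)

Each candidate pair (kinase *k*, phosphosite *s*) is represented by the
concatenation of the kinase's protein profile and the site's phospho
profile across the shared samples (2·n features), z-scored per column over
the whole pair universe so every pair lives on one scale. Pairs present in
the validated prior are positives; all others are unlabeled — the
positive–unlabeled setting, with extreme imbalance.

Training follows the easyensemble principle: each of `n_bags` (default
100) bags keeps the full positive set and draws `⌈neg_per_pos·|P|⌉`
unlabeled pairs without replacement as that bag's provisional negatives
(default balanced, `neg_per_pos = 1`). A support-vector machine is fit per
bag and calibrated to probabilities with a Platt-style sigmoid (logistic
regression on the bag's training decision values). The score of a pair is
the mean calibrated probability across bags; averaging over many negative
draws washes out the contamination of any single negative sample by true
(unlabeled) substrates.

**Kernel and regularization.** The default is an RBF kernel with `C = 1.5`
(configurable, `kernel`/`svm_c`). A single global linear hyperplane over
concatenated profiles cannot express the coupling the problem needs — "is
the site's profile consistent with this kinase's profile?" is a relational
(bilinear) property, and with positives pooled across kinases a linear
model measurably under-performs (edge-recovery AUC ≈ 0.85 vs ≈ 0.98 on the
standard synthetic cohort). The margin penalty is deliberately moderate:
with large `C` the classifier separates its training positives almost
perfectly and every validated pair's score saturates near 1.0; the
substrate-set threshold (below) then cuts within numerical noise, and
whole kinases drop out of the network for reasons unrelated to signal.
`C = 1.5` keeps validated scores spread so the threshold cuts by signal.

**Substrate sets (SOPS).** The global threshold τ is the largest score
retaining at least 50 % of the validated pairs quantified in the matrix
(candidate thresholds are the validated scores themselves; retention uses
ω ≥ τ, so ties are kept). A kinase's SOPS is every site with ω ≥ τ whose
phospho profile has positive Spearman correlation with the kinase's
protein profile. A per-kinase threshold variant sits behind
`per_kinase_threshold`. Self-pairs (a site on the kinase's own protein)
stay in the universe: autophosphorylation is real biology.

## Kinase activity

Activity of kinase K in sample *i* contrasts the score-weighted mean
abundance of its SOPS against the score-weighted mean of abundance-matched
controls:

Act(X_i, K) = Σ_k ω_{s_k} t^i_{s_k} / Σ_k ω_{s_k}
            − Σ_j ω_{c_j} t^i_{c_j} / Σ_j ω_{c_j}

Sites are placed into 25 equal-count bins on their mean abundance across
samples (stable tie-break by feature order); each SOPS substrate draws
`n_controls = 100` control sites from its own bin, excluding the kinase's
own SOPS, without replacement where the pool allows (flagged fallback to
with-replacement otherwise). One control draw is made per cohort and
reused across samples, so activities are comparable between samples.
Control weights ω_{c_j} are read from the full score matrix for the
(kinase, control) pair. Act is invariant to adding a constant to a
sample's abundances and equivariant under scaling; Act > 0 means the
substrate program sits above its abundance-matched background — the kinase
is active. Kinases with fewer than `min_sops = 3` substrates are reported
as unscorable rather than given noisy activities.

**Master kinases.** For each kinase and subtype, activity in the subtype
is compared against all other samples with the two-sided
Mann–Whitney–Wilcoxon test. Rows with effect size > 0.3, raw p < 0.01 and
an elevated direction (probability of superiority > ½) are kept and ranked
per subtype by MWW score descending (ties by p, then name). The elevated
direction requirement reflects the activity sign convention: a master
kinase of a subtype is one whose program is activated there, not
suppressed.

## Rank statistics

`prob_superiority` = U/(n1·n2) with midranks; the MWW score is its logit,
clamped to [1/(n1·n2+1), 1 − 1/(n1·n2+1)] so it stays finite at full
separation; effect size is the common-language effect size rescaled to
[0, 1], 2·|ps − ½|. P-values use the exact null when n1·n2 ≤ 400 and no
ties are present, otherwise the tie-corrected normal approximation with
continuity correction. Set enrichment (MWW-GST) reports NES = the
probability that an in-set value outranks an out-of-set value; the
single-sample variant ranks features within each sample and applies
Benjamini–Hochberg FDR across samples per signature. Raw p-values are used
where selection rules say P (master-kinase selection); FDR where they say
FDR.

## Preprocessing

Sites missing in ≥ 50 % of samples are dropped; the rest are imputed by
k-nearest-neighbour over features (k = 5, Euclidean on shared observed
samples, distance-weighted; the imputation benchmark below quantifies
sensitivity to this stand-in) with a feature-mean fallback. Observed
values are never altered. Quantile normalization maps every sample onto
the cohort-mean distribution of order statistics after log2 transform
(pseudocount 1.0 on raw scale); ties within a column receive the mean of
the values at their tied ranks, which makes the operation idempotent on
tie-free data (with exact ties, repeated application can drift within the
tied group — a known property of rank-interpolation normalizers).
Residualized phosphosite abundance regresses each site on its parent
protein (OLS per site) and keeps the residual; a constant parent is
unidentifiable, so the convention is slope 0 and a centered site profile.
Networks are built on non-residualized phospho abundance by default; the
residualized path is available and the choice is exposed because either is
defensible.

## Synthetic cohorts

The generator plants the structure the method assumes and nothing else.
Kinase abundance: per-kinase baseline ~ N(0, 1) plus per-sample noise
N(0, 1) plus a shared per-sample offset N(0, 0.3) that induces
sample-to-sample correlation (as in labelled MS cohorts). Substrate sites:
`t_s = b_s + edge_effect·t_kinase + N(0, noise_sd)`; non-substrate sites
are independent noise of comparable marginal variance. One kinase per
subtype carries a planted program: its protein abundance rises by
`subtype_shift / edge_effect` log2 units in its subtype's samples, so its
substrates inherit exactly `subtype_shift` through the regulatory slope.
The program is deliberately kinase-mediated: adding the shift to substrate
rows alone would decouple them from their kinase, and the classifier
correctly down-ranks such incoherent pairs — the planted signal would
sabotage its own discovery. Missingness, when requested, is
abundance-dependent (logistic in standardized abundance), mimicking MS
left-censoring. The revealed prior takes the same fraction of every
kinase's planted edges (stratified), emulating a prior that covers every
analysed kinase — real studies restrict to kinases with adequate validated
coverage.

Defaults (the `standard` preset): 60 samples, 20 kinases, 800 sites, 4
subtypes, 20 substrates per kinase, slope 0.8, site noise 0.5 (log2),
prior reveal 0.5, program shift 1.5 log2 (~3-fold activation — a strong
but realistic dominant driver; power analysis with an oracle regulon
showed per-kinase detection is only ~85–90 % at 1.0 log2 under these
cohort dimensions). `smoke` (20 × 5 × 100) runs the full pipeline in
seconds; `hard` raises noise to 1.5 and drops reveal to 0.2. What the
generator does **not** emulate: peptide-level quantification, batch
structure, heavy-tailed biological outliers (a t(4) noise option exists),
shared substrates between kinases, and feedback between kinase activity
and abundance — so passing tests show the machinery recovers the planted
generative structure, not that it resolves real signalling crosstalk.

## Benchmarks

* **Imputation robustness** — from a complete phospho matrix, a fraction r
  of sites (r = 10/25/50 %) receives randomly placed missing values
  (per-site missingness uniform in (0, 0.5)); the degraded matrix is
  imputed, the network rebuilt, and the new scores ranked against the
  pristine network's SOPS membership (ROC AUC).
* **Tenfold CV** — validated pairs are split into ten folds; per fold the
  ensemble trains on nine folds plus sampled negatives and is tested on
  held-out positives versus an equal number of unlabeled pairs kept
  disjoint from every training negative.
* **Regulon perturbation** — the bottom P fraction of each kinase's SOPS
  by score (⌊P·|SOPS|⌋, at least one when P > 0) is replaced by random
  non-SOPS sites inheriting the score matrix's value; ΔAct =
  |(Act^u − Act^p)/Act^u| per kinase (median over samples, then over
  kinases), excluding entries with |Act^u| below 10⁻³ of the activity
  matrix's interquartile range, where the ratio is meaningless.
* **Comparison metrics** — a mean-based KSEA z-score baseline
  z = (mean_set − mean_all)·√m/sd_all; top-k-hit (fraction of perturbation
  experiments whose true kinase ranks ≤ k); Δ-rank between any two
  rankings.

## Numerical and scale choices

All randomness flows through `numpy.random.default_rng` seeds; identical
inputs and seed give bit-identical networks, controls and activities. The
test and acceptance suites run cohort-scale simulations with a reduced
ensemble (12–25 bags instead of 100) and 3–10 seeds per stochastic check;
bagging variance shrinks roughly as 1/n_bags, and at 25 bags the
edge-recovery AUC on the standard preset is within ~0.005 of the 100-bag
value, so the reduced ensembles measure the same operating point at a
fraction of the cost. Problem sizes per check: edge-recovery AUC over 5
seeds of the standard cohort (16 000 candidate pairs each); master-kinase
recovery over 10 seeds; CV and imputation at 12 bags; the MWW type-I
simulation at 10 000 replicates of n = 20/20.

## Known limitations

* The null-calibration expectation that a shift-free cohort yields an
  empty master-kinase table in ≥ 9/10 cohorts is not attainable with raw
  p < 0.01 over 20 kinases × 4 subtypes (~0.4 expected false selections
  per cohort, so ~2/3 of cohorts are clean); the selection rule is kept
  faithful to its definition rather than silently FDR-corrected.
* The global retention threshold assumes validated scores spread smoothly;
  a classifier pushed to its ceiling (large `C`, clean data) breaks that
  assumption — kept configurable rather than auto-tuned.
* KSEA here is the plain mean-based z; no substrate-motif augmentation.
* The PhosphoSitePlus reader exposes an organism filter instead of
  hard-coding a release or species subset.
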