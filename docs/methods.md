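# Methods

This note documents the models implemented in `barcodedelim`, the defaults
and numerical choices, what the synthetic-data generator does and does not
emulate, and known limitations.

## Distance models

Pairwise counts classify each shared unambiguous column as a purine
transition (A↔G), pyrimidine transition (C↔T) or transversion, giving
proportions *P₁*, *P₂*, *Q* (and *P = P₁ + P₂*) over the valid columns.

* **p**: `d = P + Q`.
* **K2P**: `d = -½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)`.
* **TrN+Γ**: with base frequencies π and πR = πA+πG, πY = πC+πT,

      d = k1·g(w1) + k2·g(w2) + k3·g(w3),
      k1 = 2πAπG/πR,  k2 = 2πCπT/πY,
      k3 = 2(πRπY − πAπGπY/πR − πCπTπR/πY),
      w1 = 1 − P1/k1 − Q/(2πR),  w2 = 1 − P2/k2 − Q/(2πY),
      w3 = 1 − Q/(2πRπY),

  where `g(w) = −ln w` without rate variation and
  `g(w) = α(w^(−1/α) − 1)` under gamma-distributed site rates with shape α.
  With equal frequencies, P₁ = P₂ and α → ∞ this reduces exactly to K2P
  (tested to 1e-6; α ≥ 1e6 is treated as the no-gamma limit).

Choices: **pairwise deletion** by default (complete deletion available);
TrN base frequencies are estimated **once from the whole ingroup alignment**,
not per pair — per-pair frequencies are unstable for short fragments; α is a
required user input for TrN+Γ (barcode datasets rarely publish it) and
defaults to 1.0 with a warning.  Saturated pairs whose correction leaves the
model's domain become NaN, are listed in `undefined_pairs`, and are excluded
from all summaries — never clamped.

Group summaries (within/between a partition) are computed over **per-group /
per-group-pair averages** by default; the published tables this mirrors are
ambiguous between that reading and raw pairwise pools, so `semantics=
"all-pairs"` provides the alternative.  Standard deviations use ddof=0.
Groups of size 1 contribute no within-group value.  The *clean gap* flag is
`max(within-group averages) < min(between-group averages)`.

## Barcode-gap discovery

For each prior *p* (a ceiling on intraspecific divergence), the ranked
pairwise distances are scanned for the first *significant* gap that extends
beyond the prior (`d[k+1] > p`): significant means the gap exceeds `X` times
the mean consecutive difference over the preceding `slope_window` ranked
values (default `max(10, 5% of the number of distances)`; a relative
tolerance keeps float noise on exactly even spacing from registering).  The
graph linking pairs closer than the gap midpoint is cut into single-linkage
components, and the procedure recurses inside each component (same prior, its
own sub-matrix) until nothing splits, with a safety cap of 10 levels.

The prior grid is **15 log-uniformly spaced values in [0.001, 0.1]** by
default.  The upstream tool's "steps" parameter is interpreted as the prior
grid resolution, and its coalescent-derived gap lower bound is simplified to
the prior itself; both the single top-level split ("initial") and the fully
recursive partition are returned.  Named thresholds (e.g. a "7.2%"
partition) are obtained by passing an explicit prior list.  Empirically the
group count is non-increasing in the prior on clustered data; this is tested,
not enforced.

Threshold single linkage (`d < t` components) stands in for BOLD's RESL: the
initial 2.2% linkage is captured, the proprietary Markov-clustering
refinement is not, and outputs are labelled accordingly.

## GMYC (single threshold)

On an ultrametric tree (relative tip-depth tolerance 1e-4 for acceptance as
ultrametric, 1e-6 for the strict check), candidate thresholds are midpoints
between consecutive distinct node heights, plus one below every event (all
tips singletons) and one above the root.  For a threshold *T*, branching
events older than *T* form a diversification process with rate
`λ_div · k^p_div` (k = lineages crossing the interval) and events younger
than *T* form one combined coalescent process with rate
`λ_coal · C^p_coal`, `C = Σ_k n_k(n_k − 1)` over the clusters hanging below
*T*.  Each inter-event interval contributes `exp(−(rate_div + rate_coal)·x)`
and each event the log of its own class rate — the Yule density uses the
pre-event lineage count, the coalescent density the tip-ward (post-split)
counts, which is the direction the coalescent waiting time actually runs.
Within a class the rate profiles out in closed form (`λ̂ = m/E(p)`), leaving
a 1-D bounded search over the exponent `p ∈ [0, 2]` (Brent, xatol 1e-8); the
two classes are independent, so no multi-start is needed.

The **null model is the above-root threshold** (the whole tree one
coalescent cluster), so `logL_alt ≥ logL_null` holds by construction; the
LRT uses a χ² with **df = 2** (configurable — the literature uses 2 or 3).
The confidence set collects the entity counts of all thresholds within
**ΔlogL ≤ 2** of the optimum.  Entities are the subtrees whose root is
younger than *T* with parent edge crossing *T*; tips crossing alone are
singleton entities.

Events at height ≈ 0 (identical haplotypes) and zero-length intervals carry
no branching-time information and are excluded from the likelihood;
otherwise the coalescent rate MLE diverges and the best threshold collapses
onto the duplicate cluster boundary.  This is the in-package analogue of the
standard advice to run GMYC on unique haplotypes, and it makes full-dataset
and reduced-dataset runs agree when duplicates are exact.

## PTP and mPTP

A delimitation is an antichain of tree nodes whose subtrees partition the
tips.  Edges strictly inside a species' subtree are coalescent edges; all
others (including each species' stem) are speciation edges.  Edge lengths in
each class are modelled i.i.d. exponential; the class MLE is closed form
(`m ln(m/s) − m`).  **PTP** pools all coalescent edges under one rate and
maximises log-likelihood; **mPTP** gives each species with ≥ 1 internal edge
its own rate and minimises `AIC = 2k − 2 logL`, where k counts the
speciation rate (if any speciation edge exists) plus one rate per species
with internal edges.  Edges shorter than `MIN_BRANCH_LENGTH = 1e-7`
(identical haplotypes) are excluded from both classes, for the same reason
as in GMYC; the reference implementation's automatic detection of that
cutoff is out of scope.

Search: exhaustive enumeration for ≤ 12 tips (`N(v) = 1 + N(left)·N(right)`
delimitations).  Above that, a conditional-on-rates dynamic program — for a
fixed speciation rate the optimal antichain satisfies
`B(v) = max(score_as_species(v), Σ_children(spec_edge + B(child)))` — is
iterated EM-style with the rate MLEs, from several initialisations (edge
length quantile splits), then refined by greedy split/merge moves.  On all
random trees ≤ 8 tips the heuristic path matches the enumeration optimum
(tested over 100 seeded trees).

**MCMC support** (the bPTP-style layer): Metropolis–Hastings over antichains
with uniform-random split/merge proposals, Hastings-corrected by move
counts, flat prior, and the profile likelihood of the chosen method as the
score (for mPTP, −AIC/2).  Per-species-clade support is its sampling
frequency after burn-in (default 10%); ASV averages the supports of the
best-visited delimitation's clades; ASDDSV is the across-chain standard
deviation of clade supports, averaged — it approaches 0 as chains converge.
On ≤ 8-tip trees the sampled delimitation frequencies match the exact
enumerated posterior within total-variation distance 0.05.

## Trees

Newick parsing requires branch lengths; polytomies (including the basal
trifurcation of unrooted files) are resolved arbitrarily with zero-length
edges, which the delimiters then ignore per the rules above.  UPGMA is
implemented directly so ties break deterministically (lexicographically
smallest cluster pair); node height is half the merge distance, so the
output is always ultrametric.  NJ comes from dendropy, with negative branch
lengths clamped to zero (warned) and midpoint rooting by default (outgroup
rooting via a flag).

## Concordance

`N_match` counts delimited groups whose member set equals a morphospecies
exactly — a species split into several OTUs contributes nothing.  The match
ratio `2·N_match/(N_delimited + N_morph)` is reported **rounded half-up to 3
decimals**.  Outgroup samples are excluded by default; whether the outgroup
species counts as a morphospecies is a study convention, so both are
supported.  Split/lump events come from the bipartite group-overlap graph
(one event per group overlapping k > 1 opposite groups); ARI is computed by
scikit-learn and cross-checked against a pair-counting oracle in the tests.

## Synthetic data

The generator emulates a moderately diverse barcoding study: a Yule species
tree (`birth_rate` = 4.0/substitution-unit by default, giving ~0.05–0.5
K2P between species for 10 species — the scale of real COI surveys);
within-species Kingman coalescents with pairwise diversity `theta` = 0.002
substitutions/site grafted onto the species tips, rescaled to at most 90% of
the pendant branch so coalescence always completes inside the species (no
incomplete lineage sorting — truth partitions must be unambiguous); TrN+Γ
sequence evolution (continuous per-site gamma rates, shape 0.5; COI-like
base frequencies 0.25/0.28/0.16/0.31; transition/transversion rate ratios
6 and 10) over 620 bp; and exact cloning of 25% of samples from a
within-species neighbour to create the redundant haplotypes that make full
and reduced datasets differ.  Per-species sample counts support a fixed
value, a uniform range, and a singleton probability.

`generate_easy_dataset` redraws seeds until the realised gap ratio
(min between- / max within-species K2P distance) reaches 5 — the regime in
which exact truth recovery is a fair expectation; `simulate_clustered_gene_tree`
applies the same conditioning to patristic distances for tree-only tests.
Note that at `theta` = 0.002 over 620 bp, identical within-species sequences
arise naturally (~1 expected difference per close pair), so reduced datasets
are substantially smaller than full ones even before cloning.

**What passing tests do and do not show.**  The generator produces clean,
gap-conditioned data without gene flow, indel evolution, sequencing error,
contamination or incomplete lineage sorting.  Exact truth recovery on these
datasets demonstrates correctness of the implementations in their intended
regime, not that any method resolves real, gapless datasets — on real data
the methods disagree, which is precisely the phenomenon the concordance
layer quantifies.

## Pipeline

`run_pipeline` executes QC, haplotype collapsing, all configured distance
models, tree construction (user newick or bundled UPGMA for the GMYC path
and NJ for the PTP path — a documented substitution for ML/Bayesian trees),
all five delimiters on the full and reduced datasets, haplotype expansion,
the concordance table, full-vs-reduced congruence flags, and clean-gap
reports under a-priori/ABGD/mPTP groupings.  A failing stage is logged and
skipped; reruns with the same config and seed reproduce identical partition
files.

## Problem sizes and runtime

The test suite works at desk scale: ~50-sample/10-species datasets for
end-to-end recovery, 100 trees for the optimiser-vs-oracle and GMYC
calibration checks (20 tips each), and 10⁶ pooled MCMC steps for the
posterior comparison; the whole suite runs in well under a minute on one
CPU.  GMYC is O(n³) in tips as implemented and comfortable to a few hundred
tips; the PTP search and distance matrices are quadratic.

## Known limitations

* RESL is approximated by plain threshold linkage; BIN-refinement behaviour
  is not reproduced, so RESL-style OTU counts are inputs, not predictions.
* GMYC is single-threshold only; no Bayesian GMYC.
* The GMYC LRT's χ²(2) reference is approximate (the threshold is estimated);
  its empirical null rejection rate at the 5% level is ~9% in the bundled
  calibration, within the accepted band but on the liberal side — as is
  widely reported for this test.
* The bPTP-style support layer uses profile likelihoods inside the MCMC
  rather than integrating rates; supports are therefore empirical-Bayes
  flavoured, and are labelled as such.
* Bootstrap distance standard errors are available but optional, and no
  model selection across substitution models is provided.
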