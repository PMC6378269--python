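# barcodedelim

Single-locus DNA-barcode species delimitation and concordance analysis.

DNA barcoding surveys sequence one mitochondrial marker (for animals,
typically ~650 bp of cytochrome c oxidase subunit I, COI) for hundreds of
specimens and ask: how many species are here, and do molecular clusters agree
with the morphology-based identifications?  Different delimitation algorithms
routinely disagree — distance-based clustering tends to lump, tree-based
coalescent models tend to split — so a careful study runs several methods on
both the full dataset and the dataset reduced to unique haplotypes, and
quantifies how well each inferred partition matches the morphospecies.

`barcodedelim` implements that entire workflow as a tested Python library:

* **Alignment handling** — FASTA I/O and validation, reading-frame/stop-codon
  QC under the vertebrate mitochondrial code, exact-haplotype collapsing
  (full vs reduced datasets), conserved/variable/parsimony-informative site
  counts.
* **Distances** — pairwise divergences under three substitution models:
  uncorrected *p*; Kimura 2-parameter,
  `d = -½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` with transition/transversion
  proportions *P*, *Q*; and Tamura–Nei with gamma rate variation (TrN+Γ),
  the closed form over the two transition classes *P₁*, *P₂* and *Q* with
  each `−ln w` term replaced by `α(w^(−1/α) − 1)`.  Plus group summaries,
  barcode-gap histograms and transition/transversion saturation profiles.
* **Distance-based delimitation** — recursive barcode-gap discovery over a
  log-spaced grid of intraspecific-divergence priors (gap significant when
  wider than X times the local slope of the ranked distances), and threshold
  single linkage (a documented stand-in for BOLD's RESL/BIN assignment).
* **Tree-based delimitation** — single-threshold GMYC (general mixed
  Yule-coalescent: a threshold age separates a diversification process with
  rate `λ_div · k^p` from within-cluster coalescents with rate
  `λ_coal · (Σ nₖ(nₖ−1))^p`, compared to a one-process null by LRT); PTP and
  mPTP (speciation vs coalescent edges as exponential classes, one shared or
  per-species coalescent rate, AIC selection); MCMC delimitation-support
  sampling with the ASDDSV convergence diagnostic; and an exhaustive
  antichain enumerator used as an exact oracle on small trees.
* **Concordance** — exact-match counts against morphospecies and the match
  ratio `2·N_match / (N_delimited + N_morph)`, split/lump events, adjusted
  Rand index, full-vs-reduced congruence after haplotype expansion, and
  clean-barcoding-gap reports under reassigned groupings.
* **Synthetic data** — a generator with known species truth (Yule species
  tree → within-species coalescents → TrN+Γ sequence evolution → exact
  haplotype duplication), so every stage of the pipeline is testable without
  real data.

UPGMA and neighbor-joining builders are bundled so the tree-based methods can
run from a distance matrix alone; in a real study you would hand them your
ML or Bayesian trees (newick with branch lengths; ultrametric for GMYC).

## Worked example

```python
from barcodedelim import (SimulationParams, generate_easy_dataset,
                          DistanceModelConfig, distance_matrix,
                          abgd_partition, gmyc_fit, upgma_tree,
                          match_count, match_ratio)
from barcodedelim.partition import n_groups

ds = generate_easy_dataset(SimulationParams(seed=7))     # 50 samples, 10 species
m = distance_matrix(ds.alignment, DistanceModelConfig(model="K2P"))

for r in abgd_partition(m).by_prior:
    nm = match_count(r.partition, ds.truth)
    print(f"prior {r.prior:.4f}  groups {r.n_groups:2d}  "
          f"match ratio {match_ratio(nm, r.n_groups, 10):.3f}")
```

prints (abridged):

```
prior 0.0010  groups 21  match ratio 0.000
prior 0.0037  groups 10  match ratio 1.000
prior 0.0100  groups 10  match ratio 1.000
prior 0.0373  groups 10  match ratio 1.000
prior 0.1000  groups  8  match ratio 0.667
```

At priors below the within-species divergence the clusterer splits haplotype
groups apart (21 groups, none matching a species exactly — ratio 0); across
the whole mid-range of priors it recovers the 10 true species exactly
(ratio 1.0); at too-large priors it lumps close species (ratio < 1).  On the
same dataset `gmyc_fit(upgma_tree(m))` reports 10 entities (confidence set
{10}), LR = 24.3, p ≈ 5e-6 — the one-process null is firmly rejected.

The full study design is one call: `run_pipeline(validate_config({...}))`
executes QC → full/reduced datasets → distances under all three models →
trees → all five delimiters on both datasets → a concordance table and a
JSON report (see `examples/05_full_pipeline.py`).  Each `examples/*.py`
script is a short narrative of one capability and prints what it computes.

A thin CLI covers the same ground from the shell:

```bash
delim simulate --seed 7 --out data/
delim abgd --alignment data/alignment.fasta --out abgd_out/
delim gmyc --tree tree.nwk --out gmyc.tsv
delim pipeline --config run.yaml
```

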