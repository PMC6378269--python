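"""Synthetic barcode datasets with known species truth.

The generator emulates the structure of a single-locus barcoding study of a
moderately diverse clade: a Yule species tree, within-species Kingman
coalescents grafted onto its tips (samples always coalesce inside their own
species, so the truth partition is unambiguous), and ~520–660 bp sequences
evolved under a Tamura–Nei substitution model with continuous gamma
rate-variation across sites.  Uneven per-species sampling (including
singletons) and a tunable fraction of exactly duplicated haplotypes mirror
field datasets where the full and reduced (unique-haplotype) alignments
differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .alignment import Alignment, write_fasta
from .distances import DistanceMatrix, DistanceModelConfig, distance_matrix
from .errors import ConfigurationError
from .partition import Partition, write_partition_tsv
from .trees import parse_newick, write_newick


@dataclass(frozen=True)
class SamplesPerSpecies:
    """Either a fixed count per species, or a uniform range with an
    independent per-species singleton probability."""

    fixed: int | None = 5
    minimum: int = 2
    maximum: int = 8
    p_singleton: float = 0.0

    def draw(self, rng: np.random.Generator) -> int:
        if self.fixed is not None:
            return self.fixed
        if rng.random() < self.p_singleton:
            return 1
        return int(rng.integers(self.minimum, self.maximum + 1))


@dataclass(frozen=True)
class SimulationParams:
    n_species: int = 10
    birth_rate: float = 4.0           # Yule rate; sets species-tree depth in subs/site
    theta: float = 0.002              # within-species pairwise diversity, subs/site
    samples_per_species: SamplesPerSpecies = field(default_factory=SamplesPerSpecies)
    seq_length: int = 620
    kappa_purine: float = 6.0         # A<->G transition/transversion rate ratio
    kappa_pyrimidine: float = 10.0    # C<->T transition/transversion rate ratio
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.28, 0.16, 0.31)
    alpha: float = 0.5                # gamma shape of among-site rate variation
    duplicate_fraction: float = 0.25  # samples replaced by exact haplotype copies
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ConfigurationError("need at least 2 species")
        if min(self.birth_rate, self.theta, self.alpha) <= 0:
            raise ConfigurationError("rates and alpha must be positive")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ConfigurationError("duplicate_fraction must be in [0, 1]")
        freqs = tuple(float(f) for f in self.base_frequencies)
        if len(freqs) != 4 or any(f <= 0 for f in freqs) or abs(sum(freqs) - 1) > 1e-9:
            raise ConfigurationError("base_frequencies must be 4 positive values summing to 1")
        object.__setattr__(self, "base_frequencies", freqs)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["samples_per_species"] = self.samples_per_species.__dict__.copy()
        return d


@dataclass(frozen=True)
class SimulatedDataset:
    alignment: Alignment
    truth: Partition
    species_tree: dendropy.Tree
    gene_tree: dendropy.Tree
    params: SimulationParams
    realized_gap: tuple[float, float]  # (max intra distance, min inter distance)

    @property
    def gap_ratio(self) -> float:
        max_intra, min_inter = self.realized_gap
        if max_intra == 0.0:
            return float("inf")
        return min_inter / max_intra


class _SimNode:
    """Minimal mutable node used while growing simulated trees."""

    __slots__ = ("label", "children", "birth", "end")

    def __init__(self, label: str | None, birth: float):
        self.label = label
        self.children: list[_SimNode] = []
        self.birth = birth   # absolute time the lineage appeared
        self.end = birth     # absolute time it split or reached the present

    def newick(self, parent_end: float | None = None) -> str:
        if self.children:
            inner = ",".join(c.newick(self.end) for c in self.children)
            body = f"({inner})"
        else:
            body = self.label or "tip"
        if parent_end is None:
            return body + ";"
        return f"{body}:{self.end - self.birth!r}"


def _simnode_newick(root: _SimNode) -> str:
    if root.children:
        inner = ",".join(c.newick(root.end) for c in root.children)
        return f"({inner});"
    return f"{root.label};"


def simulate_species_tree(
    n: int, birth_rate: float, rng: np.random.Generator
) -> dendropy.Tree:
    """Yule pure-birth tree with n tips; branch lengths in substitutions/site.

    Lineages wait Exp(k * birth_rate) between splits while k are alive; the
    present is one further exponential wait after the last split, so the two
    deepest tips subtend the full tree height.
    """
    if n < 2:
        raise ConfigurationError("need at least 2 species")
    root = _SimNode(None, 0.0)
    active = [root]
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        lineage = active.pop(int(rng.integers(k)))
        lineage.end = t
        lineage.children = [_SimNode(None, t), _SimNode(None, t)]
        active.extend(lineage.children)
    t += rng.exponential(1.0 / (n * birth_rate))
    for i, tip in enumerate(
        sorted(active, key=lambda nd: nd.birth), start=1
    ):
        tip.label = f"sp{i:02d}"
        tip.end = t
    return parse_newick(_simnode_newick(root))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _kingman_fragment(
    labels: list[str], theta: float, rng: np.random.Generator, max_depth: float
) -> tuple[str, float]:
    """Newick fragment of a Kingman coalescent over ``labels``.

    With k lineages the next coalescence waits Exp(k(k-1)/theta), so a pair
    has expected divergence ``theta`` (two branches of expected depth
    theta/2).  If the realised depth would exceed ``max_depth`` (the species'
    pendant span), all node heights are rescaled to 90% of it, keeping the
    coalescent strictly inside its species.
    """
    k = len(labels)
    heights = []
    h = 0.0
    for j in range(k, 1, -1):
        h += rng.exponential(theta / (j * (j - 1)))
        heights.append(h)
    depth = heights[-1] if heights else 0.0
    if depth > max_depth:
        scale = 0.9 * max_depth / depth
        heights = [x * scale for x in heights]
        depth = heights[-1]

    frags = [(lab, 0.0) for lab in labels]
    for h in heights:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        (fb, hb) = frags.pop(j)
        (fa, ha) = frags.pop(i)
        frags.append((f"({fa}:{h - ha!r},{fb}:{h - hb!r})", h))
    return frags[0][0], depth


def simulate_gene_tree(
    sp_tree: dendropy.Tree,
    samples_per_species: SamplesPerSpecies,
    theta: float,
    seed,
) -> tuple[dendropy.Tree, Partition]:
    """Graft within-species coalescents onto the species-tree tips.

    Samples are named ``<species>_t01`` etc.  Coalescence always completes
    inside the species' pendant branch (no incomplete lineage sorting), so
    the returned truth partition is exact.  Ultrametric when ``sp_tree`` is.
    """
    rng = _as_rng(seed)
    truth: Partition = {}

    def build(node: dendropy.Node) -> str:
        if node.is_leaf():
            species = node.taxon.label
            pendant = node.edge.length or 0.0
            n = samples_per_species.draw(rng)
            labels = [f"{species}_t{j:02d}" for j in range(1, n + 1)]
            for lab in labels:
                truth[lab] = species
            if n == 1:
                return f"{labels[0]}:{pendant!r}"
            frag, depth = _kingman_fragment(labels, theta, rng, pendant)
            return f"{frag}:{pendant - depth!r}"
        kids = ",".join(build(c) for c in node.child_nodes())
        if node.parent_node is None:
            return f"({kids});"
        return f"({kids}):{node.edge.length or 0.0!r}"

    text = build(sp_tree.seed_node)
    return parse_newick(text), truth


def tn93_rate_matrix(
    base_frequencies, kappa_purine: float, kappa_pyrimidine: float
) -> np.ndarray:
    """Tamura–Nei instantaneous rate matrix (ACGT order), scaled to one
    expected substitution per site per unit branch length."""
    pi = np.asarray(base_frequencies, dtype=float)
    S = np.ones((4, 4))  # exchangeabilities; transversion baseline 1
    S[0, 2] = S[2, 0] = kappa_purine      # A<->G
    S[1, 3] = S[3, 1] = kappa_pyrimidine  # C<->T
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.sum(pi * np.diag(Q)))
    return Q / mu


def simulate_alignment(
    gene_tree: dendropy.Tree, params: SimulationParams, seed=None
) -> Alignment:
    """Evolve sequences along ``gene_tree`` under TrN with continuous gamma
    site rates, then clone ``duplicate_fraction`` of the samples from a
    within-species neighbour to create redundant haplotypes."""
    rng = _as_rng(params.seed if seed is None else seed)
    L = params.seq_length
    pi = np.asarray(params.base_frequencies)
    Q = tn93_rate_matrix(pi, params.kappa_purine, params.kappa_pyrimidine)
    eigvals, V = np.linalg.eig(Q)
    eigvals, V = eigvals.real, V.real
    Vinv = np.linalg.inv(V)
    site_rates = rng.gamma(shape=params.alpha, scale=1.0 / params.alpha, size=L)

    def transition_probs(t: float) -> np.ndarray:
        expL = np.exp(np.outer(site_rates, eigvals) * t)       # (L, 4)
        P = np.einsum("ij,sj,jk->sik", V, expL, Vinv)           # (L, 4, 4)
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=2, keepdims=True)

    def draw(prob_rows: np.ndarray) -> np.ndarray:
        u = rng.random(L)
        return (u[:, None] > np.cumsum(prob_rows, axis=1)).sum(axis=1).clip(0, 3)

    root_seq = draw(np.tile(pi, (L, 1)))
    seqs: dict[str, np.ndarray] = {}

    def evolve(node: dendropy.Node, state: np.ndarray) -> None:
        if node.parent_node is not None:
            t = node.edge.length or 0.0
            if t > 0:
                P = transition_probs(t)
                state = draw(P[np.arange(L), state, :])
        if node.is_leaf():
            seqs[node.taxon.label] = state
        else:
            for child in node.child_nodes():
                evolve(child, state.copy())

    evolve(gene_tree.seed_node, root_seq)

    ids = sorted(seqs)
    n_dup = int(round(params.duplicate_fraction * len(ids)))
    if n_dup:
        species_of = {sid: sid.rsplit("_t", 1)[0] for sid in ids}
        eligible = [
            sid for sid in ids
            if sum(1 for o in ids if species_of[o] == species_of[sid]) >= 2
        ]
        targets = rng.choice(len(eligible), size=min(n_dup, len(eligible)), replace=False)
        for t_i in sorted(int(x) for x in targets):
            sid = eligible[t_i]
            donors = [o for o in ids if o != sid and species_of[o] == species_of[sid]]
            donor = donors[int(rng.integers(len(donors)))]
            seqs[sid] = seqs[donor].copy()

    bases = np.array(list("ACGT"))
    return Alignment(
        ids=tuple(ids),
        seqs=tuple("".join(bases[s]) for s in (seqs[i] for i in ids)),
        length=L,
    )


def realized_barcode_gap(
    a: Alignment, truth: Partition, model: DistanceModelConfig | None = None
) -> tuple[float, float]:
    """(max within-species, min between-species) pairwise distance."""
    m = distance_matrix(a, model or DistanceModelConfig(model="K2P"))
    max_intra, min_inter = 0.0, float("inf")
    for i in range(m.n):
        for j in range(i + 1, m.n):
            v = m.d[i, j]
            if np.isnan(v):
                continue
            if truth[m.ids[i]] == truth[m.ids[j]]:
                max_intra = max(max_intra, float(v))
            else:
                min_inter = min(min_inter, float(v))
    return max_intra, min_inter


def generate_dataset(
    params: SimulationParams, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Chain the three simulators and (optionally) write the dataset files:
    FASTA alignment, truth TSV, species and gene newick, params JSON."""
    rng = _as_rng(params.seed)
    sp_tree = simulate_species_tree(params.n_species, params.birth_rate, rng)
    gene_tree, truth = simulate_gene_tree(
        sp_tree, params.samples_per_species, params.theta, rng
    )
    aln = simulate_alignment(gene_tree, params, seed=rng)
    gap = realized_barcode_gap(aln, truth)
    ds = SimulatedDataset(aln, truth, sp_tree, gene_tree, params, gap)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(aln, out / "alignment.fasta")
        write_partition_tsv(truth, out / "truth.tsv")
        write_newick(sp_tree, out / "species.nwk")
        write_newick(gene_tree, out / "gene.nwk")
        with open(out / "params.json", "w") as fh:
            json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return ds


def simulate_clustered_gene_tree(
    n_species: int,
    birth_rate: float,
    theta: float,
    samples_per_species: SamplesPerSpecies,
    seed,
    min_gap_ratio: float = 5.0,
    max_attempts: int = 100,
) -> tuple[dendropy.Tree, Partition]:
    """A gene tree with strong species clustering: redraws until the minimum
    between-species patristic distance is ``min_gap_ratio`` times the maximum
    within-species one (short Yule internodes can otherwise place two species
    arbitrarily close, where no method could separate them)."""
    from .trees import distance_matrix_from_tree

    rng = _as_rng(seed)
    for _ in range(max_attempts):
        sp = simulate_species_tree(n_species, birth_rate, rng)
        gt, truth = simulate_gene_tree(sp, samples_per_species, theta, rng)
        m = distance_matrix_from_tree(gt)
        max_intra, min_inter = 0.0, float("inf")
        for i in range(m.n):
            for j in range(i + 1, m.n):
                if truth[m.ids[i]] == truth[m.ids[j]]:
                    max_intra = max(max_intra, float(m.d[i, j]))
                else:
                    min_inter = min(min_inter, float(m.d[i, j]))
        if max_intra == 0.0 or min_inter / max_intra >= min_gap_ratio:
            return gt, truth
    raise RuntimeError(f"no strongly clustered tree in {max_attempts} draws")


def generate_easy_dataset(
    params: SimulationParams, min_gap_ratio: float = 5.0, max_attempts: int = 30
) -> SimulatedDataset:
    """Redraw datasets (advancing the seed) until the realised barcode gap
    ratio (min inter / max intra) reaches ``min_gap_ratio``.

    Delimitation methods are only expected to recover the truth exactly when
    a clear gap exists; this helper conditions on that stated regime.
    """
    from dataclasses import replace

    best, best_ratio = None, -1.0
    for attempt in range(max_attempts):
        p = replace(params, seed=(params.seed + 9973 * attempt) % (2**31 - 1))
        ds = generate_dataset(p)
        if ds.gap_ratio >= min_gap_ratio:
            return ds
        if ds.gap_ratio > best_ratio:
            best, best_ratio = ds, ds.gap_ratio
    raise RuntimeError(
        f"no dataset with gap ratio >= {min_gap_ratio} in {max_attempts} draws "
        f"(best {best_ratio:.2f}); loosen the settings"
    )
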