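"""Tree-based species delimitation: GMYC, PTP, mPTP, and MCMC support.

All three models work on a rooted binary tree and return a partition of the
tips into species whose members are exactly the tip sets of disjoint subtrees
(an *antichain* of nodes: no chosen node is ancestral to another, and their
subtrees cover every tip).

* :func:`gmyc_fit` — single-threshold general mixed Yule coalescent on an
  ultrametric tree: a threshold height ``T`` separates between-species
  branching (one process with rate ``lambda_div * k**p_div`` in the number of
  lineages ``k``) from within-species coalescence (one combined process with
  rate ``lambda_coal * C**p_coal`` where ``C = sum_k n_k (n_k - 1)`` over
  clusters).  The threshold maximising the profile likelihood is compared to
  the one-process null (threshold above the root) by a likelihood-ratio test.
* :func:`ptp_ml` / :func:`mptp_ml` — Poisson tree processes on a tree with
  branch lengths in substitutions: edges between species and edges within a
  species are modelled as separate exponential classes.  PTP pools all
  within-species edges under one rate and maximises the likelihood; mPTP
  gives every species its own rate and selects the delimitation by AIC.
* :func:`delim_support_mcmc` — Metropolis–Hastings split/merge sampling over
  antichain delimitations with a flat prior, reporting per-species-clade
  support frequencies and the across-chain ASDDSV convergence diagnostic.
* :func:`enumerate_delimitations` — exhaustive antichain enumeration, used
  as the exact-search path on small trees and as an independent oracle in
  tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .errors import TreeError
from .partition import Partition, from_components
from .trees import is_ultrametric, node_heights

#: edges shorter than this carry no usable branching-time information
#: (identical haplotypes); they are excluded from likelihood evaluation, as
#: rate MLEs would otherwise diverge and shred duplicate clusters
MIN_BRANCH_LENGTH = 1e-7


class TreeIndex:
    """Array view of a rooted binary dendropy tree used by the delimiters."""

    def __init__(self, tree: dendropy.Tree, min_branch_length: float = MIN_BRANCH_LENGTH):
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self.idx = {id(nd): k for k, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.children: list[tuple[int, int] | None] = [None] * self.n_nodes
        self.edge_len = np.zeros(self.n_nodes)
        self.edge_used = np.zeros(self.n_nodes, dtype=bool)
        self.tip_label: dict[int, str] = {}
        heights = node_heights(tree)
        self.height = np.zeros(self.n_nodes)
        for k, nd in enumerate(nodes):
            self.height[k] = heights[nd]
            if nd.parent_node is not None:
                self.edge_len[k] = nd.edge.length or 0.0
                self.edge_used[k] = self.edge_len[k] >= min_branch_length
            kids = nd.child_nodes()
            if kids:
                if len(kids) != 2:
                    raise TreeError("delimitation requires a binary tree")
                self.children[k] = (self.idx[id(kids[0])], self.idx[id(kids[1])])
            else:
                self.tip_label[k] = nd.taxon.label
        for k, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[k] = self.idx[id(nd.parent_node)]
        self.root = self.n_nodes - 1  # postorder puts the root last
        self.n_tips = len(self.tip_label)

        # per-node subtree aggregates (strictly-below edges)
        self.tips_below: list[frozenset[str]] = [frozenset()] * self.n_nodes
        self.sub_edge_sum = np.zeros(self.n_nodes)
        self.sub_edge_count = np.zeros(self.n_nodes, dtype=int)
        for k in range(self.n_nodes):
            if self.children[k] is None:
                self.tips_below[k] = frozenset({self.tip_label[k]})
            else:
                a, b = self.children[k]
                self.tips_below[k] = self.tips_below[a] | self.tips_below[b]
                self.sub_edge_sum[k] = (
                    self.sub_edge_sum[a] + self.sub_edge_sum[b]
                    + self.edge_len[a] * self.edge_used[a]
                    + self.edge_len[b] * self.edge_used[b]
                )
                self.sub_edge_count[k] = (
                    self.sub_edge_count[a] + self.sub_edge_count[b]
                    + int(self.edge_used[a]) + int(self.edge_used[b])
                )
        self.total_edge_sum = float(self.sub_edge_sum[self.root])
        self.total_edge_count = int(self.sub_edge_count[self.root])

    def is_leaf(self, k: int) -> bool:
        return self.children[k] is None

    def partition_of(self, antichain: frozenset[int]) -> Partition:
        order = sorted(antichain, key=lambda k: min(self.tips_below[k]))
        return from_components([sorted(self.tips_below[k]) for k in order], prefix="SP")

    def species_sets(self, antichain: frozenset[int]) -> list[frozenset[str]]:
        return [self.tips_below[k] for k in sorted(antichain)]

    # -- antichain moves -------------------------------------------------
    def split_moves(self, antichain: frozenset[int]) -> list[int]:
        return [k for k in antichain if not self.is_leaf(k)]

    def merge_moves(self, antichain: frozenset[int]) -> list[int]:
        """Parents whose two children are both in the antichain."""
        out = []
        for k in antichain:
            p = self.parent[k]
            if p >= 0 and k == min(self.children[p]):
                sib = sum(self.children[p]) - k
                if sib in antichain:
                    out.append(p)
        return out

    def apply_split(self, antichain: frozenset[int], node: int) -> frozenset[int]:
        a, b = self.children[node]
        return (antichain - {node}) | {a, b}

    def apply_merge(self, antichain: frozenset[int], parent: int) -> frozenset[int]:
        a, b = self.children[parent]
        return (antichain - {a, b}) | {parent}


# ---------------------------------------------------------------------------
# enumeration oracle

def _enumerate(ti: TreeIndex, node: int) -> list[frozenset[int]]:
    out = [frozenset({node})]
    if not ti.is_leaf(node):
        a, b = ti.children[node]
        for da in _enumerate(ti, a):
            for db in _enumerate(ti, b):
                out.append(da | db)
    return out


def delimitation_count(ti_or_tree) -> int:
    """Number of valid antichain delimitations, N(v) = 1 + N(left)*N(right)."""
    ti = ti_or_tree if isinstance(ti_or_tree, TreeIndex) else TreeIndex(ti_or_tree)

    def rec(k: int) -> int:
        if ti.is_leaf(k):
            return 1
        a, b = ti.children[k]
        return 1 + rec(a) * rec(b)

    return rec(ti.root)


def enumerate_delimitations(
    tree: dendropy.Tree, max_tips: int = 12
) -> list[list[frozenset[str]]]:
    """All valid antichain delimitations as lists of species tip sets."""
    ti = TreeIndex(tree)
    if ti.n_tips > max_tips:
        raise TreeError(
            f"refusing to enumerate delimitations for {ti.n_tips} tips (max {max_tips})"
        )
    return [ti.species_sets(a) for a in _enumerate(ti, ti.root)]


# ---------------------------------------------------------------------------
# PTP family

def _class_loglik(total_length: float, m: int) -> tuple[float, float | None]:
    """Max log-likelihood of m i.i.d. exponential edge lengths summing to
    total_length, with the rate at its MLE m/total_length."""
    if m == 0:
        return 0.0, None
    rate = m / total_length
    return m * math.log(rate) - m, rate


@dataclass(frozen=True)
class PtpResult:
    method: str
    species: tuple[frozenset[str], ...]
    partition: Partition
    logL: float
    n_params: int
    AIC: float
    lambda_speciation: float | None
    lambda_coalescent: float | None = None          # PTP pooled rate
    lambda_per_species: dict[str, float] = field(default_factory=dict)  # mPTP

    @property
    def n_species(self) -> int:
        return len(self.species)


def _ptp_stats(ti: TreeIndex, antichain: frozenset[int]):
    within_m = int(sum(ti.sub_edge_count[k] for k in antichain))
    within_s = float(sum(ti.sub_edge_sum[k] for k in antichain))
    spec_m = ti.total_edge_count - within_m
    spec_s = ti.total_edge_sum - within_s
    return spec_m, spec_s, within_m, within_s


def ptp_loglik(ti: TreeIndex, antichain: frozenset[int]) -> tuple[float, int]:
    spec_m, spec_s, within_m, within_s = _ptp_stats(ti, antichain)
    ll = _class_loglik(spec_s, spec_m)[0] + _class_loglik(within_s, within_m)[0]
    n_params = (spec_m > 0) + (within_m > 0)
    return ll, n_params


def mptp_loglik(ti: TreeIndex, antichain: frozenset[int]) -> tuple[float, int]:
    spec_m, spec_s, _, _ = _ptp_stats(ti, antichain)
    ll = _class_loglik(spec_s, spec_m)[0]
    n_params = int(spec_m > 0)
    for k in antichain:
        m = int(ti.sub_edge_count[k])
        if m:
            ll += _class_loglik(float(ti.sub_edge_sum[k]), m)[0]
            n_params += 1
    return ll, n_params


def _aic(ll: float, k: int) -> float:
    return 2.0 * k - 2.0 * ll


def _random_antichain(ti: TreeIndex, rng: np.random.Generator) -> frozenset[int]:
    chain = frozenset({ti.root})
    n_ops = int(rng.integers(0, ti.n_tips))
    for _ in range(n_ops):
        splits = ti.split_moves(chain)
        if not splits:
            break
        chain = ti.apply_split(chain, splits[int(rng.integers(len(splits)))])
    return chain


def _hill_climb(ti: TreeIndex, objective, rng: np.random.Generator, n_restarts: int = 5):
    """Greedy best-improvement over split/merge moves; returns the best
    antichain over several starts (root-only, all-tips, random)."""
    starts = [
        frozenset({ti.root}),
        frozenset(k for k in range(ti.n_nodes) if ti.is_leaf(k)),
    ]
    while len(starts) < 2 + n_restarts:
        starts.append(_random_antichain(ti, rng))

    best_state, best_score = None, -math.inf
    for state in starts:
        score = objective(state)
        improved = True
        while improved:
            improved = False
            cand_best, cand_score = None, score
            for node in ti.split_moves(state):
                nxt = ti.apply_split(state, node)
                s = objective(nxt)
                if s > cand_score:
                    cand_best, cand_score = nxt, s
            for parent in ti.merge_moves(state):
                nxt = ti.apply_merge(state, parent)
                s = objective(nxt)
                if s > cand_score:
                    cand_best, cand_score = nxt, s
            if cand_best is not None:
                state, score = cand_best, cand_score
                improved = True
        if score > best_score:
            best_state, best_score = state, score
    return best_state, best_score


def _dp_best(ti: TreeIndex, spec_logf: np.ndarray, species_score: np.ndarray) -> frozenset[int]:
    """Optimal antichain when the per-edge speciation log-density and the
    per-node make-this-a-species score are fixed: B(v) = max(species_score[v],
    sum_children(spec_logf[c] + B(c))), solved bottom-up."""
    B = np.zeros(ti.n_nodes)
    split_here = np.zeros(ti.n_nodes, dtype=bool)
    for v in range(ti.n_nodes):  # postorder by construction
        kids = ti.children[v]
        if kids is None:
            B[v] = species_score[v]
            continue
        a, b = kids
        as_split = spec_logf[a] + B[a] + spec_logf[b] + B[b]
        if as_split > species_score[v]:
            B[v], split_here[v] = as_split, True
        else:
            B[v] = species_score[v]
    out: set[int] = set()
    stack = [ti.root]
    while stack:
        v = stack.pop()
        if split_here[v]:
            stack.extend(ti.children[v])
        else:
            out.add(v)
    return frozenset(out)


def _dp_em(ti: TreeIndex, method: str, objective, lam_s0: float, lam_c0: float,
           max_iter: int = 50) -> frozenset[int]:
    """Coordinate ascent: DP-optimal antichain given rates, then rate MLEs
    given the antichain, until the antichain stabilises."""
    lam_s, lam_c = lam_s0, lam_c0
    prev: frozenset[int] | None = None
    best, best_score = None, -math.inf
    for _ in range(max_iter):
        spec_logf = np.where(
            ti.edge_used, math.log(lam_s) - lam_s * ti.edge_len, 0.0
        )
        spec_logf[ti.root] = 0.0
        if method == "PTP":
            species_score = (
                ti.sub_edge_count * math.log(lam_c) - lam_c * ti.sub_edge_sum
            )
        else:  # mPTP: per-species profile likelihood minus its AIC parameter
            with np.errstate(divide="ignore", invalid="ignore"):
                ll_k = np.where(
                    ti.sub_edge_count > 0,
                    ti.sub_edge_count
                    * (np.log(np.maximum(ti.sub_edge_count, 1) / np.maximum(ti.sub_edge_sum, 1e-300)) - 1.0),
                    0.0,
                )
            species_score = ll_k - (ti.sub_edge_count > 0)
        antichain = _dp_best(ti, spec_logf, species_score)
        score = objective(antichain)
        if score > best_score:
            best, best_score = antichain, score
        if antichain == prev:
            break
        prev = antichain
        spec_m, spec_s, within_m, within_s = _ptp_stats(ti, antichain)
        lam_s = spec_m / spec_s if spec_m else lam_s
        lam_c = within_m / within_s if within_m else lam_c
    return best


def _search(ti: TreeIndex, objective, max_exact: int, seed: int, method: str) -> frozenset[int]:
    if ti.n_tips <= max_exact:
        return max(_enumerate(ti, ti.root), key=objective)
    rng = np.random.default_rng(seed)
    candidates: list[frozenset[int]] = []
    # rate initialisations from splits of the ranked used edge lengths
    lengths = np.sort(ti.edge_len[ti.edge_used])
    for q in (0.5, 0.7, 0.9):
        cut = int(q * lengths.size)
        lo, hi = lengths[:cut], lengths[cut:]
        if lo.size == 0 or hi.size == 0 or lo.mean() == 0:
            continue
        candidates.append(
            _dp_em(ti, method, objective, lam_s0=1.0 / hi.mean(), lam_c0=1.0 / lo.mean())
        )
    pooled = 1.0 / lengths.mean()
    candidates.append(_dp_em(ti, method, objective, lam_s0=pooled, lam_c0=pooled * 10))
    state, _ = _hill_climb(ti, objective, rng)
    candidates.append(state)
    # refine the best DP/EM solution with greedy moves
    best = max(candidates, key=objective)
    improved = True
    score = objective(best)
    while improved:
        improved = False
        for move in ti.split_moves(best):
            nxt = ti.apply_split(best, move)
            if objective(nxt) > score:
                best, score, improved = nxt, objective(nxt), True
        for move in ti.merge_moves(best):
            nxt = ti.apply_merge(best, move)
            if objective(nxt) > score:
                best, score, improved = nxt, objective(nxt), True
    return best


def _finish_ptp(ti: TreeIndex, antichain: frozenset[int], method: str) -> PtpResult:
    spec_m, spec_s, within_m, within_s = _ptp_stats(ti, antichain)
    lam_spec = spec_m / spec_s if spec_m else None
    partition = ti.partition_of(antichain)
    species = tuple(ti.species_sets(antichain))
    if method == "PTP":
        ll, k = ptp_loglik(ti, antichain)
        lam_coal = within_m / within_s if within_m else None
        return PtpResult("PTP", species, partition, ll, k, _aic(ll, k), lam_spec, lam_coal)
    ll, k = mptp_loglik(ti, antichain)
    label_of = {min(ti.tips_below[a]): a for a in antichain}
    lam_by: dict[str, float] = {}
    for sp_label, members in sorted(
        ((partition[next(iter(s))], s) for s in species), key=lambda t: t[0]
    ):
        node = label_of[min(members)]
        m = int(ti.sub_edge_count[node])
        if m:
            lam_by[sp_label] = m / float(ti.sub_edge_sum[node])
    return PtpResult("mPTP", species, partition, ll, k, _aic(ll, k), lam_spec,
                     lambda_per_species=lam_by)


def _require_delimitable(tree: dendropy.Tree) -> TreeIndex:
    ti = TreeIndex(tree)
    if ti.n_tips < 3:
        raise TreeError("PTP-family delimitation needs at least 3 tips")
    return ti


def ptp_ml(tree: dendropy.Tree, max_exact: int = 12, seed: int = 0) -> PtpResult:
    """Single-rate PTP: maximise the two-class exponential likelihood over
    antichain delimitations (exact enumeration up to ``max_exact`` tips,
    greedy split/merge hill climbing with restarts beyond)."""
    ti = _require_delimitable(tree)
    best = _search(ti, lambda a: ptp_loglik(ti, a)[0], max_exact, seed, "PTP")
    return _finish_ptp(ti, best, "PTP")


def mptp_ml(tree: dendropy.Tree, max_exact: int = 12, seed: int = 0) -> PtpResult:
    """Multi-rate PTP: each species gets its own coalescent rate; the
    delimitation minimising AIC = 2k - 2logL wins."""
    ti = _require_delimitable(tree)
    best = _search(ti, lambda a: -_aic(*mptp_loglik(ti, a)), max_exact, seed, "mPTP")
    return _finish_ptp(ti, best, "mPTP")


# ---------------------------------------------------------------------------
# GMYC

@dataclass(frozen=True)
class GmycResult:
    best_threshold_T: float
    logL_alt: float
    logL_null: float
    LR: float
    p_value: float
    entities: Partition
    n_entities: int
    ci_entity_counts: frozenset[int]
    lambda_div: float | None
    lambda_coal: float | None
    p_div: float | None
    p_coal: float | None
    candidate_thresholds: tuple[float, ...] = ()
    candidate_logL: tuple[float, ...] = ()


def _profile_class(event_terms: list[float], exposures: list[tuple[float, float]]):
    """Maximise sum_e log(lam * t_e**p) - lam * sum_i n_i**p x_i over lam>0
    and p in [0, 2]; the rate lam profiles out in closed form."""
    m = len(event_terms)
    if m == 0:
        return 0.0, None, None
    terms = np.array(event_terms)
    ns = np.array([n for n, _ in exposures])
    xs = np.array([x for _, x in exposures])
    log_terms_sum = float(np.sum(np.log(terms)))

    def neg_ll(p: float) -> float:
        E = float(np.sum(np.power(ns, p) * xs))
        if E <= 0:
            return math.inf
        return -(m * math.log(m / E) - m + p * log_terms_sum)

    res = minimize_scalar(neg_ll, bounds=(0.0, 2.0), method="bounded",
                          options={"xatol": 1e-8})
    p_hat = float(res.x)
    ll = -float(res.fun)
    E = float(np.sum(np.power(ns, p_hat) * xs))
    lam = m / E if E > 0 else math.inf
    return ll, lam, p_hat


def _gmyc_threshold_fit(heights_desc: np.ndarray, cluster_events, T: float,
                        z_floor: float = 0.0):
    """Profile log-likelihood of the mixed model at threshold T.

    ``heights_desc``: internal event heights, descending (root first).
    ``cluster_events()``: see gmyc_fit — per-cluster event heights.
    Events at height <= ``z_floor`` (identical haplotypes joining at the
    present) and zero-length waiting intervals carry no branching-time
    information and are excluded from the likelihood.
    """
    m = heights_desc.size
    bounds = np.concatenate([heights_desc, [0.0]])
    clusters = cluster_events()  # list of (n_tips, sorted desc event heights)

    def coal_C(h: float) -> float:
        """sum_k n_k (n_k - 1) with n_k the cluster lineage counts at (just
        below) height h: 1 + number of cluster events at height >= h."""
        total = 0.0
        for _n_tips_k, ev in clusters:
            nk = 1 + int(np.sum(ev >= h))
            total += nk * (nk - 1)
        return total

    div_events: list[float] = []
    div_expo: list[tuple[float, float]] = []
    coal_events: list[float] = []
    coal_expo: list[tuple[float, float]] = []

    for i in range(m):
        a, b = float(bounds[i]), float(bounds[i + 1])
        k = i + 2  # lineages crossing this interval
        if b >= T:
            if a > b:
                div_expo.append((k, a - b))
        elif a <= T:
            C = coal_C(a)
            if C > 0 and a > b:
                coal_expo.append((C, a - b))
        else:  # straddles T
            if a > T:
                div_expo.append((k, a - T))
            C = coal_C(T)
            if C > 0 and T > b:
                coal_expo.append((C, T - b))
        if i + 1 < m:  # event at height bounds[i+1] ends this interval
            h_ev = float(bounds[i + 1])
            if h_ev <= z_floor:
                continue  # identical haplotypes: no timing information
            if h_ev >= T:
                # Yule density: rate uses the pre-event lineage count
                div_events.append(k)
            else:
                # coalescent density: rate uses the tip-ward lineage counts
                coal_events.append(max(coal_C(h_ev), 2.0))

    ll_div, lam_div, p_div = _profile_class(div_events, div_expo)
    ll_coal, lam_coal, p_coal = _profile_class(coal_events, coal_expo)
    return ll_div + ll_coal, (lam_div, p_div, lam_coal, p_coal)


def gmyc_fit(
    tree: dendropy.Tree,
    lrt_df: int = 2,
    delta_logl_ci: float = 2.0,
    ultrametric_tolerance: float = 1e-4,
) -> GmycResult:
    """Single-threshold GMYC fit on an ultrametric tree.

    Candidate thresholds are midpoints between consecutive distinct node
    heights (plus one below all events — every tip its own entity — and one
    above the root, which is the one-process null).  The likelihood-ratio
    test compares the best threshold against that null with a chi-square on
    ``lrt_df`` degrees of freedom; the confidence set collects the entity
    counts of all thresholds within ``delta_logl_ci`` log units of the best.
    """
    ok, dev = is_ultrametric(tree, ultrametric_tolerance)
    if not ok:
        raise TreeError(
            f"GMYC needs an ultrametric tree (max tip-height deviation {dev:.3g})"
        )
    ti = TreeIndex(tree)
    if ti.n_tips < 3:
        raise TreeError("GMYC needs at least 3 tips")

    internal = [k for k in range(ti.n_nodes) if not ti.is_leaf(k)]
    heights_desc = np.sort(ti.height[internal])[::-1]
    root_h = float(heights_desc[0])
    if root_h <= 0:
        raise TreeError("tree height must be positive")

    distinct = np.unique(heights_desc)  # ascending
    candidates: list[float] = []
    if distinct[0] > 0:
        candidates.append(float(distinct[0]) / 2.0)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates.extend(float(x) for x in mids)
    t_null = root_h * (1.0 + 1e-9) + 1e-12
    candidates.append(t_null)

    def cluster_roots(T: float) -> list[int]:
        if T > root_h:
            return [ti.root]
        return [
            k for k in range(ti.n_nodes)
            if ti.height[k] < T
            and ti.parent[k] >= 0
            and ti.height[ti.parent[k]] >= T
        ]

    # cache per-threshold cluster event-height arrays
    def make_cluster_events(T: float):
        roots = cluster_roots(T)
        data = []
        for r in roots:
            ev = []
            stack = [r]
            while stack:
                v = stack.pop()
                if not ti.is_leaf(v):
                    ev.append(ti.height[v])
                    stack.extend(ti.children[v])
            data.append((len(ti.tips_below[r]), np.sort(np.array(ev))[::-1]))

        def cluster_events():
            return data

        return cluster_events, roots

    z_floor = 1e-9 * root_h
    cand_ll: list[float] = []
    cand_params = []
    for T in candidates:
        cluster_events, _ = make_cluster_events(T)
        ll, params = _gmyc_threshold_fit(heights_desc, cluster_events, T, z_floor)
        cand_ll.append(ll)
        cand_params.append(params)

    logL_null = cand_ll[-1]
    best_i = int(np.argmax(cand_ll))
    logL_alt = cand_ll[best_i]
    T_best = candidates[best_i]
    lam_div, p_div, lam_coal, p_coal = cand_params[best_i]
    LR = max(0.0, 2.0 * (logL_alt - logL_null))
    p_value = float(chi2.sf(LR, lrt_df)) if LR > 0 else 1.0

    def entity_count(T: float) -> int:
        return len(cluster_roots(T))

    ci_counts = frozenset(
        entity_count(candidates[i])
        for i in range(len(candidates))
        if logL_alt - cand_ll[i] <= delta_logl_ci
    )
    roots = cluster_roots(T_best)
    roots.sort(key=lambda k: min(ti.tips_below[k]))
    entities = from_components([sorted(ti.tips_below[r]) for r in roots], prefix="SP")

    return GmycResult(
        best_threshold_T=float(T_best),
        logL_alt=float(logL_alt),
        logL_null=float(logL_null),
        LR=float(LR),
        p_value=p_value,
        entities=entities,
        n_entities=len(roots),
        ci_entity_counts=ci_counts,
        lambda_div=lam_div,
        lambda_coal=lam_coal,
        p_div=p_div,
        p_coal=p_coal,
        candidate_thresholds=tuple(candidates),
        candidate_logL=tuple(cand_ll),
    )


# ---------------------------------------------------------------------------
# MCMC delimitation support

@dataclass(frozen=True)
class SupportResult:
    method: str
    per_clade_support: dict[frozenset[str], float]
    asv: float
    asddsv: float | None
    map_partition: Partition
    map_species: tuple[frozenset[str], ...]
    n_chains: int
    n_steps: int
    thinning: int
    burn_in_fraction: float
    seed: int
    sample_counts: dict[frozenset[frozenset[str]], int] = field(default_factory=dict)


def _score_fn(ti: TreeIndex, method: str):
    method = method.upper().replace("B", "")  # bPTP support == PTP likelihood
    if method == "PTP":
        return "PTP", lambda a: ptp_loglik(ti, a)[0]
    if method == "MPTP":
        return "mPTP", lambda a: -0.5 * _aic(*mptp_loglik(ti, a))
    raise TreeError(f"unknown PTP method {method!r}")


def delim_support_mcmc(
    tree: dendropy.Tree,
    method: str = "PTP",
    n_chains: int = 2,
    n_steps: int = 50_000,
    thinning: int = 10,
    burn_in_fraction: float = 0.1,
    seed: int = 0,
) -> SupportResult:
    """Flat-prior Metropolis–Hastings over antichain delimitations.

    Proposals pick uniformly among all eligible split and merge moves; the
    Hastings correction uses the move counts of the two states.  The sampled
    frequency of each species clade (across post-burn-in samples) is its
    support; ASDDSV is the mean across clades of the standard deviation of
    support across chains.
    """
    ti = _require_delimitable(tree)
    label, score = _score_fn(ti, method)
    burn_in = int(burn_in_fraction * n_steps)
    if n_steps <= burn_in:
        raise TreeError("n_steps must exceed the burn-in")
    if n_chains < 1:
        raise TreeError("need at least one chain")

    cache: dict[frozenset[int], float] = {}

    def cached_score(a: frozenset[int]) -> float:
        s = cache.get(a)
        if s is None:
            s = score(a)
            cache[a] = s
        return s

    chain_clade_counts: list[dict[frozenset[str], int]] = []
    chain_n_samples: list[int] = []
    delim_counts: dict[frozenset[frozenset[str]], int] = {}
    best_state, best_score = None, -math.inf

    for chain in range(n_chains):
        rng = np.random.default_rng(seed + chain)
        state = frozenset({ti.root})
        s_cur = cached_score(state)
        counts: dict[frozenset[str], int] = {}
        n_samples = 0
        for step in range(n_steps):
            splits = ti.split_moves(state)
            merges = ti.merge_moves(state)
            n_moves = len(splits) + len(merges)
            pick = int(rng.integers(n_moves))
            if pick < len(splits):
                proposal = ti.apply_split(state, splits[pick])
            else:
                proposal = ti.apply_merge(state, merges[pick - len(splits)])
            n_moves_prop = len(ti.split_moves(proposal)) + len(ti.merge_moves(proposal))
            s_prop = cached_score(proposal)
            log_accept = (s_prop - s_cur) + math.log(n_moves / n_moves_prop)
            if log_accept >= 0 or rng.random() < math.exp(log_accept):
                state, s_cur = proposal, s_prop
            if s_cur > best_score:
                best_state, best_score = state, s_cur
            if step >= burn_in and (step - burn_in) % thinning == 0:
                n_samples += 1
                key = frozenset(ti.tips_below[k] for k in state)
                delim_counts[key] = delim_counts.get(key, 0) + 1
                for k in state:
                    clade = ti.tips_below[k]
                    counts[clade] = counts.get(clade, 0) + 1
        chain_clade_counts.append(counts)
        chain_n_samples.append(n_samples)

    all_clades = set().union(*chain_clade_counts) if chain_clade_counts else set()
    per_clade: dict[frozenset[str], float] = {}
    per_clade_by_chain: dict[frozenset[str], list[float]] = {}
    for clade in all_clades:
        freqs = [
            chain_clade_counts[c].get(clade, 0) / chain_n_samples[c]
            for c in range(n_chains)
        ]
        per_clade[clade] = float(np.mean(freqs))
        per_clade_by_chain[clade] = freqs

    map_species = tuple(sorted(ti.species_sets(best_state), key=min))
    map_partition = ti.partition_of(best_state)
    map_clades = list(map_species)
    asv = float(np.mean([per_clade.get(c, 0.0) for c in map_clades]))
    if n_chains >= 2:
        asddsv = float(
            np.mean([np.std(per_clade_by_chain.get(c, [0.0]), ddof=0) for c in map_clades])
        )
    else:
        asddsv = None

    return SupportResult(
        method=label,
        per_clade_support=per_clade,
        asv=asv,
        asddsv=asddsv,
        map_partition=map_partition,
        map_species=map_species,
        n_chains=n_chains,
        n_steps=n_steps,
        thinning=thinning,
        burn_in_fraction=burn_in_fraction,
        seed=seed,
        sample_counts=delim_counts,
    )


def exact_delimitation_posterior(
    tree: dendropy.Tree, method: str = "PTP", max_tips: int = 12
) -> dict[frozenset[frozenset[str]], float]:
    """Exact flat-prior posterior over all delimitations (enumeration oracle)."""
    ti = TreeIndex(tree)
    if ti.n_tips > max_tips:
        raise TreeError(f"too many tips ({ti.n_tips}) for exact posterior")
    _, score = _score_fn(ti, method)
    chains = _enumerate(ti, ti.root)
    scores = np.array([score(a) for a in chains])
    w = np.exp(scores - scores.max())
    w /= w.sum()
    return {
        frozenset(ti.tips_below[k] for k in a): float(p)
        for a, p in zip(chains, w)
    }
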