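"""Pairwise evolutionary distances under p, K2P and TrN+G models.

Distances are expressed in expected substitutions per site.  Three models are
supported:

``p``
    Uncorrected proportion of differing sites, ``p = P + Q`` where ``P`` and
    ``Q`` are the transition and transversion proportions.
``K2P``
    Kimura's two-parameter correction,
    ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)``.
``TrN+G``
    Tamura–Nei correction with two transition classes (purine ``P1``,
    pyrimidine ``P2``) and unequal base frequencies, with gamma-distributed
    among-site rate variation of shape ``alpha``: every ``-ln(w)`` term of the
    plain TrN formula is replaced by ``alpha * (w**(-1/alpha) - 1)``.

Saturated pairs whose correction leaves the model's domain are flagged as
undefined (NaN in the matrix) rather than clamped, and are excluded from all
summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import Alignment
from .errors import AssignmentError, ConfigurationError, DegeneratePairError, InputError
from .partition import Partition, groups_of

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
#: index pairs that are transitions
_PURINE_TS = frozenset({(0, 2), (2, 0)})      # A<->G
_PYRIMIDINE_TS = frozenset({(1, 3), (3, 1)})  # C<->T

MODELS = ("p", "K2P", "TrN+G")


def encode_alignment(a: Alignment) -> np.ndarray:
    """(n_samples, length) uint8 matrix; 0..3 = ACGT, 4 = gap/ambiguous."""
    out = np.full((a.n_samples, a.length), 4, dtype=np.uint8)
    for row, (_, seq) in enumerate(a.records()):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for base, code in _CODE.items():
            out[row, arr == ord(base)] = code
    return out


@dataclass(frozen=True)
class PairwiseCounts:
    n_valid: int
    n_transitions_purine: int
    n_transitions_pyrimidine: int
    n_transversions: int

    @property
    def P1(self) -> float:
        return self.n_transitions_purine / self.n_valid

    @property
    def P2(self) -> float:
        return self.n_transitions_pyrimidine / self.n_valid

    @property
    def P(self) -> float:
        return self.P1 + self.P2

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_valid


@dataclass(frozen=True)
class DistanceModelConfig:
    model: str = "K2P"
    alpha: float | None = None
    base_frequencies: tuple[float, float, float, float] | None = None
    deletion: str = "pairwise"

    def __post_init__(self) -> None:
        canonical = {m.lower(): m for m in MODELS}
        m = canonical.get(self.model.lower())
        if m is None:
            raise ConfigurationError(f"unknown model {self.model!r}; choose from {MODELS}")
        object.__setattr__(self, "model", m)
        if self.deletion not in ("pairwise", "complete"):
            raise ConfigurationError("deletion must be 'pairwise' or 'complete'")
        if self.alpha is not None and self.alpha <= 0:
            raise ConfigurationError("gamma shape alpha must be positive")
        if self.base_frequencies is not None:
            freqs = tuple(float(f) for f in self.base_frequencies)
            if len(freqs) != 4 or any(f <= 0 for f in freqs):
                raise ConfigurationError("base_frequencies must be 4 positive values")
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ConfigurationError("base_frequencies must sum to 1")
            object.__setattr__(self, "base_frequencies", freqs)

    def resolved_alpha(self) -> float:
        if self.alpha is None:
            warnings.warn(
                "TrN+G gamma shape alpha not set; defaulting to 1.0",
                stacklevel=3,
            )
            return 1.0
        return self.alpha


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal; NaN marks undefined pairs
    model: DistanceModelConfig
    undefined_pairs: frozenset[tuple[str, str]] = frozenset()

    @property
    def n(self) -> int:
        return len(self.ids)

    def value(self, i: str, j: str) -> float:
        a, b = self.ids.index(i), self.ids.index(j)
        return float(self.d[a, b])

    def offdiag_values(self, include_undefined: bool = False) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        vals = self.d[iu]
        return vals if include_undefined else vals[~np.isnan(vals)]

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in keep]
        sub = self.d[np.ix_(idx, idx)]
        kept = set(keep)
        undef = frozenset(p for p in self.undefined_pairs if p[0] in kept and p[1] in kept)
        return DistanceMatrix(tuple(keep), sub, self.model, undef)


@dataclass(frozen=True)
class SummaryStats:
    minimum: float
    maximum: float
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class GroupDistanceSummary:
    overall: SummaryStats | None
    intra: SummaryStats | None
    inter: SummaryStats | None
    per_group_intra: dict[str, float] = field(default_factory=dict)
    per_pair_inter: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def clean_gap(self) -> bool:
        """True when the largest within-group average is strictly below the
        smallest between-group average (a clean barcoding gap)."""
        if self.intra is None or self.inter is None:
            return False
        return self.intra.maximum < self.inter.minimum


def _summary(values: np.ndarray) -> SummaryStats | None:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return None
    return SummaryStats(
        minimum=float(values.min()),
        maximum=float(values.max()),
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        n=int(values.size),
    )


def estimate_base_frequencies(a: Alignment, ingroup_only: bool = True) -> tuple[float, ...]:
    """Empirical ACGT frequencies pooled over the (ingroup) alignment."""
    enc = encode_alignment(a.drop_outgroup() if ingroup_only and a.outgroup_ids else a)
    counts = np.bincount(enc[enc < 4].ravel(), minlength=4).astype(float)
    if counts.sum() == 0:
        raise InputError("alignment contains no unambiguous bases")
    return tuple(counts / counts.sum())


def _complete_mask(enc: np.ndarray) -> np.ndarray:
    return (enc < 4).all(axis=0)


def pairwise_counts_encoded(
    xi: np.ndarray, xj: np.ndarray, column_mask: np.ndarray | None = None
) -> PairwiseCounts:
    valid = (xi < 4) & (xj < 4)
    if column_mask is not None:
        valid &= column_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise DegeneratePairError("sequence pair shares no valid columns")
    a, b = xi[valid], xj[valid]
    diff = a != b
    pur = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    pyr = int((((a == 1) & (b == 3)) | ((a == 3) & (b == 1))).sum())
    tv = int(diff.sum()) - pur - pyr
    return PairwiseCounts(n_valid, pur, pyr, tv)


def pairwise_counts(
    a: Alignment, i: str, j: str, deletion: str = "pairwise"
) -> PairwiseCounts:
    """Transition/transversion counts for one pair of samples."""
    if i == j:
        raise InputError("pairwise_counts requires two distinct samples")
    enc = encode_alignment(a)
    ia, ja = a.ids.index(i), a.ids.index(j)
    mask = _complete_mask(enc) if deletion == "complete" else None
    return pairwise_counts_encoded(enc[ia], enc[ja], mask)


def _k2p(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # avoid -0.0


def _tn93_gamma(
    P1: float, P2: float, Q: float, freqs: tuple[float, ...], alpha: float
) -> float:
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    k1 = 2.0 * pa * pg / pr
    k2 = 2.0 * pc * pt / py
    k3 = 2.0 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * pr)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * py)
    w3 = 1.0 - Q / (2.0 * pr * py)
    if w1 <= 0.0 or w2 <= 0.0 or w3 <= 0.0:
        return math.nan

    def g(w: float) -> float:
        # gamma-corrected analogue of -ln(w); alpha -> inf recovers -ln(w)
        if alpha >= 1e6:
            return -math.log(w)
        return alpha * (w ** (-1.0 / alpha) - 1.0)

    return k1 * g(w1) + k2 * g(w2) + k3 * g(w3)


def evolutionary_distance(c: PairwiseCounts, cfg: DistanceModelConfig) -> float:
    """Model-corrected distance for one pair; NaN when the correction is
    undefined (saturated pair)."""
    if cfg.model == "p":
        return c.P + c.Q
    if cfg.model == "K2P":
        return _k2p(c.P, c.Q)
    freqs = cfg.base_frequencies
    if freqs is None:
        raise ConfigurationError(
            "TrN+G needs base_frequencies; estimate them from the alignment "
            "(distance_matrix does this automatically)"
        )
    return _tn93_gamma(c.P1, c.P2, c.Q, freqs, cfg.resolved_alpha())


def distance_matrix(a: Alignment, cfg: DistanceModelConfig) -> DistanceMatrix:
    """All-pairs distance matrix under ``cfg``.

    For TrN+G, base frequencies default to the empirical ingroup frequencies
    of ``a`` (estimated once for the whole alignment, not per pair).
    """
    if a.n_samples < 2:
        raise InputError("need at least 2 samples for a distance matrix")
    if cfg.model == "TrN+G" and cfg.base_frequencies is None:
        cfg = replace(cfg, base_frequencies=estimate_base_frequencies(a))
    enc = encode_alignment(a)
    mask = _complete_mask(enc) if cfg.deletion == "complete" else None
    n = a.n_samples
    d = np.zeros((n, n), dtype=float)
    undefined: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            try:
                c = pairwise_counts_encoded(enc[i], enc[j], mask)
                val = evolutionary_distance(c, cfg)
            except DegeneratePairError:
                val = math.nan
            if math.isnan(val):
                undefined.add((a.ids[i], a.ids[j]))
            d[i, j] = d[j, i] = val
    return DistanceMatrix(a.ids, d, cfg, frozenset(undefined))


def group_summary(
    m: DistanceMatrix, part: Partition, semantics: str = "group-average"
) -> GroupDistanceSummary:
    """Within/between-group distance summaries under a partition.

    With ``semantics='group-average'`` (default) the intra summary is taken
    over per-group average within-group distances and the inter summary over
    per-group-pair average between-group distances; ``'all-pairs'`` summarises
    the raw pairwise values instead.  Groups of size 1 contribute no intra
    value.
    """
    if semantics not in ("group-average", "all-pairs"):
        raise ConfigurationError("semantics must be 'group-average' or 'all-pairs'")
    missing = set(m.ids) - set(part)
    if missing:
        raise AssignmentError(f"partition misses ids: {sorted(missing)[:5]}")
    idx = {sid: k for k, sid in enumerate(m.ids)}
    members = groups_of({sid: part[sid] for sid in m.ids})
    labels = sorted(members)

    def pair_values(ids_a: list[int], ids_b: list[int] | None = None) -> np.ndarray:
        if ids_b is None:
            sub = m.d[np.ix_(ids_a, ids_a)]
            vals = sub[np.triu_indices(len(ids_a), k=1)]
        else:
            vals = m.d[np.ix_(ids_a, ids_b)].ravel()
        return vals[~np.isnan(vals)]

    per_group_intra: dict[str, float] = {}
    intra_all: list[np.ndarray] = []
    for g in labels:
        ids_g = [idx[s] for s in sorted(members[g])]
        if len(ids_g) < 2:
            continue
        vals = pair_values(ids_g)
        if vals.size:
            per_group_intra[g] = float(vals.mean())
            intra_all.append(vals)

    per_pair_inter: dict[tuple[str, str], float] = {}
    inter_all: list[np.ndarray] = []
    for ai in range(len(labels)):
        for bi in range(ai + 1, len(labels)):
            ga, gb = labels[ai], labels[bi]
            vals = pair_values(
                [idx[s] for s in sorted(members[ga])],
                [idx[s] for s in sorted(members[gb])],
            )
            if vals.size:
                per_pair_inter[(ga, gb)] = float(vals.mean())
                inter_all.append(vals)

    if semantics == "group-average":
        intra_summary = _summary(np.array(list(per_group_intra.values())))
        inter_summary = _summary(np.array(list(per_pair_inter.values())))
    else:
        intra_summary = _summary(np.concatenate(intra_all) if intra_all else np.array([]))
        inter_summary = _summary(np.concatenate(inter_all) if inter_all else np.array([]))

    return GroupDistanceSummary(
        overall=_summary(m.offdiag_values()),
        intra=intra_summary,
        inter=inter_summary,
        per_group_intra=per_group_intra,
        per_pair_inter=per_pair_inter,
    )


def distance_histogram(m: DistanceMatrix, bin_width: float) -> pd.DataFrame:
    """Counts of defined pairwise distances per half-open bin [k*w, (k+1)*w)."""
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    vals = m.offdiag_values()
    if vals.size == 0:
        return pd.DataFrame({"bin_left": [], "bin_right": [], "count": []})
    k = np.floor(vals / bin_width).astype(int)
    n_bins = int(k.max()) + 1
    counts = np.bincount(k, minlength=n_bins)
    left = np.arange(n_bins) * bin_width
    return pd.DataFrame(
        {"bin_left": left, "bin_right": left + bin_width, "count": counts}
    )


def saturation_profile(
    a: Alignment, codon_positions: set[int] | None = None, frame: int = 1
) -> pd.DataFrame:
    """Transitions/transversions vs K2P distance per pair, on selected codon
    positions (a substitution-saturation diagnostic: transversions keep
    accumulating roughly linearly while transitions plateau)."""
    positions = codon_positions or {1, 2, 3}
    if not positions or not positions <= {1, 2, 3}:
        raise ConfigurationError("codon_positions must be a non-empty subset of {1,2,3}")
    enc = encode_alignment(a)
    col_pos = ((np.arange(a.length) - (frame - 1)) % 3) + 1
    mask = np.isin(col_pos, sorted(positions))
    rows = []
    for i in range(a.n_samples):
        for j in range(i + 1, a.n_samples):
            try:
                c = pairwise_counts_encoded(enc[i], enc[j], mask)
            except DegeneratePairError:
                continue
            rows.append(
                {
                    "id_i": a.ids[i],
                    "id_j": a.ids[j],
                    "transitions": c.n_transitions_purine + c.n_transitions_pyrimidine,
                    "transversions": c.n_transversions,
                    "k2p_distance": _k2p(c.P, c.Q),
                }
            )
    return pd.DataFrame(rows)


def bootstrap_standard_error(
    a: Alignment,
    i: str,
    j: str,
    cfg: DistanceModelConfig,
    n_replicates: int = 1000,
    seed: int = 0,
) -> float:
    """Site-resampling standard error of one pairwise distance (optional)."""
    if cfg.model == "TrN+G" and cfg.base_frequencies is None:
        cfg = replace(cfg, base_frequencies=estimate_base_frequencies(a))
    enc = encode_alignment(a)
    xi, xj = enc[a.ids.index(i)], enc[a.ids.index(j)]
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_replicates):
        cols = rng.integers(0, a.length, size=a.length)
        try:
            c = pairwise_counts_encoded(xi[cols], xj[cols])
            val = evolutionary_distance(c, cfg)
        except DegeneratePairError:
            continue
        if not math.isnan(val):
            reps.append(val)
    if len(reps) < 2:
        return math.nan
    return float(np.std(reps, ddof=1))


def write_matrix_tsv(m: DistanceMatrix, path: str | Path) -> None:
    """Square TSV with id header row/column; undefined pairs as 'NA'."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(m.ids) + "\n")
        for i, sid in enumerate(m.ids):
            cells = [
                "NA" if math.isnan(m.d[i, j]) else f"{m.d[i, j]:.8f}"
                for j in range(m.n)
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_matrix_tsv(path: str | Path, model: DistanceModelConfig | None = None) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = tuple(str(c) for c in df.columns)
    d = df.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise InputError(f"{path}: matrix is not square")
    undef = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if math.isnan(d[i, j]):
                undef.add((ids[i], ids[j]))
    return DistanceMatrix(ids, d, model or DistanceModelConfig(), frozenset(undef))
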