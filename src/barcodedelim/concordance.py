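"""Concordance between delimitation partitions and morphospecies.

The central statistic is the *match ratio*

    match_ratio = 2 * N_match / (N_delimited + N_morph)

where ``N_match`` counts delimited groups whose member set equals a
morphospecies exactly (a species split into cryptic lineages therefore
contributes no match), ``N_delimited`` is the number of groups the method
delimited and ``N_morph`` the number of morphospecies.  Unlike raw
``N_match``, the ratio penalises both over-splitting and lumping
symmetrically.  Reported values are rounded half-up to 3 decimals.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from sklearn.metrics import adjusted_rand_score

from .alignment import HaplotypeMap
from .distances import DistanceMatrix, GroupDistanceSummary, group_summary
from .errors import AssignmentError, InputError
from .partition import Partition, check_universe, group_sets, groups_of, n_groups


def round_half_up(x: float, digits: int = 3) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConcordanceRecord:
    method: str
    dataset: str  # "full" or "reduced"
    n_delimited: int
    n_match: int
    n_morph: int
    match_ratio: float
    ci: tuple[int, int] | None = None

    def formatted_count(self) -> str:
        """OTU count formatted Table-style, e.g. ``46 (44-49)``."""
        if self.ci is None:
            return str(self.n_delimited)
        return f"{self.n_delimited} ({self.ci[0]}-{self.ci[1]})"


@dataclass(frozen=True)
class PartitionComparison:
    n_exact_matches: int
    split_events: int
    lump_events: int
    adjusted_rand_index: float


def match_count(delim: Mapping[str, str], morph: Mapping[str, str]) -> int:
    """Number of delimited groups exactly equal to some morphospecies."""
    check_universe(delim, morph)
    return len(group_sets(delim) & group_sets(morph))


def match_ratio(n_match: int, n_delimited: int, n_morph: int) -> float:
    """2*N_match / (N_delimited + N_morph), rounded half-up to 3 decimals."""
    if min(n_match, n_delimited, n_morph) < 0:
        raise ValueError("counts must be non-negative")
    if n_match > min(n_delimited, n_morph):
        raise ValueError("n_match cannot exceed min(n_delimited, n_morph)")
    if n_delimited + n_morph == 0:
        raise ValueError("n_delimited + n_morph must be positive")
    return round_half_up(2.0 * n_match / (n_delimited + n_morph), 3)


def compare_partitions(a: Mapping[str, str], b: Mapping[str, str]) -> PartitionComparison:
    """Exact matches, split/lump event counts and adjusted Rand index.

    A group of ``a`` overlapping k > 1 groups of ``b`` is one split event (of
    degree k); a group of ``b`` overlapping k > 1 groups of ``a`` is one lump
    event.
    """
    check_universe(a, b)
    ids = sorted(a)
    ari = float(adjusted_rand_score([a[i] for i in ids], [b[i] for i in ids]))

    def events(src: Mapping[str, str], dst: Mapping[str, str]) -> int:
        count = 0
        for members in groups_of(src).values():
            if len({dst[m] for m in members}) > 1:
                count += 1
        return count

    return PartitionComparison(
        n_exact_matches=len(group_sets(a) & group_sets(b)),
        split_events=events(a, b),
        lump_events=events(b, a),
        adjusted_rand_index=ari,
    )


def expand_reduced_partition(p: Mapping[str, str], h: HaplotypeMap) -> Partition:
    """Lift a partition over haplotype representatives to all samples."""
    out: Partition = {}
    for sid, rep in h.representative_of.items():
        if rep not in p:
            raise AssignmentError(
                f"representative {rep!r} (for sample {sid!r}) missing from partition"
            )
        out[sid] = p[rep]
    return out


def concordance_record(
    method: str,
    dataset: str,
    delim: Mapping[str, str] | tuple[int, int],
    morph: Mapping[str, str] | int,
    ci: tuple[int, int] | None = None,
) -> ConcordanceRecord:
    """One record, either from partitions or from pre-tabulated counts.

    ``delim`` is a partition or a ``(n_delimited, n_match)`` pair; ``morph``
    is the reference partition or ``n_morph``.
    """
    if isinstance(delim, Mapping):
        if not isinstance(morph, Mapping):
            raise InputError("partition-mode records need the morphospecies partition")
        n_delim = n_groups(delim)
        n_m = match_count(delim, morph)
        n_morph_ = n_groups(morph)
    else:
        n_delim, n_m = delim
        n_morph_ = morph if isinstance(morph, int) else n_groups(morph)
    return ConcordanceRecord(
        method=method,
        dataset=dataset,
        n_delimited=n_delim,
        n_match=n_m,
        n_morph=n_morph_,
        match_ratio=match_ratio(n_m, n_delim, n_morph_),
        ci=ci,
    )


def concordance_table(
    methods: Sequence[tuple],
    morph: Mapping[str, str] | int,
) -> list[ConcordanceRecord]:
    """Build Table-style concordance records for several methods.

    Each entry of ``methods`` is ``(label, dataset, delim)`` or
    ``(label, dataset, delim, ci)`` with ``delim`` a partition or a
    ``(n_delimited, n_match)`` count pair.
    """
    records = []
    for entry in methods:
        label, dataset, delim = entry[0], entry[1], entry[2]
        ci = entry[3] if len(entry) > 3 else None
        records.append(concordance_record(label, dataset, delim, morph, ci=ci))
    return records


def write_concordance_tsv(records: Sequence[ConcordanceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("method\tdataset\tn_delimited\tn_match\tn_morph\tmatch_ratio\totus\n")
        for r in records:
            fh.write(
                f"{r.method}\t{r.dataset}\t{r.n_delimited}\t{r.n_match}\t"
                f"{r.n_morph}\t{r.match_ratio:.3f}\t{r.formatted_count()}\n"
            )


@dataclass(frozen=True)
class GapReassignmentEntry:
    model: str
    partition_label: str
    summary: GroupDistanceSummary
    clean_gap: bool


def gap_reassignment_report(
    matrices_by_model: Mapping[str, DistanceMatrix],
    partitions: Mapping[str, Mapping[str, str]],
    semantics: str = "group-average",
) -> list[GapReassignmentEntry]:
    """Within/between-group distance summaries for each substitution model
    under each grouping, flagging whether the grouping yields a clean
    barcoding gap (max within-group average < min between-group average)."""
    entries = []
    for model_label, m in matrices_by_model.items():
        for part_label, part in partitions.items():
            s = group_summary(m, dict(part), semantics=semantics)
            entries.append(
                GapReassignmentEntry(
                    model=model_label,
                    partition_label=part_label,
                    summary=s,
                    clean_gap=s.clean_gap,
                )
            )
    return entries
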