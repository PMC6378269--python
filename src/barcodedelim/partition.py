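"""Partitions: assignments of sample identifiers to group labels.

A partition is represented as a plain ``dict`` mapping each sample id to an
opaque group label (a string).  Morphospecies tables and every delimitation
method in this package produce or consume this representation.  On disk a
partition is a two-column tab-separated table ``sample_id<TAB>group_label``
with an optional header line.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from pathlib import Path

from .errors import AssignmentError, InputError

Partition = dict[str, str]


def groups_of(partition: Mapping[str, str]) -> dict[str, set[str]]:
    """Invert a partition into ``{group_label: set_of_sample_ids}``."""
    out: dict[str, set[str]] = {}
    for sid, label in partition.items():
        out.setdefault(label, set()).add(sid)
    return out


def group_sets(partition: Mapping[str, str]) -> set[frozenset[str]]:
    """The set of member sets, label-free (useful for exact-match counting)."""
    return {frozenset(m) for m in groups_of(partition).values()}


def n_groups(partition: Mapping[str, str]) -> int:
    return len(set(partition.values()))


def check_universe(a: Mapping[str, str], b: Mapping[str, str]) -> None:
    """Raise unless both partitions cover exactly the same sample ids."""
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))[:5]
        only_b = sorted(set(b) - set(a))[:5]
        raise AssignmentError(
            f"partitions cover different sample ids (e.g. {only_a} vs {only_b})"
        )


def restrict(partition: Mapping[str, str], ids: Iterable[str]) -> Partition:
    """Restrict a partition to ``ids``; every id must be assigned."""
    out: Partition = {}
    for sid in ids:
        if sid not in partition:
            raise AssignmentError(f"sample {sid!r} is not assigned to any group")
        out[sid] = partition[sid]
    return out


def from_components(components: Iterable[Iterable[str]], prefix: str = "OTU") -> Partition:
    """Build a partition from disjoint member groups, labelling them
    ``{prefix}_0001`` ... in order of each group's first-listed member."""
    part: Partition = {}
    for k, members in enumerate(components, start=1):
        label = f"{prefix}_{k:04d}"
        for sid in members:
            part[sid] = label
    return part


def read_partition_tsv(path: str | Path) -> Partition:
    """Read a two-column (sample_id, group_label) TSV; header optional.

    A first line whose columns look like header words (``sample``/``id``/
    ``group``/``label``, case-insensitive) is skipped.
    """
    path = Path(path)
    part: Partition = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise InputError(f"{path}:{ln}: expected 2 tab-separated columns")
            sid, label = fields[0].strip(), fields[1].strip()
            if ln == 1 and {w for w in (sid.lower(), label.lower())} <= {
                "sample", "sample_id", "id", "group", "group_label", "label", "species",
            }:
                continue
            if sid in part:
                raise InputError(f"{path}:{ln}: duplicate sample id {sid!r}")
            part[sid] = label
    if not part:
        raise InputError(f"{path}: empty partition file")
    return part


def write_partition_tsv(partition: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup_label\n")
        for sid in sorted(partition):
            fh.write(f"{sid}\t{partition[sid]}\n")
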