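"""Barcode alignment I/O, validation and summaries.

The working object is an :class:`Alignment`: a fixed-length nucleotide matrix
over named samples, optionally with a designated outgroup.  From it the module
derives the two datasets every downstream analysis runs on — the *full*
dataset (all samples) and the *reduced* dataset (one representative per unique
haplotype) — plus per-sample protein-coding quality checks and per-column site
statistics (conserved / variable / parsimony-informative / singleton).
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import AlignmentError, ConfigurationError, IdentifierError, InputError

# IUPAC nucleotide alphabet (plus gap); anything outside is rejected on read.
_VALID_CHARS = frozenset("ACGTRYSWKMBDHVN-")
_UNAMBIGUOUS = frozenset("ACGT")

#: genetic-code label -> NCBI translation table id
GENETIC_CODES = {
    "standard": 1,
    "vertebrate_mito": 2,
    "invertebrate_mito": 5,
}


@dataclass(frozen=True)
class Alignment:
    """A fixed-length nucleotide alignment over uniquely named samples."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    length: int
    outgroup_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise IdentifierError("duplicate sample ids in alignment")
        for sid, seq in zip(self.ids, self.seqs):
            if len(seq) != self.length:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, expected {self.length}"
                )
        unknown = self.outgroup_ids - set(self.ids)
        if unknown:
            raise IdentifierError(f"outgroup ids not in alignment: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def ingroup_ids(self) -> tuple[str, ...]:
        return tuple(i for i in self.ids if i not in self.outgroup_ids)

    def sequence(self, sample_id: str) -> str:
        try:
            return self.seqs[self.ids.index(sample_id)]
        except ValueError:
            raise IdentifierError(f"unknown sample id {sample_id!r}") from None

    def records(self) -> Iterable[tuple[str, str]]:
        return zip(self.ids, self.seqs)

    def subset(self, keep: Sequence[str]) -> "Alignment":
        """Sub-alignment over ``keep`` (in the given order)."""
        keep_set = set(keep)
        missing = keep_set - set(self.ids)
        if missing:
            raise IdentifierError(f"unknown sample ids: {sorted(missing)}")
        idx = {sid: k for k, sid in enumerate(self.ids)}
        return Alignment(
            ids=tuple(keep),
            seqs=tuple(self.seqs[idx[s]] for s in keep),
            length=self.length,
            outgroup_ids=self.outgroup_ids & keep_set,
        )

    def drop_outgroup(self) -> "Alignment":
        return self.subset(self.ingroup_ids)


@dataclass(frozen=True)
class HaplotypeMap:
    """Maps every sample to the representative of its exact-sequence haplotype."""

    representative_of: dict[str, str]
    haplotype_count: int

    def expand_ids(self, representative: str) -> list[str]:
        return [s for s, r in self.representative_of.items() if r == representative]


@dataclass(frozen=True)
class SiteStats:
    n_conserved: int
    n_variable: int
    n_parsimony_informative: int
    n_singleton: int
    n_sites_considered: int

    def to_dict(self) -> dict[str, int]:
        return {
            "n_conserved": self.n_conserved,
            "n_variable": self.n_variable,
            "n_parsimony_informative": self.n_parsimony_informative,
            "n_singleton": self.n_singleton,
            "n_sites_considered": self.n_sites_considered,
        }


@dataclass(frozen=True)
class SampleQc:
    sample_id: str
    ungapped_length: int
    internal_stop_codons: tuple[int, ...]  # 1-based codon indices
    has_gaps: bool

    @property
    def coding_clean(self) -> bool:
        return not self.internal_stop_codons and not self.has_gaps


@dataclass(frozen=True)
class QcReport:
    reading_frame: int
    genetic_code: str
    samples: tuple[SampleQc, ...] = field(default_factory=tuple)

    @property
    def all_clean(self) -> bool:
        return all(s.coding_clean for s in self.samples)

    def to_dict(self) -> dict:
        return {
            "reading_frame": self.reading_frame,
            "genetic_code": self.genetic_code,
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "ungapped_length": s.ungapped_length,
                    "internal_stop_codons": list(s.internal_stop_codons),
                    "has_gaps": s.has_gaps,
                    "coding_clean": s.coding_clean,
                }
                for s in self.samples
            ],
        }


def read_alignment(
    path: str | Path, outgroup_labels: Sequence[str] | None = None
) -> Alignment:
    """Read a FASTA alignment (wrapped or unwrapped), upper-casing sequences.

    All records must have equal length and unique ids; at least two records
    are required.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    ids: list[str] = []
    seqs: list[str] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise IdentifierError(f"duplicate sample id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise AlignmentError(
                f"sequence {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        ids.append(rec.id)
        seqs.append(seq)
    if len(ids) < 2:
        raise InputError(f"{path}: need at least 2 sequences, found {len(ids)}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(
            f"{path}: sequences have unequal lengths {sorted(lengths)}; "
            "input must be pre-aligned"
        )
    outgroup = frozenset(outgroup_labels or ())
    return Alignment(tuple(ids), tuple(seqs), lengths.pop(), outgroup)


def write_fasta(a: Alignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in a.records():
            fh.write(f">{sid}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def check_coding(
    a: Alignment, frame: int = 1, code: str = "vertebrate_mito"
) -> QcReport:
    """Translate each sequence and report internal stop codons and gaps.

    ``frame`` is the 1-based offset of the first complete codon.  Codons
    containing gaps or ambiguity codes are not classified as stops.  A stop
    codon in the final (possibly terminal) codon position is not counted as
    internal.
    """
    if frame not in (1, 2, 3):
        raise ConfigurationError(f"reading frame must be 1, 2 or 3, got {frame}")
    if code not in GENETIC_CODES:
        raise ConfigurationError(
            f"unknown genetic code {code!r}; known: {sorted(GENETIC_CODES)}"
        )
    table = CodonTable.unambiguous_dna_by_id[GENETIC_CODES[code]]
    stop_codons = set(table.stop_codons)

    samples = []
    for sid, seq in a.records():
        ungapped = seq.replace("-", "")
        coding = ungapped[frame - 1 :]
        n_codons = len(coding) // 3
        stops = [
            k + 1
            for k in range(n_codons)
            if coding[3 * k : 3 * k + 3] in stop_codons
        ]
        internal = tuple(k for k in stops if k != n_codons)
        samples.append(
            SampleQc(
                sample_id=sid,
                ungapped_length=len(ungapped),
                internal_stop_codons=internal,
                has_gaps="-" in seq,
            )
        )
    return QcReport(reading_frame=frame, genetic_code=code, samples=tuple(samples))


def collapse_haplotypes(a: Alignment) -> tuple[Alignment, HaplotypeMap]:
    """Collapse exact duplicate sequences to their first-encountered sample.

    Identity is exact string equality after upper-casing (done on read), so
    sequences differing only by an N do *not* collapse.  Idempotent.
    """
    rep_by_seq: dict[str, str] = {}
    representative_of: dict[str, str] = {}
    keep: list[str] = []
    for sid, seq in a.records():
        rep = rep_by_seq.get(seq)
        if rep is None:
            rep_by_seq[seq] = sid
            representative_of[sid] = sid
            keep.append(sid)
        else:
            representative_of[sid] = rep
    reduced = a.subset(keep)
    return reduced, HaplotypeMap(representative_of, haplotype_count=len(keep))


def site_statistics(
    a: Alignment,
    exclude_outgroup: bool = True,
    complete_deletion: bool = True,
) -> SiteStats:
    """Count conserved / variable / parsimony-informative / singleton columns.

    With ``complete_deletion`` (default) a column is dropped from
    consideration whenever any considered sequence carries a gap or a
    non-ACGT code there; otherwise those characters are ignored within the
    column and the column counts as long as at least one unambiguous base
    remains.
    """
    seqs = [s for sid, s in a.records() if not (exclude_outgroup and sid in a.outgroup_ids)]
    if not seqs:
        raise InputError("no sequences left after outgroup exclusion")

    n_cons = n_var = n_pi = n_single = n_considered = 0
    for col in zip(*seqs):
        states = [c for c in col if c in _UNAMBIGUOUS]
        if complete_deletion and len(states) != len(col):
            continue
        if not states:
            continue
        n_considered += 1
        counts: dict[str, int] = {}
        for c in states:
            counts[c] = counts.get(c, 0) + 1
        if len(counts) == 1:
            n_cons += 1
        else:
            n_var += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                n_pi += 1
            else:
                n_single += 1
    return SiteStats(
        n_conserved=n_cons,
        n_variable=n_var,
        n_parsimony_informative=n_pi,
        n_singleton=n_single,
        n_sites_considered=n_considered,
    )


def write_haplotype_map_tsv(h: HaplotypeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\trepresentative_id\n")
        for sid in sorted(h.representative_of):
            fh.write(f"{sid}\t{h.representative_of[sid]}\n")


def write_json(obj, path: str | Path) -> None:
    """Serialize a SiteStats/QcReport (anything with ``to_dict``) to JSON."""
    payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
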