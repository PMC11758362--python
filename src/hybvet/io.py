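"""Readers, writers and shared record types.

Every external format the suite touches is handled here: FASTA sequence
sets, 12-column tabular homology hits (the ``outfmt 6`` dialect:
``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore``), and 3-column per-position depth tables (the
``samtools depth`` dialect).

Coordinate convention
---------------------
On disk, hit and depth coordinates are 1-based inclusive, as the
producing tools emit them.  Internally, all interval arithmetic uses
0-based half-open coordinates; the conversion happens exactly once, at
this I/O boundary (:meth:`TabularHit.subject_interval` and friends).
Minus-strand hits arrive with ``s_start > s_end`` and are normalized to
``(min, max)`` with an explicit strand flag.

Sequence comparison throughout the package is case-insensitive while
input case (e.g. soft-masking) is preserved on output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq


class FormatError(ValueError):
    """An input file violates its format contract."""


class Source(str, Enum):
    """Provenance of a target sequence."""

    GENOME_DERIVED = "genome_derived"
    TRANSCRIPT_DERIVED = "transcript_derived"


class Method(str, Enum):
    """How a target entered the panel."""

    REFINEMENT = "refinement"
    SINGLE_COPY_MINING = "single_copy_mining"
    UNIVERSAL_MATCH = "universal_match"
    OTHER = "other"


@dataclass
class TargetSeq:
    """A named nucleotide sequence with a provenance tag.

    ``length`` is the quantity called *L* throughout the paralogy
    statistics: the total length of the target in base pairs.
    """

    id: str
    residues: str
    source: Source = Source.TRANSCRIPT_DERIVED
    method: Method = Method.OTHER

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"empty sequence for {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "TargetSeq":
        return replace(self, residues=str(Seq(self.residues).reverse_complement()))


@dataclass(frozen=True)
class TabularHit:
    """One homology match between a query and a subject sequence.

    Coordinates are stored 1-based inclusive (the on-disk convention).
    A normalized hit has ``s_start <= s_end``; ``strand`` records
    whether the subject interval was reversed on input.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    strand: str = "+"

    def normalized(self) -> "TabularHit":
        """Return the hit with subject coordinates in ascending order.

        Involutive: normalizing an already-normalized hit is a no-op.
        """
        if self.s_start <= self.s_end:
            return self
        return replace(self, s_start=self.s_end, s_end=self.s_start, strand="-")

    @property
    def subject_interval(self) -> tuple[int, int]:
        """Subject span as a 0-based half-open interval (requires normalized)."""
        if self.s_start > self.s_end:
            raise ValueError("hit is not normalized; call .normalized() first")
        return self.s_start - 1, self.s_end

    @property
    def query_interval(self) -> tuple[int, int]:
        """Query span as a 0-based half-open interval."""
        return self.q_start - 1, self.q_end


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: residues}`` mapping.

    Duplicate ids are rejected (the id is named in the error); an empty
    file is an error.  Wrapped and blank-line-separated records are
    concatenated; case is preserved.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise FormatError(f"no sequences in {path}")
    return records


def read_targets(
    path: str | Path,
    source: Source = Source.TRANSCRIPT_DERIVED,
    method: Method = Method.OTHER,
) -> list[TargetSeq]:
    """Read a FASTA file as a list of :class:`TargetSeq` with one provenance tag."""
    return [
        TargetSeq(name, seq, source=source, method=method)
        for name, seq in read_fasta(path).items()
    ]


def write_fasta(
    sequences: Mapping[str, str] | Iterable[TargetSeq],
    path: str | Path,
    width: int = 70,
) -> None:
    """Write sequences to ``path`` in FASTA, wrapping lines at ``width``."""
    if isinstance(sequences, Mapping):
        items = list(sequences.items())
    else:
        items = [(s.id, s.residues) for s in sequences]
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_tabular_hits(path: str | Path) -> list[TabularHit]:
    """Parse a 12-column tab-separated hit table.

    Subject coordinates are normalized to ``(min, max)`` with
    ``strand="-"`` iff ``s_start > s_end`` on input.  Row order is
    preserved.  An empty file is valid (zero hits).
    """
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = TabularHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    align_len=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if hit.align_len < 1:
                raise FormatError(f"{path}:{lineno}: alignment length < 1")
            if hit.q_start > hit.q_end:
                raise FormatError(
                    f"{path}:{lineno}: query start {hit.q_start} > end {hit.q_end}"
                )
            hits.append(hit.normalized())
    return hits


def write_tabular_hits(hits: Iterable[TabularHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect, restoring minus-strand coordinate order."""
    with open(path, "w") as fh:
        for h in hits:
            s_start, s_end = h.s_start, h.s_end
            if h.strand == "-" and s_start < s_end:
                s_start, s_end = s_end, s_start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        h.pct_identity,
                        h.align_len,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        s_start,
                        s_end,
                        h.evalue,
                        h.bit_score,
                    )
                )
                + "\n"
            )


def read_depth_table(
    path: str | Path, lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Read a 3-column depth TSV into dense per-position vectors.

    ``lengths`` declares the references and their lengths; the returned
    vectors are dense over positions ``1..L`` with absent positions
    filled with depth 0 (depth tools typically omit zero-depth rows).

    Raises :class:`FormatError` for undeclared references, positions
    beyond the declared length, or negative depth.
    """
    vectors = {ref: np.zeros(int(L), dtype=np.int64) for ref, L in lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            ref = fields[0]
            if ref not in vectors:
                raise FormatError(
                    f"{path}:{lineno}: undeclared reference {ref!r}"
                )
            try:
                pos = int(fields[1])
                depth = int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth {depth}")
            if not 1 <= pos <= lengths[ref]:
                raise FormatError(
                    f"{path}:{lineno}: position {pos} outside 1..{lengths[ref]} "
                    f"for {ref!r}"
                )
            vectors[ref][pos - 1] = depth
    return vectors


def write_depth_table(
    depths: Mapping[str, np.ndarray], path: str | Path, skip_zero: bool = True
) -> None:
    """Write dense depth vectors as a 3-column TSV (1-based positions).

    With ``skip_zero`` (the default, matching depth tools), zero-depth
    positions are omitted and the table is sparse.
    """
    with open(path, "w") as fh:
        for ref, vec in depths.items():
            for i, d in enumerate(np.asarray(vec), start=1):
                if skip_zero and d == 0:
                    continue
                fh.write(f"{ref}\t{i}\t{int(d)}\n")


@dataclass
class Alignment:
    """A multiple sequence alignment: equal-length rows keyed by id."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        if self.rows:
            n = len(self.rows[0])
            for name, row in zip(self.ids, self.rows):
                if len(row) != n:
                    raise ValueError(
                        f"ragged alignment: row {name!r} has length {len(row)}, "
                        f"expected {n}"
                    )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    @classmethod
    def read(cls, path: str | Path) -> "Alignment":
        records = read_fasta(path)
        return cls(list(records), list(records.values()))

    def write(self, path: str | Path) -> None:
        write_fasta(dict(zip(self.ids, self.rows)), path)
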