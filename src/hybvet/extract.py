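"""Genome-guided extraction of full-gene (exon + intron) targets.

Given protein translations of candidate targets mapped to a draft
genome assembly (protein-query vs nucleotide-subject hits), this
module decides, per target, whether a single scaffold carries the
gene, computes the genomic span of the mapped region — the difference
between the largest end and the smallest start of the qualifying
matches, an estimate of the full gene length including introns — and
extracts the spanned sequence, reverse-complemented for minus-strand
genes.

Rules, in order:

* scaffolds shorter than 500 bp are discarded up front;
* hits with identity < 70% or E-value >= 1e-6 are discarded;
* a target whose qualifying hits touch more than one scaffold is
  rejected outright (``multi_scaffold``), even if one scaffold alone
  would qualify;
* otherwise more than 70% of the protein's length (union of query
  intervals, strict ``>``) must map to that scaffold.

Coverage is measured on the protein query because the query is the
constant reference across scaffolds.  The extracted genomic form is
only adopted if it subsequently passes depth-based vetting
(:func:`revert_failed_genomic`); supercontigs that are too short
relative to their reference CDS fall back to the CDS
(:func:`choose_target_form`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .io import Method, Source, TabularHit, TargetSeq


class Outcome(str, Enum):
    GENOMIC = "genomic"
    TRANSCRIPT_FALLBACK = "transcript_fallback"
    REJECTED = "rejected"


class Reason(str, Enum):
    OK = "ok"
    MULTI_SCAFFOLD = "multi_scaffold"
    LOW_QUERY_COVERAGE = "low_query_coverage"
    FAILED_DEPTH_VET = "failed_depth_vet"
    SUPERCONTIG_TOO_SHORT = "supercontig_too_short"


@dataclass(frozen=True)
class GeneRegion:
    """A gene's genomic span: 0-based half-open coordinates on one scaffold."""

    target_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    query_coverage: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def span_len(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExtractionDecision:
    target_id: str
    outcome: Outcome
    reason: Reason


def filter_scaffolds(
    scaffolds: Mapping[str, str], min_len: int = 500
) -> dict[str, str]:
    """Drop scaffolds shorter than ``min_len`` bases (strict ``<`` removed)."""
    return {name: seq for name, seq in scaffolds.items() if len(seq) >= min_len}


def filter_protein_hits(
    hits: Iterable[TabularHit],
    min_ident: float = 70.0,
    max_evalue: float = 1e-6,
) -> list[TabularHit]:
    """Keep hits with identity >= ``min_ident`` and E-value strictly below ``max_evalue``."""
    return [
        h
        for h in hits
        if h.pct_identity >= min_ident and h.evalue < max_evalue
    ]


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of 0-based half-open intervals."""
    merged_total = 0
    current_start = current_end = None
    for start, end in sorted(intervals):
        if current_end is None or start > current_end:
            if current_end is not None:
                merged_total += current_end - current_start
            current_start, current_end = start, end
        else:
            current_end = max(current_end, end)
    if current_end is not None:
        merged_total += current_end - current_start
    return merged_total


def assign_scaffold(
    target_id: str,
    hits: Sequence[TabularHit],
    protein_len: int,
    min_qcov: float = 0.70,
) -> GeneRegion | ExtractionDecision:
    """Decide the single scaffold carrying a target and its genomic span.

    Hits must already be filtered (:func:`filter_protein_hits`).  The
    target is rejected if its hits touch two or more scaffolds, or if
    the union of query (protein) intervals covers ``<= min_qcov`` of
    the protein length (strict ``>`` required to pass).  The region's
    strand is that of the highest-bit-score hit; ties are broken
    deterministically (bit score desc, then scaffold id, then start).
    The result does not depend on the order of ``hits``.
    """
    if protein_len <= 0:
        raise ValueError("protein length must be positive")
    hits = [h.normalized() for h in hits]
    scaffold_ids = {h.subject_id for h in hits}
    if len(scaffold_ids) > 1:
        return ExtractionDecision(target_id, Outcome.REJECTED, Reason.MULTI_SCAFFOLD)
    coverage = (
        union_length(h.query_interval for h in hits) / protein_len if hits else 0.0
    )
    if coverage <= min_qcov:
        return ExtractionDecision(
            target_id, Outcome.REJECTED, Reason.LOW_QUERY_COVERAGE
        )
    ordered = sorted(
        hits, key=lambda h: (-h.bit_score, h.subject_id, h.subject_interval[0])
    )
    strand = ordered[0].strand
    if len({h.strand for h in hits}) > 1:
        warnings.warn(
            f"mixed-strand hits for target {target_id!r}; using the strand of "
            "the highest-scoring hit",
            stacklevel=2,
        )
    return GeneRegion(
        target_id=target_id,
        scaffold_id=ordered[0].subject_id,
        start=min(h.subject_interval[0] for h in hits),
        end=max(h.subject_interval[1] for h in hits),
        strand=strand,
        query_coverage=coverage,
    )


def extract_region(
    scaffolds: Mapping[str, str], region: GeneRegion
) -> TargetSeq:
    """Cut the region's span out of its scaffold, in gene orientation.

    Minus-strand regions are reverse-complemented so the returned
    sequence reads 5'->3' along the gene.
    """
    if region.scaffold_id not in scaffolds:
        raise ValueError(f"unknown scaffold {region.scaffold_id!r}")
    scaffold = scaffolds[region.scaffold_id]
    if region.end > len(scaffold):
        raise ValueError(
            f"region {region.start}..{region.end} exceeds scaffold "
            f"{region.scaffold_id!r} of length {len(scaffold)}"
        )
    seq = TargetSeq(
        id=region.target_id,
        residues=scaffold[region.start : region.end],
        source=Source.GENOME_DERIVED,
        method=Method.OTHER,
    )
    if region.strand == "-":
        seq = seq.reverse_complement()
    return seq


def choose_target_form(
    supercontig_len: int, reference_cds_len: int, min_frac: float = 0.70
) -> str:
    """Prefer the supercontig unless it is too short relative to its CDS.

    Returns ``"cds"`` iff ``supercontig_len < min_frac *
    reference_cds_len`` (strict), else ``"supercontig"``.  The rule is
    agnostic to the supercontig's internal make-up.
    """
    if supercontig_len <= 0 or reference_cds_len <= 0:
        raise ValueError("lengths must be positive")
    if supercontig_len < min_frac * reference_cds_len:
        return "cds"
    return "supercontig"


def revert_failed_genomic(
    genomic: Mapping[str, TargetSeq],
    transcripts: Mapping[str, TargetSeq],
    depth_pass: Mapping[str, bool],
) -> tuple[dict[str, TargetSeq], list[ExtractionDecision]]:
    """Adopt genomic forms that pass depth vetting; revert the rest.

    Every target needs a transcript form (the already-vetted fallback);
    every genomic candidate needs a depth verdict.  The final set keeps
    the genomic form where the verdict passed and the transcript form
    otherwise.  Decisions are emitted for the genomic candidates.
    """
    final: dict[str, TargetSeq] = {}
    decisions: list[ExtractionDecision] = []
    for target_id, transcript in transcripts.items():
        if target_id in genomic:
            if target_id not in depth_pass:
                raise ValueError(
                    f"genomic candidate {target_id!r} has no depth verdict"
                )
            if depth_pass[target_id]:
                final[target_id] = genomic[target_id]
                decisions.append(
                    ExtractionDecision(target_id, Outcome.GENOMIC, Reason.OK)
                )
            else:
                final[target_id] = transcript
                decisions.append(
                    ExtractionDecision(
                        target_id,
                        Outcome.TRANSCRIPT_FALLBACK,
                        Reason.FAILED_DEPTH_VET,
                    )
                )
        else:
            final[target_id] = transcript
    return final, decisions
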