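"""Alignment end-trimming ("chomping") and informativeness metrics.

Poorly aligned, low-identity stretches at the ends of individual
sequences in a multiple sequence alignment are a common artifact of
assembling divergent flanking regions.  The chomper recodes them to
gaps: the majority-rule consensus of the alignment is computed once
and used as the reference against which every row is trimmed
independently, in two rounds (forward from the left edge, reverse from
the right).  Each round slides a fixed-width window inward one column
at a time; while the window's identity to the consensus is below the
threshold, the row's nucleotides in that window are recoded to ``-``,
and the round stops at the first window that reaches the threshold.
Recoding is cumulative and never deletes columns, so the alignment
shape is preserved and the operation is idempotent.

Window identity is computed over the columns where both the consensus
and the row carry an unambiguous base (A/C/G/T, case-insensitive);
a window with no comparable columns scores 0, so trimming continues
through gap runs.

Also here: the parsimony-informative site classifier and a per-target
intron-content summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .io import Alignment

_BASES = frozenset("ACGT")
GAP = "-"


@dataclass(frozen=True)
class ChompConfig:
    """Sliding-window trimming parameters.

    ``window`` is the window width in alignment columns, ``threshold``
    the identity fraction a window must reach to stop trimming, and
    ``stride`` the number of columns the window advances per step.
    """

    window: int = 50
    threshold: float = 0.8
    stride: int = 1

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must be within [0, 1]")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class ChompEntry:
    """Per-row trimming report.

    Stops are window start offsets: ``forward_stop`` counts columns
    from the left edge, ``reverse_stop`` from the right edge; ``None``
    means no window reached the threshold in that round.
    """

    seq_id: str
    head_recoded: int
    tail_recoded: int
    forward_stop: int | None
    reverse_stop: int | None


@dataclass
class ChompReport:
    entries: list[ChompEntry]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


class SiteClass(str, Enum):
    CONSTANT = "constant"
    SINGLETON_VARIABLE = "singleton_variable"
    PARSIMONY_INFORMATIVE = "parsimony_informative"
    ALL_GAP_OR_AMBIGUOUS = "all_gap_or_ambiguous"


def majority_consensus(alignment: Alignment) -> str:
    """Per-column most frequent base among A/C/G/T, case-folded.

    Gaps and ambiguity codes are ignored; ties break in the fixed
    order A < C < G < T; a column with no unambiguous base yields
    ``-``.
    """
    if alignment.n_rows < 2:
        raise ValueError("consensus needs at least two rows")
    arr = np.array(
        [list(row.upper()) for row in alignment.rows], dtype="U1"
    )
    # counts stacked in ACGT order; argmax takes the first max, which
    # realises the documented tie order
    counts = np.stack([(arr == b).sum(axis=0) for b in "ACGT"])
    best = counts.argmax(axis=0)
    total = counts.sum(axis=0)
    bases = np.array(list("ACGT"), dtype="U1")
    consensus = bases[best]
    consensus[total == 0] = GAP
    return "".join(consensus)


def window_identity(
    consensus: str, row: str, start_col: int, cfg: ChompConfig
) -> float:
    """Identity between consensus and row over one window.

    ``matches / comparable`` where comparable columns are those in
    which both strings have an unambiguous base; 0 if none are
    comparable.
    """
    if start_col < 0 or start_col + cfg.window > len(consensus):
        raise ValueError(
            f"window [{start_col}, {start_col + cfg.window}) off the end of "
            f"{len(consensus)} columns"
        )
    return _identity(consensus, row, start_col, start_col + cfg.window)


def _identity(consensus: str, row: list[str] | str, start: int, end: int) -> float:
    comparable = 0
    matches = 0
    for j in range(start, end):
        a = consensus[j].upper()
        b = row[j].upper()
        if a in _BASES and b in _BASES:
            comparable += 1
            if a == b:
                matches += 1
    return matches / comparable if comparable else 0.0


def chomp_sequence(
    consensus: str, row: str, cfg: ChompConfig = ChompConfig(), seq_id: str = ""
) -> tuple[str, ChompEntry]:
    """Trim one row against the consensus; returns the row and a report.

    Forward round: windows start at column 0 and advance by ``stride``;
    every window whose identity is below the threshold has the row's
    non-gap characters within it recoded to ``-``; the round stops at
    the first window reaching the threshold.  The reverse round does
    the same from the right edge.  An alignment shorter than the
    window is handled as a single truncated window spanning all
    columns.
    """
    n = len(row)
    if len(consensus) != n:
        raise ValueError("consensus and row lengths differ")
    w = min(cfg.window, n)
    chars = list(row)

    def run(reverse: bool) -> tuple[int, int | None]:
        recoded = 0
        offset = 0
        while offset + w <= n:
            start = (n - offset - w) if reverse else offset
            if _identity(consensus, chars, start, start + w) >= cfg.threshold:
                return recoded, offset
            for j in range(start, start + w):
                if chars[j] != GAP:
                    chars[j] = GAP
                    recoded += 1
            offset += cfg.stride
        return recoded, None

    head_recoded, forward_stop = run(reverse=False)
    tail_recoded, reverse_stop = run(reverse=True)
    return "".join(chars), ChompEntry(
        seq_id, head_recoded, tail_recoded, forward_stop, reverse_stop
    )


def chomp_alignment(
    alignment: Alignment,
    cfg: ChompConfig = ChompConfig(),
    consensus: str | None = None,
) -> tuple[Alignment, ChompReport]:
    """Chomp every row of an alignment against its majority consensus.

    The consensus is computed once from the input alignment (or taken
    from ``consensus``) and each row is trimmed against it
    independently; the column count never changes.
    """
    if alignment.n_rows < 2:
        raise ValueError("chomping needs at least two rows")
    ref = consensus if consensus is not None else majority_consensus(alignment)
    if len(ref) != alignment.n_columns:
        raise ValueError("consensus length does not match the alignment")
    new_rows = []
    entries = []
    for seq_id, row in zip(alignment.ids, alignment.rows):
        trimmed, entry = chomp_sequence(ref, row, cfg, seq_id=seq_id)
        new_rows.append(trimmed)
        entries.append(entry)
    return Alignment(list(alignment.ids), new_rows), ChompReport(entries)


def drop_all_gap_columns(alignment: Alignment) -> Alignment:
    """Remove columns consisting solely of gaps (an optional post-chomp step)."""
    arr = np.array([list(row) for row in alignment.rows], dtype="U1")
    keep = ~(arr == GAP).all(axis=0)
    return Alignment(
        list(alignment.ids), ["".join(r) for r in arr[:, keep]]
    )


def classify_sites(
    alignment: Alignment,
) -> tuple[list[SiteClass], int, float]:
    """Classify every column and count parsimony-informative sites.

    A column is parsimony-informative iff at least two distinct
    unambiguous bases each occur in at least two rows (gaps and
    ambiguity codes ignored).  Columns with one distinct base are
    constant, other variable columns are singleton-variable, and
    columns with no unambiguous base at all are degenerate.  Returns
    the per-column classes, the PI count, and PI count / n_columns.
    """
    arr = np.array([list(row.upper()) for row in alignment.rows], dtype="U1")
    counts = np.stack([(arr == b).sum(axis=0) for b in "ACGT"])
    n_distinct = (counts >= 1).sum(axis=0)
    n_recurrent = (counts >= 2).sum(axis=0)
    classes: list[SiteClass] = []
    for j in range(alignment.n_columns):
        if n_distinct[j] == 0:
            classes.append(SiteClass.ALL_GAP_OR_AMBIGUOUS)
        elif n_distinct[j] == 1:
            classes.append(SiteClass.CONSTANT)
        elif n_recurrent[j] >= 2:
            classes.append(SiteClass.PARSIMONY_INFORMATIVE)
        else:
            classes.append(SiteClass.SINGLETON_VARIABLE)
    pi_count = sum(c is SiteClass.PARSIMONY_INFORMATIVE for c in classes)
    pi_proportion = pi_count / alignment.n_columns if alignment.n_columns else 0.0
    return classes, pi_count, pi_proportion


def intron_fraction(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample intron content and per-target summaries.

    ``records`` needs columns ``sample``, ``target``, ``intron_len``
    and ``gene_len`` (intron length is zero when no intronic region was
    identified).  Per record, ``fraction = intron_len / gene_len`` (0
    when the gene length is 0).  Per target, the maximum gene length
    across samples serves as a proxy for the gene's true length.
    Returns (per-record table with the fraction column, per-target
    summary).
    """
    required = {"sample", "target", "intron_len", "gene_len"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (records["intron_len"] < 0).any() or (records["gene_len"] < 0).any():
        raise ValueError("lengths must be nonnegative")
    bad = records["intron_len"] > records["gene_len"]
    if bad.any():
        first = records[bad].iloc[0]
        raise ValueError(
            f"intron length exceeds gene length for target "
            f"{first['target']!r} in sample {first['sample']!r}"
        )
    per_record = records.copy()
    gene_len = per_record["gene_len"].astype(float)
    per_record["fraction"] = np.where(
        gene_len > 0, per_record["intron_len"] / gene_len.replace(0, np.nan), 0.0
    )
    per_record["fraction"] = per_record["fraction"].fillna(0.0)
    summary = (
        per_record.groupby("target")
        .agg(
            max_gene_len=("gene_len", "max"),
            total_intron_len=("intron_len", "sum"),
            mean_fraction=("fraction", "mean"),
            n_samples=("sample", "nunique"),
        )
        .reset_index()
    )
    return per_record, summary
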