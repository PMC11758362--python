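"""Paralogy, missingness and copy number from capture assemblies.

For each sample, all assembled contigs are matched to the reference
targets with a nucleotide homology search; from the resulting hit
table, each site of a target gets a coverage count *c*: the number of
**distinct contigs** with at least one match covering that site
(multiple, possibly self-overlapping hits from one fragmented contig
count once — a chimeric split hit must not look like a paralog).

With L the target length, l_0 the number of uncovered sites and
l_{c>=2} the number of sites covered by two or more contigs:

* paralogy      P = l_{c>=2} / (L - l_0)   (undefined if fully missing)
* missingness   M = l_0 / L
* copy number   C = mean of c over covered sites (undefined if none)

Repeating this per sample populates the samples x targets paralogy
matrix, from which targets with high mean P or mean M are discarded
and samples with aberrant genome-wide paralogy (e.g. ploidy shifts)
are flagged.

Undefined cells (fully missing target in a sample) are excluded from
per-target means rather than treated as zero: missingness is not
evidence of single-copy status.  All flag thresholds are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TabularHit


@dataclass
class CoverageProfile:
    """Per-site distinct-contig coverage over one target."""

    target_id: str
    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=np.int64)
        if self.c.ndim != 1 or len(self.c) == 0:
            raise ValueError("coverage vector must be 1-D and non-empty")
        if (self.c < 0).any():
            raise ValueError("coverage counts must be nonnegative")

    @property
    def L(self) -> int:
        return len(self.c)

    @property
    def l_0(self) -> int:
        return int(np.count_nonzero(self.c == 0))

    @property
    def l_1(self) -> int:
        return int(np.count_nonzero(self.c == 1))

    @property
    def l_ge2(self) -> int:
        return int(np.count_nonzero(self.c >= 2))


@dataclass(frozen=True)
class ParalogyStats:
    """P, M and C for one target in one sample; P and C may be undefined (None)."""

    target_id: str
    sample_id: str
    P: float | None
    M: float
    C: float | None


def filter_hits(
    hits: Iterable[TabularHit], min_len: int = 150, min_ident: float = 70.0
) -> list[TabularHit]:
    """Drop matches below the length and identity thresholds.

    A hit is kept iff ``align_len >= min_len`` and ``pct_identity >=
    min_ident`` (values *below* the thresholds are removed, so the
    boundary is kept).  Order is preserved.
    """
    return [
        h
        for h in hits
        if h.align_len >= min_len and h.pct_identity >= min_ident
    ]


def site_coverage(
    hits: Iterable[TabularHit], length: int, target_id: str | None = None
) -> CoverageProfile:
    """Count, per site of the target, the distinct contigs covering it.

    ``hits`` are matches with the target as subject and contigs as
    queries.  A site's count is the number of distinct contig ids with
    at least one hit interval covering it; strand is irrelevant (the
    normalized subject interval is used).  Sites outside every hit get
    c = 0.  A hit interval exceeding the target length is an error.
    """
    if length < 1:
        raise ValueError("target length must be positive")
    masks: dict[str, np.ndarray] = {}
    tid = target_id
    for h in hits:
        h = h.normalized()
        if tid is None:
            tid = h.subject_id
        elif target_id is not None and h.subject_id != target_id:
            raise ValueError(
                f"hit subject {h.subject_id!r} does not match target {target_id!r}"
            )
        s0, s1 = h.subject_interval
        if s0 < 0 or s1 > length:
            raise ValueError(
                f"hit {h.query_id!r} spans {h.s_start}..{h.s_end}, outside "
                f"target of length {length}"
            )
        mask = masks.get(h.query_id)
        if mask is None:
            mask = masks[h.query_id] = np.zeros(length, dtype=bool)
        mask[s0:s1] = True
    c = np.zeros(length, dtype=np.int64)
    for mask in masks.values():
        c += mask
    return CoverageProfile(tid if tid is not None else "", c)


def paralogy_stats(
    profile: CoverageProfile, sample_id: str = "sample"
) -> ParalogyStats:
    """Compute P, M and C from a coverage profile.

    P = l_{c>=2} / (L - l_0) when any site is covered, else None;
    M = l_0 / L; C = mean coverage over covered sites, else None.
    """
    L = profile.L
    l_0 = profile.l_0
    covered = L - l_0
    if covered > 0:
        P: float | None = profile.l_ge2 / covered
        C: float | None = float(profile.c[profile.c >= 1].mean())
    else:
        P = None
        C = None
    return ParalogyStats(profile.target_id, sample_id, P, l_0 / L, C)


class ParalogyMatrix:
    """Samples x targets matrices of P and M with cross-sample summaries.

    Undefined cells are NaN and are excluded from means.
    """

    def __init__(self, P: pd.DataFrame, M: pd.DataFrame) -> None:
        if not P.index.equals(M.index) or not P.columns.equals(M.columns):
            raise ValueError("P and M matrices must share samples and targets")
        self.P = P
        self.M = M

    @property
    def samples(self) -> list[str]:
        return list(self.P.index)

    @property
    def targets(self) -> list[str]:
        return list(self.P.columns)

    def mean_p(self, drop_samples: Iterable[str] = ()) -> pd.Series:
        """Per-target mean P across samples (NaN cells excluded)."""
        drop = list(drop_samples)
        return self.P.drop(index=drop).mean(axis=0, skipna=True)

    def mean_m(self, drop_samples: Iterable[str] = ()) -> pd.Series:
        drop = list(drop_samples)
        return self.M.drop(index=drop).mean(axis=0, skipna=True)

    def sample_mean_p(self) -> pd.Series:
        """Per-sample mean P across targets (NaN cells excluded)."""
        return self.P.mean(axis=1, skipna=True)


def build_paralogy_matrix(stats: Iterable[ParalogyStats]) -> ParalogyMatrix:
    """Assemble per-sample statistics into the paralogy matrix.

    Each (sample, target) pair may appear at most once; missing cells
    (pairs never observed, or undefined P) become NaN.
    """
    samples: list[str] = []
    targets: list[str] = []
    p_cells: dict[tuple[str, str], float] = {}
    m_cells: dict[tuple[str, str], float] = {}
    for s in stats:
        key = (s.sample_id, s.target_id)
        if key in m_cells:
            raise ValueError(
                f"duplicate entry for sample {s.sample_id!r}, "
                f"target {s.target_id!r}"
            )
        if s.sample_id not in samples:
            samples.append(s.sample_id)
        if s.target_id not in targets:
            targets.append(s.target_id)
        p_cells[key] = np.nan if s.P is None else s.P
        m_cells[key] = s.M
    P = pd.DataFrame(np.nan, index=samples, columns=targets)
    M = pd.DataFrame(np.nan, index=samples, columns=targets)
    for (sample, target), v in p_cells.items():
        P.at[sample, target] = v
    for (sample, target), v in m_cells.items():
        M.at[sample, target] = v
    return ParalogyMatrix(P, M)


def _check_threshold(threshold: float) -> None:
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be within [0, 1], got {threshold}")


def flag_paralogs(
    matrix: ParalogyMatrix,
    second: ParalogyMatrix | None = None,
    threshold: float = 0.40,
    drop_samples: Iterable[str] = (),
) -> set[str]:
    """Targets whose mean P exceeds ``threshold`` (strict) in either matrix.

    The two matrices typically come from searches against two reference
    forms of the same targets (e.g. actual targets vs their CDS
    versions); a single-matrix mode is supported.
    """
    _check_threshold(threshold)
    mean_p = matrix.mean_p(drop_samples)
    flagged = set(mean_p[mean_p > threshold].index)
    if second is not None:
        mean_p2 = second.mean_p(drop_samples)
        flagged |= set(mean_p2[mean_p2 > threshold].index)
    return flagged


def flag_missing(
    matrix: ParalogyMatrix,
    threshold: float = 0.40,
    drop_samples: Iterable[str] = (),
) -> set[str]:
    """Targets whose mean M exceeds ``threshold`` (strict), on the designated matrix."""
    _check_threshold(threshold)
    mean_m = matrix.mean_m(drop_samples)
    return set(mean_m[mean_m > threshold].index)


@dataclass
class RefinementResult:
    """Outcome of removing flagged targets from a panel."""

    retained: list[str]
    paralog_flagged: set[str]
    missing_flagged: set[str]

    @property
    def n_removed(self) -> int:
        # union, so doubly-flagged targets are not double-counted
        return len(self.paralog_flagged | self.missing_flagged)


def refine_superset(
    targets: Sequence[str],
    paralog_flags: Iterable[str],
    missing_flags: Iterable[str],
) -> RefinementResult:
    """Remove paralog- and missingness-flagged targets from the panel."""
    target_set = set(targets)
    paralog = set(paralog_flags) & target_set
    missing = set(missing_flags) & target_set
    removed = paralog | missing
    retained = [t for t in targets if t not in removed]
    return RefinementResult(retained, paralog, missing)


def flag_outlier_samples(
    matrix: ParalogyMatrix, delta: float = 0.20
) -> set[str]:
    """Samples deviating from the per-target mean P by more than ``delta`` on average.

    For each sample s: mean over targets t of ``|P[s,t] - meanP[t]|``,
    with undefined cells excluded pairwise.  A genome-wide shift of this
    size usually indicates a ploidy difference rather than per-locus
    paralogy.
    """
    mean_p = matrix.P.mean(axis=0, skipna=True)
    deviation = (matrix.P - mean_p).abs().mean(axis=1, skipna=True)
    return set(deviation[deviation > delta].index)


def length_ratio_flag(lengths: Sequence[float], ratio: float = 0.75) -> bool:
    """Length-based per-sample paralog flag.

    Flag iff there are at least two contigs and the second-longest is
    strictly longer than ``ratio`` times the longest.
    """
    if any(l < 0 for l in lengths):
        raise ValueError("contig lengths must be nonnegative")
    if len(lengths) < 2:
        return False
    ordered = sorted(lengths, reverse=True)
    return ordered[1] > ratio * ordered[0]


def plot_paralogy_heatmap(matrix: ParalogyMatrix, path: str | Path) -> None:
    """Save a samples x targets heatmap of P, both axes ordered by mean P."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sample_order = matrix.sample_mean_p().sort_values(ascending=False).index
    target_order = matrix.mean_p().sort_values(ascending=False).index
    data = matrix.P.loc[sample_order, target_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.05 * len(target_order)), max(3, 0.15 * len(sample_order)))
    )
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xlabel("targets (by mean P)")
    ax.set_ylabel("samples (by mean P)")
    fig.colorbar(im, ax=ax, label="P")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
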