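"""Depth-based vetting of candidate targets from shotgun reads.

Whole-genome shotgun (or off-target capture) reads are a largely
unbiased sample of the genome, so mapped read depth over a candidate
target carries copy-number information: a missing target has depth
near zero, a duplicated one roughly twice the depth of the single-copy
bulk.  This module implements two filter cascades built on that idea:

* :func:`vet_by_median_depth` — remove any target whose median depth
  deviates by more than ``k`` standard deviations from the grand mean
  across all targets, per species; a target failing in *any* species
  fails overall.
* :func:`offtarget_prefilter` — a three-stage cascade for screening
  large candidate sets with sparse off-target reads: breadth of
  coverage, then depth relative to the grand mean, then length.

Mapping-quality filtering (e.g. keeping MAPQ > 20 alignments) belongs
upstream, in the production of the depth table.

Boundary semantics, fixed here and tested: "deviated by more than"
is a strict ``>``; "at least 80% covered" is ``>=``; "shorter than
1,500 bp" is a strict ``<``.  Standard deviations are sample SDs
(n - 1 denominator), so at least two targets are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

REASON_PASS = "pass"
REASON_DEPTH_OUTLIER = "depth_outlier"
REASON_LOW_BREADTH = "low_breadth"
REASON_TOO_SHORT = "too_short"


@dataclass(frozen=True)
class TargetDepthStats:
    """Per-target depth summary over all L positions (zeros included).

    ``mean_depth`` is total depth divided by length; ``median_depth``
    the median over all positions; ``breadth`` the fraction of
    positions covered by at least one read.
    """

    target_id: str
    length: int
    mean_depth: float
    median_depth: float
    breadth: float


@dataclass(frozen=True)
class GrandStats:
    """Across-target mean and sample SD of a per-target summary statistic."""

    statistic: str
    grand_mean: float
    grand_sd: float
    n_targets: int


@dataclass
class VetVerdict:
    """Pass/fail verdict for one target, per species and overall."""

    target_id: str
    species_pass: dict[str, bool]
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        """Overall pass: the target must pass in every species tested."""
        return all(self.species_pass.values())

    @property
    def reason(self) -> str:
        for species, ok in self.species_pass.items():
            if not ok:
                return self.reasons.get(species, REASON_DEPTH_OUTLIER)
        return REASON_PASS


def summarize_depth(
    depths: Mapping[str, np.ndarray], lengths: Mapping[str, int]
) -> list[TargetDepthStats]:
    """Summarize dense depth vectors into per-target statistics.

    Every target in ``lengths`` must have a vector of exactly its
    declared length.  Zero-depth positions count toward the mean and
    median (median of an even count is the mean of the middle two).
    """
    out = []
    for target_id, length in lengths.items():
        if target_id not in depths:
            raise ValueError(f"no depth vector for target {target_id!r}")
        vec = np.asarray(depths[target_id])
        if len(vec) != length:
            raise ValueError(
                f"depth vector for {target_id!r} has length {len(vec)}, "
                f"declared {length}"
            )
        out.append(
            TargetDepthStats(
                target_id=target_id,
                length=int(length),
                mean_depth=float(vec.sum()) / length,
                median_depth=float(np.median(vec)),
                breadth=float(np.count_nonzero(vec >= 1)) / length,
            )
        )
    return out


def grand_stats(values: Sequence[float], statistic: str) -> GrandStats:
    """Mean and sample SD (n-1) of a per-target statistic across all targets."""
    if len(values) < 2:
        raise ValueError(
            "grand SD is undefined for fewer than two targets "
            f"(got {len(values)})"
        )
    arr = np.asarray(values, dtype=float)
    return GrandStats(
        statistic=statistic,
        grand_mean=float(arr.mean()),
        grand_sd=float(arr.std(ddof=1)),
        n_targets=len(arr),
    )


def vet_by_median_depth(
    stats_by_species: Mapping[str, Sequence[TargetDepthStats]],
    k_sd: float = 1.0,
    grand_statistic: str = "median",
) -> list[VetVerdict]:
    """Flag targets whose median depth is an outlier in any species.

    Per species, the grand mean and sample SD are computed over the
    per-target median depths (``grand_statistic="mean"`` switches both
    the test statistic and the grand baseline to per-target means), and
    a target fails that species iff ``|stat - grand_mean| > k_sd *
    grand_sd`` (strict).  Absent targets (all-zero depth) are included
    in the grand statistics.  The overall verdict fails iff the target
    fails in any species.
    """
    if grand_statistic not in ("median", "mean"):
        raise ValueError(f"unknown grand_statistic {grand_statistic!r}")
    attr = "median_depth" if grand_statistic == "median" else "mean_depth"

    target_order: list[str] = []
    species_fail: dict[str, dict[str, bool]] = {}
    for species, stats in stats_by_species.items():
        values = [getattr(s, attr) for s in stats]
        gs = grand_stats(values, grand_statistic)
        fails = {
            s.target_id: abs(v - gs.grand_mean) > k_sd * gs.grand_sd
            for s, v in zip(stats, values)
        }
        species_fail[species] = fails
        for s in stats:
            if s.target_id not in target_order:
                target_order.append(s.target_id)

    verdicts = []
    for target_id in target_order:
        species_pass = {}
        reasons = {}
        for species, fails in species_fail.items():
            if target_id not in fails:
                raise ValueError(
                    f"target {target_id!r} has no depth stats for "
                    f"species {species!r}"
                )
            failed = fails[target_id]
            species_pass[species] = not failed
            reasons[species] = REASON_DEPTH_OUTLIER if failed else REASON_PASS
        verdicts.append(VetVerdict(target_id, species_pass, reasons))
    return verdicts


def offtarget_prefilter(
    stats: Sequence[TargetDepthStats],
    min_breadth: float = 0.80,
    k_sd: float = 2.0,
    min_len: int = 1500,
    species: str = "pooled",
) -> list[VetVerdict]:
    """Three-stage prefilter for large candidate sets with sparse reads.

    Stages, applied in order (the reason code records the first failed
    stage):

    1. breadth: fail if less than ``min_breadth`` of the length is
       covered by at least one read (strict ``<``);
    2. depth: keep iff the mean depth exceeds — but stays within
       ``k_sd`` sample SDs of — the grand mean depth, i.e.
       ``grand_mean < mean_depth <= grand_mean + k_sd * grand_sd``.
       Grand statistics are computed over *all* input genes, before
       the breadth filter;
    3. length: fail if shorter than ``min_len`` bases (strict ``<``).
    """
    gs = grand_stats([s.mean_depth for s in stats], "mean")
    upper = gs.grand_mean + k_sd * gs.grand_sd
    verdicts = []
    for s in stats:
        if s.breadth < min_breadth:
            reason = REASON_LOW_BREADTH
        elif not (gs.grand_mean < s.mean_depth <= upper):
            reason = REASON_DEPTH_OUTLIER
        elif s.length < min_len:
            reason = REASON_TOO_SHORT
        else:
            reason = REASON_PASS
        verdicts.append(
            VetVerdict(
                s.target_id,
                {species: reason == REASON_PASS},
                {species: reason},
            )
        )
    return verdicts


def expected_coverage(
    n_read_pairs: float, mean_pair_bases: float, footprint: float
) -> float:
    """Expected mean coverage of a target footprint from a read budget.

    ``n_read_pairs * mean_pair_bases / footprint``, unrounded.  E.g.
    one million ~290 bp read pairs over a 1.16 Mb panel give ~250X.
    """
    if footprint <= 0:
        raise ValueError("footprint must be positive")
    if n_read_pairs < 0 or mean_pair_bases < 0:
        raise ValueError("read counts and lengths must be nonnegative")
    return n_read_pairs * mean_pair_bases / footprint


def round_to_ten(x: float) -> int:
    """Convenience reporter: round a coverage value to the nearest ten."""
    return int(round(x / 10.0) * 10)
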