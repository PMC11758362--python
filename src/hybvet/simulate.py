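"""Seeded generators for every input the vetting suite consumes.

Each generator plants a known ground truth — copy numbers, gene spans
and strands, terminal junk lengths — so every stage of the suite can
be exercised and checked at desk scale without external downloads or
third-party search binaries: homology-hit tables are generated
directly with exact coordinates rather than by running an aligner.

Defaults encode the study conditions the suite is meant for: a panel
of 115 candidate targets of 1.5-3 kb, of which 100 are single-copy,
10 carry a diverged duplicate (10% per-base substitution, typical of
reasonably recent plant gene duplicates) and 5 are absent from the
genome; shotgun depth is Poisson around a base of 30 reads per copy.
An overdispersed negative-binomial depth option exists to stress the
SD-based filters.  All generators are bit-reproducible for a fixed
seed and configuration.

Not modelled: read-level errors, GC or mappability bias, and repeat
landscapes — the generators emulate the *summaries* (depth tables and
hit tables) that real pipelines would produce from such data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import Alignment, TabularHit
from .wgs import TargetDepthStats

_BASES = np.array(list("ACGT"), dtype="U1")


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs shared by the generators.

    ``duplicate_fraction`` and ``absent_fraction`` are the proportions
    of targets planted with copy number 2 and 0; ``divergence`` is the
    per-base substitution probability between duplicate copies;
    ``base_depth`` the expected read depth per genome copy.  The
    intron model (``n_introns`` per gene, intron length range) shapes
    the planted gene structures for extraction fixtures.
    """

    seed: int = 0
    n_targets: int = 115
    length_range: tuple[int, int] = (1500, 3000)
    duplicate_fraction: float = 10 / 115
    absent_fraction: float = 5 / 115
    divergence: float = 0.10
    base_depth: float = 30.0
    n_introns: int = 2
    intron_length_range: tuple[int, int] = (200, 500)
    overdispersion: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.duplicate_fraction <= 1 and 0 <= self.absent_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.duplicate_fraction + self.absent_fraction > 1:
            raise ValueError("duplicate and absent fractions sum past 1")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must lie in [0, 1]")


@dataclass
class TargetTruth:
    """Planted copy numbers and duplicate-copy sequences."""

    copy_number: dict[str, int]
    paralog_seqs: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class GeneTruth:
    """A planted gene: its span on the scaffold and the true gene sequence.

    ``start``/``end`` are 0-based half-open on the (primary) scaffold;
    ``gene_seq`` reads 5'->3' along the gene (i.e. reverse-complemented
    relative to the scaffold for minus-strand genes).  ``split`` marks
    the gene whose last exon was moved to a second scaffold.
    """

    target_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    gene_seq: str
    protein_len: int
    exon_spans: tuple[tuple[int, int], ...]
    split: bool = False


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base with probability ``rate`` (always to a different base)."""
    arr = np.array(list(seq), dtype="U1")
    hit = rng.random(len(arr)) < rate
    idx = np.flatnonzero(hit)
    if len(idx):
        base_idx = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(base_idx + rng.integers(1, 4, size=len(idx))) % 4]
    return "".join(arr)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def simulate_targets(cfg: SimConfig) -> tuple[dict[str, str], TargetTruth]:
    """Generate a candidate panel with planted copy numbers.

    I.i.d. uniform base composition; targets planted as duplicated get
    a diverged paralog copy recorded in the truth; absent targets are
    recorded with copy number 0.
    """
    rng = np.random.default_rng(cfg.seed)
    n_dup = round(cfg.n_targets * cfg.duplicate_fraction)
    n_abs = round(cfg.n_targets * cfg.absent_fraction)
    ids = [f"target{i + 1:04d}" for i in range(cfg.n_targets)]
    special = rng.choice(cfg.n_targets, size=n_dup + n_abs, replace=False)
    copy_number = {tid: 1 for tid in ids}
    for i in special[:n_dup]:
        copy_number[ids[i]] = 2
    for i in special[n_dup:]:
        copy_number[ids[i]] = 0

    targets: dict[str, str] = {}
    paralogs: dict[str, str] = {}
    lo, hi = cfg.length_range
    for tid in ids:
        seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        targets[tid] = seq
        if copy_number[tid] == 2:
            paralogs[tid] = _mutate(rng, seq, cfg.divergence)
    return targets, TargetTruth(copy_number, paralogs)


def simulate_depth(
    targets: Mapping[str, str],
    truth: TargetTruth,
    cfg: SimConfig,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-position read depth under the planted copy numbers.

    depth_i ~ Poisson(copy_number * base_depth) independently per
    position; absent targets are all-zero.  With
    ``cfg.overdispersion`` set (a dispersion parameter r), depth is
    negative-binomial with the same mean and variance mean * (1 +
    mean / r), to stress the SD-based filters.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    depths: dict[str, np.ndarray] = {}
    for tid, seq in targets.items():
        mean = truth.copy_number.get(tid, 1) * cfg.base_depth
        L = len(seq)
        if mean == 0:
            depths[tid] = np.zeros(L, dtype=np.int64)
        elif cfg.overdispersion is None:
            depths[tid] = rng.poisson(mean, size=L)
        else:
            r = cfg.overdispersion
            depths[tid] = rng.negative_binomial(r, r / (r + mean), size=L)
    return depths


def simulate_genome_with_genes(
    targets: Mapping[str, str],
    cfg: SimConfig,
    split_target: str | None = None,
) -> tuple[dict[str, str], list[TabularHit], list[GeneTruth]]:
    """Plant each target as an exon/intron gene in its own scaffold.

    The target sequence (trimmed to a codon multiple) supplies the
    exons, which are embedded in a random-strand gene separated by
    introns drawn from the config's intron model, flanked by random
    sequence.  Emitted hits mimic a perfect protein-vs-genome search:
    identity 100, tiny E-values, exact per-exon coordinates in protein
    (query) and genomic (subject) space, with minus-strand hits carrying
    descending subject coordinates before normalization.

    ``split_target`` names one gene whose last exon is planted on a
    second scaffold, to exercise the multi-scaffold rejection rule.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    scaffolds: dict[str, str] = {}
    hits: list[TabularHit] = []
    genes: list[GeneTruth] = []
    n_exons = cfg.n_introns + 1
    ilo, ihi = cfg.intron_length_range

    for k, (tid, target_seq) in enumerate(targets.items()):
        cds = target_seq[: len(target_seq) - len(target_seq) % 3]
        protein_len = len(cds) // 3
        # split the CDS into n_exons codon-aligned chunks
        cuts = sorted(
            rng.choice(np.arange(1, protein_len), size=n_exons - 1, replace=False)
        )
        bounds_aa = [0, *cuts, protein_len]
        exons = [
            cds[3 * a : 3 * b] for a, b in zip(bounds_aa[:-1], bounds_aa[1:])
        ]
        introns = [
            _random_seq(rng, int(rng.integers(ilo, ihi + 1)))
            for _ in range(cfg.n_introns)
        ]
        gene_parts = [exons[0]]
        for intron, exon in zip(introns, exons[1:]):
            gene_parts.extend([intron, exon])
        gene_seq = "".join(gene_parts)
        strand = "+" if rng.random() < 0.5 else "-"
        split = tid == split_target

        # exon spans in gene space (0-based half-open)
        spans = []
        pos = 0
        for exon, intron in zip(exons, introns + [""]):
            spans.append((pos, pos + len(exon)))
            pos += len(exon) + len(intron)

        scaffold_id = f"scaffold{k + 1:04d}"
        flank_l = _random_seq(rng, int(rng.integers(300, 801)))
        flank_r = _random_seq(rng, int(rng.integers(300, 801)))
        planted = gene_seq if strand == "+" else _revcomp(gene_seq)
        if split:
            # last exon goes to its own scaffold (plus strand there)
            head = gene_seq[: spans[-1][0]]
            planted_head = head if strand == "+" else _revcomp(head)
            scaffolds[scaffold_id] = flank_l + planted_head + flank_r
            aux_id = f"{scaffold_id}b"
            aux_flank = _random_seq(rng, 300)
            scaffolds[aux_id] = aux_flank + exons[-1] + aux_flank
        else:
            scaffolds[scaffold_id] = flank_l + planted + flank_r
        offset = len(flank_l)
        gene_len = len(gene_seq) if not split else spans[-1][0]

        for i, ((g0, g1), (a0, a1)) in enumerate(zip(spans, zip(bounds_aa[:-1], bounds_aa[1:]))):
            aa_len = a1 - a0
            if split and i == len(spans) - 1:
                s0, s1 = 300, 300 + (g1 - g0)
                subj, hit_strand = aux_id, "+"
            else:
                subj = scaffold_id
                hit_strand = strand
                if strand == "+":
                    s0, s1 = offset + g0, offset + g1
                else:
                    s0, s1 = offset + gene_len - g1, offset + gene_len - g0
            s_start, s_end = (s0 + 1, s1) if hit_strand == "+" else (s1, s0 + 1)
            hits.append(
                TabularHit(
                    query_id=tid,
                    subject_id=subj,
                    pct_identity=100.0,
                    align_len=aa_len,
                    mismatches=0,
                    gap_opens=0,
                    q_start=a0 + 1,
                    q_end=a1,
                    s_start=s_start,
                    s_end=s_end,
                    evalue=1e-50,
                    bit_score=round(1.9 * aa_len, 1),
                ).normalized()
            )
        genes.append(
            GeneTruth(
                target_id=tid,
                scaffold_id=scaffold_id,
                start=offset,
                end=offset + len(gene_seq),
                strand=strand,
                gene_seq=gene_seq,
                protein_len=protein_len,
                exon_spans=tuple(spans),
                split=split,
            )
        )
    return scaffolds, hits, genes


def simulate_capture_assembly(
    targets: Mapping[str, str],
    truth: TargetTruth,
    cfg: SimConfig,
    sample_id: str = "sample1",
    seed: int | None = None,
) -> tuple[dict[str, str], list[TabularHit]]:
    """Contigs and their hit table for one capture sample.

    Single-copy targets yield 1-3 adjacent tiling contigs from one
    haplotype (per-site coverage 1 everywhere covered, so P = 0);
    duplicated targets additionally yield a contig from the second
    copy overlapping the first on at least 80% of the covered length
    (so P >= 0.8); absent targets yield nothing (M = 1).  Hits carry
    exact coordinates; second-copy hits have identity reduced by the
    configured divergence.
    """
    rng = np.random.default_rng(
        (cfg.seed if seed is None else seed) + abs(hash(sample_id)) % 100_000
    )
    contigs: dict[str, str] = {}
    hits: list[TabularHit] = []
    for tid, seq in targets.items():
        copies = truth.copy_number.get(tid, 1)
        if copies == 0:
            continue
        L = len(seq)
        n_tiles = int(rng.integers(1, 4))
        # contiguous tiles, each at least 200 bp
        while True:
            cuts = np.sort(rng.integers(200, L - 199, size=n_tiles - 1)) if n_tiles > 1 else np.array([], dtype=int)
            bounds = [0, *cuts.tolist(), L]
            if all(b - a >= 200 for a, b in zip(bounds[:-1], bounds[1:])):
                break
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            name = f"{sample_id}_{tid}_c{i}"
            contigs[name] = seq[a:b]
            hits.append(
                TabularHit(
                    query_id=name,
                    subject_id=tid,
                    pct_identity=round(float(rng.uniform(96.0, 100.0)), 1),
                    align_len=b - a,
                    mismatches=0,
                    gap_opens=0,
                    q_start=1,
                    q_end=b - a,
                    s_start=a + 1,
                    s_end=b,
                    evalue=1e-30,
                    bit_score=round(1.8 * (b - a), 1),
                )
            )
        if copies >= 2:
            frac = float(rng.uniform(0.85, 1.0))
            b = max(200, int(round(frac * L)))
            name = f"{sample_id}_{tid}_p0"
            paralog = truth.paralog_seqs.get(tid, seq)
            contigs[name] = paralog[:b]
            hits.append(
                TabularHit(
                    query_id=name,
                    subject_id=tid,
                    pct_identity=round(100.0 * (1 - cfg.divergence), 1),
                    align_len=b,
                    mismatches=int(round(b * cfg.divergence)),
                    gap_opens=0,
                    q_start=1,
                    q_end=b,
                    s_start=1,
                    s_end=b,
                    evalue=1e-20,
                    bit_score=round(1.5 * b, 1),
                )
            )
    return contigs, hits


def simulate_msa(
    cfg: SimConfig,
    n_rows: int = 8,
    n_columns: int = 400,
    divergence: float = 0.02,
    n_junk_rows: int = 2,
    junk_length_range: tuple[int, int] = (55, 80),
    junk_mode: str = "uniform",
    seed: int | None = None,
) -> tuple[Alignment, dict[str, tuple[int, int]]]:
    """An alignment with planted low-identity terminal junk.

    Core columns descend from a random ancestor with small per-row
    divergence; the first ``n_junk_rows`` rows get junk of recorded
    head and tail lengths.  ``junk_mode="uniform"`` draws junk bases
    uniformly (expected 25% identity to anything — chance matches can
    legitimately halt the trimming crawl inside the junk);
    ``junk_mode="mismatch"`` draws each junk base from the three bases
    differing from the ancestor, so the full junk run is guaranteed
    below any identity threshold.  Returns the alignment and
    ``{row_id: (head_len, tail_len)}`` with zeros for clean rows.
    """
    if junk_mode not in ("uniform", "mismatch"):
        raise ValueError(f"unknown junk_mode {junk_mode!r}")
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 7)
    if n_rows < 2:
        raise ValueError("need at least two rows")
    ancestor = _random_seq(rng, n_columns)
    ids = []
    rows = []
    junk: dict[str, tuple[int, int]] = {}
    jlo, jhi = junk_length_range
    for i in range(n_rows):
        row_id = f"seq{i + 1}"
        row = _mutate(rng, ancestor, divergence)
        if i < n_junk_rows:
            head = int(rng.integers(jlo, jhi + 1))
            tail = int(rng.integers(jlo, jhi + 1))
            if junk_mode == "uniform":
                head_seq = _random_seq(rng, head)
                tail_seq = _random_seq(rng, tail)
            else:
                head_seq = _mutate(rng, ancestor[:head], 1.0)
                tail_seq = _mutate(rng, ancestor[n_columns - tail :], 1.0)
            row = head_seq + row[head : n_columns - tail] + tail_seq
            junk[row_id] = (head, tail)
        else:
            junk[row_id] = (0, 0)
        ids.append(row_id)
        rows.append(row)
    return Alignment(ids, rows), junk


# ---------------------------------------------------------------------------
# Engineered bookkeeping fixtures: miniature datasets whose planted flag
# counts make whole filter cascades checkable end to end.


def planted_flag_stats(
    n_targets: int = 303,
    n_paralog: int = 13,
    n_missing: int = 5,
    n_samples: int = 4,
    high_p: float = 0.6,
    low_p: float = 0.1,
    high_m: float = 0.6,
    low_m: float = 0.05,
    seed: int = 0,
) -> tuple[list, set[str], set[str]]:
    """Per-sample paralogy statistics with planted mean-P and mean-M flags.

    The first ``n_paralog`` targets get P around ``high_p`` (above the
    0.4 flag threshold), the next ``n_missing`` get M around
    ``high_m``; the sets are disjoint.  Small seeded jitter keeps the
    fixture from being degenerate.  Returns (stats, expected paralog
    ids, expected missing ids).
    """
    from .assembly import ParalogyStats

    rng = np.random.default_rng(seed)
    ids = [f"t{i + 1:04d}" for i in range(n_targets)]
    paralog_ids = set(ids[:n_paralog])
    missing_ids = set(ids[n_paralog : n_paralog + n_missing])
    stats = []
    for s in range(n_samples):
        sample = f"s{s + 1}"
        for tid in ids:
            p = high_p if tid in paralog_ids else low_p
            m = high_m if tid in missing_ids else low_m
            stats.append(
                ParalogyStats(
                    tid,
                    sample,
                    P=float(np.clip(p + rng.normal(0, 0.02), 0, 1)),
                    M=float(np.clip(m + rng.normal(0, 0.02), 0, 1)),
                    C=1.0,
                )
            )
    return stats, paralog_ids, missing_ids


def planted_depth_stats(
    pass_ids: Sequence[str],
    fail_ids: Sequence[str],
    pass_median: float = 30.0,
    fail_median: float = 300.0,
    length: int = 2000,
) -> list[TargetDepthStats]:
    """Depth summaries where exactly ``fail_ids`` are median-depth outliers.

    The bulk sits at ``pass_median`` and the planted failures at
    ``fail_median``.  For a two-level fixture with strictly more
    passes than failures, the failures deviate from the grand mean by
    more than one sample SD while the bulk does not (the deviations
    are 270*n_pass/n vs 270*n_fail/n against an SD of
    270*sqrt(n_pass*n_fail/(n*(n-1))) at the default levels), so the
    planted counts are exactly what the median-depth vet recovers.
    """
    if len(pass_ids) <= len(fail_ids):
        raise ValueError("need strictly more passing than failing targets")
    return [
        TargetDepthStats(tid, length, pass_median, pass_median, 1.0)
        for tid in pass_ids
    ] + [
        TargetDepthStats(tid, length, fail_median, fail_median, 1.0)
        for tid in fail_ids
    ]
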