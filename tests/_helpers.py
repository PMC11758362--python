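"""Shared factories and independent brute-force oracles for the tests.

The oracles are deliberately naive, loop-based transcriptions of the
definitions (per-site interval stabbing, per-window identity crawling)
so that the vectorised library implementations are checked against a
structurally different computation.
"""

from __future__ import annotations

import numpy as np

from hybvet.io import TabularHit


def make_hit(
    query: str = "contig1",
    subject: str = "t1",
    ident: float = 95.0,
    q: tuple[int, int] = (1, 100),
    s: tuple[int, int] = (1, 100),
    alen: int | None = None,
    evalue: float = 1e-10,
    bit: float = 200.0,
) -> TabularHit:
    """A 12-column hit with sensible defaults, normalized."""
    if alen is None:
        alen = abs(s[1] - s[0]) + 1
    return TabularHit(
        query_id=query,
        subject_id=subject,
        pct_identity=ident,
        align_len=alen,
        mismatches=0,
        gap_opens=0,
        q_start=q[0],
        q_end=q[1],
        s_start=s[0],
        s_end=s[1],
        evalue=evalue,
        bit_score=bit,
    ).normalized()


def oracle_site_coverage(hits, length: int) -> list[int]:
    """Per-site distinct-contig counts by stabbing every (site, hit) pair."""
    counts = []
    for pos in range(1, length + 1):  # 1-based site index
        contigs = set()
        for h in hits:
            lo, hi = min(h.s_start, h.s_end), max(h.s_start, h.s_end)
            if lo <= pos <= hi:
                contigs.add(h.query_id)
        counts.append(len(contigs))
    return counts


def oracle_paralogy(c: list[int]) -> tuple[float | None, float, float | None]:
    """P, M, C by direct counting over a coverage list."""
    L = len(c)
    l0 = sum(1 for x in c if x == 0)
    lge2 = sum(1 for x in c if x >= 2)
    covered = [x for x in c if x >= 1]
    P = lge2 / (L - l0) if L > l0 else None
    M = l0 / L
    C = sum(covered) / len(covered) if covered else None
    return P, M, C


def oracle_chomp_row(
    consensus: str, row: str, window: int = 50, threshold: float = 0.8
) -> str:
    """Naive reference chomper: explicit per-window crawling on lists."""
    n = len(row)
    w = min(window, n)
    chars = list(row)

    def window_ident(start: int) -> float:
        comparable = 0
        matches = 0
        for j in range(start, start + w):
            a = consensus[j].upper()
            b = chars[j].upper()
            if a in "ACGT" and b in "ACGT":
                comparable += 1
                if a == b:
                    matches += 1
        if comparable == 0:
            return 0.0
        return matches / comparable

    start = 0
    while start + w <= n:
        if window_ident(start) >= threshold:
            break
        for j in range(start, start + w):
            if chars[j] != "-":
                chars[j] = "-"
        start += 1
    start = n - w
    while start >= 0:
        if window_ident(start) >= threshold:
            break
        for j in range(start, start + w):
            if chars[j] != "-":
                chars[j] = "-"
        start -= 1
    return "".join(chars)


def oracle_outlier_samples(P: dict[str, dict[str, float | None]], delta: float) -> set[str]:
    """Sample outlier rule by explicit loops over a dict-of-dicts P matrix."""
    targets = sorted({t for row in P.values() for t in row})
    mean_p = {}
    for t in targets:
        vals = [P[s][t] for s in P if P[s].get(t) is not None]
        if vals:
            mean_p[t] = sum(vals) / len(vals)
    flagged = set()
    for s, row in P.items():
        devs = [
            abs(row[t] - mean_p[t])
            for t in targets
            if row.get(t) is not None and t in mean_p
        ]
        if devs and sum(devs) / len(devs) > delta:
            flagged.add(s)
    return flagged


def random_hit_instance(
    rng: np.random.Generator,
    max_len: int = 500,
    max_hits: int = 50,
    subject: str = "t1",
) -> tuple[list[TabularHit], int]:
    """A random pile of (possibly minus-strand) hits on one target."""
    L = int(rng.integers(50, max_len + 1))
    n_hits = int(rng.integers(0, max_hits + 1))
    hits = []
    for _ in range(n_hits):
        a = int(rng.integers(1, L + 1))
        b = int(rng.integers(1, L + 1))
        lo, hi = min(a, b), max(a, b)
        contig = f"c{int(rng.integers(1, 9))}"
        minus = bool(rng.random() < 0.3)
        s = (hi, lo) if minus else (lo, hi)
        hits.append(make_hit(query=contig, subject=subject, s=s))
    return hits, L
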