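"""Independent oracles used by the test suite.

Each function re-derives an expected result by brute force (all-pairs
scans, exhaustive enumeration, closed-form formulas) without using the
implementation under test or its libraries (no interval trees, no scipy
distributions, no aligner).
"""

from __future__ import annotations

import itertools
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from lncforge.models import TranscriptModel


def _ov(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _gap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    if _ov(a, b):
        return 0
    return b[0] - a[1] - 1 if a[1] < b[0] else a[0] - b[1] - 1


def oracle_classify(
    lnc: TranscriptModel, refs: Sequence[TranscriptModel]
) -> Tuple[str, Optional[str], Optional[int]]:
    """All-pairs positional classification: (category, nearest gene, distance)."""
    sense, anti, hosts = set(), set(), set()
    for r in refs:
        if r.chrom != lnc.chrom:
            continue
        if any(_ov(le, re_) for le in lnc.exons for re_ in r.exons):
            (sense if r.strand == lnc.strand else anti).add(r.gene_id)
        for s, e in r.introns:
            if s <= lnc.start and lnc.end <= e:
                hosts.add(r.gene_id)
    if sense:
        return "sense", min(sense), 0
    if anti:
        return "antisense", min(anti), 0
    if hosts:
        return "intronic", min(hosts), 0
    best: Optional[Tuple[int, str]] = None
    for r in refs:
        if r.chrom != lnc.chrom:
            continue
        g = _gap((lnc.start, lnc.end), (r.start, r.end))
        if best is None or g < best[0] or (g == best[0] and r.gene_id < best[1]):
            best = (g, r.gene_id)
    if best is None:
        return "intergenic", None, None
    return "intergenic", best[1], best[0]


def oracle_cis_pairs(
    lncs: Sequence[TranscriptModel], genes: Sequence[TranscriptModel], window: int
) -> set:
    """O(n^2) scan for (lnc transcript, gene) pairs within the window."""
    out = set()
    for l in lncs:
        for g in genes:
            if l.chrom == g.chrom and _gap((l.start, l.end), (g.start, g.end)) <= window:
                out.add((l.transcript_id, g.gene_id))
    return out


def oracle_pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Direct covariance-formula Pearson correlation (plain loops)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def oracle_hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exhaustive enumeration of all n-subsets of the population."""
    hits = 0
    total = 0
    for combo in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for i in combo if i < K) >= k:
            hits += 1
    return hits / total if total else 1.0


def oracle_local_alignment_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Best local alignment score by exhaustive monotone-matching enumeration.

    A local alignment is a pair of equal-length strictly increasing index
    sequences (the aligned columns); interior skipped stretches are affine
    gaps (open + extend*(len-1) each, per sequence); dangling ends are
    free. The empty alignment scores 0.
    """
    best = 0.0
    n, m = len(a), len(b)
    for k in range(1, min(n, m) + 1):
        for ia in itertools.combinations(range(n), k):
            for ib in itertools.combinations(range(m), k):
                s = 0.0
                for x, y in zip(ia, ib):
                    s += match if a[x] == b[y] else mismatch
                for t in range(k - 1):
                    ga = ia[t + 1] - ia[t] - 1
                    gb = ib[t + 1] - ib[t] - 1
                    if ga:
                        s += gap_open + gap_extend * (ga - 1)
                    if gb:
                        s += gap_open + gap_extend * (gb - 1)
                if s > best:
                    best = s
    return best


def random_catalog(
    rng: np.random.Generator,
    n: int,
    prefix: str,
    chroms: Sequence[str] = ("chr1", "chr2"),
    biotype: str = "unknown",
    span: int = 200_000,
    with_attributes: bool = False,
) -> List[TranscriptModel]:
    """Random valid transcripts (possibly mutually overlapping)."""
    out = []
    for i in range(n):
        chrom = str(rng.choice(list(chroms)))
        strand = str(rng.choice(["+", "-"]))
        n_ex = int(rng.integers(1, 5))
        pos = int(rng.integers(1, span))
        exons = []
        for _ in range(n_ex):
            length = int(rng.integers(50, 800))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(50, 3_000))
        attrs = {"note": f"r{int(rng.integers(0, 1000))}"} if with_attributes else {}
        out.append(
            TranscriptModel(
                f"{prefix}_{i:04d}", f"{prefix}G_{i:04d}", chrom, strand,
                tuple(exons), biotype, attrs,
            )
        )
    return out
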