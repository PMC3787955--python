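"""Independent brute-force oracles used by the test suite.

Each function re-derives a pipeline quantity by the most naive route
available (per-base boolean masks, all-pairs scans, exact rational
enumeration) and is kept free of the implementation paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial
from typing import Dict, List, Sequence, Tuple

import numpy as np


def hwe_exact_p_fraction(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided HWE p by full enumeration in rational arithmetic."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if min(n_a, n_b) == 0:
        return 1.0

    def weight(k: int) -> Fraction:
        rest_a = (n_a - k) // 2
        rest_b = (n_b - k) // 2
        return Fraction(
            factorial(n) * 2**k,
            factorial(rest_a) * factorial(k) * factorial(rest_b),
        )

    ks = list(range(n_a % 2, min(n_a, n_b) + 1, 2))
    weights = {k: weight(k) for k in ks}
    total = sum(weights.values())
    obs = weights[n_ab]
    return float(sum(w for w in weights.values() if w <= obs) / total)


def pairwise_overlap_clusters(
    intervals: Sequence[Tuple[str, int, int]]
) -> List[List[int]]:
    """O(n^2) transitive clustering by 1-bp overlap (inclusive coords)."""
    n = len(intervals)
    adj = [[] for _ in range(n)]
    for i in range(n):
        ci, si, ei = intervals[i]
        for j in range(i + 1, n):
            cj, sj, ej = intervals[j]
            if ci == cj and si <= ej and sj <= ei:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    clusters = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        clusters.append(sorted(comp))
    return clusters


def mask_components(
    intervals: Sequence[Tuple[str, int, int]], chrom_size: int
) -> Dict[str, List[Tuple[int, int]]]:
    """Flood-fill merged regions from a per-base boolean mask."""
    chroms = {c for c, _, _ in intervals}
    out: Dict[str, List[Tuple[int, int]]] = {}
    for chrom in sorted(chroms):
        mask = np.zeros(chrom_size + 2, dtype=bool)
        for c, s, e in intervals:
            if c == chrom:
                mask[s : e + 1] = True
        regions = []
        pos = 1
        while pos <= chrom_size:
            if mask[pos]:
                start = pos
                while pos <= chrom_size and mask[pos]:
                    pos += 1
                regions.append((start, pos - 1))
            else:
                pos += 1
        out[chrom] = regions
    return out


def mask_vote_regions(
    per_source: Dict[str, Sequence[Tuple[str, int, int]]],
    chrom_size: int,
    min_support: int,
) -> Dict[str, List[Tuple[int, int]]]:
    """Pooled-union regions whose overlap component touches >= min_support sources.

    Builds the union mask of all sources, flood-fills components, then
    keeps a component iff intervals from >= min_support distinct sources
    intersect it.
    """
    pooled = [iv for ivs in per_source.values() for iv in ivs]
    comps = mask_components(pooled, chrom_size)
    kept: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, regions in comps.items():
        for s, e in regions:
            sources = {
                name
                for name, ivs in per_source.items()
                for (c, a, b) in ivs
                if c == chrom and a <= e and s <= b
            }
            if len(sources) >= min_support:
                kept.setdefault(chrom, []).append((s, e))
    return kept


def allpairs_hits(
    regions: Sequence[Tuple[int, str, int, int]],
    features: Sequence[Tuple[str, str, int, int]],
) -> set:
    """All-pairs (region_id, feature_id) overlap set; >= 1 shared base."""
    hits = set()
    for rid, rc, rs, re in regions:
        for fid, fc, fs, fe in features:
            if rc == fc and rs <= fe and fs <= re:
                hits.add((rid, fid))
    return hits
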