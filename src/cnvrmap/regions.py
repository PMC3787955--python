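"""Per-algorithm CNV filtering and aggregation into CNVRs.

"Overlapping" everywhere means >= 1 shared base under 1-based inclusive
coordinates; abutting intervals ([100,200] and [201,300]) do not merge.
CNVRs are the connected components of the transitive overlap graph, one
chromosome at a time.  A ``min_reciprocal`` option tightens the edge
criterion for sensitivity analysis; the default (0) is the plain 1-bp
rule.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Sequence, Tuple

from cnvrmap.model import (
    Cnvr,
    CnvCall,
    FeatureRecord,
    GenomicInterval,
    chrom_sort_key,
    status_of_states,
)


@dataclass(frozen=True)
class FilterPolicy:
    """Post-calling knock-out rules applied per algorithm.

    ``min_carriers`` drops overlap-clusters carried by fewer distinct
    samples (the "present in only one individual" rule).  By default
    recurrence is counted across states; ``same_state_recurrence``
    restricts a cluster to calls of one state.
    """

    min_snps: int = 3
    min_carriers: int = 2
    same_state_recurrence: bool = False

    def __post_init__(self) -> None:
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        if self.min_carriers < 1:
            raise ValueError("min_carriers must be >= 1")


def overlap_components(
    intervals: Sequence[GenomicInterval], min_reciprocal: float = 0.0
) -> List[List[int]]:
    """Indices of connected components under transitive 1-bp overlap.

    With ``min_reciprocal > 0`` an edge additionally requires that
    reciprocal overlap fraction; the plain rule uses a linear sweep, the
    reciprocal rule a pairwise union-find per chromosome.
    """
    by_chrom: Dict[str, List[int]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append(i)

    components: List[List[int]] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        idx = sorted(by_chrom[chrom], key=lambda i: (intervals[i].start, intervals[i].end))
        if min_reciprocal <= 0:
            current: List[int] = []
            cur_end = -1
            for i in idx:
                if current and intervals[i].start <= cur_end:
                    current.append(i)
                    cur_end = max(cur_end, intervals[i].end)
                else:
                    if current:
                        components.append(current)
                    current = [i]
                    cur_end = intervals[i].end
            if current:
                components.append(current)
        else:
            parent = {i: i for i in idx}

            def find(a: int) -> int:
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            for a_pos, i in enumerate(idx):
                for j in idx[a_pos + 1:]:
                    if intervals[j].start > intervals[i].end:
                        break
                    if intervals[i].reciprocal_overlap(intervals[j]) >= min_reciprocal:
                        parent[find(j)] = find(i)
            groups: Dict[int, List[int]] = {}
            for i in idx:
                groups.setdefault(find(i), []).append(i)
            components.extend(sorted(groups.values(), key=lambda g: min(g)))
    return components


def filter_calls(calls: Sequence[CnvCall], policy: FilterPolicy = FilterPolicy()) -> List[CnvCall]:
    """Apply the min-SNP and recurrence knock-outs to one algorithm's calls.

    Order of rules is fixed: the SNP-support filter first, then the
    carrier filter on overlap-clusters of the survivors.  Output keeps
    the input's relative order.
    """
    algs = {c.algorithm_id for c in calls}
    if len(algs) > 1:
        raise ValueError(
            f"filter_calls expects one algorithm, got {sorted(algs)} "
            "(recurrence is a per-algorithm notion)"
        )
    supported = [c for c in calls if c.n_snps >= policy.min_snps]
    if not supported:
        return []

    if policy.same_state_recurrence:
        groups = [
            [c for c in supported if c.state == state] for state in ("gain", "loss")
        ]
        groups = [g for g in groups if g]
    else:
        groups = [supported]

    keep = set()
    for group in groups:
        comps = overlap_components([c.interval for c in group])
        for comp in comps:
            carriers = {group[i].sample_id for i in comp}
            if len(carriers) >= policy.min_carriers:
                keep.update(id(group[i]) for i in comp)
    return [c for c in supported if id(c) in keep]


def merge_to_cnvrs(
    calls: Sequence[CnvCall], min_reciprocal: float = 0.0
) -> List[Cnvr]:
    """Aggregate overlapping calls into CNVRs.

    Each connected overlap component becomes one CNVR spanning
    [min start, max end] of its members; CNVRs come back sorted by
    chromosome then start and are numbered from 1 (numbering restarts
    per run -- cross-run identity is by coordinates).
    """
    if not calls:
        return []
    comps = overlap_components([c.interval for c in calls], min_reciprocal)
    raw: List[Tuple[GenomicInterval, str, frozenset, frozenset, int]] = []
    for comp in comps:
        members = [calls[i] for i in comp]
        interval = GenomicInterval(
            members[0].interval.chrom,
            min(m.interval.start for m in members),
            max(m.interval.end for m in members),
        )
        raw.append(
            (
                interval,
                status_of_states([m.state for m in members]),
                frozenset(m.algorithm_id for m in members),
                frozenset(m.sample_id for m in members),
                len(members),
            )
        )
    raw.sort(key=lambda r: (chrom_sort_key(r[0].chrom), r[0].start, r[0].end))
    return [
        Cnvr(
            cnvr_id=i,
            interval=interval,
            status=status,
            algorithms=algorithms,
            samples=samples,
            n_calls=n,
        )
        for i, (interval, status, algorithms, samples, n) in enumerate(raw, start=1)
    ]


class GapScreenResult(NamedTuple):
    kept: List[Cnvr]
    discarded: List[Cnvr]
    triggers: Dict[int, List[str]]  # cnvr_id -> gap feature ids


def screen_gaps(
    cnvrs: Sequence[Cnvr], gaps: Sequence[FeatureRecord]
) -> GapScreenResult:
    """Discard CNVRs overlapping any assembly gap / contig boundary.

    A gap hit implies the region spans more than one contig of the
    draft assembly, so any >= 1-bp overlap triggers discard.
    """
    kept: List[Cnvr] = []
    discarded: List[Cnvr] = []
    triggers: Dict[int, List[str]] = {}
    for r in cnvrs:
        hits = [g.feature_id for g in gaps if r.interval.overlaps(g.interval)]
        if hits:
            discarded.append(r)
            triggers[r.cnvr_id] = hits
        else:
            kept.append(r)
    return GapScreenResult(kept, discarded, triggers)


@dataclass(frozen=True)
class CnvrSummary:
    n: int
    n_gain: int
    n_loss: int
    n_gain_loss: int
    min_kb: float
    median_kb: float
    max_kb: float
    mean_kb: float
    coverage_mb: float
    coverage_fraction: float | None = None


def summarize(cnvrs: Sequence[Cnvr], genome_size_bp: int | None = None) -> CnvrSummary:
    """Descriptive statistics of a CNVR set.

    Lengths use the printed-table span convention (``(end-start)/1000``
    kb); coverage is the non-redundant union of intervals in Mb, with a
    genome fraction when a genome size is supplied.
    """
    if not cnvrs:
        raise ValueError("cannot summarize an empty CNVR set")
    kbs = sorted(r.interval.span_kb for r in cnvrs)
    n_gain = sum(1 for r in cnvrs if r.status == "gain")
    n_loss = sum(1 for r in cnvrs if r.status == "loss")
    coverage_bp = union_coverage_bp([r.interval for r in cnvrs])
    return CnvrSummary(
        n=len(cnvrs),
        n_gain=n_gain,
        n_loss=n_loss,
        n_gain_loss=len(cnvrs) - n_gain - n_loss,
        min_kb=kbs[0],
        median_kb=statistics.median(kbs),
        max_kb=kbs[-1],
        mean_kb=sum(kbs) / len(kbs),
        coverage_mb=coverage_bp / 1e6,
        coverage_fraction=(coverage_bp / genome_size_bp) if genome_size_bp else None,
    )


def union_coverage_bp(intervals: Sequence[GenomicInterval]) -> int:
    """Total bases covered by the union of the intervals."""
    total = 0
    for comp in overlap_components(intervals):
        lo = min(intervals[i].start for i in comp)
        hi = max(intervals[i].end for i in comp)
        total += hi - lo + 1
    return total
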