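"""Multi-algorithm consensus CNVR map and agreement statistics.

Per-algorithm CNVR sets are pooled, overlap components are formed across
algorithms (1-bp transitive rule), and components whose members span at
least ``min_support`` distinct algorithms become consensus CNVRs.  The
consensus span is the *union* of its member CNVRs -- published consensus
regions reach tens of Mb, which only a union across carriers and callers
can produce; an intersection mode exists for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from cnvrmap.model import Cnvr, GenomicInterval, chrom_sort_key, status_of_states
from cnvrmap.regions import overlap_components
from cnvrmap.utils import percent


@dataclass(frozen=True)
class ConsensusCnvr:
    """A consensus region with its per-algorithm constituent CNVRs."""

    cnvr_id: int
    interval: GenomicInterval
    status: str
    algorithms: frozenset
    member_cnvrs: Dict[str, Tuple[int, ...]] = field(default_factory=dict)

    @property
    def n_algorithms(self) -> int:
        return len(self.algorithms)


def _member_status(statuses: Sequence[str]) -> str:
    states = set()
    for s in statuses:
        states.update({"gain", "loss"} if s == "gain-loss" else {s})
    return status_of_states(sorted(states))


def build_consensus(
    per_algorithm_cnvrs: Dict[str, Sequence[Cnvr]],
    min_support: int = 2,
    span: str = "union",
) -> List[ConsensusCnvr]:
    """Build the >= ``min_support``-algorithm consensus CNVR list."""
    if len(per_algorithm_cnvrs) < 2:
        raise ValueError("need at least two algorithm CNVR sets")
    if min_support < 2:
        raise ValueError("min_support must be >= 2")
    if min_support > len(per_algorithm_cnvrs):
        raise ValueError(
            f"min_support={min_support} exceeds the "
            f"{len(per_algorithm_cnvrs)} supplied algorithms"
        )
    if span not in ("union", "intersection"):
        raise ValueError("span must be 'union' or 'intersection'")

    pooled: List[Tuple[str, Cnvr]] = [
        (alg, r) for alg, rs in per_algorithm_cnvrs.items() for r in rs
    ]
    comps = overlap_components([r.interval for _, r in pooled])

    raw = []
    for comp in comps:
        members = [pooled[i] for i in comp]
        algorithms = frozenset(alg for alg, _ in members)
        if len(algorithms) < min_support:
            continue
        chrom = members[0][1].interval.chrom
        if span == "union":
            lo = min(r.interval.start for _, r in members)
            hi = max(r.interval.end for _, r in members)
        else:
            lo = max(r.interval.start for _, r in members)
            hi = min(r.interval.end for _, r in members)
            if hi < lo:  # no common core across all members
                lo, hi = min(
                    ((r.interval.start, r.interval.end) for _, r in members),
                )
        member_ids: Dict[str, Tuple[int, ...]] = {}
        for alg, r in members:
            member_ids[alg] = tuple(list(member_ids.get(alg, ())) + [r.cnvr_id])
        raw.append(
            (
                GenomicInterval(chrom, lo, hi),
                _member_status([r.status for _, r in members]),
                algorithms,
                member_ids,
            )
        )
    raw.sort(key=lambda r: (chrom_sort_key(r[0].chrom), r[0].start, r[0].end))
    return [
        ConsensusCnvr(i, interval, status, algorithms, member_ids)
        for i, (interval, status, algorithms, member_ids) in enumerate(raw, start=1)
    ]


def algorithm_agreement(
    per_algorithm_cnvrs: Dict[str, Sequence[Cnvr]],
    consensus: Sequence[ConsensusCnvr],
) -> pd.DataFrame:
    """Per-algorithm counts of CNVRs overlapping the consensus map.

    Returns a frame with ``algorithm, n_total, n_overlapping, fraction``
    where fraction is a half-up-rounded percentage to 2 decimals.
    """
    if not per_algorithm_cnvrs:
        raise ValueError("no algorithm CNVR sets supplied")
    rows = []
    for alg, cnvrs in per_algorithm_cnvrs.items():
        n_overlap = sum(
            1
            for r in cnvrs
            if any(r.interval.overlaps(c.interval) for c in consensus)
        )
        rows.append(
            {
                "algorithm": alg,
                "n_total": len(cnvrs),
                "n_overlapping": n_overlap,
                "fraction": percent(n_overlap, len(cnvrs), 2) if cnvrs else 0.0,
            }
        )
    return pd.DataFrame(rows)


def cross_study_overlap(
    cnvrs_a: Sequence[Cnvr], cnvrs_b: Sequence[Cnvr]
) -> Tuple[int, float]:
    """How many of set A's CNVRs overlap any CNVR of set B.

    Returns ``(n_overlapping, percentage)`` with the percentage rounded
    half-up to 2 decimals (0.00 for an empty A).
    """
    if not cnvrs_a:
        return 0, 0.0
    n = sum(
        1
        for a in cnvrs_a
        if any(a.interval.overlaps(b.interval) for b in cnvrs_b)
    )
    return n, percent(n, len(cnvrs_a), 2)
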