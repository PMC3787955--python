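"""Per-cohort CNVR sets and breed-unique / cross-generation comparison.

Cohorts (breed x generation, e.g. the two founder breeds and the F2
crossbreds) are analyzed separately with identical pipeline parameters;
breed-unique CNVRs are those overlapping nothing in any other cohort
(overlap, not coordinate identity, since boundaries differ between
cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from cnvrmap.model import Cnvr, SampleInfo
from cnvrmap.utils import percent


@dataclass
class CohortCnvrSet:
    cohort_id: str
    cnvrs: List[Cnvr]
    provenance: Dict[str, object] = field(default_factory=dict)


def group_samples(samples: Sequence[SampleInfo]) -> Dict[str, List[str]]:
    """Partition sample ids into breed+generation cohorts."""
    groups: Dict[str, List[str]] = {}
    for s in samples:
        groups.setdefault(f"{s.breed}:{s.generation}", []).append(s.sample_id)
    return groups


def unique_cnvrs(
    target: CohortCnvrSet, others: Sequence[CohortCnvrSet]
) -> List[Cnvr]:
    """CNVRs of ``target`` overlapping no CNVR of any other cohort."""
    pool = [r for o in others for r in o.cnvrs]
    return [
        r
        for r in target.cnvrs
        if not any(r.interval.overlaps(p.interval) for p in pool)
    ]


def generation_overlap(
    f0_sets: Sequence[CohortCnvrSet], f2_set: CohortCnvrSet
) -> Tuple[int, int, float]:
    """Fraction of founder-cohort CNVRs rediscovered in the F2 set.

    F0 CNVRs are pooled across breeds but kept as separate records (a
    region found in both breeds counts twice, matching how per-breed
    tallies are reported).  Returns ``(n_f0_total, n_overlapping,
    percentage)`` with half-up rounding to 2 decimals.
    """
    pool = [r for s in f0_sets for r in s.cnvrs]
    if not pool:
        raise ValueError("empty F0 CNVR pool")
    n_overlap = sum(
        1
        for r in pool
        if any(r.interval.overlaps(f.interval) for f in f2_set.cnvrs)
    )
    return len(pool), n_overlap, percent(n_overlap, len(pool), 2)
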