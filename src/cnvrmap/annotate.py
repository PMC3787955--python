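"""Interval joins of CNVRs against annotation features.

A feature is "in" a CNVR given any >= 1-bp overlap (full-containment
counts are reported alongside, since both readings appear in the
literature this table layout comes from).  Point features (SNPs) hit iff
their position lies inside the CNVR.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from cnvrmap.model import Cnvr, FeatureRecord
from cnvrmap.utils import percent

FEATURE_WITHIN_CNVR = "feature_within_cnvr"
CNVR_WITHIN_FEATURE = "cnvr_within_feature"
PARTIAL = "partial"


@dataclass(frozen=True)
class OverlapHit:
    cnvr_id: int
    feature_id: str
    feature_kind: str
    overlap_bp: int
    containment: str

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("a hit needs >= 1 bp of overlap")


def overlap_join(
    cnvrs: Sequence[Cnvr],
    features: Sequence[FeatureRecord],
    min_overlap_bp: int = 1,
) -> List[OverlapHit]:
    """One hit per (CNVR, feature) pair sharing >= ``min_overlap_bp`` bases.

    Output order is deterministic: CNVRs in the given order, features in
    the given order within each CNVR.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    hits: List[OverlapHit] = []
    for r in cnvrs:
        for f in features:
            ov = r.interval.overlap_bp(f.interval)
            if ov < min_overlap_bp:
                continue
            if r.interval.contains(f.interval):
                containment = FEATURE_WITHIN_CNVR
            elif f.interval.contains(r.interval):
                containment = CNVR_WITHIN_FEATURE
            else:
                containment = PARTIAL
            hits.append(
                OverlapHit(
                    cnvr_id=r.cnvr_id,
                    feature_id=f.feature_id,
                    feature_kind=f.kind,
                    overlap_bp=ov,
                    containment=containment,
                )
            )
    return hits


@dataclass
class AnnotationSummary:
    n_cnvrs: int
    n_cnvrs_with_hits: int
    fraction_cnvrs_with_hits: float
    n_features_hit: int
    biotype_counts: Dict[str, int] = field(default_factory=dict)
    biotype_fractions: Dict[str, float] = field(default_factory=dict)
    trait_counts: Dict[str, int] = field(default_factory=dict)
    n_features_contained: int = 0


def summarize_annotation(
    hits: Sequence[OverlapHit],
    cnvrs: Sequence[Cnvr],
    features: Sequence[FeatureRecord],
    decimals: int = 2,
) -> AnnotationSummary:
    """Hit-bearing CNVR fraction plus biotype / trait tallies.

    Counts deduplicate by id on both sides: a feature hitting several
    CNVRs is one annotated feature, and vice versa.  Biotype counts (for
    gene features, from the ``biotype`` attribute) always sum to the
    total number of annotated genes; per-biotype percentages use that
    total as denominator.
    """
    by_feature = {f.feature_id: f for f in features}
    hit_cnvrs = {h.cnvr_id for h in hits}
    hit_features = {h.feature_id for h in hits}
    contained = {
        h.feature_id for h in hits if h.containment == FEATURE_WITHIN_CNVR
    }

    biotypes: Counter = Counter()
    traits: Counter = Counter()
    for fid in hit_features:
        f = by_feature[fid]
        if f.kind == "gene":
            biotypes[f.attributes.get("biotype", "unknown")] += 1
        elif f.kind == "qtl":
            traits[f.attributes.get("trait", "unknown")] += 1

    n_genes = sum(biotypes.values())
    return AnnotationSummary(
        n_cnvrs=len(cnvrs),
        n_cnvrs_with_hits=len(hit_cnvrs),
        fraction_cnvrs_with_hits=(
            percent(len(hit_cnvrs), len(cnvrs), decimals) if cnvrs else 0.0
        ),
        n_features_hit=len(hit_features),
        biotype_counts=dict(biotypes),
        biotype_fractions={
            b: percent(c, n_genes, decimals) for b, c in biotypes.items()
        },
        trait_counts=dict(traits),
        n_features_contained=len(contained),
    )


def snp_colocation(
    cnvrs: Sequence[Cnvr], snp_features: Sequence[FeatureRecord]
) -> Dict[str, Tuple[int, int, float]]:
    """Per-trait counts of significant SNPs falling inside any CNVR.

    Returns ``{trait: (n_in_cnvrs, n_total, percentage)}`` with half-up
    rounding to 2 decimals.  Every SNP feature must carry a ``trait``
    attribute.
    """
    missing = [f.feature_id for f in snp_features if "trait" not in f.attributes]
    if missing:
        raise ValueError(f"snp features missing 'trait' attribute: {missing}")
    totals: Counter = Counter()
    inside: Counter = Counter()
    for f in snp_features:
        trait = f.attributes["trait"]
        totals[trait] += 1
        if any(r.interval.overlaps(f.interval) for r in cnvrs):
            inside[trait] += 1
    return {
        t: (inside[t], totals[t], percent(inside[t], totals[t], 2))
        for t in sorted(totals)
    }
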