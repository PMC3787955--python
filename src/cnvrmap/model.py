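"""Shared domain types for the CNVR pipeline.

Coordinates are stored 1-based inclusive throughout: every printed table
this pipeline needs to reproduce uses that convention, and keeping it
internal makes those tables byte-comparable fixtures.  BED input/output
converts at the boundary (see :mod:`cnvrmap.io`).

Two distinct length accessors exist on :class:`GenomicInterval`:

* :attr:`GenomicInterval.length_bp` -- the inclusive base count
  ``end - start + 1``, used for all internal interval algebra;
* :attr:`GenomicInterval.span_bp` -- the coordinate difference
  ``end - start``, which is what published CNVR tables of this kind put
  in their "Length (Kb)" column (``span_bp / 1000``).

They are named differently on purpose so neither can silently stand in
for the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

GAIN = "gain"
LOSS = "loss"
GAIN_LOSS = "gain-loss"

#: Valid states for a single CNV call (one call is never "gain-loss").
CALL_STATES = frozenset({GAIN, LOSS})
#: Valid statuses for a merged CNVR.
CNVR_STATUSES = frozenset({GAIN, LOSS, GAIN_LOSS})

GENOTYPES = ("AA", "AB", "BB")
MISSING_GENOTYPE = "--"

FEATURE_KINDS = frozenset({"gene", "qtl", "snp", "dgv_region", "gap"})


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label for comparison.

    Strips an optional ``chr``/``Chr`` prefix and upper-cases the rest,
    so ``"chrX"``, ``"x"`` and ``"X"`` compare equal.  No numeric
    assumption is made; ``"1"`` stays a string.
    """
    label = str(chrom).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if not label:
        raise ValueError("empty chromosome label")
    return label.upper()


def chrom_sort_key(chrom: str) -> tuple:
    """Sort key placing numeric chromosomes numerically, then X, Y, others."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome span in 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length_bp(self) -> int:
        """Inclusive length in bp: ``end - start + 1`` (always > 0)."""
        return self.end - self.start + 1

    @property
    def span_bp(self) -> int:
        """Coordinate span ``end - start`` (the printed-table convention)."""
        return self.end - self.start

    @property
    def span_kb(self) -> float:
        """``span_bp / 1000`` -- the "Length (Kb)" column value."""
        return self.span_bp / 1000.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if disjoint or on different chroms)."""
        if self.chrom != other.chrom:
            return 0
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(overlap/len(self), overlap/len(other)) on inclusive lengths."""
        ov = self.overlap_bp(other)
        if ov == 0:
            return 0.0
        return min(ov / self.length_bp, ov / other.length_bp)


@dataclass(frozen=True)
class CnvCall:
    """One CNV segment for one sample from one calling algorithm."""

    sample_id: str
    algorithm_id: str
    interval: GenomicInterval
    state: str
    n_snps: int
    copy_number: Optional[int] = None

    def __post_init__(self) -> None:
        if self.state not in CALL_STATES:
            raise ValueError(
                f"call state must be one of {sorted(CALL_STATES)}, "
                f"got {self.state!r}"
            )
        if self.n_snps < 1:
            raise ValueError(f"n_snps must be >= 1, got {self.n_snps}")


def status_of_states(states: Sequence[str]) -> str:
    """Collapse constituent call states into a CNVR status."""
    uniq = set(states)
    if not uniq:
        raise ValueError("no states supplied")
    if not uniq <= CALL_STATES:
        raise ValueError(f"unexpected states: {uniq - CALL_STATES}")
    if uniq == {GAIN}:
        return GAIN
    if uniq == {LOSS}:
        return LOSS
    return GAIN_LOSS


@dataclass(frozen=True)
class Cnvr:
    """A merged copy-number-variable region.

    ``interval`` is the union span (min start, max end) of the
    constituent calls; ``status`` is gain/loss if all constituents agree
    and gain-loss otherwise.
    """

    cnvr_id: int
    interval: GenomicInterval
    status: str
    algorithms: frozenset = field(default_factory=frozenset)
    samples: frozenset = field(default_factory=frozenset)
    n_calls: int = 0

    def __post_init__(self) -> None:
        if self.status not in CNVR_STATUSES:
            raise ValueError(
                f"status must be one of {sorted(CNVR_STATUSES)}, "
                f"got {self.status!r}"
            )
        object.__setattr__(self, "algorithms", frozenset(self.algorithms))
        object.__setattr__(self, "samples", frozenset(self.samples))


@dataclass(frozen=True)
class SnpRecord:
    """A SNP map entry (position only; genotypes live in the matrix)."""

    snp_id: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    generation: str
    breed: str
    sex: str = ""

    def __post_init__(self) -> None:
        if self.generation not in {"F0", "F1", "F2"}:
            raise ValueError(f"generation must be F0/F1/F2, got {self.generation!r}")
        if not self.breed:
            raise ValueError("breed must be non-empty")


@dataclass(frozen=True)
class FeatureRecord:
    """A gene/QTL/SNP/DGV-region/gap annotation interval."""

    feature_id: str
    interval: GenomicInterval
    kind: str
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(
                f"kind must be one of {sorted(FEATURE_KINDS)}, got {self.kind!r}"
            )
        if self.kind == "snp" and self.interval.start != self.interval.end:
            raise ValueError(
                f"snp feature {self.feature_id!r} must have start == end"
            )
        object.__setattr__(self, "attributes", dict(self.attributes))


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds for genotype QC (all strict inequalities)."""

    snp_call_rate_min: float = 0.90
    maf_min: float = 0.03
    hwe_p_min: float = 1e-6
    sample_call_rate_min: float = 0.90

    def __post_init__(self) -> None:
        for name in (
            "snp_call_rate_min",
            "maf_min",
            "hwe_p_min",
            "sample_call_rate_min",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class QpcrAssay:
    """CT replicates for one test sample and its no-CNV calibrator."""

    sample_id: str
    cnvr_id: str
    target_ct: tuple
    control_ct: tuple
    calibrator_target_ct: tuple
    calibrator_control_ct: tuple

    def __post_init__(self) -> None:
        for well in (
            "target_ct",
            "control_ct",
            "calibrator_target_ct",
            "calibrator_control_ct",
        ):
            values = tuple(float(v) for v in getattr(self, well))
            if len(values) < 1:
                raise ValueError(
                    f"assay {self.sample_id}/{self.cnvr_id}: "
                    f"well {well} has no replicates"
                )
            for v in values:
                if not (v > 0) or v != v or v in (float("inf"),):
                    raise ValueError(
                        f"assay {self.sample_id}/{self.cnvr_id}: "
                        f"well {well} has non-finite or non-positive CT {v}"
                    )
            object.__setattr__(self, well, values)
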