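"""Seeded synthetic data for the whole pipeline.

Generates a planted-truth CNVR landscape on a toy genome, emulated call
sets for several callers with distinct sensitivity / false-positive /
boundary-jitter profiles, genotype matrices with controllable QC
failures, and qPCR CT tables -- so every stage is testable offline with
known ground truth.  Identical seeds give byte-identical outputs.

Probe positions come from a uniformly spaced SNP map (default one probe
per 40 kb, the density scale of a 60K porcine chip on a ~2.4 Gb
genome); ``n_snps`` on emitted calls is always counted from that map,
never drawn independently, so the min-SNP filter interacts with CNV
size the way it does on real chips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from cnvrmap.model import (
    GAIN,
    GAIN_LOSS,
    LOSS,
    CnvCall,
    GenomicInterval,
    SampleInfo,
    SnpRecord,
    chrom_sort_key,
)


# ---------------------------------------------------------------------------
# Specs and truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """One breed x generation cohort and its CNVR carrier frequency."""

    cohort_id: str
    breed: str
    generation: str
    n_samples: int
    carrier_freq: float = 0.25


@dataclass(frozen=True)
class CallerProfile:
    """Error model for one emulated CNV caller."""

    algorithm_id: str
    sensitivity: float = 0.9
    fp_rate: float = 0.05  # false segments per Mb per sample
    boundary_jitter_sd: float = 5_000.0  # bp
    state_flip_prob: float = 0.02
    min_snps_emitted: int = 3
    size_bias_log_sd: float = 0.0  # lognormal length distortion
    fp_length_median: float = 40_000.0
    fp_length_log_sd: float = 0.6

    def __post_init__(self) -> None:
        for name in ("sensitivity", "state_flip_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.boundary_jitter_sd < 0:
            raise ValueError("boundary_jitter_sd must be >= 0")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")


DEFAULT_PROFILES = (
    CallerProfile("gada", sensitivity=0.92, fp_rate=0.05, boundary_jitter_sd=6_000),
    CallerProfile("penncnv", sensitivity=0.90, fp_rate=0.03, boundary_jitter_sd=4_000),
    CallerProfile("quantisnp", sensitivity=0.88, fp_rate=0.06, boundary_jitter_sd=5_000),
    CallerProfile("cnvpartition", sensitivity=0.75, fp_rate=0.01, boundary_jitter_sd=3_000),
)


@dataclass(frozen=True)
class PlantedCnvr:
    cnvr_id: int
    interval: GenomicInterval
    status: str
    carriers: Dict[str, int]  # sample_id -> integer copy number


@dataclass
class TruthSet:
    genome: Dict[str, int]
    cnvrs: List[PlantedCnvr]
    samples: List[SampleInfo]
    snp_map: List[SnpRecord]
    cohorts: List[CohortSpec] = field(default_factory=list)


def default_genome(n_chroms: int = 10, chrom_size: int = 100_000_000) -> Dict[str, int]:
    return {str(i): chrom_size for i in range(1, n_chroms + 1)}


def make_snp_map(genome: Dict[str, int], spacing: int = 40_000) -> List[SnpRecord]:
    """Uniformly spaced probe map across the genome."""
    snps: List[SnpRecord] = []
    i = 1
    for chrom in sorted(genome, key=chrom_sort_key):
        for pos in range(spacing // 2, genome[chrom] + 1, spacing):
            snps.append(SnpRecord(f"SNP{i:06d}", chrom, pos))
            i += 1
    return snps


def make_samples(cohorts: Sequence[CohortSpec]) -> List[SampleInfo]:
    samples: List[SampleInfo] = []
    i = 1
    for c in cohorts:
        for _ in range(c.n_samples):
            samples.append(SampleInfo(f"S{i:04d}", c.generation, c.breed, ""))
            i += 1
    return samples


# ---------------------------------------------------------------------------
# Truth simulation
# ---------------------------------------------------------------------------


def simulate_truth(
    genome: Dict[str, int],
    n_cnvrs: int,
    cohorts: Sequence[CohortSpec],
    seed: int,
    size_range: Tuple[int, int] = (200_000, 5_000_000),
    status_mix: Tuple[float, float, float] = (70, 43, 136),
    min_gap: int = 50_000,
    fixed_carriers_per_cnvr: Optional[int] = None,
    max_placement_tries: int = 1_000,
) -> TruthSet:
    """Plant non-overlapping true CNVRs with per-cohort carriers.

    Lengths are log-uniform over ``size_range``; statuses follow the
    (gain, loss, gain-loss) mix (default normalized 70:43:136, the
    status proportions of the map this emulates).  Carriers are drawn
    per cohort at its ``carrier_freq`` -- or exactly
    ``fixed_carriers_per_cnvr`` random samples when given -- and
    gain/loss carriers get integer copy numbers 3/1; gain-loss regions
    mix both.  Planted regions never overlap (``min_gap`` bp apart), so
    truth matching is unambiguous.
    """
    if not genome:
        raise ValueError("empty genome")
    rng = np.random.default_rng(seed)
    samples = make_samples(cohorts)
    snp_map = make_snp_map(genome)

    lo, hi = size_range
    if not (0 < lo <= hi):
        raise ValueError(f"bad size_range {size_range}")
    genome_bp = sum(genome.values())
    if n_cnvrs * lo > genome_bp:
        raise ValueError(
            f"infeasible packing: {n_cnvrs} regions of >= {lo} bp "
            f"exceed the {genome_bp} bp genome"
        )

    chroms = sorted(genome, key=chrom_sort_key)
    weights = np.array([genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    mix = np.array(status_mix, dtype=float)
    mix /= mix.sum()

    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    cnvrs: List[PlantedCnvr] = []
    sample_ids = [s.sample_id for s in samples]
    cohort_members = {
        c.cohort_id: [
            s.sample_id
            for s in samples
            if s.breed == c.breed and s.generation == c.generation
        ]
        for c in cohorts
    }

    for cnvr_id in range(1, n_cnvrs + 1):
        length = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        interval = None
        for _ in range(max_placement_tries):
            chrom = rng.choice(chroms, p=weights)
            size = genome[chrom]
            if size < length:
                continue
            start = int(rng.integers(1, size - length + 2))
            end = start + length - 1
            clash = any(
                start <= e + min_gap and s - min_gap <= end
                for s, e in placed[chrom]
            )
            if not clash:
                interval = GenomicInterval(chrom, start, end)
                placed[chrom].append((start, end))
                break
        if interval is None:
            raise ValueError(
                f"infeasible packing: could not place region {cnvr_id} "
                f"of {length} bp after {max_placement_tries} tries"
            )

        status = (GAIN, LOSS, GAIN_LOSS)[int(rng.choice(3, p=mix))]
        if fixed_carriers_per_cnvr is not None:
            k = min(fixed_carriers_per_cnvr, len(sample_ids))
            carriers = list(rng.choice(sample_ids, size=k, replace=False))
        else:
            carriers = []
            for c in cohorts:
                for sid in cohort_members[c.cohort_id]:
                    if rng.random() < c.carrier_freq:
                        carriers.append(sid)
            while len(carriers) < 2 and sample_ids:
                extra = str(rng.choice(sample_ids))
                if extra not in carriers:
                    carriers.append(extra)

        copy_numbers: Dict[str, int] = {}
        if status == GAIN:
            copy_numbers = {sid: 3 for sid in carriers}
        elif status == LOSS:
            copy_numbers = {sid: 1 for sid in carriers}
        else:
            states = rng.random(len(carriers)) < 0.5
            copy_numbers = {
                sid: (3 if up else 1) for sid, up in zip(carriers, states)
            }
            if len(carriers) >= 2 and len(set(copy_numbers.values())) == 1:
                first = carriers[0]
                copy_numbers[first] = 1 if copy_numbers[first] == 3 else 3
        cnvrs.append(PlantedCnvr(cnvr_id, interval, status, copy_numbers))

    return TruthSet(
        genome=dict(genome),
        cnvrs=cnvrs,
        samples=samples,
        snp_map=snp_map,
        cohorts=list(cohorts),
    )


# ---------------------------------------------------------------------------
# Caller emulation
# ---------------------------------------------------------------------------


def _snp_positions(snp_map: Sequence[SnpRecord]) -> Dict[str, np.ndarray]:
    by_chrom: Dict[str, List[int]] = {}
    for s in snp_map:
        by_chrom.setdefault(s.chrom, []).append(s.pos)
    return {c: np.asarray(sorted(p)) for c, p in by_chrom.items()}


def _count_snps(positions: Dict[str, np.ndarray], iv: GenomicInterval) -> int:
    pos = positions.get(iv.chrom)
    if pos is None:
        return 0
    return int(
        np.searchsorted(pos, iv.end, side="right")
        - np.searchsorted(pos, iv.start, side="left")
    )


def emit_caller_calls(
    truth: TruthSet, profile: CallerProfile, seed: int
) -> List[CnvCall]:
    """Emulate one caller's output over the planted truth.

    Each (planted region, carrier) pair is detected with probability
    ``sensitivity``; detected calls get normally jittered boundaries
    (clipped to the chromosome), optional lognormal length distortion,
    state flips, and ``n_snps`` counted from the probe map.  False
    segments arrive per sample at ``fp_rate`` per Mb with lognormal
    lengths.  Calls covering fewer than ``min_snps_emitted`` probes are
    never emitted (the caller cannot see them).
    """
    rng = np.random.default_rng(seed)
    positions = _snp_positions(truth.snp_map)
    calls: List[CnvCall] = []

    for planted in truth.cnvrs:
        chrom_size = truth.genome[planted.interval.chrom]
        for sample_id in sorted(planted.carriers):
            if rng.random() >= profile.sensitivity:
                continue
            start, end = planted.interval.start, planted.interval.end
            if profile.size_bias_log_sd > 0:
                scale = math.exp(rng.normal(0.0, profile.size_bias_log_sd))
                center = (start + end) / 2
                half = (end - start + 1) * scale / 2
                start, end = int(center - half), int(center + half)
            if profile.boundary_jitter_sd > 0:
                start += int(round(rng.normal(0, profile.boundary_jitter_sd)))
                end += int(round(rng.normal(0, profile.boundary_jitter_sd)))
            start = max(1, min(start, chrom_size))
            end = max(start, min(end, chrom_size))
            cn = planted.carriers[sample_id]
            state = GAIN if cn > 2 else LOSS
            if rng.random() < profile.state_flip_prob:
                state = LOSS if state == GAIN else GAIN
            iv = GenomicInterval(planted.interval.chrom, start, end)
            n_snps = _count_snps(positions, iv)
            if n_snps < max(1, profile.min_snps_emitted):
                continue
            calls.append(
                CnvCall(sample_id, profile.algorithm_id, iv, state, n_snps, cn)
            )

    if profile.fp_rate > 0:
        chroms = sorted(truth.genome, key=chrom_sort_key)
        mu = math.log(profile.fp_length_median)
        for sample in truth.samples:
            for chrom in chroms:
                size = truth.genome[chrom]
                n_fp = rng.poisson(profile.fp_rate * size / 1e6)
                for _ in range(n_fp):
                    length = int(rng.lognormal(mu, profile.fp_length_log_sd))
                    length = max(1, min(length, size))
                    start = int(rng.integers(1, size - length + 2))
                    iv = GenomicInterval(chrom, start, start + length - 1)
                    n_snps = _count_snps(positions, iv)
                    if n_snps < max(1, profile.min_snps_emitted):
                        continue
                    state = GAIN if rng.random() < 0.5 else LOSS
                    calls.append(
                        CnvCall(
                            sample.sample_id, profile.algorithm_id, iv, state, n_snps
                        )
                    )

    calls.sort(
        key=lambda c: (
            c.sample_id,
            chrom_sort_key(c.interval.chrom),
            c.interval.start,
            c.interval.end,
        )
    )
    return calls


# ---------------------------------------------------------------------------
# Genotype matrices with planted QC failures
# ---------------------------------------------------------------------------


def emit_genotypes(
    n_samples: int,
    n_snps: int,
    seed: int,
    maf_range: Tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.01,
    n_low_maf: int = 0,
    n_hwe_violating: int = 0,
    n_low_call_rate_snps: int = 0,
    n_low_call_rate_samples: int = 0,
    low_call_rate: float = 0.85,
):
    """Genotype matrix under HWE plus planted single-rule failures.

    Returns ``(frame, truth)`` where ``frame`` is a sample x SNP pandas
    frame of AA/AB/BB/``--`` and ``truth`` maps each planted SNP/sample
    to the one rule it violates (``maf``, ``hwe``, ``call_rate``).
    Background SNPs are drawn under exact HWE proportions at a MAF
    sampled from ``maf_range`` with light uniform missingness.
    """
    import pandas as pd

    n_planted = n_low_maf + n_hwe_violating + n_low_call_rate_snps
    if n_planted > n_snps:
        raise ValueError("planted SNP failures exceed n_snps")
    if n_low_call_rate_samples > n_samples:
        raise ValueError("planted sample failures exceed n_samples")

    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    snp_ids = [f"SNP{i:05d}" for i in range(1, n_snps + 1)]
    geno = np.empty((n_samples, n_snps), dtype=object)

    truth = {"snps": {}, "samples": {}}
    kinds = (
        ["maf"] * n_low_maf
        + ["hwe"] * n_hwe_violating
        + ["call_rate"] * n_low_call_rate_snps
        + ["pass"] * (n_snps - n_planted)
    )
    rng.shuffle(kinds)

    for j, kind in enumerate(kinds):
        truth["snps"][snp_ids[j]] = kinds[j]
        if kind == "hwe":
            geno[:, j] = "AB"  # extreme heterozygote excess
            continue
        if kind == "maf":
            maf = 0.01
        else:
            maf = rng.uniform(*maf_range)
        p = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        draws = rng.choice(3, size=n_samples, p=p)
        col = np.array(["AA", "AB", "BB"], dtype=object)[draws]
        if kind == "call_rate":
            miss = rng.random(n_samples) < (1 - low_call_rate)
            # guarantee the rate is strictly below threshold
            need = int(math.ceil(n_samples * (1 - low_call_rate + 0.02)))
            if miss.sum() < need:
                miss[rng.choice(n_samples, size=need, replace=False)] = True
            col[miss] = "--"
        elif missing_rate > 0:
            col[rng.random(n_samples) < missing_rate] = "--"
        geno[:, j] = col

    bad_samples = list(rng.choice(n_samples, size=n_low_call_rate_samples, replace=False))
    for i in bad_samples:
        truth["samples"][sample_ids[i]] = "call_rate"
        miss = rng.random(n_snps) < 0.15
        need = int(math.ceil(n_snps * 0.12))
        if miss.sum() < need:
            miss[rng.choice(n_snps, size=need, replace=False)] = True
        row = geno[i, :].copy()
        row[miss] = "--"
        geno[i, :] = row
    for sid in sample_ids:
        truth["samples"].setdefault(sid, "pass")

    frame = pd.DataFrame(geno, index=sample_ids, columns=snp_ids)
    return frame, truth


# ---------------------------------------------------------------------------
# qPCR CT tables
# ---------------------------------------------------------------------------

_CONTROL_CT = 25.0
_TARGET_BASE_CT = 28.0


def emit_qpcr(
    truth: TruthSet,
    selected_cnvr_ids: Sequence[int],
    seed: int,
    samples_per_cnvr: int = 8,
    ct_noise_sd: float = 0.1,
    n_replicates: int = 4,
) -> List[dict]:
    """CT replicate rows for selected planted CNVRs.

    The ideal target ddCT for a sample with copy number ``cn`` is
    ``-log2(cn / 2)`` relative to a designated 2-copy calibrator;
    replicate CTs are ideal values plus Gaussian noise.  Returns
    long-format rows consumable by :func:`cnvrmap.io.read_qpcr_assays`,
    with carriers listed first and non-carrier (2-copy) samples filling
    the remaining slots.
    """
    rng = np.random.default_rng(seed)
    by_id = {p.cnvr_id: p for p in truth.cnvrs}
    all_ids = [s.sample_id for s in truth.samples]
    rows: List[dict] = []

    def well(ideal: float) -> str:
        reps = ideal + rng.normal(0.0, ct_noise_sd, size=n_replicates)
        return ",".join(f"{v:.8f}" for v in reps)

    for cnvr_id in selected_cnvr_ids:
        planted = by_id[cnvr_id]
        carriers = sorted(planted.carriers)
        non_carriers = [s for s in all_ids if s not in planted.carriers]
        calibrator = non_carriers[0] if non_carriers else None
        if calibrator is None:
            raise ValueError(
                f"planted region {cnvr_id} leaves no 2-copy calibrator sample"
            )
        rows.append(
            {
                "cnvr_id": f"CNVR{cnvr_id}",
                "sample_id": calibrator,
                "role": "calibrator",
                "target_cts": well(_TARGET_BASE_CT),
                "control_cts": well(_CONTROL_CT),
            }
        )
        chosen = carriers[:samples_per_cnvr]
        for extra in non_carriers[1:]:
            if len(chosen) >= samples_per_cnvr:
                break
            chosen.append(extra)
        for sid in chosen:
            cn = planted.carriers.get(sid, 2)
            ideal_target = _TARGET_BASE_CT - math.log2(cn / 2.0)
            rows.append(
                {
                    "cnvr_id": f"CNVR{cnvr_id}",
                    "sample_id": sid,
                    "role": "test",
                    "target_cts": well(ideal_target),
                    "control_cts": well(_CONTROL_CT),
                }
            )
    return rows


# ---------------------------------------------------------------------------
# Scoring against truth
# ---------------------------------------------------------------------------


def score_against_truth(
    regions: Sequence,
    truth: TruthSet,
    min_reciprocal: float = 0.5,
) -> Dict[str, float]:
    """Sensitivity/precision of a region set against the planted truth.

    Matching requires ``min_reciprocal`` reciprocal overlap (default
    50%, deliberately stricter than the pipeline's 1-bp merge rule so
    sprawling unions are not credited).  ``regions`` may be anything
    with an ``interval`` attribute.
    """
    matched_truth = set()
    matched_pred = 0
    for i, r in enumerate(regions):
        hit = False
        for p in truth.cnvrs:
            if r.interval.reciprocal_overlap(p.interval) >= min_reciprocal:
                matched_truth.add(p.cnvr_id)
                hit = True
        matched_pred += hit
    n_truth = len(truth.cnvrs)
    n_pred = len(list(regions))
    return {
        "sensitivity": (len(matched_truth) / n_truth) if n_truth else 0.0,
        "precision": (matched_pred / n_pred) if n_pred else 0.0,
        "n_truth": n_truth,
        "n_predicted": n_pred,
        "n_truth_recovered": len(matched_truth),
    }
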