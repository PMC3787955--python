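"""Genotype quality control: SNP call-rate, MAF and HWE filters.

Filter order is fixed: (1) SNP filters evaluated on all samples, then
(2) a sample call-rate filter evaluated on the surviving SNPs only.  All
exclusions are strict inequalities (a SNP at exactly the call-rate
threshold is retained).  Departure from Hardy-Weinberg is assessed with
the exact test conditional on allele counts rather than a chi-square
approximation: at the 1e-6 exclusion level the chi-square tail is
unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from cnvrmap.model import QcThresholds


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tallies for one biallelic SNP."""

    n_AA: int
    n_AB: int
    n_BB: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("n_AA", "n_AB", "n_BB", "n_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_typed(self) -> int:
        return self.n_AA + self.n_AB + self.n_BB

    @property
    def total(self) -> int:
        return self.n_typed + self.n_missing


def snp_call_rate(counts: GenotypeCounts) -> float:
    """Fraction of samples with a genotype call at this SNP."""
    if counts.total == 0:
        raise ValueError("call rate undefined with zero samples")
    return counts.n_typed / counts.total


def minor_allele_frequency(counts: GenotypeCounts) -> float:
    """MAF from typed genotypes only (missing excluded from denominator)."""
    if counts.n_typed == 0:
        raise ValueError("MAF undefined with no typed genotypes")
    p_b = (2 * counts.n_BB + counts.n_AB) / (2 * counts.n_typed)
    return min(p_b, 1.0 - p_b)


def hwe_exact_p(counts: GenotypeCounts) -> float:
    """Two-sided exact Hardy-Weinberg test, conditional on allele counts.

    Sums, over every heterozygote count compatible with the observed
    allele totals, the conditional probabilities that do not exceed that
    of the observed configuration.  Monomorphic SNPs have a single
    configuration and return 1.0.
    """
    n_ab = counts.n_AB
    n_typed = counts.n_typed
    if n_typed < 1:
        raise ValueError("HWE test needs at least one typed genotype")
    rare = 2 * min(counts.n_AA, counts.n_BB) + n_ab
    common = 2 * n_typed - rare
    if rare == 0:
        return 1.0

    # P(het = k | allele counts) up to a constant, in log space for
    # numerical safety at large n; normalized afterwards.
    def log_weight(k: int) -> float:
        n_rr = (rare - k) // 2
        n_cc = (common - k) // 2
        return (
            k * math.log(2.0)
            - math.lgamma(k + 1)
            - math.lgamma(n_rr + 1)
            - math.lgamma(n_cc + 1)
        )

    ks = range(rare % 2, min(rare, common) + 1, 2)
    logs = {k: log_weight(k) for k in ks}
    m = max(logs.values())
    weights = {k: math.exp(v - m) for k, v in logs.items()}
    total = sum(weights.values())
    obs = weights[n_ab]
    # 1e-12 relative slack absorbs float noise in the <= comparison.
    p = sum(w for w in weights.values() if w <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


@dataclass
class QcReport:
    """Per-SNP and per-sample verdicts plus survivor counts per stage."""

    snp_table: pd.DataFrame
    sample_table: pd.DataFrame
    counts: Dict[str, int]
    thresholds: QcThresholds
    warnings: List[str] = field(default_factory=list)
    unstable_snps: List[str] = field(default_factory=list)
    metadata: Dict[str, str] = field(default_factory=dict)


def _snp_counts_frame(genotypes: pd.DataFrame) -> pd.DataFrame:
    values = genotypes.to_numpy(dtype=object)
    out = pd.DataFrame(index=genotypes.columns)
    out["n_AA"] = (values == "AA").sum(axis=0)
    out["n_AB"] = (values == "AB").sum(axis=0)
    out["n_BB"] = (values == "BB").sum(axis=0)
    out["n_missing"] = len(genotypes) - out[["n_AA", "n_AB", "n_BB"]].sum(axis=1)
    return out


def _evaluate_snps(
    genotypes: pd.DataFrame,
    thresholds: QcThresholds,
    hwe_samples: Optional[Sequence[str]],
) -> pd.DataFrame:
    tallies = _snp_counts_frame(genotypes)
    if hwe_samples is not None:
        hwe_tallies = _snp_counts_frame(genotypes.loc[list(hwe_samples)])
    else:
        hwe_tallies = tallies

    records = []
    for snp_id in genotypes.columns:
        row = tallies.loc[snp_id]
        c = GenotypeCounts(int(row.n_AA), int(row.n_AB), int(row.n_BB), int(row.n_missing))
        call_rate = snp_call_rate(c)
        if c.n_typed > 0:
            maf = minor_allele_frequency(c)
        else:
            maf = float("nan")
        h = hwe_tallies.loc[snp_id]
        hc = GenotypeCounts(int(h.n_AA), int(h.n_AB), int(h.n_BB), int(h.n_missing))
        hwe_p = hwe_exact_p(hc) if hc.n_typed > 0 else float("nan")

        failing = []
        if call_rate < thresholds.snp_call_rate_min:
            failing.append("call_rate")
        if not math.isnan(maf) and maf < thresholds.maf_min:
            failing.append("maf")
        if not math.isnan(hwe_p) and hwe_p < thresholds.hwe_p_min:
            failing.append("hwe")
        records.append(
            {
                "snp_id": snp_id,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "pass": not failing,
                "failing_rules": ";".join(failing),
            }
        )
    return pd.DataFrame.from_records(records).set_index("snp_id")


def run_qc(
    genotypes: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
    hwe_samples: Optional[Sequence[str]] = None,
    iterate: bool = False,
) -> tuple:
    """Run the two-pass QC chain; returns ``(report, filtered_matrix)``.

    ``genotypes`` is a sample x SNP frame of AA/AB/BB/``--`` strings.
    ``hwe_samples`` restricts the HWE test to a sample subset (default:
    all samples).  With ``iterate=True`` the SNP filters are re-applied
    after sample removal until the survivor sets stabilize; by default
    the report only *flags* SNPs whose verdict would change
    (``unstable_snps``).
    """
    if genotypes.empty:
        raise ValueError("empty genotype matrix")

    snp_table = _evaluate_snps(genotypes, thresholds, hwe_samples)
    kept_snps = snp_table.index[snp_table["pass"]].tolist()
    stage1 = genotypes[kept_snps]

    # Stage 2: sample call rate on surviving SNPs only.
    if kept_snps:
        typed = (stage1.to_numpy(dtype=object) != "--").sum(axis=1)
        sample_cr = typed / len(kept_snps)
    else:
        sample_cr = np.zeros(len(genotypes))
    sample_table = pd.DataFrame(
        {
            "call_rate": sample_cr,
            "pass": sample_cr >= thresholds.sample_call_rate_min,
        },
        index=genotypes.index,
    )
    kept_samples = sample_table.index[sample_table["pass"]].tolist()
    filtered = stage1.loc[kept_samples]

    warnings: List[str] = []
    if not kept_snps:
        warnings.append("all SNPs removed by stage-1 filters")
    if not kept_samples:
        warnings.append("all samples removed by stage-2 call-rate filter")

    # Stability: would any surviving SNP's verdict change if the SNP
    # filters were recomputed on the surviving samples?
    unstable: List[str] = []
    if kept_snps and len(kept_samples) not in (0, len(genotypes)):
        resub = hwe_samples
        if resub is not None:
            resub = [s for s in resub if s in kept_samples]
            resub = resub or None
        retab = _evaluate_snps(filtered, thresholds, resub)
        unstable = retab.index[~retab["pass"]].tolist()

    report = QcReport(
        snp_table=snp_table,
        sample_table=sample_table,
        counts={
            "n_snps_input": genotypes.shape[1],
            "n_snps_pass": len(kept_snps),
            "n_samples_input": genotypes.shape[0],
            "n_samples_pass": len(kept_samples),
        },
        thresholds=thresholds,
        warnings=warnings,
        unstable_snps=unstable,
        metadata={"hwe_test": "exact, conditional on allele counts (two-sided)"},
    )

    if iterate and unstable:
        sub_report, filtered = run_qc(filtered, thresholds, hwe_samples=None, iterate=True)
        report.counts["n_snps_pass"] = sub_report.counts["n_snps_pass"]
        report.counts["n_samples_pass"] = sub_report.counts["n_samples_pass"]
        report.metadata["iterated"] = "true"
    return report, filtered
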