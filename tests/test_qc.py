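import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvrmap.model import QcThresholds
from cnvrmap.qc import (
    GenotypeCounts,
    hwe_exact_p,
    minor_allele_frequency,
    run_qc,
    snp_call_rate,
)
from cnvrmap.simulate import emit_genotypes

from oracles import hwe_exact_p_fraction


class TestSnpCallRate:
    def test_boundary_value_is_retained(self):
        counts = GenotypeCounts(45, 45, 0, n_missing=10)
        assert snp_call_rate(counts) == 0.90
        # exclusion is strictly < threshold
        assert not snp_call_rate(counts) < QcThresholds().snp_call_rate_min

    def test_all_missing(self):
        assert snp_call_rate(GenotypeCounts(0, 0, 0, n_missing=10)) == 0.0

    def test_zero_samples_errors(self):
        with pytest.raises(ValueError):
            snp_call_rate(GenotypeCounts(0, 0, 0, 0))


class TestMaf:
    def test_direct_formula(self):
        assert minor_allele_frequency(GenotypeCounts(90, 8, 2)) == pytest.approx(0.06)

    def test_monomorphic(self):
        assert minor_allele_frequency(GenotypeCounts(100, 0, 0)) == 0.0

    def test_no_typed_genotypes_errors(self):
        with pytest.raises(ValueError):
            minor_allele_frequency(GenotypeCounts(0, 0, 0, 5))

    @given(
        st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
    )
    def test_matches_allele_enumeration(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        # oracle: spell out every genotype string and tally alleles
        alleles = list("AA" * n_aa + "AB" * n_ab + "BB" * n_bb)
        freq_b = alleles.count("B") / len(alleles)
        expected = min(freq_b, 1 - freq_b)
        got = minor_allele_frequency(GenotypeCounts(n_aa, n_ab, n_bb))
        assert got == pytest.approx(expected)
        assert 0 <= got <= 0.5


class TestHweExact:
    def test_monomorphic_p_is_one(self):
        assert hwe_exact_p(GenotypeCounts(37, 0, 0)) == 1.0

    def test_frozen_enumeration_values(self):
        # expected values computed with the rational-arithmetic
        # enumeration oracle (oracles.hwe_exact_p_fraction)
        assert hwe_exact_p(GenotypeCounts(25, 50, 25)) == pytest.approx(1.0, abs=1e-12)
        assert hwe_exact_p(GenotypeCounts(50, 21, 29)) == pytest.approx(
            1.6631342793191425e-08, rel=1e-10
        )
        assert hwe_exact_p(GenotypeCounts(3, 1, 5)) == pytest.approx(
            0.03167420814479638, rel=1e-12
        )

    def test_extreme_het_excess_below_threshold(self):
        p = hwe_exact_p(GenotypeCounts(0, 200, 0))
        assert p == pytest.approx(hwe_exact_p_fraction(0, 200, 0), rel=1e-9)
        assert p < 1e-6

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            GenotypeCounts(-1, 0, 0)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_matches_fraction_oracle(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        got = hwe_exact_p(GenotypeCounts(n_aa, n_ab, n_bb))
        want = hwe_exact_p_fraction(n_aa, n_ab, n_bb)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-300)
        assert 0 < got <= 1.0

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_allele_relabeling_symmetry(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        assert hwe_exact_p(GenotypeCounts(n_aa, n_ab, n_bb)) == pytest.approx(
            hwe_exact_p(GenotypeCounts(n_bb, n_ab, n_aa)), rel=1e-12
        )


def brute_force_snp_verdicts(genotypes: pd.DataFrame, thresholds: QcThresholds):
    """Independent per-column recount of every SNP verdict."""
    verdicts = {}
    for snp in genotypes.columns:
        col = list(genotypes[snp])
        n_aa, n_ab, n_bb = col.count("AA"), col.count("AB"), col.count("BB")
        n_missing = len(col) - n_aa - n_ab - n_bb
        ok = True
        if (n_aa + n_ab + n_bb) / len(col) < thresholds.snp_call_rate_min:
            ok = False
        typed = n_aa + n_ab + n_bb
        if typed:
            freq_b = (2 * n_bb + n_ab) / (2 * typed)
            if min(freq_b, 1 - freq_b) < thresholds.maf_min:
                ok = False
            if hwe_exact_p_fraction(n_aa, n_ab, n_bb) < thresholds.hwe_p_min:
                ok = False
        verdicts[snp] = ok
    return verdicts


class TestRunQc:
    def test_clean_matrix_untouched(self):
        rng = np.random.default_rng(1)
        geno = pd.DataFrame(
            rng.choice(["AA", "AB", "BB"], p=[0.25, 0.5, 0.25], size=(60, 30)),
            index=[f"S{i}" for i in range(60)],
            columns=[f"SNP{j}" for j in range(30)],
        )
        report, filtered = run_qc(geno)
        assert filtered.shape == geno.shape
        assert report.counts["n_snps_pass"] == 30
        assert report.counts["n_samples_pass"] == 60

    def test_planted_failures_match_truth_labels(self):
        geno, truth = emit_genotypes(
            n_samples=400,
            n_snps=60,
            seed=9,
            missing_rate=0.0,
            n_low_maf=4,
            n_hwe_violating=3,
            n_low_call_rate_snps=3,
            n_low_call_rate_samples=2,
        )
        report, filtered = run_qc(geno)
        for snp, label in truth["snps"].items():
            passed = bool(report.snp_table.loc[snp, "pass"])
            assert passed == (label == "pass"), (snp, label)
            if label != "pass":
                assert label in report.snp_table.loc[snp, "failing_rules"]
        for sample, label in truth["samples"].items():
            assert bool(report.sample_table.loc[sample, "pass"]) == (label == "pass")

    def test_verdicts_match_brute_force_recount(self):
        geno, _ = emit_genotypes(
            n_samples=150,
            n_snps=50,
            seed=21,
            missing_rate=0.08,
            maf_range=(0.01, 0.5),
            n_hwe_violating=2,
        )
        thresholds = QcThresholds()
        report, _ = run_qc(geno, thresholds)
        expected = brute_force_snp_verdicts(geno, thresholds)
        got = {snp: bool(report.snp_table.loc[snp, "pass"]) for snp in geno.columns}
        assert got == expected

    def test_planted_low_call_rate_sample_removed_at_stage_two(self):
        geno, truth = emit_genotypes(
            n_samples=100, n_snps=40, seed=3, n_low_call_rate_samples=1
        )
        (bad_sample,) = [s for s, v in truth["samples"].items() if v != "pass"]
        report, filtered = run_qc(geno)
        assert bad_sample not in filtered.index

    def test_survivor_counts_non_increasing(self):
        geno, _ = emit_genotypes(
            n_samples=80, n_snps=40, seed=5, n_low_maf=3, n_low_call_rate_samples=1
        )
        report, filtered = run_qc(geno)
        assert report.counts["n_snps_pass"] <= report.counts["n_snps_input"]
        assert report.counts["n_samples_pass"] <= report.counts["n_samples_input"]

    def test_idempotence_on_own_output(self):
        geno, _ = emit_genotypes(
            n_samples=120,
            n_snps=50,
            seed=13,
            n_low_maf=2,
            n_hwe_violating=2,
            n_low_call_rate_samples=2,
        )
        _, filtered = run_qc(geno)
        report2, filtered2 = run_qc(filtered)
        assert filtered2.shape == filtered.shape
        assert list(filtered2.columns) == list(filtered.columns)
        assert list(filtered2.index) == list(filtered.index)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            run_qc(pd.DataFrame())

    def test_all_snps_removed_warns(self):
        geno = pd.DataFrame(
            {"SNP1": ["AA"] * 10, "SNP2": ["BB"] * 10},
            index=[f"S{i}" for i in range(10)],
        )
        report, filtered = run_qc(geno)  # monomorphic -> MAF 0 -> removed
        assert filtered.shape[1] == 0
        assert any("SNP" in w for w in report.warnings)

    def test_hwe_sample_subset_argument(self):
        # het excess confined to the non-subset samples -> SNP survives
        # when HWE is tested on the balanced subset only
        rows = ["AB"] * 130 + ["AA"] * 5 + ["AB"] * 10 + ["BB"] * 5
        geno = pd.DataFrame(
            {"SNP1": rows}, index=[f"S{i}" for i in range(150)]
        )
        subset = [f"S{i}" for i in range(130, 150)]  # 5 AA, 10 AB, 5 BB
        report_all, _ = run_qc(geno)
        report_sub, _ = run_qc(geno, hwe_samples=subset)
        assert not bool(report_all.snp_table.loc["SNP1", "pass"])
        assert bool(report_sub.snp_table.loc["SNP1", "pass"])
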