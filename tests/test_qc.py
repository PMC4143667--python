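"""Genotype QC: allele frequencies, HWE exact test, filter pipeline."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bivarlmm import (
    GenotypeMatrix,
    QcThresholds,
    allele_stats,
    apply_qc,
    hwe_exact_test,
    minor_allele_freq,
)
from bivarlmm.errors import (
    EmptyResultError,
    InvalidParameterError,
    UndefinedFrequencyError,
)


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact-rational Levene-Haldane tail via direct enumeration.

    P(n_ab | allele counts) = C(n, n_aa, n_ab, n_bb) 2^n_ab / C(2n, n_a);
    the p-value sums probabilities <= that of the observed het count.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n_a == 0 or n_a == 2 * n:
        return Fraction(1)
    denom = comb(2 * n, n_a)

    def prob(h):
        if (n_a - h) % 2 or h > min(n_a, 2 * n - n_a) or (n_a - h) // 2 < 0:
            return Fraction(0)
        aa = (n_a - h) // 2
        bb = n - aa - h
        if bb < 0:
            return Fraction(0)
        ways = Fraction(
            comb(n, aa) * comb(n - aa, h) * 2**h, denom
        )
        return ways

    p_obs = prob(n_ab)
    total = sum(prob(h) for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
                if prob(h) <= p_obs)
    return total


class TestMinorAlleleFreq:
    def test_hand_count(self):
        d = [0] * 50 + [1] * 40 + [2] * 10
        assert minor_allele_freq(d) == pytest.approx(0.30)

    def test_monomorphic(self):
        assert minor_allele_freq([0] * 20) == 0.0

    def test_flip_when_nominal_minor_is_major(self):
        st_ = allele_stats([0] * 10 + [2] * 90)
        assert st_.maf == pytest.approx(0.10)
        assert st_.flipped
        # counts reported against the sample-minor allele
        assert (st_.n_hom_minor, st_.n_het, st_.n_hom_major) == (10, 0, 90)

    def test_missing_ignored_in_denominator(self):
        d = [0, 1, 2, np.nan, np.nan]
        assert minor_allele_freq(d) == pytest.approx(0.5)

    def test_all_missing_rejected(self):
        with pytest.raises(UndefinedFrequencyError):
            minor_allele_freq([np.nan, np.nan])


class TestHweExactTest:
    def test_worked_values(self):
        assert hwe_exact_test(1, 2, 1) == pytest.approx(1.0)
        assert hwe_exact_test(2, 0, 2) == pytest.approx(6 / 70)
        assert hwe_exact_test(0, 0, 57) == 1.0

    def test_matches_enumeration_small_n(self):
        for n in range(1, 13):
            for aa in range(n + 1):
                for ab in range(n - aa + 1):
                    bb = n - aa - ab
                    got = hwe_exact_test(aa, ab, bb)
                    want = float(hwe_enumeration_oracle(aa, ab, bb))
                    assert got == pytest.approx(want, abs=1e-12), (aa, ab, bb)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(aa=st.integers(0, 60), ab=st.integers(0, 60), bb=st.integers(0, 60))
    def test_symmetric_in_homozygote_swap(self, aa, ab, bb):
        if aa + ab + bb == 0:
            return
        assert hwe_exact_test(aa, ab, bb) == pytest.approx(hwe_exact_test(bb, ab, aa))

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            hwe_exact_test(-1, 2, 3)


def _make_gm(dosages):
    dosages = np.asarray(dosages, float)
    n_snp = dosages.shape[1]
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(n_snp)],
            "chrom": "1",
            "pos": np.arange(n_snp) + 1,
            "minor_allele": "A",
            "major_allele": "G",
        }
    )
    return GenotypeMatrix(dosages, [f"i{i}" for i in range(len(dosages))], snps)


class TestApplyQc:
    def test_maf_filter(self):
        rng = np.random.default_rng(0)
        common = rng.binomial(2, 0.3, 200)
        rare = np.zeros(200)
        rare[:4] = 1  # maf 0.01
        gm = _make_gm(np.column_stack([rare, common]))
        kept, report = apply_qc(gm)
        assert kept.n_snps == 1
        assert kept.snp_ids.tolist() == ["s1"]
        assert "maf<0.05" in report.snp_table.loc[0, "fail_reasons"]

    def test_call_rate_filter(self):
        rng = np.random.default_rng(1)
        good = rng.binomial(2, 0.3, 100).astype(float)
        bad = good.copy()
        bad[:10] = np.nan  # 90% call rate
        # pad columns so no subject drops below its own call-rate threshold
        filler = np.column_stack([rng.binomial(2, 0.4, 100) for _ in range(18)]).astype(float)
        gm = _make_gm(np.column_stack([good, bad, filler]))
        kept, report = apply_qc(gm)
        assert "s1" not in kept.snp_ids
        row = report.snp_table.set_index("snp_id").loc["s1"]
        assert "call_rate<0.95" in row["fail_reasons"]

    def test_hwe_filter_attained_size_conservative(self):
        # at true HWE the exact test rejects at most the nominal rate
        rng = np.random.default_rng(2)
        dosages = rng.binomial(2, 0.3, size=(300, 2000)).astype(float)
        gm = _make_gm(dosages)
        _, report = apply_qc(gm, QcThresholds(min_maf=0.0, min_hwe_p=1e-3))
        frac_fail = (report.snp_table["hwe_p"] < 1e-3).mean()
        # binomial 99% upper bound at nominal 1e-3 over 2000 SNPs
        assert frac_fail <= 1e-3 + 2.58 * np.sqrt(1e-3 * (1 - 1e-3) / 2000)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        dosages = rng.binomial(2, rng.uniform(0.02, 0.5, 50), size=(120, 50)).astype(float)
        dosages[rng.random(dosages.shape) < 0.02] = np.nan
        gm = _make_gm(dosages)
        once, _ = apply_qc(gm)
        twice, _ = apply_qc(once)
        np.testing.assert_array_equal(once.dosages, twice.dosages)
        assert once.snp_ids.tolist() == twice.snp_ids.tolist()

    def test_all_removed_raises_with_report(self):
        gm = _make_gm(np.zeros((50, 2)))  # monomorphic -> fails MAF
        with pytest.raises(EmptyResultError) as exc:
            apply_qc(gm)
        assert exc.value.report is not None
        assert exc.value.report.n_snps_retained == 0

    def test_monomorphic_hwe_p_is_one(self):
        gm = _make_gm(np.zeros((30, 1)))
        with pytest.raises(EmptyResultError) as exc:
            apply_qc(gm)
        assert exc.value.report.snp_table.loc[0, "hwe_p"] == 1.0
        assert "maf<0.05" in exc.value.report.snp_table.loc[0, "fail_reasons"]
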