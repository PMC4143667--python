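"""GWAS genotype quality control.

Filters a :class:`~bivarlmm.data.GenotypeMatrix` the way a pre-association
cleaning step conventionally does: subjects by genotyping call rate first,
then SNPs by call rate, minor allele frequency, and the Hardy-Weinberg exact
test, with every per-SNP statistic recomputed on the retained subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .data import GenotypeMatrix
from .errors import EmptyResultError, InvalidParameterError, UndefinedFrequencyError

__all__ = [
    "QcThresholds",
    "QcReport",
    "AlleleStats",
    "allele_stats",
    "minor_allele_freq",
    "hwe_exact_test",
    "apply_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    """QC cutoffs: MAF >= 0.05, call rates >= 0.95, HWE p >= 1e-3."""

    min_maf: float = 0.05
    min_snp_call_rate: float = 0.95
    min_subject_call_rate: float = 0.95
    min_hwe_p: float = 1e-3

    def __post_init__(self):
        for name in ("min_maf", "min_snp_call_rate", "min_subject_call_rate", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class AlleleStats:
    """Sample allele summary for one SNP.

    ``flipped`` is True when the nominal minor allele exceeds frequency 0.5
    in this sample, in which case ``maf`` (and the genotype counts) refer to
    the sample-minor allele.
    """

    maf: float
    flipped: bool
    n_called: int
    n_hom_minor: int
    n_het: int
    n_hom_major: int


def allele_stats(dosages) -> AlleleStats:
    """MAF and genotype counts for one SNP's dosage vector (NaN = missing)."""
    d = np.asarray(dosages, float)
    called = d[~np.isnan(d)]
    if called.size == 0:
        raise UndefinedFrequencyError("all genotypes missing; MAF undefined")
    if not np.isin(called, (0.0, 1.0, 2.0)).all():
        raise InvalidParameterError("dosages must be in {0, 1, 2} or NaN")
    n = called.size
    n2 = int((called == 2.0).sum())
    n1 = int((called == 1.0).sum())
    n0 = n - n1 - n2
    freq = (2 * n2 + n1) / (2.0 * n)  # frequency of the nominal minor allele
    if freq > 0.5:
        return AlleleStats(1.0 - freq, True, n, n0, n1, n2)
    return AlleleStats(freq, False, n, n2, n1, n0)


def minor_allele_freq(dosages) -> float:
    """Sample minor-allele frequency (always <= 0.5); see :func:`allele_stats`."""
    return allele_stats(dosages).maf


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg equilibrium test (Levene-Haldane).

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed count (standard two-sided tail, no mid-p).

    Returns a p-value in (0, 1].  Monomorphic samples return 1.0.
    """
    counts = (n_hom_minor, n_het, n_hom_major)
    if any(int(c) != c or c < 0 for c in counts):
        raise InvalidParameterError(f"genotype counts must be non-negative integers: {counts}")
    a, b, c = (int(x) for x in counts)
    n = a + b + c
    if n < 1:
        raise InvalidParameterError("need at least one genotyped diploid")
    n_min = 2 * a + b
    n_maj = 2 * c + b
    if n_min > n_maj:  # test is symmetric in the two alleles
        n_min, n_maj = n_maj, n_min
    if n_min == 0:
        return 1.0
    hets = np.arange(n_min % 2, n_min + 1, 2)
    logp = (
        hets * np.log(2.0)
        - gammaln((n_min - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_maj - hets) / 2 + 1)
    )
    logp -= logsumexp(logp)
    p_obs = logp[hets == b][0]
    # 1e-12 log-space slack: larger than gammaln round-off, smaller than the
    # gap between distinct attainable probabilities for any realistic n.
    tail = logp[logp <= p_obs + 1e-12]
    return float(min(1.0, np.exp(logsumexp(tail))))


@dataclass
class QcReport:
    """Per-SNP and per-subject QC metrics with pass/fail flags."""

    snp_table: pd.DataFrame
    subject_table: pd.DataFrame
    thresholds: QcThresholds

    @property
    def n_snps_retained(self) -> int:
        return int(self.snp_table["pass"].sum())

    @property
    def n_subjects_retained(self) -> int:
        return int(self.subject_table["pass"].sum())

    def summary(self) -> str:
        t = self.thresholds
        return (
            f"QC summary\n"
            f"  subjects: {self.n_subjects_retained}/{len(self.subject_table)} retained "
            f"(call rate >= {t.min_subject_call_rate})\n"
            f"  SNPs:     {self.n_snps_retained}/{len(self.snp_table)} retained "
            f"(MAF >= {t.min_maf}, call rate >= {t.min_snp_call_rate}, "
            f"HWE p >= {t.min_hwe_p})\n"
        )


def apply_qc(genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None):
    """Filter a genotype matrix by the default GWAS QC criteria.

    Subjects are filtered by call rate first; SNP statistics (call rate, MAF,
    HWE) are then computed on the retained subjects only.  Monomorphic SNPs
    get ``hwe_p = 1`` but fail the MAF filter.

    Returns
    -------
    (retained, report) : (GenotypeMatrix, QcReport)

    Raises
    ------
    EmptyResultError
        If every subject or every SNP is removed (the report is attached).
    """
    thr = thresholds or QcThresholds()
    if genotypes.n_snps == 0 or genotypes.n_subjects == 0:
        raise InvalidParameterError("empty genotype matrix")

    miss = np.isnan(genotypes.dosages)
    subj_call = 1.0 - miss.mean(axis=1)
    subj_pass = subj_call >= thr.min_subject_call_rate
    subject_table = pd.DataFrame(
        {"subject_id": genotypes.subjects, "call_rate": subj_call, "pass": subj_pass}
    )

    report_cols = {
        "snp_id": genotypes.snp_ids,
        "maf": np.nan,
        "call_rate": np.nan,
        "hwe_p": np.nan,
        "flipped": False,
        "pass": False,
        "fail_reasons": "",
    }
    snp_table = pd.DataFrame(report_cols)

    if not subj_pass.any():
        raise EmptyResultError(
            "all subjects removed by call-rate filter",
            report=QcReport(snp_table, subject_table, thr),
        )

    sub = genotypes.dosages[subj_pass, :]
    for j in range(genotypes.n_snps):
        col = sub[:, j]
        call_rate = 1.0 - np.isnan(col).mean()
        reasons = []
        if np.isnan(col).all():
            maf, hwe_p, flipped = np.nan, np.nan, False
            reasons.append("all_missing")
        else:
            st = allele_stats(col)
            maf, flipped = st.maf, st.flipped
            hwe_p = hwe_exact_test(st.n_hom_minor, st.n_het, st.n_hom_major)
            if maf < thr.min_maf:
                reasons.append(f"maf<{thr.min_maf}")
            if hwe_p < thr.min_hwe_p:
                reasons.append(f"hwe_p<{thr.min_hwe_p}")
        if call_rate < thr.min_snp_call_rate:
            reasons.append(f"call_rate<{thr.min_snp_call_rate}")
        snp_table.loc[j, ["maf", "call_rate", "hwe_p", "flipped"]] = (
            maf, call_rate, hwe_p, flipped,
        )
        snp_table.loc[j, "pass"] = not reasons
        snp_table.loc[j, "fail_reasons"] = ";".join(reasons)

    report = QcReport(snp_table, subject_table, thr)
    snp_pass = snp_table["pass"].to_numpy(bool)
    if not snp_pass.any():
        raise EmptyResultError("all SNPs removed by QC filters", report=report)
    retained = genotypes.subset(subject_mask=subj_pass, snp_mask=snp_pass)
    assert retained.n_snps == report.n_snps_retained
    assert retained.n_subjects == report.n_subjects_retained
    return retained, report
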