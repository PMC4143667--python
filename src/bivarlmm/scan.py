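"""Genome-scan driver: per-SNP bivariate fits, hits, Manhattan/QQ data.

Each SNP gets its own full REML refit (variance components warm-started from
a covariates-only null fit); an approximate fast mode that freezes the
variance components at their null estimates is available and clearly
labelled as such.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix
from .design import ModelSpec
from .errors import EmptyResultError, InvalidParameterError
from .model import BivariateLMM
from .qc import allele_stats

__all__ = ["scan", "genomewide_hits", "qq_data", "manhattan_data", "GENOME_WIDE_ALPHA"]

#: Conventional dense-scan genome-wide significance threshold.
GENOME_WIDE_ALPHA = 7.2e-8

_SCAN_COLUMNS = [
    "snp_id", "chrom", "pos", "minor_allele", "maf", "n_subjects",
    "beta_sbp", "beta_dbp", "se_sbp", "se_dbp", "cov12",
    "wald", "df2", "p_f", "p_chi2", "converged",
]


def scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    spec: Optional[ModelSpec] = None,
    refit_variance: bool = True,
    df_policy: Optional[str] = None,
) -> pd.DataFrame:
    """Run the per-SNP joint association scan.

    Parameters
    ----------
    genotypes : QC'd genotype matrix.
    phenotypes : long-format phenotype table.
    spec : model specification (defaults to the final bivariate model).
    refit_variance : refit all variance components per SNP (default).  When
        False the variance components stay frozen at the null-model
        estimates — an approximation that only re-solves the GLS fixed
        effects and is noticeably faster.
    df_policy : df policy override for the F test.

    Returns
    -------
    DataFrame with one row per SNP, sorted by ascending F-test p-value
    (ties by chromosome, position); non-converged fits are retained but
    flagged.
    """
    if genotypes.n_snps == 0:
        raise EmptyResultError("no SNPs to scan")
    spec = spec or ModelSpec()

    null_model = BivariateLMM(phenotypes, dosages=None, spec=spec)
    null_fit = null_model.fit()
    vc0 = null_fit.vc

    t1, t2 = spec.trait_labels
    rows = []
    for j in range(genotypes.n_snps):
        meta = genotypes.snps.iloc[j]
        dos = genotypes.dosage_series(meta["snp_id"])
        st = allele_stats(dos.to_numpy())
        model = BivariateLMM(phenotypes, dosages=dos, spec=spec)
        if refit_variance:
            fit = model.fit(start=vc0)
        else:
            # fast mode: GLS at the frozen null variance components
            final = model.engine.evaluate(vc0)
            cov = np.linalg.inv(final.A)
            fit = _FrozenFit(model, final.beta, 0.5 * (cov + cov.T))
        jt = fit.joint_genotype_test(policy=df_policy)
        rows.append(
            {
                "snp_id": meta["snp_id"],
                "chrom": str(meta["chrom"]),
                "pos": int(meta["pos"]),
                "minor_allele": meta["minor_allele"],
                "maf": st.maf,
                "n_subjects": model.design.n_subjects,
                f"beta_{t1}": jt.beta[0],
                f"beta_{t2}": jt.beta[1],
                f"se_{t1}": float(np.sqrt(jt.S[0, 0])),
                f"se_{t2}": float(np.sqrt(jt.S[1, 1])),
                "cov12": float(jt.S[0, 1]),
                "wald": jt.wald,
                "df2": jt.df2,
                "p_f": jt.p_f,
                "p_chi2": jt.p_chi2,
                "converged": bool(getattr(fit, "converged", True)),
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(["p_f", "chrom", "pos"], kind="stable").reset_index(drop=True)
    return out


class _FrozenFit:
    """Minimal fit facade for the frozen-variance fast scan mode."""

    converged = True

    def __init__(self, model, beta, cov):
        self.model = model
        self._beta = beta
        self._cov = cov

    def joint_genotype_test(self, policy=None):
        from .design import compute_df2
        from .inference import wald_joint_test

        names = self.model.design.xnames
        idx = [i for i, n in enumerate(names) if n.endswith(":genotype")]
        beta_g = self._beta[idx]
        S = self._cov[np.ix_(idx, idx)]
        return wald_joint_test(beta_g, S, compute_df2(self.model.design, policy))


def genomewide_hits(rows: pd.DataFrame, alpha: float = GENOME_WIDE_ALPHA) -> pd.DataFrame:
    """Subset of scan rows with F-test p strictly below ``alpha``."""
    if len(rows) == 0:
        raise InvalidParameterError("empty scan table")
    if not 0 < alpha <= 1:
        raise InvalidParameterError(f"alpha must be in (0, 1], got {alpha}")
    return rows.loc[rows["p_f"] < alpha].copy()


def qq_data(p_values):
    """Expected/observed -log10 p pairs plus the genomic inflation factor.

    ``expected[i] = -log10((i - 0.5)/m)`` against sorted observed p-values.
    The inflation factor is the conventional median-based lambda_GC computed
    by converting each p-value to a 1-df chi-square quantile and dividing
    the median by 0.45494 (the chi-square_1 median); p-values from the 2-df
    joint test are converted through the same 1-df convention.

    Returns
    -------
    (expected, observed, lambda_gc)
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise InvalidParameterError("no p-values")
    if np.any(p > 1) or np.any(p < 0):
        raise InvalidParameterError("p-values must lie in (0, 1]")
    tiny = np.finfo(float).tiny
    if np.any(p == 0):
        p = np.maximum(p, tiny)
    m = p.size
    # pair the i-th smallest p with expected quantile (i - 0.5)/m
    observed = -np.log10(np.sort(p))
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    lambda_gc = float(np.median(stats.chi2.isf(p, df=1)) / stats.chi2.isf(0.5, df=1))
    return expected, observed, lambda_gc


def manhattan_data(rows: pd.DataFrame) -> pd.DataFrame:
    """Cumulative genome coordinates and -log10 p for a Manhattan plot.

    Chromosomes are concatenated in numeric order; rows with a missing
    position are skipped.  Returns columns ``snp_id, chrom, pos, x, neglog10p``.
    """
    df = rows.copy()
    missing = df["pos"].isna()
    if missing.any():
        import warnings

        warnings.warn(f"skipping {int(missing.sum())} rows with missing bp position")
        df = df.loc[~missing]

    def _chrom_key(c):
        try:
            return (0, int(c))
        except (TypeError, ValueError):
            return (1, str(c))

    chroms = sorted(df["chrom"].unique(), key=_chrom_key)
    offset = 0.0
    out = []
    for c in chroms:
        sub = df.loc[df["chrom"] == c].sort_values("pos")
        x = offset + sub["pos"].to_numpy(float)
        out.append(
            pd.DataFrame(
                {
                    "snp_id": sub["snp_id"].to_numpy(),
                    "chrom": c,
                    "pos": sub["pos"].to_numpy(),
                    "x": x,
                    "neglog10p": -np.log10(np.maximum(sub["p_f"].to_numpy(float),
                                                      np.finfo(float).tiny)),
                }
            )
        )
        offset += float(sub["pos"].max())
    return pd.concat(out, ignore_index=True)
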