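"""Joint Wald tests for SNP effects on one or two traits.

The 2-df joint test of H0: beta_G = (beta_SBP, beta_DBP) = 0 uses
W = beta' S^-1 beta with S the 2 x 2 covariance of the estimates; the
p-value is reported both from the chi-square reference (large-sample) and
from F(2, df2) with a policy-based denominator df, side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats

from .design import compute_df2
from .errors import InvalidParameterError, SingularCovarianceError

__all__ = ["JointTestResult", "wald_joint_test", "compute_df2"]


@dataclass
class JointTestResult:
    """Wald test of q coefficients jointly being zero.

    ``wald`` is W = beta' S^-1 beta; ``f_stat`` = W/q is referred to
    F(q, df2) and W to chi-square with q df.
    """

    beta: np.ndarray
    S: np.ndarray
    wald: float
    f_stat: float
    df1: int
    df2: int
    p_f: float
    p_chi2: float

    def __str__(self):
        b = ", ".join(f"{v:.4f}" for v in self.beta)
        return (
            f"JointTestResult(beta=[{b}], W={self.wald:.4f}, "
            f"F({self.df1},{self.df2})={self.f_stat:.4f}, "
            f"p_F={self.p_f:.3e}, p_chi2={self.p_chi2:.3e})"
        )


def wald_joint_test(beta_g, S, df2: int) -> JointTestResult:
    """Joint Wald test of H0: all tested coefficients are zero.

    Parameters
    ----------
    beta_g : length-q coefficient estimates (q = 2 for the bivariate SNP test).
    S : q x q symmetric positive-definite covariance of ``beta_g``.
    df2 : denominator degrees of freedom for the F reference.

    Raises
    ------
    SingularCovarianceError
        If S is not positive definite (e.g. the SNP is collinear with the
        covariates).
    """
    beta_g = np.atleast_1d(np.asarray(beta_g, float))
    S = np.atleast_2d(np.asarray(S, float))
    k = beta_g.size
    if S.shape != (k, k) or not np.allclose(S, S.T, atol=1e-8 * max(1.0, np.abs(S).max())):
        raise InvalidParameterError("S must be symmetric with shape matching beta_g")
    if df2 < 1:
        raise InvalidParameterError(f"df2 must be >= 1, got {df2}")
    try:
        c, low = scipy.linalg.cho_factor(S)
    except np.linalg.LinAlgError as e:
        raise SingularCovarianceError(f"covariance of tested coefficients singular: {e}")
    wald = float(beta_g @ scipy.linalg.cho_solve((c, low), beta_g))
    f_stat = wald / k
    p_chi2 = float(stats.chi2.sf(wald, df=k))
    p_f = float(stats.f.sf(f_stat, k, df2))
    return JointTestResult(
        beta=beta_g, S=S, wald=wald, f_stat=f_stat, df1=k, df2=int(df2),
        p_f=max(p_f, np.nextafter(0, 1)), p_chi2=max(p_chi2, np.nextafter(0, 1)),
    )
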