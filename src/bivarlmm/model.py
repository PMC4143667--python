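"""Model and results classes for the bivariate longitudinal mixed model.

`BivariateLMM` is constructed from a long-format phenotype table plus an
optional per-subject dosage vector; `fit()` maximizes the REML
log-likelihood over an unconstrained parameterization of the variance
components and returns an :class:`LMMResults` carrying the GLS fixed-effect
estimates, their covariance, the variance components, fit diagnostics, and
the joint SNP tests.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import ModelSpec, StackedDesign, build_design, compute_df2
from .errors import (
    DegenerateCovarianceError,
    IncomparableModelsError,
    InvalidParameterError,
)
from .inference import JointTestResult, wald_joint_test
from .reml import ParamMap, REMLEngine, VarianceComponents

__all__ = [
    "BivariateLMM",
    "LMMResults",
    "fit_bivariate",
    "fit_univariate",
    "compare_aic",
]


def _mom_start(design: StackedDesign) -> VarianceComponents:
    """Method-of-moments starting values from per-trait OLS residuals."""
    n_traits = len(design.traits)
    X = design.stacked_x()
    y = design.stacked_y()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    # per-subject, per-trait residual means and within-subject variances
    means = {k: [] for k in range(n_traits)}
    pair_means = []  # (mean_0, mean_1) for subjects observed on both traits
    within = {k: [] for k in range(n_traits)}
    m_counts = {k: [] for k in range(n_traits)}
    t2 = []
    for g in design.groups:
        r = g.Y - np.einsum("bnp,p->bn", g.X, beta)
        for b in range(g.n_subjects):
            subj_mean = {}
            for k in range(n_traits):
                mask = g.trait[b] == k
                if not mask.any():
                    continue
                rk = r[b, mask]
                subj_mean[k] = rk.mean()
                means[k].append(rk.mean())
                m_counts[k].append(mask.sum())
                if mask.sum() > 1:
                    within[k].append(rk.var(ddof=1))
            if n_traits == 2 and 0 in subj_mean and 1 in subj_mean:
                pair_means.append((subj_mean[0], subj_mean[1]))
        t2.append(g.time.ravel() ** 2)
    mean_t2 = max(float(np.mean(np.concatenate(t2))), 1.0)

    sigma2 = np.empty(n_traits)
    g_int = np.empty(n_traits)
    g_slope = np.empty(n_traits)
    for k in range(n_traits):
        total = float(np.var(np.asarray(means[k]))) + (
            float(np.mean(within[k])) if within[k] else 0.0
        )
        total = max(total, 1e-6)
        sigma2[k] = max(float(np.mean(within[k])) if within[k] else 0.5 * total, 0.05 * total)
        mbar = float(np.mean(m_counts[k])) if m_counts[k] else 1.0
        between = float(np.var(np.asarray(means[k]), ddof=1)) if len(means[k]) > 1 else total
        g_int[k] = max(between - sigma2[k] / mbar, 0.05 * total)
        g_slope[k] = 0.05 * g_int[k] / mean_t2

    q = design.q
    G = np.zeros((q, q))
    rand = list(design.spec.random_effects)
    shared = design.spec.random_effects_shared

    def re_var(k, name):
        if name == "intercept":
            return g_int[k]
        if name == "time":
            return g_slope[k]
        return 0.1 * g_int[k]

    if q:
        if shared or n_traits == 1:
            for j, name in enumerate(rand):
                G[j, j] = re_var(0, name)
        else:
            qpt = design.q_per_trait
            for k in range(n_traits):
                for j, name in enumerate(rand):
                    G[k * qpt + j, k * qpt + j] = re_var(k, name)
            if design.spec.cross_trait_random and len(pair_means) > 2 and "intercept" in rand:
                pm = np.asarray(pair_means)
                c12 = float(np.cov(pm.T)[0, 1])
                j0 = rand.index("intercept")
                lim = 0.9 * np.sqrt(G[j0, j0] * G[qpt + j0, qpt + j0])
                G[j0, qpt + j0] = G[qpt + j0, j0] = np.clip(0.8 * c12, -lim, lim)

    vc = VarianceComponents(G=G, sigma2=sigma2)
    fam = design.spec.covariance_family
    if fam == "UN_RE_OU":
        vc.ou = {"C": np.diag(0.2 * np.resize(sigma2, 2)), "decay": np.array([0.5, 0.5])}
        vc.sigma2 = 0.8 * vc.sigma2
    elif fam == "AR1_VISIT":
        vc.ar1 = {"sigma2_w": 0.3 * sigma2, "rho": np.full(n_traits, 0.3)}
        vc.sigma2 = 0.7 * vc.sigma2
    return vc


class BivariateLMM:
    """Bivariate (or univariate) linear mixed model for longitudinal traits.

    Parameters
    ----------
    phenotypes : long-format phenotype table.
    dosages : per-subject additive dosages (Series indexed by subject_id or
        mapping); ``None`` fits the covariates-only null model.
    spec : :class:`~bivarlmm.design.ModelSpec`.
    traits : optional subset of ``spec.trait_labels`` (a single label gives
        the univariate special case).

    Examples
    --------
    >>> model = BivariateLMM(pheno_df, dosages=gm.dosage_series("snp1"))
    >>> res = model.fit()
    >>> res.joint_genotype_test().p_f  # doctest: +SKIP
    """

    def __init__(self, phenotypes: pd.DataFrame, dosages=None,
                 spec: Optional[ModelSpec] = None, traits=None):
        self.spec = spec or ModelSpec()
        self.design = build_design(phenotypes, dosages, self.spec, traits=traits)
        self.engine = REMLEngine(self.design)
        self.pmap = ParamMap(
            q=self.design.q,
            n_traits=len(self.design.traits),
            family=self.spec.covariance_family,
            cross_trait_random=self.spec.cross_trait_random,
            q_per_trait=self.design.q_per_trait,
            shared=self.spec.random_effects_shared,
        )

    @classmethod
    def from_dataframe(cls, phenotypes, dosages=None, spec=None, traits=None):
        return cls(phenotypes, dosages=dosages, spec=spec, traits=traits)

    # ------------------------------------------------------------------

    def loglike(self, vc: VarianceComponents) -> float:
        """REML log-likelihood at the given variance components."""
        return self.engine.loglik(vc)

    def fit(self, start: Optional[VarianceComponents] = None, maxiter: int = 500,
            gtol: float = 1e-7, ftol: float = 1e-10, verbose: bool = False) -> "LMMResults":
        """Maximize the REML log-likelihood (quasi-Newton, L-BFGS-B).

        ``start`` warm-starts the optimizer (e.g. from a null-model fit);
        otherwise method-of-moments starting values are used.
        """
        if start is not None:
            vc0 = start
            fam = self.spec.covariance_family
            if fam == "UN_RE_OU" and vc0.ou is None:
                vc0 = VarianceComponents(
                    G=vc0.G, sigma2=0.8 * vc0.sigma2,
                    ou={"C": np.diag(0.2 * np.resize(vc0.sigma2, 2)),
                        "decay": np.array([0.5, 0.5])},
                )
            elif fam == "AR1_VISIT" and vc0.ar1 is None:
                vc0 = VarianceComponents(
                    G=vc0.G, sigma2=0.7 * vc0.sigma2,
                    ar1={"sigma2_w": 0.3 * vc0.sigma2,
                         "rho": np.full(len(self.design.traits), 0.3)},
                )
        else:
            vc0 = _mom_start(self.design)
        theta0 = self.pmap.pack(vc0)

        analytic = self.spec.covariance_family == "UN_RE"
        trace = []

        def objective(theta):
            vc = self.pmap.unpack(theta)
            try:
                res = self.engine.evaluate(vc, need_grad=analytic,
                                           pmap=self.pmap, theta=theta)
            except (DegenerateCovarianceError, InvalidParameterError):
                bad = np.full_like(theta, 0.0)
                return (1e10, bad) if analytic else 1e10
            if verbose:
                trace.append(res.loglik)
                print(f"iter {len(trace):4d}  loglik {res.loglik:.8f}")
            if analytic:
                return -res.loglik, -res.grad
            return -res.loglik

        opt = optimize.minimize(
            objective, theta0, jac=analytic if analytic else None,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol,
                     "maxfun": 50 * maxiter},
        )
        theta_hat = opt.x
        vc_hat = self.pmap.unpack(theta_hat)
        final = self.engine.evaluate(vc_hat)
        cov_beta = np.linalg.inv(final.A)
        cov_beta = 0.5 * (cov_beta + cov_beta.T)
        L = self.pmap.chol(theta_hat)
        boundary = bool(self.design.q and np.any(
            np.diag(L) < 1e-4 * max(np.diag(L).max(), 1e-12)
        ))
        names = self.design.xnames
        return LMMResults(
            model=self,
            params=pd.Series(final.beta, index=names),
            cov_params=pd.DataFrame(cov_beta, index=names, columns=names),
            vc=vc_hat,
            llf=final.loglik,
            n_vc_params=self.pmap.n_params,
            converged=bool(opt.success),
            n_iter=int(opt.nit),
            message=str(opt.message),
            boundary=boundary,
        )


class LMMResults:
    """REML fit results: estimates, uncertainties, diagnostics, tests."""

    def __init__(self, model, params, cov_params, vc, llf, n_vc_params,
                 converged, n_iter, message, boundary):
        self.model = model
        self.params = params
        self.cov_params = cov_params
        self.vc = vc
        self.llf = float(llf)
        self.n_vc_params = int(n_vc_params)
        self.converged = converged
        self.n_iter = n_iter
        self.message = message
        self.boundary = boundary
        self.n_obs = model.design.n_obs
        self.n_subjects = model.design.n_subjects

    # -- basic quantities ---------------------------------------------------

    @property
    def aic(self) -> float:
        """-2 REML loglik + 2 x (free covariance parameters) (REML AIC)."""
        return -2.0 * self.llf + 2.0 * self.n_vc_params

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())),
                         index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Two-sided large-sample (normal) p-values per coefficient."""
        return pd.Series(2 * stats.norm.sf(np.abs(self.tvalues)),
                         index=self.params.index)

    def df2(self, policy: Optional[str] = None) -> int:
        """Denominator df for F tests under the requested policy."""
        return compute_df2(self.model.design, policy)

    # -- SNP tests ----------------------------------------------------------

    def _genotype_names(self):
        names = [n for n in self.params.index if n.endswith(":genotype")]
        if not names:
            raise InvalidParameterError("model has no genotype term")
        return names

    def joint_genotype_test(self, df2: Optional[int] = None,
                            policy: Optional[str] = None) -> JointTestResult:
        """Joint Wald test of the SNP effect on all modelled traits.

        For the bivariate model this is the 2-df test of
        H0: beta_SBP = beta_DBP = 0 reported with both the F(2, df2) and the
        chi-square(2) reference distributions.
        """
        names = self._genotype_names()
        beta_g = self.params[names].to_numpy()
        S = self.cov_params.loc[names, names].to_numpy()
        if df2 is None:
            df2 = self.df2(policy)
        return wald_joint_test(beta_g, S, df2)

    def genotype_test(self, trait: str, df2: Optional[int] = None,
                      policy: Optional[str] = None) -> JointTestResult:
        """1-df Wald test of the SNP effect on one trait."""
        name = f"{trait}:genotype"
        if name not in self.params.index:
            raise InvalidParameterError(f"no genotype coefficient for trait {trait!r}")
        if df2 is None:
            df2 = self.df2(policy)
        return wald_joint_test(
            self.params[[name]].to_numpy(),
            self.cov_params.loc[[name], [name]].to_numpy(),
            df2,
        )

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        kind = "Bivariate" if len(self.model.design.traits) == 2 else "Univariate"
        lines = [
            f"{kind} Linear Mixed Model (REML)",
            "=" * 64,
            f"No. subjects: {self.n_subjects:<8d} No. observations: {self.n_obs}",
            f"Covariance family: {self.model.spec.covariance_family:<12s} "
            f"Converged: {self.converged}",
            f"REML log-likelihood: {self.llf:.4f}    AIC: {self.aic:.4f}",
            "-" * 64,
            f"{'':24s}{'coef':>10s}{'std err':>10s}{'z':>8s}{'P>|z|':>10s}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:24s}{self.params[name]:10.4f}{self.bse[name]:10.4f}"
                f"{self.tvalues[name]:8.2f}{self.pvalues[name]:10.2e}"
            )
        lines.append("-" * 64)
        lines.append("Random-effect covariance G:")
        for row in np.atleast_2d(self.vc.G):
            lines.append("  " + "  ".join(f"{v:10.4f}" for v in row))
        sig = ", ".join(
            f"{t}: {s:.4f}" for t, s in zip(self.model.design.traits, self.vc.sigma2)
        )
        lines.append(f"Residual variances: {sig}")
        if self.vc.ou is not None:
            lines.append(f"OU process C: {np.asarray(self.vc.ou['C']).tolist()}, "
                         f"decay: {np.asarray(self.vc.ou['decay']).tolist()}")
        if self.vc.ar1 is not None:
            lines.append(f"AR(1): sigma2_w={np.asarray(self.vc.ar1['sigma2_w']).tolist()}, "
                         f"rho={np.asarray(self.vc.ar1['rho']).tolist()}")
        if self.boundary:
            lines.append("Note: variance-component estimate at/near boundary.")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict(),
            "cov_params": self.cov_params.to_numpy().tolist(),
            "vc": {
                "G": np.asarray(self.vc.G).tolist(),
                "sigma2": np.asarray(self.vc.sigma2).tolist(),
                "ou": None if self.vc.ou is None else {
                    "C": np.asarray(self.vc.ou["C"]).tolist(),
                    "decay": np.asarray(self.vc.ou["decay"]).tolist(),
                },
                "ar1": None if self.vc.ar1 is None else {
                    "sigma2_w": np.asarray(self.vc.ar1["sigma2_w"]).tolist(),
                    "rho": np.asarray(self.vc.ar1["rho"]).tolist(),
                },
            },
            "reml_loglik": self.llf,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "converged": bool(self.converged),
            "n_iter": self.n_iter,
            "boundary": bool(self.boundary),
        }
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def fit_bivariate(phenotypes, dosages=None, spec=None, **fit_kw) -> LMMResults:
    """Convenience wrapper: build and fit the bivariate model."""
    return BivariateLMM(phenotypes, dosages=dosages, spec=spec).fit(**fit_kw)


def fit_univariate(phenotypes, dosages=None, spec=None, trait="sbp", **fit_kw) -> LMMResults:
    """Fit the univariate special case for a single trait."""
    spec = spec or ModelSpec()
    if trait not in spec.trait_labels:
        raise InvalidParameterError(
            f"trait {trait!r} not in spec.trait_labels {spec.trait_labels}"
        )
    return BivariateLMM(phenotypes, dosages=dosages, spec=spec, traits=(trait,)).fit(**fit_kw)


def compare_aic(fits) -> pd.DataFrame:
    """Rank fits on the same data by ascending AIC.

    Ties (within 1e-10) break toward fewer covariance parameters.  Raises
    :class:`IncomparableModelsError` when the fits' responses differ.
    """
    fits = list(fits)
    if not fits:
        raise InvalidParameterError("no fits to compare")
    fp0 = fits[0].model.design.response_fingerprint()
    for f in fits[1:]:
        if f.model.design.response_fingerprint() != fp0:
            raise IncomparableModelsError(
                "fits use different response rows; AIC not comparable"
            )
    rows = pd.DataFrame(
        {
            "family": [f.model.spec.covariance_family for f in fits],
            "reml_loglik": [f.llf for f in fits],
            "n_vc_params": [f.n_vc_params for f in fits],
            "aic": [f.aic for f in fits],
        }
    )
    rows = rows.sort_values(["aic", "n_vc_params"], kind="stable").reset_index(names="fit_index")
    rows["rank"] = np.arange(1, len(rows) + 1)
    return rows
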