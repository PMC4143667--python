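"""Power and type-I-error simulation: bivariate joint test vs univariate tests.

Replicates the comparison design of the motivating study: many simulated
longitudinal cohorts, each analysed three ways on the same data — the
bivariate model with the 2-df joint SNP test, and the two univariate models
with 1-df tests — with rejection proportions tallied at a nominal and a
genome-wide threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .design import ModelSpec
from .errors import InvalidParameterError
from .model import BivariateLMM, fit_univariate
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["PowerConfig", "PowerReport", "estimate_power", "tabulate_top_pvalues"]

_METHODS = ("bivariate", "univariate_sbp", "univariate_dbp")


@dataclass
class PowerConfig:
    """Replicated-cohort power study configuration.

    Defaults: 200 replicates of the default synthetic cohort (141 subjects,
    3 exams, causal SNP at MAF 0.30 with effects (-1.4951, -2.3810) mmHg),
    evaluated at alpha = 0.05 and the genome-wide 7.2e-8.
    """

    cohort: SimulationConfig = field(default_factory=SimulationConfig)
    n_replicates: int = 200
    alphas: tuple = (0.05, 7.2e-8)
    test_statistic: str = "f"  # headline statistic: "f" or "chi2"
    seed: int = 0
    spec: ModelSpec = field(default_factory=ModelSpec)

    def validate(self):
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        if not all(0 < a < 1 for a in self.alphas):
            raise InvalidParameterError("alphas must lie in (0, 1)")
        if self.test_statistic not in ("f", "chi2"):
            raise InvalidParameterError("test_statistic must be 'f' or 'chi2'")
        self.cohort.validate()


@dataclass
class PowerReport:
    """Per-replicate p-values plus rejection summaries.

    ``replicates`` has one row per simulated data set with F- and
    chi-square-based p-values for each method and per-method convergence
    flags; failed replicates stay in the table but are excluded from the
    rejection denominators of the affected method.
    """

    replicates: pd.DataFrame
    power_table: pd.DataFrame
    share_bivariate_smallest: float
    n_failed: dict
    config: PowerConfig

    def summary(self) -> str:
        lines = ["Power study summary", "=" * 60]
        for _, r in self.power_table.iterrows():
            lines.append(
                f"{r['method']:16s} alpha={r['alpha']:<9.3g} "
                f"power={r['power']:.3f} [{r['ci_low']:.3f}, {r['ci_high']:.3f}] "
                f"({int(r['n_reject'])}/{int(r['n_eval'])})"
            )
        lines.append(
            f"bivariate p smallest in {100 * self.share_bivariate_smallest:.1f}% of replicates"
        )
        failed = {k: v for k, v in self.n_failed.items() if v}
        if failed:
            lines.append(f"failed replicates (excluded from denominators): {failed}")
        return "\n".join(lines)


def _replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)])


def estimate_power(config: PowerConfig, progress: bool = False) -> PowerReport:
    """Run the replicated power (or, with null effects, type-I error) study.

    For each replicate a fresh cohort is simulated, then the bivariate joint
    test and both univariate SNP tests are computed on the same data.  Fully
    reproducible given ``config.seed``.
    """
    config.validate()
    seeds = _replicate_seeds(config.seed, config.n_replicates)
    pcol = "p_f" if config.test_statistic == "f" else "p_chi2"

    rows = []
    for rep in range(config.n_replicates):
        cfg = SimulationConfig.from_dict(config.cohort.to_dict())
        cfg.seed = int(seeds[rep])
        pheno, gm = simulate_cohort(cfg)
        dos = gm.dosage_series(gm.snp_ids[0])
        row = {"replicate": rep + 1, "seed": cfg.seed}
        try:
            fit = BivariateLMM(pheno, dosages=dos, spec=config.spec).fit()
            jt = fit.joint_genotype_test()
            row.update(
                p_f_bivariate=jt.p_f, p_chi2_bivariate=jt.p_chi2,
                converged_bivariate=fit.converged,
            )
        except Exception:
            row.update(p_f_bivariate=np.nan, p_chi2_bivariate=np.nan,
                       converged_bivariate=False)
        for trait, meth in (("sbp", "univariate_sbp"), ("dbp", "univariate_dbp")):
            try:
                ufit = fit_univariate(pheno, dosages=dos, spec=config.spec, trait=trait)
                ut = ufit.genotype_test(trait)
                row.update({f"p_f_{meth}": ut.p_f, f"p_chi2_{meth}": ut.p_chi2,
                            f"converged_{meth}": ufit.converged})
            except Exception:
                row.update({f"p_f_{meth}": np.nan, f"p_chi2_{meth}": np.nan,
                            f"converged_{meth}": False})
        rows.append(row)
        if progress and (rep + 1) % 25 == 0:
            print(f"  replicate {rep + 1}/{config.n_replicates}")
    reps = pd.DataFrame(rows)

    meth_cols = {m: f"{pcol}_{'bivariate' if m == 'bivariate' else m}" for m in _METHODS}
    ok = {m: reps[f"converged_{m}"].to_numpy(bool) & reps[meth_cols[m]].notna().to_numpy()
          for m in _METHODS}
    n_failed = {m: int((~ok[m]).sum()) for m in _METHODS}

    table_rows = []
    for m in _METHODS:
        p = reps.loc[ok[m], meth_cols[m]].to_numpy(float)
        for alpha in config.alphas:
            n_eval = p.size
            n_rej = int((p < alpha).sum())
            lo, hi = proportion_confint(n_rej, n_eval, alpha=0.05, method="wilson") \
                if n_eval else (np.nan, np.nan)
            table_rows.append(
                dict(method=m, alpha=alpha, n_eval=n_eval, n_reject=n_rej,
                     power=n_rej / n_eval if n_eval else np.nan, ci_low=lo, ci_high=hi)
            )
    power_table = pd.DataFrame(table_rows)

    all_ok = ok["bivariate"] & ok["univariate_sbp"] & ok["univariate_dbp"]
    sub = reps.loc[all_ok]
    if len(sub):
        biv = sub[meth_cols["bivariate"]].to_numpy(float)
        u1 = sub[meth_cols["univariate_sbp"]].to_numpy(float)
        u2 = sub[meth_cols["univariate_dbp"]].to_numpy(float)
        share = float(np.mean((biv < u1) & (biv < u2)))
    else:
        share = np.nan

    return PowerReport(
        replicates=reps, power_table=power_table,
        share_bivariate_smallest=share, n_failed=n_failed, config=config,
    )


def tabulate_top_pvalues(report: PowerReport, k: int = 3) -> pd.DataFrame:
    """Per-method top-k replicates by p-value, with the other methods' p's.

    One section per method: the k replicates where that method's p-value was
    smallest, alongside all three methods' p-values in those replicates (the
    classic side-by-side layout).  ``k`` larger than the replicate count is
    truncated with a warning.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    reps = report.replicates
    pcol = "p_f" if report.config.test_statistic == "f" else "p_chi2"
    n = len(reps)
    if k > n:
        import warnings

        warnings.warn(f"k={k} exceeds {n} replicates; truncating")
        k = n
    out = []
    for m in _METHODS:
        col = f"{pcol}_{'bivariate' if m == 'bivariate' else m}"
        top = reps.dropna(subset=[col]).nsmallest(k, col)
        for rank, (_, r) in enumerate(top.iterrows(), start=1):
            out.append(
                dict(
                    method=m, rank=rank, replicate=int(r["replicate"]),
                    p_bivariate=r[f"{pcol}_bivariate"],
                    p_sbp=r[f"{pcol}_univariate_sbp"],
                    p_dbp=r[f"{pcol}_univariate_dbp"],
                )
            )
    return pd.DataFrame(out)
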