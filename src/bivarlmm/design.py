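"""Stacked design construction for the bivariate longitudinal mixed model.

The bivariate model stacks both traits' observations per subject:

    Y_i = X_i beta + Z_i gamma_i + W_i + eps_i

where ``X_i`` is block-structured so every fixed effect gets its own
coefficient per trait (equivalent to interacting each regressor with a
trait-indicator dummy), and ``Z_i`` likewise for the random effects.  Rows
are (visit, trait) pairs restricted to non-missing trait values —
available-case deletion at the row level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import (
    EmptyDesignError,
    InvalidParameterError,
    OverParameterizedDesignError,
)

__all__ = ["ModelSpec", "StackedDesign", "build_design", "compute_df2"]

_FAMILIES = ("UN_RE", "UN_RE_OU", "AR1_VISIT")
_DF_POLICIES = ("containment", "residual")

#: fixed-effect name -> phenotype-table column (None = constructed)
_COVARIATE_SOURCES = {
    "intercept": None,
    "genotype": None,
    "time": "time",
    "baseline_age": "baseline_age",
    "sex": "sex",
    "medication": "medication",
    "smoking": "smoking",
}


@dataclass(frozen=True)
class ModelSpec:
    """Model structure: fixed/random effects, covariance family, df policy.

    ``covariance_family``:

    - ``UN_RE``     unstructured random-effect covariance G plus diagonal
                    trait-specific residuals (the default final model);
    - ``UN_RE_OU``  adds a bivariate Ornstein-Uhlenbeck serial process;
    - ``AR1_VISIT`` adds a per-trait AR(1) serial term on the visit index
                    (equal-interval assumption, kept for AIC comparison).

    ``random_effects_shared=True`` gives both traits one common set of
    random-effect columns per subject (the SAS-style "subject + time" coding
    with a 2-column Z); the default is trait-specific blocks (4-column Z).
    """

    fixed_effects: tuple = (
        "intercept", "genotype", "time", "baseline_age", "medication", "sex", "smoking",
    )
    random_effects: tuple = ("intercept", "time")
    covariance_family: str = "UN_RE"
    df_policy: str = "containment"
    trait_labels: tuple = ("sbp", "dbp")
    cross_trait_random: bool = True
    random_effects_shared: bool = False

    def __post_init__(self):
        if self.covariance_family not in _FAMILIES:
            raise InvalidParameterError(
                f"covariance_family must be one of {_FAMILIES}, got {self.covariance_family!r}"
            )
        if self.df_policy not in _DF_POLICIES:
            raise InvalidParameterError(
                f"df_policy must be one of {_DF_POLICIES}, got {self.df_policy!r}"
            )
        unknown = [f for f in self.fixed_effects if f not in _COVARIATE_SOURCES]
        if unknown:
            raise InvalidParameterError(f"unknown fixed effects: {unknown}")
        not_fixed = [r for r in self.random_effects if r not in self.fixed_effects]
        if not_fixed:
            raise InvalidParameterError(
                f"random_effects must be a subset of fixed_effects; extra: {not_fixed}"
            )
        if not 1 <= len(self.trait_labels) <= 2:
            raise InvalidParameterError("trait_labels must name one or two traits")


@dataclass
class DesignGroup:
    """Batch of subjects sharing a common per-subject row count.

    Arrays are stacked along axis 0 (one slice per subject): ``Y (b, n)``,
    ``X (b, n, p)``, ``Z (b, n, q)``, integer ``trait`` codes, ``time`` in
    years, and 1-based ``visit`` indices.
    """

    Y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    trait: np.ndarray
    time: np.ndarray
    visit: np.ndarray
    subject_ids: list

    @property
    def n_subjects(self) -> int:
        return self.Y.shape[0]

    @property
    def n_rows(self) -> int:
        return self.Y.shape[1]


@dataclass
class StackedDesign:
    """Per-subject stacked design blocks grouped by shape for batched algebra."""

    groups: list
    xnames: list
    traits: tuple
    spec: ModelSpec
    q_per_trait: int
    dropped: dict = field(default_factory=dict)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def p(self) -> int:
        return len(self.xnames)

    @property
    def q(self) -> int:
        return self.groups[0].Z.shape[2] if self.groups else 0

    @property
    def n_obs(self) -> int:
        return sum(g.Y.size for g in self.groups)

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups)

    @property
    def subject_ids(self) -> list:
        out = []
        for g in self.groups:
            out.extend(g.subject_ids)
        return out

    def stacked_x(self) -> np.ndarray:
        return np.concatenate([g.X.reshape(-1, self.p) for g in self.groups], axis=0)

    def stacked_y(self) -> np.ndarray:
        return np.concatenate([g.Y.reshape(-1) for g in self.groups])

    def rank_x(self) -> int:
        return int(np.linalg.matrix_rank(self.stacked_x()))

    def rank_z_total(self) -> int:
        """Sum of per-subject random-effect design ranks (block-diagonal Z)."""
        if self.q == 0:
            return 0
        total = 0
        for g in self.groups:
            total += int(np.sum(np.linalg.matrix_rank(g.Z)))
        return total

    def response_fingerprint(self) -> tuple:
        y = self.stacked_y()
        return (y.size, float(np.round(y.sum(), 6)), float(np.round((y**2).sum(), 4)))


def build_design(
    phenotypes: pd.DataFrame,
    dosages: Optional[pd.Series] = None,
    spec: Optional[ModelSpec] = None,
    traits: Optional[tuple] = None,
) -> StackedDesign:
    """Assemble per-subject stacked (Y, X, Z) blocks.

    Parameters
    ----------
    phenotypes : long-format phenotype table (see ``data.PHENOTYPE_COLUMNS``).
    dosages : Series of additive dosages indexed by subject_id, or a mapping;
        ``None`` drops the genotype term from the fixed effects (null model).
    spec : ModelSpec, defaults to ``ModelSpec()``.
    traits : override ``spec.trait_labels`` (e.g. a single trait for a
        univariate fit).

    Subjects with a missing dosage, or with no usable (visit, trait) row
    after removing rows with missing trait values or covariates, are dropped
    and counted in ``design.dropped``.
    """
    spec = spec or ModelSpec()
    traits = tuple(traits) if traits is not None else tuple(spec.trait_labels)
    for t in traits:
        if t not in spec.trait_labels:
            raise InvalidParameterError(
                f"trait {t!r} not in spec.trait_labels {spec.trait_labels}"
            )
    n_traits = len(traits)

    fixed = list(spec.fixed_effects)
    if dosages is None and "genotype" in fixed:
        fixed.remove("genotype")
    if dosages is not None and not isinstance(dosages, pd.Series):
        dosages = pd.Series(dict(dosages))

    shared = spec.random_effects_shared
    rand = list(spec.random_effects)
    q_per_trait = len(rand)
    q = q_per_trait if shared or q_per_trait == 0 else q_per_trait * n_traits
    p_per_trait = len(fixed)
    p = p_per_trait * n_traits
    xnames = [f"{t}:{f}" for t in traits for f in fixed]

    cov_cols = sorted({c for f in fixed if (c := _COVARIATE_SOURCES[f]) is not None})

    dropped = {"missing_dosage": 0, "no_usable_rows": 0, "rows_removed": 0}

    ph = phenotypes.sort_values(["subject_id", "exam"], kind="stable").reset_index(drop=True)
    sid_all = ph["subject_id"].to_numpy()
    if dosages is not None:
        dval_all = ph["subject_id"].map(dosages).to_numpy(float)
        subj_missing = ph.loc[np.isnan(dval_all), "subject_id"].unique()
        dropped["missing_dosage"] = len(subj_missing)
        keep = ~np.isnan(dval_all)
        ph, dval_all, sid_all = ph[keep].reset_index(drop=True), dval_all[keep], sid_all[keep]
        if len(ph) == 0:
            raise EmptyDesignError("no usable subjects after assembling the design")
    else:
        dval_all = np.zeros(len(ph))

    cov_ok = (
        ~ph[cov_cols].isna().any(axis=1).to_numpy() if cov_cols else np.ones(len(ph), bool)
    )

    # Base per-visit covariate values, one column per fixed effect.
    base = np.empty((len(ph), p_per_trait))
    for jf, f in enumerate(fixed):
        if f == "intercept":
            base[:, jf] = 1.0
        elif f == "genotype":
            base[:, jf] = dval_all
        else:
            base[:, jf] = ph[_COVARIATE_SOURCES[f]].to_numpy(float)

    zbase = np.empty((len(ph), q_per_trait))
    for jr, r in enumerate(rand):
        if r == "intercept":
            zbase[:, jr] = 1.0
        elif r == "genotype":
            zbase[:, jr] = dval_all
        else:
            zbase[:, jr] = ph[_COVARIATE_SOURCES[r]].to_numpy(float)

    # Expand to (visit, trait) rows, trait-major within subject.
    parts = []
    for k, trait in enumerate(traits):
        vals = ph[trait].to_numpy(float)
        usable = cov_ok & ~np.isnan(vals)
        dropped["rows_removed"] += int((~usable).sum())
        idx = np.flatnonzero(usable)
        X_k = np.zeros((idx.size, p))
        X_k[:, k * p_per_trait : (k + 1) * p_per_trait] = base[idx]
        Z_k = np.zeros((idx.size, q))
        if q_per_trait:
            col0 = 0 if shared else k * q_per_trait
            Z_k[:, col0 : col0 + q_per_trait] = zbase[idx]
        parts.append(
            dict(
                sid=sid_all[idx], order=idx, trait=np.full(idx.size, k),
                y=vals[idx], X=X_k, Z=Z_k,
                time=ph["time"].to_numpy(float)[idx],
                visit=ph["exam"].to_numpy(float)[idx],
            )
        )

    sid_rows = np.concatenate([pt["sid"] for pt in parts])
    trait_rows = np.concatenate([pt["trait"] for pt in parts])
    order_rows = np.concatenate([pt["order"] for pt in parts])
    y_rows = np.concatenate([pt["y"] for pt in parts])
    X_rows = np.concatenate([pt["X"] for pt in parts])
    Z_rows = np.concatenate([pt["Z"] for pt in parts])
    t_rows = np.concatenate([pt["time"] for pt in parts])
    v_rows = np.concatenate([pt["visit"] for pt in parts])
    if y_rows.size == 0:
        raise EmptyDesignError("no usable subjects after assembling the design")

    # Sort rows subject-major, trait-major, visit order within trait.
    sorter = np.lexsort((order_rows, trait_rows, sid_rows))
    sid_rows, trait_rows = sid_rows[sorter], trait_rows[sorter]
    y_rows, X_rows, Z_rows = y_rows[sorter], X_rows[sorter], Z_rows[sorter]
    t_rows, v_rows = t_rows[sorter], v_rows[sorter]

    uniq, starts, counts = np.unique(sid_rows, return_index=True, return_counts=True)
    n_pheno_subjects = phenotypes["subject_id"].nunique()
    dropped["no_usable_rows"] = int(
        n_pheno_subjects - dropped["missing_dosage"] - uniq.size
    )

    by_shape: dict = {}
    for sid, s0, cnt in zip(uniq, starts, counts):
        sl = slice(s0, s0 + cnt)
        by_shape.setdefault(cnt, []).append(
            (sid, y_rows[sl], X_rows[sl], Z_rows[sl], trait_rows[sl], t_rows[sl], v_rows[sl])
        )

    groups = []
    for n_rows in sorted(by_shape):
        entries = by_shape[n_rows]
        groups.append(
            DesignGroup(
                Y=np.stack([e[1] for e in entries]),
                X=np.stack([e[2] for e in entries]),
                Z=np.stack([e[3] for e in entries]),
                trait=np.stack([e[4] for e in entries]),
                time=np.stack([e[5] for e in entries]),
                visit=np.stack([e[6] for e in entries]),
                subject_ids=[e[0] for e in entries],
            )
        )
    return StackedDesign(
        groups=groups, xnames=xnames, traits=traits, spec=spec,
        q_per_trait=q_per_trait, dropped=dropped,
    )


def compute_df2(design: StackedDesign, policy: Optional[str] = None) -> int:
    """Denominator degrees of freedom for the joint F test.

    ``residual``    : N_obs - rank(X)
    ``containment`` : N_obs - rank(X) - sum_i rank(Z_i)

    On the complete two-trait, three-exam design with a 2-column shared Z per
    subject this yields ``N - p - 2*n_subjects`` (e.g. 846 - 12 - 282 = 552
    for 141 subjects and a 12-column X).
    """
    policy = policy or design.spec.df_policy
    if policy not in _DF_POLICIES:
        raise InvalidParameterError(f"unknown df policy {policy!r}")
    df2 = design.n_obs - design.rank_x()
    if policy == "containment":
        df2 -= design.rank_z_total()
    if df2 <= 0:
        raise OverParameterizedDesignError(
            f"df2 = {df2} <= 0 under policy {policy!r}; design over-parameterized"
        )
    return int(df2)
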