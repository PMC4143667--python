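"""Restricted maximum likelihood machinery for the stacked mixed model.

Marginally, each subject's stacked response is multivariate normal,

    Y_i ~ N(X_i beta,  V_i),    V_i = Z_i G Z_i' + R_i + Sigma_i,

with ``G`` the (unstructured) random-effect covariance shared across
subjects, ``R_i`` an optional serial-process covariance (bivariate
Ornstein-Uhlenbeck in continuous time, or per-trait AR(1) on the visit
index), and ``Sigma_i`` diagonal with trait-specific residual variances.
The REML log-likelihood used throughout (constant convention fixed here) is

    l_R = -1/2 [ (N - p) log 2*pi + sum_i log|V_i|
                 + log|sum_i X_i' V_i^-1 X_i| + sum_i r_i' V_i^-1 r_i ]

with ``r_i`` the GLS residuals at the profiled beta-hat.  Variance
parameters are optimized on an unconstrained scale: log-Cholesky for G and
the OU stationary covariance C, log for residual variances and OU decay
rates, atanh for AR(1) correlations.  Analytic gradients are implemented for
the UN_RE family; the serial families fall back to finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .design import StackedDesign
from .errors import (
    DegenerateCovarianceError,
    InvalidParameterError,
    RankDeficiencyError,
)

__all__ = ["VarianceComponents", "ou_covariance", "marginal_covariance", "REMLEngine"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class VarianceComponents:
    """Variance parameters of the stacked model.

    ``G`` is q x q symmetric PSD (for the default bivariate model, 4 x 4 in
    the order sbp-intercept, sbp-slope, dbp-intercept, dbp-slope);
    ``sigma2`` holds one residual variance per trait.  ``ou`` is
    ``{"C": 2x2 PSD, "decay": (lam1, lam2)}``; ``ar1`` is
    ``{"sigma2_w": per-trait variances, "rho": per-trait correlations}``.
    """

    G: np.ndarray
    sigma2: np.ndarray
    ou: Optional[dict] = None
    ar1: Optional[dict] = None

    def __post_init__(self):
        self.G = np.atleast_2d(np.asarray(self.G, float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, float))
        if self.G.size and not np.allclose(self.G, self.G.T, atol=1e-10):
            raise InvalidParameterError("G must be symmetric")
        if self.G.size and np.linalg.eigvalsh(self.G).min() < -1e-8 * max(1.0, np.abs(self.G).max()):
            raise InvalidParameterError("G is not positive semidefinite")
        if np.any(self.sigma2 <= 0):
            raise InvalidParameterError("residual variances must be > 0")
        if self.ou is not None:
            C = np.asarray(self.ou["C"], float)
            if not np.allclose(C, C.T, atol=1e-10):
                raise InvalidParameterError("OU C must be symmetric")
            if np.linalg.eigvalsh(C).min() < -1e-8 * max(1.0, np.abs(C).max()):
                raise InvalidParameterError("OU C is not positive semidefinite")
            if np.any(np.asarray(self.ou["decay"], float) <= 0):
                raise InvalidParameterError("OU decay rates must be > 0")
        if self.ar1 is not None:
            if np.any(np.abs(np.asarray(self.ar1["rho"], float)) >= 1):
                raise InvalidParameterError("AR(1) correlations must satisfy |rho| < 1")
            if np.any(np.asarray(self.ar1["sigma2_w"], float) < 0):
                raise InvalidParameterError("AR(1) variances must be >= 0")

    @property
    def n_free(self) -> int:
        """Number of free covariance parameters (for information criteria)."""
        q = self.G.shape[0] if self.G.size else 0
        k = q * (q + 1) // 2 + self.sigma2.size
        if self.ou is not None:
            k += 3 + 2
        if self.ar1 is not None:
            k += 2 * len(np.atleast_1d(self.ar1["rho"]))
        return k


def ou_covariance(C, decay, s: float, t: float) -> np.ndarray:
    """Cross-covariance block of the bivariate OU process at times s <= t.

    Diagonal entries decay as ``exp(-lam_k (t - s))``; the cross-trait entry
    decays at the average rate ``(lam1 + lam2)/2`` (symmetrized restriction
    of the general matrix-exponential form).  At ``s == t`` the stationary
    covariance ``C`` is returned exactly.
    """
    C = np.asarray(C, float)
    lam = np.asarray(decay, float)
    if C.shape != (2, 2) or not np.allclose(C, C.T, atol=1e-10):
        raise InvalidParameterError("C must be symmetric 2x2")
    if np.linalg.eigvalsh(C).min() < -1e-10 * max(1.0, np.abs(C).max()):
        raise InvalidParameterError("C is not positive semidefinite")
    if np.any(lam <= 0):
        raise InvalidParameterError("decay rates must be > 0")
    if not 0 <= s <= t:
        raise InvalidParameterError("times must satisfy 0 <= s <= t")
    lam_bar = 0.5 * (lam[:, None] + lam[None, :])
    return C * np.exp(-lam_bar * (t - s))


def _serial_matrix(vc: VarianceComponents, trait, time, visit):
    """Serial-process covariance for one subject's stacked rows (n x n)."""
    tr = np.asarray(trait, int)
    if vc.ou is not None:
        C = np.asarray(vc.ou["C"], float)
        lam = np.asarray(vc.ou["decay"], float)
        dt = np.abs(time[:, None] - time[None, :])
        lam_bar = 0.5 * (lam[tr][:, None] + lam[tr][None, :])
        return C[tr[:, None], tr[None, :]] * np.exp(-lam_bar * dt)
    if vc.ar1 is not None:
        s2 = np.atleast_1d(np.asarray(vc.ar1["sigma2_w"], float))
        rho = np.atleast_1d(np.asarray(vc.ar1["rho"], float))
        dv = np.abs(visit[:, None] - visit[None, :])
        same = tr[:, None] == tr[None, :]
        return np.where(same, s2[tr][:, None] * rho[tr][:, None] ** dv, 0.0)
    return 0.0


def marginal_covariance(vc: VarianceComponents, Z, time, trait, visit=None) -> np.ndarray:
    """Marginal covariance V_i = Z_i G Z_i' + R_i + Sigma_i for one subject.

    ``trait`` holds integer trait codes per stacked row.  Raises
    :class:`DegenerateCovarianceError` if the result is not positive
    definite.
    """
    trait = np.asarray(trait, int)
    time = np.asarray(time, float)
    if visit is None:
        visit = np.zeros_like(time)
    Z = np.asarray(Z, float)
    n = len(trait)
    V = np.zeros((n, n))
    if Z.size and vc.G.size:
        V += Z @ vc.G @ Z.T
    V += np.asarray(_serial_matrix(vc, trait, time, visit))
    V[np.diag_indices(n)] += vc.sigma2[trait]
    try:
        np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        raise DegenerateCovarianceError(
            "marginal covariance not positive definite (check G / serial / residual"
            " variance settings)"
        )
    return V


# ---------------------------------------------------------------------------
# Unconstrained parameterization


class ParamMap:
    """Maps VarianceComponents <-> an unconstrained parameter vector.

    G (and OU C) use a log-Cholesky parameterization: lower-triangular
    factors stored row-major with log-transformed diagonals.  When
    ``cross_trait_random`` is off, the Cholesky entries linking the two
    traits' random-effect blocks (and the OU cross term) are fixed at zero
    and excluded from the vector, which constrains G to block-diagonal.
    """

    def __init__(self, q: int, n_traits: int, family: str = "UN_RE",
                 cross_trait_random: bool = True, q_per_trait: Optional[int] = None,
                 shared: bool = False):
        self.q, self.n_traits, self.family = q, n_traits, family
        self.shared = shared
        qpt = q_per_trait if q_per_trait is not None else (q // max(n_traits, 1) or q)
        self.chol_idx = []
        for i in range(q):
            for j in range(i + 1):
                if (not cross_trait_random and not shared and n_traits > 1
                        and i // qpt != j // qpt):
                    continue  # cross-trait block fixed at zero
                self.chol_idx.append((i, j))
        self.cross_trait_random = cross_trait_random
        self.n_g = len(self.chol_idx)
        self.n_sigma = n_traits
        self.n_serial = 0
        if family == "UN_RE_OU":
            self.ou_idx = [(0, 0)] + ([(1, 0), (1, 1)] if cross_trait_random and n_traits == 2
                                      else ([(1, 1)] if n_traits == 2 else []))
            self.n_serial = len(self.ou_idx) + n_traits  # C chol + log decay
        elif family == "AR1_VISIT":
            self.n_serial = 2 * n_traits  # log sigma2_w + atanh rho per trait

    @property
    def n_params(self) -> int:
        return self.n_g + self.n_sigma + self.n_serial

    def pack(self, vc: VarianceComponents) -> np.ndarray:
        theta = np.empty(self.n_params)
        if self.q:
            G = np.asarray(vc.G, float)
            try:
                L = np.linalg.cholesky(G)
            except np.linalg.LinAlgError:
                # lift tiny/zero eigenvalues so the Cholesky factor exists
                w, U = np.linalg.eigh(G)
                floor = 1e-8 * max(1.0, w.max() if w.size else 1.0)
                L = np.linalg.cholesky(U @ np.diag(np.maximum(w, floor)) @ U.T)
            L = np.where(np.abs(L) < 1e-300, 1e-300, L)  # log of exact zeros
        pos = 0
        for i, j in self.chol_idx:
            theta[pos] = np.log(L[i, j]) if i == j else L[i, j]
            pos += 1
        theta[pos : pos + self.n_sigma] = np.log(vc.sigma2)
        pos += self.n_sigma
        if self.family == "UN_RE_OU":
            C = np.asarray(vc.ou["C"], float)
            w, U = np.linalg.eigh(C)
            floor = 1e-8 * max(1.0, w.max())
            Lc = np.linalg.cholesky(U @ np.diag(np.maximum(w, floor)) @ U.T)
            for i, j in self.ou_idx:
                theta[pos] = np.log(Lc[i, j]) if i == j else Lc[i, j]
                pos += 1
            theta[pos : pos + self.n_traits] = np.log(
                np.atleast_1d(np.asarray(vc.ou["decay"], float))[: self.n_traits]
            )
            pos += self.n_traits
        elif self.family == "AR1_VISIT":
            theta[pos : pos + self.n_traits] = np.log(
                np.maximum(np.atleast_1d(vc.ar1["sigma2_w"])[: self.n_traits], 1e-10)
            )
            pos += self.n_traits
            theta[pos : pos + self.n_traits] = np.arctanh(
                np.clip(np.atleast_1d(vc.ar1["rho"])[: self.n_traits], -0.999, 0.999)
            )
            pos += self.n_traits
        return theta

    def chol(self, theta: np.ndarray) -> np.ndarray:
        L = np.zeros((self.q, self.q))
        for pos, (i, j) in enumerate(self.chol_idx):
            L[i, j] = np.exp(theta[pos]) if i == j else theta[pos]
        return L

    def unpack(self, theta: np.ndarray) -> VarianceComponents:
        L = self.chol(theta)
        G = L @ L.T
        pos = self.n_g
        sigma2 = np.exp(theta[pos : pos + self.n_sigma])
        pos += self.n_sigma
        ou = ar1 = None
        if self.family == "UN_RE_OU":
            Lc = np.zeros((2, 2))
            for i, j in self.ou_idx:
                Lc[i, j] = np.exp(theta[pos]) if i == j else theta[pos]
                pos += 1
            if self.n_traits == 1:
                Lc[1, 1] = Lc[0, 0]
            decay = np.exp(theta[pos : pos + self.n_traits])
            pos += self.n_traits
            if self.n_traits == 1:
                decay = np.repeat(decay, 2)
            ou = {"C": Lc @ Lc.T, "decay": decay}
        elif self.family == "AR1_VISIT":
            s2w = np.exp(theta[pos : pos + self.n_traits])
            pos += self.n_traits
            rho = np.clip(np.tanh(theta[pos : pos + self.n_traits]),
                          -1 + 1e-10, 1 - 1e-10)
            pos += self.n_traits
            ar1 = {"sigma2_w": s2w, "rho": rho}
        return VarianceComponents(G=G, sigma2=sigma2, ou=ou, ar1=ar1)


# ---------------------------------------------------------------------------
# Batched likelihood evaluation


@dataclass
class _EvalResult:
    loglik: float
    beta: np.ndarray
    A: np.ndarray  # sum_i X_i' V_i^-1 X_i
    grad: Optional[np.ndarray] = None
    extras: dict = field(default_factory=dict)


class REMLEngine:
    """Batched REML log-likelihood (and gradient) over a StackedDesign."""

    def __init__(self, design: StackedDesign):
        self.design = design
        self.p = design.p
        self.q = design.q
        self.n_obs = design.n_obs
        self.family = design.spec.covariance_family
        # Precompute per-group geometry for serial families.
        self._dt = []
        self._dv = []
        self._trpair = []
        for g in design.groups:
            self._dt.append(np.abs(g.time[:, :, None] - g.time[:, None, :]))
            self._dv.append(np.abs(g.visit[:, :, None] - g.visit[:, None, :]))
            self._trpair.append((g.trait[:, :, None], g.trait[:, None, :]))

    # -- covariance assembly -------------------------------------------------

    def _build_v(self, vc: VarianceComponents, gi: int) -> np.ndarray:
        g = self.design.groups[gi]
        b, n = g.Y.shape
        V = np.zeros((b, n, n))
        if self.q:
            V += np.einsum("bik,kl,bjl->bij", g.Z, vc.G, g.Z, optimize=True)
        if vc.ou is not None:
            C = np.asarray(vc.ou["C"], float)
            lam = np.asarray(vc.ou["decay"], float)
            ti, tj = self._trpair[gi]
            lam_bar = 0.5 * (lam[ti] + lam[tj])
            V += C[ti, tj] * np.exp(-lam_bar * self._dt[gi])
        elif vc.ar1 is not None:
            s2 = np.atleast_1d(np.asarray(vc.ar1["sigma2_w"], float))
            rho = np.atleast_1d(np.asarray(vc.ar1["rho"], float))
            ti, tj = self._trpair[gi]
            same = ti == tj
            V += np.where(same, s2[ti] * np.abs(rho[ti]) ** self._dv[gi]
                          * np.sign(rho[ti]) ** self._dv[gi], 0.0)
        idx = np.arange(n)
        V[:, idx, idx] += vc.sigma2[g.trait]
        return V

    # -- likelihood ----------------------------------------------------------

    def evaluate(self, vc: VarianceComponents, need_grad: bool = False,
                 pmap: Optional[ParamMap] = None, theta: Optional[np.ndarray] = None) -> _EvalResult:
        p = self.p
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        logdet_v = 0.0
        cache = []
        for gi, g in enumerate(self.design.groups):
            V = self._build_v(vc, gi)
            try:
                cho = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                raise DegenerateCovarianceError(
                    "marginal covariance not positive definite during REML evaluation"
                )
            logdet_v += 2.0 * float(np.log(np.diagonal(cho, axis1=1, axis2=2)).sum())
            Vinv_X = np.linalg.solve(V, g.X)
            Vinv_y = np.linalg.solve(V, g.Y[..., None])[..., 0]
            A += np.einsum("bnp,bnr->pr", g.X, Vinv_X)
            bvec += np.einsum("bnp,bn->p", g.X, Vinv_y)
            cache.append((V, Vinv_X))
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0 or not np.isfinite(logdet_a):
            svals = np.linalg.svd(A, compute_uv=False)
            aliased = [self.design.xnames[i] for i in range(p)
                       if svals[min(i, len(svals) - 1)] < 1e-10 * svals[0]]
            raise RankDeficiencyError(
                "fixed-effect cross-product singular (collinear design)", aliased=aliased
            )
        beta = np.linalg.solve(A, bvec)
        qform = 0.0
        us = []
        for gi, g in enumerate(self.design.groups):
            V, _ = cache[gi]
            r = g.Y - np.einsum("bnp,p->bn", g.X, beta)
            u = np.linalg.solve(V, r[..., None])[..., 0]
            qform += float(np.sum(r * u))
            us.append(u)
        ll = -0.5 * (logdet_v + logdet_a + qform + (self.n_obs - p) * _LOG_2PI)
        res = _EvalResult(loglik=ll, beta=beta, A=A)
        if not need_grad:
            return res

        if self.family != "UN_RE":
            raise NotImplementedError("analytic gradient only for the UN_RE family")
        assert pmap is not None and theta is not None
        L = pmap.chol(theta)
        q = self.q
        n_traits = len(self.design.traits)
        M_tot = np.zeros((q, q))
        W_tot = np.zeros((q, q))
        C2 = np.zeros((q, q))
        t1_sig = np.zeros(n_traits)
        t3_sig = np.zeros(n_traits)
        F_sig = [np.zeros((p, p)) for _ in range(n_traits)]
        for gi, g in enumerate(self.design.groups):
            V, Vinv_X = cache[gi]
            u = us[gi]
            Vinv = np.linalg.inv(V)
            if q:
                Vinv_Z = np.linalg.solve(V, g.Z)
                M_tot += np.einsum("bnq,bnr->qr", g.Z, Vinv_Z)
                K = np.einsum("bnp,bnq->bpq", Vinv_X, g.Z)  # X' V^-1 Z
                AinvK = np.linalg.solve(A[None, :, :], K)
                C2 += np.einsum("bpq,bpr->qr", K, AinvK)
                w = np.einsum("bnq,bn->bq", g.Z, u)
                W_tot += np.einsum("bq,br->qr", w, w)
            diagV = np.diagonal(Vinv, axis1=1, axis2=2)
            for k in range(n_traits):
                mask = (g.trait == k)
                t1_sig[k] += float(diagV[mask].sum())
                t3_sig[k] += float((u[mask] ** 2).sum())
                Em = Vinv_X * mask[..., None]
                F_sig[k] += np.einsum("bnp,bnr->pr", Em, Vinv_X)
        grad = np.zeros(pmap.n_params)
        if q:
            S = -0.5 * (M_tot - C2 - W_tot)
            dL = 2.0 * (S @ L)
            for pos, (i, j) in enumerate(pmap.chol_idx):
                grad[pos] = dL[i, j] * (L[i, j] if i == j else 1.0)
        for k in range(n_traits):
            t2 = float(np.trace(np.linalg.solve(A, F_sig[k])))
            dldsig = -0.5 * (t1_sig[k] - t2 - t3_sig[k])
            grad[pmap.n_g + k] = dldsig * vc.sigma2[k]
        res.grad = grad
        return res

    def loglik(self, vc: VarianceComponents) -> float:
        return self.evaluate(vc).loglik
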