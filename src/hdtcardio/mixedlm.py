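"""Random-intercept linear mixed models with REML and Satterthwaite contrasts.

The inference layer needs exactly one model class: a Gaussian linear model
with categorical fixed effects and a random intercept per subject,

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, s2_u),  e_ij ~ N(0, s2_e).

With subjects as independent blocks the marginal covariance is block
diagonal, V_i = s2_e I + s2_u J, and everything — the REML log-likelihood,
its gradient, the GLS fixed effects and the Fisher information of the
variance components — has closed form via the Sherman-Morrison identity.
That keeps a single fit at a fraction of a millisecond, which matters for the
Monte-Carlo calibration checks, and makes the Satterthwaite denominator
degrees of freedom exact at the optimum:

    df(c) = 2 [c' C c]^2 / Var(c' C c),   C = (X' V^-1 X)^-1,

with Var obtained from the analytic gradient of c'Cc with respect to
(s2_u, s2_e) and the inverse REML Fisher information.  Multi-row Wald tests
combine per-eigencontrast Satterthwaite df the way lmerTest does.

When the subject variance is estimated at the boundary (s2_u = 0) the fit
falls back to ordinary least squares with classical residual df; the result
is flagged so callers can report it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DesignError, EstimationError

_BOUNDARY_TOL = 1e-8


@dataclass
class ContrastTest:
    name: str
    estimate: float
    se: float
    df: float
    t: float
    p: float
    null_value: float = 0.0

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        q = stats.t.ppf(0.5 + level / 2, self.df)
        return self.estimate - q * self.se, self.estimate + q * self.se


@dataclass
class WaldTest:
    name: str
    f: float
    ndf: int
    ddf: float
    p: float


@dataclass
class MixedFit:
    """REML fit of a random-intercept model (see module docstring)."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_subject: float
    sigma2_resid: float
    loglik: float
    theta_cov: np.ndarray | None  # covariance of (s2_u, s2_e); None at boundary
    boundary: bool
    fe_names: list[str]
    n_obs: int
    n_groups: int
    # internals needed for Satterthwaite
    _X: np.ndarray = None
    _group_sizes: np.ndarray = None
    _group_starts: np.ndarray = None
    _y: np.ndarray = None

    @property
    def fitted(self) -> np.ndarray:
        return self._X @ self.beta

    @property
    def resid(self) -> np.ndarray:
        return self._y - self.fitted

    # -- Satterthwaite machinery --------------------------------------------
    def _phi_grad(self, c: np.ndarray) -> tuple[float, np.ndarray]:
        """phi = c'Cc and its analytic gradient wrt (s2_u, s2_e)."""
        c = np.asarray(c, dtype=float)
        phi = float(c @ self.cov_beta @ c)
        s2u, s2e = self.sigma2_subject, self.sigma2_resid
        a = s2e + self._group_sizes * s2u
        w = s2u / a
        # u = V^-1 X C c, built per group via Sherman-Morrison
        Xc = self._X @ (self.cov_beta @ c)
        u = np.empty_like(Xc)
        gsum = np.add.reduceat(Xc, self._group_starts)
        for g, (st, n) in enumerate(zip(self._group_starts, self._group_sizes)):
            u[st : st + n] = (Xc[st : st + n] - w[g] * gsum[g]) / s2e
        usum = np.add.reduceat(u, self._group_starts)
        grad = np.array([float(usum @ usum), float(u @ u)])
        return phi, grad

    def contrast(
        self, c: np.ndarray, null_value: float = 0.0, name: str = ""
    ) -> ContrastTest:
        """Single-df contrast c'beta tested against ``null_value`` with
        Satterthwaite denominator degrees of freedom (two-sided p)."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        phi, grad = self._phi_grad(c)
        se = float(np.sqrt(phi))
        if self.boundary or self.theta_cov is None:
            df = float(self.n_obs - len(self.beta))
        else:
            var_phi = float(grad @ self.theta_cov @ grad)
            df = 2 * phi**2 / var_phi if var_phi > 0 else float(self.n_obs - len(self.beta))
            df = float(np.clip(df, 1.0, self.n_obs - 1))
        t = (est - null_value) / se
        p = float(2 * stats.t.sf(abs(t), df))
        return ContrastTest(name=name, estimate=est, se=se, df=df, t=t, p=p, null_value=null_value)

    def wald(self, L: np.ndarray, name: str = "") -> WaldTest:
        """Multi-row Wald F test of L beta = 0 with Satterthwaite df combined
        over the eigencontrasts of L C L'."""
        L = np.atleast_2d(np.asarray(L, dtype=float))
        M = L @ self.cov_beta @ L.T
        q = L.shape[0]
        d, U = np.linalg.eigh(M)
        keep = d > 1e-12 * d.max()
        d, U = d[keep], U[:, keep]
        q_eff = int(keep.sum())
        t2 = ((U.T @ (L @ self.beta)) ** 2) / d
        f = float(t2.sum() / q_eff)
        if self.boundary or self.theta_cov is None:
            ddf = float(self.n_obs - len(self.beta))
        else:
            nus = []
            for j in range(q_eff):
                cj = L.T @ U[:, j]
                phi, grad = self._phi_grad(cj)
                var_phi = float(grad @ self.theta_cov @ grad)
                nu = 2 * phi**2 / var_phi if var_phi > 0 else self.n_obs - len(self.beta)
                nus.append(float(np.clip(nu, 1.0 + 1e-6, self.n_obs - 1)))
            E = sum(nu / (nu - 2) for nu in nus if nu > 2)
            ddf = 2 * E / (E - q_eff) if E > q_eff else min(nus)
        p = float(stats.f.sf(f, q_eff, ddf))
        return WaldTest(name=name, f=f, ndf=q_eff, ddf=ddf, p=p)


def _reml_negloglik_grad(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    sizes: np.ndarray,
    starts: np.ndarray,
    S: np.ndarray,
    u_sums: np.ndarray,
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
) -> tuple[float, np.ndarray]:
    s2u, s2e = theta
    n_obs, p = X.shape
    a = s2e + sizes * s2u
    w = s2u / a
    XtViX = (XtX - (S.T * w) @ S) / s2e
    XtViy = (Xty - S.T @ (w * u_sums)) / s2e
    yViy = (yty - float(w @ u_sums**2)) / s2e
    try:
        cho = np.linalg.cholesky(XtViX)
    except np.linalg.LinAlgError as exc:
        raise DesignError("singular fixed-effect design") from exc
    beta = np.linalg.solve(XtViX, XtViy)
    quad = yViy - float(beta @ XtViy)
    logdet_V = float(np.sum((sizes - 1) * np.log(s2e) + np.log(a)))
    logdet_XtViX = 2 * float(np.sum(np.log(np.diag(cho))))
    nll = 0.5 * ((n_obs - p) * np.log(2 * np.pi) + logdet_V + logdet_XtViX + quad)
    # gradient: dl/dtheta_k = -0.5 tr(P V_k) + 0.5 (Py)' V_k (Py)
    C = np.linalg.inv(XtViX)
    r = y - X @ beta
    rsum = np.add.reduceat(r, starts)
    e = np.empty_like(r)
    for g, (st, n) in enumerate(zip(starts, sizes)):
        e[st : st + n] = (r[st : st + n] - w[g] * rsum[g]) / s2e
    esum = np.add.reduceat(e, starts)
    # trace terms
    tr_Vi_Z = float(np.sum(sizes / a))
    tr_Vi = float(np.sum(sizes * (s2e + (sizes - 1) * s2u) / (s2e * a)))
    # X'V^-1 ZZ' V^-1 X = sum_i s_i s_i' / a_i^2
    M1 = (S.T / a**2) @ S
    c2 = s2u * (2 * a - sizes * s2u) / a**2
    M2 = (XtX - (S.T * c2) @ S) / s2e**2
    tr_P_Z = tr_Vi_Z - float(np.sum(C * M1))
    tr_P_I = tr_Vi - float(np.sum(C * M2))
    g_u = -0.5 * tr_P_Z + 0.5 * float(esum @ esum)
    g_e = -0.5 * tr_P_I + 0.5 * float(e @ e)
    return nll, -np.array([g_u, g_e])


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    fe_names: list[str] | None = None,
) -> MixedFit:
    """REML fit of ``y = X beta + (1 | groups) + error``.

    Observations are re-sorted internally so each group's rows are
    contiguous; results are invariant to input order.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    groups = np.asarray(groups)
    if not np.all(np.isfinite(y)):
        raise DesignError("outcome contains non-finite values")
    n_obs, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise DesignError(
            "rank-deficient fixed-effect design (empty factor cell?)"
        )
    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    _, starts, sizes = np.unique(groups, return_index=True, return_counts=True)
    S = np.add.reduceat(X, starts, axis=0)
    u_sums = np.add.reduceat(y, starts)
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)
    fe_names = fe_names or [f"x{j}" for j in range(p)]

    args = (X, y, sizes, starts, S, u_sums, XtX, Xty, yty)
    # moment-based start: split the OLS residual variance half and half
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    v0 = float(np.var(y - X @ beta0, ddof=min(p, n_obs - 1)))
    if v0 <= 1e-12 * max(float(np.var(y)), 1.0):
        # (near-)deterministic data: REML is degenerate, report the exact
        # least-squares solution with boundary semantics
        rss = float(np.sum((y - X @ beta0) ** 2))
        s2e = rss / max(n_obs - p, 1)
        cov_beta = s2e * np.linalg.inv(XtX)
        return MixedFit(
            beta=beta0, cov_beta=cov_beta, sigma2_subject=0.0, sigma2_resid=s2e,
            loglik=np.nan, theta_cov=None, boundary=True, fe_names=fe_names,
            n_obs=n_obs, n_groups=sizes.size,
            _X=X, _group_sizes=sizes, _group_starts=starts, _y=y,
        )
    v0 = max(v0, 1e-12)
    best = None
    for frac in (0.5, 0.05, 0.95):
        res = optimize.minimize(
            _reml_negloglik_grad,
            x0=np.array([frac * v0, (1 - frac) * v0]),
            args=args,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None), (1e-12 * v0 + 1e-300, None)],
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise EstimationError("REML optimisation failed")
    s2u, s2e = best.x
    boundary = s2u <= _BOUNDARY_TOL * v0

    if boundary:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        s2e = rss / (n_obs - p)
        cov_beta = s2e * np.linalg.inv(XtX)
        return MixedFit(
            beta=beta, cov_beta=cov_beta, sigma2_subject=0.0, sigma2_resid=s2e,
            loglik=-best.fun, theta_cov=None, boundary=True, fe_names=fe_names,
            n_obs=n_obs, n_groups=sizes.size,
            _X=X, _group_sizes=sizes, _group_starts=starts, _y=y,
        )

    a = s2e + sizes * s2u
    w = s2u / a
    XtViX = (XtX - (S.T * w) @ S) / s2e
    XtViy = (Xty - S.T @ (w * u_sums)) / s2e
    beta = np.linalg.solve(XtViX, XtViy)
    cov_beta = np.linalg.inv(XtViX)

    # exact REML Fisher information at the optimum via dense block matrices
    Vinv_blocks = []
    for g, n in enumerate(sizes):
        Vinv_blocks.append((np.eye(n) - w[g] * np.ones((n, n))) / s2e)
    Vinv = np.zeros((n_obs, n_obs))
    pos = 0
    for blk in Vinv_blocks:
        n = blk.shape[0]
        Vinv[pos : pos + n, pos : pos + n] = blk
        pos += n
    VX = Vinv @ X
    P = Vinv - VX @ cov_beta @ VX.T
    ZZt = np.zeros((n_obs, n_obs))
    pos = 0
    for n in sizes:
        ZZt[pos : pos + n, pos : pos + n] = 1.0
        pos += n
    A = P @ ZZt
    I11 = 0.5 * float(np.sum(A * A.T))
    I12 = 0.5 * float(np.sum(A * P))
    I22 = 0.5 * float(np.sum(P * P))
    info = np.array([[I11, I12], [I12, I22]])
    try:
        theta_cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        theta_cov = None

    return MixedFit(
        beta=beta, cov_beta=cov_beta, sigma2_subject=float(s2u),
        sigma2_resid=float(s2e), loglik=-best.fun, theta_cov=theta_cov,
        boundary=False, fe_names=fe_names, n_obs=n_obs, n_groups=sizes.size,
        _X=X, _group_sizes=sizes, _group_starts=starts, _y=y,
    )
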