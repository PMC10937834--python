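"""Linear mixed models with a single grouping factor, fitted by profiled REML.

This module is the shared estimation engine for the package. It covers the
two model families the pipeline needs:

* random *coefficients* on a small design (``q`` = 1 or 2 random-effect
  columns per participant) — the cosinor variants;
* a random participant *intercept* under an arbitrary fixed-effect design —
  the repeated-measures ANOVA models.

The likelihood is expressed entirely through per-group sufficient statistics
(``Z'Z``, ``Z'X``, ``Z'y``, ``X'X``, ``X'y``, ``y'y``), which makes a single
evaluation O(groups · q²) and allows the same code to fit thousands of
response columns sharing one design in a vectorized batch (one column of
``Y`` per transcript), and to refit cluster-bootstrap replicates as
group-weight vectors without touching the raw data.

Inference on fixed effects uses t/F statistics with Satterthwaite
denominator degrees of freedom (numerical derivatives of the REML surface),
with a Wald-normal alternative. Multi-degree-of-freedom terms use the
Fai–Cornelius eigen-decomposition combination, as in lmerTest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats

__all__ = ["MixedModel", "MixedFit", "nelder_mead_batch"]

_THETA_LO = -8.0  # lower clamp for log-scale Cholesky diagonals (Gamma ~ 0)
_THETA_HI = 6.0


def _as_group_codes(groups) -> tuple[np.ndarray, np.ndarray]:
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    return labels, codes


def _chol_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    """Map unconstrained parameters to the lower Cholesky factor of Gamma.

    Gamma = L L' is the random-effect covariance relative to the residual
    variance. q=1 -> theta=(a,), L=[[e^a]]; q=2 -> theta=(a,b,c),
    L=[[e^a,0],[c,e^b]].
    """
    theta = np.atleast_2d(theta)
    T = theta.shape[0]
    L = np.zeros((T, q, q))
    if q == 1:
        L[:, 0, 0] = np.exp(np.clip(theta[:, 0], _THETA_LO, _THETA_HI))
    elif q == 2:
        L[:, 0, 0] = np.exp(np.clip(theta[:, 0], _THETA_LO, _THETA_HI))
        L[:, 1, 1] = np.exp(np.clip(theta[:, 1], _THETA_LO, _THETA_HI))
        L[:, 1, 0] = np.clip(theta[:, 2], -50.0, 50.0)
    else:  # pragma: no cover - the pipeline only uses q in {1, 2}
        raise ValueError(f"unsupported random-effect dimension q={q}")
    return L


def _inv_logdet_small(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched inverse and log-determinant for stacks of 1x1 / 2x2 SPD matrices."""
    q = K.shape[-1]
    if q == 1:
        det = K[..., 0, 0]
        inv = (1.0 / det)[..., None, None]
        return inv, np.log(det)
    a = K[..., 0, 0]
    b = K[..., 0, 1]
    c = K[..., 1, 0]
    d = K[..., 1, 1]
    det = a * d - b * c
    inv = np.empty_like(K)
    inv[..., 0, 0] = d / det
    inv[..., 0, 1] = -b / det
    inv[..., 1, 0] = -c / det
    inv[..., 1, 1] = a / det
    return inv, np.log(det)


def nelder_mead_batch(
    fun: Callable[[np.ndarray, np.ndarray], np.ndarray],
    x0: np.ndarray,
    step: float = 0.6,
    maxiter: int = 400,
    ftol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimize many independent low-dimensional problems in lock-step.

    ``fun(x, idx)`` evaluates problem ``idx[t]`` at point ``x[t]`` for a batch
    of points, returning a vector. Problems whose simplex function spread
    falls below ``ftol`` (relative) are frozen and dropped from subsequent
    evaluations, so late iterations only pay for stragglers.

    Returns (x_best, f_best, converged).
    """
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    T, d = x0.shape
    all_idx = np.arange(T)

    simplex = np.repeat(x0[:, None, :], d + 1, axis=1)
    for j in range(d):
        simplex[:, j + 1, j] += step
    fvals = np.empty((T, d + 1))
    for v in range(d + 1):
        fvals[:, v] = fun(simplex[:, v, :], all_idx)

    active = np.ones(T, dtype=bool)
    for _ in range(maxiter):
        idx = all_idx[active]
        if idx.size == 0:
            break
        sx = simplex[idx]
        sf = fvals[idx]
        order = np.argsort(sf, axis=1)
        sf = np.take_along_axis(sf, order, axis=1)
        sx = np.take_along_axis(sx, order[:, :, None], axis=1)

        spread = sf[:, -1] - sf[:, 0]
        scale = np.abs(sf[:, 0]) + 1.0
        done = spread <= ftol * scale
        if done.any():
            keep = ~done
            simplex[idx] = sx
            fvals[idx] = sf
            active[idx[done]] = False
            idx = idx[keep]
            if idx.size == 0:
                break
            sx = sx[keep]
            sf = sf[keep]

        centroid = sx[:, :-1, :].mean(axis=1)
        worst = sx[:, -1, :]
        xr = centroid + (centroid - worst)
        fr = fun(xr, idx)

        new_x = sx.copy()
        new_f = sf.copy()

        # reflection accepted (between best and second-worst)
        refl = (fr >= sf[:, 0]) & (fr < sf[:, -2])
        # expansion
        expand = fr < sf[:, 0]
        if expand.any():
            xe = centroid[expand] + 2.0 * (centroid[expand] - worst[expand])
            fe = fun(xe, idx[expand])
            better = fe < fr[expand]
            xa = np.where(better[:, None], xe, xr[expand])
            fa = np.where(better, fe, fr[expand])
            new_x[expand, -1, :] = xa
            new_f[expand, -1] = fa
        new_x[refl, -1, :] = xr[refl]
        new_f[refl, -1] = fr[refl]

        # contraction
        contract = fr >= sf[:, -2]
        if contract.any():
            inside = fr >= sf[:, -1]
            base = np.where(inside[:, None], worst, xr)
            xc = centroid[contract] + 0.5 * (base[contract] - centroid[contract])
            fc = fun(xc, idx[contract])
            ok = fc < np.minimum(fr[contract], sf[contract, -1])
            ci = np.flatnonzero(contract)
            acc = ci[ok]
            new_x[acc, -1, :] = xc[ok]
            new_f[acc, -1] = fc[ok]
            # shrink the rest toward the best vertex
            shr = ci[~ok]
            if shr.size:
                best = sx[shr, 0:1, :]
                new_x[shr, 1:, :] = best + 0.5 * (sx[shr, 1:, :] - best)
                for v in range(1, d + 1):
                    new_f[shr, v] = fun(new_x[shr, v, :], idx[shr])

        simplex[idx] = new_x
        fvals[idx] = new_f

    order = np.argsort(fvals, axis=1)
    fbest = np.take_along_axis(fvals, order[:, :1], axis=1)[:, 0]
    xbest = np.take_along_axis(simplex, order[:, :1, None], axis=1)[:, 0, :]
    return xbest, fbest, ~active


@dataclass
class MixedFit:
    """Result of a (batch) REML fit. Arrays are indexed [column, ...]."""

    beta: np.ndarray          # (T, p) fixed effects
    se: np.ndarray            # (T, p)
    df: np.ndarray            # (T, p) denominator df per coefficient
    tvalues: np.ndarray       # (T, p)
    pvalues: np.ndarray       # (T, p)
    sigma2: np.ndarray        # (T,) residual variance
    cov_re: np.ndarray        # (T, q, q) random-effect covariance (data scale)
    cov_beta: np.ndarray      # (T, p, p) covariance of beta-hat
    ranef: np.ndarray         # (T, G, q) conditional modes (BLUPs)
    theta: np.ndarray         # (T, d) variance parameters at the optimum
    converged: np.ndarray     # (T,) bool
    deviance: np.ndarray      # (T,) profiled -2 REML log-likelihood (up to const)
    n: int
    p: int
    q: int
    group_labels: np.ndarray = field(default=None, repr=False)
    model: "MixedModel" = field(default=None, repr=False)

    @property
    def n_cols(self) -> int:
        return self.beta.shape[0]


class MixedModel:
    """REML mixed model ``y = X b + Z u_g + e`` for one grouping factor.

    Parameters
    ----------
    X : (n, p) fixed-effect design, shared by every response column.
    Z : (n, q) random-effect design (``q`` <= 2), e.g. ``X`` itself for the
        random-slopes cosinor or a column of ones for a random intercept.
    groups : length-n labels mapping rows to participants.
    Y : (n,) or (n, T) response column(s).
    group_weights : optional (T, G) nonnegative multiplicities per group —
        used for participant-cluster bootstrap replicates.
    """

    def __init__(self, Y, X, groups, Z=None, group_weights=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = X.shape
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != n:
            raise ValueError("Y and X row counts differ")
        if Z is None:
            Z = np.ones((n, 1))
        Z = np.asarray(Z, dtype=float)
        q = Z.shape[1]
        if q not in (1, 2):
            raise ValueError("only q in {1, 2} random-effect columns supported")
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("non-finite values in design or response")

        labels, codes = _as_group_codes(groups)
        G = len(labels)
        T = Y.shape[1]

        # per-group sufficient statistics
        self.C = np.zeros((G, q, q))
        self.D = np.zeros((G, q, p))
        self.XtX = np.zeros((G, p, p))
        self.e = np.zeros((G, q, T))
        self.XtY = np.zeros((G, p, T))
        self.ytY = np.zeros((G, T))
        self.ng = np.zeros(G)
        for g in range(G):
            m = codes == g
            Xg, Zg, Yg = X[m], Z[m], Y[m]
            self.C[g] = Zg.T @ Zg
            self.D[g] = Zg.T @ Xg
            self.XtX[g] = Xg.T @ Xg
            self.e[g] = Zg.T @ Yg
            self.XtY[g] = Xg.T @ Yg
            self.ytY[g] = (Yg * Yg).sum(axis=0)
            self.ng[g] = m.sum()

        self._uniform_w = group_weights is None
        self._DtD = np.einsum("gqi,gqj->gij", self.D, self.D)
        if q == 2:
            self._d1 = self.D[:, 0, :]
            self._d2 = self.D[:, 1, :]
            self._O11 = np.einsum("gi,gj->gij", self._d1, self._d1)
            self._O22 = np.einsum("gi,gj->gij", self._d2, self._d2)
            self._O12s = np.einsum("gi,gj->gij", self._d1, self._d2)
            self._O12s = self._O12s + np.transpose(self._O12s, (0, 2, 1))
        self._XtX_sum = self.XtX.sum(axis=0)
        self._XtY_sum = self.XtY.sum(axis=0)
        self._ytY_sum = self.ytY.sum(axis=0)
        if group_weights is None:
            group_weights = np.ones((T, G))
        self.w = np.asarray(group_weights, dtype=float)
        if self.w.shape != (T, G):
            raise ValueError("group_weights must have shape (T, G)")

        self.n, self.p, self.q, self.G, self.T = n, p, q, G, T
        self.labels = labels
        self.codes = codes
        self.d = 1 if q == 1 else 3

    def _theta0_mom(self) -> np.ndarray:
        """Method-of-moments starting values for the variance parameters.

        Per-group least-squares coefficient estimates scatter around the
        population values with covariance G + sigma^2 E[(Z'Z)^-1]; solving
        that moment equation gives a starting Gamma close to the REML
        optimum, which cuts optimizer iterations substantially.
        """
        T, G, q = self.T, self.G, self.q
        Cinv = np.linalg.pinv(self.C)                       # (G, q, q)
        ok = self.ng > q
        b = np.einsum("gij,gjt->git", Cinv, self.e)         # per-group coefs
        # pooled within-group residual variance about the group fits
        res = self.ytY - np.einsum("gqt,gqt->gt", self.e, b)
        dof = np.maximum(self.ng - q, 0.0)
        sigma2 = np.maximum(res[ok].sum(0) / max(dof[ok].sum(), 1.0), 1e-12)
        bw = b[ok]                                           # (Gok, q, T)
        S = np.einsum("git,gjt->ijt", bw - bw.mean(0), bw - bw.mean(0)) / max(
            ok.sum() - 1, 1
        )                                                    # (q, q, T)
        Gam = S.transpose(2, 0, 1) / sigma2[:, None, None] - Cinv[ok].mean(0)
        theta0 = np.full((T, self.d), -2.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            if q == 1:
                v = np.maximum(Gam[:, 0, 0], 1e-4)
                theta0[:, 0] = 0.5 * np.log(v)
            else:
                v1 = np.maximum(Gam[:, 0, 0], 1e-4)
                v2 = np.maximum(Gam[:, 1, 1] - Gam[:, 1, 0] ** 2 / v1, 1e-4)
                theta0[:, 0] = 0.5 * np.log(v1)
                theta0[:, 2] = Gam[:, 1, 0] / np.sqrt(v1)
                theta0[:, 1] = 0.5 * np.log(v2)
        return np.clip(np.nan_to_num(theta0, nan=-2.0), _THETA_LO, _THETA_HI)

    # -- likelihood pieces -------------------------------------------------

    def _pieces(self, theta: np.ndarray, idx: np.ndarray):
        """GLS building blocks at per-column variance parameters ``theta``.

        Contractions are spelled out as two-operand einsums (no path
        search) — this loop is the package's hot spot.
        """
        L = _chol_from_theta(theta, self.q)           # (t, q, q)
        w = self.w[idx]                               # (t, G)
        uniform = self._uniform_w
        if self.q == 1:
            # scalar algebra: K = 1 + gamma * Z'Z per (column, group)
            gamma = L[:, 0, 0] ** 2                   # (t,)
            Cg = self.C[:, 0, 0]                      # (G,)
            K = 1.0 + gamma[:, None] * Cg[None, :]
            logdetK = np.log(K)
            Tscal = gamma[:, None] / K                # (t, G)
            Tw_s = Tscal if uniform else Tscal * w
            eg = self.e[:, 0, idx]                    # (G, t)
            dg = self.D[:, 0, :]                      # (G, p)
            XtViX_corr = np.einsum("tg,gij->tij", Tw_s, self._DtD)
            XtViy_corr = (Tw_s * eg.T) @ dg           # (t, p)
            ytViy_corr = (Tw_s * (eg.T ** 2)).sum(axis=1)
            Tm = Tscal[:, :, None, None]
        else:
            # hand-rolled 2x2 algebra on (t, G) component arrays
            l1 = L[:, 0, 0][:, None]
            l2 = L[:, 1, 1][:, None]
            lc = L[:, 1, 0][:, None]
            c11, c12, c22 = (self.C[:, 0, 0][None], self.C[:, 0, 1][None],
                             self.C[:, 1, 1][None])
            # K = I + L' C L (symmetric)
            a1 = c11 * l1 + c12 * lc
            a2 = c12 * l1 + c22 * lc
            k11 = 1.0 + l1 * a1 + lc * a2
            k12 = l2 * (c12 * l1 + c22 * lc)
            k22 = 1.0 + l2 * c22 * l2
            det = k11 * k22 - k12 * k12
            logdetK = np.log(det)
            ik11, ik12, ik22 = k22 / det, -k12 / det, k11 / det
            # T = L K^-1 L' (symmetric)
            b11 = ik11 * l1
            b12 = ik11 * lc + ik12 * l2
            b21 = ik12 * l1
            b22 = ik12 * lc + ik22 * l2
            t11 = l1 * b11
            t12 = l1 * b12
            t22 = lc * b12 + l2 * b22
            if not uniform:
                t11w, t12w, t22w = t11 * w, t12 * w, t22 * w
            else:
                t11w, t12w, t22w = t11, t12, t22
            XtViX_corr = (
                np.einsum("tg,gij->tij", t11w, self._O11)
                + np.einsum("tg,gij->tij", t12w, self._O12s)
                + np.einsum("tg,gij->tij", t22w, self._O22)
            )
            e1 = self.e[:, 0, idx].T                  # (t, G)
            e2 = self.e[:, 1, idx].T
            Te1 = t11w * e1 + t12w * e2
            Te2 = t12w * e1 + t22w * e2
            XtViy_corr = Te1 @ self._d1 + Te2 @ self._d2
            ytViy_corr = (Te1 * e1 + Te2 * e2).sum(axis=1)
            Tm = np.empty((len(theta), self.G, 2, 2))
            Tm[..., 0, 0], Tm[..., 0, 1] = t11, t12
            Tm[..., 1, 0], Tm[..., 1, 1] = t12, t22

        if uniform:
            XtViX = self._XtX_sum - XtViX_corr
            XtViy = self._XtY_sum[:, idx].T - XtViy_corr
            ytViy = self._ytY_sum[idx] - ytViy_corr
            logdetV0 = logdetK.sum(axis=1)
            n_eff = np.full(len(idx), float(self.n))
        else:
            XtViX = np.einsum("tg,gij->tij", w, self.XtX) - XtViX_corr
            XtViy = np.einsum("tg,gpt->tp", w, self.XtY[..., idx]) - XtViy_corr
            ytViy = np.einsum("tg,gt->t", w, self.ytY[:, idx]) - ytViy_corr
            logdetV0 = (w * logdetK).sum(axis=1)
            n_eff = w @ self.ng
        return L, Tm, XtViX, XtViy, ytViy, logdetV0, n_eff

    def profiled_deviance(self, theta: np.ndarray, idx: Optional[np.ndarray] = None) -> np.ndarray:
        """-2 REML log-likelihood with the residual variance profiled out."""
        if idx is None:
            idx = np.arange(self.T)
        theta = np.atleast_2d(theta)
        _, _, XtViX, XtViy, ytViy, logdetV0, n_eff = self._pieces(theta, idx)
        beta = np.linalg.solve(XtViX, XtViy[..., None])[..., 0]
        rss = np.maximum(ytViy - np.einsum("tp,tp->t", beta, XtViy), 1e-300)
        sign, logdetXVX = np.linalg.slogdet(XtViX)
        bad = sign <= 0
        dev = (n_eff - self.p) * np.log(rss) + logdetV0 + logdetXVX
        dev[bad] = np.inf
        return dev

    def full_deviance(self, theta_s: np.ndarray, idx: Optional[np.ndarray] = None) -> np.ndarray:
        """-2 REML log-likelihood as a function of (theta, log sigma^2)."""
        if idx is None:
            idx = np.arange(self.T)
        theta_s = np.atleast_2d(theta_s)
        theta, s = theta_s[:, :-1], theta_s[:, -1]
        _, _, XtViX, XtViy, ytViy, logdetV0, n_eff = self._pieces(theta, idx)
        beta = np.linalg.solve(XtViX, XtViy[..., None])[..., 0]
        rss = np.maximum(ytViy - np.einsum("tp,tp->t", beta, XtViy), 1e-300)
        _, logdetXVX = np.linalg.slogdet(XtViX)
        return (n_eff - self.p) * s + logdetV0 + logdetXVX + rss * np.exp(-s)

    def cov_beta_unscaled(self, theta: np.ndarray, idx: np.ndarray) -> np.ndarray:
        """(X' V0^-1 X)^-1 at per-column theta (multiply by sigma^2 for Cov)."""
        _, _, XtViX, _, _, _, _ = self._pieces(np.atleast_2d(theta), idx)
        return np.linalg.inv(XtViX)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        theta0: Optional[np.ndarray] = None,
        df_method: str = "satterthwaite",
        maxiter: int = 400,
        ftol: float = 1e-9,
    ) -> MixedFit:
        T, d, q, p = self.T, self.d, self.q, self.p
        if theta0 is None:
            theta0 = self._theta0_mom()
        theta, dev, conv = nelder_mead_batch(
            self.profiled_deviance, theta0, maxiter=maxiter, ftol=ftol
        )
        idx = np.arange(T)
        L, Tm, XtViX, XtViy, ytViy, logdetV0, n_eff = self._pieces(theta, idx)
        beta = np.linalg.solve(XtViX, XtViy[..., None])[..., 0]
        rss = np.maximum(ytViy - np.einsum("tp,tp->t", beta, XtViy), 0.0)
        dof = n_eff - p
        sigma2 = rss / dof
        cov_unscaled = np.linalg.inv(XtViX)
        cov_beta = sigma2[:, None, None] * cov_unscaled
        se = np.sqrt(np.maximum(np.einsum("tpp->tp", cov_beta), 0.0))

        gamma = L @ np.transpose(L, (0, 2, 1))
        cov_re = sigma2[:, None, None] * gamma

        # conditional modes  u_g = Gamma (I - C_g T_g)(Z'y - Z'X beta)
        resid_e = np.transpose(self.e, (2, 0, 1)) - np.einsum(
            "gqp,tp->tgq", self.D, beta
        )
        M = np.eye(q) - np.einsum("gij,tgjk->tgik", self.C, Tm, optimize=True)
        ranef = np.einsum("tij,tgjk,tgk->tgi", gamma, M, resid_e, optimize=True)
        ranef *= self.w[:, :, None]  # zero weight -> group absent

        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
        if df_method == "wald":
            df = np.full((T, p), np.inf)
            pvals = 2.0 * stats.norm.sf(np.abs(tvals))
        elif df_method == "satterthwaite":
            df = self._satterthwaite_df(theta, sigma2, cov_unscaled, idx)
            pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        else:
            raise ValueError(f"unknown df_method {df_method!r}")

        return MixedFit(
            beta=beta, se=se, df=df, tvalues=tvals, pvalues=pvals,
            sigma2=sigma2, cov_re=cov_re, cov_beta=cov_beta, ranef=ranef,
            theta=theta, converged=conv, deviance=dev,
            n=self.n, p=p, q=q, group_labels=self.labels, model=self,
        )

    # -- Satterthwaite machinery -------------------------------------------

    def _vcov_varpar(self, theta: np.ndarray, sigma2: np.ndarray, idx: np.ndarray) -> np.ndarray:
        """Asymptotic covariance of (theta, log sigma^2) from the REML Hessian."""
        t = len(idx)
        d1 = self.d + 1
        x0 = np.column_stack([theta, np.log(np.maximum(sigma2, 1e-300))])
        h = 1e-4 * np.maximum(1.0, np.abs(x0))
        H = np.zeros((t, d1, d1))
        f0 = self.full_deviance(x0, idx)
        for i in range(d1):
            for j in range(i, d1):
                if i == j:
                    xp = x0.copy(); xp[:, i] += h[:, i]
                    xm = x0.copy(); xm[:, i] -= h[:, i]
                    H[:, i, i] = (
                        self.full_deviance(xp, idx) - 2 * f0 + self.full_deviance(xm, idx)
                    ) / h[:, i] ** 2
                else:
                    xpp = x0.copy(); xpp[:, i] += h[:, i]; xpp[:, j] += h[:, j]
                    xpm = x0.copy(); xpm[:, i] += h[:, i]; xpm[:, j] -= h[:, j]
                    xmp = x0.copy(); xmp[:, i] -= h[:, i]; xmp[:, j] += h[:, j]
                    xmm = x0.copy(); xmm[:, i] -= h[:, i]; xmm[:, j] -= h[:, j]
                    H[:, i, j] = H[:, j, i] = (
                        self.full_deviance(xpp, idx)
                        - self.full_deviance(xpm, idx)
                        - self.full_deviance(xmp, idx)
                        + self.full_deviance(xmm, idx)
                    ) / (4 * h[:, i] * h[:, j])
        # Cov = 2 * H^-1 for the Hessian of -2logLik; use pinv at boundaries
        W = np.empty_like(H)
        for k in range(t):
            W[k] = 2.0 * np.linalg.pinv(H[k], rcond=1e-10, hermitian=True)
        return W

    def _var_contrast(self, theta_s: np.ndarray, idx: np.ndarray,
                      cvecs: np.ndarray) -> np.ndarray:
        """Var(c' beta-hat) at variance parameters; cvecs (k,p) or (t,k,p)."""
        theta, s = theta_s[:, :-1], theta_s[:, -1]
        cov_u = self.cov_beta_unscaled(theta, idx)
        if cvecs.ndim == 2:
            v = np.einsum("ki,tij,kj->tk", cvecs, cov_u, cvecs)
        else:
            v = np.einsum("tki,tij,tkj->tk", cvecs, cov_u, cvecs)
        return np.exp(s)[:, None] * v

    def contrast_df(
        self, theta: np.ndarray, sigma2: np.ndarray, cvecs: np.ndarray,
        idx: Optional[np.ndarray] = None, W: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Satterthwaite df per contrast; ``cvecs`` (k, p) shared or
        (T, k, p) per column. Returns (T, k)."""
        if idx is None:
            idx = np.arange(self.T)
        d1 = self.d + 1
        x0 = np.column_stack([np.atleast_2d(theta), np.log(np.maximum(sigma2, 1e-300))])
        if W is None:
            W = self._vcov_varpar(np.atleast_2d(theta), sigma2, idx)
        h = 1e-4 * np.maximum(1.0, np.abs(x0))
        cvecs = np.asarray(cvecs, dtype=float)
        if cvecs.ndim == 1:
            cvecs = cvecs[None, :]
        k = cvecs.shape[-2]
        t = len(idx)
        grads = np.zeros((t, k, d1))
        for i in range(d1):
            xp = x0.copy(); xp[:, i] += h[:, i]
            xm = x0.copy(); xm[:, i] -= h[:, i]
            grads[:, :, i] = (
                self._var_contrast(xp, idx, cvecs)
                - self._var_contrast(xm, idx, cvecs)
            ) / (2 * h[:, i])[:, None]
        f0 = self._var_contrast(x0, idx, cvecs)
        denom = np.einsum("tmi,tij,tmj->tm", grads, W, grads)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = 2.0 * f0**2 / denom
        n_eff = self.w[idx] @ self.ng
        upper = (n_eff - self.p)[:, None]
        df = np.where(np.isfinite(df) & (df > 0), df, upper)
        return np.clip(df, 1.0, upper)

    def _satterthwaite_df(self, theta, sigma2, cov_unscaled, idx) -> np.ndarray:
        return self.contrast_df(theta, sigma2, np.eye(self.p), idx=idx)

    # -- F tests -----------------------------------------------------------

    def ftest(self, fit: MixedFit, Lmat: np.ndarray,
              W: Optional[np.ndarray] = None):
        """F-test of H0: L beta = 0 with Satterthwaite denominator df.

        Returns (F, num_df, den_df, p) with per-column arrays. Multi-row L
        uses the Fai–Cornelius combination over the eigen-contrasts of
        L Cov(beta) L'; fully vectorized across response columns.
        """
        Lmat = np.atleast_2d(np.asarray(Lmat, dtype=float))
        k = Lmat.shape[0]
        T = fit.n_cols
        idx = np.arange(T)
        if W is None:
            W = self._vcov_varpar(fit.theta, fit.sigma2, idx)
        M = np.einsum("ki,tij,mj->tkm", Lmat, fit.cov_beta, Lmat)
        evals, evecs = np.linalg.eigh(M)
        tol = np.maximum(1e-12, 1e-10 * evals.max(axis=1, keepdims=True))
        keep = evals > tol                                   # (T, k)
        rank = keep.sum(axis=1)
        lam = np.where(keep, evals, np.inf)
        contr = np.einsum("tkm,kp->tmp", evecs, Lmat)        # (T, k, p) rows
        proj = np.einsum("tmp,tp->tm", contr, fit.beta)
        F = np.where(rank > 0, (proj**2 / lam).sum(axis=1) / np.maximum(rank, 1), 0.0)
        dfs = self.contrast_df(fit.theta, fit.sigma2, contr, idx=idx, W=W)
        dfs = np.where(keep, np.maximum(dfs, 1.0 + 1e-6), np.nan)
        gt2 = np.where(keep & (dfs > 2.0), dfs, np.nan)
        allgt2 = keep.sum(axis=1) == np.isfinite(gt2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            E = np.nansum(gt2 / (gt2 - 2.0), axis=1)
            dd_fc = 2.0 * E / (E - rank)
        fallback = float(fit.n - fit.p)
        dfs_filled = np.where(np.isfinite(dfs), dfs, fallback)
        first_df = np.where(keep, dfs_filled, -np.inf).max(axis=1)
        mean_df = np.where(
            keep.any(axis=1),
            np.where(keep, dfs_filled, 0.0).sum(axis=1) / np.maximum(rank, 1),
            fallback,
        )
        den_df = np.where(
            rank == 1, first_df,
            np.where(allgt2 & (E > rank), dd_fc, mean_df),
        )
        den_df = np.where(np.isfinite(den_df), den_df, fallback)
        num_df = rank.astype(float)
        p = stats.f.sf(F, np.maximum(num_df, 1.0), np.maximum(den_df, 1.0))
        p = np.where(rank > 0, p, 1.0)
        return F, num_df, den_df, p


def fit_mixed(
    Y, X, groups, Z=None, df_method: str = "satterthwaite",
    group_weights=None, **kwargs,
) -> MixedFit:
    """Convenience wrapper: build a :class:`MixedModel` and fit it."""
    return MixedModel(Y, X, groups, Z=Z, group_weights=group_weights).fit(
        df_method=df_method, **kwargs
    )
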