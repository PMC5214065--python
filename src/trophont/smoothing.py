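"""Penalized cubic-spline trend models with lake random intercepts.

The workhorse for size-structured trend inference: a Gaussian additive
mixed model

    y_i = f(x_i) + b_{lake(i)} + e_i,
    f: natural cubic regression spline on k quantile knots with a
       second-derivative (curvature) penalty,
    b:  per-lake random intercepts (ridge penalty),

fitted as a doubly penalized least-squares problem whose two penalty
weights are chosen by restricted maximum likelihood (REML; GCV optional).
The smooth is centered (sum of its fitted values constrained to zero) so
the model intercept is identifiable; the smooth's unpenalized null space is
the linear trend, hence its effective degrees of freedom run from 1
(straight line) to k - 1 (fully flexible).

Significance of the smooth uses a Wald-type statistic on the fitted smooth
coefficients with a fractional-rank pseudo-inverse of their Bayesian
covariance at rank = edf, referred to an F(edf, n - edf_total) distribution
— the standard approximate test for penalized smooths. A within-lake
permutation test is available as a small-sample alternative.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy import stats as sps
from scipy.linalg import cho_factor, cho_solve, eigh, null_space, qr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import _spline
from .exceptions import ConvergenceError, ValidationError

__all__ = ["SplineGAMM", "fit_smooth", "permutation_test_smooth"]


class SplineGAMM(BaseEstimator, RegressorMixin):
    """Penalized cubic regression spline with group random intercepts.

    Parameters
    ----------
    k : int
        Number of spline knots (placed at covariate quantiles). k = 3 keeps
        the curve to at most one bend, guarding against overfitting in
        small samples.
    method : {'REML', 'GCV'}
        Criterion for selecting the two penalty weights.
    lam : tuple of float, optional
        Fixed (smooth, random-intercept) penalty weights on the internally
        rescaled penalty blocks; skips criterion optimization. Mainly for
        diagnostics (e.g. the infinite-smoothing linear limit).

    Attributes (after fit)
    ----------
    knots_, coef_, intercept_ : spline geometry and coefficients
    lambda_smooth_, lambda_group_ : selected penalty weights
    edf_smooth_, edf_total_ : effective degrees of freedom
    f_stat_, p_value_ : approximate F test of the smooth term
    group_levels_, group_effects_ : random-intercept labels and BLUPs
    fitted_, band_lower_, band_upper_ : per-observation fit and 95% band
    """

    def __init__(self, k: int = 3, method: str = "REML", lam=None):
        self.k = k
        self.method = method
        self.lam = lam

    # ------------------------------------------------------------------
    def fit(self, X, y, groups=None):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValidationError("X and y must have equal length")
        n = x.size
        if n < 3 * self.k:
            raise ValidationError(f"need n >= 3k = {3 * self.k} observations")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValidationError("inputs must be finite")
        if np.ptp(x) == 0.0:
            raise ValidationError("covariate is constant")
        if self.method not in ("REML", "GCV"):
            raise ValidationError(f"unknown smoothing criterion {self.method!r}")

        if groups is None:
            groups = np.zeros(n, dtype=int)
        groups = np.asarray(groups)
        if groups.shape != (n,):
            raise ValidationError("groups must match the observations")
        levels, g_idx = np.unique(groups, return_inverse=True)
        L = len(levels)

        # smooth block: centered value-at-knot basis
        knots = _spline.choose_knots(x, self.k)
        F_full, S = _spline.penalty_matrices(knots)
        N = _spline.basis(x, knots, F_full)
        c = N.mean(axis=0)
        Z = null_space(c[None, :])  # (k, k-1)
        Xs = N @ Z
        Sz = Z.T @ S @ Z
        Sz = 0.5 * (Sz + Sz.T)
        q = Xs.shape[1]

        # random-intercept block
        G = np.zeros((n, L))
        G[np.arange(n), g_idx] = 1.0

        C = np.column_stack([np.ones(n), Xs, G])
        p = C.shape[1]
        idx_s = slice(1, 1 + q)
        idx_g = slice(1 + q, p)

        # rescale penalty blocks to the magnitude of their design blocks so
        # log-lambda searches start near 0
        s_scale = np.linalg.norm(Xs.T @ Xs) / max(np.linalg.norm(Sz), 1e-300)
        Szs = Sz * s_scale
        g_scale = np.linalg.norm(G.T @ G) / np.sqrt(L)

        CtC = C.T @ C
        Cty = C.T @ y
        yty = float(y @ y)

        eig_s = eigh(Szs, eigvals_only=True)
        eig_s = eig_s[eig_s > eig_s.max() * 1e-9] if eig_s.max() > 0 else eig_s[:0]
        rank_s = len(eig_s)  # k - 2
        m_null = 1 + (q - rank_s)  # intercept + smooth null space

        def penalized(rho):
            # clamp the search box: beyond ~e^25 the fit is numerically
            # indistinguishable from the limit and exp() overflows
            lam_s, lam_g = np.exp(np.clip(rho, -25.0, 25.0))
            A = CtC.copy()
            A[idx_s, idx_s] += lam_s * Szs
            A[idx_g, idx_g] += lam_g * g_scale * np.eye(L)
            if not np.isfinite(A).all():
                return None
            try:
                cf = cho_factor(A + 1e-10 * np.eye(p))
            except (np.linalg.LinAlgError, ValueError):
                return None
            theta = cho_solve(cf, Cty)
            return A, cf, theta

        def reml_score(rho):
            rho = np.clip(rho, -25.0, 25.0)
            out = penalized(rho)
            if out is None:
                return np.inf
            _, cf, theta = out
            P = max(yty - float(Cty @ theta), 1e-300)
            sigma2 = P / (n - m_null)
            logdet_a = 2.0 * np.sum(np.log(np.diag(cf[0])))
            logdet_lam = (
                rank_s * rho[0]
                + np.sum(np.log(eig_s))
                + L * (rho[1] + np.log(g_scale))
            )
            return (
                (n - m_null) * (1.0 + np.log(2.0 * np.pi * sigma2))
                + logdet_a
                - logdet_lam
            )

        def gcv_score(rho):
            out = penalized(rho)
            if out is None:
                return np.inf
            _, cf, theta = out
            edf = float(np.trace(cho_solve(cf, CtC)))
            rss = max(yty - 2 * float(Cty @ theta) + float(theta @ CtC @ theta), 0.0)
            denom = max(n - edf, 1e-8)
            return n * rss / denom**2

        score = reml_score if self.method == "REML" else gcv_score

        if self.lam is not None:
            rho_hat = np.log(np.asarray(self.lam, dtype=float))
            if rho_hat.shape != (2,):
                raise ValidationError("lam must be a (smooth, group) pair")
        else:
            grid = [
                np.array([a, b])
                for a in (-8.0, -4.0, 0.0, 4.0, 8.0)
                for b in (-8.0, -4.0, 0.0, 4.0, 8.0)
            ]
            rho0 = min(grid, key=lambda r: score(r))
            res = optimize.minimize(
                score, rho0, method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
            )
            if not np.isfinite(res.fun):
                raise ConvergenceError(
                    "smoothing-parameter search failed", trace=res
                )
            rho_hat = np.clip(res.x, -25.0, 25.0)

        out = penalized(rho_hat)
        if out is None:
            raise ConvergenceError("penalized system singular at optimum")
        A, cf, theta = out

        P = max(yty - float(Cty @ theta), 0.0)
        sigma2 = P / (n - m_null)
        M = cho_solve(cf, CtC)
        edf_vec = np.diag(M)
        Vb = cho_solve(cf, np.eye(p)) * max(sigma2, 1e-300)

        self.n_obs_ = n
        self.knots_ = knots
        self._F_full = F_full
        self._Z = Z
        self.intercept_ = float(theta[0])
        self.coef_smooth_ = theta[idx_s].copy()
        self.coef_ = theta.copy()
        self.lambda_smooth_ = float(np.exp(rho_hat[0]))
        self.lambda_group_ = float(np.exp(rho_hat[1]))
        self.sigma2_ = float(sigma2)
        self.edf_smooth_ = float(np.sum(edf_vec[idx_s]))
        self.edf_total_ = float(np.sum(edf_vec))
        self.group_levels_ = levels
        self.group_effects_ = theta[idx_g].copy()
        self.x_range_ = (float(x.min()), float(x.max()))

        fitted = C @ theta
        se_fit = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, Vb, C), 0.0))
        self.fitted_ = fitted
        self.band_lower_ = fitted - 1.96 * se_fit
        self.band_upper_ = fitted + 1.96 * se_fit

        self.f_stat_, self.p_value_ = self._smooth_test(
            Xs, theta[idx_s], Vb[idx_s, idx_s]
        )
        return self

    # ------------------------------------------------------------------
    def _smooth_test(self, Xs, beta_s, Vs):
        """Fractional-rank Wald F test of the whole smooth term."""
        n = self.n_obs_
        q = Xs.shape[1]
        nu = float(np.clip(self.edf_smooth_, 1.0, q))
        # work in the whitened space of fitted smooth values
        R = qr(Xs, mode="economic")[1]
        btil = R @ beta_s
        Vtil = R @ Vs @ R.T
        d, U = eigh(Vtil)
        order = np.argsort(d)[::-1]
        d, U = d[order], U[:, order]
        keep = d > max(d.max(), 0.0) * 1e-10 if d.size else d > 0
        d, U = d[keep], U[:, keep]
        if d.size == 0:
            return 0.0, 1.0
        r0 = int(np.floor(nu))
        frac = nu - r0
        dinv = np.zeros_like(d)
        dinv[: min(r0, d.size)] = 1.0 / d[: min(r0, d.size)]
        if frac > 1e-3 and r0 < d.size:
            dinv[r0] = frac / d[r0]
        z = U.T @ btil
        t_stat = float(z @ (dinv * z))
        f_stat = t_stat / nu
        df2 = max(n - self.edf_total_, 1.0)
        p = float(sps.f.sf(f_stat, nu, df2))
        return f_stat, p

    # ------------------------------------------------------------------
    def predict(self, X, group=None, return_band: bool = False):
        """Population-level prediction (random intercepts at zero) unless a
        group label is given. Defined on the fitted covariate range only."""
        check_is_fitted(self, "coef_")
        x = np.asarray(X, dtype=float).ravel()
        N = _spline.basis(x, self.knots_, self._F_full)
        Xs = N @ self._Z
        mu = self.intercept_ + Xs @ self.coef_smooth_
        if group is not None:
            where = np.nonzero(self.group_levels_ == group)[0]
            if where.size == 0:
                raise ValidationError(f"unknown group {group!r}")
            mu = mu + self.group_effects_[where[0]]
        if return_band:
            raise NotImplementedError("bands are reported for fitted points")
        return mu


def fit_smooth(response, covariate, lake_ids=None, k: int = 3,
               method: str = "REML", lam=None, seed=None) -> SplineGAMM:
    """Fit a penalized-spline trend of ``response`` on ``covariate`` with
    lake random intercepts. The fit itself is deterministic; ``seed`` is
    accepted for interface symmetry with the permutation test."""
    model = SplineGAMM(k=k, method=method, lam=lam)
    return model.fit(covariate, response, groups=lake_ids)


def permutation_test_smooth(response, covariate, lake_ids=None, k: int = 3,
                            n_perm: int = 999, seed: int = 0) -> dict:
    """Within-lake permutation test of the smooth term.

    The covariate is permuted within each lake (preserving the random-
    intercept structure), the model refitted, and the observed F statistic
    referred to the permutation distribution.
    """
    response = np.asarray(response, dtype=float).ravel()
    covariate = np.asarray(covariate, dtype=float).ravel()
    if lake_ids is None:
        lake_ids = np.zeros(response.size, dtype=int)
    lake_ids = np.asarray(lake_ids)
    obs = fit_smooth(response, covariate, lake_ids, k=k)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = covariate.copy()
        for lab in np.unique(lake_ids):
            m = lake_ids == lab
            perm[m] = rng.permutation(perm[m])
        f = fit_smooth(response, perm, lake_ids, k=k).f_stat_
        if f >= obs.f_stat_:
            count += 1
    return {
        "f_observed": obs.f_stat_,
        "p_permutation": (1 + count) / (1 + n_perm),
        "n_perm": n_perm,
    }
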