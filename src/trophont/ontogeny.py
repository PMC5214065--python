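"""Size-structured inference: logistic piscivory onset and the large-fish
sensitivity filter.

The onset model is an ordinary binomial GLM with logit link,

    logit P(fish prey in stomach) = beta0 + beta1 * fork_length,

fitted by iteratively reweighted least squares with step-halving (so the
deviance decreases monotonically). The size at which piscivory becomes the
more likely state — the 50%-probability length, an L50 in the fisheries
sense — is the analytic crossing point -beta0/beta1. Trout-only
communities, where no stomach ever contains fish, have only one response
class: the curve is undefined there and the fit raises a
``DegenerateClassesError`` rather than returning a meaningless estimate.

Penalized-spline trend models live in :mod:`trophont.smoothing` and are
re-exported here so all ontogeny models share one import surface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import (
    ConvergenceError,
    DegenerateClassesError,
    SeparationError,
    ValidationError,
)
from .smoothing import SplineGAMM, fit_smooth, permutation_test_smooth  # noqa: F401

__all__ = [
    "PiscivoryLogistic",
    "fit_piscivory_logistic",
    "length_at_probability",
    "sensitivity_filter",
    "SplineGAMM",
    "fit_smooth",
    "permutation_test_smooth",
]

_MIN_N = 10


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


class PiscivoryLogistic(BaseEstimator, ClassifierMixin):
    """Binomial logit fit of piscivory presence on fork length.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the deviance change.
    max_iter : int
        Maximum IRLS iterations.

    Attributes (after fit)
    ----------
    beta0_, beta1_ : intercept and per-mm slope on the logit scale
    se_ : (se_beta0, se_beta1) from the inverse Fisher information
    length_p50_ : the 50%-probability length, -beta0/beta1 (mm);
        ``nan`` when beta1 <= 0
    deviance_path_ : per-iteration deviance (monotone non-increasing)
    converged_, n_iter_, n_obs_ : fit diagnostics
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        lengths = np.asarray(X, dtype=float).ravel()
        flags = np.asarray(y).astype(float).ravel()
        if lengths.shape != flags.shape:
            raise ValidationError("lengths and flags must have equal length")
        n = lengths.size
        if n < _MIN_N:
            raise ValidationError(f"need n >= {_MIN_N} observations")
        if not np.isfinite(lengths).all():
            raise ValidationError("lengths must be finite")
        if not np.isin(flags, (0.0, 1.0)).all():
            raise ValidationError("flags must be binary")
        if flags.min() == flags.max():
            raise DegenerateClassesError(
                "only one response class present; piscivory-onset curve undefined"
            )
        self._check_separation(lengths, flags)

        Xd = np.column_stack([np.ones(n), lengths])
        beta = np.zeros(2)
        mu = np.full(n, flags.mean())
        # start from the null model's intercept
        beta[0] = logit(flags.mean())
        dev = _deviance(flags, np.full(n, flags.mean()))
        path = [dev]
        converged = False
        for _ in range(self.max_iter):
            eta = Xd @ beta
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            score = Xd.T @ (flags - mu)
            fisher = (Xd * w[:, None]).T @ Xd
            try:
                step = np.linalg.solve(fisher, score)
            except np.linalg.LinAlgError:
                raise ConvergenceError("singular Fisher information", trace=path)
            # step-halving keeps the deviance monotone
            factor = 1.0
            for _h in range(30):
                cand = beta + factor * step
                dev_new = _deviance(flags, expit(Xd @ cand))
                if dev_new <= dev + 1e-14:
                    break
                factor *= 0.5
            beta = beta + factor * step
            path.append(dev_new)
            if abs(dev - dev_new) < self.tol * (abs(dev) + 0.1):
                converged = True
                dev = dev_new
                break
            dev = dev_new
        if not converged:
            raise ConvergenceError(
                f"IRLS did not converge in {self.max_iter} iterations", trace=path
            )
        if np.max(np.abs(Xd @ beta)) > 30.0:
            raise SeparationError(
                "fitted logits diverged; data are (quasi-)separated"
            )

        mu = expit(Xd @ beta)
        w = mu * (1.0 - mu)
        cov = np.linalg.inv((Xd * w[:, None]).T @ Xd)
        self.classes_ = np.array([False, True])
        self.beta0_ = float(beta[0])
        self.beta1_ = float(beta[1])
        self.coef_ = beta[1:].reshape(1, 1)
        self.intercept_ = beta[:1]
        self.se_ = (float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])))
        self.deviance_ = dev
        self.deviance_path_ = np.asarray(path)
        self.converged_ = converged
        self.n_iter_ = len(path) - 1
        self.n_obs_ = n
        self.length_p50_ = (
            -self.beta0_ / self.beta1_ if self.beta1_ > 0 else float("nan")
        )
        return self

    @staticmethod
    def _check_separation(lengths: np.ndarray, flags: np.ndarray) -> None:
        """Complete separation check, exact for a single covariate."""
        lo = lengths[flags == 0.0]
        hi = lengths[flags == 1.0]
        if lo.max() < hi.min():
            raise SeparationError(
                "complete separation: every piscivore longer than every "
                f"non-piscivore (boundary {(lo.max() + hi.min()) / 2:.1f} mm)",
                boundary=float((lo.max() + hi.min()) / 2),
            )
        if hi.max() < lo.min():
            raise SeparationError(
                "complete separation: every piscivore shorter than every "
                f"non-piscivore (boundary {(hi.max() + lo.min()) / 2:.1f} mm)",
                boundary=float((hi.max() + lo.min()) / 2),
            )

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "beta0_")
        lengths = np.asarray(X, dtype=float).ravel()
        p = expit(self.beta0_ + self.beta1_ * lengths)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1] >= 0.5

    def length_at_probability(self, p: float = 0.5) -> float:
        check_is_fitted(self, "beta0_")
        return length_at_probability(self, p)


def fit_piscivory_logistic(lengths, flags, **kwargs) -> PiscivoryLogistic:
    """Fit the piscivory-onset logistic model; returns the fitted estimator."""
    return PiscivoryLogistic(**kwargs).fit(lengths, flags)


def length_at_probability(fit, p: float = 0.5) -> float:
    """Length at which the fitted piscivory probability equals ``p``.

    ``fit`` may be a fitted :class:`PiscivoryLogistic` or any object with
    ``beta0_``/``beta1_`` (or ``beta0``/``beta1``) attributes.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError("p must be strictly between 0 and 1")
    b0 = getattr(fit, "beta0_", getattr(fit, "beta0", None))
    b1 = getattr(fit, "beta1_", getattr(fit, "beta1", None))
    if b0 is None or b1 is None:
        raise ValidationError("fit must expose beta0/beta1")
    if b1 <= 0:
        raise ValidationError("non-increasing piscivory: beta1 <= 0")
    return float((logit(p) - b0) / b1)


def sensitivity_filter(
    fish: pd.DataFrame, max_length: float = 400.0
) -> tuple[pd.DataFrame, int]:
    """Drop fish longer than ``max_length`` mm (threshold inclusive: a fish
    of exactly ``max_length`` is retained). Returns the filtered table and
    the number of rows removed."""
    keep = fish["fork_length_mm"] <= max_length
    removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValidationError("sensitivity filter removed every fish")
    return fish.loc[keep].copy(), removed
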