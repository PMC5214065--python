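"""Two-source (littoral/pelagic) stable-isotope mixing model.

A consumer's carbon signature places it on the littoral-pelagic energy
axis; its nitrogen signature, referenced against the carbon-weighted
baseline, gives a continuous trophic position:

    alpha = (d13C_c - d13C_pel) / (d13C_lit - d13C_pel),  clamped to [0, 1]
    TP    = lambda + (d15N_c - [alpha * d15N_lit + (1 - alpha) * d15N_pel]) / Delta15N

with baseline trophic level ``lambda = 2`` (primary-consumer end-members:
littoral macrozoobenthos, pelagic zooplankton) and per-level nitrogen
fractionation ``Delta15N = 3.4`` permil by convention. Both constants are
parameters: the two-source formulation cited in the field literature leaves
them to the analyst, and these defaults are the conventional choice, not a
measured quantity. Carbon is assumed to fractionate negligibly with trophic
level, keeping the mixing model two-parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateBaselineError, ValidationError

__all__ = [
    "BaselineSet",
    "TwoSourceMixingModel",
    "aggregate_baseline",
    "littoral_reliance",
    "trophic_position",
    "forward_isotopes",
    "tp_table",
]

DEFAULT_LAMBDA = 2.0
DEFAULT_DELTA15N = 3.4
DEFAULT_EPSILON = 0.5  # permil; minimum end-member d13C separation

_PLAUSIBLE_D13C = (-45.0, -5.0)
_PLAUSIBLE_D15N = (0.0, 25.0)


@dataclass(frozen=True)
class BaselineSet:
    """Per-lake littoral and pelagic isotope end-members.

    ``littoral``/``pelagic`` are ``(d13C mean, d15N mean, n)`` triples.
    """

    lake_id: str
    littoral: tuple[float, float, int]
    pelagic: tuple[float, float, int]
    lam: float = DEFAULT_LAMBDA
    delta15n: float = DEFAULT_DELTA15N
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        if self.delta15n <= 0:
            raise ValidationError("delta15n must be positive")
        if self.littoral[2] < 1 or self.pelagic[2] < 1:
            raise ValidationError("each end-member needs n >= 1 samples")
        if abs(self.littoral[0] - self.pelagic[0]) <= self.epsilon:
            raise DegenerateBaselineError(
                f"lake {self.lake_id!r}: end-member d13C separation "
                f"{abs(self.littoral[0] - self.pelagic[0]):.3f} permil <= "
                f"epsilon {self.epsilon} permil"
            )


def aggregate_baseline(
    samples: pd.DataFrame,
    lake_id: str,
    lam: float = DEFAULT_LAMBDA,
    delta15n: float = DEFAULT_DELTA15N,
    epsilon: float = DEFAULT_EPSILON,
) -> BaselineSet:
    """Habitat-wise arithmetic means of invertebrate baseline samples.

    ``samples`` needs columns lake_id, habitat ('littoral'/'pelagic'),
    d13C, d15N. Missing habitats and indistinguishable end-members raise.
    """
    sub = samples[samples["lake_id"] == lake_id]
    ends = {}
    for habitat in ("littoral", "pelagic"):
        h = sub[sub["habitat"] == habitat]
        if len(h) == 0:
            raise ValidationError(
                f"lake {lake_id!r}: no {habitat} baseline samples"
            )
        ends[habitat] = (float(h["d13C"].mean()), float(h["d15N"].mean()), len(h))
    return BaselineSet(lake_id, ends["littoral"], ends["pelagic"], lam, delta15n, epsilon)


def _check_plausible(d13c: np.ndarray, d15n: np.ndarray) -> None:
    lo, hi = _PLAUSIBLE_D13C
    if np.any((d13c < lo) | (d13c > hi)):
        warnings.warn("d13C outside plausible range [-45, -5] permil", stacklevel=3)
    lo, hi = _PLAUSIBLE_D15N
    if np.any((d15n < lo) | (d15n > hi)):
        warnings.warn("d15N outside plausible range [0, 25] permil", stacklevel=3)


def littoral_reliance(d13c, b: BaselineSet, clamp: bool = True):
    """Littoral carbon reliance alpha from the two-point d13C mixing line."""
    d13c = np.asarray(d13c, dtype=float)
    raw = (d13c - b.pelagic[0]) / (b.littoral[0] - b.pelagic[0])
    if clamp:
        return np.clip(raw, 0.0, 1.0)
    return raw


def trophic_position(d13c, d15n, b: BaselineSet):
    """Trophic position from the alpha-weighted baseline d15N."""
    d13c = np.asarray(d13c, dtype=float)
    d15n = np.asarray(d15n, dtype=float)
    alpha = littoral_reliance(d13c, b)
    base_n = alpha * b.littoral[1] + (1.0 - alpha) * b.pelagic[1]
    tp = b.lam + (d15n - base_n) / b.delta15n
    if np.any(np.asarray(tp) < 0):
        warnings.warn(f"negative trophic position in lake {b.lake_id!r}", stacklevel=2)
    return tp


def forward_isotopes(tp, alpha, b: BaselineSet):
    """Invert the mixing model: isotope values a consumer at (tp, alpha)
    would show against baseline ``b``. Exact inverse of
    :func:`trophic_position` / :func:`littoral_reliance` for alpha in [0,1].
    """
    tp = np.asarray(tp, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha < 0) | (alpha > 1)):
        raise ValidationError("alpha must lie in [0, 1]")
    d13c = alpha * b.littoral[0] + (1.0 - alpha) * b.pelagic[0]
    base_n = alpha * b.littoral[1] + (1.0 - alpha) * b.pelagic[1]
    d15n = base_n + (tp - b.lam) * b.delta15n
    return d13c, d15n


class TwoSourceMixingModel(BaseEstimator, TransformerMixin):
    """Transformer mapping consumer (d13C, d15N) pairs to (alpha, TP).

    ``fit`` aggregates a lake's invertebrate baseline samples into littoral
    and pelagic end-members; ``transform`` applies the two-source model to
    consumer isotope pairs.

    Parameters
    ----------
    lam : float
        Trophic level assigned to the baselines (primary consumers -> 2.0).
    delta15n : float
        Nitrogen fractionation per trophic level, permil.
    epsilon : float
        Minimum end-member d13C separation; below this, mixing is
        numerically meaningless and fitting raises.
    """

    def __init__(
        self,
        lam: float = DEFAULT_LAMBDA,
        delta15n: float = DEFAULT_DELTA15N,
        epsilon: float = DEFAULT_EPSILON,
    ):
        self.lam = lam
        self.delta15n = delta15n
        self.epsilon = epsilon

    def fit(self, X: pd.DataFrame, y=None, lake_id: str | None = None):
        """Aggregate baseline samples (columns lake_id, habitat, d13C, d15N).

        With multiple lakes present, ``lake_id`` selects one.
        """
        if lake_id is None:
            lakes = X["lake_id"].unique()
            if len(lakes) != 1:
                raise ValidationError(
                    "baseline table holds several lakes; pass lake_id"
                )
            lake_id = lakes[0]
        self.baseline_ = aggregate_baseline(
            X, lake_id, self.lam, self.delta15n, self.epsilon
        )
        return self

    @classmethod
    def from_baseline(cls, b: BaselineSet) -> "TwoSourceMixingModel":
        m = cls(lam=b.lam, delta15n=b.delta15n, epsilon=b.epsilon)
        m.baseline_ = b
        return m

    def transform(self, X) -> np.ndarray:
        """Columns of X: d13C, d15N. Returns columns (alpha, TP)."""
        check_is_fitted(self, "baseline_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValidationError("X must be (n, 2): columns d13C, d15N")
        if not np.isfinite(X).all():
            raise ValidationError("isotope values must be finite")
        _check_plausible(X[:, 0], X[:, 1])
        alpha = littoral_reliance(X[:, 0], self.baseline_)
        tp = trophic_position(X[:, 0], X[:, 1], self.baseline_)
        return np.column_stack([alpha, tp])


def tp_table(
    fish: pd.DataFrame,
    baselines: dict[str, BaselineSet],
    group_cols: tuple[str, ...] = ("lake_id", "community_type"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fish trophic positions plus grouped mean +/- SD summaries.

    ``fish`` needs columns fish_id, lake_id, d13C, d15N (plus any grouping
    columns). Returns ``(per_fish, summary)``; summary rows carry an
    ``n1_flag`` marking single-member groups whose SD is reported as 0.
    """
    missing = sorted(set(fish["lake_id"]) - set(baselines))
    if missing:
        raise ValidationError(f"no baseline for lakes: {missing}")

    rows = []
    for lake, sub in fish.groupby("lake_id", sort=False):
        b = baselines[lake]
        raw = littoral_reliance(sub["d13C"].to_numpy(), b, clamp=False)
        clamped = np.clip(raw, 0.0, 1.0)
        tp = trophic_position(sub["d13C"].to_numpy(), sub["d15N"].to_numpy(), b)
        out = sub[["fish_id", "lake_id"]].copy()
        for c in group_cols:
            if c in sub.columns:
                out[c] = sub[c].to_numpy()
        out["alpha_raw"] = raw
        out["alpha"] = clamped
        out["tp"] = tp
        rows.append(out)
    per_fish = pd.concat(rows, ignore_index=True)

    summaries = []
    for col in group_cols:
        if col not in per_fish.columns:
            continue
        for key, sub in per_fish.groupby(col, sort=False):
            n = len(sub)
            sd = float(sub["tp"].std(ddof=1)) if n > 1 else 0.0
            summaries.append(
                {
                    "group_by": col,
                    "group": key,
                    "n": n,
                    "tp_mean": float(sub["tp"].mean()),
                    "tp_sd": sd,
                    "n1_flag": n == 1,
                }
            )
    return per_fish, pd.DataFrame(summaries)
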