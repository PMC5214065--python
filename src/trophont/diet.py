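"""Stomach-content model: prey proportions, piscivory, and individual
dietary specialization.

The central statistic is the proportional-similarity overlap between an
individual's diet proportions ``p_i`` and the population diet ``q``,

    PS_i = 1 - 0.5 * sum_j |p_ij - q_j|,

reported here as its complement ``1 - PS_i`` (half the L1 distance between
the two simplex vectors): 0 for an individual eating exactly like the
population, approaching 1 for an individual concentrated on a category the
population barely uses.

Diet proportions come from stomach fullness points: each prey category's
contribution to total stomach fullness, normalized within the individual.
Piscivory is a presence/absence flag (any fish-prey category with positive
points). Empty stomachs carry no diet information and are excluded both
from the diet matrix and from prevalence denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import EmptyStomachError, UnmappedPreyError, ValidationError

__all__ = [
    "Stomach",
    "PreyCategoryMap",
    "DietMatrix",
    "DietSpecialization",
    "prey_proportions",
    "build_diet_matrix",
    "population_diet",
    "individual_specialization",
    "piscivory_flag",
    "piscivory_table",
    "prevalence_piscivory",
]

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class Stomach:
    """One fish stomach: visual fullness and per-prey fullness points."""

    fish_id: str
    fullness_pct: float
    points: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.fullness_pct <= 100.0:
            raise ValidationError(
                f"fullness_pct must be in [0, 100], got {self.fullness_pct}"
            )
        for label, pts in self.points.items():
            if pts < 0:
                raise ValidationError(
                    f"negative points for prey {label!r} in fish {self.fish_id!r}"
                )

    @property
    def total_points(self) -> float:
        return float(sum(self.points.values()))

    @property
    def is_empty(self) -> bool:
        return self.total_points <= 0.0


@dataclass(frozen=True)
class PreyCategoryMap:
    """Total map from raw prey labels to a standardized shared vocabulary.

    ``fish_prey`` is the subset of standardized categories that are fish;
    any positive contribution from one of them marks the individual as
    piscivorous.
    """

    mapping: Mapping[str, str]
    fish_prey: frozenset[str] = frozenset()

    def __post_init__(self):
        unknown = set(self.fish_prey) - set(self.mapping.values())
        if unknown:
            raise ValidationError(
                f"fish_prey categories absent from map targets: {sorted(unknown)}"
            )

    @property
    def categories(self) -> list[str]:
        """Standardized categories in stable (first-appearance) order."""
        seen: dict[str, None] = {}
        for v in self.mapping.values():
            seen.setdefault(v, None)
        return list(seen)

    def resolve(self, raw_label: str) -> str:
        try:
            return self.mapping[raw_label]
        except KeyError:
            raise UnmappedPreyError(raw_label) from None

    @classmethod
    def identity(cls, categories: Sequence[str], fish_prey: Iterable[str] = ()):
        return cls({c: c for c in categories}, frozenset(fish_prey))

    @classmethod
    def from_file(cls, path) -> "PreyCategoryMap":
        """Read a three-column delimited map: raw_label, standard_category,
        is_fish_prey (0/1)."""
        df = pd.read_csv(path)
        required = {"raw_label", "standard_category", "is_fish_prey"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"prey map must have columns {sorted(required)}, got {list(df.columns)}"
            )
        mapping = dict(zip(df["raw_label"], df["standard_category"]))
        fish = frozenset(df.loc[df["is_fish_prey"].astype(int) == 1, "standard_category"])
        return cls(mapping, fish)


@dataclass
class DietMatrix:
    """Individuals x standardized prey categories, row-stochastic."""

    individuals: list[str]
    categories: list[str]
    P: np.ndarray
    q: np.ndarray
    excluded: list[str] = field(default_factory=list)  # empty-stomach fish

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.P.shape != (len(self.individuals), len(self.categories)):
            raise ValidationError("P shape inconsistent with labels")
        if self.P.size and not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("diet matrix rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.individuals, columns=self.categories)


def _as_simplex(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValidationError(f"{name} must be 1-d")
    if np.any(v < -1e-12) or not np.isfinite(v).all():
        raise ValidationError(f"{name} must be finite and non-negative")
    if abs(v.sum() - 1.0) > _SUM_TOL:
        raise ValidationError(f"{name} must sum to 1 (got {v.sum():.8f})")
    return v


def prey_proportions(
    st: Stomach, pmap: PreyCategoryMap, categories: Sequence[str] | None = None
) -> pd.Series:
    """Normalize a stomach's fullness points into diet proportions.

    Raw labels are resolved through ``pmap`` and aggregated within
    standardized categories. Raises :class:`EmptyStomachError` for an empty
    stomach (total points zero) so callers can exclude the fish.
    """
    total = st.total_points
    if total <= 0.0:
        raise EmptyStomachError(st.fish_id)
    cats = list(categories) if categories is not None else pmap.categories
    out = pd.Series(0.0, index=cats)
    for raw, pts in st.points.items():
        std = pmap.resolve(raw)
        if std not in out.index:
            raise ValidationError(
                f"category {std!r} not in requested category list"
            )
        out[std] += pts / total
    return out


def build_diet_matrix(
    stomachs: Iterable[Stomach], pmap: PreyCategoryMap
) -> DietMatrix:
    """Assemble the row-stochastic diet matrix, excluding empty stomachs."""
    cats = pmap.categories
    rows, ids, excluded = [], [], []
    for st in stomachs:
        try:
            rows.append(prey_proportions(st, pmap, cats).to_numpy())
            ids.append(st.fish_id)
        except EmptyStomachError:
            excluded.append(st.fish_id)
    if not ids:
        raise ValidationError("no non-empty stomachs to build a diet matrix from")
    P = np.vstack(rows)
    q = population_diet(P)
    return DietMatrix(ids, cats, P, q, excluded)


def population_diet(P, method: str = "mean", weights=None) -> np.ndarray:
    """Population diet vector ``q``.

    ``method='mean'`` (default): unweighted arithmetic mean of individual
    proportion rows, so a full stomach counts no more than a near-empty one.
    ``method='pooled'``: rows weighted by ``weights`` (e.g. total fullness
    points), equivalent to pooling raw points before normalizing.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValidationError("P must be a non-empty 2-d matrix")
    if method == "mean":
        q = P.mean(axis=0)
    elif method == "pooled":
        if weights is None:
            raise ValidationError("method='pooled' requires weights")
        w = np.asarray(weights, dtype=float)
        if w.shape != (P.shape[0],) or np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("weights must be non-negative with positive sum")
        q = (P * w[:, None]).sum(axis=0) / w.sum()
    else:
        raise ValidationError(f"unknown population_diet method {method!r}")
    return q / q.sum()


def individual_specialization(p, q) -> float:
    """Individual dietary specialization ``1 - PS_i = 0.5 * sum |p_j - q_j|``.

    Both arguments must be proportion vectors over the same ordered
    categories. Returns a value in [0, 1]: 0 iff the individual's diet
    equals the population diet.
    """
    p = _as_simplex(p, "p")
    q = _as_simplex(q, "q")
    if p.shape != q.shape:
        raise ValidationError(
            f"p and q must have equal length ({p.shape[0]} vs {q.shape[0]})"
        )
    return float(0.5 * np.abs(p - q).sum())


def piscivory_flag(st: Stomach, pmap: PreyCategoryMap) -> bool:
    """True iff any fish-prey category contributes positive points.

    An empty stomach returns False; use :func:`piscivory_table` to carry the
    exclusion marker needed for prevalence denominators.
    """
    if st.is_empty:
        return False
    return any(
        pts > 0 and pmap.resolve(raw) in pmap.fish_prey
        for raw, pts in st.points.items()
    )


def piscivory_table(stomachs: Iterable[Stomach], pmap: PreyCategoryMap) -> pd.DataFrame:
    """Per-fish piscivory flags with empty-stomach exclusion markers."""
    rec = [
        {
            "fish_id": st.fish_id,
            "piscivory_flag": piscivory_flag(st, pmap),
            "excluded": st.is_empty,
        }
        for st in stomachs
    ]
    return pd.DataFrame(rec, columns=["fish_id", "piscivory_flag", "excluded"])


def prevalence_piscivory(flags, excluded=None) -> float:
    """Prevalence of piscivory in percent among non-excluded individuals."""
    flags = np.asarray(flags, dtype=bool)
    if excluded is None:
        excluded = np.zeros(flags.shape, dtype=bool)
    excluded = np.asarray(excluded, dtype=bool)
    keep = ~excluded
    if keep.sum() == 0:
        raise ValidationError("prevalence undefined: all individuals excluded")
    return float(100.0 * flags[keep].sum() / keep.sum())


class DietSpecialization(BaseEstimator, TransformerMixin):
    """Transformer computing ``1 - PS_i`` for each diet-proportion row.

    ``fit`` learns the population diet ``q_`` from the training rows;
    ``transform`` maps each row to its specialization statistic. Fitting and
    transforming on the same matrix reproduces the classical within-
    population index; fitting on a pooled community matrix and transforming
    per lake gives the pooled-population variant.

    Parameters
    ----------
    method : {'mean', 'pooled'}
        How the population diet is aggregated (see :func:`population_diet`).
    """

    def __init__(self, method: str = "mean"):
        self.method = method

    def fit(self, X, y=None, weights=None):
        X = self._validate_rows(X)
        self.q_ = population_diet(X, method=self.method, weights=weights)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "q_")
        X = self._validate_rows(X)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} categories, expected {self.n_features_in_}"
            )
        return 0.5 * np.abs(X - self.q_).sum(axis=1)

    @staticmethod
    def _validate_rows(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-d (individuals x categories)")
        if not np.isfinite(X).all() or np.any(X < -1e-12):
            raise ValidationError("diet proportions must be finite and non-negative")
        if X.size and np.max(np.abs(X.sum(axis=1) - 1.0)) > _SUM_TOL:
            raise ValidationError("each diet row must sum to 1")
        return X
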