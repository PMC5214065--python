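"""Nonparametric group comparisons and correlation tests.

Thin, validated wrappers around scipy: a tie-corrected Kruskal-Wallis test
for contrasting trophic metrics across fish-community types, and
Pearson/Spearman correlation for the piscivory-abundance association. The
source study labels its three-group statistic "Z"; here it is reported as
the rank-based H with chi-square degrees of freedom (groups - 1), the
standard convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError

__all__ = ["GroupedSample", "kruskal_wallis", "correlation_test"]


@dataclass
class GroupedSample:
    """Numeric values partitioned into labelled groups."""

    values: np.ndarray
    groups: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.shape != self.groups.shape:
            raise ValidationError("values and groups must have equal length")
        if not np.isfinite(self.values).all():
            raise ValidationError("values must be finite")

    def split(self) -> dict:
        labels = np.unique(self.groups)
        out = {lab: self.values[self.groups == lab] for lab in labels}
        for lab, v in out.items():
            if v.size == 0:
                raise ValidationError(f"group {lab!r} is empty")
        return out


def kruskal_wallis(gs: GroupedSample) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    Returns ``(H, df, p)`` with ``df = groups - 1``. When every value is
    identical there is no separation at all: H = 0, p = 1.
    """
    parts = list(gs.split().values())
    if len(parts) < 2:
        raise ValidationError("need at least 2 groups")
    if gs.values.size < 5:
        raise ValidationError("need total n >= 5")
    df = len(parts) - 1
    if np.ptp(gs.values) == 0.0:
        return 0.0, df, 1.0
    h, p = sps.kruskal(*parts)
    return float(h), df, float(p)


def correlation_test(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value.

    Pearson p comes from the t distribution with n - 2 df; Spearman uses
    scipy's exact/asymptotic handling. Zero variance in either variable is
    an error (the coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValidationError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("values must be finite")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValidationError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(r), float(p)
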