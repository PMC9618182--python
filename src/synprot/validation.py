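"""Validation statistics: orthogonal-method regression and summary t-tests.

Pooled discovery proteomics is typically validated by quantifying a
handful of proteins with an orthogonal method (e.g. western blot band
intensity normalized to total-protein stain, case over control) and
regressing those ratios against the proteomics ratios.  Cohort summary
tables report group characteristics as mean +/- SD with group sizes, so
a two-sample t-test computable from summary statistics alone is also
provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError

__all__ = ["SummaryStats", "RegressionResult", "regression_validation", "summary_ttest"]


@dataclass(frozen=True)
class SummaryStats:
    """Group summary: mean, standard deviation and sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ConfigError(f"standard deviation must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def regression_validation(
    pairs: Sequence[tuple[float, float]]
) -> RegressionResult:
    """Ordinary least squares of proteomics ratios on orthogonal ratios.

    Parameters
    ----------
    pairs
        ``(orthogonal_ratio, proteomics_ratio)`` tuples; at least three,
        all finite, with non-zero variance on the orthogonal axis.

    Returns
    -------
    RegressionResult
        Slope, intercept, R^2 (squared Pearson correlation) and the
        two-sided p-value for the zero-slope null.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ConfigError("regression needs >= 3 (x, y) pairs")
    if not np.all(np.isfinite(arr)):
        raise ConfigError("non-finite values in regression input")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ConfigError("zero variance in orthogonal-method ratios")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def summary_ttest(
    a: SummaryStats, b: SummaryStats, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample two-tailed t-test from group means, SDs and sizes.

    Student's pooled-variance test by default; set ``welch=True`` for the
    unequal-variance form.  Returns ``(t, df, p)``.  Two groups with
    equal means and zero spread are degenerate and return ``(0, df, 1)``.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            df = a.n + b.n - 2 if not welch else float(a.n + b.n - 2)
            return 0.0, float(df), 1.0
        raise ConfigError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=not welch
    )
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        df = a.n + b.n - 2
    return float(t), float(df), float(p)
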