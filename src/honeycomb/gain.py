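"""Genetic-gain estimation across selection cycles.

The rate of gain is the ordinary-least-squares slope of single-plant
yields of the selected families on calendar year (grams per plant per
year); the relative gain divides the slope by the grand mean of the
control plants and is expressed as percent per year.  Helpers for the
distribution-shape and control-comparison statistics used alongside the
regression (sample skewness, two-sample t-tests, percent superiority) live
here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "GainEstimate",
    "GainModel",
    "fit_rate_of_gain",
    "relative_gain",
    "sample_skewness",
    "two_sample_t",
    "percent_superiority",
]


@dataclass(frozen=True)
class GainEstimate:
    """Results of the gain regression.

    ``slope`` is in g/plant/year, ``relative_gain`` (available once a
    control grand mean is supplied) in percent per year.
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_se: float
    n_obs: int
    control_grand_mean: float | None = None

    @property
    def relative_gain(self) -> float | None:
        if self.control_grand_mean is None:
            return None
        return relative_gain(self.slope, self.control_grand_mean)

    def summary(self) -> str:
        lines = [
            "Rate-of-gain regression (OLS, yield ~ year)",
            f"  n observations     {self.n_obs}",
            f"  slope              {self.slope:.4g} g/plant/year (SE {self.slope_se:.3g})",
            f"  intercept          {self.intercept:.4g} g",
            f"  R-squared          {self.r_squared:.3f}",
            f"  p(slope)           {self.p_value:.3g}",
        ]
        if self.control_grand_mean is not None:
            lines.append(
                f"  control grand mean {self.control_grand_mean:.4g} g"
            )
            lines.append(
                f"  relative gain      {self.relative_gain:.2f} % per year"
            )
        return "\n".join(lines)


class GainModel:
    """OLS model of single-plant yield on calendar year.

    Built from ``(year, yield)`` records -- by convention all individual
    plant replications of the selected families, not yearly means.
    ``fit`` returns a :class:`GainEstimate`.
    """

    def __init__(self, years, yields):
        years = np.asarray(years, dtype=float)
        yields = np.asarray(yields, dtype=float)
        if years.shape != yields.shape or years.ndim != 1:
            raise ValueError("years and yields must be 1-d and equally long")
        ok = np.isfinite(years) & np.isfinite(yields)
        self.years = years[ok]
        self.yields = yields[ok]
        if len(np.unique(self.years)) < 3:
            raise ValueError("gain regression needs at least three distinct years")

    @classmethod
    def from_dataframe(
        cls, records: pd.DataFrame, year: str = "year", value: str = "pod_g"
    ) -> "GainModel":
        return cls(records[year], records[value])

    def fit(self, control_grand_mean: float | None = None) -> GainEstimate:
        if control_grand_mean is not None and control_grand_mean <= 0:
            raise ValueError("control grand mean must be positive")
        X = sm.add_constant(self.years)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sm.OLS(self.yields, X).fit()
            r2 = float(res.rsquared)
        return GainEstimate(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            r_squared=r2 if np.isfinite(r2) else 0.0,
            p_value=float(res.pvalues[1]),
            slope_se=float(res.bse[1]),
            n_obs=int(res.nobs),
            control_grand_mean=control_grand_mean,
        )


def fit_rate_of_gain(records, control_grand_mean: float | None = None) -> GainEstimate:
    """Fit the gain regression from an iterable of ``(year, yield_g)``
    pairs or a DataFrame with ``year``/``pod_g`` columns."""
    if isinstance(records, pd.DataFrame):
        model = GainModel.from_dataframe(records)
    else:
        arr = np.asarray(list(records), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("records must be (year, yield) pairs")
        model = GainModel(arr[:, 0], arr[:, 1])
    return model.fit(control_grand_mean)


def relative_gain(slope: float, control_grand_mean: float) -> float:
    """``100 * slope / control_grand_mean`` -- percent gain per year."""
    if control_grand_mean <= 0:
        raise ValueError("control grand mean must be positive")
    return 100.0 * slope / control_grand_mean


def sample_skewness(values) -> float:
    """Adjusted Fisher--Pearson standardised third moment."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3:
        raise ValueError("skewness requires at least three values")
    if np.std(arr, ddof=1) == 0:
        raise ValueError("skewness undefined for a constant sample")
    return float(scipy.stats.skew(arr, bias=False))


def two_sample_t(a, b, variant: str = "student") -> tuple[float, float, float]:
    """Two-sided two-sample t-test: returns ``(t, df, p)``.

    ``variant="student"`` pools the variances; ``"welch"`` does not assume
    equal variances.  Degenerate inputs (fewer than two values per group,
    or zero variance in both groups) raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        raise ValueError("zero variance in both samples: t undefined")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    res = scipy.stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def percent_superiority(candidate_mean: float, control_mean: float) -> float:
    """``100 * (candidate - control) / control`` -- percent yield advantage
    of a selection over the control."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (candidate_mean - control_mean) / control_mean
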