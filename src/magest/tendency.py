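"""Continuous-estimate analysis: central-tendency regression.

Slider estimates (0-100) are regressed on the normalized magnitude of the
tested dimension (0 = smallest level, 100 = largest).  The slope of the
best-fitting line indexes the degree of central tendency: 1 is veridical
responding, 0 is complete regression to the mean of the stimulus set;
the intercept indexes a global over- or under-estimation bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import LEVEL_FACTORS


def normalize_magnitude(levels, value: float) -> float:
    """Map a magnitude onto percent of the tested range (level 1 -> 0, level 6 -> 100)."""
    levels = sorted(levels)
    if len(levels) < 2:
        raise ValueError("need at least two levels")
    return 100.0 * (value - levels[0]) / (levels[-1] - levels[0])


def factor_percent(level_factor) -> np.ndarray:
    """Normalized magnitude directly from the design level factor."""
    lf = np.asarray(level_factor, dtype=float)
    lo, hi = min(LEVEL_FACTORS), max(LEVEL_FACTORS)
    return 100.0 * (lf - lo) / (hi - lo)


@dataclass
class TendencyFit:
    """OLS slope/intercept of estimates vs normalized magnitude."""

    slope: float
    intercept: float
    r2: float
    n: int
    dimension: str | None = None
    condition: str | None = None

    def summary(self) -> str:
        return (
            "Central-tendency regression (OLS)\n"
            + "=" * 36
            + f"\n{'n trials':<14}{self.n:>12d}"
            + f"\n{'slope':<14}{self.slope:>12.4f}"
            + f"\n{'intercept':<14}{self.intercept:>12.4f}"
            + f"\n{'R^2':<14}{self.r2:>12.4f}"
        )


class CentralTendencyModel:
    """Linear model of continuous estimates against normalized magnitude."""

    def __init__(self, magnitude_percent, estimate_percent):
        self.x = np.asarray(magnitude_percent, dtype=float)
        self.y = np.asarray(estimate_percent, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("magnitude and estimate vectors must have equal length")
        if len(self.x) < 6:
            raise ValueError("need at least 6 observations")
        if np.ptp(self.x) == 0:
            raise ValueError("zero variance in the magnitude predictor")

    def fit(self, dimension: str | None = None, condition: str | None = None) -> TendencyFit:
        res = sm.OLS(self.y, sm.add_constant(self.x)).fit()
        return TendencyFit(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            r2=float(res.rsquared) if np.isfinite(res.rsquared) else 0.0,
            n=len(self.x),
            dimension=dimension,
            condition=condition,
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fit = self.fit()
        ax.plot(self.x, self.y, ".", alpha=0.4)
        xs = np.array([0.0, 100.0])
        ax.plot(xs, fit.intercept + fit.slope * xs, "-", label=f"slope={fit.slope:.2f}")
        ax.plot(xs, xs, "k--", lw=0.8, label="veridical")
        ax.set_xlabel("magnitude (%)")
        ax.set_ylabel("estimate (%)")
        ax.legend()
        return ax


def fit_tendency(magnitude_percent, estimate_percent, **keys) -> TendencyFit:
    """Convenience wrapper around :class:`CentralTendencyModel`."""
    return CentralTendencyModel(magnitude_percent, estimate_percent).fit(**keys)


def tendency_table(
    responses: pd.DataFrame,
    by: tuple[str, ...] = ("participant", "target", "condition"),
    per_level_means: bool = False,
) -> pd.DataFrame:
    """Per-cell central-tendency fits as a tidy table.

    ``responses`` must carry ``level_factor`` and ``estimate_percent``
    columns plus the grouping keys.  By default pooled trials are regressed;
    with ``per_level_means=True`` the six per-level mean estimates are used
    instead.
    """
    keys = [k for k in by if k in responses.columns]
    rows = []
    for key_vals, grp in responses.groupby(keys, sort=True):
        if per_level_means:
            grp = (
                grp.groupby("level_factor", as_index=False)["estimate_percent"].mean()
            )
        x = factor_percent(grp["level_factor"])
        fit = fit_tendency(x, grp["estimate_percent"].to_numpy())
        row = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        row.update(slope=fit.slope, intercept=fit.intercept, r2=fit.r2, n=fit.n)
        rows.append(row)
    return pd.DataFrame(rows)
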