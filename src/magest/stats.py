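"""Correlation statistics for slope tables.

Pearson correlation matrices across design cells, Fisher z-tests for
differences between correlations, first-order partial correlations, and
Bonferroni thresholding of the cell-wise matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps


class ZTestResult(NamedTuple):
    z: float
    p: float


def fisher_z_diff(r1: float, r2: float, n1: int, n2: int) -> ZTestResult:
    """Fisher z-test for the difference of two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p from
    the standard normal.  Treats the two coefficients as coming from
    independent samples.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1 (z-transform diverges)")
    if min(n1, n2) <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return ZTestResult(z=z, p=2.0 * sps.norm.sf(abs(z)))


def steiger_z_diff(r_jk: float, r_jh: float, r_kh: float, n: int) -> ZTestResult:
    """Steiger's z-test for two dependent correlations sharing variable j.

    The statistically proper alternative when both coefficients come from
    the same sample (compare r_jk against r_jh given their overlap r_kh).
    """
    for r in (r_jk, r_jh):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1")
    if n <= 3:
        raise ValueError("need n > 3")
    z1, z2 = math.atanh(r_jk), math.atanh(r_jh)
    rbar2 = ((r_jk + r_jh) / 2.0) ** 2
    psi = r_kh * (1.0 - 2.0 * rbar2) - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r_kh**2)
    cov = psi / (1.0 - rbar2) ** 2
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - cov)))
    return ZTestResult(z=z, p=2.0 * sps.norm.sf(abs(z)))


def partial_corr(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y controlling for z."""
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 0:
        raise ValueError("degenerate denominator: |r_xz| or |r_yz| is 1")
    return (r_xy - r_xz * r_yz) / math.sqrt(denom)


@dataclass(frozen=True)
class CorrelationTriplet:
    """The three pairwise slope correlations between D, N and S."""

    r_dn: float
    r_ds: float
    r_ns: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("need at least 4 participants")
        if not self.is_positive_semidefinite():
            warnings.warn(
                "implied 3x3 correlation matrix is not positive semi-definite "
                "(rounded inputs?)",
                stacklevel=2,
            )

    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [1.0, self.r_dn, self.r_ds],
                [self.r_dn, 1.0, self.r_ns],
                [self.r_ds, self.r_ns, 1.0],
            ]
        )

    def is_positive_semidefinite(self, tol: float = 1e-9) -> bool:
        return bool(np.linalg.eigvalsh(self.matrix()).min() >= -tol)


@dataclass
class CorrelationMatrixResult:
    """Cell-wise Pearson matrix with a multiple-comparison mask."""

    r: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame  # True where the Bonferroni-adjusted test passes
    n: int
    n_comparisons: int
    alpha_adjusted: float
    r_threshold: float


def correlation_matrix(
    slope_table: pd.DataFrame,
    alpha: float = 0.05,
) -> CorrelationMatrixResult:
    """Pairwise Pearson correlations across design-cell columns.

    ``slope_table`` has one row per participant and one column per cell.
    The Bonferroni family is the number of unique off-diagonal cell pairs;
    ``r_threshold`` is the |r| needed to pass the adjusted level at this n.
    Constant columns yield NaN correlations and are never flagged.
    """
    if slope_table.shape[0] < 4:
        raise ValueError("need at least 4 participants")
    if slope_table.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    cols = list(slope_table.columns)
    m = len(cols)
    n = slope_table.shape[0]
    n_comp = m * (m - 1) // 2
    alpha_adj = alpha / n_comp
    r = pd.DataFrame(np.eye(m), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((m, m)), index=cols, columns=cols)
    for i in range(m):
        for j in range(i + 1, m):
            xi = slope_table[cols[i]].to_numpy(dtype=float)
            xj = slope_table[cols[j]].to_numpy(dtype=float)
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sps.pearsonr(xi, xj)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    mask = (p < alpha_adj).fillna(False)
    np.fill_diagonal(mask.values, False)
    t_crit = sps.t.ppf(1.0 - alpha_adj / 2.0, n - 2)
    r_threshold = float(t_crit / math.sqrt(n - 2 + t_crit**2))
    return CorrelationMatrixResult(
        r=r, p=p, mask=mask, n=n,
        n_comparisons=n_comp, alpha_adjusted=alpha_adj, r_threshold=r_threshold,
    )
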