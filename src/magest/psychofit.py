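"""Categorical psychometric analysis: binning, logit fits, PSE, Weber Ratio.

Continuous slider responses are first binned into '+' / '-' choices by
which half of the response axis they fall in.  Per participant, dimension
and condition the proportion of '+' responses across the six magnitude
levels is fitted with a two-parameter logistic

    p(+ | x) = 1 / (1 + exp(-(x - mu) / s))

by Bernoulli maximum likelihood on trials.  The point of subjective
equality is PSE = f^{-1}(0.5) = mu, and the Weber Ratio is

    WR = 0.5 * (f^{-1}(0.75) - f^{-1}(0.25)) / PSE = s ln 3 / mu,

an index of discrimination sensitivity normalized by the indifference
point.  Goodness of fit is the residual deviance of the binned fit against
the saturated model, referred to chi-square with (levels - 2) df.

The module also implements the participant-exclusion rules, the 2-SD
group-mean outlier replacement, and the iterative difficulty-calibration
loop that matches PSE and WR across dimensions by rescaling the session
means for numerosity and surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .design import DEFAULT_MEANS, INITIAL_MEANS, magnitude_levels


class FitError(RuntimeError):
    """Unusable psychometric fit requested for PSE/WR extraction."""


class CalibrationError(RuntimeError):
    """Difficulty calibration failed to converge; carries the last state."""

    def __init__(self, message: str, last_state: dict | None = None):
        super().__init__(message)
        self.last_state = last_state or {}


def binarize(slider_percent: float, polarity: str = "plus_top") -> str:
    """Bin a slider position (0 = bottom, 100 = top) into '+' or '-'.

    A click on the half of the axis nearer the '+' extreme is a 'plus'; the
    exact midpoint (the cursor's starting position) counts as 'minus'.
    """
    if not 0.0 <= slider_percent <= 100.0:
        raise ValueError(f"slider position {slider_percent!r} outside [0, 100]")
    if polarity not in ("plus_top", "plus_bottom"):
        raise ValueError(f"unknown polarity {polarity!r}")
    pos = slider_percent if polarity == "plus_top" else 100.0 - slider_percent
    return "plus" if pos > 50.0 else "minus"


class PsychometricModel:
    """Two-parameter logistic choice model for one (participant, condition) cell.

    Parameters
    ----------
    levels : array-like of float
        The tested magnitudes (at least two distinct values).
    n_plus : array-like of int
        '+' responses per level.
    n_total : array-like of int
        Trials per level; their sum must be at least 12.
    """

    def __init__(self, levels, n_plus, n_total):
        self.levels = np.asarray(levels, dtype=float)
        self.n_plus = np.asarray(n_plus, dtype=float)
        self.n_total = np.asarray(n_total, dtype=float)
        if not (len(self.levels) == len(self.n_plus) == len(self.n_total)):
            raise ValueError("levels, n_plus, n_total must have equal length")
        if len(np.unique(self.levels)) < 2:
            raise ValueError("need at least two distinct magnitude levels")
        if self.n_total.sum() < 12:
            raise ValueError("need at least 12 trials in total")
        if np.any(self.n_plus > self.n_total) or np.any(self.n_plus < 0):
            raise ValueError("n_plus must lie in [0, n_total]")

    # -- likelihood ---------------------------------------------------------
    def nloglik(self, mu: float, s: float) -> float:
        p = np.clip(expit((self.levels - mu) / s), 1e-12, 1 - 1e-12)
        return -float(
            np.sum(self.n_plus * np.log(p) + (self.n_total - self.n_plus) * np.log1p(-p))
        )

    def _start(self) -> tuple[float, float]:
        prop = self.n_plus / np.maximum(self.n_total, 1)
        mu0 = float(np.interp(0.5, prop, self.levels)) if prop[-1] > prop[0] else float(
            np.mean(self.levels)
        )
        s0 = float(np.ptp(self.levels)) / 4.0
        return mu0, s0

    def fit(self, start: tuple[float, float] | None = None) -> "PsychometricResults":
        mu0, s0 = start if start is not None else self._start()
        span = float(np.ptp(self.levels))
        total_plus, total = self.n_plus.sum(), self.n_total.sum()

        degenerate = None
        if total_plus == 0 or total_plus == total:
            degenerate = "all responses on one side"

        trace: list[float] = []

        def objective(theta):
            val = self.nloglik(theta[0], math.exp(theta[1]))
            return val

        res = None
        if degenerate is None:
            x0 = np.array([mu0, math.log(s0)])
            trace.append(objective(x0))
            res = optimize.minimize(
                objective,
                x0,
                method="Nelder-Mead",
                callback=lambda xk: trace.append(objective(xk)),
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
            )
            mu_hat, s_hat = float(res.x[0]), float(math.exp(res.x[1]))
        else:
            mu_hat, s_hat = mu0, s0

        separated = degenerate is None and s_hat < 1e-2 * span
        flat = degenerate is None and (
            s_hat > 50.0 * span or not np.isfinite(mu_hat)
        )
        converged = (
            degenerate is None
            and res is not None
            and bool(res.success)
            and not separated
            and not flat
        )
        return PsychometricResults(
            model=self,
            mu=mu_hat,
            s=s_hat,
            converged=converged,
            n_trials=int(total),
            nll_trace=np.array(trace),
            flags=[f for f, on in (
                (degenerate, degenerate is not None),
                ("separation", separated),
                ("flat", flat),
            ) if on],
        )


@dataclass
class PsychometricResults:
    """Fitted logistic: location mu (= PSE), scale s, and diagnostics."""

    model: PsychometricModel
    mu: float
    s: float
    converged: bool
    n_trials: int
    nll_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    flags: list[str] = field(default_factory=list)

    def predict(self, x) -> np.ndarray:
        return expit((np.asarray(x, dtype=float) - self.mu) / self.s)

    def inverse(self, p: float) -> float:
        """Magnitude at which the fitted curve reaches proportion ``p``."""
        return self.mu + self.s * math.log(p / (1.0 - p))

    @property
    def pse(self) -> float:
        """Point of subjective equality, f^{-1}(0.5) = mu."""
        return self.mu

    @property
    def wr(self) -> float:
        """Weber Ratio, 0.5 (f^{-1}(0.75) - f^{-1}(0.25)) / PSE = s ln3 / mu."""
        if self.mu <= 0:
            raise FitError("Weber Ratio undefined for non-positive PSE")
        return self.s * math.log(3.0) / self.mu

    @property
    def deviance(self) -> float:
        m = self.model
        p_hat = np.clip(self.predict(m.levels), 1e-12, 1 - 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            k, n = m.n_plus, m.n_total
            t1 = np.where(k > 0, k * np.log(k / (n * p_hat)), 0.0)
            t2 = np.where(n - k > 0, (n - k) * np.log((n - k) / (n * (1 - p_hat))), 0.0)
        return float(2.0 * np.sum(t1 + t2))

    @property
    def df(self) -> int:
        return int(np.sum(self.model.n_total > 0)) - 2

    @property
    def gof_p(self) -> float:
        """Residual-deviance p-value against the saturated model."""
        return float(stats.chi2.sf(self.deviance, self.df))

    def summary(self) -> str:
        lines = [
            "Psychometric logistic fit (Bernoulli ML)",
            "=" * 44,
            f"{'n trials':<22}{self.n_trials:>12d}",
            f"{'location mu (PSE)':<22}{self.mu:>12.4f}",
            f"{'scale s':<22}{self.s:>12.4f}",
        ]
        if self.converged and self.mu > 0:
            lines.append(f"{'Weber Ratio':<22}{self.wr:>12.4f}")
        lines += [
            f"{'deviance (df)':<22}{self.deviance:>9.3f} ({self.df})",
            f"{'goodness-of-fit p':<22}{self.gof_p:>12.4f}",
            f"{'converged':<22}{str(self.converged):>12}",
        ]
        if self.flags:
            lines.append(f"{'flags':<22}{', '.join(self.flags):>12}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.plot(m.levels, m.n_plus / np.maximum(m.n_total, 1), "ko", label="observed")
        xs = np.linspace(m.levels.min(), m.levels.max(), 200)
        ax.plot(xs, self.predict(xs), "-", label="logistic fit")
        ax.axhline(0.5, color="grey", lw=0.5)
        ax.set_xlabel("magnitude")
        ax.set_ylabel("proportion '+'")
        ax.legend()
        return ax


def fit_logit(levels, n_plus, n_total) -> PsychometricResults:
    """Convenience wrapper: build a PsychometricModel and fit it."""
    return PsychometricModel(levels, n_plus, n_total).fit()


def pse(fit: PsychometricResults) -> float:
    if not fit.converged:
        raise FitError(f"fit unusable ({', '.join(fit.flags) or 'not converged'})")
    return fit.pse


def weber_ratio(fit: PsychometricResults) -> float:
    if not fit.converged:
        raise FitError(f"fit unusable ({', '.join(fit.flags) or 'not converged'})")
    return fit.wr


# -- participant exclusion & outlier handling -------------------------------

def exclude_participants(
    controls: dict,
    gof_rule: str = "greater",
    alpha: float = 0.05,
) -> tuple[list, dict]:
    """Apply the control-condition exclusion rules to a cohort.

    ``controls`` maps participant -> dimension -> mapping with keys
    ``top_plus_prop`` (observed '+' proportion at the largest level) and
    ``gof_p``.  A participant is dropped when the top-level proportion never
    reaches 0.5 in some dimension, or when the goodness-of-fit p-value
    violates the rule: ``gof_rule='greater'`` drops p > alpha (the rule as
    stated for the original analysis); ``'less'`` drops p < alpha (the usual
    deviance-test convention).
    """
    if gof_rule not in ("greater", "less"):
        raise ValueError("gof_rule must be 'greater' or 'less'")
    kept, dropped = [], {}
    for pid, dims in controls.items():
        if not dims:
            raise ValueError(f"participant {pid!r} has no control conditions")
        reasons = []
        for dim, info in dims.items():
            if info["top_plus_prop"] < 0.5:
                reasons.append(f"max-level:{dim}")
            p = info["gof_p"]
            if (gof_rule == "greater" and p > alpha) or (gof_rule == "less" and p < alpha):
                reasons.append(f"gof:{dim}")
        if reasons:
            dropped[pid] = reasons
        else:
            kept.append(pid)
    return kept, dropped


def outlier_replace(values, ddof: int = 1) -> tuple[np.ndarray, int]:
    """Replace values beyond mean +/- 2 SD by the group mean (single pass).

    Mean and SD are computed on the original list; returns the new array and
    the number of replacements.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    mean, sd = v.mean(), v.std(ddof=ddof)
    if sd == 0:
        return v.copy(), 0
    mask = np.abs(v - mean) > 2.0 * sd
    out = np.where(mask, mean, v)
    return out, int(mask.sum())


# -- difficulty calibration --------------------------------------------------

@dataclass(frozen=True)
class CalibrationCriteria:
    """When are PSE and WR considered matched across dimensions?"""

    pse_band: tuple[float, float] = (0.95, 1.05)
    wr_ratio_max: float = 3.0
    wr_abs_max: float = 0.25
    wr_spread_rule: object = None  # optional hook: callable(wrs) -> bool

    def satisfied(self, pse_by_dim: dict, wr_by_dim: dict, means: dict) -> bool:
        for dim, p in pse_by_dim.items():
            ratio = p / means[dim]
            if not self.pse_band[0] <= ratio <= self.pse_band[1]:
                return False
        wrs = list(wr_by_dim.values())
        if max(wrs) / max(min(wrs), 1e-12) >= self.wr_ratio_max:
            return False
        if any(w >= self.wr_abs_max for w in wrs):
            return False
        if self.wr_spread_rule is not None and not self.wr_spread_rule(wrs):
            return False
        return True


@dataclass
class CalibrationResult:
    n_mean: float
    s_mean: float
    iterations: int
    history: list[dict]


def calibrate(
    probe,
    criteria: CalibrationCriteria | None = None,
    means: dict[str, float] | None = None,
    d_mean: float = 800.0,
    max_iter: int = 50,
) -> CalibrationResult:
    """Iteratively rescale N_mean and S_mean until task difficulty matches.

    ``probe`` is a callable ``probe(dim, mean_value) -> (levels, n_plus,
    n_total)`` that runs one 30-trial block (5 trials x 6 levels) of the
    observer on the given dimension.  Each iteration fits the three blocks,
    then replaces each accumulated dimension's mean by its measured PSE
    (multiplicative update: mean *= PSE/mean).  Duration's mean is fixed.
    """
    criteria = CalibrationCriteria() if criteria is None else criteria
    means = dict(INITIAL_MEANS if means is None else means)
    means["duration"] = d_mean
    history = []
    for it in range(1, max_iter + 1):
        pse_by_dim, wr_by_dim = {}, {}
        for dim, m in means.items():
            levels, n_plus, n_total = probe(dim, m)
            fit = fit_logit(levels, n_plus, n_total)
            pse_by_dim[dim] = pse(fit)
            wr_by_dim[dim] = weber_ratio(fit)
        history.append({"means": dict(means), "pse": pse_by_dim, "wr": wr_by_dim})
        if criteria.satisfied(pse_by_dim, wr_by_dim, means):
            return CalibrationResult(
                n_mean=means["numerosity"],
                s_mean=means["surface"],
                iterations=it,
                history=history,
            )
        for dim in ("numerosity", "surface"):
            means[dim] *= pse_by_dim[dim] / means[dim]
    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations",
        last_state=history[-1] if history else {},
    )


def make_observer_probe(
    params,
    geometry=None,
    seed: int = 0,
    n_per_level: int = 5,
):
    """A calibration probe backed by the synthetic observer.

    Returns a callable running ``n_per_level`` trials at each of the six
    levels of the probed dimension (non-targets at their means, linear
    regime) and reporting binned '+' counts.
    """
    from .design import TrialCondition
    from .observer import simulate_trial
    from .stimgen import DEFAULT_GEOMETRY, realize_stimulus

    geometry = DEFAULT_GEOMETRY if geometry is None else geometry
    state = {"call": 0}

    def probe(dim: str, mean_value: float):
        from .design import DIMENSIONS, LEVEL_FACTORS

        state["call"] += 1
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, state["call"], params.seed % (2**31)])
        )
        # the probed dimension is recentred on the candidate mean; the other
        # accumulated dimensions stay at the observer's session means
        means = dict(params.prior_mean)
        means[dim] = mean_value
        levels = magnitude_levels(mean_value)
        others = tuple(d for d in DIMENSIONS if d != dim)
        n_plus, n_total = [], []
        for lf in LEVEL_FACTORS:
            plus = 0
            for _ in range(n_per_level):
                cond = TrialCondition(
                    1, dim, lf, ((others[0], "mean"), (others[1], "mean")), "linear"
                )
                stim = realize_stimulus(cond, means, geometry, rng, place=False)
                rec = simulate_trial(cond, stim, params, means, rng)
                plus += rec.categorical == "plus"
            n_plus.append(plus)
            n_total.append(n_per_level)
        return levels, n_plus, n_total

    return probe
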