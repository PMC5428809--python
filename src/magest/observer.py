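"""Synthetic Bayesian observer producing continuous slider estimates.

The observer combines a noisy sensory measurement with a per-dimension
Gaussian prior (posterior mean = precision-weighted average), which yields
the central-tendency effect: estimates regress toward the prior mean with
an effective slope w = sigma_p^2 / (sigma_p^2 + sigma_s^2) < 1.

Numerosity and surface are accumulated quantities.  With rate coupling
enabled, the observer estimates them as (accumulation rate) x (perceived
duration): the rate is read off the event table with an exponential
primacy window (early evidence weighs more), and the perceived duration is
itself a posterior combination biased toward the duration prior.  Two
interference signatures follow structurally:

* a short (long) trial duration is over- (under-) estimated, inflating
  (deflating) numerosity and surface estimates — while duration estimates
  themselves are immune to numerosity/surface manipulations;
* front-loaded (fast-slow) evidence raises the primacy-weighted rate and
  hence numerosity/surface estimates relative to back-loaded (slow-fast)
  delivery, while duration is again unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DEFAULT_MEANS, TrialSchedule, magnitude_levels
from .stimgen import DEFAULT_GEOMETRY, GeometryConfig, StimulusRealization, realize_stimulus

ACCUMULATED_DIMS = ("numerosity", "surface")


@dataclass
class ObserverParams:
    """Per-dimension priors and noise of one synthetic participant.

    prior_mean / prior_sd : Gaussian prior per dimension (stimulus units).
    sensory_cv            : coefficient of variation of the noisy sensory
                            measurement (scalar noise: sd scales with magnitude).
    rate_coupling         : estimate N and S as primacy-weighted rate x
                            perceived duration (the interference pathway).
    primacy_halflife_frac : half-life of the rate-reading window as a
                            fraction of trial duration, in (0, 1].
    lapse_rate            : probability of a uniform random slider response.
    log_space             : combine prior and likelihood on log magnitude
                            (off by default; the slider analysis is linear).
    """

    prior_mean: dict[str, float]
    prior_sd: dict[str, float]
    sensory_cv: dict[str, float]
    rate_coupling: bool = True
    primacy_halflife_frac: float = 0.5
    lapse_rate: float = 0.02
    log_space: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for d, v in self.prior_sd.items():
            if not v > 0:
                raise ValueError(f"prior_sd[{d}] must be positive")
        for d, v in self.sensory_cv.items():
            if not v > 0:
                raise ValueError(f"sensory_cv[{d}] must be positive")
        if not 0 < self.primacy_halflife_frac <= 1:
            raise ValueError("primacy_halflife_frac must lie in (0, 1]")
        if not 0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")

    @classmethod
    def default(
        cls,
        means: dict[str, float] | None = None,
        prior_width_frac: float = 0.25,
        sensory_cv: float = 0.15,
        **kwargs,
    ) -> "ObserverParams":
        """Observer centred on the session means (priors 25 % wide, cv 0.15)."""
        means = DEFAULT_MEANS if means is None else means
        return cls(
            prior_mean=dict(means),
            prior_sd={d: prior_width_frac * m for d, m in means.items()},
            sensory_cv={d: sensory_cv for d in means},
            **kwargs,
        )


@dataclass
class ResponseRecord:
    """One trial's continuous estimate and its categorical binning."""

    trial_id: int
    target: str
    true_magnitude: float
    estimate_percent: float  # magnitude convention: 0 = smallest, 100 = largest
    categorical: str  # 'plus' | 'minus'
    polarity: str  # 'plus_top' | 'plus_bottom'


def _posterior_mean(x: float, mu_p: float, sd_p: float, sd_s: float) -> float:
    w = sd_p**2 / (sd_p**2 + sd_s**2)
    return w * x + (1.0 - w) * mu_p


def perceive_duration(d_true: float, params: ObserverParams, seed) -> float:
    """Perceived trial duration: noisy measurement shrunk toward the prior.

    x ~ Normal(D, (cv * D)^2); returns w x + (1 - w) mu_p with
    w = sigma_p^2 / (sigma_p^2 + (cv * D)^2).
    """
    if d_true <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cv = params.sensory_cv["duration"]
    mu_p, sd_p = params.prior_mean["duration"], params.prior_sd["duration"]
    if params.log_space:
        x = rng.normal(math.log(d_true), cv)
        return math.exp(_posterior_mean(x, math.log(mu_p), sd_p / mu_p, cv))
    sd_s = cv * d_true
    x = rng.normal(d_true, sd_s)
    return _posterior_mean(x, mu_p, sd_p, sd_s)


def primacy_weighted_rate(
    onsets_ms: np.ndarray,
    quantities: np.ndarray,
    d_ms: float,
    halflife_frac: float,
) -> float:
    """Accumulation rate (quantity per ms) with exponential primacy weighting.

    Evidence at time t is weighted exp(-t ln2 / (halflife_frac * D)); the
    weighted sum is normalized by the integral of the weight over [0, D], so
    a temporally uniform stream returns its true average rate unbiased while
    front-loaded (back-loaded) streams read out high (low).
    """
    lam = math.log(2.0) / (halflife_frac * d_ms)
    window = (1.0 - math.exp(-lam * d_ms)) / lam
    return float(np.sum(quantities * np.exp(-lam * np.asarray(onsets_ms)))) / window


def perceive_accumulated(
    m_true: float,
    d_true: float,
    stim: StimulusRealization,
    dim: str,
    params: ObserverParams,
    seed,
) -> float:
    """Perceived numerosity or surface for one trial.

    With rate coupling the sensory magnitude is (primacy-weighted rate) x
    (perceived duration); without it, the true magnitude.  Either way the
    measurement is perturbed with cv-scaled Gaussian noise and shrunk toward
    the dimension's prior.
    """
    if dim not in ACCUMULATED_DIMS:
        raise ValueError(f"dim must be one of {ACCUMULATED_DIMS}")
    if not stim.events:
        raise ValueError("empty event table: nothing to accumulate")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if params.rate_coupling:
        q = np.ones(len(stim.events)) if dim == "numerosity" else stim.areas_mm2
        rate = primacy_weighted_rate(
            stim.onsets_ms, q, d_true, params.primacy_halflife_frac
        )
        d_hat = perceive_duration(d_true, params, rng)
        m_sens = rate * d_hat
    else:
        m_sens = m_true

    cv = params.sensory_cv[dim]
    mu_p, sd_p = params.prior_mean[dim], params.prior_sd[dim]
    if params.log_space:
        x = rng.normal(math.log(max(m_sens, 1e-12)), cv)
        return math.exp(_posterior_mean(x, math.log(mu_p), sd_p / mu_p, cv))
    sd_s = cv * m_sens
    x = rng.normal(m_sens, sd_s)
    return max(_posterior_mean(x, mu_p, sd_p, sd_s), 0.0)


def respond(
    estimate: float,
    dim_levels: list[float],
    polarity: str,
    lapse: float,
    seed,
    trial_id: int = 0,
    target: str = "",
    true_magnitude: float = float("nan"),
) -> ResponseRecord:
    """Map a perceived magnitude onto the 0-100 slider and bin it.

    The smallest level maps to 0 and the largest to 100 (magnitude
    convention); out-of-range percepts clip to the scale ends.  With
    probability ``lapse`` the response is replaced by a uniform draw.
    """
    from .psychofit import binarize  # local import to avoid a cycle

    if len(dim_levels) < 2:
        raise ValueError("need at least 2 levels to anchor the slider")
    levels = sorted(dim_levels)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pct = 100.0 * (estimate - levels[0]) / (levels[-1] - levels[0])
    pct = float(np.clip(pct, 0.0, 100.0))
    if lapse > 0 and rng.uniform() < lapse:
        pct = float(rng.uniform(0.0, 100.0))
    slider = pct if polarity == "plus_top" else 100.0 - pct
    return ResponseRecord(
        trial_id=trial_id,
        target=target,
        true_magnitude=true_magnitude,
        estimate_percent=pct,
        categorical=binarize(slider, polarity),
        polarity=polarity,
    )


def simulate_trial(
    cond,
    stim: StimulusRealization,
    params: ObserverParams,
    means: dict[str, float],
    rng: np.random.Generator,
    trial_id: int = 0,
) -> ResponseRecord:
    """One stimulus -> one slider response."""
    mags = cond.resolve_magnitudes(means)
    m_true = mags[cond.target]
    d_true = mags["duration"]
    if cond.target == "duration":
        est = perceive_duration(d_true, params, rng)
    else:
        est = perceive_accumulated(m_true, d_true, stim, cond.target, params, rng)
    polarity = "plus_top" if rng.uniform() < 0.5 else "plus_bottom"
    levels = magnitude_levels(means[cond.target])
    return respond(
        est, levels, polarity, params.lapse_rate, rng,
        trial_id=trial_id, target=cond.target, true_magnitude=m_true,
    )


def simulate_session(
    schedule: TrialSchedule,
    params: ObserverParams,
    means: dict[str, float] | None = None,
    geometry: GeometryConfig = DEFAULT_GEOMETRY,
    place: bool = False,
) -> pd.DataFrame:
    """Run one observer through a whole schedule.

    Fully deterministic given (schedule.seed, params.seed).  By default
    stimuli are realized without spatial placement (the observer reads only
    onsets and dot areas); pass ``place=True`` for full realizations.
    """
    means = DEFAULT_MEANS if means is None else means
    ss = np.random.SeedSequence([schedule.seed % (2**31), params.seed % (2**31)])
    children = ss.spawn(len(schedule.trials))
    rows = []
    for i, cond in enumerate(schedule.trials):
        rng = np.random.default_rng(children[i])
        stim = realize_stimulus(cond, means, geometry, rng, place=place)
        rec = simulate_trial(cond, stim, params, means, rng, trial_id=i)
        nts = sorted(cond.nontarget_settings)
        rows.append(
            {
                "trial_id": i,
                "block": schedule.block_ids[i] if schedule.block_ids else 1,
                "experiment": cond.experiment,
                "target": cond.target,
                "condition": cond.condition,
                "level_factor": cond.level_factor,
                "regime": cond.regime,
                "nontarget_dim_1": nts[0][0],
                "nontarget_setting_1": nts[0][1],
                "nontarget_dim_2": nts[1][0],
                "nontarget_setting_2": nts[1][1],
                "true_magnitude": rec.true_magnitude,
                "estimate_percent": rec.estimate_percent,
                "categorical": rec.categorical,
                "polarity": rec.polarity,
            }
        )
    return pd.DataFrame(rows)


def sample_cohort(
    n_participants: int,
    seed: int,
    means: dict[str, float] | None = None,
    base_cv: float = 0.15,
    prior_width_frac: float = 0.25,
    between_sd: float = 0.35,
    loadings: dict[str, float] | None = None,
    **observer_kwargs,
) -> list[ObserverParams]:
    """Draw a cohort of observers with correlated individual sensitivities.

    Each participant's sensory cv per dimension is log-normally scaled by a
    latent factor with dimension loadings (duration and numerosity load
    strongly on a shared factor, surface weakly), so the degree of central
    tendency is correlated across participants more tightly between D and N
    than between either and S — the generative structure behind the
    slope-correlation analyses.
    """
    means = DEFAULT_MEANS if means is None else means
    loadings = {"duration": 0.9, "numerosity": 0.9, "surface": 0.55} if loadings is None else loadings
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_participants)
    cohort = []
    for p in range(n_participants):
        shared = rng.normal()
        cvs = {}
        for d in means:
            lam = loadings[d]
            z = lam * shared + math.sqrt(1.0 - lam**2) * rng.normal()
            cvs[d] = base_cv * math.exp(between_sd * z)
        cohort.append(
            ObserverParams(
                prior_mean=dict(means),
                prior_sd={d: prior_width_frac * m for d, m in means.items()},
                sensory_cv=cvs,
                seed=int(seeds[p]),
                **observer_kwargs,
            )
        )
    return cohort
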