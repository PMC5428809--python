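"""End-to-end pipeline: design -> stimuli -> observers -> fits -> statistics.

One configuration object drives a fully seeded run: enumerate the design,
schedule it, simulate a cohort of synthetic observers, fit the categorical
psychometrics (PSE/WR) and the continuous central-tendency regressions per
participant and condition, and run the slope-correlation statistics.  Every
stage can also consume real response tables in the documented CSV schema.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as dsg
from . import observer as obs
from . import psychofit as pf
from . import stats as st
from . import tendency as td
from .stimgen import DEFAULT_GEOMETRY, GeometryConfig


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one simulated experiment."""

    experiment: int = 1
    cohort_size: int = 17
    design_seed: int = 1
    observer_seed: int = 2
    means: dict = field(default_factory=lambda: dict(dsg.DEFAULT_MEANS))
    first_regime: str = "fastslow"
    rate_coupling: bool = True
    primacy_halflife_frac: float = 0.5
    lapse_rate: float = 0.02
    base_cv: float = 0.15
    prior_width_frac: float = 0.25
    between_sd: float = 0.35
    place_dots: bool = False
    gof_rule: str = "less"
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def fits_table(responses: pd.DataFrame, means: dict) -> pd.DataFrame:
    """Per (participant, target, regime, condition) psychometric fits.

    Bins the continuous estimates, counts '+' per level, and fits the
    logistic; unusable fits are kept with ``converged=False``.
    """
    rows = []
    keys = ["participant", "target", "regime", "condition"]
    for (pid, target, regime, condition), grp in responses.groupby(keys, sort=True):
        levels = dsg.magnitude_levels(means[target])
        n_plus, n_total = [], []
        for lf in dsg.LEVEL_FACTORS:
            sub = grp[np.isclose(grp["level_factor"], lf)]
            n_plus.append(int((sub["categorical"] == "plus").sum()))
            n_total.append(len(sub))
        fit = pf.PsychometricModel(levels, n_plus, n_total).fit()
        top_prop = n_plus[-1] / n_total[-1] if n_total[-1] else np.nan
        rows.append(
            {
                "participant": pid,
                "target": target,
                "regime": regime,
                "condition": condition,
                "pse": fit.mu,
                "wr": fit.wr if (fit.converged and fit.mu > 0) else np.nan,
                "gof_p": fit.gof_p,
                "n": fit.n_trials,
                "converged": fit.converged,
                "top_plus_prop": top_prop,
            }
        )
    return pd.DataFrame(rows)


def apply_outlier_replacement(
    fits: pd.DataFrame, metrics: tuple[str, ...] = ("pse", "wr")
) -> tuple[pd.DataFrame, dict]:
    """2-SD group-mean replacement of PSE/WR within each condition cell."""
    out = fits.copy()
    counts: dict[str, int] = {}
    for metric in metrics:
        total = 0
        for key, grp in out.groupby(["target", "regime", "condition"], sort=True):
            vals = grp[metric].to_numpy(dtype=float)
            if len(vals) < 3 or np.isnan(vals).any():
                continue
            new, k = pf.outlier_replace(vals)
            out.loc[grp.index, metric] = new
            total += k
        counts[metric] = total
    return out, counts


def _simulate_cohort(config: PipelineConfig) -> tuple[pd.DataFrame, dsg.TrialSchedule]:
    conditions = dsg.enumerate_design(config.experiment)
    schedule = dsg.make_schedule(conditions, config.design_seed, config.first_regime)
    cohort = obs.sample_cohort(
        config.cohort_size,
        config.observer_seed,
        means=config.means,
        base_cv=config.base_cv,
        prior_width_frac=config.prior_width_frac,
        between_sd=config.between_sd,
        rate_coupling=config.rate_coupling,
        primacy_halflife_frac=config.primacy_halflife_frac,
        lapse_rate=config.lapse_rate,
    )
    frames = []
    for p, params in enumerate(cohort):
        df = obs.simulate_session(
            schedule, params, config.means, DEFAULT_GEOMETRY, place=config.place_dots
        )
        df.insert(0, "participant", p)
        frames.append(df)
    return pd.concat(frames, ignore_index=True), schedule


def _mean_pse(fits: pd.DataFrame, target: str, condition: str, regime=None) -> float:
    sub = fits[(fits["target"] == target) & (fits["condition"] == condition)]
    if regime is not None:
        sub = sub[sub["regime"] == regime]
    return float(sub["pse"].mean())


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and optionally write) the aggregate report."""
    responses, schedule = _simulate_cohort(config)

    fits = fits_table(responses, config.means)
    fits, replaced = apply_outlier_replacement(fits)

    controls = {}
    for pid, grp in fits[fits["condition"] == "control"].groupby("participant"):
        controls[pid] = {
            row["target"]: {"top_plus_prop": row["top_plus_prop"], "gof_p": row["gof_p"]}
            for _, row in grp.iterrows()
        }
    kept, dropped = pf.exclude_participants(controls, gof_rule=config.gof_rule)

    slopes = td.tendency_table(responses, by=("participant", "target", "regime", "condition"))
    collapsed = td.tendency_table(responses, by=("participant", "target"))

    wide = collapsed.pivot(index="participant", columns="target", values="slope")
    triplet = st.CorrelationTriplet(
        r_dn=float(wide["duration"].corr(wide["numerosity"])),
        r_ds=float(wide["duration"].corr(wide["surface"])),
        r_ns=float(wide["numerosity"].corr(wide["surface"])),
        n=len(wide),
    ) if len(wide) >= 4 else None

    report: dict = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "n_trials": len(schedule),
        "cohort_size": config.cohort_size,
        "excluded": {str(k): v for k, v in dropped.items()},
        "outliers_replaced": replaced,
        "mean_slope": {
            t: float(collapsed[collapsed["target"] == t]["slope"].mean())
            for t in dsg.DIMENSIONS
        },
    }

    if triplet is not None:
        z_dn_ds = st.fisher_z_diff(triplet.r_dn, triplet.r_ds, triplet.n, triplet.n)
        z_dn_ns = st.fisher_z_diff(triplet.r_dn, triplet.r_ns, triplet.n, triplet.n)
        report["slope_correlations"] = {
            "r_dn": triplet.r_dn,
            "r_ds": triplet.r_ds,
            "r_ns": triplet.r_ns,
            "n": triplet.n,
            "z_dn_vs_ds": z_dn_ds.z,
            "p_dn_vs_ds": z_dn_ds.p,
            "z_dn_vs_ns": z_dn_ns.z,
            "p_dn_vs_ns": z_dn_ns.p,
            "partial_dn_given_s": st.partial_corr(triplet.r_dn, triplet.r_ds, triplet.r_ns),
            "partial_ns_given_d": st.partial_corr(triplet.r_ns, triplet.r_dn, triplet.r_ds),
        }

    if config.experiment == 1:
        pse_summary = {
            t: {
                c: _mean_pse(fits, t, c)
                for c in sorted(fits[fits["target"] == t]["condition"].unique())
            }
            for t in dsg.DIMENSIONS
        }
        report["mean_pse"] = pse_summary
        report["flags"] = {
            "pse_n_dmin_lt_dmax": pse_summary["numerosity"]["duration_min"]
            < pse_summary["numerosity"]["duration_max"],
            "pse_s_dmin_lt_dmax": pse_summary["surface"]["duration_min"]
            < pse_summary["surface"]["duration_max"],
            "duration_shift_small": _duration_shift_small(fits, config.means),
        }
    else:
        pse_summary = {
            t: {
                f"{reg}:{c}": _mean_pse(fits, t, c, reg)
                for reg in ("fastslow", "slowfast")
                for c in sorted(
                    fits[(fits["target"] == t) & (fits["regime"] == reg)]["condition"].unique()
                )
            }
            for t in dsg.DIMENSIONS
        }
        report["mean_pse"] = pse_summary
        report["flags"] = {
            # overestimation => lower PSE, so FastSlow < SlowFast for N and S
            "pse_n_fs_lt_sf": pse_summary["numerosity"]["fastslow:control"]
            < pse_summary["numerosity"]["slowfast:control"],
            "pse_s_fs_lt_sf": pse_summary["surface"]["fastslow:control"]
            < pse_summary["surface"]["slowfast:control"],
            "duration_regime_shift_small": abs(
                pse_summary["duration"]["fastslow:control"]
                - pse_summary["duration"]["slowfast:control"]
            )
            < 0.05 * config.means["duration"],
        }

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        schedule.to_csv(out / "schedule.csv")
        responses.to_csv(out / "responses.csv", index=False)
        fits.to_csv(out / "fits.csv", index=False)
        slopes.to_csv(out / "tendency.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _duration_shift_small(fits: pd.DataFrame, means: dict, frac: float = 0.05) -> bool:
    base = _mean_pse(fits, "duration", "control")
    ok = True
    for c in fits[fits["target"] == "duration"]["condition"].unique():
        if c == "control":
            continue
        ok &= abs(_mean_pse(fits, "duration", c) - base) < frac * means["duration"]
    return bool(ok)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
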