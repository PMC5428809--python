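"""Factorial designs and trial schedules for the two magnitude-estimation experiments.

Experiment 1 crosses three target dimensions (duration D, numerosity N,
surface S) with five non-target conditions (control plus each other
dimension at its minimal or maximal value) under a linear evidence
accumulation regime.  Experiment 2 manipulates the accumulation regime
(fast-slow vs slow-fast) and the non-target duration for N and S only;
duration itself is tested only in the control condition.

Every tested dimension takes six values: 75, 90, 95, 105, 110 and 125 %
of its session mean.  Each design cell is repeated 12 times.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LEVEL_FACTORS: tuple[float, ...] = (0.75, 0.90, 0.95, 1.05, 1.10, 1.25)
DIMENSIONS: tuple[str, ...] = ("duration", "numerosity", "surface")
REGIMES: tuple[str, ...] = ("linear", "fastslow", "slowfast")
REPETITIONS: int = 12

#: min / max of a non-target dimension are its extreme levels (0.75x, 1.25x)
NONTARGET_FACTORS: dict[str, float] = {"min": 0.75, "mean": 1.0, "max": 1.25}

#: session means after difficulty calibration (ms, dots, mm^2)
DEFAULT_MEANS: dict[str, float] = {"duration": 800.0, "numerosity": 32.0, "surface": 476.0}
#: pre-calibration starting values used by the calibration loop
INITIAL_MEANS: dict[str, float] = {"duration": 800.0, "numerosity": 30.0, "surface": 432.0}


class DesignError(ValueError):
    """Invalid design request (unknown experiment, empty schedule, ...)."""


@dataclass(frozen=True)
class MagnitudeDimension:
    """A magnitude dimension and its session mean (ms / dots / mm^2)."""

    name: str
    mean_value: float

    def __post_init__(self) -> None:
        if self.name not in DIMENSIONS:
            raise DesignError(f"unknown dimension {self.name!r}")
        if not self.mean_value > 0:
            raise DesignError("mean_value must be positive")


@dataclass(frozen=True, order=True)
class TrialCondition:
    """One design cell: what is judged, what is manipulated, and how dots accumulate."""

    experiment: int
    target: str
    level_factor: float
    nontarget_settings: tuple[tuple[str, str], ...]  # ((dim, 'min'|'mean'|'max'), ...)
    regime: str
    repetition_index: int = 1

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise DesignError(f"unknown experiment {self.experiment!r}")
        if self.target not in DIMENSIONS:
            raise DesignError(f"unknown target {self.target!r}")
        if self.level_factor not in LEVEL_FACTORS:
            raise DesignError(f"level_factor {self.level_factor!r} not a design level")
        if self.regime not in REGIMES:
            raise DesignError(f"unknown regime {self.regime!r}")

    @property
    def condition(self) -> str:
        """Condition label: 'control' or '<nontarget>_<min|max>'."""
        for dim, setting in self.nontarget_settings:
            if setting != "mean":
                return f"{dim}_{setting}"
        return "control"

    def resolve_magnitudes(self, means: dict[str, float] | None = None) -> dict[str, float]:
        """Concrete (D, N, S) values for this cell given the session means."""
        means = DEFAULT_MEANS if means is None else means
        out = {self.target: means[self.target] * self.level_factor}
        for dim, setting in self.nontarget_settings:
            out[dim] = means[dim] * NONTARGET_FACTORS[setting]
        return out


@dataclass
class TrialSchedule:
    """A seeded, pseudo-randomized ordering of trial conditions.

    ``block_ids`` runs parallel to ``trials``; Experiment 2 schedules carry a
    ten-block structure alternating between the two accumulation regimes.
    """

    trials: list[TrialCondition]
    seed: int
    block_structure: list[tuple[int, str]] = field(default_factory=list)
    block_ids: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, cond in enumerate(self.trials):
            nts = sorted(cond.nontarget_settings)
            rows.append(
                {
                    "experiment": cond.experiment,
                    "block": self.block_ids[i] if self.block_ids else 1,
                    "trial_index": i,
                    "target": cond.target,
                    "level_factor": cond.level_factor,
                    "regime": cond.regime,
                    "nontarget_dim_1": nts[0][0],
                    "nontarget_setting_1": nts[0][1],
                    "nontarget_dim_2": nts[1][0],
                    "nontarget_setting_2": nts[1][1],
                    "repetition_index": cond.repetition_index,
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialSchedule":
        trials, block_ids = [], []
        for _, row in df.iterrows():
            trials.append(
                TrialCondition(
                    experiment=int(row["experiment"]),
                    target=row["target"],
                    level_factor=float(row["level_factor"]),
                    nontarget_settings=(
                        (row["nontarget_dim_1"], row["nontarget_setting_1"]),
                        (row["nontarget_dim_2"], row["nontarget_setting_2"]),
                    ),
                    regime=row["regime"],
                    repetition_index=int(row.get("repetition_index", 1)),
                )
            )
            block_ids.append(int(row["block"]))
        seed = int(df["seed"].iloc[0]) if len(df) else 0
        blocks: list[tuple[int, str]] = []
        for b, t in zip(block_ids, trials):
            if not blocks or blocks[-1][0] != b:
                blocks.append((b, t.regime))
        return cls(trials=trials, seed=seed, block_structure=blocks, block_ids=block_ids)

    @classmethod
    def from_csv(cls, path) -> "TrialSchedule":
        return cls.from_frame(pd.read_csv(path))


def magnitude_levels(mean_value: float) -> list[float]:
    """The six tested magnitudes: 75, 90, 95, 105, 110 and 125 % of the mean."""
    if not mean_value > 0:
        raise DesignError("mean_value must be positive")
    return [mean_value * f for f in LEVEL_FACTORS]


def _others(target: str) -> tuple[str, str]:
    return tuple(d for d in DIMENSIONS if d != target)  # type: ignore[return-value]


def enumerate_design(experiment: int) -> list[TrialCondition]:
    """All trials of the requested experiment, one ``TrialCondition`` each.

    Experiment 1: 3 dimensions x 5 conditions x 6 levels x 12 repetitions = 1080.
    Experiment 2: 144 duration + 432 numerosity + 432 surface trials = 1008,
    each cell under both the fast-slow and slow-fast regimes.
    """
    if experiment not in (1, 2):
        raise DesignError(f"unknown experiment {experiment!r}; expected 1 or 2")

    conditions: list[TrialCondition] = []

    def cells(target: str) -> list[tuple[tuple[str, str], ...]]:
        a, b = _others(target)
        out = [((a, "mean"), (b, "mean"))]
        for manip in (a, b):
            other = b if manip == a else a
            for setting in ("min", "max"):
                out.append(tuple(sorted([(manip, setting), (other, "mean")])))
        return out

    if experiment == 1:
        for target in DIMENSIONS:
            for nts in cells(target):
                for level in LEVEL_FACTORS:
                    for rep in range(1, REPETITIONS + 1):
                        conditions.append(
                            TrialCondition(1, target, level, tuple(nts), "linear", rep)
                        )
    else:
        for regime in ("fastslow", "slowfast"):
            for target in DIMENSIONS:
                if target == "duration":
                    # control only: no N/S interference cells for duration
                    nts_list = [(("numerosity", "mean"), ("surface", "mean"))]
                else:
                    other = "surface" if target == "numerosity" else "numerosity"
                    nts_list = [
                        tuple(sorted([("duration", s), (other, "mean")]))
                        for s in ("mean", "min", "max")
                    ]
                for nts in nts_list:
                    for level in LEVEL_FACTORS:
                        for rep in range(1, REPETITIONS + 1):
                            conditions.append(
                                TrialCondition(2, target, level, tuple(nts), regime, rep)
                            )
    return conditions


def make_schedule(
    conditions: list[TrialCondition],
    seed: int,
    first_regime: str = "fastslow",
) -> TrialSchedule:
    """Pseudo-randomize a condition list into a seeded schedule.

    Experiment 1 trials are fully interleaved.  Experiment 2 trials are dealt
    into ten blocks (five per regime, sizes equal up to 1) that alternate
    between regimes, starting with ``first_regime`` (counterbalancing hook).
    """
    if not conditions:
        raise DesignError("cannot schedule an empty condition list")
    rng = np.random.default_rng(seed)
    regimes = sorted({c.regime for c in conditions})

    if regimes == ["fastslow", "slowfast"]:
        if first_regime not in regimes:
            raise DesignError(f"first_regime must be one of {regimes}")
        second = "slowfast" if first_regime == "fastslow" else "fastslow"
        per_regime = {}
        for reg in (first_regime, second):
            idx = [i for i, c in enumerate(conditions) if c.regime == reg]
            rng.shuffle(idx)
            per_regime[reg] = [list(a) for a in np.array_split(idx, 5)]
        trials, block_ids, block_structure = [], [], []
        for b in range(10):
            reg = first_regime if b % 2 == 0 else second
            block = per_regime[reg][b // 2]
            block_structure.append((b + 1, reg))
            for i in block:
                trials.append(conditions[i])
                block_ids.append(b + 1)
        return TrialSchedule(trials, seed, block_structure, block_ids)

    order = rng.permutation(len(conditions))
    trials = [conditions[i] for i in order]
    return TrialSchedule(trials, seed, [(1, regimes[0])], [1] * len(trials))
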