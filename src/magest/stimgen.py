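"""Dynamic dot-cloud stimulus simulation.

One trial is a cloud of short-lived grey dots inside an annulus around
fixation.  A trial is characterized by its duration D (ms), its numerosity
N (cumulative dot count) and its surface S (cumulative area covered by the
dots over the whole trial, mm^2).  Dots are delivered under one of three
accumulation regimes:

* ``linear`` — 2 to 7 dots at a time in 9 to 13 iterations, so the
  cumulative count grows roughly proportionally with time;
* ``fastslow`` — a fraction drawn uniformly from 75 +/- 10 % of the dots
  appears within the first quarter of the trial;
* ``slowfast`` — a fraction drawn uniformly from 25 +/- 10 % of the dots
  appears within the first three quarters of the trial (the remainder is
  packed into the final quarter).

Onsets are quantized to the monitor frame grid (85 Hz) and dot lifetimes
to whole frames inside [35, 294] ms, truncated so every dot extinguishes
before the trial ends.  Simultaneously visible dots never overlap
spatially; placement is by seeded rejection sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import TrialCondition, DEFAULT_MEANS


class StimulusError(RuntimeError):
    """Infeasible stimulus request or exhausted placement budget."""


@dataclass(frozen=True)
class GeometryConfig:
    """Display geometry and dot parameter ranges.

    ``outer_diameter_deg`` may be None, in which case each realization draws
    it uniformly from ``outer_diameter_deg_range`` (the virtual disk varied
    from trial to trial).
    """

    outer_diameter_deg: float | None = None
    outer_diameter_deg_range: tuple[float, float] = (12.3, 15.2)
    inner_diameter_deg: float = 3.3
    dot_diameter_deg_range: tuple[float, float] = (0.35, 1.14)
    dot_duration_ms_range: tuple[float, float] = (35.0, 294.0)
    refresh_hz: float = 85.0
    viewing_distance_cm: float = 60.0
    screen_px: tuple[int, int] = (1024, 768)
    luminance_set: tuple[int, ...] = (57, 64, 73, 85, 102, 128)

    def __post_init__(self) -> None:
        if self.refresh_hz <= 0:
            raise ValueError("refresh_hz must be positive")
        lo, hi = self.outer_diameter_deg_range
        inner = self.inner_diameter_deg
        outer = self.outer_diameter_deg if self.outer_diameter_deg is not None else lo
        if inner >= outer:
            raise ValueError("inner disk must be smaller than outer disk")
        for a, b in (self.dot_diameter_deg_range, self.dot_duration_ms_range):
            if not a < b:
                raise ValueError("ranges must be non-degenerate")

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.refresh_hz

    def duration_frames(self) -> tuple[int, int]:
        """Feasible dot lifetimes in whole frames inside the ms range."""
        lo, hi = self.dot_duration_ms_range
        fmin = math.ceil(lo / self.frame_ms - 1e-9)
        fmax = math.floor(hi / self.frame_ms + 1e-9)
        return max(fmin, 1), fmax


DEFAULT_GEOMETRY = GeometryConfig()


def deg_to_mm(deg: float, viewing_distance_cm: float = 60.0) -> float:
    """Visual angle to millimetres on the screen plane."""
    return 10.0 * viewing_distance_cm * math.tan(math.radians(deg))


def mm_to_deg(mm: float, viewing_distance_cm: float = 60.0) -> float:
    return math.degrees(math.atan(mm / (10.0 * viewing_distance_cm)))


def dot_area_mm2(diameter_deg: float, viewing_distance_cm: float = 60.0) -> float:
    d_mm = deg_to_mm(diameter_deg, viewing_distance_cm)
    return math.pi * (d_mm / 2.0) ** 2


@dataclass
class DotEvent:
    """One dot: when it appears, how long it lives, where, how big, how bright."""

    onset_ms: float
    duration_ms: float
    x_deg: float
    y_deg: float
    diameter_deg: float
    luminance: int

    def area_mm2(self, viewing_distance_cm: float = 60.0) -> float:
        return dot_area_mm2(self.diameter_deg, viewing_distance_cm)

    def overlaps_time(self, other: "DotEvent") -> bool:
        return (self.onset_ms < other.onset_ms + other.duration_ms) and (
            other.onset_ms < self.onset_ms + self.duration_ms
        )


@dataclass
class StimulusRealization:
    """A fully realized trial stimulus with its target (D, N, S) spec."""

    d_ms: float
    n_count: int
    s_mm2: float
    regime: str
    events: list[DotEvent]
    realized_surface_mm2: float
    outer_diameter_deg: float
    geometry: GeometryConfig = field(default_factory=lambda: DEFAULT_GEOMETRY)

    @property
    def onsets_ms(self) -> np.ndarray:
        return np.array([e.onset_ms for e in self.events])

    @property
    def areas_mm2(self) -> np.ndarray:
        dist = self.geometry.viewing_distance_cm
        return np.array([e.area_mm2(dist) for e in self.events])

    def to_frame(self, trial_id=0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": trial_id,
                "onset_ms": [e.onset_ms for e in self.events],
                "duration_ms": [e.duration_ms for e in self.events],
                "x_deg": [e.x_deg for e in self.events],
                "y_deg": [e.y_deg for e in self.events],
                "diameter_deg": [e.diameter_deg for e in self.events],
                "luminance": [e.luminance for e in self.events],
            }
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def onset_schedule(
    d_ms: float,
    n: int,
    regime: str,
    seed,
    geometry: GeometryConfig = DEFAULT_GEOMETRY,
) -> list[tuple[float, int]]:
    """Dot onset times for one trial as (iteration_time_ms, dots_in_iteration).

    Times are quantized to the frame grid and capped so that even a
    minimum-lifetime dot appearing at the last onset fits inside ``d_ms``.
    """
    if d_ms <= 0:
        raise StimulusError("trial duration must be positive")
    if n < 2:
        raise StimulusError("need at least 2 dots per trial")
    rng = _as_rng(seed)
    fm = geometry.frame_ms
    fmin_dur, _ = geometry.duration_frames()
    total_frames = math.floor(d_ms / fm + 1e-9)
    max_onset_frame = total_frames - fmin_dur
    if max_onset_frame < 1:
        raise StimulusError(f"duration {d_ms} ms too short for any dot lifetime")

    def frames_before(t_ms: float) -> int:
        # largest frame index whose onset is strictly before t_ms
        f = math.floor(t_ms / fm + 1e-9)
        if f * fm >= t_ms - 1e-9:
            f -= 1
        return f

    if regime == "linear":
        ks = [k for k in range(9, 14) if 2 * k <= n <= 7 * k]
        if not ks:
            raise StimulusError(
                f"N={n} infeasible for 9-13 iterations of 2-7 dots "
                f"(feasible N range is 18-91)"
            )
        k = int(rng.choice(ks))
        sizes = None
        for _ in range(1000):
            extra = rng.multinomial(n - 2 * k, [1.0 / k] * k)
            if extra.max() <= 5:
                sizes = 2 + extra
                break
        if sizes is None:  # deterministic fallback: as even as possible
            base, rem = divmod(n, k)
            sizes = np.array([base + (1 if i < rem else 0) for i in range(k)])
        frames = np.round(np.linspace(0, max_onset_frame, k)).astype(int)
        return [(f * fm, int(s)) for f, s in zip(frames, sizes)]

    if regime in ("fastslow", "slowfast"):
        if regime == "fastslow":
            frac_early = rng.uniform(0.65, 0.85)
            boundary = 0.25 * d_ms
        else:
            frac_early = rng.uniform(0.15, 0.35)
            boundary = 0.75 * d_ms
        n_early = int(np.clip(round(frac_early * n), 0, n))
        early_hi = frames_before(boundary)
        late_lo = early_hi + 1
        if early_hi < 0 or late_lo > max_onset_frame:
            raise StimulusError("trial too short for a two-segment regime")
        f_early = rng.integers(0, early_hi + 1, size=n_early)
        f_late = rng.integers(late_lo, max_onset_frame + 1, size=n - n_early)
        frames = np.concatenate([f_early, f_late])
        out: dict[int, int] = {}
        for f in frames:
            out[int(f)] = out.get(int(f), 0) + 1
        return [(f * fm, c) for f, c in sorted(out.items())]

    raise StimulusError(f"unknown regime {regime!r}")


def partition_surface(
    s_mm2: float,
    n: int,
    geometry: GeometryConfig = DEFAULT_GEOMETRY,
    seed=None,
) -> list[float]:
    """Split a cumulative surface target into N dot diameters (degrees).

    Diameters start uniform over the permitted range and are rescaled
    multiplicatively (with clipping at the range bounds) until the summed
    circle areas match ``s_mm2`` within 0.5 %.
    """
    if n < 1:
        raise StimulusError("need at least one dot")
    dist = geometry.viewing_distance_cm
    dlo, dhi = geometry.dot_diameter_deg_range
    amin, amax = dot_area_mm2(dlo, dist), dot_area_mm2(dhi, dist)
    if not (n * amin <= s_mm2 <= n * amax):
        raise StimulusError(
            f"surface {s_mm2:.1f} mm^2 infeasible for N={n}; "
            f"feasible interval is [{n * amin:.1f}, {n * amax:.1f}] mm^2"
        )
    rng = _as_rng(seed)
    diam_mm = np.array([deg_to_mm(d, dist) for d in rng.uniform(dlo, dhi, size=n)])
    areas = np.pi * (diam_mm / 2.0) ** 2
    for _ in range(100):
        total = areas.sum()
        if abs(total - s_mm2) <= 0.005 * s_mm2:
            break
        areas = np.clip(areas * (s_mm2 / total), amin, amax)
    else:
        raise StimulusError("surface partition failed to converge")
    diam_mm = 2.0 * np.sqrt(areas / np.pi)
    return [mm_to_deg(d, dist) for d in diam_mm]


def place_dots(
    events: list[DotEvent],
    geometry: GeometryConfig = DEFAULT_GEOMETRY,
    seed=None,
    max_attempts: int = 10_000,
    max_restarts: int = 20,
) -> list[DotEvent]:
    """Assign annulus positions so simultaneously visible dots never touch.

    Each dot lies wholly inside the outer disk and wholly outside the inner
    (fixation-protection) disk.  Rejection sampling; after ``max_attempts``
    failures on one dot the whole trial is restarted, at most
    ``max_restarts`` times.
    """
    rng = _as_rng(seed)
    outer = geometry.outer_diameter_deg
    if outer is None:
        outer = rng.uniform(*geometry.outer_diameter_deg_range)
    outer_r = outer / 2.0
    inner_r = geometry.inner_diameter_deg / 2.0

    for e in events:
        r = e.diameter_deg / 2.0
        if inner_r + r > outer_r - r:
            raise StimulusError(
                f"dot diameter {e.diameter_deg:.2f} deg cannot fit in the "
                f"{geometry.inner_diameter_deg}-{outer:.1f} deg annulus"
            )

    order = sorted(range(len(events)), key=lambda i: events[i].onset_ms)
    for restart in range(max_restarts + 1):
        placed: list[DotEvent] = []
        ok = True
        for i in order:
            e = events[i]
            r = e.diameter_deg / 2.0
            rlo, rhi = inner_r + r, outer_r - r
            for attempt in range(max_attempts):
                rad = math.sqrt(rng.uniform(rlo**2, rhi**2))
                theta = rng.uniform(0.0, 2.0 * math.pi)
                x, y = rad * math.cos(theta), rad * math.sin(theta)
                cand = replace(e, x_deg=x, y_deg=y)
                if all(
                    not cand.overlaps_time(p)
                    or math.hypot(x - p.x_deg, y - p.y_deg)
                    > r + p.diameter_deg / 2.0
                    for p in placed
                ):
                    placed.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            placed.sort(key=lambda e: e.onset_ms)
            return placed
    raise StimulusError(
        f"dot placement exhausted ({max_restarts} restarts x "
        f"{max_attempts} attempts) for a {len(events)}-dot trial"
    )


def realize_stimulus(
    condition: TrialCondition,
    means: dict[str, float] | None = None,
    geometry: GeometryConfig = DEFAULT_GEOMETRY,
    seed=None,
    place: bool = True,
) -> StimulusRealization:
    """Compose a full stimulus: onsets -> lifetimes -> sizes -> placement -> luminance.

    With ``place=False`` the spatial placement step is skipped (positions are
    NaN); onset times, lifetimes, diameters and luminances — everything the
    synthetic observer consumes — are produced identically.
    """
    means = DEFAULT_MEANS if means is None else means
    rng = _as_rng(seed)
    mags = condition.resolve_magnitudes(means)
    d_ms = float(mags["duration"])
    n = int(round(mags["numerosity"]))
    s_mm2 = float(mags["surface"])

    outer = geometry.outer_diameter_deg
    if outer is None:
        outer = float(rng.uniform(*geometry.outer_diameter_deg_range))
    geom = replace(geometry, outer_diameter_deg=outer)

    # Corner cells pairing a small surface target with a large dot count can
    # undershoot the preferred minimum dot size; shrink the lower diameter
    # bound just enough (10 % slack) so the surface target stays exact.
    dist = geom.viewing_distance_cm
    dlo, dhi = geom.dot_diameter_deg_range
    if s_mm2 < n * dot_area_mm2(dlo, dist):
        dlo = mm_to_deg(2.0 * math.sqrt((0.9 * s_mm2 / n) / math.pi), dist)
        geom = replace(geom, dot_diameter_deg_range=(dlo, dhi))

    fm = geom.frame_ms
    fmin_dur, fmax_dur = geom.duration_frames()
    total_frames = math.floor(d_ms / fm + 1e-9)

    sched = onset_schedule(d_ms, n, condition.regime, rng, geom)
    onsets = np.concatenate([[t] * c for t, c in sched])
    onset_frames = np.round(onsets / fm).astype(int)

    dur_frames = rng.integers(fmin_dur, fmax_dur + 1, size=n)
    dur_frames = np.minimum(dur_frames, total_frames - onset_frames)
    durations = np.minimum(dur_frames * fm, d_ms - onsets)

    diameters = partition_surface(s_mm2, n, geom, rng)
    lums = rng.choice(geom.luminance_set, size=n)

    events = [
        DotEvent(
            onset_ms=float(onsets[i]),
            duration_ms=float(durations[i]),
            x_deg=float("nan"),
            y_deg=float("nan"),
            diameter_deg=float(diameters[i]),
            luminance=int(lums[i]),
        )
        for i in range(n)
    ]
    if place:
        events = place_dots(events, geom, rng)

    realized = sum(e.area_mm2(geom.viewing_distance_cm) for e in events)
    return StimulusRealization(
        d_ms=d_ms,
        n_count=n,
        s_mm2=s_mm2,
        regime=condition.regime,
        events=events,
        realized_surface_mm2=realized,
        outer_diameter_deg=outer,
        geometry=geom,
    )
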