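"""Two-state master-equation analysis of receptor surface recycling.

The fraction ``f`` of a cell's receptors residing on the surface obeys

    df/dt = -kappa_endo * f + kappa_exo * (1 - f)

with per-receptor internalization rate ``kappa_endo`` and per-internal-
receptor delivery rate ``kappa_exo``.  The solution is

    f(t) = f_s + (f0 - f_s) * exp(-t / t_s)

with steady level ``f_s = kappa_exo / (kappa_endo + kappa_exo)`` and
characteristic (saturation) time ``t_s = 1 / (kappa_endo + kappa_exo)``.

This module provides those closed forms, the borders of the rate phase
space compatible with experimentally observed growth durations and steady
levels, the detectability-threshold line ``kappa_endo =
(1/f_c - 1) * kappa_exo`` below which clustering would escape detection,
and the occupancy-corrected effective endocytosis rate
``kappa'_endo = n * kappa_endo``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RatePair",
    "MasterEquationSolution",
    "PhaseSpaceSpec",
    "RateLine",
    "EffectiveRate",
    "REFERENCE_RATES",
    "DEFAULT_PHASE_SPACE",
    "steady_state_fraction",
    "characteristic_time",
    "solve",
    "solution",
    "ts_border_lines",
    "fs_border_lines",
    "threshold_line",
    "fs_min_from_ratio",
    "required_endo_rate",
    "required_exo_rate",
    "effective_endo_rate",
    "phase_space_raster",
]


@dataclass(frozen=True)
class RatePair:
    """Endocytosis / exocytosis rate pair, both in 1/s."""

    kappa_endo: float
    kappa_exo: float

    def __post_init__(self) -> None:
        if self.kappa_endo < 0 or self.kappa_exo < 0:
            raise ValueError("rates must be nonnegative")

    @property
    def total(self) -> float:
        return self.kappa_endo + self.kappa_exo


@dataclass(frozen=True)
class MasterEquationSolution:
    """Closed-form relaxation of the surface fraction."""

    f0: float
    f_s: float
    t_s: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be nonnegative")
        out = self.f_s + (self.f0 - self.f_s) * np.exp(-t / self.t_s)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RateLine:
    """Line ``a * kappa_endo + b * kappa_exo = c`` in the rate phase space."""

    a: float
    b: float
    c: float
    label: str = ""

    def evaluate(self, rates: RatePair) -> float:
        return self.a * rates.kappa_endo + self.b * rates.kappa_exo - self.c

    def contains(self, rates: RatePair, rtol: float = 1e-9) -> bool:
        scale = max(abs(self.a * rates.kappa_endo), abs(self.b * rates.kappa_exo), abs(self.c))
        return abs(self.evaluate(rates)) <= rtol * max(scale, 1e-300)


@dataclass(frozen=True)
class PhaseSpaceSpec:
    """Experimental bounds delimiting the rate phase space.

    ``ts_min``/``ts_max`` bound the observed growth-regime duration,
    ``fs_min``/``fs_max`` the steady saturation level, and ``fs_c`` is the
    smallest saturation level detectable in the imaging experiments.
    """

    ts_min: float
    ts_max: float
    fs_min: float
    fs_max: float
    fs_c: float

    def __post_init__(self) -> None:
        if not 0 < self.ts_min <= self.ts_max:
            raise ValueError("need 0 < ts_min <= ts_max")
        if not 0 < self.fs_min <= self.fs_max <= 1:
            raise ValueError("need 0 < fs_min <= fs_max <= 1")
        if not 0 < self.fs_c < self.fs_min:
            raise ValueError("need fs_c in (0, fs_min)")

    def in_ts_band(self, rates: RatePair) -> bool:
        return 1.0 / self.ts_max <= rates.total <= 1.0 / self.ts_min

    def in_fs_band(self, rates: RatePair) -> bool:
        return self.fs_min <= steady_state_fraction(rates) <= self.fs_max

    def in_cluster_forming_zone(self, rates: RatePair) -> bool:
        return self.in_ts_band(rates) and self.in_fs_band(rates)


@dataclass(frozen=True)
class EffectiveRate:
    """Occupancy-corrected endocytosis rate ``kappa'_endo = n * kappa_endo``."""

    n: float
    kappa_endo_eff: float


#: Representative rate pair in the bulk of the cluster-forming zone.
REFERENCE_RATES = RatePair(kappa_endo=1e-4, kappa_exo=0.5e-4)


def steady_state_fraction(rates: RatePair) -> float:
    """Steady surface fraction ``f_s = kappa_exo / (kappa_endo + kappa_exo)``."""
    if rates.total <= 0:
        raise ValueError("kappa_endo + kappa_exo must be positive")
    return rates.kappa_exo / rates.total


def characteristic_time(rates: RatePair) -> float:
    """Saturation time ``t_s = 1 / (kappa_endo + kappa_exo)`` in seconds."""
    if rates.total <= 0:
        raise ValueError("kappa_endo + kappa_exo must be positive")
    return 1.0 / rates.total


def solve(rates: RatePair, f0: float = 0.0) -> MasterEquationSolution:
    """Closed-form solution object for given rates and initial fraction."""
    if not 0 <= f0 <= 1:
        raise ValueError("f0 must lie in [0, 1]")
    return MasterEquationSolution(
        f0=float(f0),
        f_s=steady_state_fraction(rates),
        t_s=characteristic_time(rates),
    )


def solution(rates: RatePair, f0: float, t) -> float | np.ndarray:
    """Evaluate ``f(t) = f_s + (f0 - f_s) exp(-t/t_s)``."""
    return solve(rates, f0)(t)


def ts_border_lines(spec: PhaseSpaceSpec) -> tuple[RateLine, RateLine]:
    """Borders ``kappa_endo + kappa_exo = 1/ts_min`` and ``= 1/ts_max``.

    Rate pairs between the two lines relax on a timescale compatible with
    the observed growth-regime durations.
    """
    return (
        RateLine(1.0, 1.0, 1.0 / spec.ts_min, label="ts_min"),
        RateLine(1.0, 1.0, 1.0 / spec.ts_max, label="ts_max"),
    )


def fs_border_lines(spec: PhaseSpaceSpec) -> tuple[RateLine, RateLine]:
    """Borders ``kappa_endo = (1/fs - 1) * kappa_exo`` for fs_min and fs_max."""
    lines = []
    for fs, label in ((spec.fs_min, "fs_min"), (spec.fs_max, "fs_max")):
        if not 0 < fs < 1:
            raise ValueError("fs borders require fs in (0, 1)")
        lines.append(RateLine(1.0, -(1.0 / fs - 1.0), 0.0, label=label))
    return tuple(lines)


def threshold_line(fs_c: float) -> RateLine:
    """Detectability threshold ``kappa_endo = (1/fs_c - 1) * kappa_exo``."""
    if not 0 < fs_c < 1:
        raise ValueError("fs_c must lie in (0, 1)")
    return RateLine(1.0, -(1.0 / fs_c - 1.0), 0.0, label="fs_c")


def fs_min_from_ratio(fs_max: float, ratio: float) -> float:
    """Lower saturation bound from the observed fluctuation ratio fs_max/fs_min."""
    if not 0 < fs_max <= 1:
        raise ValueError("fs_max must lie in (0, 1]")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    return fs_max / ratio


def required_endo_rate(kappa_exo: float, fs_c: float) -> float:
    """Endocytosis rate pushing the steady level down to ``fs_c``.

    Inverts the steady-state formula at fixed ``kappa_exo``:
    ``kappa_endo = (1/fs_c - 1) * kappa_exo``.
    """
    if not 0 < fs_c < 1:
        raise ValueError("fs_c must lie in (0, 1)")
    if not kappa_exo > 0:
        raise ValueError("kappa_exo must be positive")
    return (1.0 / fs_c - 1.0) * kappa_exo


def required_exo_rate(kappa_endo: float, fs_c: float) -> float:
    """Exocytosis rate pushing the steady level down to ``fs_c``.

    ``kappa_exo = kappa_endo * fs_c / (1 - fs_c)``.
    """
    if not 0 < fs_c < 1:
        raise ValueError("fs_c must lie in (0, 1)")
    if not kappa_endo > 0:
        raise ValueError("kappa_endo must be positive")
    return kappa_endo * fs_c / (1.0 - fs_c)


def effective_endo_rate(n: float, kappa_endo: float) -> EffectiveRate:
    """Occupancy-corrected rate ``kappa'_endo = n * kappa_endo``."""
    if not 0 <= n <= 1:
        raise ValueError("surface occupation density n must lie in [0, 1]")
    return EffectiveRate(n=float(n), kappa_endo_eff=n * kappa_endo)


#: Default phase-space bounds reproducing the worked detectability example:
#: fs_max = 0.5, fluctuation ratio 1.85 (hence fs_min ~= 0.27), threshold
#: fs_c = 0.02.  The growth-duration bounds are conventions (the observed
#: range is roughly 10 minutes to 2 hours) and should be overridden with
#: study-specific values.
DEFAULT_PHASE_SPACE = PhaseSpaceSpec(
    ts_min=600.0,
    ts_max=7200.0,
    fs_min=fs_min_from_ratio(0.5, 1.85),
    fs_max=0.5,
    fs_c=0.02,
)


def phase_space_raster(
    kappa_endo_range: tuple[float, float] = (1e-6, 1e-2),
    kappa_exo_range: tuple[float, float] = (1e-6, 1e-2),
    n_points: int = 50,
    spec: PhaseSpaceSpec | None = None,
) -> pd.DataFrame:
    """Rasterize ``t_s`` and ``f_s`` over a log-spaced rate grid.

    Returns a tidy DataFrame with one row per grid point and, when a
    ``spec`` is given, boolean membership columns for the ts band, the fs
    band, and their intersection (the cluster-forming zone).
    """
    ke = np.logspace(*np.log10(kappa_endo_range), n_points)
    kx = np.logspace(*np.log10(kappa_exo_range), n_points)
    rows = []
    for e in ke:
        for x in kx:
            pair = RatePair(e, x)
            row = {
                "kappa_endo": e,
                "kappa_exo": x,
                "t_s": characteristic_time(pair),
                "f_s": steady_state_fraction(pair),
            }
            if spec is not None:
                row["in_ts_band"] = spec.in_ts_band(pair)
                row["in_fs_band"] = spec.in_fs_band(pair)
                row["in_zone"] = spec.in_cluster_forming_zone(pair)
            rows.append(row)
    return pd.DataFrame(rows)
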