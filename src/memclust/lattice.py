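"""Stochastic endo/exocytosis simulation of receptors on a membrane lattice.

The plasma membrane is a periodic square lattice (default spacing 5 nm, the
order of magnitude of a single receptor) whose sites are empty or hold one
receptor.  Two event types drive the dynamics:

* **endocytosis** — a uniformly random site becomes the center of an
  internalization event; every receptor within a disc of radius drawn
  uniformly from 5-10 sites (a 50-100 nm clathrin-coated vesicle) moves to
  the internal pool;
* **exocytosis** — a vesicle arrives at a target drawn either uniformly or
  from a multi-peaked Gaussian mixture of *hot spots* (sites where
  microtubules reach the membrane); it carries a uniform random number of
  receptors up to its capacity, which are placed on empty sites of the
  target disc (surplus receptors stay internal).

Events are scheduled in continuous time (Gillespie sampling) with the
event frequencies calibrated so that the realized mean per-receptor
internalization rate is ``kappa_endo`` and the mean per-internal-receptor
delivery rate is ``kappa_exo``: an endocytosis event covers on average
``abar`` of the ``n_sites`` lattice sites, so events fire at total rate
``kappa_endo * n_sites / abar``; an exocytosis event delivers on average
``E[capacity]/2`` receptors, so events fire at
``kappa_exo * internal_pool / (E[capacity]/2)``.  This calibration is what
makes trajectories directly comparable to the two-state master equation
(``memclust.theory``); deviations from its mean-field prediction then
measure genuine spatial/discreteness effects, including the occupancy
correction absorbed in the effective rate ``kappa'_endo = n * kappa_endo``.

Receptor number is conserved: surface count + internal pool is constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import SizeDistribution, size_distribution
from .labeling import label_clusters
from ._steady import NoSteadyStateError, steady_window_stats

__all__ = [
    "Hotspot",
    "LatticeConfig",
    "LatticeState",
    "Trajectory",
    "SaturationEstimate",
    "EmptySurfaceError",
    "default_hotspots",
    "init_lattice",
    "endocytosis_event",
    "exocytosis_event",
    "run",
    "estimate_saturation",
    "state_cluster_distribution",
]

EMPTY, UNLIGANDED, LIGANDED = 0, 1, 2

#: Cap on the expected number of events in one run (guards runaway configs).
MAX_EXPECTED_EVENTS = 2e7


class EmptySurfaceError(RuntimeError):
    """Raised when a cluster distribution is requested from an empty surface."""


@dataclass(frozen=True)
class Hotspot:
    """One peak of the exocytosis target distribution (units: lattice sites)."""

    center: tuple[float, float]
    sigma: tuple[float, float]
    weight: float


@dataclass(frozen=True)
class LatticeConfig:
    """Simulation parameters.

    Defaults model a 10 um cell at 5 nm resolution (2000 x 2000 sites).
    ``total_receptors`` defaults to 10% of the site count; ``hotspots=None``
    means spatially uniform vesicle arrival; ``vesicle_capacity=None`` lets
    a vesicle carry at most as many receptors as its footprint holds.
    """

    kappa_endo: float
    kappa_exo: float
    system_size_um: float = 10.0
    grid_spacing_nm: float = 5.0
    vesicle_radius_range: tuple[int, int] = (5, 10)
    vesicle_capacity: int | None = None
    hotspots: tuple[Hotspot, ...] | None = None
    total_receptors: int | None = None
    seed: int = 0
    duration: float = 1.0
    sample_interval: float | None = None
    record_liganded: bool = True

    def __post_init__(self) -> None:
        if self.kappa_endo < 0 or self.kappa_exo < 0:
            raise ValueError("rates must be nonnegative")
        if self.system_size_um <= 0 or self.grid_spacing_nm <= 0:
            raise ValueError("system size and grid spacing must be positive")
        lo, hi = self.vesicle_radius_range
        if not 1 <= lo <= hi or hi > self.n_side // 2:
            raise ValueError("vesicle radius range must lie within [1, lattice side / 2]")
        if self.hotspots is not None:
            w = sum(h.weight for h in self.hotspots)
            if not self.hotspots or abs(w - 1.0) > 1e-9:
                raise ValueError("hotspot weights must sum to 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_side(self) -> int:
        return int(round(self.system_size_um * 1000.0 / self.grid_spacing_nm))

    @property
    def n_sites(self) -> int:
        return self.n_side**2

    @property
    def n_total(self) -> int:
        if self.total_receptors is not None:
            return int(self.total_receptors)
        return self.n_sites // 10


@dataclass
class LatticeState:
    """Evolving simulator state.

    ``occupancy`` holds 0 (empty), 1 (unliganded receptor) or 2 (liganded
    receptor).  The liganded flag is carried for visualization parity only
    and has no dynamical role.
    """

    occupancy: np.ndarray
    internal_pool: int
    time: float
    n_total: int

    @property
    def surface_count(self) -> int:
        return int(np.count_nonzero(self.occupancy))

    @property
    def surface_fraction(self) -> float:
        return self.surface_count / self.n_total

    def check_conservation(self) -> None:
        if self.surface_count + self.internal_pool != self.n_total:
            raise AssertionError("receptor conservation violated")


@dataclass(frozen=True)
class Trajectory:
    """Sampled surface fraction f(t), with optional state snapshots."""

    times: np.ndarray
    surface_fraction: np.ndarray
    snapshots: tuple[tuple[float, np.ndarray], ...] = ()

    def __post_init__(self) -> None:
        f = np.asarray(self.surface_fraction, dtype=float)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("surface fraction must lie in [0, 1]")
        if np.any(np.diff(np.asarray(self.times, dtype=float)) < 0):
            raise ValueError("times must be non-decreasing")


@dataclass(frozen=True)
class SaturationEstimate:
    """Steady-state summary of a trajectory."""

    f_s_hat: float
    t_s_hat: float
    fluctuation: float


def default_hotspots(
    n_side: int,
    rng: np.random.Generator,
    n_peaks: int = 10,
    sigma_sites: float = 40.0,
) -> tuple[Hotspot, ...]:
    """Equal-weight isotropic hot spots at uniformly random positions.

    The default width of 40 sites corresponds to 200 nm at 5 nm spacing.
    """
    centers = rng.uniform(0, n_side, size=(n_peaks, 2))
    w = 1.0 / n_peaks
    return tuple(
        Hotspot(center=(float(c[0]), float(c[1])), sigma=(sigma_sites, sigma_sites), weight=w)
        for c in centers
    )


def _disc_offsets(radius_range: tuple[int, int]) -> dict[int, np.ndarray]:
    """Site offsets (dy, dx) with Euclidean distance <= r, per radius."""
    lo, hi = radius_range
    out = {}
    for r in range(lo, hi + 1):
        g = np.arange(-r, r + 1)
        dy, dx = np.meshgrid(g, g, indexing="ij")
        keep = dy**2 + dx**2 <= r**2
        out[r] = np.stack([dy[keep], dx[keep]], axis=1)
    return out


def init_lattice(config: LatticeConfig) -> LatticeState:
    """Empty membrane: all receptors internal, time zero."""
    n = config.n_side
    occ = np.zeros((n, n), dtype=np.uint8)
    return LatticeState(
        occupancy=occ, internal_pool=config.n_total, time=0.0, n_total=config.n_total
    )


def _draw_radius(config: LatticeConfig, rng: np.random.Generator) -> int:
    lo, hi = config.vesicle_radius_range
    return int(rng.integers(lo, hi + 1))


def endocytosis_event(
    state: LatticeState,
    config: LatticeConfig,
    rng: np.random.Generator,
    _discs: dict[int, np.ndarray] | None = None,
) -> LatticeState:
    """Internalize every receptor within a random disc (periodic wrap)."""
    discs = _discs if _discs is not None else _disc_offsets(config.vesicle_radius_range)
    n = state.occupancy.shape[0]
    center = rng.integers(0, n, size=2)
    r = _draw_radius(config, rng)
    coords = (discs[r] + center) % n
    ys, xs = coords[:, 0], coords[:, 1]
    removed = int(np.count_nonzero(state.occupancy[ys, xs]))
    if removed:
        state.occupancy[ys, xs] = EMPTY
        state.internal_pool += removed
    return state


def _draw_target_center(
    config: LatticeConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    if config.hotspots is None:
        return rng.integers(0, n, size=2)
    weights = [h.weight for h in config.hotspots]
    peak = config.hotspots[rng.choice(len(config.hotspots), p=weights)]
    center = rng.normal(loc=peak.center, scale=peak.sigma)
    return np.round(center).astype(np.int64) % n


def exocytosis_event(
    state: LatticeState,
    config: LatticeConfig,
    rng: np.random.Generator,
    _discs: dict[int, np.ndarray] | None = None,
) -> LatticeState:
    """Deliver a vesicle of receptors to a random target disc.

    The delivered count is uniform on {0, ..., capacity} but never exceeds
    the internal pool or the number of empty sites in the disc.
    """
    discs = _discs if _discs is not None else _disc_offsets(config.vesicle_radius_range)
    n = state.occupancy.shape[0]
    center = _draw_target_center(config, n, rng)
    r = _draw_radius(config, rng)
    coords = (discs[r] + center) % n
    capacity = len(coords) if config.vesicle_capacity is None else config.vesicle_capacity
    requested = int(rng.integers(0, capacity + 1))
    if requested == 0 or state.internal_pool == 0:
        return state
    ys, xs = coords[:, 0], coords[:, 1]
    empty_idx = np.flatnonzero(state.occupancy[ys, xs] == EMPTY)
    k = min(requested, state.internal_pool, empty_idx.size)
    if k:
        chosen = rng.choice(empty_idx, size=k, replace=False)
        state.occupancy[ys[chosen], xs[chosen]] = LIGANDED if config.record_liganded else UNLIGANDED
        state.internal_pool -= k
    return state


def run(
    config: LatticeConfig,
    snapshot_times: tuple[float, ...] = (),
    check_conservation: bool = False,
) -> Trajectory:
    """Simulate the endo/exocytosis process and record f(t).

    Continuous-time scheduling: waiting times are exponential with the
    total event rate, and the event type is chosen proportionally to the
    calibrated endo/exo event rates (see module docstring).  The surface
    fraction is sampled every ``sample_interval`` seconds (default:
    duration / 400).  Runs are bitwise reproducible under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    state = init_lattice(config)
    discs = _disc_offsets(config.vesicle_radius_range)
    site_counts = {r: len(o) for r, o in discs.items()}
    abar = float(np.mean(list(site_counts.values())))
    if config.vesicle_capacity is None:
        mean_payload = abar / 2.0
    else:
        mean_payload = config.vesicle_capacity / 2.0

    rate_endo_events = config.kappa_endo * config.n_sites / abar
    max_rate_exo = config.kappa_exo * config.n_total / mean_payload
    expected = (rate_endo_events + max_rate_exo) * config.duration
    if expected > MAX_EXPECTED_EVENTS:
        raise ValueError(
            f"configuration implies ~{expected:.2e} events; reduce the rates, the "
            "duration, or the lattice size (or raise total receptors less)"
        )

    dt_sample = config.sample_interval or config.duration / 400.0
    sample_times = np.arange(0.0, config.duration + 0.5 * dt_sample, dt_sample)
    fractions = np.empty_like(sample_times)
    snapshots: list[tuple[float, np.ndarray]] = []
    snap_queue = sorted(snapshot_times)

    i_sample = 0
    t = 0.0
    while True:
        rate_exo_events = config.kappa_exo * state.internal_pool / mean_payload
        total_rate = rate_endo_events + rate_exo_events
        t_next = t + (rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf)
        # emit samples (and snapshots) that fall before the next event
        while i_sample < sample_times.size and sample_times[i_sample] <= min(
            t_next, config.duration
        ):
            fractions[i_sample] = state.surface_fraction
            i_sample += 1
        while snap_queue and snap_queue[0] <= min(t_next, config.duration):
            snapshots.append((snap_queue.pop(0), state.occupancy.copy()))
        if t_next > config.duration:
            break
        t = t_next
        state.time = t
        if rng.random() < rate_endo_events / total_rate:
            endocytosis_event(state, config, rng, _discs=discs)
        else:
            exocytosis_event(state, config, rng, _discs=discs)
        if check_conservation:
            state.check_conservation()

    while i_sample < sample_times.size:  # pad if the loop ended early
        fractions[i_sample] = state.surface_fraction
        i_sample += 1
    return Trajectory(
        times=sample_times, surface_fraction=fractions, snapshots=tuple(snapshots)
    )


def estimate_saturation(traj: Trajectory, window_frac: float = 0.5) -> SaturationEstimate:
    """Steady level, saturation time and fluctuation of a trajectory.

    ``f_s_hat`` and ``fluctuation`` are the mean and SD of the trailing
    window (by default the trailing half — lattice trajectories are
    batch-noisy and autocorrelated on the scale of t_s, so a wide window
    is needed to decorrelate the stationarity check; run simulations for
    >= 10 t_s so that the window is past the growth phase).  ``t_s_hat``
    is the first sampled time at which f reaches ``(1 - 1/e) * f_s_hat``.

    Raises
    ------
    NoSteadyStateError
        If the trajectory has no statistically steady trailing window.
    """
    f = np.asarray(traj.surface_fraction, dtype=float)
    t = np.asarray(traj.times, dtype=float)
    _, f_s_hat, sd = steady_window_stats(f, window_frac=window_frac)
    if f_s_hat == 0:
        return SaturationEstimate(f_s_hat=0.0, t_s_hat=float(t[0]), fluctuation=sd)
    reached = f >= (1.0 - 1.0 / np.e) * f_s_hat
    if not reached.any():
        raise NoSteadyStateError("trajectory never reaches the saturation criterion")
    t_s_hat = float(t[int(np.argmax(reached))])
    return SaturationEstimate(f_s_hat=float(f_s_hat), t_s_hat=t_s_hat, fluctuation=float(sd))


def state_cluster_distribution(
    state: LatticeState,
    connectivity: int = 4,
    bins_per_decade: int = 5,
) -> SizeDistribution:
    """Cluster-size distribution of the current surface occupancy.

    Delegates to the shared Hoshen-Kopelman labeling with periodic
    boundaries (the lattice is a torus), then to the log-binned histogram.
    """
    occ = state.occupancy > 0
    if not occ.any():
        raise EmptySurfaceError("no receptors on the surface")
    labeling = label_clusters(occ, connectivity=connectivity, periodic=True)
    return size_distribution(labeling.sizes, bins_per_decade=bins_per_decade)
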