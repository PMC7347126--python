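"""Endo/exocytosis lattice simulator: events, calibration, saturation."""

import numpy as np
import pytest

from memclust import lattice, theory
from memclust.lattice import (
    EmptySurfaceError,
    Hotspot,
    LatticeConfig,
    LatticeState,
    SaturationEstimate,
    Trajectory,
    default_hotspots,
    endocytosis_event,
    estimate_saturation,
    exocytosis_event,
    init_lattice,
    run,
    state_cluster_distribution,
)
from memclust._steady import NoSteadyStateError

from conftest import flood_fill_labels


def small_config(**kwargs):
    defaults = dict(
        kappa_endo=1e-4,
        kappa_exo=0.5e-4,
        system_size_um=0.5,  # 100 x 100 sites
        grid_spacing_nm=5.0,
        seed=0,
        duration=1000.0,
    )
    defaults.update(kwargs)
    return LatticeConfig(**defaults)


class TestInit:
    def test_default_geometry_is_2000_square(self):
        config = LatticeConfig(kappa_endo=1e-4, kappa_exo=0.5e-4)
        assert config.n_side == 2000
        state = init_lattice(config)
        assert state.occupancy.shape == (2000, 2000)

    def test_starts_empty_with_full_internal_pool(self):
        config = small_config()
        state = init_lattice(config)
        assert state.surface_fraction == 0.0
        assert state.internal_pool == config.n_total
        assert state.time == 0.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            small_config(kappa_endo=-1.0)
        with pytest.raises(ValueError):
            small_config(vesicle_radius_range=(0, 10))
        with pytest.raises(ValueError):
            small_config(vesicle_radius_range=(5, 90))
        with pytest.raises(ValueError):
            small_config(
                hotspots=(Hotspot(center=(5.0, 5.0), sigma=(2.0, 2.0), weight=0.7),)
            )


def brute_force_disc_size(radius: int) -> int:
    count = 0
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy * dy + dx * dx <= radius * radius:
                count += 1
    return count


class TestEndocytosis:
    def test_event_on_empty_surface_changes_nothing(self):
        config = small_config()
        state = init_lattice(config)
        before = state.occupancy.copy()
        endocytosis_event(state, config, np.random.default_rng(1))
        np.testing.assert_array_equal(state.occupancy, before)
        assert state.internal_pool == config.n_total

    @pytest.mark.parametrize("radius", [5, 7, 10])
    def test_full_lattice_loses_exactly_one_disc(self, radius):
        config = small_config(
            vesicle_radius_range=(radius, radius), total_receptors=100 * 100
        )
        state = init_lattice(config)
        state.occupancy[:] = 1
        state.internal_pool = 0
        endocytosis_event(state, config, np.random.default_rng(4))
        expected = brute_force_disc_size(radius)
        assert state.internal_pool == expected
        assert state.surface_count == config.n_sites - expected
        state.check_conservation()

    def test_receptors_outside_disc_untouched(self):
        config = small_config(vesicle_radius_range=(5, 5), total_receptors=2000)
        state = init_lattice(config)
        rng = np.random.default_rng(8)
        coords = rng.integers(0, 100, size=(500, 2))
        state.occupancy[coords[:, 0], coords[:, 1]] = 1
        placed = state.surface_count
        state.internal_pool = config.n_total - placed
        before = state.occupancy.copy()
        endocytosis_event(state, config, np.random.default_rng(5))
        changed = before != state.occupancy
        # every change is a removal, and all removals lie inside one disc
        # of radius 5 (periodic wrap): diameter <= 10 in wrapped distance
        ys, xs = np.nonzero(changed)
        assert np.all(before[ys, xs] == 1) and np.all(state.occupancy[ys, xs] == 0)
        if ys.size > 1:
            dy = np.abs(ys[:, None] - ys[None, :])
            dx = np.abs(xs[:, None] - xs[None, :])
            dy = np.minimum(dy, 100 - dy)
            dx = np.minimum(dx, 100 - dx)
            assert np.sqrt(dy**2 + dx**2).max() <= 10.0
        state.check_conservation()


class TestExocytosis:
    def test_empty_internal_pool_changes_nothing(self):
        config = small_config()
        state = init_lattice(config)
        state.internal_pool = 0
        before = state.occupancy.copy()
        exocytosis_event(state, config, np.random.default_rng(2))
        np.testing.assert_array_equal(state.occupancy, before)

    def test_fully_occupied_target_region_blocks_placement(self):
        config = small_config(total_receptors=100 * 100 + 50)
        state = init_lattice(config)
        state.occupancy[:] = 1
        state.internal_pool = 50
        exocytosis_event(state, config, np.random.default_rng(3))
        assert state.internal_pool == 50
        assert state.surface_count == config.n_sites

    def test_hotspot_centers_follow_wrapped_gaussian(self):
        # sampling oracle: empirical x-marginal vs the wrapped normal pmf
        n_side, sigma, cy, cx = 64, 5.0, 20.0, 40.0
        config = small_config(
            system_size_um=n_side * 5.0 / 1000.0,
            hotspots=(Hotspot(center=(cy, cx), sigma=(sigma, sigma), weight=1.0),),
        )
        rng = np.random.default_rng(77)
        draws = np.array(
            [lattice._draw_target_center(config, n_side, rng) for _ in range(100_000)]
        )
        from scipy.stats import norm

        grid = np.arange(n_side)
        pmf = np.zeros(n_side)
        for k in range(-4, 5):  # wrap the rounded-normal mass onto the lattice
            pmf += norm.cdf(grid + 0.5 + k * n_side, loc=cx, scale=sigma) - norm.cdf(
                grid - 0.5 + k * n_side, loc=cx, scale=sigma
            )
        emp = np.bincount(draws[:, 1], minlength=n_side) / len(draws)
        assert 0.5 * np.abs(emp - pmf).sum() < 0.03  # total variation

    def test_conservation_through_mixed_events(self):
        config = small_config(total_receptors=800)
        state = init_lattice(config)
        rng = np.random.default_rng(10)
        for _ in range(300):
            if rng.random() < 0.5:
                endocytosis_event(state, config, rng)
            else:
                exocytosis_event(state, config, rng)
            state.check_conservation()


class TestRun:
    def test_pure_endocytosis_empties_the_surface(self):
        config = small_config(kappa_endo=5e-3, kappa_exo=0.0, duration=2000.0)
        traj = run(config)
        assert traj.surface_fraction[-1] == 0.0

    def test_bitwise_reproducible(self):
        config = small_config(duration=5000.0, hotspots=None)
        a, b = run(config), run(config)
        np.testing.assert_array_equal(a.surface_fraction, b.surface_fraction)
        np.testing.assert_array_equal(a.times, b.times)

    def test_runaway_configuration_rejected_with_guidance(self):
        config = small_config(kappa_endo=10.0, kappa_exo=10.0, duration=1e9)
        with pytest.raises(ValueError, match="events"):
            run(config)

    def test_conservation_during_run(self):
        config = small_config(duration=20000.0, hotspots=None)
        run(config, check_conservation=True)  # raises on violation

    def test_steady_level_matches_mean_field(self):
        # uniform delivery: mean-field predicts f_s = kx / (ke + kx) = 1/3
        rates = theory.RatePair(1e-4, 0.5e-4)
        config = LatticeConfig(
            kappa_endo=rates.kappa_endo,
            kappa_exo=rates.kappa_exo,
            system_size_um=2.5,  # 500 x 500
            duration=16.0 / rates.total,
            hotspots=None,
            seed=2,
        )
        sat = estimate_saturation(run(config))
        f_mf = theory.steady_state_fraction(rates)
        assert abs(sat.f_s_hat - f_mf) / f_mf < 0.15
        t_mf = theory.characteristic_time(rates)
        assert abs(sat.t_s_hat - t_mf) / t_mf < 0.25

    def test_steady_level_monotone_in_rates(self):
        def steady(ke, kx):
            config = LatticeConfig(
                kappa_endo=ke,
                kappa_exo=kx,
                system_size_um=1.5,
                duration=16.0 / (ke + kx),
                hotspots=None,
                seed=6,
            )
            return estimate_saturation(run(config)).f_s_hat

        base = steady(1e-4, 0.5e-4)
        assert steady(4e-4, 0.5e-4) < base  # faster loss, lower level
        assert steady(1e-4, 2e-4) > base  # faster delivery, higher level

    def test_hotspots_give_heavier_cluster_tails(self):
        # hot spots covering a few percent of the membrane concentrate
        # deliveries; vesicle footprints there overlap and merge
        def pooled_sizes(hotspots, seed):
            duration = 12.0 / 1.5e-4
            config = LatticeConfig(
                kappa_endo=1e-4,
                kappa_exo=0.5e-4,
                system_size_um=2.5,
                duration=duration,
                hotspots=hotspots,
                seed=seed,
            )
            snaps = tuple(duration * (0.7 + 0.1 * i) for i in range(3))
            traj = run(config, snapshot_times=snaps)
            from memclust.labeling import label_clusters

            return np.concatenate(
                [
                    label_clusters(occ > 0, connectivity=4, periodic=True).sizes
                    for _, occ in traj.snapshots
                ]
            )

        spots = default_hotspots(
            500, np.random.default_rng(3), n_peaks=5, sigma_sites=20.0
        )
        uniform_sizes = pooled_sizes(None, 3)
        spot_sizes = pooled_sizes(spots, 3)
        pooled_median = np.median(np.concatenate([uniform_sizes, spot_sizes]))

        def tail_mass(sizes):
            return sizes[sizes > pooled_median].sum() / sizes.sum()

        assert tail_mass(spot_sizes) > tail_mass(uniform_sizes)


class TestSaturation:
    def test_exact_exponential_trajectory(self):
        tau, f_s = 300.0, 0.4
        t = np.linspace(0.0, 10 * tau, 800)
        traj = Trajectory(times=t, surface_fraction=f_s * (1 - np.exp(-t / tau)))
        sat = estimate_saturation(traj)
        # trailing-half mean carries the residual e^(-5) relaxation bias
        assert sat.f_s_hat == pytest.approx(f_s, rel=5e-3)
        assert sat.t_s_hat == pytest.approx(tau, abs=t[1] - t[0])

    def test_constant_trajectory(self):
        t = np.linspace(0.0, 100.0, 50)
        sat = estimate_saturation(Trajectory(times=t, surface_fraction=np.full(50, 0.2)))
        assert sat.f_s_hat == pytest.approx(0.2)
        assert sat.t_s_hat == 0.0

    def test_unsettled_trajectory_raises(self):
        t = np.linspace(0.0, 100.0, 60)
        with pytest.raises(NoSteadyStateError):
            estimate_saturation(Trajectory(times=t, surface_fraction=t / 200.0))


class TestStateClusterDistribution:
    def _state(self, occupancy):
        return LatticeState(
            occupancy=occupancy,
            internal_pool=0,
            time=0.0,
            n_total=int(np.count_nonzero(occupancy)),
        )

    def test_single_receptor(self):
        occ = np.zeros((20, 20), dtype=np.uint8)
        occ[3, 7] = 1
        dist = state_cluster_distribution(self._state(occ))
        assert dist.counts.sum() == 1

    def test_checkerboard_is_all_singletons(self):
        occ = np.indices((20, 20)).sum(axis=0) % 2
        dist = state_cluster_distribution(self._state(occ.astype(np.uint8)))
        assert dist.counts.sum() == 200  # every occupied site its own cluster
        assert dist.bin_edges[0] <= 1 <= dist.bin_edges[-1]

    def test_empty_surface_raises(self):
        with pytest.raises(EmptySurfaceError):
            state_cluster_distribution(self._state(np.zeros((10, 10), dtype=np.uint8)))

    def test_periodic_sizes_match_flood_fill_oracle(self):
        rng = np.random.default_rng(12)
        occ = (rng.random((100, 100)) < 0.3).astype(np.uint8)
        dist = state_cluster_distribution(self._state(occ), connectivity=4)
        oracle = flood_fill_labels(occ.astype(bool), 4, True)
        oracle_sizes = np.bincount(oracle[occ.astype(bool)])[1:]
        oracle_sizes = oracle_sizes[oracle_sizes > 0]
        assert dist.counts.sum() == oracle_sizes.size
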