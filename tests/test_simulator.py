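"""The coupled daily loop: limits, conservation, determinism, scenarios."""

import dataclasses

import numpy as np
import pytest

from seapatch import (calibrate, compare_scenarios, find_cap_for_catch_fraction,
                      initial_allocation, run_simulation, summarize)


def test_no_fishing_limit_is_pure_natural_decay(fixture_bundle):
    _, state, config = fixture_bundle
    cfg = config.with_fleet(initial_effort=0.0, phi=0.0)
    traj = run_simulation(cfg, state)
    assert traj.catch_ind.sum() == 0.0
    m = config.population.natural_mortality_per_year
    for day in (1, 100, 240):
        expected = state.total_abundance * np.exp(-m * day / 365.0)
        assert traj.total_abundance[day - 1] == pytest.approx(expected, rel=1e-12)


def test_mass_balance_identity(fixture_bundle):
    """Initial N minus final N equals catch plus natural deaths."""
    _, state, config = fixture_bundle
    traj = run_simulation(config, state)
    removed = traj.catch_ind.sum() + traj.natural_deaths.sum()
    lost = state.total_abundance - traj.total_abundance[-1]
    assert removed == pytest.approx(lost, rel=1e-9)


def test_identical_configs_give_bit_identical_trajectories(fixture_bundle):
    _, state, config = fixture_bundle
    a = run_simulation(config, state)
    b = run_simulation(config, state)
    for name in ("n", "effort", "catch_ind", "price", "q", "profit"):
        np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
    assert a.to_frame().equals(b.to_frame())


def test_cap_zero_means_no_catch_no_npv(fixture_bundle):
    _, state, config = fixture_bundle
    traj = run_simulation(config.with_cap(0.0), state)
    assert traj.catch_ind.sum() == 0.0
    assert traj.cumulative_npv() == 0.0


def test_catch_monotone_and_abundance_antitone_in_cap(fixture_bundle):
    _, state, config = fixture_bundle
    table = compare_scenarios(config, state, [10.0, 100.0, 300.0, 691.0])
    by_cap = table.iloc[1:]  # scenario rows, increasing cap
    catches = by_cap["cumulative_catch_t"].to_numpy()
    remaining = by_cap["remaining_abundance_millions"].to_numpy()
    assert (np.diff(catches) >= 0).all()
    assert (np.diff(remaining) <= 0).all()
    sq = table.iloc[0]
    assert sq["cumulative_catch_t"] >= catches[-2]


def test_effort_zero_is_terminal_in_status_quo(fixture_bundle):
    _, state, config = fixture_bundle
    traj = run_simulation(config, state)
    day = traj.effort_cessation_day()
    assert day is not None
    assert (traj.trips[day - 1:] == 0.0).all()
    assert traj.trips[: day - 1].min() >= 0.0


def test_opening_allocation_rent_intensity_increases_with_density(fixture_bundle):
    """Denser grounds earn more per trip, so they attract more effort per
    unit of standing stock (the gravity model's rent term)."""
    _, state, config = fixture_bundle
    f0 = initial_allocation(691.0, state, config)
    assert f0.sum() == pytest.approx(691.0)
    assert (f0 > 0).all()  # every level is profitable on opening day
    intensity = f0 / state.biomass_kg
    order = np.argsort(state.density)
    assert (np.diff(intensity[order]) > 0).all()


def test_summary_bookkeeping_is_consistent(fixture_bundle):
    _, state, config = fixture_bundle
    traj = run_simulation(config, state)
    res = summarize(traj, config, state)
    w = config.population.mean_weight_kg
    window = config.season_days
    assert res.total_trips == pytest.approx(traj.trips[:window].sum())
    assert res.cumulative_catch_t == pytest.approx(
        traj.catch_ind[:window].sum() * w / 1000.0)
    assert res.avg_income_per_trip_usd == pytest.approx(
        res.cumulative_npv_musd * 1e6 / res.total_trips)
    assert res.avg_income_per_boat_usd == pytest.approx(
        res.cumulative_npv_musd * 1e6 / 691.0)
    assert res.catch_fraction_of_virgin == pytest.approx(
        res.cumulative_catch_t / (state.total_abundance * w / 1000.0))


def test_calibration_no_fishing_limit(fixture_bundle):
    """Observations explained by natural mortality alone fit a tiny fleet."""
    _, state, config = fixture_bundle
    m = config.population.natural_mortality_per_year
    n0 = state.total_abundance
    obs = [(0, n0), (74, n0 * np.exp(-m * 74 / 365)),
           (148, n0 * np.exp(-m * 148 / 365))]
    res = calibrate(config, state, obs, f0_bounds=(1.0, 2000.0))
    # with ~1 trip/day the removals are ~0.1% of the stock
    assert res.initial_effort < 25.0
    assert res.objective < 1e-4


def test_calibration_rejects_bad_observations(fixture_bundle):
    _, state, config = fixture_bundle
    with pytest.raises(ValueError):
        calibrate(config, state, [])
    with pytest.raises(ValueError):
        calibrate(config, state, [(0, -5.0)])


def test_find_cap_limits(fixture_bundle):
    _, state, config = fixture_bundle
    cap, achieved = find_cap_for_catch_fraction(0.001, config, state)
    assert cap <= 1
    with pytest.raises(ValueError):
        find_cap_for_catch_fraction(1.5, config, state)


def test_find_cap_unreachable_fraction_warns(fixture_bundle):
    _, state, config = fixture_bundle
    with pytest.warns(UserWarning, match="unreachable"):
        cap, achieved = find_cap_for_catch_fraction(0.9, config, state)
    assert cap == int(np.ceil(config.fleet.max_effort))
    assert achieved < 0.9 * state.total_abundance * state.w / 1000.0


def test_nonfinite_state_aborts_with_diagnostic(fixture_bundle):
    _, state, config = fixture_bundle
    bad = dataclasses.replace(state, n=state.n.copy())
    bad.n[0] = np.inf
    with pytest.raises((FloatingPointError, ValueError)):
        run_simulation(config, bad)
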