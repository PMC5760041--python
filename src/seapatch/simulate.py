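"""The daily bioeconomic loop, scenario engine and two-point calibration.

Each simulated day couples the three subsystems in a fixed order:

1. catchability per density level from current density (rectangular
   hyperbola, per-trip wet catch = a*D + b kg);
2. catch per level from the day's allocated trips, capped at abundance;
3. ex-vessel price from the day's total landings (linear inverse demand),
   trip costs from density, quasi-profits per level;
4. Smith entry-exit update of total fleet size and income-proportional
   re-allocation of tomorrow's trips across levels;
5. the depletion recursion (removals, then daily natural mortality).

Everything is deterministic: identical configurations give bit-identical
trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .config import SimConfig
from .economics import ex_vessel_price, npv, per_trip_profit
from .fleet import allocate_effort, catch_individuals, catchability, update_fleet
from .population import PopulationState, daily_mortality, step_population

__all__ = ["Trajectory", "ScenarioResult", "CalibrationResult",
           "run_simulation", "initial_allocation", "summarize",
           "compare_scenarios", "calibrate", "find_cap_for_catch_fraction"]


@dataclass
class Trajectory:
    """Daily output of one simulation run.

    2-D arrays have shape (horizon_days, n_levels); ``n`` is the abundance at
    the *end* of each day (after removals and natural mortality), ``density``
    the density at the *start* of the day on which that day's catch operated.
    """

    days: np.ndarray           # 1-based day index
    density: np.ndarray        # start-of-day D_i
    effort: np.ndarray         # trips f_i allocated to each level
    catch_ind: np.ndarray      # individuals removed Y_i
    q: np.ndarray              # catchability per level
    profit: np.ndarray         # realized quasi-profit per level, US$
    n: np.ndarray              # end-of-day abundance N_i
    fleet_size: np.ndarray     # total fleet F_t before the day's allocation
    price: np.ndarray          # ex-vessel price, US$/kg gutted
    landings_gutted_t: np.ndarray
    natural_deaths: np.ndarray  # individuals lost to m, summed over levels
    w: float
    annual_discount_rate: float

    @property
    def trips(self) -> np.ndarray:
        return self.effort.sum(axis=1)

    @property
    def daily_catch_t(self) -> np.ndarray:
        """Daily wet-weight catch in tonnes."""
        return self.catch_ind.sum(axis=1) * self.w / 1000.0

    @property
    def daily_profit(self) -> np.ndarray:
        return self.profit.sum(axis=1)

    @property
    def total_abundance(self) -> np.ndarray:
        return self.n.sum(axis=1)

    def cumulative_npv(self, through_day: int | None = None) -> float:
        d = self.days.size if through_day is None else through_day
        return npv(self.daily_profit[:d], self.annual_discount_rate,
                   days=self.days[:d])

    def effort_cessation_day(self) -> int | None:
        """First day of the terminal zero-effort run, or None if fishing
        continues through the horizon."""
        active = np.nonzero(self.trips > 0)[0]
        if active.size == 0:
            return 1
        last = int(active[-1])
        if last == self.days.size - 1:
            return None
        return int(self.days[last + 1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per (day, level, variable)."""
        n_days, n_levels = self.n.shape
        frames = []
        for name, arr in [("density", self.density), ("effort", self.effort),
                          ("catch_ind", self.catch_ind), ("q", self.q),
                          ("profit", self.profit), ("abundance", self.n)]:
            df = pd.DataFrame(arr, columns=np.arange(1, n_levels + 1))
            df.insert(0, "day", self.days)
            df = df.melt(id_vars="day", var_name="level", value_name="value")
            df.insert(2, "variable", name)
            frames.append(df)
        return pd.concat(frames, ignore_index=True).sort_values(
            ["day", "variable", "level"], ignore_index=True)

    def daily_frame(self) -> pd.DataFrame:
        """One row per day with whole-patch aggregates."""
        return pd.DataFrame({
            "day": self.days,
            "trips": self.trips,
            "catch_t": self.daily_catch_t,
            "landings_gutted_t": self.landings_gutted_t,
            "price_usd_kg": self.price,
            "quasi_profit_usd": self.daily_profit,
            "fleet_size": self.fleet_size,
            "abundance": self.total_abundance,
            "natural_deaths": self.natural_deaths,
            "cum_trips": np.cumsum(self.trips),
            "cum_catch_t": np.cumsum(self.daily_catch_t),
        })


def _expected_per_trip_kg(state: PopulationState, config: SimConfig) -> np.ndarray:
    """Wet kg one trip would land at each level: q * B_i (= a*D + b, >= 0)."""
    q = catchability(state.density, state.c, config.catchability)
    return q * state.biomass_kg


def _allocation_weights(pi_trip: np.ndarray, revenue_trip: np.ndarray,
                        biomass_kg: np.ndarray, config: SimConfig) -> np.ndarray:
    """Per-level 'income' signal for the spatial split of tomorrow's trips."""
    basis = config.fleet.allocation_basis
    if basis == "quasi_profit":
        income = pi_trip
    elif basis == "revenue":
        income = revenue_trip
    elif np.any(np.isfinite(pi_trip) & (pi_trip > 0)):
        # default: prefer profitable grounds; once none is profitable the
        # still-active fleet follows gross income while exit unwinds
        income = pi_trip
    else:
        income = revenue_trip
    if config.fleet.gravity:
        # gravity model: attraction = income rate x available stock
        out = np.where(np.isfinite(income), income, -np.inf)
        pos = income > 0
        out[pos] = income[pos] * biomass_kg[pos]
        return out
    return income


def initial_allocation(f0: float, state: PopulationState,
                       config: SimConfig) -> np.ndarray:
    """Opening-day trip allocation, proportional to per-trip income.

    No landings have reached the buyers yet, so the income signal is priced
    at the zero-supply intercept of the inverse demand.
    """
    if f0 < 0:
        raise ValueError("initial effort must be non-negative")
    p0 = ex_vessel_price(0.0, config.economics)
    kg = _expected_per_trip_kg(state, config)
    pi = per_trip_profit(state.density, kg, p0, config.economics)
    revenue = p0 * config.economics.gutted_fraction * kg
    f = allocate_effort(f0, _allocation_weights(pi, revenue,
                                                state.biomass_kg, config))
    if f0 > 0 and f.sum() == 0:
        warnings.warn("no density level yields income at the season opening; "
                      "no effort allocated", stacklevel=2)
    return f


def run_simulation(config: SimConfig, state0: PopulationState) -> Trajectory:
    """Run the daily closed loop over the configured horizon."""
    horizon = config.horizon_days
    n_levels = state0.n_levels
    econ = config.economics
    flt = config.fleet
    cap = np.inf if config.max_trips_per_day is None else config.max_trips_per_day
    mu = daily_mortality(state0.m_annual)

    out = {name: np.zeros((horizon, n_levels))
           for name in ("density", "effort", "catch_ind", "q", "profit", "n")}
    fleet_size = np.zeros(horizon)
    price_arr = np.zeros(horizon)
    landings_arr = np.zeros(horizon)
    deaths_arr = np.zeros(horizon)

    state = state0
    F = min(flt.initial_effort, flt.max_effort)
    f = initial_allocation(min(F, cap), state, config)

    for t in range(horizon):
        d = state.density
        q = catchability(d, state.c, config.catchability)
        y = catch_individuals(f, q, state.n)
        if not np.isfinite(y).all():
            raise FloatingPointError(
                f"non-finite state on day {t + 1}: y={y!r}, d={d!r}, f={f!r}")
        wet_kg = y * state.w
        wet_t = wet_kg.sum() / 1000.0
        gutted_t = econ.gutted_fraction * wet_t
        price = ex_vessel_price(
            wet_t if econ.price_quantity_basis == "wet" else gutted_t, econ)

        # hypothetical per-trip quasi-profit and revenue at today's price:
        # the signals fishers compare across grounds for tomorrow's allocation
        exp_kg = _expected_per_trip_kg(state, config)
        pi_trip = per_trip_profit(d, exp_kg, price, econ)
        revenue_trip = price * econ.gutted_fraction * exp_kg
        # realized level quasi-profit (Eq. pi = f (p q B - c)); identical to
        # f * pi_trip except where the catch was capped at abundance
        cost = np.where(d > 0,
                        econ.gas_alpha + econ.gas_beta / np.where(d > 0, d, 1.0)
                        + econ.other_variable_cost, 0.0)
        pi_level = price * econ.gutted_fraction * wet_kg - f * cost

        trips = f.sum()
        if trips > 0:
            signal = pi_level.sum() / trips - flt.opportunity_cost
        else:
            finite = pi_trip[np.isfinite(pi_trip)]
            best = finite.max() if finite.size else 0.0
            signal = best - flt.opportunity_cost

        out["density"][t] = d
        out["effort"][t] = f
        out["catch_ind"][t] = y
        out["q"][t] = q
        out["profit"][t] = pi_level
        fleet_size[t] = F
        price_arr[t] = price
        landings_arr[t] = gutted_t
        deaths_arr[t] = float(((state.n - y) * -np.expm1(-mu)).sum())

        F = update_fleet(F, signal, flt.phi, flt.max_effort)
        f = allocate_effort(min(F, cap),
                            _allocation_weights(pi_trip, revenue_trip,
                                                state.biomass_kg, config))
        state = step_population(state, y, mu)
        out["n"][t] = state.n

    return Trajectory(days=np.arange(1, horizon + 1), density=out["density"],
                      effort=out["effort"], catch_ind=out["catch_ind"],
                      q=out["q"], profit=out["profit"], n=out["n"],
                      fleet_size=fleet_size, price=price_arr,
                      landings_gutted_t=landings_arr, natural_deaths=deaths_arr,
                      w=state0.w,
                      annual_discount_rate=econ.annual_discount_rate)


# ---------------------------------------------------------------------------
# scenario summaries

@dataclass
class ScenarioResult:
    """End-of-season summary of one run (the management-comparison row set).

    Stock quantities are reported at the end of the season window (the
    survey-to-survey interval); ``effort_cessation_day`` and
    ``total_trips_horizon`` look across the whole simulated horizon.
    """

    label: str
    max_trips_per_day: float | None
    total_trips: float                  # within the season window
    remaining_abundance_millions: float
    final_mean_density: float           # individuals m^-2
    cumulative_catch_t: float           # wet tonnes, season window
    catch_fraction_of_virgin: float
    cumulative_npv_musd: float          # US$ millions, season window
    final_price_usd_kg: float           # last traded price in the window
    avg_income_per_trip_usd: float
    avg_income_per_boat_usd: float
    effort_cessation_day: int | None
    total_trips_horizon: float


def summarize(traj: Trajectory, config: SimConfig, state0: PopulationState,
              label: str = "status quo", n_boats: float = 691.0) -> ScenarioResult:
    window = min(config.season_days, traj.days.size)
    trips = float(traj.trips[:window].sum())
    catch_t = float(traj.daily_catch_t[:window].sum())
    remaining = float(traj.total_abundance[window - 1])
    total_npv = traj.cumulative_npv(window)
    traded = np.nonzero(traj.landings_gutted_t[:window] > 0)[0]
    final_price = (float(traj.price[traded[-1]]) if traded.size
                   else ex_vessel_price(0.0, config.economics))
    virgin_t = state0.total_abundance * state0.w / 1000.0
    return ScenarioResult(
        label=label,
        max_trips_per_day=config.max_trips_per_day,
        total_trips=trips,
        remaining_abundance_millions=remaining / 1e6,
        final_mean_density=remaining / float(state0.area.sum()),
        cumulative_catch_t=catch_t,
        catch_fraction_of_virgin=catch_t / virgin_t,
        cumulative_npv_musd=total_npv / 1e6,
        final_price_usd_kg=final_price,
        avg_income_per_trip_usd=total_npv / trips if trips > 0 else 0.0,
        avg_income_per_boat_usd=total_npv / n_boats,
        effort_cessation_day=traj.effort_cessation_day(),
        total_trips_horizon=float(traj.trips.sum()),
    )


def compare_scenarios(config: SimConfig, state0: PopulationState,
                      caps: list[float]) -> pd.DataFrame:
    """Run the status quo plus one run per daily effort cap.

    Caps bind total daily trips before spatial allocation; allocation
    proportions are unchanged.
    """
    results = [summarize(run_simulation(config.with_cap(None), state0),
                         config.with_cap(None), state0, label="status quo")]
    for cap in caps:
        if cap < 0:
            raise ValueError("caps must be non-negative")
        cfg = config.with_cap(cap)
        results.append(summarize(run_simulation(cfg, state0), cfg, state0,
                                 label=f"cap {cap:g} trips/day"))
    rows = pd.DataFrame([vars(r) for r in results])
    return rows


# ---------------------------------------------------------------------------
# calibration

@dataclass
class CalibrationResult:
    initial_effort: float
    phi: float
    objective: float
    converged: bool
    n_evaluations: int
    trajectory: Trajectory


def calibrate(config: SimConfig, state0: PopulationState,
              observations: list[tuple[int, float]],
              f0_bounds: tuple[float, float] = (10.0, 2000.0),
              phi_bounds: tuple[float, float] = (0.001, 0.2),
              grid: tuple[int, int] = (12, 12)) -> CalibrationResult:
    """Fit (initial effort F0, entry-exit phi) to observed total abundances.

    ``observations`` are (day, abundance) pairs; day 0 refers to the
    pre-fishing state.  The objective is the sum of squared relative errors
    of simulated total abundance at the observed days.  The search is a
    coarse log-spaced grid followed by bounded trust-region least squares in
    log-parameter space; it is deterministic (no randomness anywhere).

    The fleet ceiling is tied to the fitted initial effort (the whole fleet
    is deployed at the opening).  With only a pre-fishing and one
    post-fishing observation the problem has a one-dimensional ridge of
    near-exact fits (phi is weakly identified); a warning is emitted and the
    returned point is the deterministic optimum of the search.  Supplying
    intermediate abundances identifies both parameters.
    """
    obs = sorted((int(d), float(n)) for d, n in observations)
    if not obs:
        raise ValueError("no observations supplied")
    if any(n <= 0 for _, n in obs):
        raise ValueError("observed abundances must be positive")
    informative = [o for o in obs if o[0] > 0]
    if len(informative) < 2:
        warnings.warn(
            "fewer than two post-fishing observations: (F0, phi) is only "
            "partially identified (a ridge of near-exact fits exists)",
            stacklevel=2)
    horizon = max(max(d for d, _ in obs), 1)
    base = replace(config, horizon_days=horizon,
                   season_days=min(config.season_days, horizon))
    evals = 0

    def residuals(z: np.ndarray) -> np.ndarray:
        nonlocal evals
        evals += 1
        f0, phi = np.exp(z)
        cfg = base.with_fleet(initial_effort=float(f0), max_effort=float(f0),
                              phi=float(phi))
        traj = run_simulation(cfg, state0)
        return np.array(
            [(state0.total_abundance if day == 0
              else float(traj.total_abundance[day - 1])) / n_obs - 1.0
             for day, n_obs in obs])

    f0_grid = np.geomspace(f0_bounds[0], f0_bounds[1], grid[0])
    phi_grid = np.geomspace(phi_bounds[0], phi_bounds[1], grid[1])
    best, best_val = None, np.inf
    for f0 in f0_grid:
        for phi in phi_grid:
            v = float(np.sum(residuals(np.log([f0, phi])) ** 2))
            if v < best_val:
                best, best_val = np.log([f0, phi]), v
    lb = np.log([f0_bounds[0], phi_bounds[0]])
    ub = np.log([f0_bounds[1], phi_bounds[1]])
    res = optimize.least_squares(residuals, x0=best, method="trf",
                                 bounds=(lb, ub), xtol=1e-14, ftol=1e-14,
                                 gtol=1e-14)
    x, final_val = res.x, float(2 * res.cost)
    if final_val > best_val:   # refinement must never lose to the grid
        x, final_val = best, best_val
    if not res.success:
        warnings.warn("calibration refinement did not formally converge; "
                      "returning the best point found", stacklevel=2)
    f0_fit, phi_fit = (float(v) for v in np.exp(x))
    cfg = base.with_fleet(initial_effort=f0_fit, max_effort=f0_fit, phi=phi_fit)
    return CalibrationResult(initial_effort=f0_fit, phi=phi_fit,
                             objective=final_val,
                             converged=bool(res.success),
                             n_evaluations=evals,
                             trajectory=run_simulation(cfg, state0))


def find_cap_for_catch_fraction(fraction: float, config: SimConfig,
                                state0: PopulationState,
                                window_days: int | None = None) -> tuple[int, float]:
    """Smallest integer daily trip cap whose season catch reaches a fraction
    of the virgin (pre-fishing) wet biomass.

    Returns ``(cap, achieved_catch_t)``.  If the fraction is unreachable even
    without a binding cap, the uncapped maximum is reported with a warning.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    window = config.season_days if window_days is None else window_days
    cfg_base = replace(config, season_days=min(window, config.horizon_days))
    virgin_t = state0.total_abundance * state0.w / 1000.0
    target = fraction * virgin_t

    def season_catch(cap: float | None) -> float:
        cfg = cfg_base.with_cap(cap)
        traj = run_simulation(cfg, state0)
        return float(traj.daily_catch_t[:cfg.season_days].sum())

    hi = int(np.ceil(config.fleet.max_effort))
    if season_catch(hi) < target:
        achieved = season_catch(None)
        warnings.warn(f"target fraction {fraction:g} unreachable; maximum "
                      f"achievable catch is {achieved:.0f} t", stacklevel=2)
        return hi, achieved
    lo = 0
    while hi - lo > 1:          # bisection: season catch is monotone in cap
        mid = (lo + hi) // 2
        if season_catch(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi, season_catch(hi)
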