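"""Per-level population bookkeeping: the depletion recursion.

The stock is a closed unit (no recruitment, no migration) split into fixed
sub-areas (density levels).  Abundance at level *i* evolves by

    N[i, t] = (N[i, t-1] - Y[i, t-1]) * exp(-m_step)

where Y is the fished removal and ``m_step`` the natural mortality applied
per step.  Density and biomass are derived quantities: D = N / area,
B = N * w.  Sub-area sizes never change, so depletion shows up as falling
density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .assessment import DensityLevel

__all__ = ["PopulationState", "step_population", "daily_mortality"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PopulationState:
    """Abundance state of all density levels at one time step.

    ``n``, ``area`` and ``c`` are aligned per-level vectors (level 1 first).
    Abundance is continuous: the depletion recursion is a continuous-state
    model and rounding would distort calibration.
    """

    n: np.ndarray          # individuals per level
    area: np.ndarray       # m^2 per level, constant over time
    c: np.ndarray          # kg per level (catchability scale, area * w)
    w: float               # mean individual weight, kg
    m_annual: float        # natural mortality, yr^-1
    t: int = 0             # day index

    def __post_init__(self) -> None:
        object.__setattr__(self, "n", np.asarray(self.n, dtype=float))
        object.__setattr__(self, "area", np.asarray(self.area, dtype=float))
        object.__setattr__(self, "c", np.asarray(self.c, dtype=float))
        if not (self.n.shape == self.area.shape == self.c.shape):
            raise ValueError("n, area and c must be aligned per-level vectors")
        if (self.n < 0).any():
            raise ValueError("abundance must be non-negative")
        if (self.area <= 0).any():
            raise ValueError("level areas must be positive")
        if self.w <= 0 or self.m_annual < 0:
            raise ValueError("w must be positive and m non-negative")

    @classmethod
    def from_levels(cls, levels: list[DensityLevel], w: float,
                    m_annual: float) -> "PopulationState":
        levels = sorted(levels, key=lambda lv: lv.index)
        return cls(n=np.array([lv.abundance for lv in levels]),
                   area=np.array([lv.area_m2 for lv in levels]),
                   c=np.array([lv.c_kg for lv in levels]),
                   w=w, m_annual=m_annual)

    @property
    def n_levels(self) -> int:
        return self.n.size

    @property
    def density(self) -> np.ndarray:
        """Per-level density D_i = N_i / area_i (individuals m^-2)."""
        return self.n / self.area

    @property
    def biomass_kg(self) -> np.ndarray:
        """Per-level wet biomass B_i = N_i * w (kg)."""
        return self.n * self.w

    @property
    def total_abundance(self) -> float:
        return float(self.n.sum())

    @property
    def mean_density(self) -> float:
        """Patch mean density: total abundance over total area."""
        return float(self.n.sum() / self.area.sum())


def daily_mortality(m_annual: float) -> float:
    """Per-day mortality rate; 365 daily steps compose to exp(-m_annual)."""
    return m_annual / 365.0


def step_population(state: PopulationState, removals: np.ndarray,
                    m_step: float | None = None) -> PopulationState:
    """Advance the depletion recursion by one step.

    ``removals`` are fished individuals per level during the current step;
    they are clamped to available abundance (with a logged warning) if the
    catch equation over-drew a level.  ``m_step`` defaults to the daily rate
    ``m_annual / 365``.
    """
    if m_step is None:
        m_step = daily_mortality(state.m_annual)
    if m_step < 0:
        raise ValueError("m_step must be non-negative")
    y = np.asarray(removals, dtype=float)
    if y.shape != state.n.shape:
        raise ValueError("removals must be a per-level vector")
    if (y < 0).any():
        raise ValueError("removals must be non-negative")
    if (y > state.n).any():
        over = int((y > state.n).sum())
        log.warning("removals exceed abundance at %d level(s); clamping", over)
        y = np.minimum(y, state.n)
    n_next = (state.n - y) * np.exp(-m_step)
    return replace(state, n=n_next, t=state.t + 1)
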