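"""Synthetic inputs: patchy density rasters and the packaged survey fixture.

The kriged survey rasters behind the 2013 Yucatan assessment are not public,
so this module generates fields with the same statistical structure the
pipeline assumes: smooth, non-negative, with a small number of unimodal
patches whose peak densities sit around 0.30-0.45 ind m^-2 over a background
below the 0.05 ind m^-2 delineation threshold.  It also ships, as plain CSV,
the published per-level table for patch *a* (March 2013) plus the published
parameter set, so the full simulation runs with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import ndimage

from .assessment import DensityLevel, read_levels_csv
from .config import SimConfig, default_config
from .population import PopulationState
from .raster import DensityRaster

__all__ = ["GaussianPatch", "PatchSpec", "generate_patchy_raster",
           "reference_levels", "reference_fixture", "make_assessment_scenario"]


@dataclass(frozen=True)
class GaussianPatch:
    """One smooth unimodal bump: centre (m), peak (ind m^-2), spread (m)."""

    center: tuple[float, float]
    peak: float
    sigma: tuple[float, float]       # anisotropic spread (sx, sy), metres

    def __post_init__(self) -> None:
        if not 0 <= self.peak <= 0.5:
            raise ValueError("peak density outside the realistic 0-0.5 range")
        if min(self.sigma) <= 0:
            raise ValueError("spread must be positive")


@dataclass(frozen=True)
class PatchSpec:
    """Specification of a synthetic kriged-style density field."""

    patches: tuple[GaussianPatch, ...]
    extent: tuple[float, float] = (20000.0, 20000.0)   # (x, y) metres
    cell_size: float = 50.0
    noise_amplitude: float = 0.0     # smooth multiplicative-free additive noise
    noise_length: float = 500.0      # correlation length of the noise, metres
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0 or self.cell_size >= min(self.extent):
            raise ValueError("cell size must be positive and below the extent")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")


def generate_patchy_raster(spec: PatchSpec) -> DensityRaster:
    """Render a sum-of-Gaussian-kernels density field, clipped at zero.

    Optional smooth noise (white noise blurred to ``noise_length``) is added
    before clipping.  Deterministic for a given spec (seed included).
    """
    nx = int(round(spec.extent[0] / spec.cell_size))
    ny = int(round(spec.extent[1] / spec.cell_size))
    # cell-centre coordinates; row 0 is the northernmost row
    x = (np.arange(nx) + 0.5) * spec.cell_size
    y = ((ny - np.arange(ny)) - 0.5) * spec.cell_size
    xx, yy = np.meshgrid(x, y)
    values = np.zeros((ny, nx))
    for p in spec.patches:
        values += p.peak * np.exp(-((xx - p.center[0]) ** 2 / (2 * p.sigma[0] ** 2)
                                    + (yy - p.center[1]) ** 2 / (2 * p.sigma[1] ** 2)))
    if spec.noise_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        white = rng.standard_normal(values.shape)
        sigma_cells = spec.noise_length / spec.cell_size
        smooth = ndimage.gaussian_filter(white, sigma=sigma_cells)
        sd = smooth.std()
        if sd > 0:
            values += spec.noise_amplitude * smooth / sd
    return DensityRaster(values=np.clip(values, 0.0, None),
                         cell_size=spec.cell_size)


def reference_levels() -> list[DensityLevel]:
    """The packaged March-2013 per-level table for patch *a* (eight levels)."""
    ref = resources.files("seapatch.data").joinpath("levels.csv")
    with resources.as_file(ref) as path:
        return read_levels_csv(path)


def reference_fixture() -> tuple[list[DensityLevel], PopulationState, SimConfig]:
    """Levels, day-0 population state and default config, ready to simulate."""
    config = default_config()
    levels = reference_levels()
    state = PopulationState.from_levels(
        levels, w=config.population.mean_weight_kg,
        m_annual=config.population.natural_mortality_per_year)
    return levels, state, config


def make_assessment_scenario(target_levels: list[DensityLevel],
                             cell_size: float = 50.0,
                             padding_cells: int = 4) -> DensityRaster:
    """Build a raster whose binned assessment reproduces a given level table.

    The construction is a nested set of concentric rings: all cells are
    sorted by distance from the grid centre and the closest cells are
    assigned the highest target density, the next ring the second density,
    and so on, with ring sizes chosen so each level's cell count matches its
    target area to within one cell.  The result is a single connected patch
    with piecewise-constant density, exact for round-trip testing.

    Targets must have strictly descending positive densities and positive
    areas; anything else is rejected as infeasible.
    """
    if not target_levels:
        raise ValueError("no target levels given")
    levels = sorted(target_levels, key=lambda lv: lv.index)
    dens = np.array([lv.mean_density for lv in levels])
    areas = np.array([lv.area_m2 for lv in levels])
    if (dens <= 0).any() or (areas <= 0).any():
        raise ValueError("target densities and areas must be positive")
    if (np.diff(dens) >= 0).any():
        raise ValueError("target densities must be strictly descending "
                         "(level 1 densest) for a nested construction")
    cell_area = cell_size ** 2
    counts = np.maximum(1, np.round(areas / cell_area).astype(int))
    cum = np.cumsum(counts)
    side = int(np.ceil(np.sqrt(cum[-1] / np.pi)) * 2) + 2 * padding_cells
    rows, cols = np.indices((side, side))
    centre = (side - 1) / 2.0
    dist = (rows - centre) ** 2 + (cols - centre) ** 2
    if cum[-1] > side * side:
        raise ValueError("targets are infeasible on the constructed grid")
    order = np.argsort(dist, axis=None, kind="stable")
    values = np.zeros(side * side)
    start = 0
    for d, stop in zip(dens, cum):
        values[order[start:stop]] = d
        start = stop
    return DensityRaster(values=values.reshape(side, side), cell_size=cell_size,
                         cell_area=cell_area)
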