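"""Patch delineation, density-level binning and abundance integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seapatch import (DensityRaster, bin_density_levels, biomass_of,
                      delineate_patches, integrate_abundance)
from seapatch.assessment import frame_to_levels, levels_to_frame

THRESHOLD = 0.05


def brute_force_components(values, threshold, connectivity=8):
    """Independent oracle: exhaustive flood fill over the cell grid."""
    mask = np.isfinite(values) & (values >= threshold)
    seen = np.zeros_like(mask, dtype=bool)
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and not seen[r, c]:
                stack, cells = [(r, c)], []
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    cells.append((rr, cc))
                    for dr, dc in nbrs:
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < mask.shape[0] and 0 <= c2 < mask.shape[1]
                                and mask[r2, c2] and not seen[r2, c2]):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
                comps.append(cells)
    return comps


def test_all_zero_raster_has_no_patches():
    r = DensityRaster(values=np.zeros((20, 20)), cell_size=50.0)
    assert delineate_patches(r, THRESHOLD) == []


def test_peak_below_threshold_has_no_patches():
    x = np.linspace(-3, 3, 40)
    bump = 0.04 * np.exp(-(x[None, :] ** 2 + x[:, None] ** 2) / 2)
    r = DensityRaster(values=bump, cell_size=50.0)
    assert delineate_patches(r, THRESHOLD) == []


def test_two_bumps_give_two_patches_matching_cell_scan(two_bump_raster):
    patches = delineate_patches(two_bump_raster, THRESHOLD)
    assert len(patches) == 2
    assert patches[0].area >= patches[1].area  # sorted largest first
    oracle = brute_force_components(two_bump_raster.values, THRESHOLD)
    oracle_areas = sorted((len(c) * two_bump_raster.cell_area for c in oracle),
                          reverse=True)
    assert [p.area for p in patches] == pytest.approx(oracle_areas)
    assert not any(p.touches_border for p in patches)


def test_oracle_equivalence_on_rough_random_field(random_raster):
    """Component areas agree with an exhaustive flood-fill scan."""
    for conn in (4, 8):
        patches = delineate_patches(random_raster, THRESHOLD, connectivity=conn)
        oracle = brute_force_components(random_raster.values, THRESHOLD, conn)
        assert sorted(p.n_cells for p in patches) == sorted(len(c) for c in oracle)


def test_border_component_is_flagged_not_dropped():
    values = np.zeros((10, 10))
    values[0:3, 0:3] = 0.2  # touches the top-left border
    values[6:8, 6:8] = 0.2
    r = DensityRaster(values=values, cell_size=50.0)
    patches = delineate_patches(r, THRESHOLD)
    assert len(patches) == 2
    assert patches[0].touches_border and not patches[1].touches_border


def test_threshold_must_be_positive(two_bump_raster):
    with pytest.raises(ValueError):
        delineate_patches(two_bump_raster, -0.05)


def test_integrate_uniform_field_equals_density_times_area():
    r = DensityRaster(values=np.full((10, 10), 0.2), cell_size=50.0)
    region = np.ones((10, 10), dtype=bool)
    assert integrate_abundance(r, region) == pytest.approx(0.2 * 100 * 2500)


def test_integrate_matches_per_cell_loop(random_raster):
    region = random_raster.values > 0.05
    expected = sum(random_raster.values[r, c] * random_raster.cell_area
                   for r, c in zip(*np.nonzero(region)))
    assert integrate_abundance(random_raster, region) == pytest.approx(
        expected, rel=1e-12)


def test_integrate_warns_on_nodata_and_counts_it_as_zero():
    values = np.array([[0.1, np.nan], [0.3, 0.2]])
    r = DensityRaster(values=values, cell_size=10.0)
    with pytest.warns(UserWarning, match="nodata"):
        total = integrate_abundance(r, np.ones((2, 2), dtype=bool))
    assert total == pytest.approx(0.6 * 100.0)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.5, 3.0))
def test_integrate_additive_and_degree_one_homogeneous(seed, scale):
    rng = np.random.default_rng(seed)
    values = rng.uniform(0, 0.5, size=(12, 15))
    r = DensityRaster(values=values, cell_size=50.0)
    region_a = np.zeros_like(values, dtype=bool)
    region_a[:6] = True
    region_b = ~region_a
    whole = np.ones_like(values, dtype=bool)
    total = integrate_abundance(r, whole)
    assert integrate_abundance(r, region_a) + integrate_abundance(r, region_b) \
        == pytest.approx(total)
    scaled = DensityRaster(values=scale * values, cell_size=50.0)
    assert integrate_abundance(scaled, whole) == pytest.approx(scale * total)


def test_biomass_conversion():
    assert biomass_of(0, 0.5395) == 0.0
    assert biomass_of(1_000_000, 0.5) == pytest.approx(500.0)
    with pytest.raises(ValueError):
        biomass_of(10, 0.0)
    with pytest.raises(ValueError):
        biomass_of(-1, 0.5)


def test_uniform_patch_bins_to_single_level():
    r = DensityRaster(values=np.full((20, 50), 0.20), cell_size=50.0,
                      cell_area=50.0)  # 1000 cells of 50 m^2
    patch = delineate_patches(r, THRESHOLD)[0]
    levels = bin_density_levels(patch, r, interval=0.05, w=0.5395)
    assert len(levels) == 1
    lv = levels[0]
    assert lv.area_m2 == pytest.approx(50_000.0)
    assert lv.abundance == pytest.approx(10_000.0)
    assert lv.mean_density == pytest.approx(0.20)
    assert lv.c_kg == pytest.approx(50_000.0 * 0.5395)


def test_binning_partitions_patch(two_bump_raster):
    """Level areas sum to patch area; abundances to the patch integral."""
    for patch in delineate_patches(two_bump_raster, THRESHOLD):
        levels = bin_density_levels(patch, two_bump_raster, 0.05, w=0.5395)
        assert sum(lv.area_m2 for lv in levels) == pytest.approx(patch.area)
        assert sum(lv.abundance for lv in levels) == pytest.approx(
            integrate_abundance(two_bump_raster, patch.mask), rel=1e-10)
        # levels ordered densest first, indexed from 1
        dens = [lv.mean_density for lv in levels]
        assert dens == sorted(dens, reverse=True)
        assert [lv.index for lv in levels] == list(range(1, len(levels) + 1))
        # every level mean sits inside its half-open bin
        for lv in levels:
            k = int((lv.mean_density - THRESHOLD) // 0.05)
            assert THRESHOLD + 0.05 * k <= lv.mean_density < THRESHOLD + 0.05 * (k + 1)


def test_binning_rejects_bad_weight(two_bump_raster):
    patch = delineate_patches(two_bump_raster, THRESHOLD)[0]
    with pytest.raises(ValueError):
        bin_density_levels(patch, two_bump_raster, 0.05, w=0.0)
    with pytest.raises(ValueError):
        bin_density_levels(patch, two_bump_raster, -0.05, w=0.5)


def test_level_table_round_trip(fixture_bundle):
    levels, _, _ = fixture_bundle
    back = frame_to_levels(levels_to_frame(levels))
    assert [lv.index for lv in back] == [lv.index for lv in levels]
    assert [lv.c_kg for lv in back] == [lv.c_kg for lv in levels]


def test_catchability_scale_constant_matches_survey_table(fixture_bundle):
    """c_i = area_i x w reproduces every published c_i to the nearest kg."""
    levels, _, _ = fixture_bundle
    for lv in levels:
        assert round(lv.area_m2 * 0.5395) == lv.c_kg
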