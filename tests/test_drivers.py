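"""Climate velocity, roughness, NRI and the bioregion driver model."""

import numpy as np
import pandas as pd
import pytest

from speciogeo.drivers import (
    assemble_bioregion_table,
    climate_velocity,
    nri,
    region_mean,
    roughness,
    run_driver_model,
    spatial_gradient,
    velocity_over_horizons,
)
from speciogeo.grid import build_pam
from speciogeo.simulate import (
    GridSpec,
    partition_bioregions,
    simulate_bd_tree,
    simulate_elevation,
)
from speciogeo.trees import Phylogeny, parse_newick


def brute_force_gradient(z, cellsize):
    """Horn stencil evaluated cell by cell on an explicitly padded array.

    The border is extended by one cell of odd reflection applied axis by
    axis (rows first, then columns), built here with plain Python loops.
    """
    nr, nc = z.shape
    rowpad = np.empty((nr + 2, nc))
    rowpad[1:-1] = z
    for j in range(nc):
        rowpad[0, j] = 2 * z[0, j] - z[1, j]
        rowpad[-1, j] = 2 * z[-1, j] - z[-2, j]
    p = np.empty((nr + 2, nc + 2))
    p[:, 1:-1] = rowpad
    for i in range(nr + 2):
        p[i, 0] = 2 * rowpad[i, 0] - rowpad[i, 1]
        p[i, -1] = 2 * rowpad[i, -1] - rowpad[i, -2]

    out = np.empty_like(z, dtype=float)
    for i in range(nr):
        for j in range(nc):
            ii, jj = i + 1, j + 1
            dzdx = (
                (p[ii - 1, jj + 1] + 2 * p[ii, jj + 1] + p[ii + 1, jj + 1])
                - (p[ii - 1, jj - 1] + 2 * p[ii, jj - 1]
                   + p[ii + 1, jj - 1])
            ) / (8 * cellsize)
            dzdy = (
                (p[ii + 1, jj - 1] + 2 * p[ii + 1, jj] + p[ii + 1, jj + 1])
                - (p[ii - 1, jj - 1] + 2 * p[ii - 1, jj]
                   + p[ii - 1, jj + 1])
            ) / (8 * cellsize)
            out[i, j] = np.hypot(dzdx, dzdy)
    return out


def brute_force_roughness(z):
    nr, nc = z.shape
    out = np.empty_like(z, dtype=float)
    for i in range(nr):
        for j in range(nc):
            vals = [
                z[ii, jj]
                for ii in range(max(0, i - 1), min(nr, i + 2))
                for jj in range(max(0, j - 1), min(nc, j + 2))
            ]
            out[i, j] = max(vals) - min(vals)
    return out


class TestVelocity:
    def test_linear_gradient_closed_form(self):
        # 1 unit/km spatial gradient, 1 unit change per 1000 yr
        cell_km = 50.0
        rows = np.arange(12.0)[:, None] * np.ones((1, 15))
        current = rows * cell_km
        past = current - 1.0
        v = climate_velocity(current, past, 1000.0, cell_km)
        np.testing.assert_allclose(v, 0.001, rtol=1e-12)

    def test_no_change_zero_velocity(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(10, 10)).cumsum(axis=0)
        v = climate_velocity(z, z.copy(), 500.0, 10.0)
        assert np.nanmax(np.abs(v)) == 0.0

    def test_matches_stencil_oracle(self):
        rng = np.random.default_rng(1)
        from scipy import ndimage

        z = ndimage.gaussian_filter(rng.normal(size=(30, 40)), 2.0)
        grad = spatial_gradient(z, 25.0)
        np.testing.assert_allclose(grad, brute_force_gradient(z, 25.0),
                                   atol=1e-12)

    def test_flat_raster_flagged_undefined(self):
        v = climate_velocity(np.ones((5, 5)), np.zeros((5, 5)), 100.0, 10.0)
        assert np.isnan(v).all()

    def test_multi_variable_mean_and_horizons(self):
        cell_km = 100.0
        rows = np.arange(10.0)[:, None] * np.ones((1, 10)) * cell_km
        # two variables with different temporal changes: 1 and 3 units
        stack = np.stack([
            np.stack([rows, rows - 1.0]),
            np.stack([rows, rows - 3.0]),
        ])
        v = velocity_over_horizons(stack, [1000.0], cell_km)
        np.testing.assert_allclose(v, (0.001 + 0.003) / 2, rtol=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share the grid"):
            climate_velocity(np.ones((5, 5)), np.ones((6, 5)), 1.0, 1.0)


class TestRoughness:
    def test_constant_raster_zero(self):
        assert np.all(roughness(np.full((8, 8), 3.3)) == 0)

    def test_three_by_three_center(self):
        r = roughness(np.arange(1.0, 10.0).reshape(3, 3))
        assert r[1, 1] == 8.0

    def test_matches_neighbourhood_scan(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(25, 31))
        np.testing.assert_allclose(roughness(z), brute_force_roughness(z))

    def test_region_mean_and_missing_region(self, small_grid):
        region, _ = partition_bioregions(small_grid, 3, seed=0)
        elev = simulate_elevation(small_grid, seed=1, relief=100.0)
        means = region_mean(roughness(elev), region)
        assert len(means) == 3
        for j in range(3):
            assert means[j] == pytest.approx(
                roughness(elev)[region == j].mean()
            )


class TestNRI:
    def _random_world(self, seed, n_species=40, n_cells=30, rich=(3, 10)):
        rng = np.random.default_rng(seed)
        grid = GridSpec(lat_min=0, lat_max=10, lon_min=0, lon_max=10,
                        resolution=2.0)  # 25 cells
        tree = simulate_bd_tree(0.3, 0.0, n_species, rng)
        species = tree.tip_labels
        ranges = {s: [] for s in species}
        for cell in range(min(n_cells, grid.n_cells)):
            k = int(rng.integers(*rich))
            for s in rng.choice(species, size=k, replace=False):
                ranges[s].append(cell)
        ranges = {s: np.array(c) for s, c in ranges.items() if c}
        ag = build_pam(ranges, grid)
        regions = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
        return tree, ag, regions

    def test_random_assemblages_centre_on_zero(self):
        tree, ag, regions = self._random_world(3)
        per_region, cells = nri(ag, tree, regions, n_rand=199, seed=5)
        assert abs(per_region.iloc[0]) < 0.35  # desk-scale null check

    def test_sister_pair_community_is_clustered(self):
        # pool of distant tips; one community holds only the two sisters
        tree = parse_newick(
            "((A:1,B:1):9,((C:5,D:5):4,(E:5,F:5):4):1);"
        )
        grid = GridSpec(lat_min=0, lat_max=4, lon_min=0, lon_max=4,
                        resolution=2.0)
        ranges = {
            "A": np.array([0]), "B": np.array([0]),
            "C": np.array([1]), "E": np.array([1]),
            "D": np.array([2]), "F": np.array([2]),
        }
        ag = build_pam(ranges, grid)
        regions = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
        per_region, cells = nri(ag, tree, regions, n_rand=299, seed=1)
        sister_cell = cells[cells.cell_id == 0].iloc[0]
        assert sister_cell["mpd_obs"] == pytest.approx(2.0)
        assert sister_cell["nri"] > 0

    def test_branch_doubling_leaves_nri_unchanged(self):
        tree, ag, regions = self._random_world(7)
        doubled = Phylogeny(
            tree.parent.copy(), tree.edge_length * 2.0,
            list(tree.tip_labels), tree.tip_nodes.copy(),
        )
        a_reg, a_cells = nri(ag, tree, regions, n_rand=99, seed=2)
        b_reg, b_cells = nri(ag, doubled, regions, n_rand=99, seed=2)
        np.testing.assert_allclose(
            b_cells["mpd_obs"], a_cells["mpd_obs"] * 2.0, rtol=1e-12
        )
        np.testing.assert_allclose(b_cells["nri"], a_cells["nri"],
                                   rtol=1e-9)

    def test_degenerate_two_species_pool_flagged(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        grid = GridSpec(lat_min=0, lat_max=2, lon_min=0, lon_max=4,
                        resolution=2.0)
        # region pool = {A, B} only: every shuffle maps the pair to itself
        ranges = {"A": np.array([0]), "B": np.array([0])}
        ag = build_pam(ranges, grid)
        regions = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
        # the one valid cell has a 2-species pool: every shuffle maps the
        # pair onto itself, the null sd is 0 and the cell is flagged NaN
        per_region, cells = nri(ag, tree, regions, n_rand=19, seed=0)
        assert np.isnan(cells["nri"]).all()
        assert per_region.empty


class TestDriverTableAndModel:
    def test_patristic_matrix_hand_case(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        D = tree.patristic_matrix()
        labels = tree.tip_labels
        d = {(a, b): D[i, j] for i, a in enumerate(labels)
             for j, b in enumerate(labels)}
        assert d[("A", "B")] == pytest.approx(2.0)
        assert d[("A", "C")] == pytest.approx(4.0)

    def test_constant_predictor_rejected(self, small_grid):
        region, table = partition_bioregions(small_grid, 4, seed=1)
        table = table.copy()
        table["productivity"] = 1.0  # constant
        summaries = pd.DataFrame(
            {
                "lat": small_grid.cell_centroids()[0].ravel(),
                "lon": small_grid.cell_centroids()[1].ravel(),
                "mean_rate": np.linspace(0.1, 0.3, small_grid.n_cells),
            },
            index=pd.RangeIndex(small_grid.n_cells, name="cell_id"),
        )
        vel = np.random.default_rng(0).uniform(0.1, 1, region.shape)
        rough = np.random.default_rng(1).uniform(0, 100, region.shape)
        nri_vals = pd.Series(0.0, index=range(4))
        with pytest.raises(ValueError, match="constant predictor"):
            assemble_bioregion_table(
                summaries, region,
                None, vel, rough, nri_vals, table,
            )

    def test_too_few_regions_rejected(self):
        tab = pd.DataFrame({"mean_rate": [0.1] * 5})
        with pytest.raises(ValueError, match="regions"):
            run_driver_model(tab)
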