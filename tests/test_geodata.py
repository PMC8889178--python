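"""Raster I/O, cropping, occurrence filtering, absences, pixel areas."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from enmrange import geodata
from enmrange.geodata import (
    AlignmentError,
    EmptyDesignError,
    ExtentConfig,
    ExtentError,
    UnknownSpeciesError,
    crop_extent,
    derive_absences,
    extract_covariates,
    filter_occurrences,
    pixel_area,
    read_env_stack,
    write_ascii_grid,
)

from conftest import make_stack


def occ(rows):
    return pd.DataFrame(rows, columns=["species", "lon", "lat", "presence", "source"])


# ---------------------------------------------------------------------------
# ASCII grids and stack reading


class TestStackIO:
    def test_roundtrip_preserves_values_and_nodata(self, tmp_path, stack10):
        arr = stack10.layers["v0"].copy()
        arr[0, 0] = np.nan
        p = tmp_path / "layer.asc"
        write_ascii_grid(p, arr, stack10.extent, stack10.resolution)
        back, header = geodata.read_ascii_grid(p)
        assert np.isnan(back[0, 0])
        np.testing.assert_allclose(back[1:], arr[1:], rtol=1e-6)
        assert header["cellsize"] == pytest.approx(stack10.resolution)

    def test_read_env_stack_two_aligned_layers(self, tmp_path, stack10):
        paths = []
        for name in ("a", "b"):
            p = tmp_path / f"{name}.asc"
            write_ascii_grid(p, np.ones((10, 10)), stack10.extent,
                             stack10.resolution)
            paths.append(p)
        stack = read_env_stack(paths, ["continuous", "continuous"])
        assert stack.names == ["a", "b"]
        assert stack.mask.all()

    def test_nodata_union_becomes_mask(self, tmp_path, stack10):
        a = np.ones((10, 10))
        a[0, :3] = np.nan  # 3 nodata cells
        p1, p2 = tmp_path / "a.asc", tmp_path / "b.asc"
        write_ascii_grid(p1, a, stack10.extent, stack10.resolution)
        write_ascii_grid(p2, np.ones((10, 10)), stack10.extent, stack10.resolution)
        stack = read_env_stack([p1, p2], ["continuous", "continuous"])
        assert stack.mask.sum() == 97

    def test_mismatched_extents_raise(self, tmp_path, stack10):
        other = make_stack(lat_min=-40.0)
        p1, p2 = tmp_path / "a.asc", tmp_path / "b.asc"
        write_ascii_grid(p1, np.ones((10, 10)), stack10.extent, stack10.resolution)
        write_ascii_grid(p2, np.ones((10, 10)), other.extent, other.resolution)
        with pytest.raises(AlignmentError):
            read_env_stack([p1, p2], ["continuous", "continuous"])


# ---------------------------------------------------------------------------
# Cropping


class TestCrop:
    def test_full_extent_is_identity(self, stack10):
        out = crop_extent(stack10, stack10.extent)
        assert out.shape == stack10.shape
        np.testing.assert_array_equal(out.layers["v0"], stack10.layers["v0"])

    def test_ne_quadrant_of_20x20(self):
        stack = make_stack(nrows=20, ncols=20)
        e = stack.extent
        quad_extent = ExtentConfig(
            lat_min=(e.lat_min + e.lat_max) / 2, lat_max=e.lat_max,
            lon_min=(e.lon_min + e.lon_max) / 2, lon_max=e.lon_max)
        out = crop_extent(stack, quad_extent)
        assert out.shape == (10, 10)
        np.testing.assert_array_equal(out.layers["v0"], stack.layers["v0"][:10, 10:])

    def test_misaligned_bounds_snap_outward(self):
        # oracle: index arithmetic on the source cell grid
        stack = make_stack(nrows=20, ncols=20, res=0.1)
        e = stack.extent
        req = ExtentConfig(lat_min=e.lat_min + 0.33, lat_max=e.lat_max - 0.27,
                           lon_min=e.lon_min + 0.14, lon_max=e.lon_max - 0.46)
        out = crop_extent(stack, req)
        r0 = math.floor((e.lat_max - req.lat_max) / 0.1)   # 2
        r1 = math.ceil((e.lat_max - req.lat_min) / 0.1)    # 17
        c0 = math.floor((req.lon_min - e.lon_min) / 0.1)   # 1
        c1 = math.ceil((req.lon_max - e.lon_min) / 0.1)    # 16
        assert out.shape == (r1 - r0, c1 - c0)
        np.testing.assert_array_equal(out.layers["v1"],
                                      stack.layers["v1"][r0:r1, c0:c1])
        # snapped bounds cover the request
        assert out.extent.lat_min <= req.lat_min and out.extent.lat_max >= req.lat_max

    def test_crop_is_idempotent(self, stack10):
        e = stack10.extent
        req = ExtentConfig(lat_min=e.lat_min + 0.15, lat_max=e.lat_max - 0.15,
                           lon_min=e.lon_min + 0.15, lon_max=e.lon_max - 0.15)
        once = crop_extent(stack10, req)
        twice = crop_extent(once, req)
        assert once.shape == twice.shape
        np.testing.assert_array_equal(once.layers["v0"], twice.layers["v0"])

    def test_empty_intersection_raises(self, stack10):
        with pytest.raises(ExtentError):
            crop_extent(stack10, ExtentConfig(lat_min=0, lat_max=1,
                                              lon_min=0, lon_max=1))


# ---------------------------------------------------------------------------
# Occurrence filtering


class TestFilterOccurrences:
    def test_nearby_records_collapse_to_one_cell(self):
        raw = occ([("sp", 170.123, -43.456, 1, ""), ("sp", 170.121, -43.459, 1, "")])
        out, rep = filter_occurrences(raw)
        assert len(out) == 1
        assert out.loc[0, "lon"] == pytest.approx(170.12)
        assert out.loc[0, "lat"] == pytest.approx(-43.46)
        assert rep.n_duplicates == 1

    def test_same_place_different_species_both_kept(self):
        raw = occ([("a", 170.12, -43.46, 1, ""), ("b", 170.12, -43.46, 1, "")])
        out, _ = filter_occurrences(raw)
        assert len(out) == 2

    def test_twelve_row_fixture_with_three_duplicates(self):
        # hand-enumerated: 3 rows duplicate an earlier (species, cell, presence)
        rows = [
            ("a", 170.001, -43.001, 1, ""),
            ("a", 170.004, -43.004, 1, ""),   # dup of row 0 after rounding
            ("a", 170.011, -43.001, 1, ""),
            ("a", 170.013, -43.002, 1, ""),   # dup of row 2
            ("a", 170.100, -43.100, 0, ""),
            ("b", 170.001, -43.001, 1, ""),
            ("b", 170.003, -43.002, 1, ""),   # dup of row 5
            ("b", 170.200, -43.200, 1, ""),
            ("c", 170.001, -43.001, 1, ""),
            ("c", 170.300, -43.300, 0, ""),
            ("c", 170.400, -43.400, 1, ""),
            ("c", 170.500, -43.500, 1, ""),
        ]
        out, rep = filter_occurrences(occ(rows))
        assert rep.n_duplicates == 3
        assert len(out) == 9

    def test_presence_wins_over_absence_in_same_cell(self):
        raw = occ([("a", 170.001, -43.001, 0, ""), ("a", 170.002, -43.002, 1, "")])
        out, rep = filter_occurrences(raw)
        assert len(out) == 1
        assert out.loc[0, "presence"] == 1
        assert rep.n_conflicts_resolved == 1

    def test_outside_extent_removed_and_counted(self):
        extent = ExtentConfig()
        raw = occ([("a", 170.0, -43.0, 1, ""), ("a", 10.0, 50.0, 1, "")])
        out, rep = filter_occurrences(raw, extent)
        assert len(out) == 1
        assert rep.n_outside_extent == 1

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        raw = occ([(f"s{i % 3}", 170 + rng.uniform(0, 0.5),
                    -43 - rng.uniform(0, 0.5), int(rng.integers(2)), "")
                   for i in range(50)])
        once, _ = filter_occurrences(raw)
        twice, rep = filter_occurrences(once)
        pd.testing.assert_frame_equal(once, twice)
        assert rep.n_duplicates == 0 and rep.n_conflicts_resolved == 0

    def test_round_half_away_from_zero(self):
        raw = occ([("a", 170.125, -43.125, 1, "")])
        out, _ = filter_occurrences(raw)
        assert out.loc[0, "lon"] == pytest.approx(170.13)
        assert out.loc[0, "lat"] == pytest.approx(-43.13)


# ---------------------------------------------------------------------------
# Absence derivation


class TestDeriveAbsences:
    def table_on(self, stack, cells, species, presence=1):
        rows = []
        for (r, c) in cells:
            lon = stack.extent.lon_min + (c + 0.5) * stack.resolution
            lat = stack.extent.lat_max - (r + 0.5) * stack.resolution
            rows.append((species, lon, lat, presence, ""))
        return occ(rows)

    def test_no_absences_when_target_everywhere(self, stack10):
        cells = [(0, 0), (1, 1)]
        tab = pd.concat([self.table_on(stack10, cells, "t"),
                         self.table_on(stack10, cells, "o")], ignore_index=True)
        out = derive_absences(tab, "t", stack10)
        assert (out["presence"] == 0).sum() == 0

    def test_disjoint_other_cells_become_absences(self, stack10):
        tab = pd.concat([
            self.table_on(stack10, [(0, 0)], "t"),
            self.table_on(stack10, [(2, 2), (3, 3), (4, 4), (5, 5), (6, 6)], "o"),
        ], ignore_index=True)
        out = derive_absences(tab, "t", stack10)
        assert (out["presence"] == 0).sum() == 5
        assert (out["presence"] == 1).sum() == 1

    def test_shared_cell_excluded_set_oracle(self, stack10):
        target_cells = {(0, 0), (1, 2), (3, 3)}
        other_cells = {(3, 3), (4, 4), (5, 5), (1, 2), (7, 8)}
        tab = pd.concat([
            self.table_on(stack10, sorted(target_cells), "t"),
            self.table_on(stack10, sorted(other_cells), "o"),
        ], ignore_index=True)
        out = derive_absences(tab, "t", stack10)
        expected_absence_cells = other_cells - target_cells
        arow, acol = stack10.cell_index(
            out.loc[out["presence"] == 0, "lon"].to_numpy(),
            out.loc[out["presence"] == 0, "lat"].to_numpy())
        assert set(zip(arow.tolist(), acol.tolist())) == expected_absence_cells

    def test_presence_and_absence_cells_disjoint(self, stack10, rng):
        rows = []
        for sp in ("t", "u", "v"):
            for _ in range(30):
                lon = rng.uniform(stack10.extent.lon_min, stack10.extent.lon_max)
                lat = rng.uniform(stack10.extent.lat_min, stack10.extent.lat_max)
                rows.append((sp, lon, lat, int(rng.integers(2)), ""))
        out = derive_absences(occ(rows), "t", stack10)
        prow, pcol = stack10.cell_index(
            out.loc[out["presence"] == 1, "lon"].to_numpy(),
            out.loc[out["presence"] == 1, "lat"].to_numpy())
        arow, acol = stack10.cell_index(
            out.loc[out["presence"] == 0, "lon"].to_numpy(),
            out.loc[out["presence"] == 0, "lat"].to_numpy())
        assert not (set(zip(prow, pcol)) & set(zip(arow, acol)))

    def test_unknown_species_raises(self, stack10):
        tab = self.table_on(stack10, [(0, 0)], "a")
        with pytest.raises(UnknownSpeciesError):
            derive_absences(tab, "zzz", stack10)


# ---------------------------------------------------------------------------
# Covariate extraction


class TestExtractCovariates:
    def test_cell_center_lookup(self, stack10):
        lon = stack10.extent.lon_min + 2.5 * stack10.resolution
        lat = stack10.extent.lat_max - 3.5 * stack10.resolution
        X, y, nd = extract_covariates(stack10, occ([("a", lon, lat, 1, "")]))
        assert X.loc[0, "v0"] == stack10.layers["v0"][3, 2]
        assert nd == 0 and y[0] == 1

    def test_edge_point_half_open_rule(self, stack10):
        # a point exactly on an interior cell edge belongs to the next cell
        lon = stack10.extent.lon_min + 2 * stack10.resolution
        lat = stack10.extent.lat_max - 3 * stack10.resolution
        X, _, _ = extract_covariates(stack10, occ([("a", lon, lat, 1, "")]))
        assert X.loc[0, "v0"] == stack10.layers["v0"][3, 2]
        # max-edge points belong to the last cell
        X2, _, _ = extract_covariates(stack10, occ(
            [("a", stack10.extent.lon_max, stack10.extent.lat_min, 1, "")]))
        assert X2.loc[0, "v0"] == stack10.layers["v0"][9, 9]

    def test_ten_point_loop_oracle(self, stack10, rng):
        rows = [("a", rng.uniform(stack10.extent.lon_min, stack10.extent.lon_max),
                 rng.uniform(stack10.extent.lat_min, stack10.extent.lat_max),
                 int(rng.integers(2)), "") for _ in range(10)]
        tab = occ(rows)
        X, y, _ = extract_covariates(stack10, tab)
        for i, (_, lon, lat, pres, _) in enumerate(rows):
            col = int((lon - stack10.extent.lon_min) // stack10.resolution)
            row = int((stack10.extent.lat_max - lat) // stack10.resolution)
            for name in stack10.names:
                assert X.loc[i, name] == stack10.layers[name][row, col]
            assert y[i] == pres

    def test_masked_out_rows_dropped(self):
        mask = np.ones((10, 10), dtype=bool)
        mask[0, 0] = False
        stack = make_stack(mask=mask)
        lon0 = stack.extent.lon_min + 0.5 * stack.resolution
        lat0 = stack.extent.lat_max - 0.5 * stack.resolution
        lon1 = stack.extent.lon_min + 1.5 * stack.resolution
        X, y, nd = extract_covariates(
            stack, occ([("a", lon0, lat0, 1, ""), ("a", lon1, lat0, 0, "")]))
        assert nd == 1 and len(X) == 1

    def test_all_masked_raises(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5:, :] = True
        stack = make_stack(mask=mask)
        lon = stack.extent.lon_min + 0.5 * stack.resolution
        lat = stack.extent.lat_max - 0.5 * stack.resolution
        with pytest.raises(EmptyDesignError):
            extract_covariates(stack, occ([("a", lon, lat, 1, "")]))


# ---------------------------------------------------------------------------
# Pixel areas


class TestPixelArea:
    RES = 1.0 / 120.0

    def test_equator_cell(self):
        # direct evaluation of the spherical-cap formula
        expected = (6371.0**2 * math.radians(self.RES)
                    * (math.sin(math.radians(self.RES / 2))
                       - math.sin(math.radians(-self.RES / 2))))
        assert pixel_area(0.0, self.RES) == pytest.approx(expected)
        assert pixel_area(0.0, self.RES) == pytest.approx(0.859, abs=0.002)

    def test_45S_cell(self):
        assert pixel_area(-45.0, self.RES) == pytest.approx(0.607, abs=0.002)

    def test_pole_limit(self):
        assert pixel_area(90.0, self.RES) < pixel_area(89.0, self.RES)
        assert pixel_area(90.0, self.RES) < 1e-4

    def test_band_sum_matches_analytic_band_area(self):
        # sum of cell areas over a full latitude band row = analytic zone area
        lat0, lat1 = -46.0, -40.0
        n = int(round((lat1 - lat0) / self.RES))
        centers = lat0 + (np.arange(n) + 0.5) * self.RES
        total = pixel_area(centers, self.RES).sum() * (360.0 / self.RES)
        analytic = (2 * math.pi * 6371.0**2
                    * (math.sin(math.radians(lat1)) - math.sin(math.radians(lat0))))
        assert total == pytest.approx(analytic, rel=1e-9)

    def test_numeric_integration_oracle(self):
        # independent oracle: numerically integrate R² cosφ dφ dλ
        lat, res = -43.7, self.RES
        integral, _ = quad(lambda phi: math.cos(phi),
                           math.radians(lat - res / 2), math.radians(lat + res / 2))
        expected = 6371.0**2 * math.radians(res) * integral
        assert pixel_area(lat, res) == pytest.approx(expected, rel=1e-12)
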