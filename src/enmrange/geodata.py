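"""Raster stacks, occurrence tables, and the geographic preprocessing steps.

The pipeline works on a stack of co-registered environmental grids
(continuous climate-like layers plus categorical soil/vegetation-like
layers) in geographic WGS84 coordinates, and on species-labelled
presence/absence point records.  This module provides:

* :class:`EnvStack` — the aligned multi-layer grid with a shared validity
  mask and a per-layer kind (continuous vs categorical);
* ESRI ASCII grid (.asc) read/write for individual layers;
* occurrence-record filtering (coordinates reduced to two decimal places,
  within-species duplicates removed — one record per ~1 km² cell);
* derivation of absences for a focal species from the presences of the
  other species in a multi-species compilation;
* covariate extraction at point locations;
* spherical (geodesic) pixel areas.

Cells are indexed row-major from the NW corner.  A point at (lon, lat)
belongs to column ``floor((lon - lon_min)/res)`` and row
``floor((lat_max - lat)/res)`` with half-open cell intervals; points
exactly on the eastern/southern outer edge are assigned to the last
cell so the configured extent is closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

OCCURRENCE_COLUMNS = ["species", "lon", "lat", "presence", "source"]


class AlignmentError(ValueError):
    """Layers disagree in shape, extent or resolution."""


class ExtentError(ValueError):
    """Requested extent does not intersect the stack."""


class EmptyDesignError(ValueError):
    """No occurrence records fall on valid (masked-in) cells."""


class UnknownSpeciesError(KeyError):
    """Focal species absent from the occurrence table."""


@dataclass(frozen=True)
class ExtentConfig:
    """Geographic bounding box in decimal degrees (WGS84).

    Defaults cover the New Zealand study window used throughout:
    latitudes −49°..−32°, longitudes 165°..180°.
    """

    lat_min: float = -49.0
    lat_max: float = -32.0
    lon_min: float = 165.0
    lon_max: float = 180.0

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError("extent bounds must satisfy min < max")

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )


@dataclass
class EnvStack:
    """Aligned multi-layer raster grid over one extent.

    Parameters
    ----------
    layers
        Mapping of layer name to 2-D float array (rows north to south).
        Categorical layers hold integer codes stored as floats.
    kinds
        Mapping of layer name to ``"continuous"`` or ``"categorical"``.
    extent
        Geographic bounds of the outer grid edges.
    resolution
        Cell size in degrees (default 1/120° = 30 arc-seconds).
    mask
        Boolean grid of valid cells (True = data present).  Defaults to
        the cells where every layer is finite.
    cartesian
        When True, pixel areas are unit squares (no geodesy); used for
        synthetic fixtures where exact area arithmetic matters.
    """

    layers: dict[str, np.ndarray]
    kinds: dict[str, str]
    extent: ExtentConfig
    resolution: float = 1.0 / 120.0
    mask: np.ndarray | None = None
    cartesian: bool = False
    crs_note: str = "geographic WGS84 (EPSG:4326)"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("EnvStack needs at least one layer")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise AlignmentError(f"layers have differing shapes: {shapes}")
        shape = shapes.pop()
        for name in self.layers:
            if self.kinds.get(name) not in ("continuous", "categorical"):
                raise ValueError(f"layer {name!r} needs kind continuous|categorical")
            self.layers[name] = np.asarray(self.layers[name], dtype=float)
        if self.mask is None:
            m = np.ones(shape, dtype=bool)
            for a in self.layers.values():
                m &= np.isfinite(a)
            self.mask = m
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise AlignmentError("mask shape differs from layer shape")
        nrows, ncols = shape
        exp_rows = (self.extent.lat_max - self.extent.lat_min) / self.resolution
        exp_cols = (self.extent.lon_max - self.extent.lon_min) / self.resolution
        if abs(exp_rows - nrows) > 1e-6 or abs(exp_cols - ncols) > 1e-6:
            raise AlignmentError(
                f"extent/resolution imply {exp_rows:.3f}×{exp_cols:.3f} cells, "
                f"layers are {nrows}×{ncols}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def continuous_names(self) -> list[str]:
        return [n for n in self.layers if self.kinds[n] == "continuous"]

    @property
    def categorical_names(self) -> list[str]:
        return [n for n in self.layers if self.kinds[n] == "categorical"]

    def copy(self) -> "EnvStack":
        return EnvStack(
            layers={n: a.copy() for n, a in self.layers.items()},
            kinds=dict(self.kinds),
            extent=self.extent,
            resolution=self.resolution,
            mask=self.mask.copy(),
            cartesian=self.cartesian,
            crs_note=self.crs_note,
        )

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (half-open convention)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        nrows, ncols = self.shape
        # 1e-9 cell-units snap keeps points on exact edges in the intended
        # half-open interval despite floating-point rounding
        col = np.floor((lon - self.extent.lon_min) / self.resolution + 1e-9).astype(int)
        row = np.floor((self.extent.lat_max - lat) / self.resolution + 1e-9).astype(int)
        # points on the outer max edge belong to the last cell
        col = np.where((lon == self.extent.lon_max), ncols - 1, col)
        row = np.where((lat == self.extent.lat_min), nrows - 1, row)
        return row, col

    def row_center_lat(self, row) -> np.ndarray:
        row = np.asarray(row, dtype=float)
        return self.extent.lat_max - (row + 0.5) * self.resolution

    def cell_areas(self) -> np.ndarray:
        """Per-row cell area in km² broadcast to the grid shape.

        Cartesian mode yields unit areas, making patch-area oracles exact.
        """
        nrows, ncols = self.shape
        if self.cartesian:
            return np.ones((nrows, ncols))
        lats = self.row_center_lat(np.arange(nrows))
        col_area = pixel_area(lats, self.resolution)
        return np.repeat(col_area[:, None], ncols, axis=1)

    def design_matrix(self, rows, cols) -> pd.DataFrame:
        data = {n: self.layers[n][rows, cols] for n in self.names}
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array with NaN nodata, header dict)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    idx = 0
    while idx < len(lines):
        parts = lines[idx].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            idx += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise IOError(f"{path}: missing ASCII-grid header field {key}")
    body = " ".join(lines[idx:])
    arr = np.array(body.split(), dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if arr.size != nrows * ncols:
        raise IOError(f"{path}: expected {nrows * ncols} values, found {arr.size}")
    arr = arr.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    return arr, header


def write_ascii_grid(path: str | Path, array: np.ndarray, extent: ExtentConfig,
                     resolution: float, nodata: float = -9999.0) -> None:
    arr = np.asarray(array, dtype=float)
    out = np.where(np.isfinite(arr), arr, nodata)
    nrows, ncols = arr.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {extent.lon_min:.10g}\n")
        fh.write(f"yllcorner {extent.lat_min:.10g}\n")
        fh.write(f"cellsize {resolution:.10g}\n")
        fh.write(f"nodata_value {nodata:.10g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_env_stack(paths: Sequence[str | Path], kinds: Sequence[str] | Mapping[str, str],
                   names: Sequence[str] | None = None,
                   cartesian: bool = False) -> EnvStack:
    """Read aligned single-layer ASCII grids into one :class:`EnvStack`.

    The union of per-layer nodata cells becomes the stack mask.  Layers
    must be coextensive; a mismatch raises :class:`AlignmentError`.
    """
    paths = [Path(p) for p in paths]
    if names is None:
        names = [p.stem for p in paths]
    if isinstance(kinds, Mapping):
        kind_list = [kinds[n] for n in names]
    else:
        kind_list = list(kinds)
    if len(kind_list) != len(paths):
        raise ValueError("one kind per layer required")

    layers: dict[str, np.ndarray] = {}
    ref_header: dict | None = None
    for name, path in zip(names, paths):
        arr, header = read_ascii_grid(path)
        geo = {k: header[k] for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")}
        if ref_header is None:
            ref_header = geo
        elif any(abs(geo[k] - ref_header[k]) > 1e-9 for k in geo):
            raise AlignmentError(f"{path}: extent/shape differs from first layer")
        layers[name] = arr
    assert ref_header is not None
    res = ref_header["cellsize"]
    extent = ExtentConfig(
        lat_min=ref_header["yllcorner"],
        lat_max=ref_header["yllcorner"] + ref_header["nrows"] * res,
        lon_min=ref_header["xllcorner"],
        lon_max=ref_header["xllcorner"] + ref_header["ncols"] * res,
    )
    mask = np.ones(next(iter(layers.values())).shape, dtype=bool)
    for arr in layers.values():
        mask &= np.isfinite(arr)
    return EnvStack(layers=layers, kinds=dict(zip(names, kind_list)),
                    extent=extent, resolution=res, mask=mask, cartesian=cartesian)


def write_env_stack(stack: EnvStack, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in stack.names:
        arr = np.where(stack.mask, stack.layers[name], np.nan)
        p = directory / f"{name}.asc"
        write_ascii_grid(p, arr, stack.extent, stack.resolution)
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# Cropping


def crop_extent(stack: EnvStack, extent: ExtentConfig) -> EnvStack:
    """Crop to the intersection with ``extent``, snapped outward to cell edges."""
    s, e = stack.extent, extent
    lon_lo = max(s.lon_min, e.lon_min)
    lon_hi = min(s.lon_max, e.lon_max)
    lat_lo = max(s.lat_min, e.lat_min)
    lat_hi = min(s.lat_max, e.lat_max)
    if lon_lo >= lon_hi or lat_lo >= lat_hi:
        raise ExtentError("requested extent does not intersect the stack")
    res = stack.resolution
    nrows, ncols = stack.shape
    c0 = int(np.clip(math.floor((lon_lo - s.lon_min) / res + 1e-9), 0, ncols - 1))
    c1 = int(np.clip(math.ceil((lon_hi - s.lon_min) / res - 1e-9), c0 + 1, ncols))
    r0 = int(np.clip(math.floor((s.lat_max - lat_hi) / res + 1e-9), 0, nrows - 1))
    r1 = int(np.clip(math.ceil((s.lat_max - lat_lo) / res - 1e-9), r0 + 1, nrows))
    new_extent = ExtentConfig(
        lat_min=s.lat_max - r1 * res,
        lat_max=s.lat_max - r0 * res,
        lon_min=s.lon_min + c0 * res,
        lon_max=s.lon_min + c1 * res,
    )
    return EnvStack(
        layers={n: a[r0:r1, c0:c1].copy() for n, a in stack.layers.items()},
        kinds=dict(stack.kinds),
        extent=new_extent,
        resolution=res,
        mask=stack.mask[r0:r1, c0:c1].copy(),
        cartesian=stack.cartesian,
        crs_note=stack.crs_note,
    )


# ---------------------------------------------------------------------------
# Occurrence tables


def _round_half_away(x: np.ndarray, decimals: int = 2) -> np.ndarray:
    """Round half away from zero (platform-stable, unlike banker's rounding)."""
    factor = 10.0 ** decimals
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


@dataclass
class FilterReport:
    n_raw: int = 0
    n_outside_extent: int = 0
    n_duplicates: int = 0
    n_conflicts_resolved: int = 0
    n_kept: int = 0


def filter_occurrences(
    raw: pd.DataFrame,
    extent: ExtentConfig | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Clean an occurrence table to one record per species per ~1 km² cell.

    Coordinates are rounded to two decimal places (half away from zero);
    within-species duplicate (lon, lat, presence) rows are dropped; rows
    outside ``extent`` are removed and counted.  Where one species carries
    both a presence and an absence at the same rounded location, the
    presence wins: a confirmed detection overrides a non-detection.
    The operation is idempotent.
    """
    report = FilterReport(n_raw=len(raw))
    df = raw.copy()
    for col in ("species", "lon", "lat", "presence"):
        if col not in df.columns:
            raise ValueError(f"occurrence table missing column {col!r}")
    if "source" not in df.columns:
        df["source"] = ""
    df["lon"] = _round_half_away(df["lon"].to_numpy(), 2)
    df["lat"] = _round_half_away(df["lat"].to_numpy(), 2)
    df["presence"] = df["presence"].astype(int)

    if extent is not None:
        inside = extent.contains(df["lon"].to_numpy(), df["lat"].to_numpy())
        report.n_outside_extent = int((~inside).sum())
        df = df[inside]

    n_before = len(df)
    df = df.drop_duplicates(subset=["species", "lon", "lat", "presence"], keep="first")
    report.n_duplicates = n_before - len(df)

    # presence overrides absence at the same rounded cell for one species
    n_before = len(df)
    df = (
        df.sort_values("presence", ascending=False, kind="stable")
        .drop_duplicates(subset=["species", "lon", "lat"], keep="first")
    )
    report.n_conflicts_resolved = n_before - len(df)

    df = df.sort_index().reset_index(drop=True)
    report.n_kept = len(df)
    return df[OCCURRENCE_COLUMNS], report


def derive_absences(all_records: pd.DataFrame, target: str,
                    stack: EnvStack) -> pd.DataFrame:
    """Presence/absence table for one focal species of a compilation.

    In a multi-species survey compilation, every location where some other
    species was recorded (or the focal species was explicitly recorded
    absent) is a site that was searched; if the focal species was never
    found in that grid cell, it contributes an absence.  Returns the focal
    presences plus one derived absence per such cell.
    """
    if target not in set(all_records["species"]):
        raise UnknownSpeciesError(target)
    df = all_records
    target_rows = df[df["species"] == target]
    presences = target_rows[target_rows["presence"] == 1]

    prow, pcol = stack.cell_index(presences["lon"].to_numpy(),
                                  presences["lat"].to_numpy())
    presence_cells = set(zip(prow.tolist(), pcol.tolist()))

    others = df[(df["species"] != target) | (df["presence"] == 0)]
    orow, ocol = stack.cell_index(others["lon"].to_numpy(), others["lat"].to_numpy())

    absence_rows = []
    seen: set[tuple[int, int]] = set()
    for (r, c), lon, lat in zip(
        zip(orow.tolist(), ocol.tolist()),
        others["lon"].to_numpy(),
        others["lat"].to_numpy(),
    ):
        if (r, c) in presence_cells or (r, c) in seen:
            continue
        seen.add((r, c))
        absence_rows.append(
            {"species": target, "lon": lon, "lat": lat, "presence": 0,
             "source": "derived-absence"}
        )
    absences = pd.DataFrame(absence_rows, columns=OCCURRENCE_COLUMNS)
    parts = [p for p in (presences[OCCURRENCE_COLUMNS], absences) if len(p)]
    if not parts:
        return pd.DataFrame(columns=OCCURRENCE_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def extract_covariates(stack: EnvStack, table: pd.DataFrame
                       ) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Per-record environmental values at the containing grid cell.

    Returns ``(X, y, n_dropped)`` where rows falling on masked-out cells
    (sea / nodata) are dropped and counted.  Raises
    :class:`EmptyDesignError` when nothing remains.
    """
    inside = stack.extent.contains(table["lon"].to_numpy(), table["lat"].to_numpy())
    tab = table[inside]
    row, col = stack.cell_index(tab["lon"].to_numpy(), tab["lat"].to_numpy())
    valid = stack.mask[row, col]
    n_dropped = int((~valid).sum()) + int((~inside).sum())
    row, col = row[valid], col[valid]
    if row.size == 0:
        raise EmptyDesignError("all occurrence records fall on masked-out cells")
    X = stack.design_matrix(row, col)
    y = tab["presence"].to_numpy()[valid].astype(int)
    X.index = np.arange(len(X))
    return X, y, n_dropped


# ---------------------------------------------------------------------------
# Geodesy


def pixel_area(lat, resolution: float) -> np.ndarray | float:
    """Area in km² of a ``resolution``-degree square cell centred at ``lat``.

    Spherical model: ``A = R² · Δλ · (sin φ_top − sin φ_bot)`` with
    R = 6371 km.  At 30 arc-seconds this gives ≈0.86 km² on the equator
    and ≈0.61 km² at 45°S — the "approximately 1 km²" pixel.
    """
    lat_arr = np.asarray(lat, dtype=float)
    half = resolution / 2.0
    top = np.radians(np.clip(lat_arr + half, -90.0, 90.0))
    bot = np.radians(np.clip(lat_arr - half, -90.0, 90.0))
    dlon = math.radians(resolution)
    area = EARTH_RADIUS_KM**2 * dlon * (np.sin(top) - np.sin(bot))
    if np.isscalar(lat):
        return float(area)
    return area


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read an occurrence CSV with columns species,lon,lat,presence[,source]."""
    df = pd.read_csv(path)
    if "source" not in df.columns:
        df["source"] = ""
    return df[OCCURRENCE_COLUMNS]
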