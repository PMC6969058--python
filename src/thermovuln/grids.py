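"""Regular lat/lon grids and species presence/absence ranges.

Grid convention: cells are identified by their centre coordinates, latitude
rows ordered south -> north, longitudes normalised to [-179.5, 179.5] at 1
degree spacing (other regular spacings are accepted for fields that still
need regridding).  All joins between climate fields and species ranges go
through centre coordinates, so there is a single indexing convention across
the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

log = logging.getLogger(__name__)


class GridError(ValueError):
    """Raised for irregular axes, misaligned grids or bad range matrices."""


def _check_regular(axis: np.ndarray, name: str) -> float:
    if axis.ndim != 1 or axis.size == 0:
        raise GridError(f"{name} axis must be a non-empty 1-D array")
    if axis.size == 1:
        return 1.0
    steps = np.diff(axis)
    if np.any(steps <= 0):
        raise GridError(f"{name} axis must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
        raise GridError(f"{name} axis is not regularly spaced")
    return float(steps[0])


@dataclass
class GridField:
    """Values on a regular lat/lon grid with a validity mask.

    Attributes
    ----------
    lat, lon:
        Cell-centre coordinates (degrees), each strictly increasing with
        constant spacing; ``lat`` runs south to north.
    values:
        ``(n_lat, n_lon)`` float array; meaningful only where ``mask``.
    mask:
        ``(n_lat, n_lon)`` bool array, ``True`` on valid (ocean) cells.
    """

    lat: np.ndarray
    lon: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        dlat = _check_regular(self.lat, "lat")
        dlon = _check_regular(self.lon, "lon")
        if self.lat.size > 1 and self.lon.size > 1 and not np.isclose(dlat, dlon):
            raise GridError(f"anisotropic spacing: dlat={dlat}, dlon={dlon}")
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (self.lat.size, self.lon.size)
        if self.values.shape != shape or self.mask.shape != shape:
            raise GridError(
                f"values/mask shape {self.values.shape}/{self.mask.shape} "
                f"does not match grid {shape}"
            )
        if self.n_valid == 0:
            log.warning("grid field has zero valid cells (all masked)")

    @property
    def spacing(self) -> float:
        return float(self.lat[1] - self.lat[0]) if self.lat.size > 1 else \
            float(self.lon[1] - self.lon[0]) if self.lon.size > 1 else 1.0

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def copy(self, values: np.ndarray | None = None,
             meta: dict | None = None) -> "GridField":
        return GridField(
            lat=self.lat.copy(), lon=self.lon.copy(),
            values=self.values.copy() if values is None else np.asarray(values, float),
            mask=self.mask.copy(),
            meta=dict(self.meta if meta is None else meta),
        )

    def same_grid(self, other: "GridField") -> bool:
        return (self.lat.shape == other.lat.shape
                and self.lon.shape == other.lon.shape
                and np.allclose(self.lat, other.lat)
                and np.allclose(self.lon, other.lon))

    def index_of(self, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map centre coordinates to (row, col) indices; errors off-grid."""
        lat = np.atleast_1d(np.asarray(lat, float))
        lon = np.atleast_1d(np.asarray(lon, float))
        i = np.rint((lat - self.lat[0]) / self.spacing).astype(int)
        j = np.rint((lon - self.lon[0]) / self.spacing).astype(int)
        ok = (i >= 0) & (i < self.lat.size) & (j >= 0) & (j < self.lon.size)
        if not ok.all():
            bad = np.argwhere(~ok).ravel()[:5]
            raise GridError(
                f"coordinates not on grid, e.g. {[ (lat[b], lon[b]) for b in bad ]}"
            )
        if not (np.allclose(self.lat[i], lat) and np.allclose(self.lon[j], lon)):
            raise GridError("coordinates are not cell centres of this grid")
        return i, j

    # -- I/O --------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format ``lat,lon,value`` table with NA on masked cells."""
        llat, llon = np.meshgrid(self.lat, self.lon, indexing="ij")
        vals = np.where(self.mask, self.values, np.nan)
        return pd.DataFrame(
            {"lat": llat.ravel(), "lon": llon.ravel(), "value": vals.ravel()}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, na_rep="NA")

    def write_netcdf(self, path: str | Path) -> None:
        da = xr.DataArray(
            np.where(self.mask, self.values, np.nan),
            coords={"lat": self.lat, "lon": self.lon},
            dims=("lat", "lon"),
            name="value",
        )
        da.to_dataset().to_netcdf(path, engine="scipy")


def grid_from_extent(lat_min: float, lat_max: float,
                     lon_min: float, lon_max: float,
                     spacing: float = 1.0) -> GridField:
    """An all-valid, zero-valued field covering the given extent.

    ``lat_min``/``lat_max`` etc. are outer edges; centres sit at
    ``edge + spacing/2``.
    """
    lat = np.arange(lat_min + spacing / 2, lat_max, spacing)
    lon = np.arange(lon_min + spacing / 2, lon_max, spacing)
    shape = (lat.size, lon.size)
    return GridField(lat=lat, lon=lon, values=np.zeros(shape),
                     mask=np.ones(shape, bool))


def global_grid(spacing: float = 1.0) -> GridField:
    return grid_from_extent(-90, 90, -180, 180, spacing)


def read_grid(path: str | Path) -> GridField:
    """Read a grid from NetCDF (``.nc``) or the long-format CSV dialect."""
    path = Path(path)
    if path.suffix in {".nc", ".nc4", ".cdf"}:
        ds = xr.open_dataset(path)
        name = [v for v in ds.data_vars][0]
        da = ds[name].transpose("lat", "lon")
        lat = np.asarray(da["lat"])
        lon = np.asarray(da["lon"])
        order_lat = np.argsort(lat)
        order_lon = np.argsort(lon)
        vals = np.asarray(da.values, float)[np.ix_(order_lat, order_lon)]
        mask = np.isfinite(vals)
        return GridField(lat=lat[order_lat], lon=lon[order_lon],
                         values=np.where(mask, vals, 0.0), mask=mask)
    df = pd.read_csv(path)
    for col in ("lat", "lon", "value"):
        if col not in df.columns:
            raise GridError(f"CSV raster must have columns lat,lon,value; missing {col!r}")
    lat = np.unique(df["lat"].to_numpy(float))
    lon = np.unique(df["lon"].to_numpy(float))
    grid = GridField(lat=lat, lon=lon,
                     values=np.zeros((lat.size, lon.size)),
                     mask=np.ones((lat.size, lon.size), bool))
    i, j = grid.index_of(df["lat"].to_numpy(float), df["lon"].to_numpy(float))
    vals = np.full((lat.size, lon.size), np.nan)
    vals[i, j] = df["value"].to_numpy(float)
    mask = np.isfinite(vals)
    return GridField(lat=lat, lon=lon, values=np.where(mask, vals, 0.0), mask=mask)


def regrid_field(source: GridField, target: GridField,
                 method: str = "bilinear") -> GridField:
    """Interpolate ``source`` onto the grid of ``target``.

    Methods: ``nearest`` (nearest valid cell), ``bilinear`` (regular-grid
    linear interpolation; cells touching masked/out-of-domain neighbourhoods
    come out masked), ``idw`` (inverse-squared-distance over the 4 nearest
    valid cells).  Target cells with no usable neighbours are masked.
    """
    from scipy.interpolate import RegularGridInterpolator
    from scipy.spatial import cKDTree

    if source.n_valid == 0:
        raise GridError("cannot regrid an empty (all-masked) source field")
    if source.same_grid(target):
        return source.copy()

    tlat, tlon = np.meshgrid(target.lat, target.lon, indexing="ij")
    pts = np.column_stack([tlat.ravel(), tlon.ravel()])

    if method == "bilinear":
        filled = np.where(source.mask, source.values, np.nan)
        interp = RegularGridInterpolator(
            (source.lat, source.lon), filled,
            method="linear", bounds_error=False, fill_value=np.nan)
        out = interp(pts).reshape(tlat.shape)
    elif method in {"nearest", "idw"}:
        src_lat, src_lon = np.meshgrid(source.lat, source.lon, indexing="ij")
        valid = source.mask.ravel()
        tree = cKDTree(np.column_stack([src_lat.ravel()[valid], src_lon.ravel()[valid]]))
        vals = source.values.ravel()[valid]
        if method == "nearest":
            _, idx = tree.query(pts, k=1)
            out = vals[idx].reshape(tlat.shape)
        else:
            k = min(4, vals.size)
            dist, idx = tree.query(pts, k=k)
            dist = np.atleast_2d(dist.T).T
            idx = np.atleast_2d(idx.T).T
            w = 1.0 / np.maximum(dist, 1e-12) ** 2
            exact = dist[:, 0] < 1e-9
            est = (w * vals[idx]).sum(axis=1) / w.sum(axis=1)
            est[exact] = vals[idx[exact, 0]]
            out = est.reshape(tlat.shape)
    else:
        raise GridError(f"unknown regrid method {method!r}")

    mask = np.isfinite(out) & target.mask
    return GridField(lat=target.lat.copy(), lon=target.lon.copy(),
                     values=np.where(mask, out, 0.0), mask=mask,
                     meta=dict(source.meta))


@dataclass
class RangeMatrix:
    """Species x grid-cell presence/absence.

    ``cell_lat``/``cell_lon`` list the centre coordinates of the ``n_cells``
    cells that at least one species occupies; ``presence`` is a dense
    ``(n_species, n_cells)`` boolean matrix.
    """

    species: list[str]
    cell_lat: np.ndarray
    cell_lon: np.ndarray
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.species = list(self.species)
        if len(set(self.species)) != len(self.species):
            raise GridError("duplicate species identifiers in range matrix")
        self.cell_lat = np.asarray(self.cell_lat, float)
        self.cell_lon = np.asarray(self.cell_lon, float)
        self.presence = np.asarray(self.presence, bool)
        if self.presence.shape != (len(self.species), self.cell_lat.size):
            raise GridError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.species)} species x {self.cell_lat.size} cells"
            )
        empties = [s for s, row in zip(self.species, self.presence) if not row.any()]
        if empties:
            raise GridError(f"species with empty ranges: {empties[:5]}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def range_sizes(self) -> pd.Series:
        return pd.Series(self.presence.sum(axis=1), index=self.species, name="n_cells")

    def cell_indices_on(self, grid: GridField) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of every range cell on ``grid``; errors if off-grid."""
        return grid.index_of(self.cell_lat, self.cell_lon)

    def to_dataframe(self) -> pd.DataFrame:
        si, ci = np.nonzero(self.presence)
        return pd.DataFrame(
            {"species": np.asarray(self.species, object)[si],
             "cell_lat": self.cell_lat[ci],
             "cell_lon": self.cell_lon[ci]}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "RangeMatrix":
        df = pd.read_csv(path)
        for col in ("species", "cell_lat", "cell_lon"):
            if col not in df.columns:
                raise GridError(f"range CSV missing column {col!r}")
        return cls.from_dataframe(df)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RangeMatrix":
        cells = df[["cell_lat", "cell_lon"]].drop_duplicates().sort_values(
            ["cell_lat", "cell_lon"]).to_numpy(float)
        cell_key = {tuple(c): k for k, c in enumerate(cells)}
        species = sorted(df["species"].unique())
        sp_key = {s: k for k, s in enumerate(species)}
        presence = np.zeros((len(species), len(cells)), bool)
        for s, la, lo in df[["species", "cell_lat", "cell_lon"]].itertuples(index=False):
            presence[sp_key[s], cell_key[(float(la), float(lo))]] = True
        return cls(species=species, cell_lat=cells[:, 0], cell_lon=cells[:, 1],
                   presence=presence)
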