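"""Geographic preprocessing: rasters, zonal statistics, centroids, distances, contiguity.

Raster layers (population counts, a binary urban mask, a per-capita economic
surface) are held in a small :class:`Grid` container backed by a float array
with NaN as the missing marker, read and written in the ESRI ASCII-grid
format.  Administrative units live in a plain :class:`pandas.DataFrame` (the
"unit table") with one row per fine-scale unit carrying its parent
coarse-unit id, population, urban fraction, per-capita economic value and
planar centroid coordinates in kilometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

UNIT_COLUMNS = ["id", "coarse_id", "population", "urban_prop", "gcp_pc", "cx", "cy"]


@dataclass
class Grid:
    """Rectangular raster with NaN as the missing-value marker.

    Row 0 is the northernmost row, matching the ASCII-grid convention;
    ``origin_x``/``origin_y`` locate the lower-left corner of the lower-left
    cell.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) arrays of cell-center coordinates, same shape as values."""
        nrows, ncols = self.values.shape
        cols = np.arange(ncols)
        rows = np.arange(nrows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        # row 0 is the top row
        y = self.origin_y + (nrows - 1 - rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)


@dataclass
class ZoneMap:
    """Integer zone labels aligned cell-for-cell with a :class:`Grid`.

    Zone labels are positive integers; 0 marks cells outside every zone.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("zone map must be a 2-D array")
        if (self.values < 0).any():
            raise ValueError("zone labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def zones(self) -> np.ndarray:
        z = np.unique(self.values)
        return z[z > 0]


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII grid (.asc); NODATA cells become NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match ncols/nrows header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == nodata] = np.nan
    return Grid(
        values,
        cell_size=header["cellsize"],
        origin_x=header.get("xllcorner", 0.0),
        origin_y=header.get("yllcorner", 0.0),
    )


def write_ascii_grid(grid: Grid, path: str | Path, nodata: float = -9999.0) -> None:
    vals = np.where(np.isnan(grid.values), nodata, grid.values)
    nrows, ncols = vals.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {grid.origin_y!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def impute_missing_cells(grid: Grid) -> Grid:
    """Fill missing raster cells with the mean of their non-missing 8-neighbours.

    At grid borders the Moore neighbourhood is truncated to the available
    neighbours.  Sweeps repeat until no missing cells remain, so values
    propagate into interior holes; requires at least one known cell.
    """
    vals = grid.values.copy()
    if np.isnan(vals).all():
        raise ValueError("empty grid: all cells missing")
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    while np.isnan(vals).any():
        known = ~np.isnan(vals)
        filled = np.where(known, vals, 0.0)
        sums = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
        counts = ndimage.convolve(known.astype(float), kernel, mode="constant", cval=0.0)
        target = ~known & (counts > 0)
        vals[target] = sums[target] / counts[target]
    return Grid(vals, grid.cell_size, grid.origin_x, grid.origin_y)


def resample_nearest(grid: Grid, factor: int) -> Grid:
    """Block-replicate each cell ``factor`` times per axis (nearest neighbour,
    no smoothing); the cell size shrinks by the same factor."""
    if not float(factor).is_integer() or factor < 1:
        raise ValueError("resampling factor must be a positive integer")
    factor = int(factor)
    vals = np.kron(grid.values, np.ones((factor, factor)))
    return Grid(vals, grid.cell_size / factor, grid.origin_x, grid.origin_y)


def _check_aligned(grid: Grid, zones: ZoneMap) -> None:
    if grid.shape != zones.shape:
        raise ValueError("grid and zone map shapes differ")


def zonal_stat(grid: Grid, zones: ZoneMap, stat: str = "mean") -> pd.DataFrame:
    """Per-zone mean or sum of raster values; returns columns (zone, value)."""
    _check_aligned(grid, zones)
    if np.isnan(grid.values).any():
        raise ValueError("grid has missing cells; impute first")
    if stat not in {"mean", "sum"}:
        raise ValueError(f"unknown statistic {stat!r}")
    labels = zones.zones()
    if labels.size == 0:
        raise ValueError("zone map declares no zones")
    sums = ndimage.sum_labels(grid.values, zones.values, labels)
    counts = ndimage.sum_labels(np.ones_like(grid.values), zones.values, labels)
    if (counts == 0).any():
        raise ValueError("zone with zero cells")
    value = sums if stat == "sum" else sums / counts
    return pd.DataFrame({"zone": labels, "value": value})


def urban_proportion(pop: Grid, urban_mask: Grid, zones: ZoneMap) -> pd.DataFrame:
    """Per-zone share of population living in masked (urban) cells."""
    _check_aligned(pop, zones)
    _check_aligned(urban_mask, zones)
    mask = urban_mask.values
    if not np.isin(mask[~np.isnan(mask)], [0.0, 1.0]).all():
        raise ValueError("urban mask must be binary")
    labels = zones.zones()
    total = ndimage.sum_labels(pop.values, zones.values, labels)
    if (total <= 0).any():
        raise ValueError("zone with zero total population")
    urban = ndimage.sum_labels(pop.values * mask, zones.values, labels)
    return pd.DataFrame({"zone": labels, "proportion": urban / total})


def pop_weighted_centroid(pop: Grid, zones: ZoneMap) -> pd.DataFrame:
    """Population-weighted centroid of each zone's cell centers."""
    _check_aligned(pop, zones)
    labels = zones.zones()
    xs, ys = pop.cell_centers()
    total = ndimage.sum_labels(pop.values, zones.values, labels)
    if (total <= 0).any():
        raise ValueError("zone with zero total population")
    cx = ndimage.sum_labels(pop.values * xs, zones.values, labels) / total
    cy = ndimage.sum_labels(pop.values * ys, zones.values, labels) / total
    return pd.DataFrame({"zone": labels, "cx": cx, "cy": cy})


def pairwise_distances(units: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance matrix (km) between unit centroids, indexed by id."""
    if units[["cx", "cy"]].isna().any().any():
        raise ValueError("missing centroid coordinates")
    xy = units[["cx", "cy"]].to_numpy(dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    ids = units["id"].to_numpy()
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class Adjacency:
    """Symmetric, irreflexive contiguity relation over unit ids (CONT)."""

    ids: list = field(default_factory=list)
    matrix: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=int))

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.matrix = np.asarray(self.matrix, dtype=int)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("adjacency matrix shape does not match id list")
        if (self.matrix != self.matrix.T).any():
            raise ValueError("adjacency must be symmetric")
        if np.diag(self.matrix).any():
            raise ValueError("adjacency must be irreflexive")
        self._pos = {u: k for k, u in enumerate(self.ids)}

    def contiguous(self, a, b) -> int:
        return int(self.matrix[self._pos[a], self._pos[b]])

    def edges(self) -> list[tuple]:
        out = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if self.matrix[i, j]:
                    out.append((self.ids[i], self.ids[j]))
        return out

    def degrees(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def build_contiguity(edges, units: pd.DataFrame) -> Adjacency:
    """Binary contiguity from an edge list: 1 iff two units share a boundary."""
    ids = list(units["id"])
    pos = {u: k for k, u in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)), dtype=int)
    for a, b in edges:
        if a not in pos or b not in pos:
            raise ValueError(f"unknown unit id in edge ({a}, {b})")
        if a == b:
            raise ValueError(f"self-pair edge ({a}, {b})")
        mat[pos[a], pos[b]] = 1
        mat[pos[b], pos[a]] = 1
    return Adjacency(ids, mat)


def validate_unit_table(units: pd.DataFrame) -> pd.DataFrame:
    """Check unit-table invariants and return the frame unchanged."""
    missing = [c for c in UNIT_COLUMNS if c not in units.columns]
    if missing:
        raise ValueError(f"unit table missing columns: {missing}")
    if units["id"].duplicated().any():
        raise ValueError("duplicate unit ids")
    if units["coarse_id"].isna().any() or (units["coarse_id"].astype(str) == "").any():
        raise ValueError("empty coarse_id")
    if (units["population"] < 0).any():
        raise ValueError("negative population")
    if ((units["urban_prop"] < 0) | (units["urban_prop"] > 1)).any():
        raise ValueError("urban_prop outside [0, 1]")
    pop_by_coarse = units.groupby("coarse_id")["population"].sum()
    if (pop_by_coarse <= 0).any():
        raise ValueError("coarse unit with zero total population")
    return units


def read_unit_table(path: str | Path) -> pd.DataFrame:
    units = pd.read_csv(path, comment="#", dtype={"id": str, "coarse_id": str})
    return validate_unit_table(units)


def write_unit_table(units: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        units[UNIT_COLUMNS].to_csv(fh, index=False)


def read_edges(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, comment="#", dtype=str)
    return list(df[["id_a", "id_b"]].itertuples(index=False, name=None))


def write_edges(edges, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        pd.DataFrame(edges, columns=["id_a", "id_b"]).to_csv(fh, index=False)
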