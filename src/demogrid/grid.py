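"""Axis-aligned geographic grids and raster layers.

Everything downstream of the table stage lives on a single grid template:
a WGS84 axis-aligned mesh defined by its north-west corner, square cell
size in degrees, and row/column counts.  All layers produced by the
pipeline share the template bit-exactly -- there is no resampling anywhere.

Rasters are stored as numpy arrays (row 0 = northernmost) and serialised
as ESRI ASCII grids, a plain-text interchange format readable by standard
GIS software.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Default cell size: 30 arc seconds, approximately 1 km at the equator.
DEFAULT_RESOLUTION = 1.0 / 120.0

#: Nodata sentinel for float layers; 0 is a legal data value.
DEFAULT_NODATA = -99999.0


@dataclass(frozen=True)
class GridTemplate:
    """Grid mesh contract shared by every raster layer in a run.

    Cell ``(r, c)`` spans ``x in [west + c*res, west + (c+1)*res)`` and
    ``y in (north - (r+1)*res, north - r*res]``.
    """

    west: float
    north: float
    resolution: float = DEFAULT_RESOLUTION
    n_rows: int = 0
    n_cols: int = 0
    crs: str = "EPSG:4326"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive dimensions")
        if not (-180.0 <= self.west and self.east <= 180.0):
            raise ValueError("grid extent outside [-180, 180] longitude")
        if not (self.south >= -90.0 and self.north <= 90.0):
            raise ValueError("grid extent outside [-90, 90] latitude")

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.resolution

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.resolution

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(xs, ys)`` of cell-center coordinates, shape (rows, cols)."""
        res = self.resolution
        xs = self.west + (np.arange(self.n_cols) + 0.5) * res
        ys = self.north - (np.arange(self.n_rows) + 0.5) * res
        return np.meshgrid(xs, ys)

    def aligned_with(self, other: "GridTemplate") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.west, other.west)
            and np.isclose(self.north, other.north)
            and np.isclose(self.resolution, other.resolution)
        )


class AlignmentError(ValueError):
    """Two layers that must share a grid template do not."""


@dataclass
class RasterLayer:
    """A single-band raster on a :class:`GridTemplate`.

    ``semantics`` records what cell values mean: ``proportion-fraction``
    (in [0, 1]), ``ratio`` (a dependency ratio, already x100), ``count``
    (persons per cell) or ``iso-code`` (integer country codes).
    """

    template: GridTemplate
    values: np.ndarray
    semantics: str = "count"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.template.shape:
            raise ValueError(
                f"values shape {self.values.shape} != template {self.template.shape}"
            )

    @property
    def nodata(self) -> float:
        return self.template.nodata

    def data_mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return self.values != self.nodata

    def filled(self, fill: float = 0.0) -> np.ndarray:
        out = self.values.copy()
        out[~self.data_mask()] = fill
        return out

    def total(self) -> float:
        return float(self.filled().sum())

    def with_values(self, values: np.ndarray, semantics: str | None = None) -> "RasterLayer":
        return RasterLayer(self.template, values, semantics or self.semantics)


def require_aligned(*layers: RasterLayer) -> None:
    tmpl = layers[0].template
    for lyr in layers[1:]:
        if not tmpl.aligned_with(lyr.template):
            raise AlignmentError(
                f"misaligned grids: {tmpl} vs {lyr.template}"
            )


def zonal_sum(layer: RasterLayer, zones: RasterLayer) -> dict[int, float]:
    """Sum of ``layer`` values per integer zone of ``zones``.

    Nodata cells in either layer are excluded.  Returns a mapping
    zone id -> sum over that zone's valid cells.
    """
    require_aligned(layer, zones)
    mask = layer.data_mask() & zones.data_mask()
    ids = zones.values[mask].astype(np.int64)
    vals = layer.values[mask]
    out: dict[int, float] = {}
    if ids.size == 0:
        return out
    order = np.argsort(ids, kind="stable")
    ids, vals = ids[order], vals[order]
    cut = np.flatnonzero(np.diff(ids)) + 1
    for chunk_ids, chunk_vals in zip(np.split(ids, cut), np.split(vals, cut)):
        out[int(chunk_ids[0])] = float(chunk_vals.sum())
    return out


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    """Serialise a layer as an ESRI ASCII grid (plain text)."""
    t = layer.template
    header = (
        f"ncols {t.n_cols}\n"
        f"nrows {t.n_rows}\n"
        f"xllcorner {t.west!r}\n"
        f"yllcorner {t.south!r}\n"
        f"cellsize {t.resolution!r}\n"
        f"NODATA_value {t.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, layer.values, fmt="%.10g")


def read_ascii_grid(
    path: str | Path, semantics: str = "count", crs: str = "EPSG:4326"
) -> RasterLayer:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    head: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(head["nrows"]), int(head["ncols"])
    values = values.reshape(n_rows, n_cols)
    tmpl = GridTemplate(
        west=head["xllcorner"],
        north=head["yllcorner"] + n_rows * head["cellsize"],
        resolution=head["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
        crs=crs,
        nodata=head.get("nodata_value", DEFAULT_NODATA),
    )
    return RasterLayer(tmpl, values, semantics)
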