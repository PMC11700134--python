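"""Minimal georeferenced raster container and grid utilities.

Every stage of the pipeline passes 2-D grids around — elevations in metres,
backscatter in dB, binary masks, integer country labels.  ``RasterTile``
wraps a numpy array with an affine north-up grid, a horizontal CRS tag, an
optional vertical-datum tag (``"ellipsoid"`` or ``"geoid"``, mandatory for
elevation rasters) and a nodata sentinel.

Rasters are serialised as ESRI ASCII grids (plain text) with a small JSON
sidecar carrying the CRS/vdatum tags that the ASCII header cannot express.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

NODATA = -9999.0

#: metres per degree of latitude (spherical mean); longitude scales by cos(lat)
M_PER_DEG_LAT = 111_320.0


def m_per_deg_lon(lat_deg: float) -> float:
    """Local metres per degree of longitude at latitude ``lat_deg``."""
    return M_PER_DEG_LAT * math.cos(math.radians(lat_deg))


@dataclass(frozen=True)
class GridTransform:
    """North-up affine grid: top-left corner (x0, y0), pixel sizes (dx, dy).

    ``dx`` is positive (eastward), ``dy`` negative (row index grows
    southward).  Pixel-is-area convention: the value at (row, col) applies
    to the cell whose centre is ``(x0 + (col + .5) dx, y0 + (row + .5) dy)``.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx == 0 or self.dy == 0:
            raise ValueError("pixel sizes must be nonzero")

    def pixel_center(self, row, col):
        return (self.x0 + (np.asarray(col) + 0.5) * self.dx,
                self.y0 + (np.asarray(row) + 0.5) * self.dy)

    def index_of(self, x, y):
        """(row, col) of the pixel containing point (x, y); floats floored."""
        col = np.floor((np.asarray(x) - self.x0) / self.dx).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.dy).astype(int)
        return row, col

    def center_grids(self, shape):
        rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
        return self.pixel_center(rows, cols)

    def bounds(self, shape):
        nrow, ncol = shape
        xs = sorted((self.x0, self.x0 + ncol * self.dx))
        ys = sorted((self.y0, self.y0 + nrow * self.dy))
        return xs[0], ys[0], xs[1], ys[1]


@dataclass
class RasterTile:
    """A georeferenced 2-D grid with nodata semantics."""

    values: np.ndarray
    transform: GridTransform
    crs: str = "EPSG:4326"
    vdatum: str | None = None
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.vdatum is not None and self.vdatum not in ("ellipsoid", "geoid"):
            raise ValueError(f"unknown vdatum {self.vdatum!r}")

    @property
    def shape(self):
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask()]

    def copy(self) -> "RasterTile":
        return RasterTile(self.values.copy(), self.transform, self.crs,
                          self.vdatum, self.nodata)

    def with_values(self, values: np.ndarray, vdatum: str | None = None) -> "RasterTile":
        out = self.copy()
        out.values = np.asarray(values, dtype=float)
        if vdatum is not None:
            out.vdatum = vdatum
        return out

    # ------------------------------------------------------------------ I/O
    def write_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid plus a ``.meta.json`` sidecar."""
        path = Path(path)
        t = self.transform
        if abs(t.dx) != abs(t.dy):
            cell = f"dx {abs(t.dx)!r}\ndy {abs(t.dy)!r}"
            header = (f"ncols {self.shape[1]}\nnrows {self.shape[0]}\n"
                      f"xllcorner {t.x0!r}\nyllcorner {t.y0 + self.shape[0] * t.dy!r}\n"
                      f"{cell}\nNODATA_value {self.nodata!r}\n")
        else:
            header = (f"ncols {self.shape[1]}\nnrows {self.shape[0]}\n"
                      f"xllcorner {t.x0!r}\nyllcorner {t.y0 + self.shape[0] * t.dy!r}\n"
                      f"cellsize {t.dx!r}\nNODATA_value {self.nodata!r}\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, np.where(self.valid_mask(), self.values, self.nodata),
                       fmt="%.10g")
        meta = {"crs": self.crs, "vdatum": self.vdatum}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterTile":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            for _ in range(7):
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0][0].isalpha():
                    header[parts[0].lower()] = float(parts[1])
                    pos = fh.tell()
                else:
                    break
            fh.seek(pos)
            values = np.loadtxt(fh, ndmin=2)
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        dx = header.get("dx", header.get("cellsize"))
        dy = -header.get("dy", header.get("cellsize"))
        nodata = header.get("nodata_value", NODATA)
        transform = GridTransform(header["xllcorner"],
                                  header["yllcorner"] - nrows * dy, dx, dy)
        meta_path = Path(str(path) + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        if values.shape != (nrows, ncols):
            raise ValueError("ASCII grid shape does not match header")
        return cls(values, transform, crs=meta.get("crs", "EPSG:4326"),
                   vdatum=meta.get("vdatum"), nodata=nodata)


def grids_aligned(a: GridTransform, b: GridTransform, tol: float = 1e-9) -> bool:
    return (abs(a.x0 - b.x0) < tol and abs(a.y0 - b.y0) < tol
            and abs(a.dx - b.dx) < tol and abs(a.dy - b.dy) < tol)


def require_coregistered(*tiles: RasterTile) -> None:
    first = tiles[0]
    for t in tiles[1:]:
        if t.shape != first.shape or not grids_aligned(t.transform, first.transform):
            raise ValueError("rasters are not co-registered on a common grid")


def resample_nearest(source: RasterTile, target_transform: GridTransform,
                     target_shape: tuple[int, int]) -> RasterTile:
    """Nearest-neighbour resampling onto an explicit target grid.

    Each target pixel takes the value of the source pixel containing the
    target pixel centre; centres outside the source extent (and source
    nodata) map to nodata.  Raises if the extents are disjoint.
    """
    sx0, sy0, sx1, sy1 = source.transform.bounds(source.shape)
    tx0, ty0, tx1, ty1 = target_transform.bounds(target_shape)
    if tx1 <= sx0 or tx0 >= sx1 or ty1 <= sy0 or ty0 >= sy1:
        raise ValueError("source and target extents are disjoint")

    xs, ys = target_transform.center_grids(target_shape)
    row, col = source.transform.index_of(xs, ys)
    inside = ((row >= 0) & (row < source.shape[0])
              & (col >= 0) & (col < source.shape[1]))
    out = np.full(target_shape, source.nodata, dtype=float)
    out[inside] = source.values[row[inside], col[inside]]
    return RasterTile(out, target_transform, crs=source.crs,
                      vdatum=source.vdatum, nodata=source.nodata)
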