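"""Raster covariate layers: I/O, point extraction, and synthetic generation.

All geometry is in projected planar map units (e.g. km).  Geographic
coordinates are not supported: step-selection distances require a metric
plane.  A cell's value applies to its full square, addressed by half-open
intervals ``[x0, x0 + res)`` so no point belongs to two cells.

Grids are stored internally with row 0 at the *bottom* (y increasing with
row index); file formats that store north-up rows are flipped on I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CovariateLayer",
    "Landscape",
    "read_raster",
    "write_raster",
    "extract",
    "generate_landscape",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class CovariateLayer:
    """A single raster covariate on a regular lattice.

    Parameters
    ----------
    name
        Identifier used in model formulas.
    kind
        ``"continuous"`` or ``"categorical"``.
    grid
        2-D float array, row 0 at the bottom edge.  Missing cells are NaN.
        Categorical layers store integer codes indexing ``levels``.
    xmin, ymin
        Coordinates of the lower-left corner of the lattice.
    resolution
        Square cell size in map units.
    levels
        Ordered category labels (categorical only).
    reference
        Reference level for indicator expansion (categorical only);
        defaults to the first level.
    """

    name: str
    kind: str
    grid: np.ndarray
    xmin: float
    ymin: float
    resolution: float
    levels: list[str] = field(default_factory=list)
    reference: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == CATEGORICAL:
            if not self.levels:
                codes = np.unique(self.grid[np.isfinite(self.grid)]).astype(int)
                self.levels = [str(c) for c in codes]
            if self.reference is None:
                self.reference = self.levels[0]
            if self.reference not in self.levels:
                raise ValueError(
                    f"reference {self.reference!r} not among levels {self.levels}"
                )
            finite = self.grid[np.isfinite(self.grid)]
            if finite.size and not np.isin(finite, np.arange(len(self.levels))).all():
                raise ValueError("categorical grid holds codes outside levels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the lattice."""
        nrow, ncol = self.grid.shape
        return (
            self.xmin,
            self.xmin + ncol * self.resolution,
            self.ymin,
            self.ymin + nrow * self.resolution,
        )

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) with an in-bounds mask.

        Half-open convention: a point on the right/top edge is outside.
        Out-of-bounds indices are clipped so they can be used safely; the
        mask must be consulted.
        """
        col = np.floor((np.asarray(x, float) - self.xmin) / self.resolution).astype(int)
        row = np.floor((np.asarray(y, float) - self.ymin) / self.resolution).astype(int)
        nrow, ncol = self.grid.shape
        inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
        return np.clip(row, 0, nrow - 1), np.clip(col, 0, ncol - 1), inside

    def value_at(self, x, y, method: str = "nearest") -> tuple[np.ndarray, np.ndarray]:
        """Values at points plus a validity mask (inside and not missing)."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        row, col, inside = self.cell_index(x, y)
        if method == "nearest" or self.kind == CATEGORICAL:
            vals = self.grid[row, col]
        elif method == "bilinear":
            vals = self._bilinear(x, y)
        else:
            raise ValueError(f"unknown extraction method {method!r}")
        vals = np.where(inside, vals, np.nan)
        valid = inside & np.isfinite(vals)
        return vals, valid

    def _bilinear(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        res = self.resolution
        # fractional position relative to cell-centre lattice
        fx = (x - self.xmin) / res - 0.5
        fy = (y - self.ymin) / res - 0.5
        nrow, ncol = self.grid.shape
        c0 = np.clip(np.floor(fx).astype(int), 0, ncol - 1)
        r0 = np.clip(np.floor(fy).astype(int), 0, nrow - 1)
        c1 = np.clip(c0 + 1, 0, ncol - 1)
        r1 = np.clip(r0 + 1, 0, nrow - 1)
        wx = np.clip(fx - c0, 0.0, 1.0)
        wy = np.clip(fy - r0, 0.0, 1.0)
        g = self.grid
        return (
            g[r0, c0] * (1 - wx) * (1 - wy)
            + g[r0, c1] * wx * (1 - wy)
            + g[r1, c0] * (1 - wx) * wy
            + g[r1, c1] * wx * wy
        )

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        nrow, ncol = self.grid.shape
        xs = self.xmin + (np.arange(ncol) + 0.5) * self.resolution
        ys = self.ymin + (np.arange(nrow) + 0.5) * self.resolution
        return xs, ys


@dataclass
class Landscape:
    """A set of aligned covariate layers with a rectangular study boundary."""

    layers: list[CovariateLayer]
    boundary: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("landscape needs at least one layer")
        ref = self.layers[0]
        for lyr in self.layers[1:]:
            if lyr.shape != ref.shape or lyr.resolution != ref.resolution:
                raise ValueError("layers are not aligned on one lattice")
            if not np.allclose((lyr.xmin, lyr.ymin), (ref.xmin, ref.ymin)):
                raise ValueError("layers are not aligned on one lattice")
        if self.boundary is None:
            self.boundary = ref.extent
        bx0, bx1, by0, by1 = self.boundary
        ex0, ex1, ey0, ey1 = ref.extent
        if bx0 < ex0 - 1e-9 or bx1 > ex1 + 1e-9 or by0 < ey0 - 1e-9 or by1 > ey1 + 1e-9:
            raise ValueError("boundary extends beyond layer extent")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return self.layers[0].extent

    @property
    def resolution(self) -> float:
        return self.layers[0].resolution

    def __getitem__(self, name: str) -> CovariateLayer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(name)

    def layer_names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    def contains(self, x, y) -> np.ndarray:
        bx0, bx1, by0, by1 = self.boundary
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x >= bx0) & (x < bx1) & (y >= by0) & (y < by1)


# ---------------------------------------------------------------------------
# Extraction

def indicator_columns(layer: CovariateLayer) -> list[str]:
    """Design-matrix column names contributed by one layer."""
    if layer.kind == CONTINUOUS:
        return [layer.name]
    return [
        f"{layer.name}_{lvl}" for lvl in layer.levels if lvl != layer.reference
    ]


def extract(landscape: Landscape, points, method: str = "nearest"):
    """Covariate rows at arbitrary points.

    Returns ``(values, valid)``: a dict of column name -> array, with
    categorical layers expanded to 0/1 indicators against their reference
    level, and a boolean mask that is False wherever any layer is missing
    or the point falls outside the extent.  Invalidity is flagged, never
    raised.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    x, y = pts[:, 0], pts[:, 1]
    out: dict[str, np.ndarray] = {}
    valid = np.ones(len(pts), dtype=bool)
    for lyr in landscape.layers:
        vals, ok = lyr.value_at(x, y, method=method)
        valid &= ok
        if lyr.kind == CONTINUOUS:
            out[lyr.name] = vals
        else:
            codes = np.where(ok, vals, -1).astype(int)
            for j, lvl in enumerate(lyr.levels):
                if lvl == lyr.reference:
                    continue
                out[f"{lyr.name}_{lvl}"] = (codes == j).astype(float)
    return out, valid


# ---------------------------------------------------------------------------
# Raster I/O: ESRI ASCII grid and GeoTIFF

_ASC_NODATA = -9999.0


def write_raster(layer: CovariateLayer, path) -> None:
    """Write a layer as ESRI ASCII grid (.asc) or GeoTIFF (.tif/.tiff)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        _write_ascii(layer, path)
    elif suffix in (".tif", ".tiff"):
        _write_geotiff(layer, path)
    else:
        raise ValueError(f"unknown raster format {suffix!r}")


def read_raster(
    path,
    kind: str = CONTINUOUS,
    name: str | None = None,
    levels: Sequence[str] | None = None,
    reference: str | None = None,
) -> CovariateLayer:
    """Read a GeoTIFF or ESRI ASCII grid into a :class:`CovariateLayer`.

    Layer metadata (kind, category levels, reference level) is supplied by
    the caller, not inferred from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        grid, xmin, ymin, res = _read_ascii(path)
    elif suffix in (".tif", ".tiff"):
        grid, xmin, ymin, res = _read_geotiff(path)
    else:
        raise ValueError(f"unknown raster format {suffix!r}")
    return CovariateLayer(
        name=name or path.stem,
        kind=kind,
        grid=grid,
        xmin=xmin,
        ymin=ymin,
        resolution=res,
        levels=list(levels) if levels else [],
        reference=reference,
    )


def _write_ascii(layer: CovariateLayer, path: Path) -> None:
    nrow, ncol = layer.grid.shape
    grid = np.where(np.isfinite(layer.grid), layer.grid, _ASC_NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {layer.xmin:.17g}\n")
        fh.write(f"yllcorner {layer.ymin:.17g}\n")
        fh.write(f"cellsize {layer.resolution:.17g}\n")
        fh.write(f"NODATA_value {_ASC_NODATA:.17g}\n")
        # file rows run north to south; %.17g round-trips doubles exactly
        for row in grid[::-1]:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def _read_ascii(path: Path) -> tuple[np.ndarray, float, float, float]:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value", "xllcenter", "yllcenter",
            ):
                header[key] = float(parts[1])
            else:
                rows.append(np.asarray(parts, dtype=float))
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid missing {req} header in {path}")
    grid = np.concatenate(rows)
    ncol, nrow = int(header["ncols"]), int(header["nrows"])
    if grid.size != nrow * ncol:
        raise ValueError(f"ASCII grid size mismatch in {path}")
    grid = grid.reshape(nrow, ncol)[::-1]  # back to bottom-up rows
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid = np.where(grid == nodata, np.nan, grid)
    res = header["cellsize"]
    if "xllcorner" in header:
        xmin, ymin = header["xllcorner"], header["yllcorner"]
    else:  # centre-registered variant
        xmin = header["xllcenter"] - res / 2
        ymin = header["yllcenter"] - res / 2
    return grid, xmin, ymin, res


# GeoTIFF tags: ModelPixelScale, ModelTiepoint, GDAL_NODATA
_TAG_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113


def _write_geotiff(layer: CovariateLayer, path: Path) -> None:
    import tifffile

    nrow, ncol = layer.grid.shape
    x0, x1, y0, y1 = layer.extent
    data = layer.grid[::-1].astype(np.float64)  # north-up rows
    res = float(layer.resolution)
    extratags = [
        (_TAG_SCALE, "d", 3, (res, res, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y1), 0.0)),
        (_TAG_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def _read_geotiff(path: Path) -> tuple[np.ndarray, float, float, float]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        tags = page.tags
        if _TAG_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path} is not a georeferenced TIFF")
        sx, sy = tags[_TAG_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        if abs(sx - sy) > 1e-9 * max(abs(sx), abs(sy)):
            raise ValueError("non-square cells are not supported")
        if _TAG_NODATA in tags:
            nod = tags[_TAG_NODATA].value.strip()
            if nod.lower() not in ("nan", ""):
                data = np.where(data == float(nod), np.nan, data)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    nrow = data.shape[0]
    # tiepoint maps raster (i, j) -> model (x, y); (0, 0) is the NW corner
    xmin = tie[3] - tie[0] * sx
    ymax = tie[4] + tie[1] * sy
    ymin = ymax - nrow * sy
    return data[::-1], float(xmin), float(ymin), float(sx)


# ---------------------------------------------------------------------------
# Synthetic landscapes

def _smooth_field(rng: np.random.Generator, shape, patch_scale_cells: float) -> np.ndarray:
    """Stationary Gaussian field: white noise smoothed to a target range."""
    noise = rng.standard_normal(shape)
    if patch_scale_cells > 0:
        field_ = ndimage.gaussian_filter(noise, sigma=patch_scale_cells, mode="wrap")
    else:
        field_ = noise
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_landscape(
    seed: int,
    extent: tuple[float, float, float, float],
    resolution: float,
    continuous: dict | None = None,
    categorical: dict | None = None,
) -> Landscape:
    """Generate a reproducible synthetic landscape.

    ``continuous`` entries map layer name -> ``{"patch_scale": map units,
    "variance": v}`` and produce smoothed Gaussian noise.  ``categorical``
    entries map name -> ``{"levels": [...], "proportions": [...],
    "patch_scale": s, "reference": lvl}``; a smoothed field is thresholded
    at the proportions' quantiles so realised cell fractions match the
    targets.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = extent
    ncol = int(round((xmax - xmin) / resolution))
    nrow = int(round((ymax - ymin) / resolution))
    layers: list[CovariateLayer] = []
    for lname, spec in (continuous or {}).items():
        scale_cells = spec.get("patch_scale", resolution) / resolution
        grid = _smooth_field(rng, (nrow, ncol), scale_cells)
        grid = grid * np.sqrt(spec.get("variance", 1.0))
        layers.append(
            CovariateLayer(lname, CONTINUOUS, grid, xmin, ymin, resolution)
        )
    for lname, spec in (categorical or {}).items():
        props = np.asarray(spec["proportions"], dtype=float)
        if props.min() <= 0 or abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("proportions must be positive and sum to 1")
        lvls = [str(v) for v in spec["levels"]]
        if len(lvls) != len(props):
            raise ValueError("levels and proportions differ in length")
        scale_cells = spec.get("patch_scale", resolution) / resolution
        field_ = _smooth_field(rng, (nrow, ncol), scale_cells)
        # quantile thresholds give realised proportions equal to targets
        cuts = np.quantile(field_, np.cumsum(props)[:-1])
        grid = np.digitize(field_, cuts).astype(float)
        layers.append(
            CovariateLayer(
                lname, CATEGORICAL, grid, xmin, ymin, resolution,
                levels=lvls, reference=spec.get("reference", lvls[0]),
            )
        )
    if not layers:
        raise ValueError("no layers requested")
    return Landscape(layers)
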