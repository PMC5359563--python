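"""Categorical raster maps, zone sets and alignment checks.

All downstream analysis consumes the types defined here.  Two on-disk
formats are supported for maps: single-band integer GeoTIFF and ESRI
ASCII grid; zones are read from GeoJSON polygons or from a zone-coded
raster.  Coordinates follow the GeoTIFF norm: row-major grids, origin at
the top-left corner, cell centres at half-cell offsets.

No reprojection or resampling is ever performed: resampling a
categorical map silently corrupts the transition counts it feeds, so a
geometry mismatch is a refusal, not a repair.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from shapely import contains_xy
from shapely.geometry import shape as shapely_shape

__all__ = [
    "GridTransform",
    "CategoricalMap",
    "ZoneSet",
    "Zone",
    "AlignmentReport",
    "NO_ZONE",
    "read_categorical_map",
    "write_categorical_map",
    "write_surface",
    "check_alignment",
    "rasterize_zones",
    "read_legend_csv",
    "write_legend_csv",
    "FormatError",
    "LegendError",
    "AlignmentError",
]

#: Reserved zone id for cells outside every zone.
NO_ZONE = -1


class FormatError(ValueError):
    """Raised when an input file is not a supported raster/vector format."""


class LegendError(ValueError):
    """Raised when grid codes are inconsistent with the supplied legend."""


class AlignmentError(ValueError):
    """Raised when two maps that must share a grid do not."""


@dataclass(frozen=True)
class GridTransform:
    """Affine georeference of a north-up, axis-aligned grid.

    ``x_origin``/``y_origin`` locate the outer corner of the top-left
    cell; ``dx``/``dy`` are the (positive) cell width and height in map
    units.  Row indices increase southward, so the y coordinate of a
    cell centre is ``y_origin - (row + 0.5) * dy``.
    """

    x_origin: float
    y_origin: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell size must be positive")

    def cell_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of all cell centres, shaped like the grid."""
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        x = self.x_origin + (cols + 0.5) * self.dx
        y = self.y_origin - (rows + 0.5) * self.dy
        return x, y

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy


@dataclass
class CategoricalMap:
    """Integer-coded class grid with georeferencing, legend and nodata.

    Parameters
    ----------
    grid
        2-D integer array of class codes (row-major, top-left origin).
    transform
        Grid georeference.
    legend
        Mapping from integer code to class name; every non-nodata code
        present in the grid must appear in it.
    crs_id
        Opaque CRS identifier, compared as text.
    nodata_code
        Code marking cells outside the study area, or ``None``.
    timestamp
        Decimal year the map represents.
    """

    grid: np.ndarray
    transform: GridTransform
    legend: dict[int, str]
    crs_id: str = ""
    nodata_code: int | None = None
    timestamp: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise FormatError("categorical grid must have an integer dtype")
        self._validate_legend()

    def _validate_legend(self) -> None:
        codes = set(np.unique(self.grid).tolist())
        if self.nodata_code is not None:
            codes.discard(self.nodata_code)
        missing = codes - set(self.legend)
        if missing:
            raise LegendError(
                f"grid codes {sorted(missing)} are not in the legend "
                f"{sorted(self.legend)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells inside the study area (non-nodata)."""
        if self.nodata_code is None:
            return np.ones(self.grid.shape, dtype=bool)
        return self.grid != self.nodata_code


@dataclass
class Zone:
    """A single aggregation unit: polygon geometry or boolean raster mask."""

    zone_id: int
    geometry: object | None = None  # shapely geometry
    mask: np.ndarray | None = None  # boolean grid, same shape as the template
    name: str = ""

    def representative_point(self, transform: GridTransform | None = None) -> tuple[float, float]:
        """Geometric centre of the zone (polygon centroid, or mean cell centre)."""
        if self.geometry is not None:
            c = self.geometry.centroid
            return float(c.x), float(c.y)
        if self.mask is None or transform is None:
            raise ValueError("raster zone needs a transform to locate its centre")
        rows, cols = np.nonzero(self.mask)
        if rows.size == 0:
            return float("nan"), float("nan")
        x = transform.x_origin + (cols.mean() + 0.5) * transform.dx
        y = transform.y_origin - (rows.mean() + 0.5) * transform.dy
        return float(x), float(y)


@dataclass
class ZoneSet:
    """Collection of non-overlapping zones ('villages')."""

    zones: list[Zone] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [z.zone_id for z in self.zones]
        if len(ids) != len(set(ids)):
            raise ValueError("zone_ids must be unique")

    def __len__(self) -> int:
        return len(self.zones)

    def __iter__(self):
        return iter(self.zones)

    @classmethod
    def from_geojson(cls, path: str | Path) -> "ZoneSet":
        """Read zones from a GeoJSON FeatureCollection (fields zone_id, name)."""
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("type") != "FeatureCollection":
            raise FormatError("zone file must be a GeoJSON FeatureCollection")
        zones = []
        for k, feat in enumerate(doc.get("features", [])):
            props = feat.get("properties") or {}
            zid = int(props.get("zone_id", k))
            zones.append(
                Zone(
                    zone_id=zid,
                    geometry=shapely_shape(feat["geometry"]),
                    name=str(props.get("name", f"zone_{zid}")),
                )
            )
        return cls(zones=zones)

    @classmethod
    def from_zone_raster(cls, zone_map: CategoricalMap) -> "ZoneSet":
        """Build zones from a zone-coded raster; each code becomes one zone."""
        codes = np.unique(zone_map.grid)
        if zone_map.nodata_code is not None:
            codes = codes[codes != zone_map.nodata_code]
        zones = [
            Zone(
                zone_id=int(c),
                mask=zone_map.grid == c,
                name=zone_map.legend.get(int(c), f"zone_{int(c)}"),
            )
            for c in codes
        ]
        return cls(zones=zones)


@dataclass(frozen=True)
class AlignmentReport:
    """Verdict on whether two maps share a grid geometry."""

    same_shape: bool
    same_transform: bool
    same_crs: bool
    legend_union: dict[int, str]

    @property
    def ok(self) -> bool:
        return self.same_shape and self.same_transform and self.same_crs


# ---------------------------------------------------------------------------
# legends
# ---------------------------------------------------------------------------

def read_legend_csv(path: str | Path) -> dict[int, str]:
    """Read a 2-column ``code,name`` legend CSV (header optional)."""
    legend: dict[int, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            try:
                code = int(row[0])
            except ValueError:
                continue  # header line
            legend[code] = row[1].strip() if len(row) > 1 else f"class_{code}"
    return legend


def write_legend_csv(legend: dict[int, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "name"])
        for code in sorted(legend):
            writer.writerow([code, legend[code]])


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

# private TIFF tags used to round-trip georeferencing without GDAL
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _apply_legend(
    codes: np.ndarray,
    legend: dict[int, str] | None,
    nodata_code: int | None,
    strict: bool,
) -> dict[int, str]:
    present = set(np.unique(codes).tolist())
    if nodata_code is not None:
        present.discard(nodata_code)
    if legend is None:
        return {int(c): f"class_{int(c)}" for c in sorted(present)}
    missing = present - set(legend)
    if missing and strict:
        raise LegendError(f"codes {sorted(missing)} not present in the supplied legend")
    out = dict(legend)
    for c in sorted(missing):
        out[int(c)] = f"class_{int(c)}"
    return out


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, GridTransform, int | None]:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise FormatError(f"ESRI ASCII grid is missing the {req} header")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    values = np.loadtxt(data_lines, ndmin=2)
    if values.shape != (nrows, ncols):
        raise FormatError(
            f"grid body has shape {values.shape}, header says {(nrows, ncols)}"
        )
    if not np.all(values == np.round(values)):
        raise FormatError("categorical ASCII grid contains non-integer values")
    grid = values.astype(np.int64)
    if "xllcorner" in header:
        x0 = header["xllcorner"]
    else:
        x0 = header.get("xllcenter", 0.0) - cell / 2
    if "yllcorner" in header:
        yll = header["yllcorner"]
    else:
        yll = header.get("yllcenter", 0.0) - cell / 2
    transform = GridTransform(x0, yll + nrows * cell, cell, cell)
    nodata = header.get("nodata_value")
    return grid, transform, None if nodata is None else int(nodata)


def _write_ascii_grid(m: CategoricalMap, path: Path) -> None:
    nrows, ncols = m.shape
    t = m.transform
    if abs(t.dx - t.dy) > 1e-12:
        raise FormatError("ESRI ASCII grids require square cells")
    nodata = m.nodata_code if m.nodata_code is not None else -9999
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {t.x_origin!r}\n")
        fh.write(f"yllcorner {t.y_origin - nrows * t.dy!r}\n")
        fh.write(f"cellsize {t.dx!r}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in m.grid:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def _read_geotiff(path: Path) -> tuple[np.ndarray, GridTransform, int | None, dict]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        if data.ndim != 2:
            raise FormatError("multi-band TIFF is not a categorical map")
        if not np.issubdtype(data.dtype, np.integer):
            raise FormatError("categorical GeoTIFF must have an integer band")
        scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
        tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
        if scale is None or tiepoint is None:
            raise FormatError("TIFF lacks georeferencing tags (not a GeoTIFF)")
        dx, dy = float(scale.value[0]), float(scale.value[1])
        # tiepoint maps raster (i, j, 0) -> model (x, y, 0); written at (0, 0)
        x0 = float(tiepoint.value[3]) - float(tiepoint.value[0]) * dx
        y0 = float(tiepoint.value[4]) + float(tiepoint.value[1]) * dy
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        nodata = int(float(nodata_tag.value)) if nodata_tag is not None else None
        desc = tags.get("ImageDescription")
        meta: dict = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    return data.astype(np.int64), GridTransform(x0, y0, dx, dy), nodata, meta


def _geotiff_extratags(m: CategoricalMap) -> list[tuple]:
    t = m.transform
    tags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.dx, t.dy, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x_origin, t.y_origin, 0.0)),
    ]
    if m.nodata_code is not None:
        tags.append((_TAG_GDAL_NODATA, "s", 0, str(m.nodata_code)))
    return tags


def read_categorical_map(
    path: str | Path,
    timestamp: float | None = None,
    legend: dict[int, str] | None = None,
    *,
    strict: bool | None = None,
) -> CategoricalMap:
    """Read a categorical map from GeoTIFF or ESRI ASCII grid.

    When ``legend`` is given, grid codes outside it are an error unless
    ``strict=False``, in which case missing codes are auto-named
    ``class_<code>``.  Without a legend, auto-naming applies to every
    code.  A ``<path>.legend.csv`` sidecar, if present, supplies the
    legend for formats that cannot embed one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    crs_id = ""
    meta: dict = {}
    if suffix in (".tif", ".tiff"):
        grid, transform, nodata, meta = _read_geotiff(path)
        crs_id = str(meta.get("crs_id", ""))
        if timestamp is None and meta.get("timestamp") is not None:
            timestamp = float(meta["timestamp"])
        if legend is None and meta.get("legend"):
            legend = {int(k): v for k, v in meta["legend"].items()}
    elif suffix in (".asc", ".txt", ".grd"):
        grid, transform, nodata = _read_ascii_grid(path)
        prj = path.with_suffix(path.suffix + ".prj")
        if prj.exists():
            crs_id = prj.read_text().strip()
    else:
        raise FormatError(f"unsupported raster format: {path.suffix}")
    sidecar = path.with_suffix(path.suffix + ".legend.csv")
    if legend is None and sidecar.exists():
        legend = read_legend_csv(sidecar)
    if strict is None:
        strict = legend is not None
    full_legend = _apply_legend(grid, legend, nodata, strict)
    return CategoricalMap(
        grid=grid,
        transform=transform,
        legend=full_legend,
        crs_id=crs_id,
        nodata_code=nodata,
        timestamp=timestamp,
    )


def write_categorical_map(m: CategoricalMap, path: str | Path) -> None:
    """Write a map as GeoTIFF or ESRI ASCII grid (chosen by extension).

    GeoTIFF embeds legend, CRS id and timestamp in the file; the ASCII
    format cannot, so a ``.legend.csv`` sidecar (and ``.prj`` text file
    when a CRS id is set) is written next to the grid.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        meta = {
            "crs_id": m.crs_id,
            "timestamp": m.timestamp,
            "legend": {str(k): v for k, v in m.legend.items()},
        }
        tifffile.imwrite(
            path,
            m.grid.astype(np.int32),
            description=json.dumps(meta),
            extratags=_geotiff_extratags(m),
        )
    elif suffix in (".asc", ".txt", ".grd"):
        _write_ascii_grid(m, path)
        write_legend_csv(m.legend, path.with_suffix(path.suffix + ".legend.csv"))
        if m.crs_id:
            path.with_suffix(path.suffix + ".prj").write_text(m.crs_id + "\n")
    else:
        raise FormatError(f"unsupported raster format: {path.suffix}")


def write_surface(
    grid: np.ndarray, transform: GridTransform, path: str | Path, crs_id: str = ""
) -> None:
    """Write a continuous (float) surface as a single-band GeoTIFF."""
    dummy = CategoricalMap(
        grid=np.zeros((1, 1), dtype=np.int64),
        transform=transform,
        legend={0: "x"},
        crs_id=crs_id,
    )
    tifffile.imwrite(
        Path(path),
        np.asarray(grid, dtype=np.float64),
        description=json.dumps({"crs_id": crs_id}),
        extratags=_geotiff_extratags(dummy),
    )


# ---------------------------------------------------------------------------
# alignment and zone rasterization
# ---------------------------------------------------------------------------

def check_alignment(map_a: CategoricalMap, map_b: CategoricalMap) -> AlignmentReport:
    """Report whether two maps can be cross-tabulated cell-by-cell."""
    union = dict(map_a.legend)
    for code, name in map_b.legend.items():
        if code in union and union[code] != name:
            raise LegendError(
                f"code {code} means {union[code]!r} in one map and {name!r} in the other"
            )
        union[code] = name
    return AlignmentReport(
        same_shape=map_a.shape == map_b.shape,
        same_transform=map_a.transform == map_b.transform,
        same_crs=map_a.crs_id == map_b.crs_id,
        legend_union=union,
    )


def rasterize_zones(zones: ZoneSet, template: CategoricalMap) -> np.ndarray:
    """Burn zones onto the template grid; returns an int zone-id grid.

    Cells outside every zone carry :data:`NO_ZONE`.  Polygon zones claim
    the cells whose centres they contain; where polygons overlap, the
    zone listed first wins.  A zone covering no cell triggers a warning
    but stays in the set.
    """
    out = np.full(template.shape, NO_ZONE, dtype=np.int64)
    x = y = None
    for zone in zones:
        if zone.mask is not None:
            if zone.mask.shape != template.shape:
                raise AlignmentError(
                    f"zone {zone.zone_id} mask shape {zone.mask.shape} "
                    f"does not match template {template.shape}"
                )
            claim = zone.mask & (out == NO_ZONE)
        else:
            if x is None:
                x, y = template.transform.cell_centers(template.shape)
            claim = contains_xy(zone.geometry, x, y) & (out == NO_ZONE)
        if not claim.any():
            warnings.warn(
                f"zone {zone.zone_id} ({zone.name or 'unnamed'}) covers no grid cell",
                stacklevel=2,
            )
        out[claim] = zone.zone_id
    return out
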