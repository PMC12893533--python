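"""Categorical raster I/O and alignment checks.

The pipeline's universal carrier is a rectangular grid of integer class
codes with a declared nodata code and a square cell size in meters. Two
on-disk dialects are supported: single-band integer GeoTIFF (written via
:mod:`tifffile` with GeoTIFF pixel-scale/tiepoint tags and a GDAL nodata
tag) and the six-line-header ESRI ASCII grid, which is convenient for
plain-text fixtures.

Conventions fixed here and relied on everywhere downstream:

* cells are square; rasters with unequal x/y resolution are rejected,
  never resampled;
* row 0 is the top (north) row, and the center of cell ``(r, c)`` sits at
  offset ``((c + 0.5) * cell, -(r + 0.5) * cell)`` from the grid origin;
* the geotransform, when present, is opaque metadata — every distance and
  area in the package derives from ``cell_size_m`` and grid indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile

__all__ = [
    "GridSpec",
    "CategoricalRaster",
    "RasterError",
    "AlignmentError",
    "read_categorical_raster",
    "read_ascii_grid",
    "write_categorical_raster",
    "assert_aligned",
]

# GeoTIFF/GDAL tag codes used for metadata round-tripping.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999


class RasterError(ValueError):
    """Malformed raster file or raster contract violation."""


class AlignmentError(RasterError):
    """Two rasters do not share grid shape or cell size."""


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry: shape, square cell size, nodata code, placement.

    ``geotransform`` is the GDAL-style 6-tuple
    ``(origin_x, cell, 0, origin_y, 0, -cell)``; ``None`` means
    identity placement (origin at 0,0).
    """

    nrows: int
    ncols: int
    cell_size_m: float
    nodata_code: int = DEFAULT_NODATA
    geotransform: tuple[float, float, float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise RasterError(f"grid shape must be positive, got {self.nrows}x{self.ncols}")
        if not self.cell_size_m > 0:
            raise RasterError(f"cell_size_m must be positive, got {self.cell_size_m}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m * self.cell_size_m


@dataclass
class CategoricalRaster:
    """Integer class-code grid with legend and grid geometry.

    Every non-nodata code must appear in ``legend``; the nodata code must
    not. Construct via :meth:`from_codes` to auto-fill generic labels.
    """

    spec: GridSpec
    codes: np.ndarray
    legend: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise RasterError(f"codes must be integer, got dtype {self.codes.dtype}")
        if self.codes.shape != self.spec.shape:
            raise RasterError(
                f"codes shape {self.codes.shape} != grid shape {self.spec.shape}"
            )
        if self.spec.nodata_code in self.legend:
            raise RasterError(
                f"nodata code {self.spec.nodata_code} must not appear in the legend"
            )
        present = set(np.unique(self.codes).tolist()) - {self.spec.nodata_code}
        missing = present - set(self.legend)
        if missing:
            raise RasterError(f"codes {sorted(missing)} missing from legend")

    @classmethod
    def from_codes(
        cls,
        codes: np.ndarray,
        cell_size_m: float,
        nodata_code: int = DEFAULT_NODATA,
        legend: Mapping[int, str] | None = None,
        geotransform: tuple | None = None,
    ) -> "CategoricalRaster":
        codes = np.asarray(codes)
        spec = GridSpec(
            nrows=codes.shape[0],
            ncols=codes.shape[1],
            cell_size_m=cell_size_m,
            nodata_code=nodata_code,
            geotransform=geotransform,
        )
        if legend is None:
            present = set(np.unique(codes).tolist()) - {nodata_code}
            legend = {int(c): f"class {int(c)}" for c in sorted(present)}
        return cls(spec=spec, codes=codes, legend=dict(legend))

    @property
    def data_mask(self) -> np.ndarray:
        """Boolean grid, True on non-nodata cells."""
        return self.codes != self.spec.nodata_code

    @property
    def n_data_cells(self) -> int:
        return int(self.data_mask.sum())

    def with_codes(
        self, codes: np.ndarray, legend: Mapping[int, str] | None = None
    ) -> "CategoricalRaster":
        """Same grid geometry, new code grid (and optionally legend)."""
        return CategoricalRaster(
            spec=self.spec,
            codes=np.asarray(codes),
            legend=dict(self.legend if legend is None else legend),
        )


def _check_expected_codes(raster: CategoricalRaster, expected_codes: Iterable[int]) -> None:
    expected = set(int(c) for c in expected_codes)
    bad = (~np.isin(raster.codes, list(expected))) & raster.data_mask
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise RasterError(
            f"unexpected code {int(raster.codes[r, c])} at cell ({int(r)}, {int(c)}); "
            f"expected one of {sorted(expected)}"
        )


def read_categorical_raster(
    path: str | Path, expected_codes: Iterable[int] | None = None
) -> CategoricalRaster:
    """Read a single-band integer GeoTIFF into a :class:`CategoricalRaster`.

    Cell size is taken from the GeoTIFF ModelPixelScale tag (x and y must
    agree within 0.1%); nodata from the GDAL nodata tag; the legend from a
    JSON ImageDescription if one was written by this package, otherwise
    generic labels are generated. With ``expected_codes``, any other
    non-nodata value raises, naming the code and its first cell.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            codes = page.asarray()
            tags = page.tags
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value if _TAG_MODEL_PIXEL_SCALE in tags else None
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value if _TAG_MODEL_TIEPOINT in tags else None
            nodata_tag = tags[_TAG_GDAL_NODATA].value if _TAG_GDAL_NODATA in tags else None
            description = page.description or ""
    except (OSError, tifffile.TiffFileError, KeyError, IndexError) as exc:
        raise RasterError(f"cannot read GeoTIFF {path}: {exc}") from exc
    if codes.ndim != 2:
        raise RasterError(f"{path}: expected a single-band raster, got shape {codes.shape}")
    if not np.issubdtype(codes.dtype, np.integer):
        raise RasterError(f"{path}: categorical rasters must be integer, got {codes.dtype}")

    meta: dict = {}
    if description:
        try:
            meta = json.loads(description)
        except json.JSONDecodeError:
            meta = {}

    if scale is not None:
        sx, sy = float(scale[0]), float(scale[1])
        if abs(sx - sy) > 1e-3 * max(abs(sx), abs(sy)):
            raise RasterError(
                f"{path}: non-square cells ({sx} x {sy} m); resampling is out of scope"
            )
        cell = sx
    elif "cell_size_m" in meta:
        cell = float(meta["cell_size_m"])
    else:
        raise RasterError(f"{path}: no pixel scale metadata; cell size unknown")

    if nodata_tag is not None:
        nodata = int(float(str(nodata_tag).strip("\x00 ")))
    else:
        nodata = int(meta.get("nodata_code", DEFAULT_NODATA))

    geotransform = None
    if tiepoint is not None and scale is not None and len(tiepoint) >= 6:
        ox, oy = float(tiepoint[3]), float(tiepoint[4])
        geotransform = (ox, cell, 0.0, oy, 0.0, -cell)

    legend = None
    if "legend" in meta:
        legend = {int(k): str(v) for k, v in meta["legend"].items()}
        # tolerate stale legends on foreign files: drop codes not present
        present = set(np.unique(codes).tolist()) - {nodata}
        legend = {c: legend.get(c, f"class {c}") for c in sorted(present)}

    raster = CategoricalRaster.from_codes(
        codes.astype(np.int32), cell, nodata_code=nodata, legend=legend,
        geotransform=geotransform,
    )
    if expected_codes is not None:
        _check_expected_codes(raster, expected_codes)
    return raster


_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path: str | Path) -> CategoricalRaster:
    """Read an ESRI ASCII grid (six-line header, top row first)."""
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise RasterError(f"cannot read {path}: {exc}") from exc
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines[:6]):
        parts = line.split()
        if len(parts) != 2:
            raise RasterError(f"{path}: malformed header line {i + 1}: {line!r}")
        key = parts[0].lower()
        if key not in _ASCII_HEADER_KEYS:
            raise RasterError(f"{path}: unknown header key {parts[0]!r}")
        header[key] = float(parts[1])
        body_start = i + 1
    missing = [k for k in _ASCII_HEADER_KEYS if k not in header]
    if missing:
        raise RasterError(f"{path}: header missing {missing}")

    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    body_rows = [ln for ln in lines[body_start:] if ln.strip()]
    if len(body_rows) != nrows:
        raise RasterError(
            f"{path}: header declares {nrows} rows but body has {len(body_rows)}"
        )
    grid = np.empty((nrows, ncols), dtype=np.int32)
    for r, line in enumerate(body_rows):
        tokens = line.split()
        if len(tokens) != ncols:
            raise RasterError(
                f"{path}: row {r} has {len(tokens)} values, expected {ncols}"
            )
        for c, tok in enumerate(tokens):
            try:
                grid[r, c] = int(tok)
            except ValueError as exc:
                raise RasterError(
                    f"{path}: non-integer value {tok!r} at row {r}, column {c}; "
                    "categorical rasters are integer"
                ) from exc

    cell = float(header["cellsize"])
    nodata = int(header["nodata_value"])
    ox = float(header["xllcorner"])
    oy = float(header["yllcorner"]) + nrows * cell  # upper-left origin
    return CategoricalRaster.from_codes(
        grid, cell, nodata_code=nodata, geotransform=(ox, cell, 0.0, oy, 0.0, -cell)
    )


def write_categorical_raster(
    raster: CategoricalRaster, path: str | Path, format: str = "geotiff"
) -> Path:
    """Write a raster as GeoTIFF or ESRI ASCII grid; round-trips exactly."""
    path = Path(path)
    if not path.parent.is_dir():
        raise RasterError(f"parent directory does not exist: {path.parent}")
    if format == "geotiff":
        _write_geotiff(raster, path)
    elif format == "ascii":
        _write_ascii(raster, path)
    else:
        raise RasterError(f"unknown format {format!r}; use 'geotiff' or 'ascii'")
    return path


def _write_geotiff(raster: CategoricalRaster, path: Path) -> None:
    spec = raster.spec
    gt = spec.geotransform or (0.0, spec.cell_size_m, 0.0, 0.0, 0.0, -spec.cell_size_m)
    description = json.dumps(
        {
            "cell_size_m": spec.cell_size_m,
            "nodata_code": spec.nodata_code,
            "legend": {str(k): v for k, v in raster.legend.items()},
        }
    )
    nodata_ascii = f"{spec.nodata_code}"
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (spec.cell_size_m, spec.cell_size_m, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, gt[0], gt[3], 0.0)),
        (_TAG_GDAL_NODATA, "s", len(nodata_ascii) + 1, nodata_ascii),
    ]
    try:
        tifffile.imwrite(
            path,
            raster.codes.astype(np.int32),
            compression="zlib",
            description=description,
            extratags=extratags,
        )
    except OSError as exc:
        raise RasterError(f"cannot write {path}: {exc}") from exc


def _write_ascii(raster: CategoricalRaster, path: Path) -> None:
    spec = raster.spec
    gt = spec.geotransform or (0.0, spec.cell_size_m, 0.0, 0.0, 0.0, -spec.cell_size_m)
    xll = gt[0]
    yll = gt[3] - spec.nrows * spec.cell_size_m
    lines = [
        f"ncols {spec.ncols}",
        f"nrows {spec.nrows}",
        f"xllcorner {xll:g}",
        f"yllcorner {yll:g}",
        f"cellsize {spec.cell_size_m:g}",
        f"NODATA_value {spec.nodata_code}",
    ]
    for row in raster.codes:
        lines.append(" ".join(str(int(v)) for v in row))
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise RasterError(f"cannot write {path}: {exc}") from exc


def assert_aligned(a: CategoricalRaster, b: CategoricalRaster) -> None:
    """Raise :class:`AlignmentError` unless shapes and cell size agree.

    Precondition for every two-raster operation (clipping, change,
    transition, pairing). Geotransforms are deliberately not compared;
    the pipeline is grid-native.
    """
    if a.spec.nrows != b.spec.nrows:
        raise AlignmentError(f"nrows differ: {a.spec.nrows} vs {b.spec.nrows}")
    if a.spec.ncols != b.spec.ncols:
        raise AlignmentError(f"ncols differ: {a.spec.ncols} vs {b.spec.ncols}")
    if abs(a.spec.cell_size_m - b.spec.cell_size_m) > 1e-9 * max(
        a.spec.cell_size_m, b.spec.cell_size_m
    ):
        raise AlignmentError(
            f"cell_size_m differs: {a.spec.cell_size_m} vs {b.spec.cell_size_m}"
        )
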