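"""Legend collapsing and zone clipping.

Source-specific land-use/land-cover legends are collapsed into three
analysis classes — natural cover (1), anthropic use (2), water (3) —
before any fragmentation analysis. Natural cover is the study class;
anthropic use and water are background. Water is background rather than
excluded so that the landscape area ``A`` (all non-nodata cells) is
stable across dates: zone clipping, not class content, defines ``A``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .raster_io import CategoricalRaster, RasterError, assert_aligned

__all__ = [
    "NATURAL",
    "ANTHROPIC",
    "WATER",
    "TARGET_LEGEND",
    "ReclassScheme",
    "ZoneMask",
    "load_reclass_scheme",
    "reclassify",
    "clip_to_zone",
    "natural_binary",
]

NATURAL = 1
ANTHROPIC = 2
WATER = 3
TARGET_LEGEND = {NATURAL: "natural", ANTHROPIC: "anthropic", WATER: "water"}

_BINARY_LEGEND = {0: "background", 1: "natural"}


@dataclass(frozen=True)
class ReclassScheme:
    """Total mapping from source legend codes to the three target classes."""

    mapping: Mapping[int, int]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        bad = set(self.mapping.values()) - {NATURAL, ANTHROPIC, WATER}
        if bad:
            raise RasterError(
                f"scheme {self.name!r}: target codes must be in "
                f"{{1 (natural), 2 (anthropic), 3 (water)}}, got {sorted(bad)}"
            )


@dataclass(frozen=True)
class ZoneMask:
    """Aligned binary raster; 1 marks cells inside the study zone."""

    raster: CategoricalRaster
    zone_name: str = "zone"

    def __post_init__(self) -> None:
        codes = np.unique(self.raster.codes)
        allowed = {0, 1, self.raster.spec.nodata_code}
        bad = set(codes.tolist()) - allowed
        if bad:
            raise RasterError(
                f"zone mask {self.zone_name!r} has non-binary codes {sorted(bad)}"
            )


def load_reclass_scheme(path: str | Path, name: str | None = None) -> ReclassScheme:
    """Load a two-column CSV (source_code, target_code) with a header row."""
    path = Path(path)
    mapping: dict[int, int] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise RasterError(f"{path}: empty scheme file")
        for row in reader:
            if not row or not row[0].strip():
                continue
            try:
                src, dst = int(row[0]), int(row[1])
            except (IndexError, ValueError) as exc:
                raise RasterError(f"{path}: malformed scheme row {row!r}") from exc
            mapping[src] = dst
    return ReclassScheme(mapping=mapping, name=name or path.stem)


def reclassify(raster: CategoricalRaster, scheme: ReclassScheme) -> CategoricalRaster:
    """Map every non-nodata code through the scheme; fail on unmapped codes.

    Never default-assigns: a source code absent from the mapping raises,
    naming the code. Nodata cells are preserved in place and the cell
    count is conserved.
    """
    present = set(np.unique(raster.codes).tolist()) - {raster.spec.nodata_code}
    unmapped = present - set(scheme.mapping)
    if unmapped:
        raise RasterError(
            f"scheme {scheme.name!r} does not map source code(s) {sorted(unmapped)}"
        )
    out = np.full_like(raster.codes, raster.spec.nodata_code)
    mask = raster.data_mask
    for src, dst in scheme.mapping.items():
        out[mask & (raster.codes == src)] = dst
    return raster.with_codes(out, legend=TARGET_LEGEND)


def clip_to_zone(raster: CategoricalRaster, mask: ZoneMask) -> CategoricalRaster:
    """Keep codes where the mask is 1; everything else becomes nodata.

    Downstream landscape area A is the non-nodata cell count times cell
    area, so the clip defines the analysis extent.
    """
    assert_aligned(raster, mask.raster)
    keep = mask.raster.codes == 1
    out = np.where(keep, raster.codes, raster.spec.nodata_code)
    legend = {c: l for c, l in raster.legend.items()}
    present = set(np.unique(out).tolist()) - {raster.spec.nodata_code}
    legend = {c: legend.get(c, f"class {c}") for c in sorted(present)}
    return raster.with_codes(out.astype(raster.codes.dtype), legend=legend)


def natural_binary(raster: CategoricalRaster) -> CategoricalRaster:
    """Collapse a 3-class raster to natural=1 foreground, else 0; keep nodata.

    This binary layer feeds both patch delineation and forest-area-density.
    """
    present = set(np.unique(raster.codes).tolist()) - {raster.spec.nodata_code}
    bad = present - {NATURAL, ANTHROPIC, WATER}
    if bad:
        raise RasterError(
            f"expected 3-class codes {{1,2,3}} plus nodata, found {sorted(bad)}"
        )
    out = np.full_like(raster.codes, raster.spec.nodata_code)
    mask = raster.data_mask
    out[mask] = (raster.codes[mask] == NATURAL).astype(raster.codes.dtype)
    return raster.with_codes(out, legend=_BINARY_LEGEND)
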