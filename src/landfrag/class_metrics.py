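"""Class-level landscape metrics for natural cover.

Six FRAGSTATS-style class metrics are computed from a patch labeling,
with patch areas a_ij in m², landscape area A in m² (all non-nodata
cells), and n_i patches:

* PA_MN — mean patch area, (Σ a_ij / n_i) / 10⁴, in hectares
* NP    — number of patches, n_i
* PD    — patch density, (n_i / A) · 10⁴ · 100, patches per 100 ha
* LPI   — largest patch index, (max a_ij / A) · 100, percent
* ENN_MN — mean Euclidean nearest-neighbor distance, meters
* MESH  — effective mesh size, (Σ a_ij² / A) / 10⁴, hectares

MESH is reported in hectares (the m² ratio divided by 10⁴), matching the
FRAGSTATS convention. ENN_MN averages only patches with a defined
neighbor distance; with zero patches PA_MN and ENN_MN are undefined
(NaN), with one patch ENN_MN is undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .patch_structure import PatchLabeling, compute_enn, label_patches
from .raster_io import CategoricalRaster, RasterError
from .reclassification import natural_binary

__all__ = ["ClassMetrics", "compute_class_metrics", "metrics_table", "METRIC_COLUMNS"]

METRIC_COLUMNS = [
    "pa_mn_ha",
    "np",
    "pd_per100ha",
    "lpi_pct",
    "enn_mn_m",
    "mesh_ha",
    "total_class_area_ha",
    "landscape_area_ha",
]

_M2_PER_HA = 10_000.0


@dataclass(frozen=True)
class ClassMetrics:
    pa_mn_ha: float
    np: int
    pd_per100ha: float
    lpi_pct: float
    enn_mn_m: float
    mesh_ha: float
    total_class_area_ha: float
    landscape_area_ha: float

    def as_dict(self) -> dict[str, float | int]:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def compute_class_metrics(labeling: PatchLabeling) -> ClassMetrics:
    """Evaluate the six class metrics on one labeled raster."""
    area_m2 = labeling.landscape_area_m2
    if area_m2 <= 0:
        raise RasterError("landscape area is zero (fully-nodata raster)")
    areas = [rec.area_m2 for rec in labeling.records]
    n = len(areas)
    total = float(sum(areas))
    if n == 0:
        return ClassMetrics(
            pa_mn_ha=math.nan,
            np=0,
            pd_per100ha=0.0,
            lpi_pct=0.0,
            enn_mn_m=math.nan,
            mesh_ha=0.0,
            total_class_area_ha=0.0,
            landscape_area_ha=area_m2 / _M2_PER_HA,
        )
    enns = [rec.enn_m for rec in labeling.records if rec.enn_m is not None]
    return ClassMetrics(
        pa_mn_ha=(total / n) / _M2_PER_HA,
        np=n,
        pd_per100ha=(n / area_m2) * _M2_PER_HA * 100.0,
        lpi_pct=(max(areas) / area_m2) * 100.0,
        enn_mn_m=(sum(enns) / len(enns)) if enns else math.nan,
        mesh_ha=(sum(a * a for a in areas) / area_m2) / _M2_PER_HA,
        total_class_area_ha=total / _M2_PER_HA,
        landscape_area_ha=area_m2 / _M2_PER_HA,
    )


def metrics_for_raster(raster: CategoricalRaster) -> ClassMetrics:
    """Convenience: 3-class or binary raster → natural-cover class metrics."""
    present = set(int(c) for c in pd.unique(raster.codes.ravel())) - {raster.spec.nodata_code}
    binary = raster if present <= {0, 1} else natural_binary(raster)
    return compute_class_metrics(compute_enn(label_patches(binary)))


def metrics_table(series: list[tuple[str, str, int, CategoricalRaster]]) -> pd.DataFrame:
    """Long-format metric panel: one row per (source, zone, year).

    Rasters may be 3-class or already binary. Undefined metrics are NaN
    (written as empty fields by CSV writers, never 0). Duplicate
    (source, zone, year) keys raise.
    """
    seen: set[tuple[str, str, int]] = set()
    rows = []
    for source, zone, year, raster in series:
        key = (source, zone, year)
        if key in seen:
            raise ValueError(f"duplicate (source, zone, year) key {key}")
        seen.add(key)
        metrics = metrics_for_raster(raster)
        rows.append({"source": source, "zone": zone, "year": year, **metrics.as_dict()})
    return pd.DataFrame(rows, columns=["source", "zone", "year", *METRIC_COLUMNS])
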