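"""Forest-area-density (FAD) fragmentation mapping and change accounting.

FAD assigns each natural-cover pixel the percentage of natural pixels in
a square moving window centered on it. Windows are clipped at the grid
border and the denominator is the count of in-grid, non-nodata window
cells, so border pixels are rated against their visible neighborhood.

FAD values are banded into six fragmentation classes (lower-inclusive
intervals): rare [0,10), patchy [10,40), transitional [40,60), dominant
[60,90), interior [90,100), intact = 100. Multiscale analysis evaluates
FAD at five window widths (7, 13, 27, 81, 243 pixels by default),
averages the five continuous values per pixel, and classifies the
average once ("average-then-classify"). A window at least as large as
the grid degenerates to the global foreground proportion at every pixel.

Between-date change is summarized two ways: a 7×7 transition matrix of
fragmentation classes (plus the non-natural state 0), where moves to a
lower class rank mean increasing fragmentation, and a per-scale class
proportion profile for each date.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_io import CategoricalRaster, RasterError, assert_aligned

__all__ = [
    "NODATA_CLASS",
    "FADClassScheme",
    "SIX_CLASS_SCHEME",
    "FIVE_CLASS_SCHEME",
    "TWO_CLASS_SCHEME",
    "FADConfig",
    "FADRaster",
    "FragClassRaster",
    "TransitionMatrix",
    "box_sum",
    "compute_fad",
    "classify_fad",
    "multiscale_fad",
    "transition_matrix",
    "natural_loss_area",
    "change_profile",
]

NODATA_CLASS = -1


@dataclass(frozen=True)
class FADClassScheme:
    """Ordered class names with lower-bound FAD thresholds in percent.

    ``intact_at_100`` reserves the top class for pixels at exactly 100%
    density (the 6-class convention); without it the last threshold band
    runs to 100 inclusive.
    """

    names: tuple[str, ...]
    lower_bounds: tuple[float, ...]
    intact_at_100: bool = True

    def __post_init__(self) -> None:
        n_banded = len(self.names) - (1 if self.intact_at_100 else 0)
        if len(self.lower_bounds) != n_banded:
            raise RasterError("one lower bound per banded class required")
        bounds = self.lower_bounds
        if bounds[0] != 0 or any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise RasterError("thresholds must start at 0 and increase strictly")
        if any(b >= 100 for b in bounds[1:]) or bounds[-1] >= 100:
            raise RasterError("thresholds must be below 100")

    @property
    def n_classes(self) -> int:
        return len(self.names)


SIX_CLASS_SCHEME = FADClassScheme(
    names=("rare", "patchy", "transitional", "dominant", "interior", "intact"),
    lower_bounds=(0.0, 10.0, 40.0, 60.0, 90.0),
    intact_at_100=True,
)
FIVE_CLASS_SCHEME = FADClassScheme(
    names=("rare", "patchy", "transitional", "dominant", "interior"),
    lower_bounds=(0.0, 10.0, 40.0, 60.0, 90.0),
    intact_at_100=False,
)
TWO_CLASS_SCHEME = FADClassScheme(
    names=("separated", "continuous"),
    lower_bounds=(0.0, 40.0),
    intact_at_100=False,
)

DEFAULT_SCALES = (7, 13, 27, 81, 243)


@dataclass(frozen=True)
class FADConfig:
    """Observation scales and class scheme for multiscale analysis."""

    scales: tuple[int, ...] = DEFAULT_SCALES
    scheme: FADClassScheme = SIX_CLASS_SCHEME

    def __post_init__(self) -> None:
        for w in self.scales:
            _check_window(w)


def _check_window(window: int) -> None:
    if window < 3 or window % 2 == 0:
        raise RasterError(f"window width must be odd and >= 3, got {window}")


@dataclass
class FADRaster:
    """Per-pixel FAD percent, defined (non-NaN) exactly on foreground pixels."""

    values: np.ndarray  # float64, NaN off-foreground
    scale: str  # e.g. "7" or "multiscale-average"
    cell_size_m: float
    nodata_mask: np.ndarray  # True where source raster was nodata


@dataclass
class FragClassRaster:
    """Per-pixel fragmentation class: -1 nodata, 0 non-natural, 1..k classes."""

    classes: np.ndarray  # int8
    scheme: FADClassScheme
    provenance: str
    cell_size_m: float

    def to_raster(self, nodata_code: int = -1) -> CategoricalRaster:
        legend = {0: "nonnatural"}
        legend.update({i + 1: n for i, n in enumerate(self.scheme.names)})
        codes = self.classes.astype(np.int32)
        codes[self.classes == NODATA_CLASS] = nodata_code
        return CategoricalRaster.from_codes(
            codes, self.cell_size_m, nodata_code=nodata_code, legend=legend
        )


def box_sum(values: np.ndarray, window: int) -> np.ndarray:
    """Clipped moving-window sum via a summed-area table.

    Each output cell holds the sum of ``values`` over the window×window
    neighborhood centered on it, truncated at the grid border. Exact for
    integer-valued inputs (float64 cumulative sums of 0/1 counts).
    """
    _check_window(window)
    a = np.asarray(values, dtype=np.float64)
    nr, nc = a.shape
    h = window // 2
    sat = np.zeros((nr + 1, nc + 1))
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=sat[1:, 1:])
    r0 = np.clip(np.arange(nr) - h, 0, nr)
    r1 = np.clip(np.arange(nr) + h + 1, 0, nr)
    c0 = np.clip(np.arange(nc) - h, 0, nc)
    c1 = np.clip(np.arange(nc) + h + 1, 0, nc)
    return (
        sat[np.ix_(r1, c1)] - sat[np.ix_(r0, c1)] - sat[np.ix_(r1, c0)] + sat[np.ix_(r0, c0)]
    )


def compute_fad(binary: CategoricalRaster, window: int) -> FADRaster:
    """FAD percent per foreground pixel for one window width.

    FAD = 100 · (foreground cells in window) / (non-nodata cells in
    window); background and nodata pixels are undefined (NaN).
    """
    _check_window(window)
    present = set(np.unique(binary.codes).tolist()) - {binary.spec.nodata_code}
    if not present <= {0, 1}:
        raise RasterError(f"expected binary codes {{0,1}} plus nodata, found {sorted(present)}")
    valid = binary.data_mask
    fore = (binary.codes == 1) & valid
    num = box_sum(fore, window)
    den = box_sum(valid, window)
    values = np.full(binary.codes.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = 100.0 * num / den
    values[fore] = ratio[fore]
    return FADRaster(
        values=values,
        scale=str(window),
        cell_size_m=binary.spec.cell_size_m,
        nodata_mask=~valid,
    )


def classify_fad(fad: FADRaster, scheme: FADClassScheme = SIX_CLASS_SCHEME) -> FragClassRaster:
    """Band continuous FAD values into fragmentation classes.

    Intervals are lower-inclusive; with ``intact_at_100`` a pixel lands
    in the top class only at exactly 100% density.
    """
    values = fad.values
    defined = ~np.isnan(values)
    if defined.any():
        vmin, vmax = np.nanmin(values), np.nanmax(values)
        if vmin < 0 or vmax > 100 + 1e-9:
            raise RasterError(f"FAD values outside [0, 100]: min {vmin}, max {vmax}")
    classes = np.zeros(values.shape, dtype=np.int8)
    banded = np.digitize(values[defined], fad_bins := np.asarray(scheme.lower_bounds[1:]), right=False) + 1
    if scheme.intact_at_100:
        banded[values[defined] >= 100.0] = scheme.n_classes
    classes[defined] = banded.astype(np.int8)
    classes[fad.nodata_mask] = NODATA_CLASS
    return FragClassRaster(
        classes=classes,
        scheme=scheme,
        provenance=f"fad-{fad.scale}",
        cell_size_m=fad.cell_size_m,
    )


def multiscale_fad(
    binary: CategoricalRaster, config: FADConfig = FADConfig()
) -> tuple[list[FragClassRaster], FADRaster, FragClassRaster]:
    """Per-scale class maps plus the classified multiscale average.

    The average FAD is the arithmetic mean of the per-scale continuous
    FAD values at each foreground pixel, classified once with the same
    scheme as the per-scale maps.
    """
    per_scale_fads = [compute_fad(binary, w) for w in config.scales]
    per_scale_classes = [classify_fad(f, config.scheme) for f in per_scale_fads]
    stacked = np.stack([f.values for f in per_scale_fads])
    avg = FADRaster(
        values=np.mean(stacked, axis=0),
        scale="multiscale-average",
        cell_size_m=binary.spec.cell_size_m,
        nodata_mask=per_scale_fads[0].nodata_mask,
    )
    return per_scale_classes, avg, classify_fad(avg, config.scheme)


@dataclass
class TransitionMatrix:
    """Class-transition counts between two dates, including state 0.

    ``counts[i][j]`` is the number of cells (non-nodata at both dates) in
    state *i* at date 1 and state *j* at date 2, where state 0 is
    non-natural and states 1..k are fragmentation classes in increasing
    density rank. Mass below the diagonal (i > j among classes) is a
    fragmentation increase; above, a decrease.
    """

    counts: np.ndarray  # (k+1, k+1) int64
    labels: tuple[str, ...]
    cell_area_m2: float

    @property
    def row_percent(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals
        return pct  # NaN rows where the date-1 state is empty

    def fragmentation_increase_cells(self) -> int:
        """Cells moving from a higher to a lower class rank (classes only)."""
        sub = self.counts[1:, 1:]
        return int(np.tril(sub, k=-1).sum())

    def fragmentation_decrease_cells(self) -> int:
        sub = self.counts[1:, 1:]
        return int(np.triu(sub, k=1).sum())

    def to_dataframe(self, kind: str = "counts") -> pd.DataFrame:
        if kind == "counts":
            data = self.counts
        elif kind == "percent":
            data = self.row_percent
        elif kind == "area_ha":
            data = self.counts * self.cell_area_m2 / 10_000.0
        else:
            raise ValueError(f"unknown kind {kind!r}")
        return pd.DataFrame(data, index=list(self.labels), columns=list(self.labels))


def transition_matrix(c1: FragClassRaster, c2: FragClassRaster) -> TransitionMatrix:
    """Cross-tabulate fragmentation classes between two dates."""
    if c1.scheme != c2.scheme:
        raise RasterError("transition requires the same class scheme at both dates")
    if c1.classes.shape != c2.classes.shape:
        raise RasterError(
            f"shape mismatch: {c1.classes.shape} vs {c2.classes.shape}"
        )
    if abs(c1.cell_size_m - c2.cell_size_m) > 1e-9 * c1.cell_size_m:
        raise RasterError("cell size mismatch between dates")
    k = c1.scheme.n_classes
    both = (c1.classes != NODATA_CLASS) & (c2.classes != NODATA_CLASS)
    a = c1.classes[both].astype(np.int64)
    b = c2.classes[both].astype(np.int64)
    counts = np.bincount(a * (k + 1) + b, minlength=(k + 1) ** 2).reshape(k + 1, k + 1)
    labels = ("nonnatural", *c1.scheme.names)
    return TransitionMatrix(
        counts=counts, labels=labels, cell_area_m2=c1.cell_size_m**2
    )


def natural_loss_area(b1: CategoricalRaster, b2: CategoricalRaster) -> float:
    """Hectares of natural cover present at date 1 but gone at date 2.

    Asymmetric by design: swapping the dates measures gain, not loss.
    """
    assert_aligned(b1, b2)
    lost = (b1.codes == 1) & b1.data_mask & (b2.codes == 0) & b2.data_mask
    return float(lost.sum()) * b1.spec.cell_area_m2 / 10_000.0


def change_profile(
    ms1: list[FragClassRaster],
    ms2: list[FragClassRaster],
    dates: tuple[str, str] = ("t1", "t2"),
) -> pd.DataFrame:
    """Per-scale class composition for two dates (long table).

    Columns: date, scale, class, percent — percentages of foreground
    (natural) pixels, summing to 100 within each (date, scale).
    """
    scales1 = [c.provenance for c in ms1]
    scales2 = [c.provenance for c in ms2]
    if scales1 != scales2:
        raise RasterError(f"scale mismatch between dates: {scales1} vs {scales2}")
    rows = []
    for date, rasters in zip(dates, (ms1, ms2)):
        for frag in rasters:
            fg = frag.classes > 0
            total = int(fg.sum())
            for ci, name in enumerate(frag.scheme.names, start=1):
                count = int((frag.classes == ci).sum())
                pct = 100.0 * count / total if total else float("nan")
                rows.append(
                    {"date": date, "scale": frag.provenance, "class": name, "percent": pct}
                )
    return pd.DataFrame(rows, columns=["date", "scale", "class", "percent"])
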