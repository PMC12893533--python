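"""Seeded paired-source landscape simulator.

Generates what the analysis stages assume as input: a time series of
binary forest maps for one landscape, observed through two imperfect
classifiers with opposite biases — a *coarse* source A that generalizes
the landscape (majority smoothing removes small clearings and isolated
specks, yielding fewer, larger patches) and a *fine* source B that
resolves small features but carries salt-and-pepper classification noise
(yielding many more, smaller patches).

The underlying "true" landscape follows a minimal distance-decay
frontier model: deforestation starts from a north–south road corridor,
each step clears forest cells with probability
``frontier_rate * exp(-d / frontier_decay_cells)`` (d = cell distance to
the nearest already-cleared cell) and seeds a Poisson number of small
independent clearings that themselves become frontier nuclei. Forest
area is non-increasing by construction, and everything is deterministic
given the scenario seed.

The road polyline is rasterized with 4-connected steps and dilated to a
three-cell-wide corridor, so the corridor splits the initial forest into
two 8-connected patches (a 4-connected background path separates
8-connected foreground) and survives the coarse source's majority
filter.

Source-B noise is a *persistent* per-cell flip field: the same derived
sub-seed is used for every year, modelling a systematic classifier bias.
Consequently the fine source's speck count grows monotonically with the
cleared area rather than fluctuating between close map years.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .raster_io import CategoricalRaster
from .reclassification import ANTHROPIC, NATURAL, TARGET_LEGEND

__all__ = [
    "SyntheticScenario",
    "generate_true_series",
    "derive_source_A",
    "derive_source_B",
    "generate_paired_dataset",
]

_BINARY_LEGEND = {0: "nonforest", 1: "forest"}
_NODATA = -9999

# sub-stream tags so that process noise and observation noise are independent
_PROCESS_STREAM = 101
_ROAD_STREAM = 102
_SOURCE_B_STREAM = 103

DEFAULT_YEARS = (1990, 2000, 2008, 2014, 2016, 2018, 2020, 2022)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of the paired two-source study design.

    Defaults emulate a 6 km × 6 km Landsat-resolution window (200×200
    cells of 30 m) observed at the study's eight map years.
    """

    nrows: int = 200
    ncols: int = 200
    cell_size_m: float = 30.0
    seed: int = 0
    years: tuple[int, ...] = DEFAULT_YEARS
    road_cells: tuple[tuple[int, int], ...] | None = None  # None -> seeded corridor
    frontier_rate: float = 0.4
    frontier_decay_cells: float = 2.0
    smallclear_lambda: float = 3.0
    sourceA_smooth_radius: int = 2
    sourceB_noise: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.frontier_rate <= 1.0 and 0.0 <= self.sourceB_noise <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.frontier_decay_cells <= 0:
            raise ValueError("frontier_decay_cells must be positive")
        if self.smallclear_lambda < 0 or self.sourceA_smooth_radius < 0:
            raise ValueError("rates and radii must be non-negative")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if self.road_cells is not None:
            for r, c in self.road_cells:
                if not (0 <= r < self.nrows and 0 <= c < self.ncols):
                    raise ValueError(f"road cell ({r}, {c}) outside the grid")


def _road_mask(scenario: SyntheticScenario) -> np.ndarray:
    """Width-3 north–south corridor; 4-connected center line, then dilated."""
    mask = np.zeros((scenario.nrows, scenario.ncols), dtype=bool)
    if scenario.road_cells is not None:
        rows, cols = zip(*scenario.road_cells)
        mask[list(rows), list(cols)] = True
        return mask
    rng = np.random.default_rng([scenario.seed, _ROAD_STREAM])
    col = scenario.ncols // 2
    for r in range(scenario.nrows):
        new_col = int(np.clip(col + rng.integers(-1, 2), 1, scenario.ncols - 2))
        mask[r, col] = True  # vertical step first keeps the path 4-connected
        mask[r, new_col] = True
        col = new_col
    return ndimage.binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))


def _grow_blob(
    rng: np.random.Generator, forest: np.ndarray, start: tuple[int, int], size: int
) -> list[tuple[int, int]]:
    """Small 4-connected clearing of up to ``size`` cells around ``start``."""
    nr, nc = forest.shape
    blob = [start]
    members = {start}
    for _ in range(size - 1):
        r, c = blob[rng.integers(0, len(blob))]
        candidates = [
            (r + dr, c + dc)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= r + dr < nr and 0 <= c + dc < nc and (r + dr, c + dc) not in members
        ]
        if not candidates:
            break
        cell = candidates[rng.integers(0, len(candidates))]
        blob.append(cell)
        members.add(cell)
    return blob


def _to_raster(forest: np.ndarray, scenario: SyntheticScenario) -> CategoricalRaster:
    return CategoricalRaster.from_codes(
        forest.astype(np.int32),
        scenario.cell_size_m,
        nodata_code=_NODATA,
        legend=_BINARY_LEGEND,
    )


def generate_true_series(scenario: SyntheticScenario) -> list[CategoricalRaster]:
    """One binary forest raster per scenario year; forest never regrows."""
    rng = np.random.default_rng([scenario.seed, _PROCESS_STREAM])
    road = _road_mask(scenario)
    forest = ~road
    series = [_to_raster(forest, scenario)]
    for _ in scenario.years[1:]:
        forest = forest.copy()
        # frontier clearing: probability decays with distance to cleared land
        dist = ndimage.distance_transform_edt(forest)
        prob = scenario.frontier_rate * np.exp(-dist / scenario.frontier_decay_cells)
        cleared_now = (rng.random(forest.shape) < prob) & forest
        forest[cleared_now] = False
        # independent small clearings (new frontier nuclei)
        n_clearings = rng.poisson(scenario.smallclear_lambda)
        for _ in range(n_clearings):
            forest_cells = np.argwhere(forest)
            if forest_cells.size == 0:
                break
            start = tuple(forest_cells[rng.integers(0, len(forest_cells))])
            size = int(rng.integers(1, 6))
            for r, c in _grow_blob(rng, forest, (int(start[0]), int(start[1])), size):
                forest[r, c] = False
        series.append(_to_raster(forest, scenario))
    return series


def derive_source_A(true: CategoricalRaster, radius: int) -> CategoricalRaster:
    """Generalizing (coarse) observation: clipped-window majority filter.

    Each cell takes the majority value of its (2·radius+1)² neighborhood,
    truncated at the border; ties go to forest. Radius 0 is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius == 0:
        return true.with_codes(true.codes.copy())
    from .fad_fragmentation import box_sum  # local import avoids a cycle at import time

    window = 2 * radius + 1
    valid = true.data_mask
    fore = (true.codes == 1) & valid
    n_fore = box_sum(fore, window)
    n_valid = box_sum(valid, window)
    majority = 2.0 * n_fore >= n_valid  # ties -> forest
    out = np.full_like(true.codes, true.spec.nodata_code)
    out[valid] = majority[valid].astype(true.codes.dtype)
    return true.with_codes(out, legend=_BINARY_LEGEND)


def derive_source_B(true: CategoricalRaster, noise: float, seed: int) -> CategoricalRaster:
    """Sensitive (fine) observation: per-cell flips with probability ``noise``."""
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flips = rng.random(true.codes.shape) < noise
    valid = true.data_mask
    out = true.codes.copy()
    flip_here = flips & valid
    out[flip_here] = 1 - out[flip_here]
    return true.with_codes(out, legend=_BINARY_LEGEND)


def source_b_seed(scenario: SyntheticScenario) -> int:
    """Derived sub-seed for the persistent source-B flip field (< 2^31)."""
    return int(np.random.SeedSequence([scenario.seed, _SOURCE_B_STREAM]).generate_state(1)[0] % (2**31))


def generate_paired_dataset(
    scenario: SyntheticScenario,
) -> tuple[dict[str, dict[int, CategoricalRaster]], dict]:
    """Three-class rasters per source per year, plus a reproducibility manifest.

    Non-forest is mapped to the anthropic class (the synthetic landscape
    has no water); the same flip-field seed is used for source B in all
    years (see module docstring).
    """
    truth = generate_true_series(scenario)
    b_seed = source_b_seed(scenario)
    dataset: dict[str, dict[int, CategoricalRaster]] = {"A": {}, "B": {}}
    for year, true in zip(scenario.years, truth):
        obs_a = derive_source_A(true, scenario.sourceA_smooth_radius)
        obs_b = derive_source_B(true, scenario.sourceB_noise, b_seed)
        for name, obs in (("A", obs_a), ("B", obs_b)):
            codes = np.full_like(obs.codes, _NODATA)
            valid = obs.data_mask
            codes[valid] = np.where(obs.codes[valid] == 1, NATURAL, ANTHROPIC)
            dataset[name][year] = obs.with_codes(codes, legend=TARGET_LEGEND)
    manifest = {
        "generator": "landfrag.synthetic_landscapes",
        "scenario": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(scenario).items()},
        "source_b_seed": b_seed,
        "sources": {"A": "coarse (majority-smoothed)", "B": "fine (noisy)"},
    }
    return dataset, manifest
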