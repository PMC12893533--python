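"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — breadth-first flood fill, all-pairs
distances, per-pixel window loops, direct formula evaluation — kept free
of any code shared with the production path.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

_EIGHT_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def flood_fill_partition(fore: np.ndarray) -> list[frozenset[tuple[int, int]]]:
    """8-connected components of a boolean grid as sets of (row, col)."""
    nr, nc = fore.shape
    seen = np.zeros_like(fore, dtype=bool)
    parts = []
    for r in range(nr):
        for c in range(nc):
            if fore[r, c] and not seen[r, c]:
                comp = set()
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    cr, cc = queue.popleft()
                    comp.add((cr, cc))
                    for dr, dc in _EIGHT_NEIGHBORS:
                        nr2, nc2 = cr + dr, cc + dc
                        if 0 <= nr2 < nr and 0 <= nc2 < nc and fore[nr2, nc2] and not seen[nr2, nc2]:
                            seen[nr2, nc2] = True
                            queue.append((nr2, nc2))
                parts.append(frozenset(comp))
    return parts


def brute_enn(parts: list[frozenset[tuple[int, int]]], cell_size_m: float) -> list[float | None]:
    """All-pairs minimum center-to-center distance to any other component."""
    if len(parts) <= 1:
        return [None] * len(parts)
    coords = [np.array(sorted(p), dtype=float) for p in parts]
    out = []
    for i, ci in enumerate(coords):
        best = math.inf
        for j, cj in enumerate(coords):
            if i == j:
                continue
            diff = ci[:, None, :] - cj[None, :, :]
            best = min(best, float(np.sqrt((diff**2).sum(axis=2)).min()))
        out.append(best * cell_size_m)
    return out


def naive_metrics(
    parts: list[frozenset[tuple[int, int]]],
    enns: list[float | None],
    landscape_cells: int,
    cell_size_m: float,
) -> dict[str, float]:
    """Direct Table-style formula evaluation from component cell sets."""
    cell_area = cell_size_m**2
    area_m2 = landscape_cells * cell_area
    areas = [len(p) * cell_area for p in parts]
    n = len(areas)
    out: dict[str, float] = {"np": n, "landscape_area_ha": area_m2 / 1e4}
    if n == 0:
        out.update(pa_mn_ha=math.nan, pd_per100ha=0.0, lpi_pct=0.0, enn_mn_m=math.nan,
                   mesh_ha=0.0, total_class_area_ha=0.0)
        return out
    defined = [e for e in enns if e is not None]
    out["pa_mn_ha"] = (sum(areas) / n) / 1e4
    out["pd_per100ha"] = n / area_m2 * 1e4 * 100
    out["lpi_pct"] = max(areas) / area_m2 * 100
    out["enn_mn_m"] = sum(defined) / len(defined) if defined else math.nan
    out["mesh_ha"] = sum(a * a for a in areas) / area_m2 / 1e4
    out["total_class_area_ha"] = sum(areas) / 1e4
    return out


def naive_fad(codes: np.ndarray, nodata: int, window: int) -> np.ndarray:
    """Per-pixel double-loop FAD percent; NaN off foreground."""
    nr, nc = codes.shape
    h = window // 2
    out = np.full((nr, nc), np.nan)
    for r in range(nr):
        for c in range(nc):
            if codes[r, c] != 1:
                continue
            r0, r1 = max(0, r - h), min(nr, r + h + 1)
            c0, c1 = max(0, c - h), min(nc, c + h + 1)
            fore = valid = 0
            for rr in range(r0, r1):
                for cc in range(c0, c1):
                    if codes[rr, cc] != nodata:
                        valid += 1
                        if codes[rr, cc] == 1:
                            fore += 1
            out[r, c] = 100.0 * fore / valid
    return out


def exact_two_sided_p_all_same_sign(n: int) -> float:
    """Closed form for untied all-same-sign differences: 2 / 2^n."""
    return 2.0 / 2.0**n
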