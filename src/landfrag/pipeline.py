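"""Config-driven orchestration: reclassify → clip → metrics → FAD → change → compare.

One run covers every configured source × zone independently: the same
protocol is applied to each combination, and results for one combination
never depend on the presence of others. Zone clipping happens before
patch labeling and FAD, so patches never extend across the zone
boundary. Outputs are deterministic: stable orderings, pinned CSV
dialect (UTF-8, comma, '.' decimal, header row), rounding only at the
report layer.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .class_metrics import metrics_table
from .fad_fragmentation import (
    FADConfig,
    SIX_CLASS_SCHEME,
    change_profile,
    multiscale_fad,
    natural_loss_area,
    transition_matrix,
)
from .raster_io import CategoricalRaster, read_ascii_grid, read_categorical_raster, write_categorical_raster
from .reclassification import ZoneMask, clip_to_zone, load_reclass_scheme, natural_binary, reclassify
from .source_comparison import compare_all, results_to_dataframe
from .synthetic_landscapes import SyntheticScenario, generate_paired_dataset

__all__ = ["SourceConfig", "RunConfig", "load_config", "run_pipeline", "simulate_to_dir"]

logger = logging.getLogger(__name__)

COMPARED_METRICS = ["pa_mn_ha", "np", "pd_per100ha", "lpi_pct", "enn_mn_m", "mesh_ha"]


@dataclass
class SourceConfig:
    name: str
    scheme_path: Path
    rasters: dict[int, Path]  # year -> raster path


@dataclass
class RunConfig:
    sources: list[SourceConfig]
    zones: dict[str, Path | None]  # zone name -> mask path (None = full extent)
    output_dir: Path
    fad_scales: tuple[int, ...] = (7, 13, 27, 81, 243)
    alpha: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("config needs at least one source")
        if not self.zones:
            raise ValueError("config needs at least one zone")
        for src in self.sources:
            if not src.rasters:
                raise ValueError(f"source {src.name!r} lists no rasters")


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration (see README for the schema)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _resolve(p: str | None) -> Path | None:
        if p is None:
            return None
        q = Path(p)
        return q if q.is_absolute() else base / q

    sources = [
        SourceConfig(
            name=str(name),
            scheme_path=_resolve(spec["scheme"]),
            rasters={int(y): _resolve(p) for y, p in spec["years"].items()},
        )
        for name, spec in raw["sources"].items()
    ]
    zones = {str(z): _resolve(p) for z, p in raw["zones"].items()}
    fad = raw.get("fad", {}) or {}
    comparison = raw.get("comparison", {}) or {}
    return RunConfig(
        sources=sources,
        zones=zones,
        output_dir=_resolve(raw.get("output_dir", "out")),
        fad_scales=tuple(fad.get("scales", (7, 13, 27, 81, 243))),
        alpha=float(comparison.get("alpha", 0.05)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _read_raster(path: Path) -> CategoricalRaster:
    if path.suffix.lower() in {".asc", ".txt"}:
        return read_ascii_grid(path)
    return read_categorical_raster(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full study design; returns (and writes) the manifest.

    Per source × zone: a metrics row for every year; multiscale
    fragmentation class rasters for the first and last year; the
    class-transition matrix, natural-cover loss, and change profile
    between them. Per zone: the paired source comparison across the
    first two sources.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(config.log_level, out / "run.log")
    t_start = time.time()
    manifest: dict = {
        "landfrag_version": __version__,
        "inputs": {},
        "artifacts": [],
        "stages": {},
    }

    def _register(path: Path) -> None:
        manifest["artifacts"].append(str(path.relative_to(out)))

    fad_config = FADConfig(scales=config.fad_scales, scheme=SIX_CLASS_SCHEME)

    # stage: load + reclassify
    t0 = time.time()
    schemes = {src.name: load_reclass_scheme(src.scheme_path) for src in config.sources}
    reclassified: dict[str, dict[int, CategoricalRaster]] = {}
    for src in config.sources:
        manifest["inputs"][src.name] = {
            "scheme": _sha256(src.scheme_path),
            "rasters": {int(y): _sha256(p) for y, p in sorted(src.rasters.items())},
        }
        reclassified[src.name] = {
            year: reclassify(_read_raster(p), schemes[src.name])
            for year, p in sorted(src.rasters.items())
        }
    manifest["stages"]["reclassify_s"] = round(time.time() - t0, 3)

    masks: dict[str, ZoneMask | None] = {}
    for zone, mask_path in config.zones.items():
        if mask_path is None:
            masks[zone] = None
        else:
            masks[zone] = ZoneMask(raster=_read_raster(mask_path), zone_name=zone)
            manifest["inputs"].setdefault("zones", {})[zone] = _sha256(mask_path)

    # stage: per-source×zone binaries and metrics
    t0 = time.time()
    series = []
    binaries: dict[tuple[str, str], dict[int, CategoricalRaster]] = {}
    for src in config.sources:
        for zone, mask in masks.items():
            per_year = {}
            for year, raster in reclassified[src.name].items():
                clipped = raster if mask is None else clip_to_zone(raster, mask)
                binary = natural_binary(clipped)
                per_year[year] = binary
                series.append((src.name, zone, year, binary))
            binaries[(src.name, zone)] = per_year
    metrics = metrics_table(series)
    metrics_path = out / "metrics.csv"
    metrics.round(6).to_csv(metrics_path, index=False)
    _register(metrics_path)
    manifest["stages"]["metrics_s"] = round(time.time() - t0, 3)

    # stage: FAD, transitions, change profile on (first, last) year
    t0 = time.time()
    for (src_name, zone), per_year in sorted(binaries.items()):
        years = sorted(per_year)
        y1, y2 = years[0], years[-1]
        tag = f"{zone}_{src_name}"
        ms1 = multiscale_fad(per_year[y1], fad_config)
        ms2 = multiscale_fad(per_year[y2], fad_config)
        for year, (per_scale, _avg_fad, avg_class) in ((y1, ms1), (y2, ms2)):
            for frag in (*per_scale, avg_class):
                path = out / f"fragclass_{tag}_{year}_{frag.provenance}.tif"
                write_categorical_raster(frag.to_raster(), path, format="geotiff")
                _register(path)
        trans = transition_matrix(ms1[2], ms2[2])
        trans_path = out / f"transitions_{tag}.csv"
        trans.to_dataframe("counts").to_csv(trans_path)
        _register(trans_path)
        profile = change_profile(ms1[0], ms2[0], dates=(str(y1), str(y2)))
        profile_path = out / f"change_profile_{tag}.csv"
        profile.round(6).to_csv(profile_path, index=False)
        _register(profile_path)
        loss_ha = natural_loss_area(per_year[y1], per_year[y2])
        manifest.setdefault("natural_loss_ha", {})[tag] = round(loss_ha, 4)
        logger.info("%s: natural-cover loss %s→%s = %.2f ha", tag, y1, y2, loss_ha)
    manifest["stages"]["fad_change_s"] = round(time.time() - t0, 3)

    # stage: paired source comparison per zone (first two sources)
    t0 = time.time()
    if len(config.sources) >= 2:
        s1, s2 = config.sources[0].name, config.sources[1].name
        t1 = metrics[metrics["source"] == s1]
        t2 = metrics[metrics["source"] == s2]
        results = compare_all(
            t1, t2, COMPARED_METRICS, sorted(config.zones), alpha=config.alpha
        )
        comparison_path = out / "comparison.csv"
        results_to_dataframe(results).to_csv(comparison_path, index=False)
        _register(comparison_path)
    else:
        logger.info("single source configured; skipping paired comparison")
    manifest["stages"]["comparison_s"] = round(time.time() - t0, 3)

    manifest["runtime_s"] = round(time.time() - t_start, 3)
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    logger.info("pipeline finished in %.1f s; manifest at %s", manifest["runtime_s"], manifest_path)
    return manifest


def _setup_logging(level: str, log_path: Path) -> None:
    root = logging.getLogger("landfrag")
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    # replace handlers from previous runs (idempotent under re-invocation)
    for handler in list(root.handlers):
        if getattr(handler, "_landfrag_run", False):
            root.removeHandler(handler)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    for handler in (logging.StreamHandler(), logging.FileHandler(log_path, mode="w")):
        handler.setFormatter(fmt)
        handler._landfrag_run = True  # type: ignore[attr-defined]
        root.addHandler(handler)


def simulate_to_dir(
    scenario: SyntheticScenario, out_dir: str | Path, format: str = "geotiff"
) -> Path:
    """Write a paired synthetic dataset plus manifest, scheme, and run config.

    The emitted ``config.yaml`` points at the written rasters with an
    identity reclassification scheme, so ``run --config`` works on the
    directory as-is.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, manifest = generate_paired_dataset(scenario)
    ext = "tif" if format == "geotiff" else "asc"
    scheme_path = out / "scheme_identity.csv"
    scheme_path.write_text("source_code,target_code\n1,1\n2,2\n3,3\n")
    config: dict = {
        "sources": {},
        "zones": {"full": None},
        "fad": {"scales": [7, 13, 27, 81, 243]},
        "comparison": {"alpha": 0.05},
        "output_dir": "results",
    }
    for source, per_year in sorted(dataset.items()):
        config["sources"][source] = {"scheme": scheme_path.name, "years": {}}
        for year, raster in sorted(per_year.items()):
            path = out / f"lulc_{source}_{year}.{ext}"
            write_categorical_raster(raster, path, format=format)
            config["sources"][source]["years"][year] = path.name
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    return out
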