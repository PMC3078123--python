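"""End-to-end orchestration: simulate/ingest → upscale → model → evaluate
→ validate, with one global seed, structured logging and a run manifest.

A single :class:`RunConfig` drives the whole analysis.  The global seed
deterministically derives one sub-seed per stage, so rerunning with the
same configuration reproduces byte-identical CSV/JSON outputs and
value-identical rasters.  Defaults reproduce the reference study's stated
settings: 70/30 train/test partition, 10th-percentile presence threshold,
0.7 covariation flag, convergence 1e-5, 500 iterations, regularisation
multiplier 1.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluate import covariation_screen, evaluate_species, niche_summary
from .grid import Bathymetry, LayerStack
from .io import read_raster, read_zbinned, save_stack, write_raster, write_zbinned
from .maxent import MaxentConfig, binary_map, fit, predict_logistic, sample_background
from .presences import dedup_and_filter, export_swd, load_presences
from .synthetic import (
    SyntheticWorldConfig,
    make_presences,
    make_stations,
    make_world,
)
from .upscale import IDWConfig, drape_zbins, upscale_surface
from .validation import (
    binned_profile,
    error_grid,
    filter_stations,
    intersect_layer,
    stations_from_frame,
)

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    With no input paths the pipeline simulates its own world (synthetic
    mode); otherwise it ingests the given bathymetry raster, z-binned
    NetCDF files, presence CSV and station CSV.
    """

    out_dir: str = "run"
    seed: int = 0
    # inputs (all None -> synthetic mode)
    bathymetry_path: str | None = None
    zbinned_paths: dict[str, str] = field(default_factory=dict)  # variable -> NetCDF
    surface_paths: dict[str, str] = field(default_factory=dict)  # variable -> raster
    presences_path: str | None = None
    stations_path: str | None = None
    station_variable: str = "temperature"
    # synthetic mode
    n_presences: int = 300
    n_stations: int = 400
    station_noise_sd: float = 0.0
    world: dict = field(default_factory=dict)  # SyntheticWorldConfig overrides
    # processing
    idw_power: float = 2.0
    idw_max_neighbors: int = 12
    idw_intermediate_cell_size_deg: float | None = None  # None: synthetic default
    # model
    convergence_threshold: float = 1e-5
    max_iterations: int = 500
    regularization_multiplier: float = 1.0
    n_background: int = 10_000
    # evaluation
    fraction_train: float = 0.7
    threshold_percentile: float = 10.0
    n_replicates: int = 10
    with_jackknife: bool = True
    raster_format: str = "ascii_grid"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def maxent_config(self, seed: int) -> MaxentConfig:
        return MaxentConfig(
            convergence_threshold=self.convergence_threshold,
            max_iterations=self.max_iterations,
            regularization_multiplier=self.regularization_multiplier,
            n_background=self.n_background,
            seed=seed,
        )


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s) % (2 ** 31) for s in np.random.SeedSequence(int(seed)).generate_state(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT, lineterminator="\n")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "outputs": {},
    }
    ext = ".asc" if config.raster_format == "ascii_grid" else ".tif"

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self_inner.t0, 3)
                }
                log.info("stage %s: done", name)

        return _Ctx()

    synthetic_mode = config.bathymetry_path is None
    truth = None

    with stage("ingest" if not synthetic_mode else "simulate"):
        if synthetic_mode:
            world_cfg = SyntheticWorldConfig(**{"seed": seeds[0], **config.world})
            idw = None
            if config.idw_intermediate_cell_size_deg is not None:
                idw = IDWConfig(
                    config.idw_power,
                    config.idw_max_neighbors,
                    config.idw_intermediate_cell_size_deg,
                )
            world = make_world(world_cfg, idw=idw)
            bathy, stack, truth = world.bathy, world.stack, world.truth
            fixture = out / "fixture"
            fixture.mkdir(exist_ok=True)
            write_raster(bathy.grid, fixture / f"bathymetry{ext}", config.raster_format)
            for name, f in world.fields.items():
                write_zbinned(f, fixture / f"{name}.nc")
            pset = make_presences(stack, truth, config.n_presences, seed=seeds[1])
            pd.DataFrame(
                {
                    "species": [r.species for r in pset.records],
                    "lon": pset.lons,
                    "lat": pset.lats,
                }
            ).pipe(_write_csv, fixture / "presences.csv")
            station_field = world.fields[config.station_variable]
            stations = make_stations(
                station_field, bathy, config.n_stations,
                noise_sd=config.station_noise_sd, seed=seeds[2],
            )
            pd.DataFrame(
                [(s.lon, s.lat, s.depth, s.value) for s in stations],
                columns=["lon", "lat", "depth", "value"],
            ).pipe(_write_csv, fixture / "stations.csv")
            (fixture / "truth.json").write_text(
                json.dumps(
                    {
                        "responses": truth.responses,
                        "prevalence": truth.prevalence,
                        "seed": config.seed,
                        "stage_seeds": seeds,
                    },
                    indent=1,
                )
            )
            records = pset.records
        else:
            bathy = Bathymetry(read_raster(config.bathymetry_path))
            idw = IDWConfig(
                config.idw_power,
                config.idw_max_neighbors,
                config.idw_intermediate_cell_size_deg or 0.1,
            )
            stack = LayerStack()
            stack.add("depth", bathy.grid)
            for name, path in config.zbinned_paths.items():
                stack.add(name, drape_zbins(read_zbinned(path, name), bathy, idw))
            for name, path in config.surface_paths.items():
                stack.add(name, upscale_surface(read_raster(path), bathy, idw))
            if config.presences_path is None:
                raise FileNotFoundError("presences_path required outside synthetic mode")
            records = load_presences(config.presences_path)
            stations = None
            if config.stations_path is not None:
                stations = stations_from_frame(pd.read_csv(config.stations_path))

    with stage("upscale"):
        layers_dir = out / "layers"
        save_stack(stack, layers_dir, config.raster_format)

    with stage("presences"):
        pset = dedup_and_filter(records, stack)
        export_swd(pset, stack, out / "swd.csv")

    with stage("screen"):
        corr, flags = covariation_screen(stack, seed=seeds[3])
        corr.round(10).to_csv(out / "correlation_matrix.csv", lineterminator="\n")
        summary = niche_summary(pset, stack)
        _write_csv(summary, out / "niche_summary.csv")
        manifest["correlation_flags"] = [list(f) for f in flags]

    with stage("fit"):
        mx = config.maxent_config(seeds[4])
        background = sample_background(stack, mx)
        rows, cols = pset.cell_indices(stack.reference)
        X = stack.covariates_at_cells(rows, cols)
        model = fit(X, background, mx, stack.names)
        (out / "model.json").write_text(model.to_json())
        hsi = predict_logistic(model, stack)
        write_raster(hsi, out / f"hsi{ext}", config.raster_format)

    with stage("evaluate"):
        report = evaluate_species(
            pset,
            stack,
            maxent_config=mx,
            fraction_train=config.fraction_train,
            percentile=config.threshold_percentile,
            n_replicates=config.n_replicates,
            seed=seeds[5],
            with_jackknife=config.with_jackknife,
        )
        stats_df, jk_df = report.to_frames()
        _write_csv(stats_df, out / "evaluation_stats.csv")
        _write_csv(jk_df, out / "jackknife.csv")
        bmap = binary_map(hsi, report.threshold_10pct)
        write_raster(bmap, out / f"binary_presence{ext}", config.raster_format)

    with stage("validate"):
        if stations:
            retained = filter_stations(stations)
            layer = stack.layers.get(config.station_variable)
            if layer is None:
                raise KeyError(f"station variable {config.station_variable!r} not in stack")
            result = intersect_layer(retained, layer)
            (out / "validation.json").write_text(
                json.dumps(
                    {
                        "variable": config.station_variable,
                        "n": result.n,
                        "n_dropped": result.n_dropped,
                        "pearson_r": result.pearson_r,
                        "r_squared": result.r_squared,
                        "p_value": result.p_value,
                    },
                    indent=1,
                )
            )
            for axis, width in (("depth", 50.0), ("latitude", 5.0), ("longitude", 10.0)):
                _write_csv(
                    binned_profile(result.pairs, axis, width),
                    out / f"profile_{axis}.csv",
                )
            write_raster(error_grid(result.pairs), out / f"error_grid{ext}", config.raster_format)

    with stage("manifest"):
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
        manifest["report"] = {
            "species": report.species,
            "n_presences": len(pset),
            "test_auc": report.test_auc,
            "test_auc_sd": report.test_auc_sd,
            "test_gain": report.test_gain,
            "threshold_10pct": report.threshold_10pct,
            "omission_rate": report.omission_rate,
            "wilcoxon_p": report.wilcoxon_p,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
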