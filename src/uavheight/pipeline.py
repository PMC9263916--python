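"""Experiment orchestration: simulate -> extract -> calibrate -> report.

An :class:`ExperimentConfig` describes a complete synthetic campaign: the
field layout, terrain and per-stage canopy specs, the acquisition grid
(camera angles x RTK x GCP), the ground-altitude methods to compare, and the
number of flight repetitions. :func:`run_experiment` renders every flight,
extracts plot-level SfM heights, joins them with the true measured heights,
runs the cross-flight validation for every condition and writes ranked
comparison tables plus a run manifest.

:func:`replicate_field_study` runs the full two-field protocol: polynomial
degree selection on a calibration field (nadir camera, one acquisition
condition), then the multi-condition comparison on the validation field with
the selected degree.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import RankDeficiencyError
from .calibrate import CVReport, condition_table, enumerate_cv_sets, pearson_r, run_condition
from .field import FieldLayout, make_field_layout
from .methods import chm_roi_height, method_m1, method_m2, method_m3
from .raster import RasterGrid, write_tiff
from .roi import ROI, build_inner_rois, build_outer_rois, write_geojson
from .simulate import (
    CanopySpec,
    FlightScenario,
    NoiseSpec,
    TerrainSpec,
    TrueHeights,
    generate_true_heights,
    render_dsm,
)
from .surface import PolySurface, surface_to_raster

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "StageResult",
    "ReplicationResult",
    "default_terrain",
    "field1_config",
    "field2_config",
    "run_experiment",
    "select_degree_for_field",
    "replicate_field_study",
]

log = logging.getLogger("uavheight")

METHODS = ("M1", "M2", "M3")
STAGES = ("vegetative", "reproductive")


@dataclass(frozen=True)
class ExperimentConfig:
    layout: FieldLayout
    terrain: TerrainSpec
    canopies: dict  # stage name -> CanopySpec
    noise: NoiseSpec = dc_field(default_factory=NoiseSpec)
    camera_angles: tuple[int, ...] = (-60, -90)
    rtk_options: tuple[bool, ...] = (False, True)
    gcp_options: tuple[bool, ...] = (False, True)
    methods: tuple[str, ...] = METHODS
    n_repetitions: int = 3
    dtm_degree: int = 3
    degree_candidates: tuple[int, ...] = (0, 1, 2, 3, 4)
    pixel_size: float = 0.05
    edge_unit: float = 1.0
    ring_depth: float = 0.5
    seed: int = 1

    def conditions(self) -> list[tuple[int, bool, bool, str]]:
        return [
            (angle, rtk, gcp, method)
            for angle, rtk, gcp, method in itertools.product(
                self.camera_angles, self.rtk_options, self.gcp_options, self.methods
            )
        ]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    started: float
    finished: float
    products: dict  # logical name -> path (str)

    def check_complete(self) -> None:
        missing = [p for p in self.products.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest products missing on disk: {missing}")


@dataclass
class StageResult:
    samples: dict  # condition -> DataFrame
    reports: dict  # condition -> CVReport
    table: pd.DataFrame


@dataclass
class ReplicationResult:
    degree_by_stage: dict
    r_by_degree: dict  # stage -> {degree: mean r}
    stages: dict  # stage -> StageResult
    manifest: Optional[RunManifest] = None


# ---------------------------------------------------------------------------
# presets


def default_terrain(seed: int = 0) -> TerrainSpec:
    """A gently tilted field with mild curvature and genuine cubic relief
    (the kind of terrain a plane or paraboloid cannot fully absorb), about
    100 m above datum. Coefficients act on coordinates conditioned to the
    region half-width, so values are in meters of relief over the region."""
    ground = PolySurface(
        degree=3,
        # (k,i) lex order: 1, x, y, x^2, xy, y^2, x^3, x^2 y, x y^2, y^3
        coefficients=[100.0, 0.35, -0.55, 0.12, -0.08, 0.10, 0.09, -0.06, 0.05, -0.07],
        center=(17.75, 27.0),
        scale=(17.75, 27.0),
    )
    return TerrainSpec(true_dtm=ground, seed=seed)


def field2_config(seed: int = 1, **overrides) -> ExperimentConfig:
    """The 84-plot validation field with the full 2x2x2x3 condition grid."""
    defaults = dict(
        layout=make_field_layout(n_plots=84),
        terrain=default_terrain(seed=seed),
        canopies={
            "vegetative": CanopySpec.vegetative(),
            "reproductive": CanopySpec.reproductive(),
        },
        noise=NoiseSpec.for_pixel_size(overrides.get("pixel_size", 0.05)),
        seed=seed,
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


def field1_config(seed: int = 1, **overrides) -> ExperimentConfig:
    """The 42-plot calibration field: nadir camera, no RTK/GCP, used only
    for polynomial degree selection."""
    defaults = dict(
        layout=make_field_layout(n_plots=42),
        terrain=default_terrain(seed=seed + 101),
        canopies={
            "vegetative": CanopySpec.vegetative(height_mean=0.809, height_sd=0.075,
                                                height_min=0.634, height_max=0.982),
            "reproductive": CanopySpec.reproductive(height_mean=2.73, height_sd=0.126,
                                                    height_min=2.47, height_max=3.05),
        },
        camera_angles=(-90,),
        rtk_options=(False,),
        gcp_options=(False,),
        methods=("M3",),
        noise=NoiseSpec.for_pixel_size(overrides.get("pixel_size", 0.05)),
        seed=seed,
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


# ---------------------------------------------------------------------------
# extraction


def _measurement_rois(layout: FieldLayout) -> list[ROI]:
    return [r for r in build_inner_rois(layout) if r.measurement]


def _samples_from_heights(
    ph_sfm: Sequence[float], rois: Sequence[ROI], heights: TrueHeights, repetition: int
) -> pd.DataFrame:
    measured = heights.measured_table().set_index("row_id")
    row_ids = [roi.id.rsplit("B", 1)[0] for roi in rois]
    return pd.DataFrame(
        {
            "sample_id": row_ids,
            "ph_measured": measured.loc[row_ids, "ph_measured"].to_numpy(),
            "ph_sfm": np.asarray(ph_sfm, dtype=float),
            "repetition": repetition,
            "group": [roi.group for roi in rois],
        }
    )


def _extract_condition_rep(
    method: str,
    on_dsm: RasterGrid,
    off_dsm: Optional[RasterGrid],
    meas_rois: Sequence[ROI],
    outer_rois: Sequence[ROI],
    degree: int,
) -> np.ndarray:
    if method == "M1":
        chm = method_m1(on_dsm, off_dsm)
        return np.array([chm_roi_height(chm, roi) for roi in meas_rois])
    if method == "M2":
        return np.array([method_m2(on_dsm, roi) for roi in meas_rois])
    if method == "M3":
        chm = method_m3(on_dsm, outer_rois, degree)
        return np.array([chm_roi_height(chm, roi) for roi in meas_rois])
    raise ValueError(f"unknown ground-altitude method {method!r}")


def simulate_stage_samples(
    config: ExperimentConfig, stage: str, raster_sink=None
) -> dict[tuple, pd.DataFrame]:
    """Render all flights of one growth stage and extract per-row samples
    for every condition in the grid. ``raster_sink(name, raster)`` is called
    for each rendered DSM when provided (used to write products)."""
    layout = config.layout
    canopy = config.canopies[stage]
    heights = generate_true_heights(layout, canopy, seed=config.terrain.seed)
    meas_rois = _measurement_rois(layout)
    outer_rois = build_outer_rois(layout.region, config.edge_unit, config.ring_depth)

    samples: dict[tuple, list[pd.DataFrame]] = {c: [] for c in config.conditions()}
    needs_m1 = "M1" in config.methods
    for angle, rtk, gcp in itertools.product(
        config.camera_angles, config.rtk_options, config.gcp_options
    ):
        for rep in range(1, config.n_repetitions + 1):
            t0 = time.perf_counter()
            on = render_dsm(
                layout, config.terrain, canopy,
                FlightScenario(angle, rtk, gcp, "on_season", rep, config.seed),
                config.noise, config.pixel_size, heights=heights,
            )
            off = None
            if needs_m1:
                off = render_dsm(
                    layout, config.terrain, None,
                    FlightScenario(angle, rtk, gcp, "pre_germination", rep, config.seed),
                    config.noise, config.pixel_size,
                )
            if raster_sink is not None:
                tag = f"{stage}_a{abs(angle)}_rtk{int(rtk)}_gcp{int(gcp)}_rep{rep}"
                raster_sink(f"dsm_{tag}", on)
                if off is not None:
                    raster_sink(f"dsm_pregerm_a{abs(angle)}_rtk{int(rtk)}_gcp{int(gcp)}_rep{rep}", off)
            for method in config.methods:
                ph = _extract_condition_rep(
                    method, on, off, meas_rois, outer_rois, config.dtm_degree
                )
                samples[(angle, rtk, gcp, method)].append(
                    _samples_from_heights(ph, meas_rois, heights, rep)
                )
            log.debug(
                "rendered %s angle=%d rtk=%s gcp=%s rep=%d in %.2fs",
                stage, angle, rtk, gcp, rep, time.perf_counter() - t0,
            )
    return {cond: pd.concat(parts, ignore_index=True) for cond, parts in samples.items()}


def evaluate_stage(config: ExperimentConfig, samples: dict) -> StageResult:
    n_groups = len({g for df in samples.values() for g in df["group"].unique()})
    cv_sets = enumerate_cv_sets(config.n_repetitions, n_groups)
    reports = {cond: run_condition(df, cv_sets) for cond, df in samples.items()}
    return StageResult(samples=samples, reports=reports, table=condition_table(reports))


# ---------------------------------------------------------------------------
# degree selection


def select_degree_for_field(
    config: ExperimentConfig, stage: str
) -> tuple[int, dict[int, float]]:
    """Fit the ground ring at every candidate degree on each repetition's
    DSM, correlate the resulting heights with the measured heights, average
    r over repetitions, and pick the best degree (ties toward the lowest).

    Candidate degrees whose fit fails (rank deficiency) or whose mean r is
    undefined are scored -inf, mirroring "unusable", and can never win.
    """
    from .methods import select_degree

    layout = config.layout
    canopy = config.canopies[stage]
    heights = generate_true_heights(layout, canopy, seed=config.terrain.seed)
    measured = heights.measured_table().set_index("row_id")
    meas_rois = _measurement_rois(layout)
    outer_rois = build_outer_rois(layout.region, config.edge_unit, config.ring_depth)
    angle, rtk, gcp = config.camera_angles[0], config.rtk_options[0], config.gcp_options[0]

    r_by_degree: dict[int, list[float]] = {d: [] for d in config.degree_candidates}
    for rep in range(1, config.n_repetitions + 1):
        dsm = render_dsm(
            layout, config.terrain, canopy,
            FlightScenario(angle, rtk, gcp, "on_season", rep, config.seed),
            config.noise, config.pixel_size, heights=heights,
        )
        for degree in config.degree_candidates:
            try:
                chm = method_m3(dsm, outer_rois, degree)
            except RankDeficiencyError:
                continue
            ph = [chm_roi_height(chm, roi) for roi in meas_rois]
            truth = measured.loc[[roi.id.rsplit("B", 1)[0] for roi in meas_rois], "ph_measured"]
            r_by_degree[degree].append(pearson_r(ph, truth))
    mean_r = {d: float(np.mean(v)) if v else -np.inf for d, v in r_by_degree.items()}
    return select_degree(mean_r), mean_r


# ---------------------------------------------------------------------------
# full runs


def _config_hash(config: ExperimentConfig) -> str:
    blob = yaml.safe_dump(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(
    config: ExperimentConfig,
    outdir: str | Path,
    stages: Sequence[str] = STAGES,
    write_rasters: bool = False,
) -> tuple[RunManifest, dict[str, StageResult]]:
    """Run the full condition grid for the given stages, writing per-stage
    sample tables, per-condition reports and ranked tables under ``outdir``.
    DSM rasters are written as TIFF only when ``write_rasters`` is set (they
    are bulky and reproducible from the config)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    products: dict[str, str] = {}

    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
    products["config"] = str(cfg_path)

    rois_path = outdir / "rois.geojson"
    write_geojson(
        build_inner_rois(config.layout)
        + build_outer_rois(config.layout.region, config.edge_unit, config.ring_depth),
        rois_path,
    )
    products["rois"] = str(rois_path)

    results: dict[str, StageResult] = {}
    for stage in stages:
        log.info("running stage %s (%d conditions, %d reps)",
                 stage, len(config.conditions()), config.n_repetitions)
        sink = None
        if write_rasters:
            raster_dir = outdir / "rasters"
            raster_dir.mkdir(exist_ok=True)

            def sink(name: str, raster: RasterGrid, _dir=raster_dir) -> None:
                path = _dir / f"{name}.tif"
                write_tiff(raster, path)
                products[name] = str(path)

        samples = simulate_stage_samples(config, stage, raster_sink=sink)
        result = evaluate_stage(config, samples)
        results[stage] = result

        long_path = outdir / f"samples_{stage}.csv"
        pd.concat(
            [
                df.assign(camera_angle=c[0], rtk=c[1], gcp=c[2], method=c[3])
                for c, df in samples.items()
            ],
            ignore_index=True,
        ).to_csv(long_path, index=False)
        products[f"samples_{stage}"] = str(long_path)

        table_path = outdir / f"conditions_{stage}.csv"
        result.table.to_csv(table_path, index=False)
        products[f"conditions_{stage}"] = str(table_path)

    manifest = RunManifest(
        config_hash=_config_hash(config),
        version=__version__,
        started=started,
        finished=time.time(),
        products=products,
    )
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    manifest.check_complete()
    return manifest, results


def replicate_field_study(
    outdir: Optional[str | Path] = None,
    seed: int = 1,
    n_plots_field1: int = 42,
    n_plots_field2: int = 84,
    n_repetitions: int = 3,
    pixel_size: float = 0.05,
    stages: Sequence[str] = STAGES,
) -> ReplicationResult:
    """The two-field protocol: degree selection on the calibration field,
    then the full condition comparison on the validation field using the
    selected degree (selection runs on the vegetative stage; both stages'
    selections are reported)."""
    f1 = field1_config(
        seed=seed,
        layout=make_field_layout(n_plots=n_plots_field1),
        n_repetitions=n_repetitions,
        pixel_size=pixel_size,
    )
    degree_by_stage, r_by_degree = {}, {}
    for stage in stages:
        degree_by_stage[stage], r_by_degree[stage] = select_degree_for_field(f1, stage)
    chosen = degree_by_stage[stages[0]]
    log.info("selected polynomial degree %d (per stage: %s)", chosen, degree_by_stage)

    f2 = field2_config(
        seed=seed,
        layout=make_field_layout(n_plots=n_plots_field2),
        n_repetitions=n_repetitions,
        pixel_size=pixel_size,
        dtm_degree=chosen,
    )
    manifest = None
    if outdir is not None:
        manifest, stage_results = run_experiment(f2, outdir, stages=stages)
        degree_path = Path(outdir) / "degree_selection.csv"
        pd.DataFrame(
            [
                {"stage": s, "degree": d, "mean_r": r}
                for s, by_deg in r_by_degree.items()
                for d, r in by_deg.items()
            ]
        ).to_csv(degree_path, index=False)
    else:
        stage_results = {
            stage: evaluate_stage(f2, simulate_stage_samples(f2, stage)) for stage in stages
        }
    return ReplicationResult(
        degree_by_stage=degree_by_stage,
        r_by_degree=r_by_degree,
        stages=stage_results,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# config (de)serialization


def _surface_to_dict(s: PolySurface) -> dict:
    return {
        "degree": s.degree,
        "coefficients": [float(c) for c in s.coefficients],
        "center": list(s.center),
        "scale": list(s.scale),
    }


def config_to_dict(config: ExperimentConfig) -> dict:
    d = {
        "layout": asdict(config.layout),
        "terrain": {**asdict(config.terrain), "true_dtm": _surface_to_dict(config.terrain.true_dtm)},
        "canopies": {k: asdict(v) for k, v in config.canopies.items()},
        "noise": asdict(config.noise),
        "camera_angles": list(config.camera_angles),
        "rtk_options": list(config.rtk_options),
        "gcp_options": list(config.gcp_options),
        "methods": list(config.methods),
        "n_repetitions": config.n_repetitions,
        "dtm_degree": config.dtm_degree,
        "degree_candidates": list(config.degree_candidates),
        "pixel_size": config.pixel_size,
        "edge_unit": config.edge_unit,
        "ring_depth": config.ring_depth,
        "seed": config.seed,
    }
    d["layout"]["measured_row_indices"] = list(config.layout.measured_row_indices)
    return d


def config_from_dict(d: dict) -> ExperimentConfig:
    layout_kw = dict(d["layout"])
    layout_kw["measured_row_indices"] = tuple(layout_kw["measured_row_indices"])
    terrain_kw = dict(d["terrain"])
    sd = terrain_kw.pop("true_dtm")
    surface = PolySurface(
        degree=sd["degree"],
        coefficients=sd["coefficients"],
        center=tuple(sd["center"]),
        scale=tuple(sd["scale"]),
    )
    return ExperimentConfig(
        layout=make_field_layout(**layout_kw),
        terrain=TerrainSpec(true_dtm=surface, **terrain_kw),
        canopies={k: CanopySpec(**v) for k, v in d["canopies"].items()},
        noise=NoiseSpec(**d["noise"]),
        camera_angles=tuple(d["camera_angles"]),
        rtk_options=tuple(bool(v) for v in d["rtk_options"]),
        gcp_options=tuple(bool(v) for v in d["gcp_options"]),
        methods=tuple(d["methods"]),
        n_repetitions=int(d["n_repetitions"]),
        dtm_degree=int(d["dtm_degree"]),
        degree_candidates=tuple(d["degree_candidates"]),
        pixel_size=float(d["pixel_size"]),
        edge_unit=float(d["edge_unit"]),
        ring_depth=float(d["ring_depth"]),
        seed=int(d["seed"]),
    )


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
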