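"""End-to-end stage orchestration for the synthetic biomass experiment.

Stages mirror the survey workflow: simulate a scene, ground-filter and
normalize the cloud, segment trees, fit the height–DBH models, build the
grid sample set, assemble the predictor stack, train the boosted-tree
model, predict the AGB raster, and evaluate everything against the scene's
known truth.  Each stage reads only files written by earlier stages, writes
its artifacts plus a JSON manifest (inputs, parameters, seeds, counts,
metrics) under the working directory, and is idempotent for fixed inputs
and seeds.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomass_samples, height_dbh, point_cloud, tree_segmentation
from .agb_estimator import (GBDTConfig, make_training_table, predict_raster,
                            tune_and_train)
from .raster import read_ascii, write_ascii
from .spectral_features import FEATURE_NAMES, FeatureStack, assemble_stack
from .synthetic_scene import SceneConfig, generate_scene, write_scene
from .vector import read_stands

__all__ = ["STAGES", "RunConfig", "run_stage", "run_all"]

STAGES = ("simulate", "ground", "segment", "fit-hd", "samples",
          "features", "train", "predict", "evaluate")

#: Artifact each stage must find, and the stage that writes it.
_UPSTREAM = {
    "ground": [("scene/cloud.csv", "simulate")],
    "segment": [("cloud_norm.csv", "ground")],
    "fit-hd": [],
    "samples": [("trees_segmented.csv", "segment"),
                ("scene/stands.geojson", "simulate"),
                ("growth_registry.json", "fit-hd")],
    "features": [("scene/dem.asc", "simulate")],
    "train": [("samples.csv", "samples"), ("features/B2.asc", "features")],
    "predict": [("model.pkl", "train")],
    "evaluate": [("samples.csv", "samples"), ("agb_pred.asc", "predict"),
                 ("scene/agb_truth.asc", "simulate")],
}


@dataclass
class RunConfig:
    """All knobs for one pipeline run."""

    workdir: str = "run"
    scene: SceneConfig = field(default_factory=SceneConfig)
    gbdt: GBDTConfig = field(default_factory=GBDTConfig)
    spacing_threshold_m: float | None = None  # default: mean crown diameter
    min_height_m: float = 2.0
    ground_grid_m: float = 5.0
    z_tol_m: float = 0.3
    ground_max_iter: int = 10
    field_n_pairs: int = 200
    field_noise_sd_m: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.scene, dict):
            scene = dict(self.scene)
            if "extent" in scene:
                scene["extent"] = tuple(scene["extent"])
            if "seed" not in scene:
                scene["seed"] = self.seed
            self.scene = SceneConfig(**scene)
        if isinstance(self.gbdt, dict):
            gbdt = dict(self.gbdt)
            if "split_seed" not in gbdt:
                gbdt["split_seed"] = self.seed
            self.gbdt = GBDTConfig(**gbdt)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def spacing_m(self) -> float:
        """Segmentation spacing threshold: the field mean crown diameter."""
        if self.spacing_threshold_m is not None:
            return self.spacing_threshold_m
        return self.scene.mean_crown_diameter_m


def _require(cfg: RunConfig, stage: str):
    wd = Path(cfg.workdir)
    for artifact, producer in _UPSTREAM.get(stage, []):
        if not (wd / artifact).exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs {artifact}; run stage {producer!r} first"
            )
    return wd


def _manifest(cfg: RunConfig, stage: str, **payload):
    wd = Path(cfg.workdir)
    doc = {"stage": stage, "seed": cfg.seed, **payload}
    (wd / f"manifest_{stage.replace('-', '_')}.json").write_text(
        json.dumps(doc, indent=2, sort_keys=True, default=float))
    return doc


def run_stage(stage: str, cfg: RunConfig) -> dict:
    """Run one named stage; returns its manifest dictionary."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; stages: {', '.join(STAGES)}")
    wd = _require(cfg, stage)
    wd.mkdir(parents=True, exist_ok=True)
    return _DISPATCH[stage](cfg, wd)


def run_all(cfg: RunConfig) -> list[dict]:
    return [run_stage(stage, cfg) for stage in STAGES]


# --------------------------------------------------------------- stages

def _stage_simulate(cfg: RunConfig, wd: Path):
    scene = generate_scene(cfg.scene)
    write_scene(scene, wd / "scene")
    return _manifest(
        cfg, "simulate", scene_seed=cfg.scene.seed,
        n_trees=len(scene.truth.trees), n_points=len(scene.cloud),
        n_stands=len(scene.truth.stand_polygons),
        extent=list(cfg.scene.extent),
        point_density_pts_m2=cfg.scene.point_density_pts_m2)


def _stage_ground(cfg: RunConfig, wd: Path):
    cloud = point_cloud.read_cloud(wd / "scene/cloud.csv")
    truth_cls = cloud.cls.copy()
    cloud = point_cloud.denoise(cloud)
    n_noise = int(cloud.mask("noise").sum())
    cloud = point_cloud.classify_ground(
        cloud, grid_m=cfg.ground_grid_m, z_tol_m=cfg.z_tol_m,
        max_iter=cfg.ground_max_iter)
    n_ground = int(cloud.mask("ground").sum())
    truth_ground = truth_cls == point_cloud.CLASS_CODES["ground"]
    recall = float((cloud.mask("ground") & truth_ground).sum()
                   / max(truth_ground.sum(), 1))
    norm, n_extra = point_cloud.normalize_heights(cloud)
    point_cloud.write_cloud(norm, wd / "cloud_norm.csv")
    return _manifest(cfg, "ground", n_points=len(norm), n_noise=n_noise,
                     n_ground=n_ground, ground_recall_vs_truth=recall,
                     n_extrapolated=n_extra, z_tol_m=cfg.z_tol_m)


def _stage_segment(cfg: RunConfig, wd: Path):
    cloud = point_cloud.read_cloud(wd / "cloud_norm.csv")
    segments = tree_segmentation.segment_trees(
        cloud, cfg.spacing_m, cfg.min_height_m)
    trees = tree_segmentation.extract_attributes(segments, cloud)
    trees.to_csv(wd / "trees_segmented.csv", index=False, float_format="%.8g")
    return _manifest(cfg, "segment", n_segments=len(segments),
                     spacing_threshold_m=cfg.spacing_m,
                     min_height_m=cfg.min_height_m)


def _stage_fit_hd(cfg: RunConfig, wd: Path):
    """Fit the four growth-model forms to simulated field (H, D) pairs."""
    rng = np.random.default_rng(cfg.seed + 1000)
    best, report = [], {}
    for species in cfg.scene.species_list:
        form, a, b = cfg.scene.hd_truth[species]
        d_range = tuple(sorted(height_dbh.hd_inverse(
            form, a, b, np.asarray(cfg.scene.height_range_m))))
        d, h = height_dbh.simulate_hd_pairs(
            form, a, b, cfg.field_n_pairs, d_range, cfg.field_noise_sd_m, rng)
        fits = height_dbh.fit_all_forms(d, h, species)
        sel = height_dbh.select_best(fits)
        best.append(sel)
        report[species] = {
            "selected_form": sel.form, "a": sel.a, "b": sel.b,
            "r2": sel.metrics.r2, "aic": sel.metrics.aic,
            "candidates": {f.form: f.metrics.aic for f in fits},
        }
    height_dbh.save_registry(best, wd / "growth_registry.json")
    return _manifest(cfg, "fit-hd", n_pairs=cfg.field_n_pairs,
                     noise_sd_m=cfg.field_noise_sd_m, models=report)


def _stage_samples(cfg: RunConfig, wd: Path):
    trees = pd.read_csv(wd / "trees_segmented.csv")
    stands = read_stands(wd / "scene/stands.geojson")
    registry = height_dbh.load_registry(wd / "growth_registry.json")
    trees, n_outside = tree_segmentation.assign_species(trees, stands)

    dbh = np.full(len(trees), np.nan)
    n_flagged = 0
    for species, fit in registry.items():
        m = (trees["species"] == species).to_numpy()
        if m.any():
            d, nf = height_dbh.predict_dbh(fit, trees.loc[m, "height_m"])
            dbh[m] = d
            n_flagged += nf
    trees["dbh_cm"] = dbh
    agb = np.full(len(trees), np.nan)
    ok = ~np.isnan(dbh)
    for species in trees["species"].unique():
        m = ((trees["species"] == species) & ok).to_numpy()
        if m.any():
            agb[m] = biomass_samples.tree_agb(
                species, trees.loc[m, "dbh_cm"], trees.loc[m, "height_m"])
    trees["agb_kg"] = agb
    trees.to_csv(wd / "trees_attributed.csv", index=False, float_format="%.8g")

    grid = read_ascii(wd / "scene/agb_truth.asc").grid
    result = biomass_samples.build_samples(trees, grid, stands)
    biomass_samples.samples_to_frame(result.samples).to_csv(
        wd / "samples.csv", index=False, float_format="%.8g")
    biomass_samples.samples_to_frame(result.edge_cells).to_csv(
        wd / "samples_edge.csv", index=False, float_format="%.8g")
    return _manifest(cfg, "samples", n_samples=len(result.samples),
                     n_edge=result.n_edge, n_trees_outside_stands=n_outside,
                     n_inversion_flagged=n_flagged,
                     n_trees_excluded=result.n_trees_excluded)


def _read_bands(wd: Path):
    from .spectral_features import ALL_BAND_NAMES

    return {name: read_ascii(wd / "scene/bands" / f"{name}.asc")
            for name in ALL_BAND_NAMES}


def _stage_features(cfg: RunConfig, wd: Path):
    bands = _read_bands(wd)
    dem = read_ascii(wd / "scene/dem.asc")
    target = read_ascii(wd / "scene/agb_truth.asc").grid
    stack = assemble_stack(bands, dem, target=target)
    fdir = wd / "features"
    fdir.mkdir(exist_ok=True)
    for name, r in stack.layers.items():
        write_ascii(r, fdir / f"{name}.asc")
    return _manifest(cfg, "features", n_layers=len(stack.layers),
                     missing_counts=stack.missing_counts)


def _load_stack(wd: Path) -> FeatureStack:
    return FeatureStack({name: read_ascii(wd / "features" / f"{name}.asc")
                         for name in FEATURE_NAMES})


def _stage_train(cfg: RunConfig, wd: Path):
    samples = pd.read_csv(wd / "samples.csv")
    stack = _load_stack(wd)
    sample_objs = [
        biomass_samples.AGBSample(
            cell_row=int(r.cell_row), cell_col=int(r.cell_col),
            x_center=r.x_center, y_center=r.y_center, agb_g_m2=r.agb_g_m2,
            n_trees=int(r.n_trees), species=r.species,
            s_m2=stack.grid.cell**2)
        for r in samples.itertuples()
    ]
    table, n_dropped = make_training_table(sample_objs, stack)
    bundle = tune_and_train(table, cfg.gbdt)
    with (wd / "model.pkl").open("wb") as fh:
        pickle.dump(bundle, fh)
    importance = {k: v for k, v in bundle.importance}
    meta = {
        "best_ntree": bundle.best_ntree,
        "best_shrinkage": bundle.best_shrinkage,
        "train": asdict(bundle.train_metrics),
        "valid": asdict(bundle.valid_metrics),
        "importance": importance,
    }
    (wd / "bundle.json").write_text(json.dumps(meta, indent=2, default=float))
    return _manifest(cfg, "train", n_rows=len(table), n_dropped=n_dropped,
                     **meta)


def _stage_predict(cfg: RunConfig, wd: Path):
    with (wd / "model.pkl").open("rb") as fh:
        bundle = pickle.load(fh)
    stack = _load_stack(wd)
    pred = predict_raster(bundle, stack)
    write_ascii(pred, wd / "agb_pred.asc")
    return _manifest(cfg, "predict", shape=list(pred.shape),
                     n_missing=int(np.isnan(pred.data).sum()))


def _stage_evaluate(cfg: RunConfig, wd: Path):
    samples = pd.read_csv(wd / "samples.csv")
    truth = read_ascii(wd / "scene/agb_truth.asc")
    truth.data[np.isnan(truth.data)] = 0.0
    pred = read_ascii(wd / "agb_pred.asc")
    rows = samples["cell_row"].to_numpy(int)
    cols = samples["cell_col"].to_numpy(int)
    t = truth.data[rows, cols]
    s = samples["agb_g_m2"].to_numpy()
    p = pred.data[rows, cols]

    ok3 = (samples["n_trees"].to_numpy() >= 3) & (t > 0)
    rel_err = np.abs(s[ok3] - t[ok3]) / t[ok3]
    sample_metrics = height_dbh.compute_metrics(s, t, k=2)
    pred_metrics = height_dbh.compute_metrics(p, t, k=2)
    report = {
        "n_samples": int(len(samples)),
        "n_cells_ge3_trees": int(ok3.sum()),
        "sample_vs_truth_r2": sample_metrics.r2,
        "sample_vs_truth_rmse_g_m2": sample_metrics.rmse,
        "cell_rel_err_median": float(np.median(rel_err)) if rel_err.size else None,
        "cell_rel_err_max": float(rel_err.max()) if rel_err.size else None,
        "pred_vs_truth_r2": pred_metrics.r2,
        "pred_vs_truth_rmse_g_m2": pred_metrics.rmse,
    }
    (wd / "evaluation.json").write_text(
        json.dumps(report, indent=2, default=float))
    return _manifest(cfg, "evaluate", **report)


_DISPATCH = {
    "simulate": _stage_simulate,
    "ground": _stage_ground,
    "segment": _stage_segment,
    "fit-hd": _stage_fit_hd,
    "samples": _stage_samples,
    "features": _stage_features,
    "train": _stage_train,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
}
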