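"""End-to-end analysis pipeline: simulate -> describe -> fit -> compare ->
summarize -> classify/map, with every artifact re-derivable from config +
seed alone."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import descriptives, io, simulate
from .model import GeoAdditiveLogistic
from .summaries import classify_spatial, compare_models, smooth_curve

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "make_choropleth"]


def _load_inputs(config: io.PipelineConfig, outdir: Path):
    if config.simulate is not None:
        sim = dict(config.simulate)
        truth = simulate.default_truth(
            n_children=int(sim.get("n_children", 5000)),
            n_side=int(sim.get("n_side", 6)),
            seed=config.seed,
        )
        ds = simulate.generate(truth)
        paths = simulate.save_dataset(ds, outdir / "synthetic")
        data = ds.data.drop(columns=["_eta_truth"])
        return data, ds.geography, None
    if config.data_path is None or config.geometry_path is None:
        raise ValueError("config must give data+geometry paths or a "
                         "simulate section")
    data = io.read_data_csv(config.data_path)
    geography = io.read_geojson(config.geometry_path, config.centroid_path)
    adjacency = (io.read_adjacency(config.adjacency_path, geography.region_ids)
                 if config.adjacency_path else None)
    return data, geography, adjacency


def run_pipeline(config: io.PipelineConfig) -> Path:
    """Execute every stage; artifacts land in the configured output directory.

    Any stage failure aborts with the stage name and cause.  Each output
    carries the config hash and the seed, so reruns with an identical
    configuration reproduce the artifacts exactly.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                     "stages": {}}
    stage = "setup"
    try:
        (outdir / "config_echo.yaml").write_text(yaml.safe_dump(config.raw))

        stage = "load"
        t0 = time.perf_counter()
        data, geography, adjacency = _load_inputs(config, outdir)
        run_log["stages"]["load"] = {"seconds": time.perf_counter() - t0,
                                     "rows": len(data)}

        stage = "filter"
        t0 = time.perf_counter()
        data, filter_report = io.apply_filters(data, config)
        (outdir / "filter_report.json").write_text(
            json.dumps(filter_report, indent=1))
        run_log["stages"]["filter"] = {"seconds": time.perf_counter() - t0,
                                       "rows": len(data)}

        stage = "describe"
        t0 = time.perf_counter()
        prev_region = descriptives.prevalence_by(data, "region_id")
        prev_region.to_csv(outdir / "prevalence_by_region.csv", index=False)
        cat_covs = [c for c in simulate.CATEGORY_FREQS if c in data.columns]
        by_cov = []
        for cov in cat_covs:
            t = descriptives.prevalence_by(data, cov)
            t.insert(0, "covariate", cov)
            by_cov.append(t[t.group != descriptives.OVERALL_LABEL])
        if by_cov:
            pd.concat(by_cov, ignore_index=True).to_csv(
                outdir / "prevalence_by_covariate.csv", index=False)
        screen = descriptives.chi2_screen(data, cat_covs,
                                          alpha=config.screen_alpha)
        screen.to_csv(outdir / "chi2_screen.csv", index=False)
        run_log["stages"]["describe"] = {"seconds": time.perf_counter() - t0}

        stage = "fit"
        t0 = time.perf_counter()
        fits: dict[str, GeoAdditiveLogistic] = {}
        for form in config.forms:
            model = GeoAdditiveLogistic(
                form=form, random_state=config.seed,
                **{k: v for k, v in config.model.items()},
                **{k: int(v) for k, v in config.mcmc.items()},
            )
            model.fit(data, "anaemic", geography=geography,
                      adjacency=adjacency)
            model.draws_.save(outdir / f"draws_{form}")
            fits[form] = model
            logger.info("fitted %s: DIC=%.2f", form, model.dic_.dic)
        run_log["stages"]["fit"] = {"seconds": time.perf_counter() - t0,
                                    "forms": list(fits)}

        stage = "compare"
        t0 = time.perf_counter()
        if len(fits) >= 2:
            comparison = compare_models(
                [(form, m.dic_, m.n_obs_) for form, m in fits.items()])
            comparison.to_csv(outdir / "model_comparison.csv", index=False)
            preferred = comparison.loc[0, "model"]
        else:
            preferred = next(iter(fits))
        (outdir / "dic.json").write_text(json.dumps(
            {form: vars(m.dic_) for form, m in fits.items()}, indent=1))
        run_log["stages"]["compare"] = {"seconds": time.perf_counter() - t0,
                                        "preferred": str(preferred)}

        stage = "summarize"
        t0 = time.perf_counter()
        best = fits[preferred]
        best.fixed_effect_table().to_csv(outdir / "fixed_effects.csv")
        for sb in best.blocks_.smooths:
            smooth_curve(best.draws_, best.blocks_, sb.name).to_csv(
                outdir / f"curve_{sb.name}.csv", index=False)
        run_log["stages"]["summarize"] = {"seconds": time.perf_counter() - t0}

        stage = "map"
        t0 = time.perf_counter()
        spatial_fit = next((fits[f] for f in ("M3", "M2") if f in fits), None)
        if spatial_fit is not None:
            cls = classify_spatial(spatial_fit.draws_, spatial_fit.blocks_)
            cls.to_csv(outdir / "spatial_classification.csv", index=False)
            io.write_classified_geojson(geography, cls,
                                        outdir / "spatial_effects.geojson")
            make_choropleth(geography, cls, outdir)
        run_log["stages"]["map"] = {"seconds": time.perf_counter() - t0}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=1))
    return outdir


def make_choropleth(geography, classification, outdir) -> None:
    """Three-colour credible-interval maps plus a posterior-mean map (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon
    from matplotlib.collections import PatchCollection

    rows = classification.set_index("region_id")
    colors = {"positive": "#d73027", "negative": "#4575b4",
              "insignificant": "#d9d9d9"}
    for col, fname in (("category95", "map_ci95.png"),
                       ("category80", "map_ci80.png")):
        if col not in classification.columns:
            continue
        fig, ax = plt.subplots(figsize=(6, 6))
        for rid, poly in zip(geography.region_ids, geography.polygons):
            cat = rows.loc[rid, col] if rid in rows.index else "insignificant"
            ax.add_patch(MplPolygon(np.asarray(poly), closed=True,
                                    facecolor=colors[cat], edgecolor="black",
                                    linewidth=0.4))
        ax.autoscale()
        ax.set_aspect("equal")
        ax.set_title(f"Spatial effect, {col.removeprefix('category')}% "
                     "credible interval")
        fig.savefig(Path(outdir) / fname, dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 6))
    vals = rows["mean"]
    vmax = float(np.abs(vals).max()) or 1.0
    cmap = plt.get_cmap("RdBu_r")
    patches, face = [], []
    for rid, poly in zip(geography.region_ids, geography.polygons):
        patches.append(MplPolygon(np.asarray(poly), closed=True))
        v = float(vals.loc[rid]) if rid in vals.index else 0.0
        face.append(cmap(0.5 + v / (2 * vmax)))
    pc = PatchCollection(patches, facecolor=face, edgecolor="black",
                         linewidth=0.4)
    ax.add_collection(pc)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_title("Posterior-mean spatial effect")
    fig.savefig(Path(outdir) / "map_mean.png", dpi=120)
    plt.close(fig)
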