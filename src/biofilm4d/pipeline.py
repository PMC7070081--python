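"""End-to-end orchestration: from a manifest (or in-memory time lapse) to
heightmap products, element/track/fit/merge tables and a summary report.

Every numeric default lives in :data:`DEFAULT_PARAMS` and can be
overridden from the run config; a run is deterministic given the same
config and seed (table outputs are byte-identical across reruns).
"""

from __future__ import annotations

import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import growth, merging, preprocess, segmentation, topography, tracking
from .stacks_io import ImageStack, TimeLapse, load_timelapse, write_stack

log = logging.getLogger("biofilm4d")

DEFAULT_PARAMS: dict = {
    "gaussian_variance": 0.8,      # px², 3D denoising filter; 0 disables
    "threshold": "otsu",           # or a fixed gray level
    "contrast_threshold": None,    # reflection threshold; None = Otsu
    "connectivity": 26,
    "edge_policy": "lateral",
    "unit_cell_volume": 0.35,      # µm³ per cell
    "t_ref": 420.0,                # min, SC/DC reference time
    "dc_factor": 5.0,              # strict V(t_ref) > factor·V(0) for DC
    "persistence": 1,              # frames of absence before detachment
    "max_gap": 0,                  # frames a track survives unmatched
    "growth_model": "offset_power",
    "mas_areas_um2": [3, 10, 30, 60, 115],
    "max_sd_b": 1.0,
    "min_r2": 0.5,
}


class ConfigError(ValueError):
    """Schema-level problem in the run configuration."""


def _merge_params(config: dict) -> dict:
    params = dict(DEFAULT_PARAMS)
    extra = config.get("params", {})
    unknown = set(extra) - set(params)
    if unknown:
        raise ConfigError(f"unknown params: {sorted(unknown)}; "
                          f"valid keys are {sorted(params)}")
    params.update(extra)
    return params


def _load_input(config: dict, base_dir: Path) -> TimeLapse:
    if "timelapse" in config:          # in-memory use (library callers, tests)
        return config["timelapse"]
    if "input" not in config:
        raise ConfigError("config needs 'input' (scene directory with "
                          "manifest.yaml) or an in-memory 'timelapse'")
    scene_dir = (base_dir / config["input"]).resolve()
    manifest_path = scene_dir / "manifest.yaml"
    if not manifest_path.exists():
        raise ConfigError(f"no manifest.yaml under {scene_dir}")
    manifest = yaml.safe_load(manifest_path.read_text())
    return load_timelapse(manifest, base_dir=scene_dir)


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int = 0) -> dict:
    """Run all stages and write the results bundle under ``out_dir``.

    ``config`` is a mapping (or a path to a YAML file) with keys
    ``input`` (scene directory), optional ``params`` overriding
    :data:`DEFAULT_PARAMS`, and optional ``stages`` (default: all of
    topography, segment, track, fit, merges).

    Returns the in-memory results: heightmap, per-frame elements, tracks,
    fits, merge events and the summary dict that is also written as JSON.
    """
    base_dir = Path(".")
    if isinstance(config, (str, Path)):
        base_dir = Path(config).parent
        config = yaml.safe_load(Path(config).read_text())
    params = _merge_params(config)
    stages = config.get("stages", ["topography", "segment", "track", "fit",
                                   "merges"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = _time.perf_counter()
    log.info("run start: stages=%s seed=%d params=%s", stages, seed, params)

    tl = _load_input(config, base_dir)
    times = tl.times
    geom = next(iter(tl.frames[0][1].values())).geometry
    results: dict = {"params": params, "seed": seed, "times": times}
    summary: dict = {"seed": seed, "n_frames": len(times)}

    # ---- topography -----------------------------------------------------
    heightmap = None
    if "topography" in stages:
        t0_chans = tl.frames[tl.t0_index][1]
        if "reflection" not in t0_chans:
            raise ConfigError(
                "topography stage requested but the t0 frame has no "
                "'reflection' channel; add it to the manifest or drop the stage")
        refl = t0_chans["reflection"]
        if params["gaussian_variance"] > 0:
            refl = preprocess.gaussian3d(refl, params["gaussian_variance"])
        heightmap = topography.extract_heightmap(refl,
                                                 params["contrast_threshold"])
        stats = topography.roughness(heightmap)
        summary["roughness_global"] = {"Sa": stats.Sa, "Sq": stats.Sq,
                                       "Ssk": stats.Ssk,
                                       "n_columns": stats.n_columns}
        mas = topography.mas_scan(heightmap, params["mas_areas_um2"])
        mas.to_csv(out / "mas_roughness.csv", index=False)
        write_stack(ImageStack(heightmap.h[None].astype(np.float32), geom,
                               channel="reflection"), out / "heightmap.tif")
        pd.DataFrame(heightmap.h).to_csv(out / "heightmap.csv", index=False)
        results["heightmap"], results["mas"] = heightmap, mas
        log.info("topography done: global Sa=%.3f µm over %d columns",
                 stats.Sa, stats.n_columns)

    # ---- segmentation ---------------------------------------------------
    per_frame: list[list[segmentation.Element]] = []
    element_rows = []
    coverage_rows = []
    if "segment" in stages:
        for fi, (t, chans) in enumerate(tl.frames):
            if "bacteria" not in chans:
                raise ConfigError(f"frame {fi} has no 'bacteria' channel")
            smooth = chans["bacteria"]
            if params["gaussian_variance"] > 0:
                smooth = preprocess.gaussian3d(smooth,
                                               params["gaussian_variance"])
            binr = preprocess.binarize(smooth, params["threshold"])
            elements = segmentation.label3d(binr.stack, params["connectivity"])
            elements = segmentation.filter_edge_elements(
                elements, binr.stack.shape, params["edge_policy"])
            segmentation.measure_elements(elements, geom, frame_time=t,
                                          unit_cell_volume=params["unit_cell_volume"])
            per_frame.append(elements)
            area, frac = segmentation.surface_coverage(binr.stack)
            coverage_rows.append(dict(frame=fi, time_min=t,
                                      area_um2=area, fraction=frac,
                                      total_volume_um3=sum(e.volume
                                                           for e in elements)))
            for el in elements:
                element_rows.append(dict(
                    frame=fi, time_min=t, element_id=el.id,
                    volume_um3=el.volume, qhull_um3=el.qhull_volume,
                    solidity=el.solidity_ratio, est_cells=el.est_cells,
                    colonizer_class=el.colonizer_class,
                    centroid_x_um=el.centroid[0], centroid_y_um=el.centroid[1],
                    centroid_z_um=el.centroid[2],
                    bbox=str(el.bbox), edge_flag=el.edge_flag))
        elements_df = pd.DataFrame(element_rows)
        elements_df.to_csv(out / "elements.csv", index=False)
        cov_df = pd.DataFrame(coverage_rows)
        cov_df.to_csv(out / "coverage.csv", index=False)
        results["per_frame_elements"] = per_frame
        results["elements_table"] = elements_df
        results["coverage"] = cov_df
        log.info("segmentation done: %d elements at t0, %d frames",
                 len(per_frame[0]) if per_frame else 0, len(per_frame))
        if heightmap is not None and per_frame and per_frame[tl.t0_index]:
            sites = topography.site_roughness(heightmap, per_frame[tl.t0_index])
            sites.to_csv(out / "site_roughness.csv", index=False)
            results["site_roughness"] = sites

    # ---- tracking -------------------------------------------------------
    tracks: list[tracking.Track] = []
    if "track" in stages:
        if not per_frame:
            raise ConfigError("track stage requires segment stage")
        shape = next(iter(tl.frames[0][1].values())).shape
        tracks = tracking.link_tracks(per_frame, times, shape,
                                      max_gap=params["max_gap"])
        tracking.detect_detachment(tracks, times,
                                   persistence=params["persistence"])
        for tr in tracks:
            tracking.classify_dynamics(tr, t_ref=params["t_ref"],
                                       factor=params["dc_factor"])
        results["tracks"] = tracks
        n_detached = sum(tr.status == "detached" for tr in tracks)
        summary["n_tracks"] = len(tracks)
        summary["n_detached"] = n_detached
        summary["detached_fraction"] = n_detached / len(tracks) if tracks else None
        _write_track_tables(tracks, times, out)
        log.info("tracking done: %d tracks, %d detached", len(tracks), n_detached)

    # ---- growth fitting -------------------------------------------------
    fits: list[growth.GrowthFit] = []
    if "fit" in stages:
        if not tracks:
            raise ConfigError("fit stage requires track stage")
        fits = [growth.fit_growth(tr, model=params["growth_model"])
                for tr in tracks]
        growth.fits_table(fits).to_csv(out / "growth_fits.csv", index=False)
        results["fits"] = fits
        if any(growth.is_usable(f, params["max_sd_b"], params["min_r2"])
               for f in fits):
            summary["growth"] = growth.population_summary(
                fits, tracks, params["max_sd_b"], params["min_r2"])
        log.info("growth fitting done: %d fits", len(fits))

    # ---- merging --------------------------------------------------------
    events: list[merging.MergeEvent] = []
    if "merges" in stages:
        if not tracks:
            raise ConfigError("merges stage requires track stage")
        events = merging.detect_merges(tracks, times)
        rows = []
        for ev in events:
            parts = merging.partition_merged_volume(ev, tracks, geom)
            for pid, (ts, vs) in sorted(parts.items()):
                for t, v in zip(ts, vs):
                    rows.append(dict(child=ev.child_track, parent=pid,
                                     merge_time=ev.merge_time, time_min=t,
                                     volume_um3=v))
        pd.DataFrame(rows, columns=["child", "parent", "merge_time",
                                    "time_min", "volume_um3"]
                     ).to_csv(out / "merge_partitions.csv", index=False)
        results["merge_events"] = events
        summary["n_merge_events"] = len(events)
        log.info("merging done: %d events", len(events))

    summary["runtime_s"] = round(_time.perf_counter() - t_start, 3)
    results["summary"] = summary
    (out / "summary.json").write_text(
        json.dumps({k: v for k, v in summary.items() if k != "runtime_s"},
                   indent=2, sort_keys=True, default=float) + "\n")
    log.info("run finished in %.1f s", summary["runtime_s"])
    return results


def _write_track_tables(tracks: list[tracking.Track], times: list[float],
                        out: Path) -> None:
    vol_cols = {f"v_{int(t)}min": t for t in times}
    rows, events = [], []
    for tr in tracks:
        row = dict(track_id=tr.track_id, origin_time=tr.times[0],
                   status=tr.status, dynamics_class=tr.dynamics_class,
                   n_frames=len(tr.times))
        lookup = dict(zip(tr.times, (el.volume for el in tr.elements)))
        for col, t in vol_cols.items():
            row[col] = lookup.get(t)
        rows.append(row)
        if tr.status == "detached":
            events.append(dict(track_id=tr.track_id, event="detach",
                               time_min=tr.detach_time, other=None))
        elif tr.status == "merged":
            events.append(dict(track_id=tr.track_id, event="merge",
                               time_min=tr.merge_time, other=tr.merged_into))
    pd.DataFrame(rows).to_csv(out / "tracks.csv", index=False)
    pd.DataFrame(events, columns=["track_id", "event", "time_min", "other"]
                 ).to_csv(out / "events.csv", index=False)


# ---------------------------------------------------------------------------
# Report figures
# ---------------------------------------------------------------------------

def make_report(results: dict, out_dir: str | Path) -> list[Path]:
    """Summary figure panels from a results bundle.

    Writes PNG panels (roughness occupancy histograms, V(0) vs V(final)
    scatter, a/b coefficient distributions with median/quartile lines,
    solidity vs volume, coverage and total-volume curves).  Empty inputs
    produce placeholder panels with a note rather than failing.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def placeholder(ax, msg):
        ax.text(0.5, 0.5, msg, ha="center", va="center", wrap=True)
        ax.set_axis_off()

    # roughness occupancy
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    sites, mas = results.get("site_roughness"), results.get("mas")
    if sites is not None and mas is not None and not sites.empty and not mas.empty:
        hists = topography.occupancy_histograms(sites, mas)
        for ax, metric in zip(axes, ("Sa", "Sq", "Ssk")):
            h = hists[metric]
            centers = 0.5 * (h["bins"][:-1] + h["bins"][1:])
            width = np.diff(h["bins"])
            ax.bar(centers, h["nca"], width=width, alpha=0.5, label="n.c.a.")
            ax.bar(centers, h["occupied"], width=width, alpha=0.5,
                   label="occupied")
            ax.set_xlabel(metric)
            ax.set_ylabel("density")
            ax.legend()
    else:
        for ax in axes:
            placeholder(ax, "no roughness tables")
    fig.tight_layout()
    p = out / "roughness_occupancy.png"
    fig.savefig(p, dpi=110); plt.close(fig); written.append(p)

    # growth coefficients
    fits = [f for f in results.get("fits", [])
            if growth.is_usable(f)]
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    if fits:
        for ax, key in zip(axes, ("a", "b")):
            vals = np.array([getattr(f, key) for f in fits], dtype=float)
            ax.scatter(np.zeros_like(vals), vals, s=12, alpha=0.6)
            for qv, style in ((np.median(vals), "r-"),
                              (np.quantile(vals, 0.25), "k--"),
                              (np.quantile(vals, 0.75), "k--")):
                ax.plot([-0.3, 0.3], [qv, qv], style)
            ax.set_ylabel(key)
            ax.set_xticks([])
            if key == "a" and vals.min() > 0:
                ax.set_yscale("log")
    else:
        for ax in axes:
            placeholder(ax, "no usable growth fits (static-only population)")
    fig.tight_layout()
    p = out / "growth_coefficients.png"
    fig.savefig(p, dpi=110); plt.close(fig); written.append(p)

    # V(0) vs V(final) and solidity/volume
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.8))
    tracks = results.get("tracks", [])
    if tracks:
        v0 = [tr.elements[0].volume for tr in tracks]
        vf = [tr.elements[-1].volume for tr in tracks]
        axes[0].loglog(v0, vf, "o", ms=4, alpha=0.6)
        lim = [min(v0 + vf), max(v0 + vf)]
        axes[0].loglog(lim, lim, "k:", lw=1)
        axes[0].set_xlabel("V(0) µm³"); axes[0].set_ylabel("V(final) µm³")
    else:
        placeholder(axes[0], "no tracks")
    et = results.get("elements_table")
    if et is not None and not et.empty and et["solidity"].notna().any():
        ok = et["solidity"].notna()
        axes[1].semilogx(et.loc[ok, "volume_um3"], et.loc[ok, "solidity"],
                         ".", ms=4, alpha=0.5)
        axes[1].set_xlabel("volume µm³"); axes[1].set_ylabel("qhull/volume")
    else:
        placeholder(axes[1], "no morphometric data")
    fig.tight_layout()
    p = out / "population_panels.png"
    fig.savefig(p, dpi=110); plt.close(fig); written.append(p)

    # coverage / volume curves
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    cov = results.get("coverage")
    if cov is not None and not cov.empty:
        ax.plot(cov["time_min"], cov["total_volume_um3"], "o-", label="biovolume µm³")
        ax2 = ax.twinx()
        ax2.plot(cov["time_min"], cov["area_um2"], "s--", color="tab:orange",
                 label="occupied area µm²")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("biovolume µm³"); ax2.set_ylabel("area µm²")
    else:
        placeholder(ax, "no coverage table")
    fig.tight_layout()
    p = out / "coverage_volume.png"
    fig.savefig(p, dpi=110); plt.close(fig); written.append(p)
    return written
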