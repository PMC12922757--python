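"""End-to-end orchestration: simulate -> render -> analyze -> report.

A run directory contains::

    manifest.json        versions, seeds, config hash
    config.yaml          effective configuration
    gradient.csv         solved concentration field
    spots.csv            simulated tracks (TrackMate dialect)
    ground_truth.json    generator latents
    vesicles.csv         per-cell vesicle counts + polarity readout
    channel_*.tif        rendered channels (optional)
    *_mask.tif           rendered label masks (optional)
    per_cell.csv         peri-constriction kinematics per cell
    summary.json         machine-readable population summary
    figures/*.png        report plots

Reruns with the same config are byte-identical at the summary level.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .config import (
    config_hash,
    dump_config,
    geometry_from_config,
    phenotype_from_config,
)
from .device import gradient_establishment_time, solve_gradient
from .errors import ReportError
from .intensity import calcium_fold_change, detect_spikes
from .kinematics import filter_tracks, peri_summary, read_tracks, eccentricity_timecourse
from .morphology import keratocyte_fraction, shape_metrics, classify_keratocyte
from .synthetic_data import (
    generate_calcium_traces,
    generate_vesicle_counts,
    render_frames,
    simulate_cohort,
    write_cohort,
    write_manifest,
    write_rendered_frames,
)
from .device import classify_position

log = logging.getLogger("constrictaxis")

__all__ = ["run_experiment", "make_report"]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path, payload):
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default)
    )


def run_experiment(cfg: dict, out_dir, seed: int | None = None) -> Path:
    """Run the full synthetic experiment described by ``cfg``.

    ``seed`` overrides the simulation seed (other stage seeds are offset
    from it for independence); reruns with identical config and seed are
    byte-identical at the summary level.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg = json.loads(json.dumps(cfg))  # private copy
        cfg["simulate"]["seed"] = int(seed)
        cfg["traces"]["seed"] = int(seed) + 1
        cfg["vesicles"]["seed"] = int(seed) + 2
        cfg["render"]["seed"] = int(seed) + 3
        cfg["analysis"]["bootstrap_seed"] = int(seed) + 4

    geom = geometry_from_config(cfg)
    dump_config(cfg, out / "config.yaml")

    log.info("stage 1/5: gradient")
    g = cfg["gradient"]
    field = solve_gradient(geom, D=g["D"], t_end=g["t_end"], dx=g["dx"], dt=g["dt"])
    field.to_csv(out / "gradient.csv")
    establish_s = gradient_establishment_time(field, g["tolerance"])

    log.info("stage 2/5: simulate")
    s = cfg["simulate"]
    phenotype = phenotype_from_config(cfg)
    cohort = simulate_cohort(
        phenotype, s["n_cells"], geom, dt=s["dt"], n_frames=s["n_frames"],
        seed=s["seed"],
    )
    tr = cfg["traces"]
    cohort = generate_calcium_traces(
        cohort, baseline=tr["baseline"], noise_cv=tr["noise_cv"],
        spike_amp=tr["spike_amp"], spike_decay=tr["spike_decay"], seed=tr["seed"],
    )
    vesicles = generate_vesicle_counts(
        cohort, seed=cfg["vesicles"]["seed"], dispersion=cfg["vesicles"]["dispersion"]
    )
    vesicles.to_csv(out / "vesicles.csv", index=False)
    write_cohort(cohort, out)

    log.info("stage 3/5: render")
    morpho_rows = []
    if cfg["render"]["enabled"]:
        n_render = min(cfg["render"]["n_frames"], s["n_frames"])
        indices = np.unique(
            np.linspace(1, s["n_frames"] - 1, n_render).astype(int)
        )
        frames = render_frames(
            cohort,
            pixel_size=cfg["render"]["pixel_size"],
            frame_indices=indices,
            cortical_ratio=cfg["render"]["cortical_ratio"],
            seed=cfg["render"]["seed"],
            noise_sd=cfg["render"]["noise_sd"],
            on_overlap="skip",
        )
        write_rendered_frames(frames, out)
        for fr in frames:
            for m in shape_metrics(fr.cell_mask, pixel_size=fr.pixel_size):
                cx_um = m.centroid[1]
                region = classify_position(
                    min(cx_um, geom.chamber_length), geom
                )
                morpho_rows.append(
                    {
                        "cell": m.label - 1,
                        "frame": fr.frame_index,
                        "region": region,
                        "orientation": m.orientation,
                        "eccentricity": m.eccentricity,
                        "solidity": m.solidity,
                        "keratocyte": classify_keratocyte(
                            m, cfg["analysis"]["keratocyte_thresholds"]
                        ),
                    }
                )

    log.info("stage 4/5: analyze")
    a = cfg["analysis"]
    ts = read_tracks(out / "spots.csv", frame_interval=s["dt"], geometry=geom)
    ts = filter_tracks(ts, min_final_x=a["min_final_x"])
    summary_kin = peri_summary(
        ts, n_boot=a["n_boot"], seed=a["bootstrap_seed"],
        exclude_saturated=a["exclude_saturated"],
    )
    summary_kin.per_cell.to_csv(out / "per_cell.csv", index=False)
    ecc_tc = eccentricity_timecourse(ts)

    folds = []
    spike_cells = 0
    evaluable = 0
    kept_ids = {t.track_id for t in ts}
    for trace in cohort.traces:
        if trace.track_id not in kept_ids:
            continue
        fc = calcium_fold_change(trace, geom)
        if fc is not None:
            folds.append(fc)
        spikes = detect_spikes(trace, k_mad=a["k_mad"], geometry=geom)
        evaluable += 1
        if np.any(spikes.post_constriction):
            spike_cells += 1

    morpho_df = pd.DataFrame(morpho_rows)
    kfrac = None
    if len(morpho_df):
        kfrac = keratocyte_fraction(
            morpho_df, region="after", thresholds=a["keratocyte_thresholds"]
        )
        morpho_df.to_csv(out / "morphology.csv", index=False)

    summary = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "phenotype": phenotype.label,
        "n_cells": s["n_cells"],
        "n_tracks_kept": len(ts),
        "gradient_establishment_s": establish_s,
        "crossing_fraction": summary_kin.crossing_fraction,
        "medians": summary_kin.medians,
        "ratios": summary_kin.ratios,
        "eccentricity_by_region": ecc_tc,
        "calcium": {
            "n_evaluable": evaluable,
            "median_fold_change": float(np.median(folds)) if folds else None,
            "spiking_fraction": spike_cells / evaluable if evaluable else None,
        },
        "keratocyte_fraction_post": kfrac,
        "vesicles": {
            "median_pre": float(vesicles["pre_count"].median()),
            "median_post": float(vesicles["post_count"].median()),
        },
    }
    _write_json(out / "summary.json", summary)

    write_manifest(
        out,
        {
            "tool": "constrictaxis",
            "version": __version__,
            "config_hash": config_hash(cfg),
            "seeds": {
                "simulate": cfg["simulate"]["seed"],
                "traces": cfg["traces"]["seed"],
                "vesicles": cfg["vesicles"]["seed"],
                "render": cfg["render"]["seed"],
                "bootstrap": cfg["analysis"]["bootstrap_seed"],
            },
        },
    )

    log.info("stage 5/5: report")
    make_report(out)
    return out


def make_report(run_dir) -> Path:
    """Assemble figures + verify the summary from a completed run directory."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise ReportError("missing analysis output: summary.json (run analyze first)")
    spots = run_dir / "spots.csv"
    if not spots.exists():
        raise ReportError("missing simulation output: spots.csv")
    summary = json.loads(summary_path.read_text())

    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)

    df = pd.read_csv(spots)
    cx = 100.0
    cfg_path = run_dir / "config.yaml"
    if cfg_path.exists():
        import yaml

        cfg = yaml.safe_load(cfg_path.read_text())
        cx = cfg["device"]["constriction_x"]

    # tracks colored by time
    fig, ax = plt.subplots(figsize=(7, 4))
    for tid, grp in df.groupby("TRACK_ID"):
        if tid % max(len(df["TRACK_ID"].unique()) // 60, 1):
            continue
        ax.scatter(grp["POSITION_X"], grp["POSITION_Y"], c=grp["POSITION_T"],
                   s=1, cmap="viridis")
    ax.axvline(cx, color="red", ls="--", lw=1)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title("tracks (color = time)")
    fig.savefig(fig_dir / "tracks.png", dpi=110)
    plt.close(fig)

    # before-after medians
    per_cell_path = run_dir / "per_cell.csv"
    if per_cell_path.exists():
        pc = pd.read_csv(per_cell_path)
        pairs = pc[["pre_dir", "post_dir"]].dropna()
        if len(pairs):
            fig, ax = plt.subplots(figsize=(4, 4))
            for _, row in pairs.iterrows():
                ax.plot([0, 1], [row["pre_dir"], row["post_dir"]],
                        color="gray", alpha=0.2, lw=0.5)
            ax.plot([0, 1], [pairs["pre_dir"].median(), pairs["post_dir"].median()],
                    color="red", lw=2, marker="o")
            ax.set_xticks([0, 1], ["pre", "post"])
            ax.set_ylabel("directionality")
            fig.savefig(fig_dir / "before_after_directionality.png", dpi=110)
            plt.close(fig)
        else:
            (fig_dir / "before_after_directionality.SKIPPED.txt").write_text(
                "no cells crossed the constriction; before-after plot omitted\n"
            )

    # aligned calcium traces
    if "MEAN_INTENSITY" in df.columns:
        fig, ax = plt.subplots(figsize=(7, 4))
        for tid, grp in df.groupby("TRACK_ID"):
            if tid % max(len(df["TRACK_ID"].unique()) // 40, 1):
                continue
            ax.plot(grp["POSITION_X"], grp["MEAN_INTENSITY"], lw=0.5, alpha=0.6)
        ax.axvline(cx, color="blue", lw=1)
        ax.set_xlabel("x (um)")
        ax.set_ylabel("calcium intensity (a.u.)")
        fig.savefig(fig_dir / "calcium_traces.png", dpi=110)
        plt.close(fig)

    # vesicle scatter
    ves_path = run_dir / "vesicles.csv"
    if ves_path.exists():
        ves = pd.read_csv(ves_path)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(ves["post_count"], ves["pmlc_ratio"], s=8, alpha=0.5)
        ax.set_xlabel("post-constriction vesicle count")
        ax.set_ylabel("cortex/cytosol polarity ratio")
        fig.savefig(fig_dir / "vesicles_vs_polarity.png", dpi=110)
        plt.close(fig)

    # cross-check: medians in summary equal medians recomputed from per-cell CSV
    if per_cell_path.exists():
        pc = pd.read_csv(per_cell_path)
        for col in ("pre_speed", "post_speed", "pre_dir", "post_dir"):
            stored = summary["medians"].get(col)
            vals = pc[col].dropna()
            if stored is not None and len(vals):
                if abs(float(np.median(vals)) - stored) > 1e-9:
                    raise ReportError(
                        f"summary median {col} does not match per-cell CSV"
                    )
    return fig_dir
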