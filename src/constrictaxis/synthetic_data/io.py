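"""Writers for simulated runs: spots CSV, ground-truth JSON, channel TIFFs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from ..kinematics import write_tracks
from .cohort import SimulatedCohort
from .render import RenderedFrame

__all__ = ["write_cohort", "write_rendered_frames", "write_manifest"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_cohort(cohort: SimulatedCohort, run_dir) -> dict:
    """Write tracks CSV + ground-truth JSON; returns the file map."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    spots = run_dir / "spots.csv"
    write_tracks(cohort.tracks, spots)
    gt_path = run_dir / "ground_truth.json"
    payload = {
        "seed": cohort.seed,
        "phenotype": cohort.phenotype.label,
        "n_cells": len(cohort.tracks),
        "cells": _jsonable(cohort.ground_truth),
    }
    gt_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return {"spots": str(spots), "ground_truth": str(gt_path)}


def write_rendered_frames(frames: list[RenderedFrame], run_dir) -> dict:
    """Write one multi-page TIFF per channel plus 16-bit label masks."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    if not frames:
        return {}
    files = {}
    for name in frames[0].channels:
        stack = np.stack([f.channels[name] for f in frames]).astype(np.float32)
        path = run_dir / f"channel_{name}.tif"
        tifffile.imwrite(path, stack)
        files[name] = str(path)
    for attr in ("cell_mask", "nucleus_mask"):
        stack = np.stack([getattr(f, attr) for f in frames]).astype(np.uint16)
        path = run_dir / f"{attr}.tif"
        tifffile.imwrite(path, stack)
        files[attr] = str(path)
    return files


def write_manifest(run_dir, manifest: dict) -> str:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    path = run_dir / "manifest.json"
    path.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
    return str(path)
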