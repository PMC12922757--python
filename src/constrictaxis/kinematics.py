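"""Track ingestion, exclusion filtering and peri-constriction kinematics.

Tracks are time-ordered centroid series per cell.  "Directionality" is the
confinement ratio: net Euclidean displacement divided by accumulated path
length, bounded by [0, 1].  An x-forward-migration-index variant
(``forward_migration_index``) is provided alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .device import DeviceGeometry
from .errors import FormatError, InvalidParameterError

__all__ = [
    "Track",
    "TrackSet",
    "TrackSegments",
    "PeriConstrictionSummary",
    "read_tracks",
    "write_tracks",
    "filter_tracks",
    "track_speed",
    "track_directionality",
    "forward_migration_index",
    "split_at_constriction",
    "peri_summary",
    "eccentricity_timecourse",
]

#: TrackMate-dialect required columns
REQUIRED_COLUMNS = ("TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y")
#: optional per-frame attachments recognized on read
ATTACHMENT_COLUMNS = {"MEAN_INTENSITY": "intensity", "ECCENTRICITY": "eccentricity"}


@dataclass(frozen=True)
class Track:
    """Time-ordered centroid series for one cell (um / s)."""

    track_id: int
    frames: np.ndarray
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    attachments: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.frames)
        if n < 2:
            raise InvalidParameterError(
                f"track {self.track_id}: needs at least 2 points"
            )
        for name in ("times", "x", "y"):
            if len(getattr(self, name)) != n:
                raise InvalidParameterError(f"track {self.track_id}: ragged {name}")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError(
                f"track {self.track_id}: times must be strictly increasing"
            )
        for key, arr in self.attachments.items():
            if len(arr) != n:
                raise InvalidParameterError(
                    f"track {self.track_id}: attachment {key!r} length mismatch"
                )

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class TrackSegments:
    """Pre/during/post index slices of one track around the constriction."""

    pre: np.ndarray  # indices
    during: np.ndarray
    post: np.ndarray


@dataclass(frozen=True)
class TrackSet:
    tracks: tuple
    frame_interval: float  # s
    geometry: DeviceGeometry = field(default_factory=DeviceGeometry)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [t.track_id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise InvalidParameterError("duplicate track ids in TrackSet")
        for t in self.tracks:
            dts = np.diff(t.times)
            if np.any(np.abs(dts - self.frame_interval) > 0.01 * self.frame_interval):
                # gaps of whole multiples of the interval are fine
                ratio = dts / self.frame_interval
                if np.any(np.abs(ratio - np.round(ratio)) > 0.01):
                    raise InvalidParameterError(
                        f"track {t.track_id}: non-uniform frame interval"
                    )

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


@dataclass(frozen=True)
class PeriConstrictionSummary:
    per_cell: pd.DataFrame
    crossing_fraction: float
    medians: dict
    ratios: dict  # point estimates and bootstrap CIs
    n_entered: int
    n_crossed: int


def read_tracks(
    path,
    frame_interval: float = 30.0,
    geometry: DeviceGeometry | None = None,
) -> TrackSet:
    """Read a spots-table CSV (TrackMate dialect) into a TrackSet.

    Non-numeric rows (e.g. the units header rows some exports carry) are
    dropped, logged and counted in ``provenance``.  Missing required columns
    and duplicated (track, frame) pairs raise :class:`FormatError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    numeric_cols = [c for c in df.columns if c in REQUIRED_COLUMNS
                    or c == "POSITION_T" or c in ATTACHMENT_COLUMNS]
    coerced = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = coerced[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    n_malformed = int(bad.sum())
    df = coerced[~bad]

    dup = df.duplicated(subset=["TRACK_ID", "FRAME"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            "duplicated (track, frame) pair: "
            f"({int(row['TRACK_ID'])}, {int(row['FRAME'])})"
        )

    tracks = []
    for tid, grp in df.groupby("TRACK_ID"):
        grp = grp.sort_values("FRAME")
        if len(grp) < 2:
            continue
        frames = grp["FRAME"].to_numpy(dtype=int)
        if "POSITION_T" in grp.columns and grp["POSITION_T"].notna().all():
            times = grp["POSITION_T"].to_numpy(dtype=float)
        else:
            times = frames * frame_interval
        attachments = {
            dest: grp[src].to_numpy(dtype=float)
            for src, dest in ATTACHMENT_COLUMNS.items()
            if src in grp.columns and grp[src].notna().all()
        }
        tracks.append(
            Track(
                track_id=int(tid),
                frames=frames,
                times=times,
                x=grp["POSITION_X"].to_numpy(dtype=float),
                y=grp["POSITION_Y"].to_numpy(dtype=float),
                attachments=attachments,
            )
        )
    return TrackSet(
        tracks=tuple(tracks),
        frame_interval=frame_interval,
        geometry=geometry or DeviceGeometry(),
        provenance={"source": str(path), "malformed_rows": n_malformed},
    )


def write_tracks(ts: TrackSet, path) -> None:
    """Write a TrackSet as a TrackMate-dialect spots CSV."""
    rows = []
    for t in ts:
        rec = {
            "TRACK_ID": t.track_id,
            "FRAME": t.frames,
            "POSITION_T": t.times,
            "POSITION_X": t.x,
            "POSITION_Y": t.y,
        }
        for src, dest in ATTACHMENT_COLUMNS.items():
            if dest in t.attachments:
                rec[src] = t.attachments[dest]
        rows.append(pd.DataFrame(rec))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def filter_tracks(ts: TrackSet, min_final_x: float = 100.0) -> TrackSet:
    """Exclude tracks whose net final x-displacement is strictly below
    ``min_final_x`` um (boundary inclusive: exactly 100 um is retained).
    Idempotent; exclusions are appended to the provenance filter log.
    """
    kept, excluded = [], []
    for t in ts:
        net_x = float(t.x[-1] - t.x[0])
        if net_x >= min_final_x:
            kept.append(t)
        else:
            excluded.append({"track_id": t.track_id, "final_x": net_x})
    prov = dict(ts.provenance)
    prov.setdefault("filter_log", []).append(
        {"min_final_x": min_final_x, "n_excluded": len(excluded),
         "excluded": excluded}
    )
    return replace(ts, tracks=tuple(kept), provenance=prov)


def _path_length(x, y) -> float:
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


def track_speed(track) -> float:
    """Total path length / elapsed time, in um/min."""
    elapsed = float(track.times[-1] - track.times[0])
    if elapsed <= 0:
        raise InvalidParameterError("zero elapsed time")
    return _path_length(track.x, track.y) / elapsed * 60.0


def track_directionality(track) -> float:
    """Confinement ratio: net displacement / path length, in [0, 1]."""
    path = _path_length(track.x, track.y)
    if path == 0:
        warnings.warn("stationary track: directionality defined as 0")
        return 0.0
    net = float(np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))
    return min(net / path, 1.0)


def forward_migration_index(track) -> float:
    """Net x-displacement / path length (can be negative)."""
    path = _path_length(track.x, track.y)
    if path == 0:
        warnings.warn("stationary track: FMI defined as 0")
        return 0.0
    return float(track.x[-1] - track.x[0]) / path


def split_at_constriction(track: Track, geometry: DeviceGeometry) -> TrackSegments:
    """First-entry / first-exit split around the pillar.

    * pre: frames before the first frame with ``x >= constriction_x``
    * during: frames from first entry until (excluding) the first frame with
      ``x > exit_x`` after entry
    * post: frames from first exit onward

    A cell that never reaches the constriction has empty during/post.
    """
    x = track.x
    idx = np.arange(len(x))
    entry_hits = np.nonzero(x >= geometry.constriction_x)[0]
    if entry_hits.size == 0:
        return TrackSegments(pre=idx, during=idx[:0], post=idx[:0])
    entry = int(entry_hits[0])
    exit_hits = np.nonzero((idx >= entry) & (x > geometry.exit_x))[0]
    if exit_hits.size == 0:
        return TrackSegments(pre=idx[:entry], during=idx[entry:], post=idx[:0])
    exit_i = int(exit_hits[0])
    return TrackSegments(pre=idx[:entry], during=idx[entry:exit_i], post=idx[exit_i:])


class _Segment:
    """Lightweight view of a track slice, duck-typed for the speed helpers."""

    __slots__ = ("times", "x", "y")

    def __init__(self, track: Track, indices: np.ndarray):
        self.times = track.times[indices]
        self.x = track.x[indices]
        self.y = track.y[indices]

    def __len__(self):
        return len(self.times)


def _segment_metrics(track: Track, indices: np.ndarray):
    if len(indices) < 2:
        return np.nan, np.nan
    seg = _Segment(track, indices)
    return track_speed(seg), track_directionality(seg)


def _bootstrap_ci(values, stat, n_boot, rng, level=0.95):
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        return (np.nan, np.nan)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    stats = stat(values[idx], axis=1)
    lo, hi = np.percentile(stats, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def peri_summary(
    ts: TrackSet,
    n_boot: int = 2000,
    seed: int = 0,
    exclude_saturated: bool = True,
) -> PeriConstrictionSummary:
    """Per-cell pre/post speed & directionality and population medians.

    Post-segment kinematics are computed on frames up to the saturation onset
    (``geometry.saturation_x``) by default, because cells arrest in the
    near-saturating chemoattractant zone and the arrested tail is not part of
    the migratory response.  ``post_euclidean`` (pillar exit to final point)
    always uses the full post segment.  Bootstrap CIs (percentile, seeded)
    are reported for the population medians and paired post/pre ratios.
    """
    geom = ts.geometry
    rows = []
    for t in ts:
        seg = split_at_constriction(t, geom)
        entered = seg.during.size > 0 or seg.post.size > 0
        crossed = seg.post.size > 0
        pre_speed, pre_dir = _segment_metrics(t, seg.pre)

        post_idx = seg.post
        if exclude_saturated and post_idx.size:
            inside = post_idx[t.x[post_idx] <= geom.saturation_x]
            post_kin_idx = inside if inside.size >= 2 else post_idx
        else:
            post_kin_idx = post_idx
        post_speed, post_dir = _segment_metrics(t, post_kin_idx)

        if crossed:
            x0, y0 = t.x[post_idx[0]], t.y[post_idx[0]]
            post_euc = float(np.hypot(t.x[-1] - x0, t.y[-1] - y0))
            crossing_frame = int(t.frames[post_idx[0]])
        else:
            post_euc, crossing_frame = np.nan, -1
        rows.append(
            {
                "track_id": t.track_id,
                "entered": entered,
                "crossed": crossed,
                "pre_speed": pre_speed,
                "post_speed": post_speed,
                "pre_dir": pre_dir,
                "post_dir": post_dir,
                "speed_ratio": post_speed / pre_speed if pre_speed else np.nan,
                "dir_ratio": post_dir / pre_dir if pre_dir else np.nan,
                "post_euclidean": post_euc,
                "crossing_frame": crossing_frame,
                "fmi": forward_migration_index(t),
            }
        )
    per_cell = pd.DataFrame(rows)

    n_entered = int(per_cell["entered"].sum()) if len(per_cell) else 0
    n_crossed = int(per_cell["crossed"].sum()) if len(per_cell) else 0
    crossing_fraction = n_crossed / n_entered if n_entered else 0.0

    rng = np.random.default_rng(seed)
    medians, ratios = {}, {}
    for col in ("pre_speed", "post_speed", "pre_dir", "post_dir", "post_euclidean"):
        vals = per_cell[col].to_numpy(dtype=float) if len(per_cell) else np.array([])
        ok = vals[~np.isnan(vals)]
        medians[col] = float(np.median(ok)) if ok.size else None
    # post/pre ratios as ratio-of-medians with a paired (per-cell) bootstrap;
    # the median of per-cell ratios carries a Jensen-type skew and is only
    # kept as a per-cell column
    for name, pre_col, post_col in (
        ("speed_ratio", "pre_speed", "post_speed"),
        ("dir_ratio", "pre_dir", "post_dir"),
    ):
        if len(per_cell):
            pair = per_cell[[pre_col, post_col]].dropna().to_numpy(dtype=float)
        else:
            pair = np.empty((0, 2))
        if pair.shape[0] >= 2 and np.median(pair[:, 0]) > 0:
            point = float(np.median(pair[:, 1]) / np.median(pair[:, 0]))
            idx = rng.integers(0, pair.shape[0], size=(n_boot, pair.shape[0]))
            boots = (np.median(pair[idx, 1], axis=1)
                     / np.median(pair[idx, 0], axis=1))
            lo, hi = np.percentile(boots, [2.5, 97.5])
            ratios[name] = {"median": point, "ci95": [float(lo), float(hi)]}
        else:
            ratios[name] = {"median": None, "ci95": [None, None]}

    return PeriConstrictionSummary(
        per_cell=per_cell,
        crossing_fraction=float(crossing_fraction),
        medians=medians,
        ratios=ratios,
        n_entered=n_entered,
        n_crossed=n_crossed,
    )


def eccentricity_timecourse(ts: TrackSet) -> dict:
    """Cohort mean eccentricity by region {before, during, after}.

    Requires per-frame ``eccentricity`` attachments; cells without a during
    (or post) segment simply contribute nothing to that region.
    """
    pools = {"before": [], "during": [], "after": []}
    for t in ts:
        if "eccentricity" not in t.attachments:
            raise InvalidParameterError(
                f"track {t.track_id}: missing eccentricity attachment"
            )
        ecc = t.attachments["eccentricity"]
        seg = split_at_constriction(t, ts.geometry)
        pools["before"].extend(ecc[seg.pre])
        pools["during"].extend(ecc[seg.during])
        pools["after"].extend(ecc[seg.post])
    return {
        region: (float(np.mean(v)) if v else None) for region, v in pools.items()
    }
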