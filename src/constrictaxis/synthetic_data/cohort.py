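"""Agent-based cohort simulator: biased persistent random walk through a
single constriction, with phenotype-dependent post-constriction behaviour.

Model
-----
Each cell updates a heading unit vector as
``heading' = rotate(normalize(persistence * heading + gradient_bias * x_hat),
eta)`` with ``eta ~ N(0, sigma)`` and steps by ``base_speed * dt`` with
multiplicative log-normal jitter.  On first reaching the pillar leading edge
the cell dwells a geometric number of frames in the constriction mouth, then
traverses the pillar in a straight line and continues with the post-exit
modifiers applied.  Side walls reflect; speed decays linearly to near zero
beyond the saturation onset.

``post_directionality_factor`` is the target multiplier on the *measured*
confinement ratio (net displacement / path length).  Because the mapping
from angular noise to confinement ratio is nonlinear and the confinement
ratio of a finite segment exceeds its asymptotic value (lateral excursions
inflate the net displacement), the generator inverts the mapping
numerically: the median confinement ratio of a segment of the expected
pre-/post-segment length is estimated with a seeded Monte-Carlo chain
(common random numbers, so the estimate is smooth and monotone in the noise
level) and bisected to find the post-exit noise whose expected measured
ratio is the pre-exit value times the factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from ..device import DeviceGeometry
from ..errors import InvalidParameterError
from ..kinematics import Track, TrackSet

__all__ = ["PhenotypeParams", "SimulatedCohort", "simulate_cohort", "PHENOTYPE_PRESETS"]


@dataclass(frozen=True)
class PhenotypeParams:
    """Generator-side ground truth for one cell population."""

    label: str = "control"
    base_speed: float = 12.0  # um/min
    persistence: float = 0.5  # 0..1
    gradient_bias: float = 1.0  # >= 0
    noise_sigma: float = 0.9  # radians per step
    post_speed_factor: float = 1.0
    post_directionality_factor: float = 1.0
    spike_prob: float = 0.5
    polarity_loss_prob: float = 0.2
    dwell_mean_frames: float = 4.0
    vesicle_median_pre: int = 4
    vesicle_median_post: int = 7
    step_jitter_cv: float = 0.15
    speed_cv_cell: float = 0.10  # per-cell lognormal speed heterogeneity
    pass_prob: float = 1.0  # hook; passage is guaranteed by default
    ecc_pre: float = 0.80
    ecc_during: float = 0.92
    ecc_post_polarized: float = 0.85
    ecc_post_depolarized: float = 0.55

    def __post_init__(self):
        for name in ("persistence", "spike_prob", "polarity_loss_prob", "pass_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if self.base_speed <= 0:
            raise InvalidParameterError("base_speed must be positive")
        if self.gradient_bias < 0 or self.noise_sigma < 0:
            raise InvalidParameterError("gradient_bias and noise_sigma must be >= 0")
        for name in ("post_speed_factor", "post_directionality_factor"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.dwell_mean_frames < 0 or self.step_jitter_cv < 0 \
                or self.speed_cv_cell < 0:
            raise InvalidParameterError(
                "dwell_mean_frames/step_jitter_cv/speed_cv_cell must be >= 0"
            )


#: qualitative phenotype contrasts shipped as defaults
PHENOTYPE_PRESETS = {
    "control": PhenotypeParams(label="control"),
    "knockout": PhenotypeParams(
        label="knockout",
        post_speed_factor=0.6,
        post_directionality_factor=0.75,
        spike_prob=0.0,
        polarity_loss_prob=0.8,
    ),
    "overexpresser": PhenotypeParams(
        label="overexpresser",
        post_speed_factor=1.1,
        post_directionality_factor=1.3,
        spike_prob=0.6,
        polarity_loss_prob=0.05,
    ),
}


@dataclass(frozen=True)
class SimulatedCohort:
    tracks: TrackSet
    traces: tuple = ()
    ground_truth: dict = field(default_factory=dict)
    seed: int = 0
    geometry: DeviceGeometry = field(default_factory=DeviceGeometry)
    phenotype: PhenotypeParams = field(default_factory=PhenotypeParams)

    def __post_init__(self):
        ids = sorted(t.track_id for t in self.tracks)
        if ids != sorted(self.ground_truth):
            raise InvalidParameterError("ground_truth must cover every track exactly once")


def _stationary_dircos(
    persistence: float, bias: float, sigma: float,
    n_chains: int = 512, n_steps: int = 600, burn: int = 150,
) -> float:
    """Stationary E[cos(heading angle)] of the angle recursion, by seeded MC.

    Uses a fixed internal seed and scales the same normal draws by sigma
    (common random numbers), making the estimate deterministic, smooth and
    monotone in sigma — safe to bisect.
    """
    if sigma == 0.0:
        return 1.0
    rng = np.random.default_rng(987654321)
    raw = rng.normal(size=(n_steps, n_chains))
    theta = sigma * raw[0]
    acc = 0.0
    count = 0
    for k in range(1, n_steps):
        hx = persistence * np.cos(theta) + bias
        hy = persistence * np.sin(theta)
        theta = np.arctan2(hy, hx) + sigma * raw[k]
        if k >= burn:
            acc += float(np.cos(theta).sum())
            count += n_chains
    return acc / count


def _span_dir_median(
    persistence: float, bias: float, sigma: float, span_steps: float,
    jitter_cv: float, n_chains: int = 2048, burn: int = 100,
    max_steps: int = 500,
) -> float:
    """Median confinement ratio of a walk segment spanning a fixed x-distance.

    Emulates how the pipeline measures a segment: the walk runs until its
    cumulative x-progress first reaches ``span_steps`` (in units of the mean
    step length) and the confinement ratio is taken over the steps *before*
    that first passage, matching the splitter's frame assignment.  A fixed
    internal seed with sigma-scaled draws makes the value deterministic and
    monotone in sigma — safe to bisect.
    """
    if sigma == 0.0:
        return 1.0
    rng = np.random.default_rng(246813579)
    raw = rng.normal(size=(burn + max_steps, n_chains))
    if jitter_cv > 0:
        s2 = math.log1p(jitter_cv * jitter_cv)
        lengths = np.exp(
            math.sqrt(s2) * rng.normal(size=(max_steps, n_chains)) - s2 / 2.0
        )
    else:
        lengths = np.ones((max_steps, n_chains))
    theta = sigma * raw[0]
    for k in range(1, burn):
        hx = persistence * np.cos(theta) + bias
        hy = persistence * np.sin(theta)
        theta = np.arctan2(hy, hx) + sigma * raw[k]

    X = np.zeros(n_chains)
    Y = np.zeros(n_chains)
    P = np.zeros(n_chains)
    dir_at_crossing = np.full(n_chains, np.nan)
    alive = np.ones(n_chains, dtype=bool)
    prev = np.zeros((3, n_chains))
    for k in range(max_steps):
        prev[0], prev[1], prev[2] = X, Y, P
        hx = persistence * np.cos(theta) + bias
        hy = persistence * np.sin(theta)
        theta = np.arctan2(hy, hx) + sigma * raw[burn + k]
        X = X + lengths[k] * np.cos(theta)
        Y = Y + lengths[k] * np.sin(theta)
        P = P + lengths[k]
        crossed = alive & (X >= span_steps) & (prev[2] > 0)
        if crossed.any():
            dir_at_crossing[crossed] = (
                np.hypot(prev[0][crossed], prev[1][crossed]) / prev[2][crossed]
            )
            alive &= ~crossed
        if not alive.any():
            break
    # chains that never crossed (strong wanderers) use their full segment
    rest = np.isnan(dir_at_crossing)
    if rest.any():
        dir_at_crossing[rest] = np.hypot(X[rest], Y[rest]) / P[rest]
    return float(np.median(np.clip(dir_at_crossing, 0.0, 1.0)))


@lru_cache(maxsize=256)
def _calibrate_post_sigma(
    persistence: float, bias: float, sigma_pre: float, jitter_cv: float,
    factor: float, step_um: float, x0_mean: float,
    cx: float, ex: float, sat_x: float, speed_factor: float,
) -> float:
    if factor == 1.0:
        return sigma_pre
    span_pre = (cx - x0_mean) / step_um  # in mean-step units
    dir_pre = _span_dir_median(persistence, bias, sigma_pre, span_pre, jitter_cv)
    target = min(factor * dir_pre, 0.999)

    # post span in units of the post-exit mean step length
    span_post = (sat_x - ex) / (step_um * speed_factor)
    lo, hi = 0.0, 4.0
    if _span_dir_median(persistence, bias, hi, span_post, jitter_cv) > target:
        return hi
    for _ in range(35):
        mid = 0.5 * (lo + hi)
        if _span_dir_median(persistence, bias, mid, span_post, jitter_cv) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def post_noise_sigma(
    phenotype: PhenotypeParams,
    geometry: DeviceGeometry | None = None,
    dt: float = 30.0,
    mean_start_x: float = 6.0,
) -> float:
    """Post-exit angular noise implementing ``post_directionality_factor``
    for the expected pre/post segment lengths in this geometry."""
    geom = geometry or DeviceGeometry()
    p = phenotype
    return _calibrate_post_sigma(
        round(p.persistence, 6), round(p.gradient_bias, 6),
        round(p.noise_sigma, 6), round(p.step_jitter_cv, 6),
        round(p.post_directionality_factor, 6),
        round(p.base_speed / 60.0 * dt, 6), round(mean_start_x, 3),
        geom.constriction_x, geom.exit_x, geom.saturation_x,
        round(p.post_speed_factor, 6),
    )


def _lognormal_jitter(rng, cv: float, size=None):
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    s2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


def simulate_cohort(
    phenotype: PhenotypeParams,
    n_cells: int,
    geometry: DeviceGeometry | None = None,
    dt: float = 30.0,
    n_frames: int = 180,
    seed: int = 0,
    start_x: tuple = (2.0, 10.0),
    start_y_fraction: tuple = (0.25, 0.75),
) -> SimulatedCohort:
    """Simulate ``n_cells`` tracks through the constricted chamber.

    Returns a :class:`SimulatedCohort` whose ground truth records every
    latent draw needed for recovery tests (dwell frames, polarity state,
    post-exit shape mode, noise levels).
    """
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    if n_frames < 2 or dt <= 0:
        raise InvalidParameterError("need n_frames >= 2 and dt > 0")
    geom = geometry or DeviceGeometry()
    p = phenotype
    sigma_pre = p.noise_sigma
    sigma_post = post_noise_sigma(p, geom, dt, mean_start_x=0.5 * (start_x[0] + start_x[1]))

    step_base = p.base_speed / 60.0 * dt  # um per frame
    cx, ex, L, W = geom.constriction_x, geom.exit_x, geom.chamber_length, geom.chamber_width
    dwell_x = cx + min(1.0, geom.pillar_extent / 4.0)

    children = np.random.SeedSequence(seed).spawn(n_cells)
    tracks = []
    truth = {}
    for cid in range(n_cells):
        rng = np.random.default_rng(children[cid])
        cell_speed_factor = float(_lognormal_jitter(rng, p.speed_cv_cell))
        cell_step = step_base * cell_speed_factor
        x = np.empty(n_frames)
        y = np.empty(n_frames)
        ecc = np.empty(n_frames)

        x[0] = rng.uniform(*start_x)
        y[0] = rng.uniform(start_y_fraction[0] * W, start_y_fraction[1] * W)
        regime = "pre" if x[0] < cx else "free"
        sigma = sigma_pre
        speed_factor = 1.0
        # stationary initial deviation from +x (or isotropic without drive)
        drive = p.persistence + p.gradient_bias
        if drive <= 0:
            theta = rng.uniform(-np.pi, np.pi)
        else:
            theta = sigma * rng.normal() if sigma > 0 else 0.0
        dwell_left = 0
        dwell_frames = 0
        crossed = False
        crossing_frame = -1
        polarity_lost = None
        will_spike = False

        ecc[0] = _ecc_sample(rng, p, regime, polarity_lost)
        for k in range(1, n_frames):
            if regime == "dwell":
                x[k] = x[k - 1]
                y[k] = y[k - 1]
                dwell_left -= 1
                if dwell_left <= 0:
                    regime = "pass"
                ecc[k] = _ecc_sample(rng, p, "dwell", polarity_lost)
                continue

            if regime == "pass":
                step = cell_step * _lognormal_jitter(rng, p.step_jitter_cv)
                x[k] = x[k - 1] + step
                y[k] = y[k - 1]
                if x[k] > ex:
                    regime = "post"
                    crossed = True
                    crossing_frame = k
                    speed_factor = p.post_speed_factor
                    sigma = sigma_post
                    polarity_lost = bool(rng.random() < p.polarity_loss_prob)
                    will_spike = bool(rng.random() < p.spike_prob)
                    theta = sigma * rng.normal() if sigma > 0 else 0.0
                    ecc[k] = _ecc_sample(rng, p, "post", polarity_lost)
                else:
                    ecc[k] = _ecc_sample(rng, p, "dwell", polarity_lost)
                continue

            # pre / free / post: biased persistent random walk step
            hx = p.persistence * np.cos(theta) + p.gradient_bias
            hy = p.persistence * np.sin(theta)
            if hx == 0.0 and hy == 0.0:
                base = rng.uniform(-np.pi, np.pi)
            else:
                base = math.atan2(hy, hx)
            theta = base + (sigma * rng.normal() if sigma > 0 else 0.0)

            step = cell_step * speed_factor * _lognormal_jitter(rng, p.step_jitter_cv)
            sat = _saturation_factor(x[k - 1], geom)
            step *= sat
            nx_ = x[k - 1] + step * math.cos(theta)
            ny_ = y[k - 1] + step * math.sin(theta)

            # reflective side walls and inlet wall
            if ny_ < 0:
                ny_, theta = -ny_, -theta
            elif ny_ > W:
                ny_, theta = 2 * W - ny_, -theta
            if nx_ < 0:
                nx_ = -nx_
                theta = math.pi - theta
            nx_ = min(nx_, L)

            if regime == "pre" and nx_ >= cx:
                # arrival at the constriction mouth
                nx_, ny_ = dwell_x, y[k - 1]
                dwell_frames = int(rng.geometric(1.0 / p.dwell_mean_frames)) \
                    if p.dwell_mean_frames > 0 else 0
                dwell_left = dwell_frames - 1
                regime = "dwell" if dwell_left > 0 else "pass"
                x[k], y[k] = nx_, ny_
                ecc[k] = _ecc_sample(rng, p, "dwell", polarity_lost)
                continue

            x[k], y[k] = nx_, ny_
            ecc[k] = _ecc_sample(rng, p, regime, polarity_lost)

        frames = np.arange(n_frames)
        tracks.append(
            Track(
                track_id=cid,
                frames=frames,
                times=frames * dt,
                x=x,
                y=y,
                attachments={"eccentricity": ecc},
            )
        )
        truth[cid] = {
            "phenotype": p.label,
            "start": (float(x[0]), float(y[0])),
            "dwell_frames": dwell_frames,
            "crossed": crossed,
            "crossing_frame": crossing_frame,
            "polarity_lost": polarity_lost,
            "will_spike": will_spike,
            "shape_mode_post": (
                "keratocyte" if crossed and polarity_lost is False else "amoeboid"
            ),
            "cell_speed_factor": cell_speed_factor,
            "sigma_pre": float(sigma_pre),
            "sigma_post": float(sigma_post),
        }

    ts = TrackSet(
        tracks=tuple(tracks),
        frame_interval=dt,
        geometry=geom,
        provenance={"source": "simulate_cohort", "seed": seed, "phenotype": p.label},
    )
    return SimulatedCohort(
        tracks=ts, traces=(), ground_truth=truth, seed=seed, geometry=geom, phenotype=p
    )


def _saturation_factor(x: float, geom: DeviceGeometry) -> float:
    """Linear speed decay to near zero beyond the saturation onset."""
    if x < geom.saturation_x:
        return 1.0
    span = geom.chamber_length - geom.saturation_x
    return max(1.0 - (x - geom.saturation_x) / span, 0.05)


def _ecc_sample(rng, p: PhenotypeParams, regime: str, polarity_lost) -> float:
    if regime in ("pre", "free"):
        mu, sd = p.ecc_pre, 0.03
    elif regime in ("dwell", "pass"):
        mu, sd = p.ecc_during, 0.02
    else:  # post
        if polarity_lost:
            mu, sd = p.ecc_post_depolarized, 0.05
        else:
            mu, sd = p.ecc_post_polarized, 0.03
    return float(np.clip(rng.normal(mu, sd), 0.0, 0.99))


def with_traces(cohort: SimulatedCohort, traces, truth_updates: dict) -> SimulatedCohort:
    """Return a copy of the cohort carrying calcium traces + updated truth."""
    truth = {k: dict(v) for k, v in cohort.ground_truth.items()}
    for cid, upd in truth_updates.items():
        truth[cid].update(upd)
    return replace(cohort, traces=tuple(traces), ground_truth=truth)
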