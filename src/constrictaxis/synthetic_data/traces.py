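"""Synthetic calcium traces with post-constriction spikes."""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from ..errors import InvalidParameterError
from ..intensity import CalciumTrace
from .cohort import SimulatedCohort, with_traces

__all__ = ["generate_calcium_traces"]


def generate_calcium_traces(
    cohort: SimulatedCohort,
    baseline: float = 100.0,
    noise_cv: float = 0.05,
    spike_amp: float = 400.0,
    spike_decay: float = 90.0,
    seed: int = 0,
) -> SimulatedCohort:
    """Attach a calcium trace to every track of the cohort.

    Each trace is ``baseline * (1 + Gaussian noise)``; with probability
    ``phenotype.spike_prob`` a crossed cell additionally receives one
    exponentially decaying spike whose onset lies within one cell length
    after the pillar exit.  Spike times go into the ground truth.
    """
    if baseline <= 0 or noise_cv < 0 or spike_amp < 0 or spike_decay <= 0:
        raise InvalidParameterError("invalid trace generator parameters")
    if not len(cohort.tracks):
        raise InvalidParameterError("cohort has no tracks")

    geom = cohort.geometry
    children = np.random.SeedSequence(seed).spawn(len(cohort.tracks))

    traces = []
    truth_updates = {}
    new_tracks = []
    for t, child in zip(cohort.tracks, children):
        rng = np.random.default_rng(child)
        n = len(t)
        inten = baseline * (1.0 + noise_cv * rng.normal(size=n))
        inten = np.clip(inten, 0.0, None)

        gt = cohort.ground_truth[t.track_id]
        spiked = False
        spike_time = None
        # the spike identity is a per-cell phenotype latent drawn by the walk
        # simulator at crossing time; this stage realizes its timing and shape
        if gt["crossed"] and gt.get("will_spike"):
            post = np.nonzero(
                (t.x > geom.exit_x) & (t.x <= geom.exit_x + geom.cell_length)
            )[0]
            if post.size == 0:
                post = np.nonzero(t.x > geom.exit_x)[0][:1]
            if post.size:
                onset = int(rng.choice(post))
                tt = t.times[onset:] - t.times[onset]
                inten[onset:] += spike_amp * np.exp(-tt / spike_decay)
                spiked = True
                spike_time = float(t.times[onset])

        traces.append(
            CalciumTrace(track_id=t.track_id, times=t.times, intensity=inten, x=t.x)
        )
        truth_updates[t.track_id] = {"spiked": spiked, "spike_time": spike_time}
        attachments = dict(t.attachments)
        attachments["intensity"] = inten
        new_tracks.append(replace(t, attachments=attachments))

    cohort = replace(cohort, tracks=replace(cohort.tracks, tracks=tuple(new_tracks)))
    return with_traces(cohort, traces, truth_updates)
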