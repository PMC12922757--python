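"""Per-cell vesicle counts (negative binomial, median-parameterized) paired
with a synthetic cortical-polarity readout for scatter summaries."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import InvalidParameterError
from .cohort import SimulatedCohort

__all__ = ["generate_vesicle_counts", "nbinom_mean_for_median"]


@lru_cache(maxsize=64)
def nbinom_mean_for_median(median: int, dispersion: float = 5.0) -> float:
    """Mean of a negative binomial (size ``dispersion``) whose median is
    ``median``; the midpoint of the mean-interval achieving that median."""
    if median < 0:
        raise InvalidParameterError("median must be >= 0")

    def med(mu):
        return stats.nbinom(dispersion, dispersion / (dispersion + mu)).median()

    mus = np.linspace(max(median - 2.0, 0.05), median + 3.0, 1200)
    hits = [m for m in mus if med(m) == median]
    if not hits:
        raise InvalidParameterError(
            f"no negative-binomial mean with median {median} at dispersion {dispersion}"
        )
    return float(0.5 * (hits[0] + hits[-1]))


def generate_vesicle_counts(
    cohort: SimulatedCohort,
    seed: int = 0,
    dispersion: float = 5.0,
    polarity_slope: float = 0.12,
    polarity_noise: float = 0.1,
) -> pd.DataFrame:
    """Draw (pre, post) envelope-derived vesicle counts per cell.

    Counts are negative binomial with medians taken from the phenotype
    (``vesicle_median_pre`` / ``vesicle_median_post``); cells that did not
    cross keep the pre median after the constriction.  A synthetic
    cortex-to-cytosol polarity ratio correlated with the count increase is
    attached for scatter summaries.
    """
    p = cohort.phenotype
    mu_pre = nbinom_mean_for_median(p.vesicle_median_pre, dispersion)
    mu_post = nbinom_mean_for_median(p.vesicle_median_post, dispersion)
    rng = np.random.default_rng(seed)

    rows = []
    for t in cohort.tracks:
        gt = cohort.ground_truth[t.track_id]
        pre = int(rng.negative_binomial(dispersion, dispersion / (dispersion + mu_pre)))
        mu2 = mu_post if gt["crossed"] else mu_pre
        post = int(rng.negative_binomial(dispersion, dispersion / (dispersion + mu2)))
        pmlc = max(
            1.0 + polarity_slope * (post - pre) + polarity_noise * rng.normal(), 0.2
        )
        rows.append(
            {
                "track_id": t.track_id,
                "pre_count": pre,
                "post_count": post,
                "pmlc_ratio": pmlc,
            }
        )
        cohort.ground_truth[t.track_id] = {
            **gt, "vesicle_pre": pre, "vesicle_post": post, "pmlc_ratio": pmlc,
        }
    return pd.DataFrame(rows)
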