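"""Peri-constriction calcium analysis and single-cell intensity metrics.

Windows for the calcium fold change are one cell length (default 25 um)
immediately before the pillar leading edge and immediately after the pillar
exit.  All ratio/fraction outputs are invariant to global intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, median_filter
from scipy.signal import find_peaks
from skimage.morphology import disk

from .device import DeviceGeometry
from .errors import InvalidParameterError, MaskError

__all__ = [
    "CalciumTrace",
    "RegionRatio",
    "ColocResult",
    "SpikeResult",
    "calcium_fold_change",
    "detect_spikes",
    "cortex_cytosol_ratio",
    "ne_fraction",
    "manders",
    "max_entropy_threshold",
]


@dataclass(frozen=True)
class CalciumTrace:
    """Per-cell fluorescence indexed by time and x-position along the axis."""

    track_id: int
    times: np.ndarray  # s
    intensity: np.ndarray  # a.u., >= 0
    x: np.ndarray  # um

    def __post_init__(self):
        if not (len(self.times) == len(self.intensity) == len(self.x)):
            raise InvalidParameterError("trace arrays must have equal length")
        if np.any(np.asarray(self.intensity) < 0):
            raise InvalidParameterError("intensity must be non-negative")

    def __len__(self):
        return len(self.times)


@dataclass(frozen=True)
class RegionRatio:
    cortex_mean: float
    cytosol_mean: float
    ratio: float  # cortex / cytosol (nucleus excluded when mask given)
    ratio_whole_interior: float  # cortex / whole eroded interior
    band_width: int
    label: int


@dataclass(frozen=True)
class ColocResult:
    M1: float | None
    M2: float | None
    threshold1: float
    threshold2: float


@dataclass(frozen=True)
class SpikeResult:
    times: np.ndarray
    indices: np.ndarray
    post_constriction: np.ndarray  # bool per spike


def calcium_fold_change(
    trace: CalciumTrace,
    geometry: DeviceGeometry,
    use_peak: bool = False,
):
    """Post-window / pre-window intensity ratio.

    Pre window: ``[constriction_x - cell_length, constriction_x)``;
    post window: ``(exit_x, exit_x + cell_length]``, both along x.  Mean
    intensity by default, window peak with ``use_peak``.  Returns ``None``
    when the trace does not cover both windows (not-evaluable sentinel).
    """
    x = np.asarray(trace.x, dtype=float)
    inten = np.asarray(trace.intensity, dtype=float)
    cx, ex, cl = geometry.constriction_x, geometry.exit_x, geometry.cell_length
    pre = (x >= cx - cl) & (x < cx)
    post = (x > ex) & (x <= ex + cl)
    if not pre.any() or not post.any():
        return None
    agg = np.max if use_peak else np.mean
    pre_val = float(agg(inten[pre]))
    if pre_val == 0:
        return None
    return float(agg(inten[post])) / pre_val


def detect_spikes(
    trace: CalciumTrace,
    k_mad: float = 5.0,
    min_separation: float | None = None,
    baseline_window: int = 15,
    geometry: DeviceGeometry | None = None,
) -> SpikeResult:
    """Robust spike detection on a calcium trace.

    A spike is a local maximum whose excursion above a rolling-median
    baseline exceeds ``k_mad`` times the MAD of the residual (scaled to
    sigma-equivalent).  ``min_separation`` is in seconds.  When a geometry is
    given, each spike carries a flag marking it as post-constriction
    (``x > exit_x``).
    """
    if len(trace) < 10:
        raise InvalidParameterError("need at least 10 samples to detect spikes")
    inten = np.asarray(trace.intensity, dtype=float)
    baseline = median_filter(inten, size=baseline_window, mode="nearest")
    resid = inten - baseline
    mad = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    height = k_mad * max(mad, 1e-12)

    distance = None
    if min_separation is not None:
        dt = float(np.median(np.diff(trace.times)))
        distance = max(int(round(min_separation / dt)), 1)
    peaks, _ = find_peaks(resid, height=height, distance=distance)

    if geometry is not None:
        post = np.asarray(trace.x, dtype=float)[peaks] > geometry.exit_x
    else:
        post = np.zeros(len(peaks), dtype=bool)
    return SpikeResult(
        times=np.asarray(trace.times, dtype=float)[peaks],
        indices=peaks,
        post_constriction=post,
    )


def _single_label_mask(mask: np.ndarray, label: int | None):
    mask = np.asarray(mask)
    if label is None:
        labels = np.unique(mask[mask > 0])
        if labels.size != 1:
            raise MaskError(
                f"expected a single cell label, found {labels.size}; pass label="
            )
        label = int(labels[0])
    return mask == label, int(label)


def cortex_cytosol_ratio(
    channel: np.ndarray,
    cell_mask: np.ndarray,
    band_width: int = 3,
    nucleus_mask: np.ndarray | None = None,
    label: int | None = None,
) -> RegionRatio:
    """Mean intensity in a boundary band over mean interior intensity.

    The cortex is the mask minus its erosion by a disk of radius
    ``band_width`` px; the cytosol is the eroded interior, minus the nucleus
    when a nucleus mask is supplied (the whole-interior variant is reported
    alongside).
    """
    if band_width <= 0:
        raise InvalidParameterError("band_width must be a positive pixel count")
    channel = np.asarray(channel, dtype=float)
    binary, lab = _single_label_mask(cell_mask, label)
    if channel.shape != binary.shape:
        raise MaskError("channel and cell mask shapes differ")

    interior = binary_erosion(binary, structure=disk(band_width))
    if not interior.any():
        raise MaskError(
            f"interior empty after {band_width}-px erosion; use a smaller band"
        )
    cortex = binary & ~interior
    cortex_mean = float(channel[cortex].mean())
    whole_interior_mean = float(channel[interior].mean())

    cytosol = interior
    if nucleus_mask is not None:
        cytosol = interior & ~(np.asarray(nucleus_mask) > 0)
        if not cytosol.any():
            raise MaskError("cytosol empty after removing nucleus")
    cytosol_mean = float(channel[cytosol].mean())
    return RegionRatio(
        cortex_mean=cortex_mean,
        cytosol_mean=cytosol_mean,
        ratio=cortex_mean / cytosol_mean,
        ratio_whole_interior=cortex_mean / whole_interior_mean,
        band_width=band_width,
        label=lab,
    )


def ne_fraction(
    channel: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    ne_band: int = 2,
):
    """Fractions of whole-cell integrated intensity in nuclear compartments.

    The nuclear-envelope (NE) band spans ``ne_band`` px on each side of the
    nuclear boundary (dilation minus erosion, clipped to the cell).  Returns
    ``(fraction_total_nuclear, fraction_nucleoplasm, fraction_NE)`` where
    total nuclear = nucleoplasm + NE up to rounding.
    """
    if ne_band <= 0:
        raise InvalidParameterError("ne_band must be a positive pixel count")
    channel = np.asarray(channel, dtype=float)
    cell = np.asarray(cell_mask) > 0
    nuc = np.asarray(nucleus_mask) > 0
    if channel.shape != cell.shape or cell.shape != nuc.shape:
        raise MaskError("channel/cell/nucleus shapes differ")
    if np.any(nuc & ~cell):
        raise MaskError("nucleus mask is not nested inside the cell mask")

    footprint = disk(ne_band)
    band = (binary_dilation(nuc, structure=footprint)
            & ~binary_erosion(nuc, structure=footprint)) & cell
    nucleoplasm = nuc & ~band
    nuclear = nucleoplasm | band

    total = float(channel[cell | band].sum())
    if total == 0:
        return None, None, None
    f_nuclear = float(channel[nuclear].sum()) / total
    f_nucleoplasm = float(channel[nucleoplasm].sum()) / total
    f_ne = float(channel[band].sum()) / total
    return f_nuclear, f_nucleoplasm, f_ne


def max_entropy_threshold(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    nbins: int = 256,
) -> float:
    """Kapur maximum-entropy histogram threshold.

    Picks the grey level maximizing the summed Shannon entropies of the
    below- and above-threshold histogram halves; returns a value such that
    foreground is ``image > t``.
    """
    image = np.asarray(image, dtype=float)
    vals = image[np.asarray(mask) > 0] if mask is not None else image.ravel()
    if vals.size == 0:
        raise InvalidParameterError("empty image/mask")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return lo
    hist, edges = np.histogram(vals, bins=nbins, range=(lo, hi))
    p = hist / hist.sum()
    cum = np.cumsum(p)

    best_t, best_h = edges[0], -np.inf
    for k in range(nbins - 1):
        w0 = cum[k]
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        p0 = p[: k + 1] / w0
        p1 = p[k + 1:] / w1
        h0 = -np.sum(p0[p0 > 0] * np.log(p0[p0 > 0]))
        h1 = -np.sum(p1[p1 > 0] * np.log(p1[p1 > 0]))
        if h0 + h1 > best_h:
            best_h = h0 + h1
            best_t = edges[k + 1]
    return float(best_t)


def manders(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask: np.ndarray | None = None,
    t1: float | None = None,
    t2: float | None = None,
) -> ColocResult:
    """Mander's co-occurrence coefficients.

    ``M1`` is the fraction of channel-1 intensity falling where channel 2
    exceeds its threshold (and symmetrically for ``M2``).  Thresholds default
    to the per-channel Kapur maximum-entropy split.  A zero denominator
    yields ``None`` for the affected coefficient.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise InvalidParameterError("channel shapes differ")
    sel = np.ones(ch1.shape, dtype=bool) if mask is None else np.asarray(mask) > 0
    if t1 is None:
        t1 = max_entropy_threshold(ch1, sel)
    if t2 is None:
        t2 = max_entropy_threshold(ch2, sel)

    a1 = ch1[sel]
    a2 = ch2[sel]
    s1, s2 = a1.sum(), a2.sum()
    m1 = float(a1[a2 > t2].sum() / s1) if s1 > 0 else None
    m2 = float(a2[a1 > t1].sum() / s2) if s2 > 0 else None
    return ColocResult(M1=m1, M2=m2, threshold1=float(t1), threshold2=float(t2))
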