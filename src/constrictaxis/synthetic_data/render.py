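"""Rasterize cohort frames into channel images and ground-truth label masks.

Amoeboid cells are elongated ellipses with the major axis along the heading;
keratocyte-like cells are ellipses with the major axis perpendicular to the
heading (axis ratio 2, i.e. eccentricity sqrt(3)/2).  The cortical-marker
channel is uniform inside the cell with a boundary band multiplied by
``cortical_ratio``; the band width in pixels matches the analysis default so
the identity fixture closes.  Nuclei are ~4-um ellipses, squeezed to the gap
width while the cell is inside the pillar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from ..device import classify_position
from ..errors import InvalidParameterError, RenderOverlapError
from .cohort import SimulatedCohort

__all__ = ["RenderedFrame", "render_frames", "draw_cell"]

#: must match intensity.cortex_cytosol_ratio's default band
CORTICAL_BAND_PX = 3

_AMOEBOID_AXES = (7.0, 4.2)  # um semi-axes (major along heading)
_KERATOCYTE_AXES = (8.0, 4.0)  # um, major perpendicular to heading
_NUCLEUS_RADIUS = 2.0  # um (~4 um diameter)


@dataclass(frozen=True)
class RenderedFrame:
    channels: dict  # name -> 2D float array
    cell_mask: np.ndarray  # uint16 labels, 0 background
    nucleus_mask: np.ndarray
    pixel_size: float  # um/px
    frame_index: int

    def __post_init__(self):
        for name, ch in self.channels.items():
            if ch.shape != self.cell_mask.shape:
                raise InvalidParameterError(f"channel {name!r} shape mismatch")
        if self.nucleus_mask.shape != self.cell_mask.shape:
            raise InvalidParameterError("mask shapes differ")


def _ellipse_mask(shape, cy, cx, a, b, angle_rad):
    """Pixels of an ellipse with semi-axes a (along angle) and b."""
    rr, cc = draw_ellipse(cy, cx, b, a, shape=shape, rotation=-angle_rad)
    return rr, cc


def draw_cell(
    shape: tuple,
    center_px: tuple,
    heading_rad: float,
    mode: str,
    pixel_size: float,
    squeezed_gap_um: float | None = None,
):
    """Return (cell_rr, cell_cc, nuc_rr, nuc_cc) pixel coordinates."""
    cy, cx = center_px
    if mode == "keratocyte":
        a, b = (ax / pixel_size for ax in _KERATOCYTE_AXES)
        angle = heading_rad + np.pi / 2.0
    else:
        a, b = (ax / pixel_size for ax in _AMOEBOID_AXES)
        angle = heading_rad
    cell = _ellipse_mask(shape, cy, cx, a, b, angle)

    r = _NUCLEUS_RADIUS / pixel_size
    if squeezed_gap_um is not None and squeezed_gap_um < 2 * _NUCLEUS_RADIUS:
        # squeeze to the gap while conserving area
        ry = (squeezed_gap_um / 2.0) / pixel_size
        rx = r * r / ry
        nuc = draw_ellipse(cy, cx, ry, rx, shape=shape)
    else:
        nuc = draw_ellipse(cy, cx, r, r, shape=shape)
    return cell, nuc


def render_frames(
    cohort: SimulatedCohort,
    pixel_size: float = 0.5,
    frame_indices=None,
    cortical_ratio: float = 2.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    max_retries: int = 10,
    on_overlap: str = "jitter",
) -> list[RenderedFrame]:
    """Render selected frames of a cohort.

    Overlapping cells are re-jittered up to ``max_retries`` times and then
    raise :class:`RenderOverlapError` (``on_overlap="skip"`` drops the
    offending cell instead, for bulk rendering).
    """
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be positive")
    if cortical_ratio < 1.0:
        raise InvalidParameterError("cortical_ratio must be >= 1")
    if on_overlap not in ("jitter", "skip"):
        raise InvalidParameterError("on_overlap must be 'jitter' or 'skip'")
    geom = cohort.geometry
    ny = int(round(geom.chamber_width / pixel_size))
    nx = int(round(geom.chamber_length / pixel_size))
    shape = (ny, nx)
    rng = np.random.default_rng(seed)

    traces = {tr.track_id: tr for tr in cohort.traces}
    n_frames = max(len(t) for t in cohort.tracks)
    if frame_indices is None:
        frame_indices = range(n_frames)

    out = []
    for fi in frame_indices:
        cell_mask = np.zeros(shape, dtype=np.uint16)
        nucleus_mask = np.zeros(shape, dtype=np.uint16)
        membrane = np.zeros(shape)
        nucleus_ch = np.zeros(shape)
        calcium = np.zeros(shape)
        cortical = np.zeros(shape)

        for t in cohort.tracks:
            pos = np.nonzero(t.frames == fi)[0]
            if pos.size == 0:
                continue
            i = int(pos[0])
            gt = cohort.ground_truth[t.track_id]
            x_um, y_um = float(t.x[i]), float(t.y[i])
            region = classify_position(min(x_um, geom.chamber_length), geom)
            if region == "after" and gt.get("crossed"):
                mode = gt.get("shape_mode_post", "amoeboid")
            else:
                mode = "amoeboid"
            if i + 1 < len(t):
                heading = np.arctan2(t.y[i + 1] - t.y[i], t.x[i + 1] - t.x[i])
            elif i > 0:
                heading = np.arctan2(t.y[i] - t.y[i - 1], t.x[i] - t.x[i - 1])
            else:
                heading = 0.0
            squeezed = geom.gap_width if region == "during" else None

            placed = False
            cy, cx_ = y_um / pixel_size, x_um / pixel_size
            for attempt in range(max_retries + 1):
                cell, nuc = draw_cell(shape, (cy, cx_), heading, mode,
                                      pixel_size, squeezed)
                if cell[0].size == 0:
                    break
                if np.any(cell_mask[cell]):
                    jitter = rng.uniform(-10, 10, size=2) / pixel_size
                    cy = np.clip(y_um / pixel_size + jitter[0], 0, ny - 1)
                    cx_ = np.clip(x_um / pixel_size + jitter[1], 0, nx - 1)
                    continue
                lab = t.track_id + 1
                cell_mask[cell] = lab
                nucleus_mask[nuc] = lab
                membrane[cell] = 150.0
                nucleus_ch[nuc] = 200.0
                trace = traces.get(t.track_id)
                cal = float(trace.intensity[i]) if trace is not None and i < len(trace) else 100.0
                calcium[cell] = cal
                cortical[cell] = 100.0
                placed = True
                break
            if not placed and cell[0].size:
                if on_overlap == "jitter":
                    raise RenderOverlapError(
                        f"cell {t.track_id} frame {fi}: could not place without "
                        f"overlap after {max_retries} retries"
                    )
                continue  # skip

        # cortical band: boundary shell of each cell, matching the analysis band
        from scipy.ndimage import binary_erosion
        from skimage.morphology import disk as _disk

        for lab in np.unique(cell_mask[cell_mask > 0]):
            m = cell_mask == lab
            interior = binary_erosion(m, structure=_disk(CORTICAL_BAND_PX))
            band = m & ~interior
            cortical[band] *= cortical_ratio

        if noise_sd > 0:
            for ch in (membrane, nucleus_ch, calcium, cortical):
                ch += rng.normal(0.0, noise_sd, size=shape)
                np.clip(ch, 0.0, None, out=ch)

        out.append(
            RenderedFrame(
                channels={
                    "membrane": membrane,
                    "nucleus": nucleus_ch,
                    "calcium": calcium,
                    "cortical": cortical,
                },
                cell_mask=cell_mask,
                nucleus_mask=nucleus_mask,
                pixel_size=pixel_size,
                frame_index=int(fi),
            )
        )
    return out
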