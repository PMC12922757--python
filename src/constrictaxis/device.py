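"""Constricted-chamber geometry and the 1D chemoattractant gradient.

The migration chamber is modelled as a 1D segment along the chemotaxis (x)
axis: cell inlet at ``x = 0``, chemoattractant inlet at ``x = chamber_length``,
with a single pillar constriction whose leading edge sits at
``constriction_x``.  The inlet reservoirs are idealized as fixed-concentration
boundaries, so the steady-state profile is linear, ``C(x) = x / L``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .errors import InvalidParameterError, OutOfBoundsError

__all__ = [
    "DeviceGeometry",
    "ConcentrationField",
    "solve_gradient",
    "gradient_establishment_time",
    "classify_position",
    "REGION_BEFORE",
    "REGION_DURING",
    "REGION_AFTER",
]

REGION_BEFORE = "before"
REGION_DURING = "during"
REGION_AFTER = "after"

#: cm^2/s -> um^2/s
_CM2_TO_UM2 = 1.0e8


@dataclass(frozen=True)
class DeviceGeometry:
    """Chamber dimensions in micrometres.

    ``constriction_x`` is the pillar leading edge measured from the cell
    inlet; the pillar occupies ``[constriction_x, constriction_x +
    pillar_extent]``.  ``cell_length`` is the window used for
    peri-constriction quantification and ``saturation_x`` the onset of
    near-saturating chemoattractant where cells arrest.
    ``chamber_width`` is the lateral (y) extent used by the simulator.
    """

    chamber_length: float = 300.0
    chamber_height: float = 5.0
    constriction_x: float = 100.0
    pillar_extent: float = 20.0
    gap_width: float = 3.0
    cell_length: float = 25.0
    saturation_x: float = 250.0
    chamber_width: float = 300.0

    def __post_init__(self) -> None:
        if not (0.0 < self.constriction_x < self.exit_x < self.chamber_length):
            raise InvalidParameterError(
                "require 0 < constriction_x < constriction_x + pillar_extent "
                f"< chamber_length, got constriction_x={self.constriction_x}, "
                f"pillar_extent={self.pillar_extent}, "
                f"chamber_length={self.chamber_length}"
            )
        for name in ("gap_width", "cell_length", "chamber_height", "chamber_width"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not (0.0 < self.saturation_x <= self.chamber_length):
            raise InvalidParameterError("saturation_x must lie inside the chamber")

    @property
    def exit_x(self) -> float:
        """Pillar trailing edge (post-constriction side), um."""
        return self.constriction_x + self.pillar_extent


@dataclass(frozen=True)
class ConcentrationField:
    """Normalized concentration ``C[t, x]`` on a regular space-time grid."""

    x_grid: np.ndarray  # um
    times: np.ndarray  # s
    C: np.ndarray  # shape (len(times), len(x_grid)), 0..1
    D: float  # cm^2/s

    def __post_init__(self) -> None:
        if self.C.shape != (len(self.times), len(self.x_grid)):
            raise InvalidParameterError("C must have shape (n_times, n_x)")

    @property
    def chamber_length(self) -> float:
        return float(self.x_grid[-1] - self.x_grid[0])

    def profile(self, t: float) -> np.ndarray:
        """Concentration profile at the stored time closest to ``t``."""
        i = int(np.argmin(np.abs(self.times - t)))
        return self.C[i]

    def to_dataframe(self) -> pd.DataFrame:
        tt, xx = np.meshgrid(self.times, self.x_grid, indexing="ij")
        return pd.DataFrame(
            {"x_um": xx.ravel(), "t_s": tt.ravel(), "C_norm": self.C.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def solve_gradient(
    geometry: DeviceGeometry,
    D: float = 5.0e-6,
    c0_boundary: float = 1.0,
    t_end: float = 1800.0,
    dx: float = 1.0,
    dt: float = 1.0,
) -> ConcentrationField:
    """Solve 1D diffusion with fixed reservoir boundaries.

    Crank-Nicolson (unconditionally stable) on ``[0, L]`` with
    ``C(0, t) = 0``, ``C(L, t) = c0_boundary`` and ``C(x, 0) = 0`` in the
    interior.  ``D`` is in cm^2/s; space in um, time in s.
    """
    if D <= 0 or dx <= 0 or dt <= 0 or t_end <= 0:
        raise InvalidParameterError("D, dx, dt and t_end must be positive")
    L = geometry.chamber_length
    n_steps_x = L / dx
    if abs(n_steps_x - round(n_steps_x)) > 1e-9:
        raise InvalidParameterError(f"dx={dx} must divide chamber_length={L}")
    nx = int(round(n_steps_x)) + 1
    x = np.linspace(0.0, L, nx)

    d_um = D * _CM2_TO_UM2
    r = d_um * dt / dx**2

    # Interior unknowns 1..nx-2; tridiagonal (I - r/2 A) u_new = (I + r/2 A) u
    n_int = nx - 2
    ab = np.zeros((3, n_int))
    ab[0, 1:] = -r / 2.0
    ab[1, :] = 1.0 + r
    ab[2, :-1] = -r / 2.0
    # backward-Euler matrix for the first steps (Rannacher smoothing: damps
    # the CN oscillation caused by the discontinuous initial corner, keeping
    # the discrete maximum principle)
    ab_be = np.zeros((3, n_int))
    ab_be[0, 1:] = -r
    ab_be[1, :] = 1.0 + 2.0 * r
    ab_be[2, :-1] = -r

    nt = int(np.ceil(t_end / dt)) + 1
    times = np.arange(nt) * dt
    C = np.zeros((nt, nx))
    C[:, -1] = c0_boundary

    u = C[0].copy()
    for k in range(1, nt):
        if k <= 2:
            rhs = u[1:-1].copy()
            rhs[-1] += r * c0_boundary
            u_int = solve_banded((1, 1), ab_be, rhs)
        else:
            rhs = u[1:-1] + (r / 2.0) * (u[2:] - 2.0 * u[1:-1] + u[:-2])
            # Dirichlet boundary contributions (left is 0, right is c0)
            rhs[-1] += (r / 2.0) * c0_boundary
            u_int = solve_banded((1, 1), ab, rhs)
        u = np.concatenate(([0.0], u_int, [c0_boundary]))
        C[k] = u

    # Maximum principle: interior bounded by boundary values.
    eps = 1e-9 * max(c0_boundary, 1.0)
    assert C.min() >= -eps and C.max() <= c0_boundary + eps
    return ConcentrationField(x_grid=x, times=times, C=np.clip(C, 0.0, c0_boundary), D=D)


def gradient_establishment_time(field: ConcentrationField, tol: float = 0.10):
    """First stored time at which ``max_x |C - x/L * c0| < tol * c0``.

    Returns ``None`` (not-established sentinel) when the tolerance is never
    reached within ``field.times``.
    """
    if tol <= 0:
        raise InvalidParameterError("tol must be positive")
    c0 = float(field.C[0, -1])
    linear = field.x_grid / field.chamber_length * c0
    dev = np.max(np.abs(field.C - linear[None, :]), axis=1)
    hits = np.nonzero(dev < tol * c0)[0]
    if hits.size == 0:
        return None
    return float(field.times[hits[0]])


def classify_position(x: float, geometry: DeviceGeometry) -> str:
    """Classify an x-position as before/during/after the pillar."""
    if not (0.0 <= x <= geometry.chamber_length):
        raise OutOfBoundsError(
            f"x={x} um outside chamber [0, {geometry.chamber_length}]"
        )
    if x < geometry.constriction_x:
        return REGION_BEFORE
    if x <= geometry.exit_x:
        return REGION_DURING
    return REGION_AFTER
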