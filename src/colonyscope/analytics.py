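"""Closed-form random-walk and first-passage estimates.

For an unbiased 2-D random walk with diffusion coefficient ``D``, the mean
displacement over a lag ``dt`` is ``<r> = sqrt(pi * D * dt)`` (the Rayleigh
mean of a Gaussian displacement with per-axis variance ``2 D dt``).
Inverting gives the standard mean-displacement estimator

    D = <r>**2 / (pi * dt)

With the measured colony displacement <r> = 15 um per 15-min frame this
gives D ~ 4.8 um^2/min.  The mean first-passage time of such a walk from the
centre of a disk-shaped adhesive zone of radius ``R`` to its edge is
``T = R**2 / (4 D)``; by that time roughly half of the colonies have
escaped the zone.

Internal units are um and minutes; durations and reported times use hours
at this module's surface, which is the reporting boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .colony import MIN_PER_HR, GrowthParams

__all__ = [
    "RandomWalkFit",
    "AdhesiveZone",
    "estimate_drw",
    "mean_displacement_from_drw",
    "measure_mean_displacement",
    "escape_time",
    "colony_radius_at",
    "colony_radius_geometric_mean",
]


@dataclass(frozen=True)
class AdhesiveZone:
    """Disk-shaped high-adhesion zone; ``radius`` in um (default 125)."""

    radius: float = 125.0

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("zone radius must be non-negative")


@dataclass(frozen=True)
class RandomWalkFit:
    """A mean-displacement fit: ``mean_displacement`` (um) per lag ``dt`` (min)."""

    mean_displacement: float
    dt: float

    @property
    def drw(self) -> float:
        """Fitted diffusion coefficient in um^2/min."""
        return estimate_drw(self.mean_displacement, self.dt)


def estimate_drw(mean_displacement: float, dt: float) -> float:
    """Diffusion coefficient ``<r>**2 / (pi * dt)`` in um^2/min."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if mean_displacement < 0:
        raise ValueError("mean displacement must be non-negative")
    return mean_displacement**2 / (math.pi * dt)


def mean_displacement_from_drw(drw: float, dt: float) -> float:
    """Inverse of :func:`estimate_drw`: ``<r> = sqrt(pi * D * dt)``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if drw < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    return math.sqrt(math.pi * drw * dt)


def measure_mean_displacement(trajectory: np.ndarray, frame_interval: float | None = None) -> float:
    """Mean per-frame displacement magnitude (um) of a trajectory of (x, y) positions.

    ``frame_interval`` is accepted for signature symmetry with
    :func:`estimate_drw` but does not affect the mean step length.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[0] < 2 or traj.shape[1] != 2:
        raise ValueError("trajectory must be an (n >= 2, 2) array of positions")
    steps = np.diff(traj, axis=0)
    return float(np.mean(np.hypot(steps[:, 0], steps[:, 1])))


def escape_time(zone: AdhesiveZone, drw: float) -> float:
    """Mean first-passage time (hours) to the zone edge: ``R**2 / (4 D)``."""
    if drw <= 0:
        raise ValueError("diffusion coefficient must be positive")
    return zone.radius**2 / (4.0 * drw) / MIN_PER_HR


def colony_radius_at(t_hr: float, growth: GrowthParams) -> float:
    """Continuous-growth colony radius (um) at time ``t_hr`` hours.

    Area doubles every division interval, so the radius doubles every two
    intervals: ``r(t) = r1 * 2 ** (t / (2 * interval))``.  At division
    epochs this agrees with the discrete synchronized model
    ``r1 * sqrt(2**k)``.
    """
    if t_hr < 0:
        raise ValueError("time must be non-negative")
    interval_hr = growth.division_interval / MIN_PER_HR
    return growth.r1 * 2.0 ** (t_hr / (2.0 * interval_hr))


def colony_radius_geometric_mean(duration_hr: float, growth: GrowthParams) -> float:
    """Time-geometric-mean radius (um) of the continuous trajectory over ``[0, T]``.

    ``exp(mean(log r))`` of an exponential radius trajectory is
    ``r1 * 2 ** (T / (4 * interval))`` - e.g. 30 um over 4 days with a 12-hr
    interval, as opposed to the 120-um end-of-recording radius.  Both are
    exposed because "typical colony size over the movie" is ambiguous between
    them.
    """
    if duration_hr < 0:
        raise ValueError("duration must be non-negative")
    interval_hr = growth.division_interval / MIN_PER_HR
    return growth.r1 * 2.0 ** (duration_hr / (4.0 * interval_hr))
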