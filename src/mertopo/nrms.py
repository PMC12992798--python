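"""Normalized root-mean-square (NRMS) background-activity profiles.

Along each microelectrode pass the multi-unit background RMS rises
sharply at the dorsal STN border; normalising each trajectory by the
median of its first five (most dorsal) recording sites of at least 10 s
duration makes profiles comparable across passes and patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InsufficientDataError

__all__ = [
    "TrajectoryProfile",
    "rms",
    "normalize_trajectory",
    "group_by_dose",
    "resample_to_grid",
    "DEFAULT_GRID",
]

#: Minimum duration (s) for a site to qualify as a normalisation reference.
MIN_REF_DURATION_S = 10.0

#: Number of dorsal reference sites used for normalisation.
N_REF_SITES = 5

#: Minimum number of qualifying reference sites; below this the
#: trajectory is not normalizable.
N_REF_MIN = 3

#: Dose threshold (mg/kg/h) separating high- from low-dose GA; the
#: boundary itself belongs to the low-dose group.
DOSE_THRESHOLD = 4.0

#: Common depth grid for group comparison, dorsal to ventral, 0.5-mm step.
DEFAULT_GRID = np.arange(10.0, -5.0 - 1e-9, -0.5)


@dataclass
class TrajectoryProfile:
    """Depth-indexed background RMS for one microelectrode pass.

    ``depths`` are mm to the planned target, listed dorsal to ventral
    (strictly decreasing).  ``stn_entry``/``stn_exit`` are the
    imaging-defined STN border depths (entry dorsal of exit), when the
    trajectory intersects the nucleus.
    """

    trajectory_id: str
    condition: str  # LA | GA
    propofol_rate: float | None
    depths: np.ndarray
    durations: np.ndarray
    rms: np.ndarray
    nrms: np.ndarray | None = None
    stn_entry: float | None = None
    stn_exit: float | None = None
    aligned: bool = False

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.rms = np.asarray(self.rms, dtype=float)
        if not (self.depths.size == self.durations.size == self.rms.size):
            raise ValueError("depths, durations and rms must have equal length")
        if np.any(np.diff(self.depths) >= 0):
            raise ValueError("depths must be strictly decreasing (dorsal to ventral)")
        if np.any(self.rms < 0):
            raise ValueError("rms values must be non-negative")
        if self.nrms is not None:
            self.nrms = np.asarray(self.nrms, dtype=float)
        if (
            self.stn_entry is not None
            and self.stn_exit is not None
            and not self.stn_entry > self.stn_exit
        ):
            raise ValueError("stn_entry must be dorsal of (greater than) stn_exit")


def rms(samples: Sequence[float]) -> float:
    """Root mean square, sqrt(mean(x^2))."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty sample")
    return float(np.sqrt(np.mean(x**2)))


def normalize_trajectory(profile: TrajectoryProfile) -> TrajectoryProfile:
    """Scale a trajectory's RMS by the median of its reference sites.

    The reference is the median RMS of the first :data:`N_REF_SITES`
    sites, taken in dorsal-to-ventral recording order, with duration of at
    least :data:`MIN_REF_DURATION_S`; shorter sites are skipped and the
    next qualifying site takes their place.  Trajectories offering fewer
    than :data:`N_REF_MIN` qualifying sites cannot be normalised.

    Idempotent: renormalising an already-normalised profile is a no-op,
    since the reference median of a normalised profile is 1.
    """
    qualifying = np.flatnonzero(profile.durations >= MIN_REF_DURATION_S)
    ref_idx = qualifying[:N_REF_SITES]
    if ref_idx.size < N_REF_MIN:
        raise InsufficientDataError(
            f"trajectory {profile.trajectory_id}: only {ref_idx.size} sites with "
            f"duration >= {MIN_REF_DURATION_S:g} s (need {N_REF_MIN})"
        )
    ref = float(np.median(profile.rms[ref_idx]))
    if ref <= 0:
        raise InsufficientDataError(
            f"trajectory {profile.trajectory_id}: zero reference RMS"
        )
    return replace(profile, nrms=profile.rms / ref)


def group_by_dose(
    profiles: Iterable[TrajectoryProfile],
    threshold: float = DOSE_THRESHOLD,
) -> dict[str, list[TrajectoryProfile]]:
    """Partition trajectories into LA / GA_high (> threshold) / GA_low (<=).

    LA trajectories are grouped by condition label regardless of any dose
    field; a GA trajectory without a recorded dose is an error.
    """
    groups: dict[str, list[TrajectoryProfile]] = {"LA": [], "GA_high": [], "GA_low": []}
    for p in profiles:
        if p.condition == "LA":
            groups["LA"].append(p)
        elif p.condition == "GA":
            if p.propofol_rate is None or not np.isfinite(p.propofol_rate):
                raise ValueError(
                    f"GA trajectory {p.trajectory_id} has no propofol rate"
                )
            if p.propofol_rate > threshold:
                groups["GA_high"].append(p)
            else:
                groups["GA_low"].append(p)
        else:
            raise ValueError(f"unknown condition {p.condition!r}")
    return groups


def resample_to_grid(
    profile: TrajectoryProfile,
    grid: np.ndarray = DEFAULT_GRID,
    tol: float = 0.25,
    use_nrms: bool = True,
) -> np.ndarray:
    """Nearest-depth assignment of a profile onto a common depth grid.

    Each grid cell takes the value of the nearest recorded depth within
    ``tol`` mm; cells with no recording nearby are NaN (missing, not zero).
    """
    values = profile.nrms if use_nrms else profile.rms
    if values is None:
        raise ValueError("profile has no nrms; normalise first")
    out = np.full(grid.shape, np.nan)
    for i, g in enumerate(grid):
        d = np.abs(profile.depths - g)
        j = int(np.argmin(d))
        if d[j] <= tol:
            out[i] = values[j]
    return out
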