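"""Spatial mapping of MER sites and DBS electrodes.

Places recording sites along straight stereotactic trajectories in a
common right-handed mm frame (z dorsal-positive), intersects trajectories
with a parametric ellipsoid model of the STN and SNr, aligns trajectory
depths to a common STN midpoint, classifies sites by structure, and
measures distances to a configurable clinical sweetspot.

Conventions
-----------
``depth_to_target`` is positive dorsal of the planned target (the ventral
STN border); ``position(d) = target_point - d * direction`` with
``direction`` the dorsal-to-ventral unit vector, so "deeper" means a
smaller depth value.  ``implantation_offset`` is negative when the final
electrode sits deeper than planned; recorded depths are corrected by
adding the offset before projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InsufficientDataError

__all__ = [
    "Ellipsoid",
    "AtlasGeometry",
    "TrajectoryGeometry",
    "MERSite",
    "ElectrodeModel",
    "stn_span",
    "align_depths",
    "exclude_trajectories",
    "classify_structure",
    "locate_mer_site",
    "sweetspot_distance",
    "electrode_center",
    "first_sua_normalized_distance",
]

MIN_STN_CHORD_MM = 3.0
SUA_NEIGHBOR_WINDOW_MM = 2.0
SUA_MIN_NEIGHBORS = 2


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid: center (mm) and positive semi-axes (mm)."""

    center: np.ndarray
    semi_axes: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float)
        if np.any(self.semi_axes <= 0):
            raise ValueError("ellipsoid semi-axes must be positive")

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Inside-or-on test; broadcasts over leading dimensions."""
        u = (np.asarray(xyz, dtype=float) - self.center) / self.semi_axes
        return np.sum(u**2, axis=-1) <= 1.0


@dataclass
class AtlasGeometry:
    """Parametric stand-in atlas: STN and SNr ellipsoids plus a sweetspot.

    Where the two nuclei overlap, STN takes precedence.  The sweetspot is
    a configurable point in the dorsolateral STN; no claim of anatomical
    accuracy is made for the defaults.
    """

    stn: Ellipsoid
    snr_nucleus: Ellipsoid
    sweetspot: np.ndarray

    def __post_init__(self):
        self.sweetspot = np.asarray(self.sweetspot, dtype=float)


@dataclass
class TrajectoryGeometry:
    """A straight microelectrode trajectory.

    ``target_point`` is the planned target at depth 0; ``direction`` is the
    dorsal-to-ventral unit vector.
    """

    target_point: np.ndarray
    direction: np.ndarray
    implantation_offset: float = 0.0

    def __post_init__(self):
        self.target_point = np.asarray(self.target_point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("direction must be non-zero")
        self.direction = d / norm

    def position(self, depth: float | np.ndarray) -> np.ndarray:
        """Point at a given depth-to-target (positive = dorsal of target)."""
        depth = np.asarray(depth, dtype=float)
        return self.target_point - depth[..., None] * self.direction


@dataclass
class MERSite:
    segment_id: str
    xyz: np.ndarray
    depth_to_target: float
    structure_imaging: str
    distance_to_sweetspot: float


@dataclass
class ElectrodeModel:
    """Final DBS electrode: contact positions and sweetspot offsets."""

    contact_positions: np.ndarray  # (n_contacts, 3)
    center: np.ndarray | None = None
    distance_to_sweetspot: float | None = None
    z_deviation: float | None = None


def stn_span(
    geometry: TrajectoryGeometry, atlas: AtlasGeometry
) -> tuple[float, float] | None:
    """Depths at which a trajectory enters and exits the STN ellipsoid.

    Returns (entry, exit) as depth-to-target with entry dorsal of
    (greater than) exit, or ``None`` when the line misses the nucleus.
    Tangent or zero-length intersections count as misses.
    """
    return _ellipsoid_span(geometry, atlas.stn)


def snr_span(
    geometry: TrajectoryGeometry, atlas: AtlasGeometry
) -> tuple[float, float] | None:
    """Entry/exit depths through the SNr ellipsoid (or ``None``)."""
    return _ellipsoid_span(geometry, atlas.snr_nucleus)


def _ellipsoid_span(
    geometry: TrajectoryGeometry, ell: Ellipsoid
) -> tuple[float, float] | None:
    # Solve |(p0 - d*u - c)/a|^2 = 1 for depth d (quadratic).
    p0 = (geometry.target_point - ell.center) / ell.semi_axes
    u = geometry.direction / ell.semi_axes
    a = float(u @ u)
    b = -2.0 * float(p0 @ u)
    c = float(p0 @ p0) - 1.0
    disc = b * b - 4 * a * c
    if disc <= 0:  # miss or tangent
        return None
    sq = np.sqrt(disc)
    d1 = (-b - sq) / (2 * a)
    d2 = (-b + sq) / (2 * a)
    entry, exit_ = max(d1, d2), min(d1, d2)
    if entry - exit_ <= 0:
        return None
    return float(entry), float(exit_)


def align_depths(
    spans: Sequence[tuple[float, float]],
) -> tuple[list[float], float]:
    """Per-trajectory depth shifts aligning STN midpoints to a reference.

    The reference midpoint is half the mean imaging-defined STN length
    (i.e. the midpoint of the mean-length STN with its exit anchored at
    depth 0).  Each trajectory is shifted by (reference midpoint - its own
    midpoint); adding the shift to every depth of that trajectory aligns
    all STN midpoints while conserving every STN length.

    Returns (shifts, reference_midpoint).
    """
    if len(spans) == 0:
        raise InsufficientDataError("no trajectories with a valid STN span")
    lengths = [entry - exit_ for entry, exit_ in spans]
    reference = float(np.mean(lengths)) / 2.0
    shifts = [reference - (entry + exit_) / 2.0 for entry, exit_ in spans]
    return shifts, reference


def exclude_trajectories(
    spans: Sequence[tuple[float, float] | None],
    min_chord: float = MIN_STN_CHORD_MM,
) -> tuple[list[int], dict[str, int]]:
    """Indices of trajectories kept for depth analyses, with an exclusion tally.

    Drops trajectories with (a) no STN intersection and (b) an STN chord
    shorter than ``min_chord`` mm (a chord of exactly ``min_chord`` is
    kept).  Tally keys: ``no_stn``, ``short_stn``.
    """
    kept: list[int] = []
    tally = {"no_stn": 0, "short_stn": 0}
    for i, span in enumerate(spans):
        if span is None:
            tally["no_stn"] += 1
        elif span[0] - span[1] < min_chord:
            tally["short_stn"] += 1
        else:
            kept.append(i)
    return kept, tally


def classify_structure(xyz: np.ndarray, atlas: AtlasGeometry) -> str:
    """STN | SNr | other by ellipsoid membership; STN wins overlaps."""
    xyz = np.asarray(xyz, dtype=float)
    if atlas.stn.contains(xyz):
        return "STN"
    if atlas.snr_nucleus.contains(xyz):
        return "SNr"
    return "other"


def locate_mer_site(
    geometry: TrajectoryGeometry,
    depth_to_target: float,
    implantation_offset: float | None = None,
) -> np.ndarray:
    """Project a recording depth back onto the final-electrode line.

    The recorded depth is corrected by adding the implantation offset
    (negative offset = implanted deeper) before projection.
    """
    if implantation_offset is None:
        implantation_offset = geometry.implantation_offset
    return geometry.position(depth_to_target + implantation_offset)


def sweetspot_distance(xyz: np.ndarray, sweetspot: np.ndarray) -> float:
    """Euclidean distance (mm) to the sweetspot."""
    return float(np.linalg.norm(np.asarray(xyz, float) - np.asarray(sweetspot, float)))


def electrode_center(
    model: ElectrodeModel, sweetspot: np.ndarray
) -> ElectrodeModel:
    """Electrode center (mean of contacts), sweetspot distance and z deviation.

    ``z_deviation = center_z - sweetspot_z``; negative = electrode center
    ventral of (deeper than) the sweetspot.
    """
    contacts = np.atleast_2d(np.asarray(model.contact_positions, dtype=float))
    if contacts.shape[0] < 1:
        raise InsufficientDataError("electrode has no contacts")
    center = contacts.mean(axis=0)
    sweetspot = np.asarray(sweetspot, dtype=float)
    return replace(
        model,
        contact_positions=contacts,
        center=center,
        distance_to_sweetspot=float(np.linalg.norm(center - sweetspot)),
        z_deviation=float(center[2] - sweetspot[2]),
    )


def first_sua_normalized_distance(
    stn_entry: float,
    stn_exit: float,
    sua_depths: Sequence[float],
    neighbor_window: float = SUA_NEIGHBOR_WINDOW_MM,
    min_neighbors: int = SUA_MIN_NEIGHBORS,
) -> float | None:
    """Relative depth of the first isolated unit below the dorsal STN border.

    Returns (entry - depth of the most dorsal qualifying unit) divided by
    the STN traversal length.  0 means the first unit sits exactly at the
    dorsal border; values near 1 mean single units only appeared near the
    ventral border (blurred entry).  Values outside [0, 1] are returned
    unclipped (a unit dorsal of entry gives a negative value).

    A unit qualifies only when at least ``min_neighbors`` other units lie
    within ``neighbor_window`` mm along the trajectory — isolated outliers
    (e.g. stray zona incerta neurons dorsal of the STN) are skipped.
    Returns ``None`` when no unit qualifies.
    """
    if not stn_entry > stn_exit:
        raise ValueError("stn_entry must be dorsal of stn_exit")
    length = stn_entry - stn_exit
    if length < MIN_STN_CHORD_MM:
        raise ValueError(f"STN traversal shorter than {MIN_STN_CHORD_MM} mm")
    depths = np.asarray(sua_depths, dtype=float)
    if depths.size == 0:
        return None
    qualifying = [
        d
        for d in depths
        if np.sum(np.abs(depths - d) <= neighbor_window) - 1 >= min_neighbors
    ]
    if not qualifying:
        return None
    first = max(qualifying)  # most dorsal
    return float((stn_entry - first) / length)
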