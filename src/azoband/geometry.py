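"""Trajectory dihedral diagnostics: E/Z configuration and ring coplanarity.

Two torsions diagnose whether a sampled azobenzene ensemble is physically
sensible: the C–N=N–C dihedral (180° ↔ E, 0° ↔ Z) and the inclination of
each phenyl ring against the azo plane.  A correct thermal ensemble of the
E isomer keeps the azo dihedral near ±180° and the rings near coplanarity
(0°/±180°, possibly staggered for bulky ortho substituents); a force-field
artifact instead locks the rings perpendicular (±90°), which suppresses the
geometric coupling that lends intensity to the nπ* band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import DihedralSpec, TrajectoryFrame, ValidationError

__all__ = [
    "DihedralSeries",
    "CircularHistogram",
    "dihedral",
    "ez_label",
    "dihedral_series",
    "circular_histogram",
    "coplanarity_report",
    "planarity_deviation",
]

_COLLINEAR_TOL = 1e-10


def wrap_angle(angle_deg: float) -> float:
    """Wrap an angle in degrees to (−180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    out = -np.mod(-a + 180.0, 360.0) + 180.0   # maps -180 -> 180
    return float(out) if out.ndim == 0 else out


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees, (−180, 180]) of four points.

    Standard convention: sighting along p2→p3, the angle by which the far
    bond p3→p4 rotates from the near bond p2→p1; anti-periplanar → 180,
    syn-periplanar → 0.  Degenerate (collinear) quadruples raise — a silent
    zero would corrupt the circular distributions downstream.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < _COLLINEAR_TOL:
        raise ValueError("degenerate dihedral: central atoms coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise ValueError("degenerate dihedral: three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def ez_label(angle_deg: float) -> str:
    """Classify a C–N=N–C dihedral as E (anti) or Z (syn).

    The boundary |angle| = 90 is assigned to E.
    """
    if not -180.0 < angle_deg <= 180.0:
        raise ValueError("angle must be in (-180, 180]")
    return "E" if abs(angle_deg) >= 90.0 else "Z"


@dataclass(frozen=True)
class DihedralSeries:
    """Per-frame values of one named torsion."""

    spec: DihedralSpec
    values: np.ndarray   # degrees, (−180, 180]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1:
            raise ValidationError("values must be a 1-D array of angles")
        if len(vals) and (vals.min() <= -180.0 or vals.max() > 180.0):
            raise ValidationError("dihedral values must lie in (-180, 180]")


def dihedral_series(frames: Sequence[TrajectoryFrame], spec: DihedralSpec) -> DihedralSeries:
    """Evaluate one torsion on every frame, preserving frame order."""
    values = np.empty(len(frames))
    for k, frame in enumerate(frames):
        n = len(frame.atom_names)
        if max(spec.atom_indices) >= n:
            raise IndexError(
                f"frame {frame.frame_index}: dihedral {spec.name!r} indices "
                f"{spec.atom_indices} exceed {n} atoms"
            )
        i, j, l, m = spec.atom_indices
        c = frame.coordinates
        values[k] = dihedral(c[i], c[j], c[l], c[m])
    return DihedralSeries(spec=spec, values=values)


@dataclass(frozen=True)
class CircularHistogram:
    """Frequency histogram of a torsion over the circle (−180, 180]."""

    bin_edges: np.ndarray    # degrees, partition of [-180, 180]
    counts: np.ndarray
    mode_angles: tuple[float, ...]   # local-maximum bin centers

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))


def circular_histogram(series: DihedralSeries, bin_width_deg: float = 5.0,
                       mode_prominence: float = 0.5) -> CircularHistogram:
    """Bin a torsion series on the circle and locate its modes.

    ``bin_width_deg`` must divide 360.  A bin is a mode when its count is a
    circular local maximum (≥ both neighbours) and at least
    ``mode_prominence`` × the global maximum; counts conserve the frame count.
    """
    nbins = 360.0 / bin_width_deg
    if abs(nbins - round(nbins)) > 1e-9 or bin_width_deg <= 0:
        raise ValueError("bin_width_deg must be a positive divisor of 360")
    nbins = int(round(nbins))
    edges = -180.0 + bin_width_deg * np.arange(nbins + 1)
    # values are in (-180, 180]; shift 180 into the last bin explicitly
    vals = np.where(series.values == 180.0, 180.0 - 1e-9, series.values)
    counts, _ = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    modes: list[float] = []
    if counts.max() > 0:
        left = np.roll(counts, 1)
        right = np.roll(counts, -1)
        is_mode = (counts >= left) & (counts >= right) & \
                  (counts >= mode_prominence * counts.max()) & (counts > 0)
        modes = [float(c) for c in centers[is_mode]]
    return CircularHistogram(bin_edges=edges, counts=counts,
                             mode_angles=tuple(modes))


def planarity_deviation(angle_deg) -> np.ndarray:
    """Deviation (degrees, in [0, 90]) of a torsion from the nearest of 0/±180."""
    a = np.abs(np.asarray(angle_deg, dtype=float))
    return np.minimum(a, 180.0 - a)


def coplanarity_report(phenyl_series: Sequence[DihedralSeries],
                       threshold_deg: float = 30.0,
                       artifact_max_fraction: float = 0.05,
                       bin_width_deg: float = 5.0) -> list[dict]:
    """Per-ring coplanarity fraction and perpendicular-artifact flag.

    A frame counts as (near-)coplanar when the ring torsion deviates from
    0/±180 by at most ``threshold_deg``.  The perpendicular-lock artifact is
    flagged when the coplanar fraction falls below ``artifact_max_fraction``
    while the circular distribution has a mode near ±90 — the signature of a
    force field that freezes the rings orthogonal to the azo plane.
    """
    if not phenyl_series:
        raise ValueError("need at least one phenyl torsion series")
    reports = []
    for series in phenyl_series:
        if len(series.values) == 0:
            raise ValueError(f"series {series.spec.name!r} is empty")
        dev = planarity_deviation(series.values)
        fraction = float(np.mean(dev <= threshold_deg))
        hist = circular_histogram(series, bin_width_deg=bin_width_deg)
        perp_mode = any(abs(abs(m) - 90.0) <= 15.0 for m in hist.mode_angles)
        reports.append({
            "name": series.spec.name,
            "coplanar_fraction": fraction,
            "perpendicular_artifact": bool(fraction < artifact_max_fraction and perp_mode),
            "mode_angles": hist.mode_angles,
        })
    return reports
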