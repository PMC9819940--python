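"""Snapshot-record data model and file I/O.

Every downstream stage (spectrum building, orbital statistics, geometry
diagnostics) consumes one interchange format: a JSON-Lines file with one
solvated-snapshot record per line, each carrying the vertical excitations
computed at that geometry.  Trajectories travel as plain multi-frame XYZ.

Units: excitation and orbital energies in eV, times in ps, coordinates in Å,
dihedrals in degrees wrapped to (−180, 180].  Atom indices are 0-based.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "ExcitationEntry",
    "SnapshotRecord",
    "TrajectoryFrame",
    "DihedralSpec",
    "read_snapshot_records",
    "write_snapshot_records",
    "read_xyz_trajectory",
    "read_pdb_frame",
    "write_xyz_trajectory",
    "sample_count",
]


class ValidationError(ValueError):
    """A record violated the interchange-format invariants."""


@dataclass(frozen=True)
class ExcitationEntry:
    """One excited state of one snapshot.

    ``delta_e`` is the vertical excitation energy ΔE (eV, > 0) and
    ``osc_strength`` the dimensionless oscillator strength f ≥ 0.  The MO
    energies are those of the orbital the excitation departs from (for the
    nπ* S1 state of azobenzenes, the HOMO) and the receiving orbital (LUMO);
    they are optional because only selected states carry an orbital analysis.
    """

    state_index: int
    delta_e: float
    osc_strength: float
    e_mo_initial: float | None = None
    e_mo_final: float | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.state_index, int) and self.state_index >= 1):
            raise ValidationError(f"state_index must be a positive integer, got {self.state_index!r}")
        if not self.delta_e > 0:
            raise ValidationError(f"delta_e must be > 0, got {self.delta_e!r}")
        if self.osc_strength < 0:
            raise ValidationError(f"osc_strength must be >= 0, got {self.osc_strength!r}")
        if self.e_mo_initial is not None and self.e_mo_final is not None:
            if not self.e_mo_initial < self.e_mo_final:
                raise ValidationError(
                    "e_mo_initial must lie below e_mo_final "
                    f"({self.e_mo_initial} >= {self.e_mo_final})"
                )


@dataclass(frozen=True)
class SnapshotRecord:
    """One sampled geometry with its list of vertical excitations."""

    snapshot_id: str
    time_ps: float
    excitations: tuple[ExcitationEntry, ...]
    dihedrals: dict[str, float] | None = None
    coeff_block_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "excitations", tuple(self.excitations))
        if self.time_ps < 0:
            raise ValidationError(f"record {self.snapshot_id!r}: time_ps must be >= 0")
        idx = [e.state_index for e in self.excitations]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValidationError(
                f"record {self.snapshot_id!r}: excitations must be sorted by unique state_index"
            )
        if self.dihedrals is not None:
            for name, val in self.dihedrals.items():
                if not (-180.0 < val <= 180.0):
                    raise ValidationError(
                        f"record {self.snapshot_id!r}: dihedral {name!r} = {val} outside (-180, 180]"
                    )

    def excitation(self, state_index: int) -> ExcitationEntry | None:
        for e in self.excitations:
            if e.state_index == state_index:
                return e
        return None


@dataclass(frozen=True)
class TrajectoryFrame:
    """Cartesian coordinates (Å) of one trajectory frame."""

    frame_index: int
    coordinates: np.ndarray
    atom_names: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        if coords.ndim != 2 or coords.shape != (len(self.atom_names), 3):
            raise ValidationError(
                f"frame {self.frame_index}: coordinate array {coords.shape} inconsistent "
                f"with {len(self.atom_names)} atom names"
            )


@dataclass(frozen=True)
class DihedralSpec:
    """Four 0-based atom indices defining a named torsion.

    ``role`` tags what the torsion diagnoses: ``azo_EZ`` for the C–N=N–C
    dihedral that reads the E/Z configuration, ``phenyl_inclination`` for the
    ring-vs-azo-plane torsion, ``other`` for anything else.
    """

    name: str
    atom_indices: tuple[int, int, int, int]
    role: str = "other"

    _ROLES = ("azo_EZ", "phenyl_inclination", "other")

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_indices", tuple(int(i) for i in self.atom_indices))
        if len(self.atom_indices) != 4 or len(set(self.atom_indices)) != 4:
            raise ValidationError(f"dihedral {self.name!r}: need 4 distinct atom indices")
        if any(i < 0 for i in self.atom_indices):
            raise ValidationError(f"dihedral {self.name!r}: indices must be 0-based and >= 0")
        if self.role not in self._ROLES:
            raise ValidationError(f"dihedral {self.name!r}: unknown role {self.role!r}")


# ---------------------------------------------------------------------------
# JSON Lines record I/O
# ---------------------------------------------------------------------------

_REQUIRED_EXC_FIELDS = ("state_index", "delta_e_ev", "osc_strength")


def _entry_to_json(e: ExcitationEntry) -> dict:
    return {
        "state_index": e.state_index,
        "delta_e_ev": e.delta_e,
        "osc_strength": e.osc_strength,
        "e_mo_initial_ev": e.e_mo_initial,
        "e_mo_final_ev": e.e_mo_final,
    }


def _entry_from_json(d: dict, snapshot_id: str) -> ExcitationEntry:
    for key in _REQUIRED_EXC_FIELDS:
        if key not in d:
            raise ValidationError(f"record {snapshot_id!r}: excitation missing field {key!r}")
    try:
        return ExcitationEntry(
            state_index=int(d["state_index"]),
            delta_e=float(d["delta_e_ev"]),
            osc_strength=float(d["osc_strength"]),
            e_mo_initial=None if d.get("e_mo_initial_ev") is None else float(d["e_mo_initial_ev"]),
            e_mo_final=None if d.get("e_mo_final_ev") is None else float(d["e_mo_final_ev"]),
        )
    except ValidationError as err:
        raise ValidationError(f"record {snapshot_id!r}: {err}") from None


def read_snapshot_records(path: str | Path) -> list[SnapshotRecord]:
    """Read and validate a JSON-Lines snapshot-record file.

    File order is preserved.  Any invariant violation raises
    :class:`ValidationError` naming the offending record and field.
    """
    records: list[SnapshotRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as err:
                raise ValidationError(f"line {lineno}: invalid JSON ({err})") from None
            for key in ("snapshot_id", "time_ps", "excitations"):
                if key not in d:
                    raise ValidationError(f"line {lineno}: record missing field {key!r}")
            sid = str(d["snapshot_id"])
            records.append(
                SnapshotRecord(
                    snapshot_id=sid,
                    time_ps=float(d["time_ps"]),
                    excitations=tuple(_entry_from_json(e, sid) for e in d["excitations"]),
                    dihedrals=None if d.get("dihedrals") is None
                    else {str(k): float(v) for k, v in d["dihedrals"].items()},
                    coeff_block_id=d.get("coeff_block_id"),
                )
            )
    return records


def write_snapshot_records(records: Sequence[SnapshotRecord], path: str | Path) -> int:
    """Write records as JSON Lines; returns the number written."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps({
                "snapshot_id": rec.snapshot_id,
                "time_ps": rec.time_ps,
                "excitations": [_entry_to_json(e) for e in rec.excitations],
                "dihedrals": rec.dihedrals,
                "coeff_block_id": rec.coeff_block_id,
            }) + "\n")
    return len(records)


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------

def read_xyz_trajectory(path: str | Path) -> list[TrajectoryFrame]:
    """Read a multi-frame XYZ file (count line, comment line, N atom lines).

    Raises :class:`ValidationError` with the frame index on a truncated or
    malformed frame.
    """
    frames: list[TrajectoryFrame] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].strip():  # trailing blank lines
            pos += 1
            continue
        try:
            natoms = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise ValidationError(f"frame {frame_index}: bad atom-count line {lines[pos]!r}") from None
        if pos + 2 + natoms > len(lines):
            raise ValidationError(f"frame {frame_index}: truncated (expected {natoms} atoms)")
        names: list[str] = []
        coords = np.empty((natoms, 3))
        for i in range(natoms):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise ValidationError(f"frame {frame_index}: bad coordinate line {lines[pos + 2 + i]!r}")
            names.append(parts[0])
            coords[i] = [float(x) for x in parts[1:4]]
        frames.append(TrajectoryFrame(frame_index=frame_index, coordinates=coords, atom_names=names))
        pos += 2 + natoms
        frame_index += 1
    return frames


def read_pdb_frame(path: str | Path) -> TrajectoryFrame:
    """Read a single-model PDB file as one trajectory frame.

    Only ATOM/HETATM coordinate records are consumed; multi-model files are
    rejected (use multi-frame XYZ for trajectories).
    """
    names: list[str] = []
    coords: list[list[float]] = []
    models = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("MODEL"):
                models += 1
                if models > 1:
                    raise ValidationError("multi-model PDB not supported; use XYZ")
            elif line.startswith(("ATOM", "HETATM")):
                names.append(line[12:16].strip())
                coords.append([float(line[30:38]), float(line[38:46]),
                               float(line[46:54])])
    if not coords:
        raise ValidationError("no ATOM/HETATM records found")
    return TrajectoryFrame(frame_index=0, coordinates=np.asarray(coords),
                           atom_names=names)


def write_xyz_trajectory(frames: Iterable[TrajectoryFrame], path: str | Path,
                         comment: str = "") -> int:
    """Write frames as multi-frame XYZ; returns the number of frames."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for frame in frames:
            fh.write(f"{len(frame.atom_names)}\n")
            fh.write(f"{comment} frame {frame.frame_index}\n")
            for name, (x, y, z) in zip(frame.atom_names, frame.coordinates):
                fh.write(f"{name} {x:.10f} {y:.10f} {z:.10f}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Sampling bookkeeping
# ---------------------------------------------------------------------------

def sample_count(duration_ps: float, interval_ps: float) -> int:
    """Number of uncorrelated snapshots from a run of ``duration_ps``.

    Snapshots sit at t = interval, 2·interval, …, duration (t = 0 excluded),
    so a 10 ns production run sampled every 10 ps yields 1000 snapshots.
    """
    if duration_ps <= 0 or interval_ps <= 0:
        raise ValueError("duration_ps and interval_ps must be positive")
    ratio = duration_ps / interval_ps
    if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
        raise ValueError(
            f"duration {duration_ps} ps is not a multiple of interval {interval_ps} ps"
        )
    return int(round(ratio))
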