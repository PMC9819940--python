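"""Molecular-orbital energetics and atomic-orbital composition analysis.

The bathochromic trend across halogenated azobenzenes traces back to the
orbital the excitation departs from: as the halogen's highest occupied
atomic orbital rises (F → Cl → Br), its lone pairs mix more strongly into
the molecular HOMO and push it up, narrowing the HOMO–LUMO gap.  This module
quantifies that story with

* an approximate per-atom-type AO weight, ω_αi = (1/N_α) Σ_j |c_ji|² δ_jα,
  computed directly from LCAO coefficients (the AO basis is non-orthonormal,
  so ω is approximate and not bounded above by 1);
* distributions and averages of the departing/receiving MO energies over a
  snapshot ensemble;
* the correlation between the ensemble-mean departing-MO energy and the
  free-halide sHOMO energy.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .records import SnapshotRecord, ValidationError

__all__ = [
    "HALIDE_SHOMO_EV",
    "OrbitalCoefficientBlock",
    "AtomTypeWeight",
    "ao_weight",
    "mo_energy_stats",
    "mo_energy_histogram",
    "halide_trend",
    "read_coeff_block_csv",
    "write_coeff_block_csv",
]

#: Energy of the highest occupied atomic (spin) orbital of the free halogen,
#: eV.  These are tabulated inputs to the trend analysis, never computed here.
HALIDE_SHOMO_EV = {"F": -15.2, "Cl": -11.5, "Br": -10.5}


@dataclass(frozen=True)
class OrbitalCoefficientBlock:
    """LCAO coefficients c_ji with AO→atom and atom→type maps.

    ``coefficients`` has shape (n_AO, n_MO); ``ao_atom[j]`` is the atom index
    carrying AO j; ``atom_type`` maps atom index → element/type label;
    ``mo_labels`` optionally tags MO columns (HOMO / LUMO / other).
    """

    coefficients: np.ndarray
    ao_atom: tuple[int, ...]
    atom_type: dict[int, str]
    mo_labels: dict[int, str] | None = None
    mo_energies: dict[int, float] | None = None

    def __post_init__(self) -> None:
        coeff = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coeff)
        object.__setattr__(self, "ao_atom", tuple(int(a) for a in self.ao_atom))
        if coeff.ndim != 2:
            raise ValidationError("coefficients must be a 2-D (n_AO, n_MO) matrix")
        if len(self.ao_atom) != coeff.shape[0]:
            raise ValidationError("ao_atom length must equal the number of AO rows")
        missing = set(self.ao_atom) - set(self.atom_type)
        if missing:
            raise ValidationError(f"atoms {sorted(missing)} have no type label")

    @property
    def n_ao(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_mo(self) -> int:
        return self.coefficients.shape[1]

    def atoms_of_type(self, atom_type: str) -> list[int]:
        return [a for a, t in self.atom_type.items() if t == atom_type]

    def mo_index_for(self, label: str) -> int:
        if not self.mo_labels:
            raise KeyError(f"block carries no MO labels (wanted {label!r})")
        for i, lab in self.mo_labels.items():
            if lab == label:
                return i
        raise KeyError(f"no MO labelled {label!r}")


@dataclass(frozen=True)
class AtomTypeWeight:
    """ω_αi for one atom type in one labelled MO."""

    atom_type: str
    mo_role: str
    omega: float

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValidationError("omega must be >= 0")


def ao_weight(block: OrbitalCoefficientBlock, mo_index: int, atom_type: str) -> float:
    """Approximate weight of atoms of type α in MO i.

    ω_αi = (1/N_α) Σ_j |c_ji|² δ_jα, where the sum runs over all AOs, δ_jα
    selects AOs sitting on atoms of type α, and N_α is the number of such
    atoms (e.g. two for the azo nitrogens, four for the ortho halogens).
    No orthogonalization is applied, so Σ_α N_α ω_α equals the MO norm only
    for an orthonormal AO basis.
    """
    if not 0 <= mo_index < block.n_mo:
        raise IndexError(f"mo_index {mo_index} outside 0..{block.n_mo - 1}")
    atoms = block.atoms_of_type(atom_type)
    if not atoms:
        raise ValueError(f"no atoms of type {atom_type!r} in block")
    atom_set = set(atoms)
    col = block.coefficients[:, mo_index]
    mask = np.fromiter((a in atom_set for a in block.ao_atom), dtype=bool, count=block.n_ao)
    return float(np.sum(col[mask] ** 2) / len(atoms))


def _mo_energies(records: Iterable[SnapshotRecord], which: str,
                 state_index: int) -> np.ndarray:
    if which not in ("initial", "final"):
        raise ValueError("which must be 'initial' or 'final'")
    out = []
    for rec in records:
        exc = rec.excitation(state_index)
        if exc is None:
            continue
        e = exc.e_mo_initial if which == "initial" else exc.e_mo_final
        if e is not None:
            out.append(e)
    return np.asarray(out, dtype=float)


def mo_energy_stats(records: Sequence[SnapshotRecord], which: str,
                    state_index: int = 1) -> tuple[float, float, int]:
    """Mean, sample sd and count of the departing/receiving MO energy.

    ``which`` selects ``'initial'`` (the orbital the excitation starts from)
    or ``'final'``; only records carrying that energy for ``state_index``
    contribute.
    """
    e = _mo_energies(records, which, state_index)
    if len(e) == 0:
        raise ValueError(f"no records carry the {which} MO energy for state {state_index}")
    sd = float(np.std(e, ddof=1)) if len(e) > 1 else 0.0
    return float(np.mean(e)), sd, len(e)


def mo_energy_histogram(records: Sequence[SnapshotRecord], which: str,
                        state_index: int = 1,
                        bin_width_ev: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Frequency histogram (weight 1 per snapshot) of an MO energy.

    Returns ``(bin_edges, counts)``; bins are aligned to multiples of the
    bin width and cover the data range.
    """
    if bin_width_ev <= 0:
        raise ValueError("bin_width_ev must be positive")
    e = _mo_energies(records, which, state_index)
    if len(e) == 0:
        raise ValueError(f"no records carry the {which} MO energy for state {state_index}")
    lo = np.floor(e.min() / bin_width_ev) * bin_width_ev
    hi = np.ceil(e.max() / bin_width_ev) * bin_width_ev
    if hi <= lo + 1e-12:
        hi = lo + bin_width_ev
    nbins = int(round((hi - lo) / bin_width_ev))
    edges = lo + bin_width_ev * np.arange(nbins + 1)
    counts, _ = np.histogram(e, bins=edges)
    return edges, counts


def halide_trend(pairs: Sequence[tuple[float, float]]) -> tuple[float, bool]:
    """Correlation of the departing-MO mean energy with the halide sHOMO.

    ``pairs`` are ``(sHOMO_eV, mean_MOi_eV)`` tuples, one per substituent.
    Returns the Pearson r and a flag for whether the mean MOi energy is
    nondecreasing in sHOMO — the monotonicity carries the design claim that
    a higher halide lone-pair energy lifts the molecular HOMO.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (sHOMO, mean_MOi) pairs")
    arr = np.asarray(pairs, dtype=float)
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in sHOMO or mean MOi values")
    r = float(stats.pearsonr(x, y).statistic)
    order = np.argsort(x)
    monotonic = bool(np.all(np.diff(y[order]) >= 0))
    return r, monotonic


# ---------------------------------------------------------------------------
# Coefficient-block sidecar CSV
# ---------------------------------------------------------------------------

_COEFF_COLUMNS = ["ao_index", "atom_index", "atom_type", "mo_index", "coefficient"]


def write_coeff_block_csv(block: OrbitalCoefficientBlock, path: str | Path) -> None:
    """Write a block as the sidecar CSV (one row per AO×MO coefficient)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COEFF_COLUMNS)
        for j in range(block.n_ao):
            atom = block.ao_atom[j]
            for i in range(block.n_mo):
                writer.writerow([j, atom, block.atom_type[atom], i,
                                 repr(float(block.coefficients[j, i]))])


def read_coeff_block_csv(path: str | Path) -> OrbitalCoefficientBlock:
    """Read a coefficient block from the sidecar CSV format."""
    rows = []
    with open(path, "r", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _COEFF_COLUMNS:
            raise ValidationError(f"coefficient CSV must have columns {_COEFF_COLUMNS}")
        for row in reader:
            rows.append((int(row["ao_index"]), int(row["atom_index"]),
                         row["atom_type"], int(row["mo_index"]),
                         float(row["coefficient"])))
    if not rows:
        raise ValidationError("empty coefficient CSV")
    n_ao = max(r[0] for r in rows) + 1
    n_mo = max(r[3] for r in rows) + 1
    coeff = np.zeros((n_ao, n_mo))
    ao_atom = [0] * n_ao
    atom_type: dict[int, str] = {}
    for j, atom, typ, i, c in rows:
        coeff[j, i] = c
        ao_atom[j] = atom
        atom_type[atom] = typ
    return OrbitalCoefficientBlock(coefficients=coeff, ao_atom=tuple(ao_atom),
                                   atom_type=atom_type)
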