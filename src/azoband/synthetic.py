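"""Synthetic snapshot ensembles with the statistical skeleton of QM/MM data.

Real input to the ensemble spectrum method is a stream of thousands of
TD-DFT calculations on MD snapshots — far too expensive to regenerate.
This generator emulates the *statistical structure* of that stream for
tetra-ortho-substituted azobenzenes (X = H, F, Cl, Br):

* azo C–N=N–C dihedral: wrapped normal around 180° (stable E configuration);
* phenyl-ring torsions: substituent-dependent circular mixtures — unimodal
  at 0° (Cl), bimodal 0°/±180° (H, F), staggered ±150°/±30° with unequal
  masses (Br), and a "perpendicular-lock" ±90° mode emulating the known
  force-field artifact;
* departing/receiving MO energies: normal, with substituent-dependent means;
* S1 excitation energy: positive-truncated normal;
* S1 oscillator strength: either |normal|, or — for the planar X=H case,
  where the transition is symmetry-forbidden at the C2h geometry —
  f = f_max · sin² of the ring torsional deviation from planarity, which is
  exactly zero at the symmetric geometry and positive elsewhere;
* S2: strong transition with normal energy and strength.

Everything is reproducible: a fixed seed gives bit-identical ensembles, and
per-compound streams are split deterministically from one top seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .records import DihedralSpec, ExcitationEntry, SnapshotRecord, TrajectoryFrame
from .geometry import planarity_deviation, wrap_angle
from .orbitals import OrbitalCoefficientBlock

__all__ = [
    "SubstituentConfig",
    "GeneratedEnsemble",
    "SUBSTITUENT_DEFAULTS",
    "TOY_DIHEDRALS",
    "substituent_config",
    "generate_ensemble",
    "generate_coeff_block",
    "four_compound_scenario",
]


@dataclass(frozen=True)
class SubstituentConfig:
    """Generator parameters for one compound.

    Energy means default to the ensemble averages of the compounds this
    generator emulates; widths are synthetic parameters (the figures show
    only distribution shapes).  ``phenyl_mixture`` is a list of
    ``(center_deg, sd_deg, mass)`` circular components with masses summing
    to 1.  ``coupling_planarity`` switches the S1 strength to the
    sin²-of-torsion rule that vanishes at the planar geometry.
    """

    label: str
    n_snapshots: int
    mean_e_moi: float            # eV, departing MO
    mean_e_mof: float            # eV, receiving MO
    mean_delta_e_s1: float       # eV
    mean_delta_e_s2: float       # eV
    f_s1_max: float
    f_s2: float
    sd_mo: float = 0.20          # eV
    sd_delta_e: float = 0.12     # eV
    sd_s2: float = 0.12          # eV
    phenyl_mixture: tuple[tuple[float, float, float], ...] = ((0.0, 15.0, 1.0),)
    azo_center_deg: float = 180.0
    azo_sd_deg: float = 8.0
    coupling_planarity: bool = False
    seed: int = 0
    interval_ps: float = 10.0

    def __post_init__(self) -> None:
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")
        for sd in (self.sd_mo, self.sd_delta_e, self.sd_s2, self.azo_sd_deg):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        masses = [m for _, _, m in self.phenyl_mixture]
        if abs(sum(masses) - 1.0) > 1e-9 or any(m < 0 for m in masses):
            raise ValueError("phenyl_mixture masses must be >= 0 and sum to 1")
        if any(sd < 0 for _, sd, _ in self.phenyl_mixture):
            raise ValueError("phenyl_mixture sds must be >= 0")


#: Per-substituent defaults.  ⟨ΔE(S1)⟩ and the MO-energy means follow the
#: ensemble averages of the emulated compounds; S2 and f parameters follow
#: the vertical values where available, otherwise declared synthetic; ring
#: mixtures encode the qualitative torsion distributions (see docs/methods.md).
SUBSTITUENT_DEFAULTS: dict[str, dict] = {
    "H": dict(mean_delta_e_s1=2.645, mean_e_moi=-8.357, mean_e_mof=-1.606,
              mean_delta_e_s2=4.112, f_s1_max=0.10, f_s2=0.779,
              coupling_planarity=True,
              phenyl_mixture=((0.0, 15.0, 0.5), (180.0, 15.0, 0.5))),
    "F": dict(mean_delta_e_s1=2.509, mean_e_moi=-8.376, mean_e_mof=-1.774,
              mean_delta_e_s2=4.525, f_s1_max=0.037, f_s2=0.710,
              phenyl_mixture=((0.0, 15.0, 0.5), (180.0, 15.0, 0.5))),
    "Cl": dict(mean_delta_e_s1=2.114, mean_e_moi=-7.920, mean_e_mof=-2.003,
               mean_delta_e_s2=4.512, f_s1_max=0.025, f_s2=0.60,
               phenyl_mixture=((0.0, 15.0, 1.0),)),
    "Br": dict(mean_delta_e_s1=2.091, mean_e_moi=-7.673, mean_e_mof=-1.939,
               mean_delta_e_s2=4.50, f_s1_max=0.030, f_s2=0.50,
               azo_sd_deg=10.0,
               phenyl_mixture=((150.0, 12.0, 0.35), (-150.0, 12.0, 0.35),
                               (30.0, 12.0, 0.15), (-30.0, 12.0, 0.15))),
}

#: ±90° ring mixture emulating the perpendicular force-field lock.
PERPENDICULAR_MIXTURE: tuple[tuple[float, float, float], ...] = (
    (90.0, 10.0, 0.5), (-90.0, 10.0, 0.5))


def substituent_config(label: str, n_snapshots: int = 3000, seed: int = 0,
                       perpendicular_artifact: bool = False,
                       **overrides) -> SubstituentConfig:
    """Config for a named substituent at its defaults, with overrides.

    ``perpendicular_artifact=True`` swaps the ring mixture for the ±90°
    lock (the spectra and MO draws are unchanged).
    """
    if label not in SUBSTITUENT_DEFAULTS:
        raise KeyError(f"unknown substituent {label!r}; use "
                       f"{sorted(SUBSTITUENT_DEFAULTS)} or build a custom config")
    params = dict(SUBSTITUENT_DEFAULTS[label])
    if perpendicular_artifact:
        params["phenyl_mixture"] = PERPENDICULAR_MIXTURE
    params.update(overrides)
    return SubstituentConfig(label=label, n_snapshots=n_snapshots, seed=seed, **params)


# ---------------------------------------------------------------------------
# Toy geometry: a 6-site azo core carrying exactly the configured torsions
# ---------------------------------------------------------------------------

#: Atom order of the toy molecule: CA, NA, NB, CB (azo core) plus one ring
#: probe atom per phenyl (RA on CA, RB on CB).
TOY_ATOM_NAMES = ("C", "N", "N", "C", "C", "C")

TOY_DIHEDRALS = (
    DihedralSpec("azo_CNNC", (0, 1, 2, 3), "azo_EZ"),
    DihedralSpec("phenyl_A", (4, 0, 1, 2), "phenyl_inclination"),
    DihedralSpec("phenyl_B", (1, 2, 3, 5), "phenyl_inclination"),
)

_BOND = 1.4       # Å, generic heavy-atom bond
_ANGLE = 115.0    # deg, generic sp2 valence angle


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of atom d from chain a–b–c.

    Returns d with |c−d| = bond, angle(b,c,d) = angle_deg and
    dihedral(a,b,c,d) = torsion_deg under this package's sign convention.
    """
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-math.cos(theta),
                               math.sin(theta) * math.cos(chi),
                               math.sin(theta) * math.sin(chi)])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def _toy_frame(frame_index: int, azo_deg: float, phenyl_a_deg: float,
               phenyl_b_deg: float) -> TrajectoryFrame:
    na = np.zeros(3)
    nb = np.array([1.25, 0.0, 0.0])
    theta = math.radians(_ANGLE)
    ca = na + _BOND * np.array([math.cos(theta), math.sin(theta), 0.0])
    cb = _place(ca, na, nb, _BOND, _ANGLE, azo_deg)
    ra = _place(nb, na, ca, _BOND, _ANGLE, phenyl_a_deg)
    rb = _place(na, nb, cb, _BOND, _ANGLE, phenyl_b_deg)
    coords = np.vstack([ca, na, nb, cb, ra, rb])
    return TrajectoryFrame(frame_index=frame_index, coordinates=coords,
                           atom_names=TOY_ATOM_NAMES)


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratedEnsemble:
    """Snapshot records plus the matching toy trajectory."""

    records: tuple[SnapshotRecord, ...]
    trajectory: tuple[TrajectoryFrame, ...]
    config_echo: SubstituentConfig


def _truncated_positive(rng: np.random.Generator, mean: float, sd: float,
                        size: int) -> np.ndarray:
    if sd == 0:
        if mean <= 0:
            raise ValueError("degenerate distribution at a non-positive mean")
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def _mixture_draw(rng: np.random.Generator,
                  mixture: Sequence[tuple[float, float, float]],
                  size: int) -> np.ndarray:
    centers = np.array([c for c, _, _ in mixture])
    sds = np.array([s for _, s, _ in mixture])
    masses = np.array([m for _, _, m in mixture])
    comp = rng.choice(len(mixture), size=size, p=masses)
    raw = centers[comp] + rng.normal(0.0, 1.0, size) * sds[comp]
    return wrap_angle(raw)


def generate_ensemble(config: SubstituentConfig) -> GeneratedEnsemble:
    """Draw one reproducible snapshot ensemble from a compound config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_snapshots

    azo = wrap_angle(config.azo_center_deg + rng.normal(0.0, config.azo_sd_deg, n)
                     if config.azo_sd_deg > 0 else np.full(n, config.azo_center_deg))
    phenyl_a = _mixture_draw(rng, config.phenyl_mixture, n)
    phenyl_b = _mixture_draw(rng, config.phenyl_mixture, n)

    e_moi = (rng.normal(config.mean_e_moi, config.sd_mo, n)
             if config.sd_mo > 0 else np.full(n, config.mean_e_moi))
    e_mof = (rng.normal(config.mean_e_mof, config.sd_mo, n)
             if config.sd_mo > 0 else np.full(n, config.mean_e_mof))
    # the departing orbital must stay below the receiving one; with the
    # compound defaults (gap ≫ sd) a redraw is astronomically rare
    bad = e_moi >= e_mof
    while bad.any():
        k = int(bad.sum())
        e_moi[bad] = rng.normal(config.mean_e_moi, config.sd_mo, k)
        e_mof[bad] = rng.normal(config.mean_e_mof, config.sd_mo, k)
        bad = e_moi >= e_mof

    de1 = _truncated_positive(rng, config.mean_delta_e_s1, config.sd_delta_e, n)
    de2 = _truncated_positive(rng, config.mean_delta_e_s2, config.sd_s2, n)

    if config.coupling_planarity:
        dev = np.radians(np.stack([planarity_deviation(phenyl_a),
                                   planarity_deviation(phenyl_b)]))
        f1 = config.f_s1_max * np.mean(np.sin(dev) ** 2, axis=0)
    else:
        f1 = np.minimum(np.abs(rng.normal(config.f_s1_max,
                                          0.1 * config.f_s1_max, n)), 1.0)
    f2 = _truncated_positive(rng, config.f_s2, 0.1 * config.f_s2, n)

    records = []
    frames = []
    for i in range(n):
        entries = (
            ExcitationEntry(state_index=1, delta_e=float(de1[i]),
                            osc_strength=float(f1[i]),
                            e_mo_initial=float(e_moi[i]),
                            e_mo_final=float(e_mof[i])),
            ExcitationEntry(state_index=2, delta_e=float(de2[i]),
                            osc_strength=float(f2[i])),
        )
        records.append(SnapshotRecord(
            snapshot_id=f"{config.label}-{i + 1:05d}",
            time_ps=(i + 1) * config.interval_ps,
            excitations=entries,
            dihedrals={"azo_CNNC": float(azo[i]),
                       "phenyl_A": float(phenyl_a[i]),
                       "phenyl_B": float(phenyl_b[i])},
        ))
        frames.append(_toy_frame(i, float(azo[i]), float(phenyl_a[i]),
                                 float(phenyl_b[i])))
    return GeneratedEnsemble(records=tuple(records), trajectory=tuple(frames),
                             config_echo=config)


def generate_coeff_block(targets: dict[str, dict[str, float]],
                         n_atoms: dict[str, int],
                         aos_per_atom: int = 3,
                         seed: int = 0) -> OrbitalCoefficientBlock:
    """Random LCAO block whose per-type AO weights hit given targets exactly.

    ``targets`` maps an MO label (e.g. "HOMO") to ``{atom_type: ω}``;
    coefficients on each type are drawn and rescaled so the resulting weight
    equals the target (Σ_j |c_ji|² over type α = ω · N_α).  Types absent
    from an MO's target map get zero coefficients.
    """
    if aos_per_atom < 1:
        raise ValueError("aos_per_atom must be >= 1")
    rng = np.random.default_rng(seed)
    atom_type: dict[int, str] = {}
    ao_atom: list[int] = []
    atom_index = 0
    for typ, count in n_atoms.items():
        if count < 1:
            raise ValueError(f"need >= 1 atom of type {typ!r}")
        for _ in range(count):
            atom_type[atom_index] = typ
            ao_atom.extend([atom_index] * aos_per_atom)
            atom_index += 1
    n_ao = len(ao_atom)
    labels = list(targets)
    coeff = np.zeros((n_ao, len(labels)))
    for col, label in enumerate(labels):
        for typ, omega in targets[label].items():
            if typ not in n_atoms:
                raise ValueError(f"target for unknown atom type {typ!r}")
            if omega < 0:
                raise ValueError("target weights must be >= 0")
            if omega == 0:
                continue
            mask = np.array([atom_type[a] == typ for a in ao_atom])
            raw = rng.normal(size=int(mask.sum()))
            norm = np.sqrt(np.sum(raw ** 2))
            while norm == 0:   # pragma: no cover - probability zero
                raw = rng.normal(size=int(mask.sum()))
                norm = np.sqrt(np.sum(raw ** 2))
            target_norm = math.sqrt(omega * n_atoms[typ])
            coeff[mask, col] = raw / norm * target_norm
    return OrbitalCoefficientBlock(
        coefficients=coeff, ao_atom=tuple(ao_atom), atom_type=atom_type,
        mo_labels={i: lab for i, lab in enumerate(labels)})


def four_compound_scenario(seed: int = 0,
                           n_snapshots: int = 3000) -> dict[str, GeneratedEnsemble]:
    """The H/F/Cl/Br comparison: four default ensembles from one seed.

    Per-compound streams are split from the top seed with a SeedSequence, so
    every compound is independently reproducible.
    """
    children = np.random.SeedSequence(seed).spawn(len(SUBSTITUENT_DEFAULTS))
    out = {}
    for child, label in zip(children, SUBSTITUENT_DEFAULTS):
        sub_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        out[label] = generate_ensemble(
            substituent_config(label, n_snapshots=n_snapshots, seed=sub_seed))
    return out
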