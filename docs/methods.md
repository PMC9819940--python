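# Methods

## The ensemble band model

The package treats an absorption band as the thermal average of vertical
transition probabilities. For an ensemble of geometries sampled from an MD
trajectory (one snapshot every 10 ps, so consecutive snapshots are
decorrelated; t = 0 is excluded, so a 10 ns run yields exactly 1000
snapshots), each excited state of each snapshot contributes

    w_if = f_if / ΔE_if

to the histogram bin containing its excitation energy ΔE_if. This follows
from the oscillator-strength definition f = (2mₑ/3ħ²e²)·ΔE·|μ|²: dividing f
by ΔE leaves a quantity proportional to |μ|², i.e. to the transition
probability. `dipole_sq_from_f` inverts the same relation in atomic units
(f = (2/3)·ΔE_Ha·|μ|²) when the dipole itself is wanted.

Assumptions and deliberate omissions:

* purely electronic, classical-nuclei picture — no Franck–Condon or
  Herzberg–Teller vibronic structure, no lifetime (Lorentzian) broadening;
  the band width comes entirely from the geometric spread of the ensemble;
* the histogram is accumulated on an energy grid (default 1.0–7.0 eV,
  0.05 eV bins) and only the *axis* is converted to wavelength for
  reporting; no dλ/dE Jacobian re-weighting is applied, because the model
  defines the band in energy and the wavelength axis is presentation;
* intensities are arbitrary units; the default report normalizes each
  spectrum to unit maximum;
* an optional Gaussian kernel (σ in eV, area-preserving on a covering grid)
  smooths for presentation; all conservation properties are stated for the
  raw (kernel 0) histogram.

Band maxima are reported as the bin-center wavelength of the largest
intensity inside a stated search window, with ties broken toward longer
wavelength (the red edge is what decides usability in the tissue optical
window). For *locating* maxima the pipeline uses a finer 0.01 eV grid with
a 0.10 eV kernel: the mode of a smoothed density is stable enough at
n = 3000 to resolve compounds whose mean excitation energies differ by only
~0.02 eV, which raw 0.05 eV bins are not.

## Orbital analysis

The approximate weight of atoms of type α in MO i is

    ω_αi = (1/N_α) Σ_j |c_ji|² δ_jα

with real LCAO coefficients c_ji, δ_jα selecting AOs on α atoms, and N_α
the number of α atoms (two azo nitrogens; four ortho halogens). The AO
basis is non-orthonormal, so ω is approximate and not bounded by 1; no
Löwdin orthogonalization is attempted — ω is reported exactly as defined.

The halide trend couples two quantities: the ensemble-mean energy of the
orbital the S1 excitation departs from (⟨E(MOi)⟩, the HOMO) and the energy
of the free halogen's highest occupied atomic orbital (sHOMO: −15.2 eV for
F, −11.5 eV for Cl, −10.5 eV for Br — tabulated inputs, never computed).
With only three or four substituents a rank statistic is meaningless, so
`halide_trend` reports the Pearson r together with an explicit
monotonicity flag; the flag, not the r, carries the scientific claim.

## Geometry diagnostics

Torsions use the standard signed convention (atan2 of cross products;
anti-periplanar = 180°, values in (−180°, 180]). Collinear quadruples raise
instead of returning 0 — a silent zero would silently distort the circular
distributions. E/Z classification assigns the |φ| = 90° boundary to E.

"Coplanar" is operationalized as a deviation min(|φ|, 180°−|φ|) of at most
30° from the azo plane (configurable). The perpendicular-ring artifact is
flagged when the coplanar fraction falls below 0.05 *and* the circular
histogram has a mode within 15° of ±90°; both conditions together separate
a genuinely locked-perpendicular ensemble from one that is merely broad.

## The synthetic generator

The generator emulates the statistical structure of a QM/MM + TD-DFT
snapshot stream; it makes no claim of physical realism (no solvent, no
force field, no electronic structure). Per compound it draws, per snapshot:

* azo C–N=N–C dihedral: wrapped normal, center 180°, sd 8° (10° for Br,
  whose distribution is slightly broader);
* two phenyl torsions, i.i.d. from a circular mixture of wrapped normals:
  unimodal at 0° (Cl), bimodal 0°/±180° (H, F), staggered
  ±150° (mass 0.70) / ±30° (mass 0.30) with sd 12° (Br), or the ±90°
  "perpendicular lock" used to emulate the force-field artifact;
* MO energies: normal with compound-specific means and sd 0.20 eV;
* ΔE(S1), ΔE(S2): positive-truncated normals (ΔE is generated directly,
  not as the orbital gap, since the ensemble-average excitation energy
  differs from the average HOMO–LUMO gap);
* f(S2): positive-truncated normal around a strong value;
* f(S1): either |N(f₁, 0.1·f₁)| capped at 1, or — when the planarity
  coupling is on, as for the parent compound whose S1 is forbidden at the
  C2h geometry — f = f_max · mean over the two rings of sin²(θ_dev), with
  θ_dev the ring's deviation from 0°/180°. sin² is the simplest form that
  vanishes exactly at the symmetric geometry and is positive elsewhere.

Compound means for ΔE(S1) and the MO energies are the ensemble averages of
the emulated compounds (H 2.645 / −8.357 / −1.606; F 2.509 / −8.376 /
−1.774; Cl 2.114 / −7.920 / −2.003; Br 2.091 / −7.673 / −1.939 eV); S2
energies and strengths use the vertical gas-phase values where available
(the Br S2 parameters, 4.50 eV and f = 0.30, are declared synthetic, as is
Cl's ensemble S2 strength 0.60 — the vertical S2 strength of the
chlorinated compound is anomalously small, while the ensemble UV band it
stands in for is strong). Distribution widths are free parameters chosen
once: sd(ΔE) = 0.12 eV gives the S1 band a visible ~0.3 eV FWHM (several
tens of nm at these energies, matching the qualitative spread of the
ensemble bands) without touching the S2 region.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: correlations between successive
snapshots, coupling between the azo torsion and the excitation energies,
solvent-shift fluctuations, more than two excited states, and any anharmonic
or non-Gaussian features of the real distributions. Tests against the
generator validate the *analysis machinery* (weighting, binning,
statistics, diagnostics), not the electronic-structure content.

A toy 6-site geometry (azo core C–N=N–C plus one probe atom per ring)
carries exactly the drawn torsions, so trajectory-side code paths can be
validated against the records' stored dihedral values frame by frame.

Reproducibility: one `numpy.random.Generator` per ensemble, seeded from
the config; multi-compound runs split a top-level `SeedSequence`
deterministically, so identical seeds give byte-identical outputs.

## Numerical choices

* hc = 1239.84198 eV·nm; 1 Ha = 27.211386 eV.
* Histogram bins are half-open [left, right); the spectrum's last bin also
  accepts its right edge (numpy convention), and circular bins place an
  exact 180° value in the last bin.
* Sample sd uses ddof = 1 (0 for a single observation).
* Degenerate generator widths (sd = 0) are allowed and collapse to the
  mean — useful for limiting-case tests.
* Validation errors name the offending record and field; trajectory parse
  errors name the frame index.

## Problem sizes

The full four-compound scenario runs at n = 3000 snapshots per compound
(the size the 30 ns / 10 ps sampling implies); statistical recovery tests
use three-standard-error bands at that n. Structural pipeline tests use
smaller ensembles (200–500 snapshots) where only shapes, file formats and
determinism are at stake.

## Known limitations

* The JSON-Lines schema is the only ingestion path; adapters from specific
  quantum-chemistry output formats are out of scope.
* Only single-model PDB / multi-frame XYZ trajectories are read; binary
  formats are not.
* The perpendicular-artifact detector keys on the ±90° mode specifically;
  other pathological torsion distributions require inspection of the
  circular histogram itself.
* ω values are basis-dependent and non-orthonormality is not corrected;
  compare ω only within one basis-set convention.
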