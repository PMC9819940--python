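"""Ensemble absorption spectra from snapshot excitation lists.

The band shape is assembled without any vibronic model: every vertical
excitation of every snapshot contributes its transition probability
P ∝ f/ΔE to a histogram over excitation energy.  Summed over a thermal
ensemble of geometries this histogram is proportional to the absorption
spectrum, including bands that are strictly forbidden (f = 0) at the
minimum-energy geometry but become weakly allowed once thermal distortion
breaks the symmetry — the signature behaviour of the azobenzene nπ* band.

Histograms are accumulated on an excitation-energy grid (eV); only the axis
is converted to wavelength for reporting, with no Jacobian re-weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import SnapshotRecord

__all__ = [
    "HC_EV_NM",
    "HARTREE_EV",
    "ev_to_nm",
    "nm_to_ev",
    "transition_weight",
    "dipole_sq_from_f",
    "SpectrumHistogram",
    "BandReport",
    "default_grid",
    "build_spectrum",
    "band_maximum",
    "spectrum_to_dataframe",
]

HC_EV_NM = 1239.84198     # hc, eV·nm
HARTREE_EV = 27.211386    # 1 Hartree in eV

#: Default excitation-energy grid: 1.0–7.0 eV in 0.05 eV bins.
DEFAULT_EMIN_EV = 1.0
DEFAULT_EMAX_EV = 7.0
DEFAULT_BIN_EV = 0.05


def ev_to_nm(energy_ev: float) -> float:
    """Convert a photon energy (eV) to wavelength (nm), λ = hc/E."""
    energy_ev = np.asarray(energy_ev, dtype=float)
    if np.any(energy_ev <= 0):
        raise ValueError("energy must be positive")
    out = HC_EV_NM / energy_ev
    return float(out) if out.ndim == 0 else out


def nm_to_ev(wavelength_nm: float) -> float:
    """Convert a wavelength (nm) to photon energy (eV), E = hc/λ."""
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    if np.any(wavelength_nm <= 0):
        raise ValueError("wavelength must be positive")
    out = HC_EV_NM / wavelength_nm
    return float(out) if out.ndim == 0 else out


def transition_weight(delta_e_ev: float, osc_strength: float) -> float:
    """Transition probability weight P ∝ f/ΔE of one excitation."""
    if delta_e_ev <= 0:
        raise ValueError("delta_e_ev must be positive")
    if osc_strength < 0:
        raise ValueError("osc_strength must be >= 0")
    return osc_strength / delta_e_ev


def dipole_sq_from_f(delta_e_ev: float, osc_strength: float) -> float:
    """Squared transition dipole |μ|² (atomic units) from f and ΔE.

    Inverts f = (2/3)·ΔE·|μ|² (all in atomic units), so
    |μ|² = 3f / (2·ΔE_Ha) with ΔE_Ha = ΔE_eV / 27.211386.
    """
    if delta_e_ev <= 0:
        raise ValueError("delta_e_ev must be positive")
    if osc_strength < 0:
        raise ValueError("osc_strength must be >= 0")
    return 3.0 * osc_strength / (2.0 * (delta_e_ev / HARTREE_EV))


@dataclass(frozen=True)
class SpectrumHistogram:
    """Binned, f/ΔE-weighted intensity over an excitation-energy grid."""

    bin_edges: np.ndarray          # eV, strictly increasing, len = nbins+1
    intensity: np.ndarray          # arbitrary units, >= 0, len = nbins
    normalized: bool
    kernel_width: float            # eV; 0 = raw histogram
    n_records: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "intensity", inten)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing with >= 2 entries")
        if len(inten) != len(edges) - 1:
            raise ValueError("intensity length must be len(bin_edges) - 1")
        if np.any(inten < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def bin_centers_ev(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_centers_nm(self) -> np.ndarray:
        return HC_EV_NM / self.bin_centers_ev

    def total_weight(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class BandReport:
    """Location of a band maximum inside a wavelength search window."""

    lambda_max_nm: float
    window_nm: tuple[float, float]
    peak_intensity: float

    def __post_init__(self) -> None:
        lo, hi = self.window_nm
        if not (lo <= self.lambda_max_nm <= hi):
            raise ValueError("lambda_max_nm must lie inside window_nm")


def default_grid(emin_ev: float = DEFAULT_EMIN_EV, emax_ev: float = DEFAULT_EMAX_EV,
                 bin_ev: float = DEFAULT_BIN_EV) -> np.ndarray:
    """Uniform excitation-energy bin edges."""
    n = int(round((emax_ev - emin_ev) / bin_ev))
    return emin_ev + bin_ev * np.arange(n + 1)


def _collect(records: Iterable[SnapshotRecord],
             state_filter: set[int] | None) -> tuple[np.ndarray, np.ndarray]:
    de, f = [], []
    for rec in records:
        for exc in rec.excitations:
            if state_filter is not None and exc.state_index not in state_filter:
                continue
            de.append(exc.delta_e)
            f.append(exc.osc_strength)
    return np.asarray(de, dtype=float), np.asarray(f, dtype=float)


def build_spectrum(records: Sequence[SnapshotRecord], grid: np.ndarray | None = None,
                   kernel_width_ev: float = 0.0,
                   state_filter: set[int] | None = None,
                   normalize: bool = False) -> SpectrumHistogram:
    """Accumulate the f/ΔE-weighted excitation-energy histogram.

    With ``kernel_width_ev == 0`` each excitation adds its weight to the bin
    containing its ΔE (the raw histogram; its total conserves Σ f/ΔE over the
    excitations inside the grid).  With a positive width each excitation
    deposits its weight as a Gaussian of that standard deviation evaluated on
    the bin centers — a presentation smoothing only.

    ``state_filter`` restricts to the given state indices (e.g. {1} for the
    S1 band); ``normalize`` rescales the maximum to 1 unless all-zero.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing bin edges")
    if kernel_width_ev < 0:
        raise ValueError("kernel_width_ev must be >= 0")
    records = list(records)
    de, f = _collect(records, state_filter)
    if len(de) == 0:
        intensity = np.zeros(len(grid) - 1)
    else:
        weights = f / de
        if kernel_width_ev == 0.0:
            intensity, _ = np.histogram(de, bins=grid, weights=weights)
        else:
            centers = 0.5 * (grid[:-1] + grid[1:])
            widths = np.diff(grid)
            # normalized Gaussian × bin width: smoothing approximately
            # conserves each excitation's total weight on a covering grid
            z = (centers[None, :] - de[:, None]) / kernel_width_ev
            kern = np.exp(-0.5 * z * z) / (kernel_width_ev * np.sqrt(2.0 * np.pi))
            intensity = (weights[:, None] * kern).sum(axis=0) * widths
    if normalize:
        peak = intensity.max() if len(intensity) else 0.0
        if peak > 0:
            intensity = intensity / peak
    return SpectrumHistogram(bin_edges=grid, intensity=intensity,
                             normalized=normalize, kernel_width=kernel_width_ev,
                             n_records=len(records))


def band_maximum(spectrum: SpectrumHistogram,
                 window_nm: tuple[float, float]) -> BandReport:
    """Bin-center wavelength of the intensity maximum inside ``window_nm``.

    Ties break toward longer wavelength: the red edge of the band decides
    whether a photoswitch can be driven inside the tissue optical window.
    """
    lo, hi = window_nm
    if not (0 < lo < hi):
        raise ValueError("window_nm must satisfy 0 < low < high")
    lam = spectrum.bin_centers_nm
    mask = (lam >= lo) & (lam <= hi)
    if not mask.any():
        raise ValueError(f"no spectrum bins inside window {window_nm}")
    lam_w = lam[mask]
    inten_w = spectrum.intensity[mask]
    best = inten_w.max()
    lam_best = lam_w[inten_w == best].max()
    return BandReport(lambda_max_nm=float(lam_best), window_nm=(lo, hi),
                      peak_intensity=float(best))


def spectrum_to_dataframe(spectrum: SpectrumHistogram):
    """Spectrum as a DataFrame with bin_center_ev, bin_center_nm, intensity."""
    import pandas as pd

    return pd.DataFrame({
        "bin_center_ev": spectrum.bin_centers_ev,
        "bin_center_nm": spectrum.bin_centers_nm,
        "intensity": spectrum.intensity,
    })
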