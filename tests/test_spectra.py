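import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from azoband import (
    ExcitationEntry,
    SnapshotRecord,
    band_maximum,
    build_spectrum,
    dipole_sq_from_f,
    ev_to_nm,
    nm_to_ev,
    transition_weight,
)


def brute_force_histogram(excitations, edges):
    """Independent oracle: explicit double loop over excitations and bins."""
    intensity = np.zeros(len(edges) - 1)
    for de, f in excitations:
        for b in range(len(edges) - 1):
            left, right = edges[b], edges[b + 1]
            last = b == len(edges) - 2
            if (left <= de < right) or (last and de == right):
                intensity[b] += f / de
    return intensity


class TestUnitConversion:
    # printed vertical-excitation (eV, nm) pairs for the tetra-ortho compounds
    @pytest.mark.parametrize("ev, nm", [
        (2.753, 450.3), (4.112, 301.6),
        (2.680, 462.6), (4.525, 274.0),
        (2.685, 461.8), (4.512, 274.8),
        (2.768, 448.0), (3.936, 315.0),
        (2.698, 459.6), (4.249, 291.8),
        (2.716, 456.5), (4.438, 279.4),
    ])
    def test_printed_ev_nm_pairs(self, ev, nm):
        assert ev_to_nm(ev) == pytest.approx(nm, abs=0.15)

    @given(e=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_inverse_composes_to_identity(self, e):
        assert nm_to_ev(ev_to_nm(e)) == pytest.approx(e, rel=1e-12)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            ev_to_nm(0.0)


class TestTransitionWeight:
    def test_hand_arithmetic(self):
        assert transition_weight(2.0, 0.1) == pytest.approx(0.05)

    def test_forbidden_transition_has_zero_weight(self):
        assert transition_weight(3.3, 0.0) == 0.0

    def test_linear_in_oscillator_strength(self):
        assert transition_weight(2.0, 0.2) == pytest.approx(
            2 * transition_weight(2.0, 0.1))

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            transition_weight(-2.0, 0.1)


class TestDipoleFromOscillatorStrength:
    def test_zero_strength_gives_zero_dipole(self):
        assert dipole_sq_from_f(2.0, 0.0) == 0.0

    def test_atomic_unit_identity_case(self):
        # f = (2/3)·ΔE·|μ|² in a.u.: ΔE = 1 Ha, f = 2/3 → |μ|² = 1
        assert dipole_sq_from_f(27.211386, 2.0 / 3.0) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert dipole_sq_from_f(2.0, 0.1) == pytest.approx(2.0409, abs=1e-3)


class TestBuildSpectrum:
    def test_empty_records_give_zero_spectrum(self):
        spec = build_spectrum([])
        assert spec.n_records == 0
        assert np.all(spec.intensity == 0)

    def test_everywhere_forbidden_state_gives_zero_spectrum(self):
        rec = SnapshotRecord("s", 0.0, (ExcitationEntry(1, 2.0, 0.0),))
        spec = build_spectrum([rec])
        assert spec.total_weight() == 0.0

    def test_two_snapshot_hand_summation(self, two_snapshot_records):
        edges = np.array([1.75, 2.25, 2.75])
        spec = build_spectrum(two_snapshot_records, grid=edges)
        np.testing.assert_allclose(spec.intensity, [0.05, 0.08])
        norm = build_spectrum(two_snapshot_records, grid=edges, normalize=True)
        np.testing.assert_allclose(norm.intensity, [0.625, 1.0])

    def test_matches_brute_force_oracle_on_small_ensembles(self, rng):
        for _ in range(20):
            n = rng.integers(1, 11)
            exc = [(float(rng.uniform(1.2, 6.8)), float(rng.uniform(0, 1)))
                   for _ in range(n)]
            records = [SnapshotRecord(f"s{i}", 0.0,
                                      (ExcitationEntry(1, de, f),))
                       for i, (de, f) in enumerate(exc)]
            edges = np.linspace(1.0, 7.0, int(rng.integers(3, 40)))
            spec = build_spectrum(records, grid=edges)
            np.testing.assert_allclose(spec.intensity,
                                       brute_force_histogram(exc, edges),
                                       rtol=1e-10, atol=1e-15)

    def test_total_weight_conserved_under_bin_refinement(self, rng):
        records = [SnapshotRecord(f"s{i}", 0.0,
                                  (ExcitationEntry(1, float(rng.uniform(1.5, 6.5)),
                                                   float(rng.uniform(0, 1))),))
                   for i in range(200)]
        expected = sum(e.osc_strength / e.delta_e
                       for r in records for e in r.excitations)
        for nbins in (60, 120, 240):
            spec = build_spectrum(records, grid=np.linspace(1.0, 7.0, nbins + 1))
            assert spec.total_weight() == pytest.approx(expected, rel=1e-10)

    def test_state_filter_selects_one_band(self, rng):
        records = [SnapshotRecord(f"s{i}", 0.0,
                                  (ExcitationEntry(1, 2.5, 0.02),
                                   ExcitationEntry(2, 4.2, 0.8)))
                   for i in range(5)]
        s1 = build_spectrum(records, state_filter={1})
        assert s1.total_weight() == pytest.approx(5 * 0.02 / 2.5, rel=1e-10)

    def test_smoothing_approximately_conserves_weight(self, two_snapshot_records):
        raw = build_spectrum(two_snapshot_records,
                             grid=np.linspace(1.0, 4.0, 301))
        smooth = build_spectrum(two_snapshot_records,
                                grid=np.linspace(1.0, 4.0, 301),
                                kernel_width_ev=0.05)
        assert smooth.total_weight() == pytest.approx(raw.total_weight(), rel=1e-6)

    def test_bathochromic_shift_is_mechanical(self, rng):
        """Shifting every excitation down in energy moves λmax to the red."""
        de = rng.normal(2.5, 0.1, 500)
        def lam(shift):
            records = [SnapshotRecord(f"s{i}", 0.0,
                                      (ExcitationEntry(1, float(d - shift), 0.02),))
                       for i, d in enumerate(de)]
            spec = build_spectrum(records, grid=np.linspace(1.0, 4.0, 301))
            return band_maximum(spec, (300, 900)).lambda_max_nm
        assert lam(0.3) > lam(0.0)

    def test_invalid_grid_and_kernel_rejected(self, two_snapshot_records):
        with pytest.raises(ValueError):
            build_spectrum(two_snapshot_records, grid=np.array([2.0]))
        with pytest.raises(ValueError):
            build_spectrum(two_snapshot_records, kernel_width_ev=-0.1)


class TestBandMaximum:
    def test_single_nonzero_bin(self):
        edges = np.array([2.69, 2.70])
        rec = SnapshotRecord("s", 0.0, (ExcitationEntry(1, 2.695, 0.1),))
        spec = build_spectrum([rec], grid=edges)
        report = band_maximum(spec, (400, 500))
        assert report.lambda_max_nm == pytest.approx(1239.84198 / 2.695, abs=0.1)

    def test_tie_breaks_toward_longer_wavelength(self):
        edges = np.array([1.95, 2.05, 2.45, 2.55])
        records = [SnapshotRecord("a", 0.0, (ExcitationEntry(1, 2.0, 0.2),)),
                   SnapshotRecord("b", 0.0, (ExcitationEntry(1, 2.5, 0.25),))]
        spec = build_spectrum(records, grid=edges)   # both bins weight 0.1
        np.testing.assert_allclose(spec.intensity[[0, 2]], [0.1, 0.1])
        report = band_maximum(spec, (300, 900))
        assert report.lambda_max_nm == pytest.approx(1239.84198 / 2.0, abs=0.5)

    def test_two_bin_fixture_peak_is_higher_energy_bin(self, two_snapshot_records):
        edges = np.array([1.75, 2.25, 2.75])
        spec = build_spectrum(two_snapshot_records, grid=edges)
        report = band_maximum(spec, (300, 900))
        assert report.lambda_max_nm == pytest.approx(1239.84198 / 2.5, abs=2.0)

    def test_empty_window_rejected(self, two_snapshot_records):
        spec = build_spectrum(two_snapshot_records)
        with pytest.raises(ValueError):
            band_maximum(spec, (100.0, 120.0))
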