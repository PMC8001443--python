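"""Fragment-ion arithmetic, spectrum matching, bond coverage, smoothing."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpp.ions import (
    MONOISOTOPIC_RESIDUE_MASS,
    PROTON_MASS,
    coverage_verdict,
    ion_series,
    match_spectrum,
    monoisotopic_mass,
    precursor_mz,
    savitzky_golay,
)
from bpp.models import SpectrumPeak

PEPTIDES = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=12)


def _ion(ions, ion_type, index, charge=1):
    return next(i for i in ions
                if (i.ion_type, i.index, i.charge) == (ion_type, index, charge))


class TestMasses:
    def test_diglycine(self):
        assert monoisotopic_mass("GG") == pytest.approx(132.0535, abs=1e-4)

    def test_wiqp(self):
        assert monoisotopic_mass("WIQP") == pytest.approx(542.2853, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            monoisotopic_mass("")

    @given(PEPTIDES)
    @settings(max_examples=40, deadline=None)
    def test_agrees_with_pyteomics(self, pep):
        mass = pytest.importorskip("pyteomics.mass")
        assert monoisotopic_mass(pep) == pytest.approx(
            mass.calculate_mass(sequence=pep, monoisotopic=True), abs=1e-4
        )


class TestPrecursor:
    def test_wiqp_singly_charged_reports_543_3(self):
        assert round(precursor_mz("WIQP", 1), 1) == 543.3

    def test_doubly_charged(self):
        assert precursor_mz("WIQP", 2) == pytest.approx(272.15, abs=0.01)

    def test_diglycine(self):
        assert precursor_mz("GG", 1) == pytest.approx(133.06, abs=0.01)

    @pytest.mark.parametrize("charge", [0, 4, -1])
    def test_invalid_charge(self, charge):
        with pytest.raises(ValueError):
            precursor_mz("GG", charge)


class TestIonSeries:
    def test_b2_and_y1_of_wiqp(self):
        ions = ion_series("WIQP", types="by", charges=(1,))
        assert _ion(ions, "b", 2).mz == pytest.approx(300.17, abs=0.01)
        assert _ion(ions, "y", 1).mz == pytest.approx(116.07, abs=0.01)

    def test_indices_stop_before_full_length(self):
        ions = ion_series("WIQP", types="aby", charges=(1, 2, 3))
        assert max(i.index for i in ions) == 3
        assert min(i.index for i in ions) == 1

    def test_all_six_types_and_three_charges_emitted(self):
        ions = ion_series("WIQP", types="abcxyz", charges=(1, 2, 3))
        assert len(ions) == 3 * 6 * 3

    def test_z_conventions_differ_by_one_hydrogen(self):
        default = _ion(ion_series("WIQP", "z", (1,)), "z", 1)
        biemann = _ion(ion_series("WIQP", "z", (1,), z_convention="nh3_loss"), "z", 1)
        assert default.mz - biemann.mz == pytest.approx(1.00783, abs=1e-4)

    def test_dipeptide_minimum(self):
        with pytest.raises(ValueError):
            ion_series("G", "by", (1,))

    @given(PEPTIDES)
    @settings(max_examples=60, deadline=None)
    def test_by_complementarity(self, pep):
        """mz(b_i,1) + mz(y_{L-i},1) == M + 2 protons for every bond."""
        ions = ion_series(pep, types="by", charges=(1,))
        total = monoisotopic_mass(pep) + 2 * PROTON_MASS
        for i in range(1, len(pep)):
            s = _ion(ions, "b", i).mz + _ion(ions, "y", len(pep) - i).mz
            assert s == pytest.approx(total, abs=1e-6)

    @given(PEPTIDES)
    @settings(max_examples=40, deadline=None)
    def test_charge_consistency(self, pep):
        """mz at charge 2 is (mz at charge 1 + one proton) / 2."""
        ions = ion_series(pep, types="by", charges=(1, 2))
        for ion in ions:
            if ion.charge != 1:
                continue
            twin = _ion(ions, ion.ion_type, ion.index, charge=2)
            assert twin.mz == pytest.approx((ion.mz + PROTON_MASS) / 2, abs=1e-9)

    @given(PEPTIDES)
    @settings(max_examples=30, deadline=None)
    def test_prefix_sums_against_direct_summation(self, pep):
        ions = ion_series(pep, types="b", charges=(1,))
        for i in range(1, len(pep)):
            direct = sum(MONOISOTOPIC_RESIDUE_MASS[c] for c in pep[:i]) + PROTON_MASS
            assert _ion(ions, "b", i).mz == pytest.approx(direct, abs=1e-9)


class TestMatchSpectrum:
    def test_within_tolerance_matches_and_records_delta(self):
        ions = ion_series("WIQP", "b", (1,))
        b2 = _ion(ions, "b", 2)
        peaks = [SpectrumPeak(mz=b2.mz + 0.03, intensity=10.0)]
        (m,) = match_spectrum(peaks, [b2], tolerance=0.3)
        assert m.delta == pytest.approx(0.03, abs=1e-9)

    def test_outside_tolerance_not_matched(self):
        ions = ion_series("WIQP", "b", (1,))
        b2 = _ion(ions, "b", 2)
        peaks = [SpectrumPeak(mz=b2.mz + 0.83, intensity=10.0)]
        assert match_spectrum(peaks, [b2], tolerance=0.3) == []

    def test_one_peak_may_serve_multiple_ions(self):
        ions = ion_series("LL", "by", (1,))  # b1 and y1 far apart; fake near-isobars
        peak = [SpectrumPeak(mz=ions[0].mz, intensity=1.0)]
        near = [i for i in ions if abs(i.mz - ions[0].mz) < 0.3]
        matched = match_spectrum(peak, near, tolerance=0.3)
        assert len(matched) == len(near)

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            match_spectrum([], [], tolerance=0.0)


class TestCoverageVerdict:
    def test_bond_mapping_b2_y1_y3_covers_all_of_tetrapeptide(self):
        ions = ion_series("WIQP", "by", (1,))
        chosen = [_ion(ions, "b", 2), _ion(ions, "y", 1), _ion(ions, "y", 3)]
        peaks = [SpectrumPeak(mz=i.mz, intensity=1.0) for i in chosen]
        verdict = coverage_verdict(match_spectrum(peaks, chosen, 0.3), 4)
        assert verdict.bonds_covered == {1: True, 2: True, 3: True}
        assert verdict.success

    def test_single_ion_insufficient(self):
        ions = ion_series("WIQP", "b", (1,))
        chosen = [_ion(ions, "b", 2)]
        peaks = [SpectrumPeak(mz=chosen[0].mz, intensity=1.0)]
        verdict = coverage_verdict(match_spectrum(peaks, chosen, 0.3), 4)
        assert not verdict.success
        assert verdict.bonds_covered == {1: False, 2: True, 3: False}

    def test_dipeptide_single_bond(self):
        ions = ion_series("GG", "y", (1,))
        peaks = [SpectrumPeak(mz=ions[0].mz, intensity=1.0)]
        verdict = coverage_verdict(match_spectrum(peaks, ions, 0.3), 2)
        assert verdict.success

    def test_full_by_series_always_succeeds(self):
        ions = ion_series("FFVAP", "by", (1,))
        peaks = [SpectrumPeak(mz=i.mz, intensity=1.0) for i in ions]
        verdict = coverage_verdict(match_spectrum(peaks, ions, 0.3), 5)
        assert verdict.success


class TestSavitzkyGolay:
    def test_polynomial_reproduced_exactly(self):
        t = np.arange(31, dtype=float)
        y = 2.0 + 0.5 * t - 0.03 * t ** 2
        out = savitzky_golay(np.column_stack([t, y]), window=5, poly_order=2)
        assert np.allclose(out[:, 1], y, atol=1e-9)

    def test_constant_unchanged(self):
        t = np.arange(20, dtype=float)
        y = np.full_like(t, 7.5)
        out = savitzky_golay(np.column_stack([t, y]), window=7, poly_order=2)
        assert np.allclose(out[:, 1], y, atol=1e-12)

    def test_interior_equals_per_window_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        t = np.arange(41, dtype=float)
        y = rng.normal(size=t.size)
        window, order = 7, 2
        out = savitzky_golay(np.column_stack([t, y]), window=window, poly_order=order)
        half = window // 2
        for center in range(half, t.size - half):
            xs = t[center - half : center + half + 1] - t[center]
            ys = y[center - half : center + half + 1]
            coeffs = np.polynomial.polynomial.polyfit(xs, ys, order)
            assert out[center, 1] == pytest.approx(coeffs[0], abs=1e-9)

    def test_even_window_rejected(self):
        t = np.arange(10, dtype=float)
        with pytest.raises(ValueError):
            savitzky_golay(np.column_stack([t, t]), window=4, poly_order=2)

    def test_nonuniform_spacing_rejected(self):
        t = np.array([0.0, 1.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            savitzky_golay(np.column_stack([t, t]), window=3, poly_order=1)
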