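"""Derived interfacial descriptors: Brug capacitance, time constants, plot features."""

import numpy as np
import pytest

from eiskit import (
    FrequencySpectrum,
    GenerationSpec,
    bode_summary,
    brug_capacitance,
    characteristic_frequency,
    circuit_impedance,
    generate_spectrum,
    nyquist_features,
    parse_circuit,
    rct_ordering,
    summed_capacitance,
    tau_from_frequency,
    time_constant,
)
from eiskit.derive import DerivedSummary


class TestBrug:
    def test_ideal_cpe_reduces_to_capacitor(self):
        assert brug_capacitance(2.2e-6, 1.0, 1e3, 1e5) == pytest.approx(2.2e-6, rel=1e-12)

    def test_reference_cpe_parameters_frozen_oracle(self):
        """Value fixed beforehand by 50-digit arbitrary-precision evaluation of
        [Y0 (Rs^-1 + Rct^-1)^(n-1)]^(1/n) at the CP electrode's parameters."""
        got = brug_capacitance(19.2e-6, 0.669, 3.88e3, 6.94e5)
        assert got == pytest.approx(5.2974928838336022e-06, rel=1e-12)

    def test_homogeneity_in_y0(self):
        base = brug_capacitance(1e-5, 0.7, 1e3, 1e5)
        for k in (0.1, 3.0, 42.0):
            assert brug_capacitance(k * 1e-5, 0.7, 1e3, 1e5) == pytest.approx(
                k ** (1 / 0.7) * base, rel=1e-10
            )

    def test_continuity_at_ideal_limit(self):
        y0 = 3.3e-6
        near = brug_capacitance(y0, 1 - 1e-6, 1e3, 1e5)
        assert near == pytest.approx(y0, rel=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            brug_capacitance(1e-6, 0.0, 1e3, 1e5)
        with pytest.raises(ValueError):
            brug_capacitance(-1e-6, 0.5, 1e3, 1e5)
        with pytest.raises(ValueError):
            brug_capacitance(1e-6, 1.2, 1e3, 1e5)


class TestTimeConstants:
    def test_summed_capacitance_reference_values(self):
        # C1 + C2 + C3 of the beetroot-modified electrode, in microfarad
        assert summed_capacitance([0.346, 0.349, 0.006]) == pytest.approx(0.701)

    def test_summed_capacitance_identity_and_permutation(self):
        assert summed_capacitance([1.5e-6]) == 1.5e-6
        a = summed_capacitance([1e-6, 2e-6, 3e-6])
        assert summed_capacitance([3e-6, 1e-6, 2e-6]) == pytest.approx(a, rel=1e-15)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summed_capacitance([])

    @pytest.mark.parametrize(
        "f_max,tau_2sf,last_digit",
        [(0.30, 0.53, 0.01), (6.0, 0.026, 0.001), (0.03, 5.3, 0.1)],
    )
    def test_phase_peak_frequencies_to_time_constants(self, f_max, tau_2sf, last_digit):
        # reciprocal pairs, to one unit in the last printed digit
        tau = tau_from_frequency(f_max)
        assert tau == pytest.approx(tau_2sf, abs=last_digit)

    def test_reciprocal_pair_round_trip(self):
        for tau in (1e-3, 0.53, 5.3):
            assert tau_from_frequency(characteristic_frequency(tau)) == pytest.approx(
                tau, rel=1e-15
            )
        assert characteristic_frequency(1.0) == pytest.approx(1 / (2 * np.pi))

    def test_rc_product_pathway(self):
        # direct multiplication oracle: R2*C2 of the spinach electrode
        assert time_constant(9.90e6, 0.068e-6) == pytest.approx(0.6732, rel=1e-12)

    def test_domain_errors(self):
        for fn in (characteristic_frequency, tau_from_frequency):
            with pytest.raises(ValueError):
                fn(0.0)
        with pytest.raises(ValueError):
            time_constant(-1.0, 1e-6)


class TestNyquistFeatures:
    def test_single_rc_semicircle_reproduces_parameters(self):
        r1, r2, c1 = 1e3, 1e5, 1e-7
        model = parse_circuit("R1 + (R2||C1)")
        f = np.logspace(5, -3, 81)  # >= 10 points/decade, arc fully closed
        s = circuit_impedance(model, {"R1": r1, "R2": r2, "C1": c1}, f)
        feats = nyquist_features(s)
        assert feats["hf_intercept_ohm"] == pytest.approx(r1, rel=0.01)
        assert feats["arc_diameter_ohm"] == pytest.approx(r2, rel=0.01)
        assert feats["apex_frequency_hz"] == pytest.approx(
            1 / (2 * np.pi * r2 * c1), rel=0.01
        )

    def test_open_arc_extrapolated_by_circle_fit(self):
        r1, r2, c1 = 1e3, 1e5, 1e-7
        model = parse_circuit("R1 + (R2||C1)")
        # grid stops before the arc closes
        f = np.logspace(5, np.log10(8.0), 41)
        s = circuit_impedance(model, {"R1": r1, "R2": r2, "C1": c1}, f)
        feats = nyquist_features(s)
        assert feats["arc_diameter_method"] == "semicircle-extrapolation"
        assert feats["arc_diameter_ohm"] == pytest.approx(r2, rel=0.05)

    def test_warburg_line_is_45_degrees(self):
        """The diffusion-dominated low-frequency branch of the spinach-type
        circuit approaches a 45-degree line once below the C2/W crossover."""
        s = generate_spectrum(GenerationSpec(circuit="SPI", f_low=1e-4))
        feats = nyquist_features(s)
        assert feats["lf_slope_angle_deg"] == pytest.approx(45.0, abs=3.0)

    def test_pure_resistor_features_absent_with_reason(self):
        f = np.logspace(4, -2, 61)
        s = FrequencySpectrum(f, np.full(61, 10.0 + 0j))
        feats = nyquist_features(s)
        assert isinstance(feats["arc_diameter_ohm"], dict)
        assert "absent" in feats["arc_diameter_ohm"]
        assert isinstance(feats["apex_frequency_hz"], dict)


class TestBodeSummary:
    def test_phase_sign_convention_and_pure_capacitor(self):
        f = np.logspace(4, -2, 61)
        z = 1.0 / (2j * np.pi * f * 1e-6)
        s = FrequencySpectrum(f, z)
        out = bode_summary(s)
        assert np.allclose(out["phase_deg"], -90.0)
        assert isinstance(out["phase_peak_frequency_hz"], dict)
        assert "absent" in out["phase_peak_frequency_hz"]

    def test_cp_circuit_phase_peak_matches_dense_grid_oracle(self, noiseless):
        """Quadratic interpolation on the 61-point grid lands within half a
        grid step of the dense-grid phase-peak location."""
        # oracle: brute-force argmax on a 2000-point grid, direct formula
        f = np.logspace(5, -4, 2000)
        w = 2 * np.pi * f
        z = 3.88e3 + 1 / (1 / 6.94e5 + 19.2e-6 * (1j * w) ** 0.669)
        f_oracle = f[np.argmax(-np.degrees(np.arctan2(z.imag, z.real)))]
        out = bode_summary(noiseless["CP"])
        half_step = 10 ** (0.05)  # half of a 10-per-decade grid step
        assert f_oracle / half_step <= out["phase_peak_frequency_hz"] <= f_oracle * half_step

    def test_bet_reports_all_interior_extrema(self, noiseless):
        out = bode_summary(noiseless["BET"])
        assert len(out["phase_peaks"]) >= 2
        best = max(out["phase_peaks"], key=lambda p: -p["angle_deg"])
        assert out["phase_peak_frequency_hz"] == best["frequency_hz"]

    def test_spi_peak_in_low_frequency_end_region(self, noiseless):
        """The spinach electrode's phase peak sits at the low-frequency end,
        reflecting its slow, diffusion-limited interfacial dynamics."""
        out = bode_summary(noiseless["SPI"])
        fpk = out["phase_peak_frequency_hz"]
        assert fpk < 0.1
        # dense-grid oracle for the peak angle over the default sweep window
        f = np.logspace(4, -2, 4000)
        w = 2 * np.pi * f
        inner = 9.90e6 + 1 / (1j * w * 0.068e-6 + 3.06e-8 * np.sqrt(1j * w))
        z = 3.18e4 + 1 / (1j * w * 4.75e-12 + 1 / inner)
        theta = np.degrees(np.arctan2(z.imag, z.real))
        interior = np.zeros(len(f), bool)
        interior[1:-1] = (-theta[1:-1] >= -theta[:-2]) & (-theta[1:-1] >= -theta[2:])
        angle_oracle = theta[interior].min() if interior.any() else theta.min()
        assert out["phase_peak_angle_deg"] == pytest.approx(angle_oracle, abs=0.5)

    def test_modulus_converges_to_series_resistance(self, noiseless):
        out = bode_summary(noiseless["CP"])
        assert out["modulus_ohm"][0] == pytest.approx(3.88e3, rel=0.01)


class TestRctOrdering:
    @staticmethod
    def summary(rct):
        return DerivedSummary(
            cdl_farad=1e-6, cdl_method="single", tau_s=1.0,
            f_max_hz=1 / (2 * np.pi), rct_ohm=rct,
        )

    def test_reference_fits_order_spi_cp_bet(self):
        labeled = [
            ("CP", self.summary(6.94e5)),
            ("BET", self.summary(2.72e4)),
            ("SPI", self.summary(9.90e6)),
        ]
        assert rct_ordering(labeled)["order"] == ["SPI", "CP", "BET"]

    def test_single_label_identity(self):
        assert rct_ordering([("only", self.summary(1.0))])["order"] == ["only"]

    def test_tie_reported(self):
        out = rct_ordering([("a", self.summary(5.0)), ("b", self.summary(5.0))])
        assert out["ties"] == [("a", "b")] or out["ties"] == [("b", "a")]
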