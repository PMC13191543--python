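"""CNLS fitting: seeds, recovery, chi-squared conventions, model comparison."""

import numpy as np
import pytest

from eiskit import (
    DegenerateSpectrumError,
    FrequencySpectrum,
    GenerationSpec,
    ParameterSet,
    chi_squared,
    compare_models,
    fit,
    generate_spectrum,
    initial_guess,
    parse_circuit,
    rc_branches,
)

from conftest import ELECTRODES


class TestInitialGuess:
    def test_series_resistance_seed_brackets_truth(self, fixtures, noiseless):
        # heuristic seed for the solution resistance within a factor 2
        model, params = fixtures["CP"]
        guess = initial_guess(noiseless["CP"], model)
        assert params["R1"] / 2 < guess["R1"] < params["R1"] * 2

    def test_pure_resistor_seed_equals_constant(self):
        f = np.logspace(4, -2, 61)
        spectrum = FrequencySpectrum(f, np.full(61, 123.0 + 0j))
        guess = initial_guess(spectrum, parse_circuit("R1"))
        assert guess["R1"] == pytest.approx(123.0)

    def test_three_point_spectrum_is_degenerate(self):
        f = np.array([1e3, 1e2, 1e1])
        spectrum = FrequencySpectrum(f, np.array([1 + 0j, 2 - 1j, 3 - 2j]))
        with pytest.raises(DegenerateSpectrumError):
            initial_guess(spectrum, parse_circuit("R1"))

    def test_flat_real_part_unseedable_for_rc_model(self):
        f = np.logspace(4, -2, 61)
        spectrum = FrequencySpectrum(f, np.full(61, 50.0 + 0j))
        with pytest.raises(DegenerateSpectrumError):
            initial_guess(spectrum, parse_circuit("R1 + (R2||C1)"))

    @pytest.mark.parametrize("name", ELECTRODES)
    def test_heuristic_seeds_converge_to_truth(self, name, fixtures, noiseless):
        model, params = fixtures[name]
        result = fit(noiseless[name], model)  # init from initial_guess
        for k in params.names:
            assert result.params[k] == pytest.approx(params[k], rel=1e-6), k


class TestFit:
    @pytest.mark.parametrize("name", ELECTRODES)
    def test_noiseless_recovery_from_perturbed_seeds(self, name, fixtures, noiseless):
        """Self-fit recovers every generating parameter to <= 0.1% despite
        +/-50% random perturbation of the initial guess (10 seeds)."""
        model, params = fixtures[name]
        rng = np.random.default_rng(42)
        for _ in range(10):
            factors = {k: float(rng.uniform(0.5, 1.5)) for k in params.names}
            init = params.with_values(
                {
                    k: min(f * params[k], 1.0 - 1e-9) if k == "n" else f * params[k]
                    for k, f in factors.items()
                }
            )
            result = fit(noiseless[name], model, init=init)
            assert result.converged
            for k in params.names:
                assert abs(result.params[k] / params[k] - 1) <= 1e-3, (k, name)

    def test_self_fit_from_truth_is_fixed_point(self, fixtures, noiseless):
        model, params = fixtures["CP"]
        result = fit(noiseless["CP"], model, init=params)
        assert result.chi2 == pytest.approx(0.0, abs=1e-25)
        for k in params.names:
            assert result.params[k] == pytest.approx(params[k], rel=1e-12)

    def test_modulus_weighted_chi2_scale_invariant(self, fixtures):
        model, params = fixtures["CP"]
        s = generate_spectrum(GenerationSpec(circuit="CP", noise_level=0.002, seed=11))
        k = 37.5
        scaled = s.with_impedance(s.impedance * k)
        c1 = chi_squared(s, model, params, "modulus")
        c2 = chi_squared(scaled, model, params.with_values(
            {n: v * k if n not in ("n",) else v for n, v in params.values_dict().items()}
            | {"Y0": params["Y0"] / k}
        ), "modulus")
        # same relative residuals -> identical modulus-weighted chi2
        assert c2.total == pytest.approx(c1.total, rel=1e-9)

    def test_unit_weighted_chi2_scales_quadratically(self, fixtures):
        model, params = fixtures["CP"]
        s = generate_spectrum(GenerationSpec(circuit="CP", noise_level=0.002, seed=11))
        k = 3.0
        scaled = s.with_impedance(s.impedance * k)
        # same model curve: residuals grow by k, unit-weighted chi2 by k^2;
        # equivalently doubling all residuals quadruples chi2
        c1 = chi_squared(s, model, params, "unit")
        params_k = params.with_values(
            {n: v * k for n, v in params.values_dict().items() if n.startswith("R")}
            | {"Y0": params["Y0"] / k}
        )
        c2 = chi_squared(scaled, model, params_k, "unit")
        assert c2.total == pytest.approx(k**2 * c1.total, rel=1e-9)

    def test_chi2_invariant_under_point_reordering(self, fixtures):
        model, params = fixtures["CP"]
        s = generate_spectrum(GenerationSpec(circuit="CP", noise_level=0.002, seed=3))
        reversed_ = FrequencySpectrum(s.frequencies[::-1], s.impedance[::-1])
        c1 = chi_squared(s, model, params, "modulus")
        c2 = chi_squared(reversed_, model, params, "modulus")
        assert c2.total == pytest.approx(c1.total, rel=1e-13)

    def test_exact_params_give_zero_components(self, fixtures, noiseless):
        model, params = fixtures["BET"]
        c = chi_squared(noiseless["BET"], model, params, "modulus")
        assert c.total == pytest.approx(0.0, abs=1e-28)
        assert c.real == pytest.approx(0.0, abs=1e-28)
        assert c.imag == pytest.approx(0.0, abs=1e-28)
        assert c.modulus == pytest.approx(0.0, abs=1e-28)

    def test_chi2_regression_against_summation_oracle(self, fixtures):
        """Frozen value computed by a straight-line summation oracle."""
        model, params = fixtures["CP"]
        s = generate_spectrum(GenerationSpec(circuit="CP", noise_level=0.0005, seed=7))
        c = chi_squared(s, model, params, "modulus", n_free=4)
        # independent oracle: plain loop over points, direct formula
        tot = 0.0
        for f, z in zip(s.frequencies, s.impedance):
            w = 2 * np.pi * f
            zhat = 3.88e3 + 1 / (1 / 6.94e5 + 19.2e-6 * (1j * w) ** 0.669)
            tot += abs(z) ** -2 * ((z.real - zhat.real) ** 2 + (z.imag - zhat.imag) ** 2)
        assert c.total == pytest.approx(tot / (2 * 61 - 4), rel=1e-12)
        assert c.total == pytest.approx(1.952316742120678e-07, rel=1e-9)

    def test_rsd_tracks_noise_level(self, fixtures):
        """Reported relative uncertainties double (+/-20%) with noise (Monte-Carlo)."""
        model, params = fixtures["CP"]
        med = {}
        for nl in (0.0025, 0.005):
            rsds = []
            for seed in range(1, 101):
                s = generate_spectrum(
                    GenerationSpec(circuit="CP", noise_level=nl, seed=seed)
                )
                r = fit(s, model, init=params.scaled(1.5))
                rsds.append(r.rsd_percent["R2"])
            med[nl] = float(np.median(rsds))
        ratio = med[0.005] / med[0.0025]
        assert 1.6 <= ratio <= 2.4

    def test_rsd_consistent_with_empirical_spread(self, fixtures):
        """Reported rsd agrees with the Monte-Carlo spread within a factor 2,
        and median recovered parameters stay within 2% of truth."""
        model, params = fixtures["BET"]
        values = {k: [] for k in params.names}
        rsds = {k: [] for k in params.names}
        for seed in range(1, 61):
            s = generate_spectrum(
                GenerationSpec(circuit="BET", noise_level=0.005, seed=seed)
            )
            r = fit(s, model, init=params.scaled(1.5))
            for k in params.names:
                values[k].append(r.params[k])
                rsds[k].append(r.rsd_percent[k])
        for k in params.names:
            med = float(np.median(values[k]))
            assert abs(med / params[k] - 1) <= 0.02, k
            empirical = 100.0 * np.std(values[k]) / np.mean(values[k])
            reported = float(np.median(rsds[k]))
            assert reported / 2 <= empirical <= reported * 2, k

    def test_branches_reported_sorted_by_time_constant(self, fixtures, noiseless):
        model, params = fixtures["BET"]
        result = fit(noiseless["BET"], model, init=params.scaled(1.5))
        taus = [b["tau_s"] for b in result.branches]
        assert taus == sorted(taus)
        assert len(result.branches) == 3
        # the branch set matches truth irrespective of labels
        truth = sorted(
            (params[r] * params[c], params[r])
            for r, c in (("R2", "C1"), ("R3", "C2"), ("R4", "C3"))
        )
        got = sorted((b["tau_s"], b["r_ohm"]) for b in result.branches)
        for (t0, r0), (t1, r1) in zip(truth, got):
            assert r1 == pytest.approx(r0, rel=1e-6)
            assert t1 == pytest.approx(t0, rel=1e-6)

    def test_underdetermined_fit_rejected(self):
        f = np.logspace(2, 0, 3)
        s = FrequencySpectrum(f, np.array([10 - 1j, 12 - 3j, 14 - 1j]))
        model = parse_circuit("R1 + (R2||C1) + (R3||C2) + (R4||C3)")
        init = ParameterSet.from_values(
            {"R1": 1, "R2": 1, "R3": 1, "R4": 1, "C1": 1e-6, "C2": 1e-6, "C3": 1e-6}
        )
        with pytest.raises(ValueError, match="underdetermined"):
            fit(s, model, init=init)


class TestCompareModels:
    def test_generating_topology_wins(self, noiseless):
        report = compare_models(
            noiseless["BET"],
            ["R1 + (R2||CPE)", "R1 + (R2||C1) + (R3||C2) + (R4||C3)"],
        )
        assert report[0].circuit == "R1 + (R2||C1) + (R3||C2) + (R4||C3)"
        assert report[0].chi2 < report[1].chi2

    def test_parsimony_tie_break(self):
        model = parse_circuit("R1 + (R2||C1)")
        params = ParameterSet.from_values({"R1": 1e3, "R2": 1e5, "C1": 1e-6})
        s = generate_spectrum(GenerationSpec(circuit=model, params=params))
        report = compare_models(s, ["R1 + (R2||C1)", "R1 + (R2||C1) + (R3||C2)"])
        assert report[0].circuit == "R1 + (R2||C1)"
        assert report[0].n_free == 3

    def test_failed_candidate_reported_not_raised(self):
        f = np.logspace(4, -2, 61)
        s = FrequencySpectrum(f, np.full(61, 100.0 + 0j))
        report = compare_models(s, ["R1", "R1 + (R2||C1)"])
        assert report[0].circuit == "R1"
        assert report[1].error is not None and "Degenerate" in report[1].error

    def test_too_few_candidates(self, noiseless):
        with pytest.raises(ValueError):
            compare_models(noiseless["CP"], ["R1"])

    def test_wrong_topology_flags_structured_residuals(self, noiseless):
        report = compare_models(
            noiseless["BET"],
            ["R1 + (R2||CPE)", "R1 + (R2||C1) + (R3||C2) + (R4||C3)"],
        )
        wrong = next(c for c in report if "CPE" in c.circuit)
        assert wrong.structured_residuals


def test_rc_branches_extraction(fixtures):
    model, params = fixtures["BET"]
    branches = rc_branches(model, params)
    assert [b["r_label"] for b in branches] == ["R4", "R2", "R3"]  # ascending tau
    assert branches[0]["tau_s"] == pytest.approx(1.39e5 * 0.006e-6)
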