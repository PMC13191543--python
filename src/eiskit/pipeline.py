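"""End-to-end analysis: validate, fit, derive, report.

Mirrors the measurement workflow: the Kramers-Kronig test establishes that a
spectrum is worth fitting, the CNLS fit extracts circuit parameters, and the
derived descriptors condense them into the quantities compared across
electrodes.  A KK failure is recorded and flagged but does not abort the fit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .circuits import CircuitModel, parse_circuit
from .derive import (
    DerivedSummary,
    bode_summary,
    brug_capacitance,
    nyquist_features,
    summed_capacitance,
    tau_from_frequency,
)
from .fitting import FitResult, fit, initial_guess, rc_branches
from .io import read_spectrum
from .kk import KKResult, linkk
from .parameters import ParameterSet
from .spectrum import FrequencySpectrum
from .synthetic import GenerationSpec, generate_spectrum

__all__ = ["AnalysisConfig", "ConfigError", "run_pipeline", "derive_from_fit"]

logger = logging.getLogger("eiskit")

SCHEMA_VERSION = "1"


class ConfigError(ValueError):
    """Invalid analysis configuration."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a spectrum CSV) and ``generation`` (a
    synthetic recipe) must be given.  ``circuit`` may be omitted for generated
    spectra, in which case the generating topology is fitted back.
    """

    input_path: Optional[str] = None
    generation: Optional[GenerationSpec] = None
    circuit: Optional[str] = None
    init_overrides: Mapping[str, float] = field(default_factory=dict)
    weighting: str = "modulus"
    kk_threshold: float = 1e-6
    output_dir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if (self.input_path is None) == (self.generation is None):
            raise ConfigError("exactly one of input_path and generation must be set")
        if self.input_path is not None:
            if not Path(self.input_path).exists():
                raise ConfigError(f"input path does not exist: {self.input_path}")
            if self.circuit is None:
                raise ConfigError("circuit notation is required when fitting a file")
        if self.weighting not in ("modulus", "unit"):
            raise ConfigError(f"unknown weighting {self.weighting!r}")


def derive_from_fit(
    result: FitResult,
    spectrum: Optional[FrequencySpectrum] = None,
) -> DerivedSummary:
    """Condense a fit into the descriptor row (C_dl, tau, f_max, R_ct).

    C_dl provenance: the Brug relation when the circuit has a CPE; the sum of
    the parallel-branch capacitances when it has several RC relaxations; the
    first capacitor otherwise.  tau/f_max come from the phase-angle peak of
    the measured spectrum when one is resolvable (the reciprocal RC-product
    pathway is recorded in the notes); without a spectrum the RC product of
    the slowest resolvable branch is used.
    """
    model = parse_circuit(result.circuit)
    params = result.params
    notes: Dict[str, str] = {}

    rct_name = "R2" if "R2" in params else None
    if rct_name is None:
        branch_rs = [b["r_label"] for b in rc_branches(model, params)]
        rct_name = branch_rs[0] if branch_rs else None
    if rct_name is None:
        raise ValueError("no charge-transfer resistance identifiable in the circuit")
    rct = params[rct_name]
    notes["rct"] = f"fitted {rct_name}"

    has_cpe = any(el.kind == "cpe" for el in model.elements)
    caps = [el.label for el in model.elements if el.kind == "capacitor"]
    branches = rc_branches(model, params)
    if has_cpe:
        cdl = brug_capacitance(params["Y0"], params["n"], params["R1"], rct)
        method = "brug"
        notes["cdl"] = "Brug relation from CPE (Y0, n), R1 and Rct"
    elif len(branches) >= 2:
        cdl = summed_capacitance([b["c_farad"] for b in branches])
        method = "sum"
        notes["cdl"] = "sum of parallel-branch capacitances " + "+".join(
            str(b["c_label"]) for b in branches
        )
    elif caps:
        cdl = params[caps[0]]
        method = "single"
        notes["cdl"] = f"fitted {caps[0]}"
    else:
        raise ValueError("circuit has no capacitive element; C_dl undefined")

    tau = None
    if spectrum is not None:
        bode = bode_summary(spectrum)
        fpk = bode.get("phase_peak_frequency_hz")
        if isinstance(fpk, float):
            tau = tau_from_frequency(fpk)
            f_max = fpk
            notes["tau"] = "1/(2 pi f_max) from the phase-angle peak"
    if tau is None:
        pairs = []
        if branches:
            pairs = [(b["tau_s"], f'{b["r_label"]}*{b["c_label"]}') for b in branches]
        elif "C2" in params and "R2" in params:
            pairs = [(params["R2"] * params["C2"], "R2*C2")]
        if not pairs:
            raise ValueError("no pathway to a characteristic time constant")
        tau, src = max(pairs)
        f_max = 1.0 / (2.0 * np.pi * tau)
        notes["tau"] = f"RC product {src} (no resolvable phase peak)"
    # the reciprocal RC pathway, for provenance
    if "R2" in params and "C2" in params:
        notes["tau_rc_product_s"] = repr(params["R2"] * params["C2"])
    return DerivedSummary(
        cdl_farad=cdl, cdl_method=method, tau_s=tau, f_max_hz=f_max, rct_ohm=rct, notes=notes
    )


def _report_json(report: Dict) -> str:
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(config: AnalysisConfig) -> Dict:
    """Execute validate -> fit -> derive and assemble the report bundle.

    Returns the report as a dict; when ``config.output_dir`` is set, also
    writes ``report.json``, ``nyquist.csv``, ``bode.csv`` and
    ``kk_residuals.csv`` there.  Identical config and seed produce an
    identical report (no timestamps).
    """
    config.validate()
    if config.input_path is not None:
        spectrum = read_spectrum(config.input_path)
        circuit_text = config.circuit
    else:
        spectrum = generate_spectrum(config.generation)
        circuit_text = config.circuit or spectrum.metadata["circuit"]
    model = parse_circuit(circuit_text)

    logger.info("Kramers-Kronig validation (threshold %g)", config.kk_threshold)
    kk: KKResult = linkk(spectrum, threshold=config.kk_threshold)
    if not kk.verdict:
        logger.warning(
            "Kramers-Kronig test FAILED (chi2 mod/re/im = %.3g/%.3g/%.3g); "
            "fitting proceeds but parameters may be unreliable",
            kk.chi2_modulus, kk.chi2_real, kk.chi2_imag,
        )

    init = initial_guess(spectrum, model)
    if config.init_overrides:
        init = init.with_values(dict(config.init_overrides))
    logger.info("CNLS fit of %s (%s weighting)", model.serialize(), config.weighting)
    result = fit(spectrum, model, init=init, weighting=config.weighting)
    if not result.converged:
        logger.warning("fit did not converge within the iteration budget")

    summary = derive_from_fit(result, spectrum)
    nyq = nyquist_features(spectrum)
    bode = bode_summary(spectrum)

    report = {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "config": {
            "input_path": config.input_path,
            "generated": config.generation is not None,
            "circuit": model.serialize(),
            "weighting": config.weighting,
            "kk_threshold": config.kk_threshold,
            "seed": config.seed,
        },
        "kramers_kronig": kk.to_dict(),
        "fit": result.to_dict(),
        "derived": summary.to_dict(),
        "nyquist_features": {
            k: v for k, v in nyq.items() if not isinstance(v, np.ndarray)
        },
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(_report_json(report) + "\n")
        pd.DataFrame(
            {
                "frequency_hz": spectrum.descending().frequencies,
                "z_real_ohm": spectrum.descending().z_real,
                "z_imag_ohm": spectrum.descending().z_imag,
            }
        ).to_csv(out / "nyquist.csv", index=False)
        pd.DataFrame(
            {
                "frequency_hz": bode["frequency_hz"],
                "modulus_ohm": bode["modulus_ohm"],
                "phase_deg": bode["phase_deg"],
            }
        ).to_csv(out / "bode.csv", index=False)
        pd.DataFrame(
            {
                "frequency_hz": spectrum.descending().frequencies,
                "kk_residual_real_pct": 100.0 * kk.residuals_real,
                "kk_residual_imag_pct": 100.0 * kk.residuals_imag,
            }
        ).to_csv(out / "kk_residuals.csv", index=False)
        logger.info("report bundle written to %s", out)
    return report
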