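"""Synthetic impedance spectra with the statistical structure the analysis assumes.

Three reference electrode fixtures are built in, reproducing the published
equivalent-circuit characterisation of a bare carbon-paste electrode (``CP``)
and electrodes bulk-modified with beetroot (``BET``) and spinach (``SPI``)
extracts:

``CP``
    ``R1 + (R2||CPE)`` — a single depressed charge-transfer semicircle.
``BET``
    ``R1 + (R2||C1) + (R3||C2) + (R4||C3)`` — three interfacial relaxations.
``SPI``
    ``R1 + (C1||(R2 + (C2||W)))`` — a blocking film with semi-infinite
    diffusion (Warburg) at low frequency.

Spectra are generated on a log-spaced grid swept high-to-low (instrument
acquisition order), with optional proportional Gaussian noise and optional
nonstationary drift.  Drift grows linearly with acquisition index and is added
to the real part only: it is the minimal nonstationarity that violates
Kramers-Kronig consistency, used to exercise the validity test's failure path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .circuits import CircuitModel, circuit_impedance, parse_circuit
from .parameters import ParameterSet
from .spectrum import FrequencySpectrum

__all__ = ["GenerationSpec", "electrode_fixture", "generate_spectrum", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("CP", "BET", "SPI")

# Published fitted parameters, converted to SI (ohm, F, S s^n, S s^1/2).
# SPI C1 follows the tabulated 4.75e-6 uF reading; see spi_c1_variant below.
_FIXTURES = {
    "CP": (
        "R1 + (R2||CPE)",
        {"R1": 3.88e3, "R2": 6.94e5, "Y0": 19.2e-6, "n": 0.669},
    ),
    "BET": (
        "R1 + (R2||C1) + (R3||C2) + (R4||C3)",
        {
            "R1": 3.69e4,
            "R2": 2.72e4,
            "R3": 2.65e5,
            "R4": 1.39e5,
            "C1": 0.346e-6,
            "C2": 0.349e-6,
            "C3": 0.006e-6,
        },
    ),
    "SPI": (
        "R1 + (C1||(R2 + (C2||W)))",
        {"R1": 3.18e4, "R2": 9.90e6, "C1": 4.75e-6 * 1e-6, "C2": 0.068e-6, "W": 3.06e-8},
    ),
}


def electrode_fixture(
    electrode: str, spi_c1_variant: bool = False
) -> Tuple[CircuitModel, ParameterSet]:
    """Circuit topology and fitted parameter values for a reference electrode.

    Parameters
    ----------
    electrode : {"CP", "BET", "SPI"}
    spi_c1_variant : bool
        The SPI film capacitance is reported inconsistently between the
        parameter table (4.75e-6 uF, i.e. 4.75 pF) and the accompanying text
        (4.75 uF).  The default follows the table; pass ``True`` for the
        microfarad reading.
    """
    try:
        notation, values = _FIXTURES[electrode]
    except KeyError:
        raise KeyError(
            f"unknown electrode {electrode!r}; expected one of {FIXTURE_NAMES}"
        ) from None
    values = dict(values)
    if spi_c1_variant:
        if electrode != "SPI":
            raise ValueError("spi_c1_variant applies only to the SPI fixture")
        values["C1"] = 4.75e-6
    return parse_circuit(notation), ParameterSet.from_values(values)


@dataclass(frozen=True)
class GenerationSpec:
    """Recipe for one synthetic spectrum.

    Defaults emulate the measurement design: 10 kHz down to 0.01 Hz,
    10 points per decade (61 points over 6 decades), noiseless.
    ``noise_level`` and ``drift_level`` are fractions of the local ``|Z|``.
    """

    circuit: CircuitModel | str
    params: ParameterSet | None = None
    f_high: float = 1e4
    f_low: float = 1e-2
    points_per_decade: int = 10
    noise_level: float = 0.0
    drift_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.f_high > self.f_low > 0):
            raise ValueError("need f_high > f_low > 0")
        if self.points_per_decade < 1:
            raise ValueError("points_per_decade must be >= 1")
        if self.noise_level < 0 or self.drift_level < 0:
            raise ValueError("noise_level and drift_level must be >= 0")

    def resolve(self) -> Tuple[CircuitModel, ParameterSet]:
        if isinstance(self.circuit, str):
            model, fixture_params = electrode_fixture(self.circuit)
            return model, (self.params if self.params is not None else fixture_params)
        if self.params is None:
            raise ValueError("params required when circuit is a CircuitModel")
        return self.circuit, self.params


def frequency_grid(f_high: float, f_low: float, points_per_decade: int) -> np.ndarray:
    """Log-spaced grid from ``f_high`` down to ``f_low`` inclusive.

    Point count is ``floor(decades * points_per_decade) + 1``.
    """
    decades = np.log10(f_high / f_low)
    n = int(np.floor(decades * points_per_decade)) + 1
    return np.logspace(np.log10(f_high), np.log10(f_low), n)


def generate_spectrum(spec: GenerationSpec) -> FrequencySpectrum:
    """Simulate one spectrum: clean circuit response + noise + drift.

    Noise adds independent zero-mean Gaussian perturbations to the real and
    imaginary parts, each with standard deviation ``noise_level * |Z(f)|``.
    Drift adds ``(k/(N-1)) * drift_level * |Z(f_k)]`` to the real part at
    acquisition index ``k`` (0-based, high-to-low sweep order).
    """
    model, params = spec.resolve()
    f = frequency_grid(spec.f_high, spec.f_low, spec.points_per_decade)
    clean = circuit_impedance(model, params, f)
    z = clean.impedance.copy()
    mag = np.abs(z)
    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        z = z + spec.noise_level * mag * (
            rng.standard_normal(z.size) + 1j * rng.standard_normal(z.size)
        )
    if spec.drift_level > 0:
        k = np.arange(z.size)
        z = z + (k / (z.size - 1)) * spec.drift_level * mag
    meta = {
        "circuit": model.serialize(),
        "params": params.values_dict(),
        "generation": {
            "f_high": spec.f_high,
            "f_low": spec.f_low,
            "points_per_decade": spec.points_per_decade,
            "noise_level": spec.noise_level,
            "drift_level": spec.drift_level,
            "seed": spec.seed,
        },
    }
    return FrequencySpectrum(f, z, meta)
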