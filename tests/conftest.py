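import numpy as np
import pytest

from eiskit import GenerationSpec, electrode_fixture, generate_spectrum

ELECTRODES = ("CP", "BET", "SPI")


@pytest.fixture(scope="session")
def fixtures():
    """Topology + parameter set per reference electrode."""
    return {name: electrode_fixture(name) for name in ELECTRODES}


@pytest.fixture(scope="session")
def noiseless():
    """Noiseless default-grid (61-point) spectra per reference electrode."""
    return {
        name: generate_spectrum(GenerationSpec(circuit=name)) for name in ELECTRODES
    }


def straight_line_impedance(name: str, f: np.ndarray) -> np.ndarray:
    """Independent oracle: direct complex-arithmetic formulas, no circuit tree."""
    w = 2 * np.pi * np.asarray(f, dtype=float)
    j = 1j
    if name == "CP":
        return 3.88e3 + 1.0 / (1.0 / 6.94e5 + 19.2e-6 * (j * w) ** 0.669)
    if name == "BET":
        return (
            3.69e4
            + 1.0 / (1.0 / 2.72e4 + j * w * 0.346e-6)
            + 1.0 / (1.0 / 2.65e5 + j * w * 0.349e-6)
            + 1.0 / (1.0 / 1.39e5 + j * w * 0.006e-6)
        )
    if name == "SPI":
        inner = 9.90e6 + 1.0 / (j * w * 0.068e-6 + 3.06e-8 * np.sqrt(j * w))
        return 3.18e4 + 1.0 / (j * w * 4.75e-12 + 1.0 / inner)
    raise KeyError(name)
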