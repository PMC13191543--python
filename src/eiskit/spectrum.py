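"""Frequency-domain impedance spectra.

The :class:`FrequencySpectrum` is the unit of exchange between every stage of
the pipeline: simulation, Kramers-Kronig validation, circuit fitting and
feature extraction all consume and produce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = ["FrequencySpectrum"]


@dataclass(frozen=True)
class FrequencySpectrum:
    """An impedance spectrum: frequencies in Hz and complex impedance in ohm.

    Frequencies are strictly monotonic; instruments sweep high to low, which is
    the order generators and readers in this package produce.  ``metadata`` is
    free-form provenance (perturbation amplitude, electrolyte, generation spec).

    Raises
    ------
    ValueError
        If lengths differ, fewer than two points are given, any frequency is
        not strictly positive, or the frequency grid is not strictly monotonic.
    """

    frequencies: np.ndarray
    impedance: np.ndarray
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.impedance, dtype=complex)
        if f.ndim != 1 or z.ndim != 1:
            raise ValueError("frequencies and impedance must be 1-D")
        if f.size != z.size:
            raise ValueError(
                f"length mismatch: {f.size} frequencies vs {z.size} impedance values"
            )
        if f.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if np.any(f <= 0) or not np.all(np.isfinite(f)):
            raise ValueError("all frequencies must be finite and > 0")
        df = np.diff(f)
        if not (np.all(df > 0) or np.all(df < 0)):
            raise ValueError("frequencies must be strictly monotonic")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "impedance", z)

    def __len__(self) -> int:
        return int(self.frequencies.size)

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies in rad/s."""
        return 2.0 * np.pi * self.frequencies

    @property
    def z_real(self) -> np.ndarray:
        return self.impedance.real

    @property
    def z_imag(self) -> np.ndarray:
        return self.impedance.imag

    @property
    def modulus(self) -> np.ndarray:
        return np.abs(self.impedance)

    @property
    def n_decades(self) -> float:
        """Width of the frequency span in decades."""
        return float(abs(np.log10(self.frequencies[0] / self.frequencies[-1])))

    def descending(self) -> "FrequencySpectrum":
        """Return the spectrum ordered high-to-low frequency (acquisition order)."""
        if self.frequencies[0] >= self.frequencies[-1]:
            return self
        return FrequencySpectrum(
            self.frequencies[::-1].copy(), self.impedance[::-1].copy(), dict(self.metadata)
        )

    def with_impedance(self, z: np.ndarray) -> "FrequencySpectrum":
        """A copy of this spectrum with the impedance replaced."""
        return FrequencySpectrum(self.frequencies.copy(), np.asarray(z), dict(self.metadata))
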