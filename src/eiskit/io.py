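"""Reading and writing the plain-text spectrum exchange format.

The dialect is a CSV with header ``frequency_hz,z_real_ohm,z_imag_ohm``,
comment lines starting with ``#``, decimal points and no thousands
separators.  Vendor exports that use tab or semicolon delimiters are accepted
by sniffing the delimiter; files are always returned sorted high-to-low in
frequency (acquisition order), with a warning when reordering was needed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .spectrum import FrequencySpectrum

__all__ = ["read_spectrum", "write_spectrum", "SpectrumFormatError"]

logger = logging.getLogger("eiskit")

COLUMNS = ("frequency_hz", "z_real_ohm", "z_imag_ohm")


class SpectrumFormatError(ValueError):
    """Malformed spectrum file; message names the offending data row."""


def read_spectrum(path: Union[str, Path]) -> FrequencySpectrum:
    """Read a spectrum CSV; rows are sorted high-to-low frequency.

    Row numbers in error messages are 1-based over data rows (comment lines
    excluded).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, comment="#", sep=None, engine="python", dtype=str, skipinitialspace=True
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SpectrumFormatError(f"{path}: cannot parse as CSV: {exc}") from exc
    frame.columns = [c.strip() for c in frame.columns]
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SpectrumFormatError(f"{path}: missing column(s) {missing}")
    numeric = {}
    for col in COLUMNS:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna() | frame[col].isna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
            raise SpectrumFormatError(
                f"{path}: non-numeric or empty {col!r} value at data row {row}"
            )
        numeric[col] = converted.to_numpy(dtype=float)
    f = numeric["frequency_hz"]
    nonpos = np.nonzero(f <= 0)[0]
    if nonpos.size:
        raise SpectrumFormatError(
            f"{path}: nonpositive frequency at data row {int(nonpos[0]) + 1}"
        )
    z = numeric["z_real_ohm"] + 1j * numeric["z_imag_ohm"]
    order = np.argsort(-f, kind="stable")
    if not np.array_equal(order, np.arange(f.size)):
        logger.warning("%s: rows were not sorted high-to-low in frequency; reordered", path)
        f, z = f[order], z[order]
    return FrequencySpectrum(f, z, {"source": str(path)})


def write_spectrum(spectrum: FrequencySpectrum, path: Union[str, Path]) -> None:
    """Write a spectrum in the exchange dialect (12+ significant digits)."""
    path = Path(path)
    spec = spectrum.descending()
    with path.open("w") as fh:
        fh.write("# eiskit spectrum: frequency in Hz, impedance in ohm\n")
        fh.write(",".join(COLUMNS) + "\n")
        for f, z in zip(spec.frequencies, spec.impedance):
            fh.write(f"{f:.12e},{z.real:.12e},{z.imag:.12e}\n")
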