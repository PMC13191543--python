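"""Interfacial descriptors derived from fitted parameters and raw spectra.

Covers the quantities an electrochemist reads off an impedance data set:

* effective double-layer capacitance — by the Brug relation for CPE-bearing
  circuits, by summation for multi-RC circuits, or directly for a single C;
* characteristic time constant ``tau = R C`` and frequency
  ``f_max = 1/(2 pi tau)`` (a reciprocal pair);
* Nyquist-plot features: high-frequency intercept (solution resistance),
  semicircle diameter (charge-transfer resistance), apex frequency, and the
  low-frequency slope angle (45 degrees signals Warburg diffusion);
* Bode-plot features: modulus and phase curves and the phase-angle peak;
* ranking of electrodes by charge-transfer resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .spectrum import FrequencySpectrum

__all__ = [
    "DerivedSummary",
    "brug_capacitance",
    "summed_capacitance",
    "time_constant",
    "characteristic_frequency",
    "tau_from_frequency",
    "nyquist_features",
    "bode_summary",
    "rct_ordering",
]


@dataclass(frozen=True)
class DerivedSummary:
    """One electrode's descriptor row: C_dl, tau, f_max, R_ct with provenance."""

    cdl_farad: float
    cdl_method: str               # brug | sum | single
    tau_s: float
    f_max_hz: float
    rct_ohm: float
    notes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("cdl_farad", "tau_s", "f_max_hz", "rct_ohm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> Dict:
        return {
            "cdl": {"value": self.cdl_farad, "unit": "F", "method": self.cdl_method},
            "tau": {"value": self.tau_s, "unit": "s"},
            "f_max": {"value": self.f_max_hz, "unit": "Hz"},
            "rct": {"value": self.rct_ohm, "unit": "ohm"},
            "notes": dict(self.notes),
        }

    def to_row(self) -> Dict[str, float | str]:
        """Flat CSV row (capacitance in uF, matching the conventional table units)."""
        return {
            "cdl_uF": self.cdl_farad * 1e6,
            "tau_s": self.tau_s,
            "f_max_hz": self.f_max_hz,
            "rct_ohm": self.rct_ohm,
            "cdl_method": self.cdl_method,
        }


# ---------------------------------------------------------------------------
# closed-form descriptors
# ---------------------------------------------------------------------------


def brug_capacitance(y0: float, n: float, rs: float, rct: float) -> float:
    """Effective double-layer capacitance of a CPE via the Brug relation.

        C_dl = [ Y0 * (1/Rs + 1/Rct)^(n-1) ]^(1/n)

    ``y0`` in S s^n, ``rs``/``rct`` in ohm; at ``n = 1`` the CPE is an ideal
    capacitor and the result reduces to ``y0``.
    """
    if min(y0, n, rs, rct) <= 0:
        raise ValueError("all Brug inputs must be > 0")
    if n > 1:
        raise ValueError(f"CPE exponent must satisfy 0 < n <= 1, got {n}")
    return float((y0 * (1.0 / rs + 1.0 / rct) ** (n - 1.0)) ** (1.0 / n))


def summed_capacitance(capacitances: Sequence[float]) -> float:
    """Overall double-layer capacitance of spatially distributed RC branches (sum)."""
    if len(capacitances) == 0:
        raise ValueError("capacitance list is empty")
    if any(c <= 0 for c in capacitances):
        raise ValueError("capacitances must be > 0")
    return float(math.fsum(capacitances))


def time_constant(r: float, c: float) -> float:
    """Relaxation time constant ``tau = R C`` in seconds."""
    if r <= 0 or c <= 0:
        raise ValueError("R and C must be > 0")
    return r * c


def characteristic_frequency(tau: float) -> float:
    """Phase-peak frequency of a relaxation: ``f_max = 1/(2 pi tau)``."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return 1.0 / (2.0 * math.pi * tau)


def tau_from_frequency(f_max: float) -> float:
    """Time constant from a phase-peak frequency: ``tau = 1/(2 pi f_max)``."""
    if f_max <= 0:
        raise ValueError("f_max must be > 0")
    return 1.0 / (2.0 * math.pi * f_max)


# ---------------------------------------------------------------------------
# spectrum features
# ---------------------------------------------------------------------------


def _quadratic_peak(logf: np.ndarray, y: np.ndarray, i: int) -> Tuple[float, float]:
    """Vertex of the parabola through points i-1, i, i+1 of (log f, y)."""
    x0, x1, x2 = logf[i - 1], logf[i], logf[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a == 0:
        return float(x1), float(y1)
    xv = -b / (2 * a)
    if not (min(x0, x2) <= xv <= max(x0, x2)):
        return float(x1), float(y1)
    c = y1 - a * x1**2 - b * x1
    return float(xv), float(a * xv**2 + b * xv + c)


def _circle_fit(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Algebraic (Kasa) circle fit; returns (xc, yc, radius)."""
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    xc, yc = sol[0] / 2.0, sol[1] / 2.0
    r = math.sqrt(max(sol[2] + xc**2 + yc**2, 0.0))
    return float(xc), float(yc), float(r)


def nyquist_features(spectrum: FrequencySpectrum) -> Dict[str, object]:
    """Features of the Nyquist plot (-Z'' vs Z').

    Returns a dict with ``hf_intercept_ohm`` always present; ``arc_diameter_ohm``
    and ``apex_frequency_hz`` when the spectrum shows an interior -Z'' maximum,
    and ``lf_slope_angle_deg`` from a line fit through the lowest decade.
    Undetectable features are reported as ``{"absent": <reason>}`` rather than
    raising.
    """
    spec = spectrum.descending()
    zr, zi, f = spec.z_real, spec.z_imag, spec.frequencies
    neg_zi = -zi
    out: Dict[str, object] = {"hf_intercept_ohm": float(zr[0])}

    # interior apex of the arc
    i = int(np.argmax(neg_zi))
    has_arc = 0 < i < len(spec) - 1 and neg_zi[i] > 0
    if not has_arc:
        reason = "no interior -Z'' extremum; spectrum does not resolve an arc"
        out["apex_frequency_hz"] = {"absent": reason}
        out["arc_diameter_ohm"] = {"absent": reason}
    else:
        logf_apex, _ = _quadratic_peak(np.log10(f), neg_zi, i)
        out["apex_frequency_hz"] = float(10.0**logf_apex)
        # arc closes where -Z'' falls back to <= 5% of the apex value
        closing = np.nonzero(neg_zi[i:] <= 0.05 * neg_zi[i])[0]
        if closing.size:
            j = i + int(closing[0])
            out["arc_diameter_ohm"] = float(zr[j] - zr[0])
            out["arc_diameter_method"] = "closure"
        else:
            # open arc: extrapolate with a least-squares circle through the arc
            sel = slice(max(i - len(spec) // 4, 0), min(i + len(spec) // 4 + 1, len(spec)))
            xc, yc, r = _circle_fit(zr[sel], neg_zi[sel])
            chord = r**2 - yc**2
            if chord <= 0:
                out["arc_diameter_ohm"] = {"absent": "arc does not close and circle fit "
                                                     "does not intersect the real axis"}
            else:
                out["arc_diameter_ohm"] = float(2.0 * math.sqrt(chord))
                out["arc_diameter_method"] = "semicircle-extrapolation"

    # low-frequency slope over the lowest decade of the sweep
    mask = f <= f[-1] * 10.0
    if int(mask.sum()) < 2:
        out["lf_slope_angle_deg"] = {"absent": "fewer than 2 points in the lowest decade"}
    elif np.ptp(zr[mask]) <= 1e-12 * np.max(np.abs(zr[mask])):
        out["lf_slope_angle_deg"] = {"absent": "Z' is constant over the lowest decade"}
    else:
        slope = np.polyfit(zr[mask], neg_zi[mask], 1)[0]
        out["lf_slope_angle_deg"] = float(math.degrees(math.atan(slope)))
    return out


def bode_summary(spectrum: FrequencySpectrum) -> Dict[str, object]:
    """Bode curves and the phase-angle peak.

    Phase is ``atan2(Z'', Z')`` in degrees (capacitive behaviour negative).
    All interior extrema of ``-theta`` are reported (multi-relaxation spectra
    show several); the global one is designated the phase peak, localized by
    quadratic interpolation through the three surrounding grid points.
    """
    spec = spectrum.descending()
    f = spec.frequencies
    theta = np.degrees(np.arctan2(spec.z_imag, spec.z_real))
    out: Dict[str, object] = {
        "frequency_hz": f,
        "modulus_ohm": spec.modulus,
        "phase_deg": theta,
    }
    y = -theta
    interior = [
        i
        for i in range(1, len(y) - 1)
        if y[i] >= y[i - 1] and y[i] >= y[i + 1] and (y[i] > y[i - 1] or y[i] > y[i + 1])
    ]
    peaks = []
    logf = np.log10(f)
    for i in interior:
        xf, yv = _quadratic_peak(logf, y, i)
        peaks.append({"frequency_hz": float(10.0**xf), "angle_deg": float(-yv)})
    out["phase_peaks"] = peaks
    if peaks:
        best = max(peaks, key=lambda p: -p["angle_deg"])
        out["phase_peak_frequency_hz"] = best["frequency_hz"]
        out["phase_peak_angle_deg"] = best["angle_deg"]
    else:
        out["phase_peak_frequency_hz"] = {"absent": "no interior extremum of -theta"}
        out["phase_peak_angle_deg"] = {"absent": "no interior extremum of -theta"}
    return out


def rct_ordering(
    summaries: Sequence[Tuple[str, DerivedSummary]], rtol: float = 1e-9
) -> Dict[str, object]:
    """Labels ordered by descending charge-transfer resistance; ties reported."""
    if len(summaries) < 2:
        if len(summaries) == 1:
            return {"order": [summaries[0][0]], "ties": []}
        raise ValueError("need at least one labeled summary")
    items = sorted(summaries, key=lambda kv: kv[1].rct_ohm, reverse=True)
    ties: List[Tuple[str, str]] = []
    for (la, sa), (lb, sb) in zip(items, items[1:]):
        if math.isclose(sa.rct_ohm, sb.rct_ohm, rel_tol=rtol):
            ties.append((la, lb))
    return {"order": [label for label, _ in items], "ties": ties}
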