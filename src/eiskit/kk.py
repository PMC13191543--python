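"""Linear Kramers-Kronig validity testing (lin-KK).

A spectrum from a linear, causal, stable system must satisfy the
Kramers-Kronig relations between its real and imaginary parts.  Rather than
evaluating the KK integrals directly, the spectrum is fitted with a chain of
Voigt relaxation elements with *fixed*, log-spaced time constants,

    Z_KK(w) = R_s + sum_k R_k / (1 + j w tau_k)   [+ 1/(j w C_s) optionally]

which is itself KK-compliant for any real coefficients R_k.  Because the tau_k
are fixed, the coefficients follow from a weighted *linear* least squares
(modulus weighting, coefficients unconstrained in sign).  A KK-consistent
spectrum is reconstructed to within the noise; nonstationary (drifting) or
nonlinear data leave systematic residuals and elevated chi-squared.

The verdict is "pass" when all three reduced chi-squared components (modulus,
real, imaginary) fall below the acceptance threshold (default 1e-6) and no
systematic residual deviation is flagged.  The systematic-deviation flag
combines a Wald-Wolfowitz runs test on residual signs (p < 0.05) with a
resolvability floor: a finite Voigt chain approximates CPE- or Warburg-like
dispersion with a tiny but sign-correlated error, so runs-test structure only
counts against a spectrum when the residuals are larger than
``RESIDUAL_FLOOR`` rms — an order of magnitude below the chi2 = 1e-6
acceptance scale and well above the basis-approximation floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from ._stats import runs_test_pvalue
from .spectrum import FrequencySpectrum

__all__ = ["KKResult", "LinKKValidator", "linkk", "residual_report", "RankDeficiencyError"]

#: elements per decade of the (extended) time-constant grid
ELEMENTS_PER_DECADE = 7
#: rms relative residual below which runs-test structure is not counted
RESIDUAL_FLOOR = 1e-4
#: Schoenleber mu cut used by automatic model-order selection
MU_CUT = 0.85


class RankDeficiencyError(np.linalg.LinAlgError):
    """Requested more relaxation elements than the spectrum can inform."""


@dataclass(frozen=True)
class KKResult:
    n_elements: int
    tau_grid: np.ndarray              # s, strictly increasing
    weights: np.ndarray               # ohm, one per relaxation element
    series_resistance: float          # ohm
    series_capacitance: float | None  # F, when the optional series C is enabled
    reconstruction: FrequencySpectrum
    chi2_modulus: float
    chi2_real: float
    chi2_imag: float
    residuals_real: np.ndarray        # relative (fraction of |Z|), per frequency
    residuals_imag: np.ndarray
    runs_pvalue: float
    systematic_flag: bool
    verdict: bool                     # True = pass
    threshold: float
    mu: float

    def to_dict(self) -> Dict:
        return {
            "n_elements": self.n_elements,
            "series_resistance": {"value": self.series_resistance, "unit": "ohm"},
            "series_capacitance": (
                None
                if self.series_capacitance is None
                else {"value": self.series_capacitance, "unit": "F"}
            ),
            "chi2": {
                "modulus": self.chi2_modulus,
                "real": self.chi2_real,
                "imag": self.chi2_imag,
                "unit": "",
            },
            "threshold": self.threshold,
            "mu": self.mu,
            "runs_pvalue": self.runs_pvalue,
            "systematic_deviation": self.systematic_flag,
            "verdict": "pass" if self.verdict else "fail",
        }


def _default_tau_grid(spectrum: FrequencySpectrum, n_elements: int | None) -> np.ndarray:
    """Fixed log-spaced relaxation times covering the sweep plus one decade each side."""
    w = spectrum.omega
    tau_min = 1.0 / np.max(w) / 10.0
    tau_max = 1.0 / np.min(w) * 10.0
    if n_elements is None:
        span = np.log10(tau_max / tau_min)
        n_elements = max(int(round(ELEMENTS_PER_DECADE * span)), 2)
    return np.logspace(np.log10(tau_min), np.log10(tau_max), n_elements)


def _solve(
    spectrum: FrequencySpectrum,
    tau: np.ndarray,
    series_capacitance: bool,
    strict_rank: bool,
) -> Tuple[np.ndarray, float, float | None, np.ndarray]:
    """Weighted linear LSQ for the Voigt-chain coefficients.

    Returns (weights, R_s, C_s or None, complex reconstruction).
    """
    w_ang = spectrum.omega
    mag = spectrum.modulus
    cols = [np.ones_like(w_ang, dtype=complex)]
    cols += [1.0 / (1.0 + 1j * w_ang * t) for t in tau]
    if series_capacitance:
        cols.append(1.0 / (1j * w_ang))  # coefficient is 1/C_s
    a = np.column_stack(cols)
    wt = 1.0 / mag
    a_stacked = np.vstack([a.real * wt[:, None], a.imag * wt[:, None]])
    b_stacked = np.concatenate([spectrum.z_real * wt, spectrum.z_imag * wt])
    coef, _, rank, _ = np.linalg.lstsq(a_stacked, b_stacked, rcond=None)
    if strict_rank and rank < a.shape[1]:
        raise RankDeficiencyError(
            f"{a.shape[1]} coefficients requested but informative rank is {rank}"
        )
    z_hat = a @ coef
    r_s = float(coef[0])
    c_s = float(1.0 / coef[-1]) if series_capacitance and coef[-1] != 0 else None
    weights = coef[1 : 1 + tau.size]
    if not series_capacitance:
        c_s = None
    return weights, r_s, c_s, z_hat


def _mu(weights: np.ndarray) -> float:
    """Schoenleber overfit measure: 1 - sum(|negative R_k|)/sum(|positive R_k|)."""
    neg = float(np.sum(np.abs(weights[weights < 0])))
    pos = float(np.sum(np.abs(weights[weights >= 0])))
    if pos == 0:
        return 0.0
    return 1.0 - neg / pos


class LinKKValidator:
    """Linear Kramers-Kronig validity test with a fixed Voigt-chain basis.

    Parameters
    ----------
    n_elements : int, "auto" or None
        Number of relaxation elements.  ``None`` (default) fixes 7 per decade
        of the extended time-constant span; ``"auto"`` grows the count until
        the Schoenleber mu measure drops below 0.85 (overfit onset).
    threshold : float
        Acceptance bound on each reduced chi-squared component.
    series_capacitance : bool
        Include a series 1/(jwC) term for capacitively drifting low-frequency
        behaviour (off by default).
    tau_grid : array, optional
        Explicit relaxation times (s); overrides ``n_elements``.
    """

    def __init__(
        self,
        n_elements: int | str | None = None,
        threshold: float = 1e-6,
        series_capacitance: bool = False,
        tau_grid: np.ndarray | None = None,
    ):
        self.n_elements = n_elements
        self.threshold = threshold
        self.series_capacitance = series_capacitance
        self.tau_grid = tau_grid

    def get_params(self, deep: bool = True) -> Dict:
        return {
            "n_elements": self.n_elements,
            "threshold": self.threshold,
            "series_capacitance": self.series_capacitance,
            "tau_grid": self.tau_grid,
        }

    def set_params(self, **params) -> "LinKKValidator":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, spectrum: FrequencySpectrum) -> "LinKKValidator":
        if spectrum.n_decades < 3:
            raise ValueError(
                f"lin-KK needs a span of >= 3 decades, got {spectrum.n_decades:.2f}"
            )
        n = len(spectrum)
        strict = False
        if self.tau_grid is not None:
            tau = np.sort(np.asarray(self.tau_grid, dtype=float))
            strict = True
        elif self.n_elements == "auto":
            tau = self._auto_tau(spectrum)
        elif self.n_elements is None:
            tau = _default_tau_grid(spectrum, None)
        else:
            m = int(self.n_elements)
            if m > n:
                raise ValueError(f"n_elements={m} exceeds the {n} measured frequencies")
            tau = _default_tau_grid(spectrum, m)
            strict = True

        weights, r_s, c_s, z_hat = _solve(spectrum, tau, self.series_capacitance, strict)
        self.result_ = self._assemble(spectrum, tau, weights, r_s, c_s, z_hat)
        return self

    def _auto_tau(self, spectrum: FrequencySpectrum) -> np.ndarray:
        cap = min(len(spectrum), int(round(ELEMENTS_PER_DECADE * (spectrum.n_decades + 2))))
        chosen = cap
        for m in range(3, cap + 1):
            tau = _default_tau_grid(spectrum, m)
            weights, _, _, _ = _solve(spectrum, tau, self.series_capacitance, False)
            if _mu(weights) < MU_CUT:
                chosen = m
                break
        return _default_tau_grid(spectrum, chosen)

    def _assemble(self, spectrum, tau, weights, r_s, c_s, z_hat) -> KKResult:
        n = len(spectrum)
        p = 1 + tau.size + (1 if self.series_capacitance else 0)
        dof = max(2 * n - p, 1)
        mag = spectrum.modulus
        rel_re = (spectrum.z_real - z_hat.real) / mag
        rel_im = (spectrum.z_imag - z_hat.imag) / mag
        rel_mod = (mag - np.abs(z_hat)) / mag
        half = dof / 2.0
        chi2_real = float(np.sum(rel_re**2)) / half
        chi2_imag = float(np.sum(rel_im**2)) / half
        chi2_mod = float(np.sum(rel_mod**2)) / half
        p_re = runs_test_pvalue(rel_re)
        p_im = runs_test_pvalue(rel_im)
        flag = (
            p_re < 0.05 and float(np.sqrt(np.mean(rel_re**2))) > RESIDUAL_FLOOR
        ) or (p_im < 0.05 and float(np.sqrt(np.mean(rel_im**2))) > RESIDUAL_FLOOR)
        verdict = (
            chi2_mod < self.threshold
            and chi2_real < self.threshold
            and chi2_imag < self.threshold
            and not flag
        )
        recon = spectrum.with_impedance(z_hat)
        return KKResult(
            n_elements=int(tau.size),
            tau_grid=tau,
            weights=np.asarray(weights, float),
            series_resistance=r_s,
            series_capacitance=c_s,
            reconstruction=recon,
            chi2_modulus=chi2_mod,
            chi2_real=chi2_real,
            chi2_imag=chi2_imag,
            residuals_real=rel_re,
            residuals_imag=rel_im,
            runs_pvalue=min(p_re, p_im),
            systematic_flag=bool(flag),
            verdict=bool(verdict),
            threshold=self.threshold,
            mu=_mu(np.asarray(weights, float)),
        )


def linkk(
    spectrum: FrequencySpectrum,
    n_elements: int | str | None = None,
    threshold: float = 1e-6,
    series_capacitance: bool = False,
    tau_grid: np.ndarray | None = None,
) -> KKResult:
    """Functional wrapper over :class:`LinKKValidator`."""
    v = LinKKValidator(
        n_elements=n_elements,
        threshold=threshold,
        series_capacitance=series_capacitance,
        tau_grid=tau_grid,
    ).fit(spectrum)
    return v.result_


def residual_report(result: KKResult) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-frequency relative residual table (% of |Z|) plus a summary.

    The summary carries the maximum absolute residual (%) and the runs-test
    p-value used by the systematic-deviation flag.
    """
    table = pd.DataFrame(
        {
            "frequency_hz": result.reconstruction.frequencies,
            "residual_real_pct": 100.0 * result.residuals_real,
            "residual_imag_pct": 100.0 * result.residuals_imag,
        }
    )
    summary = {
        "max_abs_residual_pct": float(
            np.max(np.abs(np.concatenate([result.residuals_real, result.residuals_imag])))
            * 100.0
        ),
        "runs_pvalue": float(result.runs_pvalue),
    }
    return table, summary
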