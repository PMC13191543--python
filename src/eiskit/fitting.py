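"""Complex nonlinear least-squares (CNLS) fitting of equivalent circuits.

The fit minimises the weighted sum of squared real and imaginary residuals

    S(p) = sum_i w_i * [ (Z'_i - Zhat'_i)^2 + (Z''_i - Zhat''_i)^2 ]

with modulus weighting ``w_i = |Z_i|^-2`` (the standard choice when impedance
magnitudes span many orders over the sweep) or unit weighting ``w_i = 1``.
Positivity of every circuit parameter is enforced by optimising the logarithm
of each parameter with a trust-region reflective solver; the CPE exponent keeps
its upper bound at the ideal-capacitor limit ``n = 1``.

Reported goodness of fit is the reduced statistic ``chi2 = S / (2N - p)`` with
``N`` frequencies and ``p`` free parameters.  Parameter uncertainties come from
the scaled inverse Gauss-Newton normal matrix, ``cov = s^2 (J^T J)^-1`` with
``s^2`` the reduced residual sum, evaluated in log-parameter space so the
diagonal directly gives *relative* standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from ._stats import runs_test_pvalue
from .circuits import (
    CircuitElement,
    CircuitModel,
    Parallel,
    Series,
    circuit_impedance,
    parse_circuit,
)
from .parameters import ParameterSet
from .spectrum import FrequencySpectrum

__all__ = [
    "DegenerateSpectrumError",
    "FitResult",
    "Chi2Components",
    "CircuitFitter",
    "initial_guess",
    "fit",
    "chi_squared",
    "compare_models",
    "rc_branches",
]


class DegenerateSpectrumError(ValueError):
    """Spectrum carries too little structure to seed the requested model."""


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chi2Components:
    """Reduced chi-squared, total and per impedance component.

    ``total`` is S/(2N-p) over stacked real+imaginary residuals; the ``real``,
    ``imag`` and ``modulus`` components each use only the respective residual,
    normalised by (2N-p)/2 so that (real + imag)/2 == total.
    """

    total: float
    real: float
    imag: float
    modulus: float


@dataclass(frozen=True)
class FitResult:
    params: ParameterSet
    rsd_percent: Dict[str, float]
    chi2: float
    chi2_components: Chi2Components
    residuals: np.ndarray  # weighted, stacked (real block then imaginary block)
    n_iter: int
    converged: bool
    degrees_of_freedom: int
    weighting: str
    circuit: str
    branches: Tuple[Dict[str, float | str], ...] = field(default_factory=tuple)

    @property
    def residuals_real(self) -> np.ndarray:
        return self.residuals[: self.residuals.size // 2]

    @property
    def residuals_imag(self) -> np.ndarray:
        return self.residuals[self.residuals.size // 2 :]

    def to_dict(self) -> Dict:
        """JSON-ready report: every value carries its unit string."""
        return {
            "circuit": self.circuit,
            "weighting": self.weighting,
            "parameters": {
                name: {
                    "value": self.params[name],
                    "unit": self.params.entry(name).unit,
                    "rsd_percent": self.rsd_percent.get(name),
                    "fixed": self.params.entry(name).fixed,
                }
                for name in self.params.names
            },
            "chi2": {
                "total": self.chi2,
                "real": self.chi2_components.real,
                "imag": self.chi2_components.imag,
                "modulus": self.chi2_components.modulus,
                "unit": "",
            },
            "branches_by_tau": list(self.branches),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "degrees_of_freedom": self.degrees_of_freedom,
        }


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _weights(spectrum: FrequencySpectrum, weighting: str) -> np.ndarray:
    """Per-point standard-deviation weights (residuals are multiplied by these)."""
    if weighting == "modulus":
        mag = spectrum.modulus
        if np.any(mag == 0):
            raise ValueError("modulus weighting undefined where |Z| = 0")
        return 1.0 / mag
    if weighting == "unit":
        return np.ones(len(spectrum))
    raise ValueError(f"unknown weighting {weighting!r}; expected 'modulus' or 'unit'")


def _stacked_residuals(
    spectrum: FrequencySpectrum,
    model: CircuitModel,
    params: ParameterSet | Mapping[str, float],
    w: np.ndarray,
) -> np.ndarray:
    z_hat = circuit_impedance(model, params, spectrum.frequencies).impedance
    dz = spectrum.impedance - z_hat
    return np.concatenate([w * dz.real, w * dz.imag])


def rc_branches(
    model: CircuitModel, params: ParameterSet | Mapping[str, float]
) -> Tuple[Dict[str, float | str], ...]:
    """Parallel R||C branches of a series chain, sorted by ascending RC time constant.

    Canonical ordering removes the permutation ambiguity of interchangeable
    relaxation branches (the labels R2||C1 vs R3||C2 carry no physics), so
    recovery experiments can compare branch sets independent of labelling.
    """
    values = params.values_dict() if isinstance(params, ParameterSet) else dict(params)
    branches: List[Dict[str, float | str]] = []
    top = model.root.children if isinstance(model.root, Series) else (model.root,)
    for node in top:
        if not isinstance(node, Parallel) or len(node.children) != 2:
            continue
        kinds = {c.kind for c in node.children if isinstance(c, CircuitElement)}
        if kinds != {"resistor", "capacitor"}:
            continue
        r_el = next(c for c in node.children if c.kind == "resistor")
        c_el = next(c for c in node.children if c.kind == "capacitor")
        r, c = values[r_el.label], values[c_el.label]
        branches.append(
            {
                "r_label": r_el.label,
                "c_label": c_el.label,
                "r_ohm": r,
                "c_farad": c,
                "tau_s": r * c,
            }
        )
    branches.sort(key=lambda b: b["tau_s"])
    return tuple(branches)


def _series_and_parallel_resistors(model: CircuitModel) -> Tuple[List[str], List[str]]:
    """Resistor labels split into top-level series resistors and the rest."""
    series_r: List[str] = []
    parallel_r: List[str] = []
    top = model.root.children if isinstance(model.root, Series) else (model.root,)
    top_series = {id(n) for n in top if isinstance(n, CircuitElement) and n.kind == "resistor"}
    for el in model.elements:
        if el.kind != "resistor":
            continue
        if id(el) in top_series or el is model.root:
            series_r.append(el.label)
        else:
            parallel_r.append(el.label)
    return series_r, parallel_r


# ---------------------------------------------------------------------------
# initial guess
# ---------------------------------------------------------------------------


def initial_guess(spectrum: FrequencySpectrum, model: CircuitModel) -> ParameterSet:
    """Geometry-based seeds for a CNLS fit.

    The high-frequency Z' intercept seeds the series resistance; the
    low-frequency Z' rise above the intercept seeds the total polarization
    resistance, split equally over parallel resistors; capacitive elements are
    seeded from the Nyquist apex frequency via ``C = 1/(2 pi f_apex R)``; a CPE
    starts at ``n = 0.8`` with ``Y0`` from the same apex relation; a Warburg is
    seeded from the magnitude of the lowest-frequency imaginary impedance.
    """
    if len(spectrum) < 5 or spectrum.n_decades < 2:
        raise DegenerateSpectrumError(
            f"need >= 5 points spanning >= 2 decades, got {len(spectrum)} points over "
            f"{spectrum.n_decades:.2f} decades"
        )
    spec = spectrum.descending()
    zr, zi, f = spec.z_real, spec.z_imag, spec.frequencies

    intercept = float(zr[0])
    r_pol = float(np.max(zr) - intercept)

    series_r, parallel_r = _series_and_parallel_resistors(model)
    needs_structure = any(k != "resistor" for k in (el.kind for el in model.elements))
    if needs_structure and r_pol <= 0:
        raise DegenerateSpectrumError(
            "Z' does not rise above the high-frequency intercept; no polarization "
            "resistance separable for the requested model"
        )

    # Nyquist apex: interior maximum of -Z''
    neg_zi = -zi
    apex_idx = int(np.argmax(neg_zi))
    f_apex = float(f[apex_idx]) if neg_zi[apex_idx] > 0 else float(np.sqrt(f[0] * f[-1]))

    seeds: Dict[str, float] = {}
    if series_r:
        each = max(intercept, 1e-3) / len(series_r)
        for name in series_r:
            seeds[name] = each
    if parallel_r:
        each = max(r_pol, 1e-3) / len(parallel_r)
        for name in parallel_r:
            seeds[name] = each
    r_branch = max(r_pol, intercept, 1e-3) / max(len(parallel_r), 1)

    w_apex = 2.0 * np.pi * f_apex
    for el in model.elements:
        if el.kind == "capacitor":
            seeds[el.label] = 1.0 / (w_apex * r_branch)
        elif el.kind == "cpe":
            y0_name, n_name = el.param_names
            seeds[n_name] = 0.8
            seeds[y0_name] = 1.0 / (r_branch * w_apex**0.8)
        elif el.kind == "warburg":
            (w_name,) = el.param_names
            w_low = 2.0 * np.pi * f[-1]
            zi_low = max(abs(float(zi[-1])), 1e-12)
            seeds[w_name] = 1.0 / (zi_low * np.sqrt(2.0 * w_low))

    guess = ParameterSet.from_values({name: seeds[name] for name in model.param_names})
    # clip strictly inside bounds
    clipped = {}
    for name in guess.names:
        e = guess.entry(name)
        clipped[name] = float(np.clip(e.value, e.lower * (1 + 1e-9), e.upper * (1 - 1e-9)))
    return guess.with_values(clipped)


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------


def chi_squared(
    spectrum: FrequencySpectrum,
    model: CircuitModel,
    params: ParameterSet | Mapping[str, float],
    weighting: str = "modulus",
    n_free: int | None = None,
) -> Chi2Components:
    """Reduced weighted chi-squared of ``params`` against ``spectrum``.

    ``n_free`` defaults to every circuit parameter free (used for dof); pass
    the number actually optimised to reproduce a fit's statistic.
    """
    w = _weights(spectrum, weighting)
    z_hat = circuit_impedance(model, params, spectrum.frequencies).impedance
    dz = spectrum.impedance - z_hat
    n = len(spectrum)
    p = len(model.param_names) if n_free is None else n_free
    dof = 2 * n - p
    if dof <= 0:
        raise ValueError(f"nonpositive degrees of freedom: 2*{n} - {p}")
    s_re = float(np.sum((w * dz.real) ** 2))
    s_im = float(np.sum((w * dz.imag) ** 2))
    d_mod = np.abs(spectrum.impedance) - np.abs(z_hat)
    s_mod = float(np.sum((w * d_mod) ** 2))
    half = dof / 2.0
    return Chi2Components(
        total=(s_re + s_im) / dof, real=s_re / half, imag=s_im / half, modulus=s_mod / half
    )


# ---------------------------------------------------------------------------
# fitter
# ---------------------------------------------------------------------------


class CircuitFitter(BaseEstimator):
    """Sklearn-style CNLS fitter for one circuit topology.

    Parameters
    ----------
    circuit : str or CircuitModel
        Topology in circuit notation (e.g. ``"R1 + (R2||CPE)"``).
    weighting : {"modulus", "unit"}
        ``modulus`` applies |Z|^-2 weights to the squared residuals.
    max_iter : int
        Trust-region iteration cap.
    ftol : float
        Convergence when the relative change of the weighted residual sum
        falls below this.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_ : ParameterSet            converged parameter values
    rsd_percent_ : dict               per-parameter relative std. dev. in %
    chi2_ : float                     reduced weighted chi-squared
    result_ : FitResult               full record incl. residuals and branches
    """

    def __init__(
        self,
        circuit: str | CircuitModel,
        weighting: str = "modulus",
        max_iter: int = 1000,
        ftol: float = 1e-10,
    ):
        self.circuit = circuit
        self.weighting = weighting
        self.max_iter = max_iter
        self.ftol = ftol

    def _model(self) -> CircuitModel:
        return self.circuit if isinstance(self.circuit, CircuitModel) else parse_circuit(self.circuit)

    def fit(self, spectrum: FrequencySpectrum, init: ParameterSet | None = None) -> "CircuitFitter":
        model = self._model()
        if init is None:
            init = initial_guess(spectrum, model)
        missing = [n for n in model.param_names if n not in init]
        if missing:
            raise KeyError(f"initial guess missing parameters: {missing}")
        w = _weights(spectrum, self.weighting)
        free = init.free_names
        p = len(free)
        n = len(spectrum)
        dof = 2 * n - p
        if dof <= 0:
            raise ValueError(f"underdetermined fit: 2*{n} points vs {p} free parameters")

        lower_v = np.array([init.entry(k).lower for k in free])
        upper_v = np.array([init.entry(k).upper for k in free])
        lower, upper = np.log(lower_v), np.log(upper_v)
        theta0 = np.clip(np.log(init.free_values()), lower, upper)

        def unpack(theta: np.ndarray) -> ParameterSet:
            # exp/log round-trip can overshoot a bound by an ulp; clip back
            return init.with_free_values(np.clip(np.exp(theta), lower_v, upper_v))

        def residuals(theta: np.ndarray) -> np.ndarray:
            return _stacked_residuals(spectrum, model, unpack(theta), w)

        res = least_squares(
            residuals,
            theta0,
            bounds=(lower, upper),
            method="trf",
            x_scale="jac",
            ftol=self.ftol,
            xtol=1e-13,
            gtol=1e-12,
            max_nfev=self.max_iter * (p + 1),
        )
        params = unpack(res.x)
        ssr = float(2.0 * res.cost)
        chi2 = ssr / dof
        rsd = self._rsd(res.jac, chi2, free)
        components = chi_squared(spectrum, model, params, self.weighting, n_free=p)
        self.params_ = params
        self.rsd_percent_ = rsd
        self.chi2_ = chi2
        self.n_iter_ = int(res.nfev)
        self.converged_ = bool(res.status > 0)
        self.result_ = FitResult(
            params=params,
            rsd_percent=rsd,
            chi2=chi2,
            chi2_components=components,
            residuals=res.fun.copy(),
            n_iter=self.n_iter_,
            converged=self.converged_,
            degrees_of_freedom=dof,
            weighting=self.weighting,
            circuit=model.serialize(),
            branches=rc_branches(model, params),
        )
        return self

    @staticmethod
    def _rsd(jac: np.ndarray, s2: float, free: Sequence[str]) -> Dict[str, float]:
        """Relative std. dev. (%) from the log-space normal matrix.

        In log space ``sigma_logp = sigma_p / p`` so the covariance diagonal is
        directly the squared relative uncertainty.  Directions lost to rank
        deficiency get NaN.
        """
        u, s, vt = np.linalg.svd(jac, full_matrices=False)
        if s.size == 0 or s[0] == 0:
            return {k: float("nan") for k in free}
        tol = np.finfo(float).eps * max(jac.shape) * s[0]
        good = s > tol
        var = np.einsum("ij,i,ij->j", vt[good], 1.0 / s[good] ** 2, vt[good]) * s2
        rsd = 100.0 * np.sqrt(np.maximum(var, 0.0))
        undefined = np.any(np.abs(vt[~good]) > 1e-8, axis=0) if np.any(~good) else np.zeros(len(free), bool)
        return {
            k: (float("nan") if undefined[i] else float(rsd[i])) for i, k in enumerate(free)
        }

    def predict(self, frequencies: np.ndarray) -> np.ndarray:
        """Model impedance at ``frequencies`` (Hz) with the fitted parameters."""
        if not hasattr(self, "params_"):
            raise AttributeError("CircuitFitter is not fitted yet")
        return circuit_impedance(self._model(), self.params_, frequencies).impedance


def fit(
    spectrum: FrequencySpectrum,
    model: CircuitModel | str,
    init: ParameterSet | None = None,
    weighting: str = "modulus",
) -> FitResult:
    """Functional wrapper over :class:`CircuitFitter`."""
    fitter = CircuitFitter(model, weighting=weighting).fit(spectrum, init=init)
    return fitter.result_


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelCandidate:
    circuit: str
    rank: int
    chi2: float | None
    n_free: int | None
    runs_pvalue: float | None
    structured_residuals: bool | None
    result: FitResult | None
    error: str | None = None


def compare_models(
    spectrum: FrequencySpectrum,
    candidates: Sequence[CircuitModel | str],
    weighting: str = "modulus",
    tie_rtol: float = 0.05,
    runs_alpha: float = 0.05,
) -> List[ModelCandidate]:
    """Fit every candidate circuit from its own initial guess and rank them.

    Ranking is by reduced chi-squared; candidates whose chi2 agree within
    ``tie_rtol`` (or both sit at the numerical-noise floor) are reordered to
    prefer fewer free parameters.  Structured residuals are flagged by a
    Wald-Wolfowitz runs test on the signs of the real weighted residuals.
    Candidates that fail to fit are reported with their error and ranked last.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate circuits to compare")
    fitted: List[Tuple[str, FitResult | None, str | None]] = []
    for cand in candidates:
        model = cand if isinstance(cand, CircuitModel) else parse_circuit(cand)
        try:
            result = fit(spectrum, model, weighting=weighting)
            fitted.append((model.serialize(), result, None))
        except Exception as exc:  # propagate per candidate, never abort
            fitted.append((model.serialize(), None, f"{type(exc).__name__}: {exc}"))

    ok = [t for t in fitted if t[1] is not None]
    bad = [t for t in fitted if t[1] is None]
    ok.sort(key=lambda t: t[1].chi2)

    # group chi2 ties, prefer fewer free parameters inside a group
    floor = 1e-18
    groups: List[List[Tuple[str, FitResult, None]]] = []
    for entry in ok:
        if groups:
            ref = groups[-1][0][1].chi2
            cur = entry[1].chi2
            if (max(ref, cur) < floor) or abs(cur - ref) <= tie_rtol * max(ref, cur):
                groups[-1].append(entry)
                continue
        groups.append([entry])
    ordered: List[Tuple[str, FitResult | None, str | None]] = []
    for g in groups:
        g.sort(key=lambda t: len(t[1].params.free_names))
        ordered.extend(g)
    ordered.extend(bad)

    out: List[ModelCandidate] = []
    for rank, (name, result, err) in enumerate(ordered, start=1):
        if result is None:
            out.append(ModelCandidate(name, rank, None, None, None, None, None, err))
        else:
            pval = runs_test_pvalue(result.residuals_real)
            # sign structure only counts when residuals are resolvable above
            # numerical noise (same floor as the Kramers-Kronig flag)
            rms = float(np.sqrt(np.mean(result.residuals_real**2)))
            out.append(
                ModelCandidate(
                    circuit=name,
                    rank=rank,
                    chi2=result.chi2,
                    n_free=len(result.params.free_names),
                    runs_pvalue=pval,
                    structured_residuals=bool(pval < runs_alpha and rms > 1e-4),
                    result=result,
                )
            )
    return out
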