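# Methods

`eiskit` analyses small-signal electrochemical impedance spectra Z(ω) with
equivalent-circuit models. This note records the models, conventions, and the
numerical and design choices behind them.

## Circuit elements and notation

A circuit is a finite series/parallel expression tree over four idealized
elements (ω = 2πf in rad/s; frequencies are handled in Hz everywhere outside
element evaluation):

| element | impedance | parameters |
|---|---|---|
| resistor | Z = R | R (Ω) |
| capacitor | Z = 1/(jωC) | C (F) |
| constant phase element (CPE) | Z = 1/(Y0 (jω)ⁿ) | Y0 (S·sⁿ), 0 < n ≤ 1 |
| Warburg (semi-infinite) | Z = 1/(W √(jω)) | W (S·s^1/2) |

The CPE convention with Y0 in S·sⁿ was chosen over the σ-form because it is
the convention under which the reference parameter values are stated; the
Warburg element is the semi-infinite admittance form (constant −45° phase),
with finite-length diffusion out of scope. Series nodes sum impedances;
parallel nodes sum admittances and invert. In the textual grammar `||` binds
tighter than `+`, both left-associative, so strings such as
`R1 + (R2||CPE)` and `R1 + (C1||(R2 + (C2||W)))` parse without extra
parentheses. Parameter names derive from element labels (`R2` → `R2`,
`CPE` → `Y0`,`n`, `CPE2` → `Y0_2`,`n_2`), which guarantees uniqueness and
round-trip-stable serialization.

## CNLS fitting

The fit minimises S(p) = Σᵢ wᵢ[(Z′ᵢ−Ẑ′ᵢ)² + (Z″ᵢ−Ẑ″ᵢ)²] with modulus
weighting wᵢ = |Zᵢ|⁻² (default) or unit weighting. Modulus weighting makes
the statistic scale-invariant and balances a sweep whose |Z| spans orders of
magnitude; it also matches a proportional-error noise model.

Numerical choices:

- **Positivity** is enforced by optimising θ = ln p with a trust-region
  reflective solver (`scipy.optimize.least_squares`, 2-point Jacobian);
  the CPE exponent keeps its upper bound at ln 1 = 0. Default bounds per
  family: R ∈ [10⁻⁶, 10¹²] Ω, C ∈ [10⁻¹⁶, 1] F, Y0 ∈ [10⁻¹², 10⁶] S·sⁿ,
  n ∈ [10⁻³, 1], W ∈ [10⁻¹², 10⁶] S·s^1/2.
- **Convergence**: relative change of the residual sum below 10⁻¹⁰, step
  tolerance 10⁻¹³, at most 1000 iterations' worth of function evaluations.
- **Goodness of fit**: reduced χ² = S/(2N − p), N frequencies, p free
  parameters. Per-component values (real, imaginary, modulus) divide each
  component's weighted sum by (2N − p)/2, so the mean of the real and
  imaginary components equals the total. With 0.05 % proportional noise this
  convention lands χ² in the 10⁻⁷ decade, the scale typical of
  well-conditioned instrument fits.
- **Uncertainties**: cov(θ) = s²(JᵀJ)⁻¹ with s² the reduced residual sum and
  J the weighted Jacobian in log space, computed by SVD. Because
  σ_ln p = σ_p/p, the diagonal directly gives the relative standard
  deviation; `rsd_percent` = 100·σ_ln p. Directions lost to rank deficiency
  are reported as NaN rather than a fabricated number. Monte-Carlo replicates
  confirm the reported rsd tracks the empirical spread and doubles with the
  noise level.
- **Initialisation** (when no explicit guess is given): the high-frequency Z′
  intercept seeds the series resistance; the low-frequency Z′ rise above it
  seeds the total polarization resistance, split equally over parallel
  resistors; capacitors are seeded from the −Z″ apex frequency via
  C = 1/(2πf_apex R); a CPE starts at n = 0.8 with Y0 from the same apex
  relation; a Warburg from the lowest-frequency |Z″|. A spectrum whose Z′
  never rises above the intercept cannot seed a model with polarization
  branches and raises a degeneracy error; a plain resistor model is exempt
  (the constant Z′ *is* the seed).
- **Label switching**: interchangeable parallel-RC branches of a series chain
  are additionally reported sorted by ascending time constant τ = RC, so
  recovery experiments compare branch sets rather than arbitrary labels.
  Parameter names themselves keep parse order — the reference parameter
  tables are not τ-ordered, and renaming would detach fitted values from the
  published labels.
- **Model comparison** fits each candidate from its own initial guess, ranks
  by χ², prefers fewer free parameters when χ² values agree within 5 % (or
  both sit at the numerical floor), and flags structured residuals by a
  Wald–Wolfowitz runs test on the signs of the real weighted residuals. A
  candidate that cannot be seeded or fitted is reported with its error and
  ranked last, never aborting the comparison.

## Linear Kramers–Kronig validation

KK consistency (linearity, causality, stability) is tested by fitting the
spectrum with a Voigt chain Z(ω) = R_s + Σₖ Rₖ/(1 + jωτₖ) whose relaxation
times are *fixed* log-spaced — 7 per decade over the measured span extended
one decade beyond each end — so the coefficients follow from a single
weighted linear least squares (|Z|⁻¹-weighted stacked real/imaginary rows,
coefficients unconstrained in sign). An optional series-capacitance term
(off by default) absorbs capacitively drifting low-frequency behaviour.
An automatic model order is available via the Schönleber μ-criterion
(grow the element count until μ < 0.85).

Verdict: pass iff all three reduced χ² components (modulus, real, imaginary;
same normalisation as the fitter) fall below the threshold (default 10⁻⁶)
*and* no systematic residual deviation is flagged. The flag combines the runs
test (p < 0.05 on either component's residual signs) with a resolvability
floor of 10⁻⁴ rms relative residual: a finite Voigt chain reproduces CPE- or
Warburg-type dispersion only to ≈10⁻⁷–10⁻⁶ relative error, and that tiny
approximation error is sign-correlated, so an unconditioned runs test would
flag even perfect synthetic spectra. The floor sits an order of magnitude
below the residual scale implied by χ² = 10⁻⁶ and two above the basis floor.
Uniform scaling of a spectrum changes neither χ² components nor the verdict.

## Derived descriptors

- Brug effective capacitance for CPE interfaces:
  C_dl = [Y0(R_s⁻¹ + R_ct⁻¹)ⁿ⁻¹]^(1/n); continuous in n with C_dl → Y0 as
  n → 1. For the CP reference parameters this evaluates to 5.30 µF — it does
  **not** reproduce the 0.224 µF quoted alongside those parameters under
  either a S·sⁿ or µS·sⁿ reading of Y0; the formula is computed faithfully
  and the discrepancy is surfaced rather than patched.
- Multi-RC interfaces: C_dl = ΣCᵢ (spatially distributed contributions);
  single-capacitor circuits report that capacitor.
- τ = RC and f_max = 1/(2πτ) are exposed as a reciprocal pair. Where a
  measured spectrum is available, τ is taken from the phase-angle peak
  (τ = 1/(2πf_max)) and the RC-product pathway is recorded in the notes;
  for the SPI reference values the two pathways genuinely disagree
  (R2·C2 = 0.673 s vs 5.3 s from the 0.03 Hz peak), so both are reported
  with provenance and the frequency pathway is treated as primary.
- Nyquist features: high-frequency Z′ intercept (solution resistance), arc
  apex frequency (quadratic interpolation in log f through the three points
  around the discrete extremum), arc diameter measured to where −Z″ falls
  back to ≤5 % of its apex (a Kasa least-squares circle fit extrapolates
  open arcs; the method used is recorded), and the low-frequency slope angle
  from a line fit through the lowest decade. Undetectable features are
  reported absent-with-reason, never raised.
- Bode features: phase = atan2(Z″, Z′) (capacitive negative); every interior
  extremum of −θ is reported and the global one designated the phase peak.

## Synthetic spectra

The generator emulates the measurement design the analysis assumes: sweeps
from 10 kHz down to 0.01 Hz (acquisition order), log-spaced, 10 points per
decade by default (61 points over 6 decades — the point count is a package
choice matching common practice; it keeps all three reference fits
well-conditioned). Three built-in fixtures carry the published topologies and
fitted values for the bare carbon-paste electrode (CP) and the beetroot (BET)
and spinach (SPI) modified electrodes, in SI units. The tabulated SPI film
capacitance (4.75×10⁻⁶ µF) and the textual reading (4.75 µF) disagree; the
fixture follows the table and the µF reading ships as an explicit variant.
Under the tabulated picofarad reading the SPI modulus does not converge to R1
until far above 10 kHz — the variant restores convergence within the sweep.

Noise adds independent zero-mean Gaussian perturbations to the real and
imaginary parts, each with σ = noise_level·|Z(f)| — the simplest model
consistent with modulus weighting. Drift adds (k/(N−1))·drift_level·|Z(f_k)|
to the real part at acquisition index k: linear in acquisition time, the
minimal nonstationarity that breaks KK consistency (drift_level = 0.02 fails
the test decisively). All randomness flows from one explicit integer seed.

What the generator does **not** emulate: electrode-to-electrode biological
variability, frequency-correlated instrument noise, harmonic distortion from
large perturbation amplitudes, and point-to-point settling artefacts. Passing
tests therefore demonstrate correctness of the analysis under the stated
noise model, not robustness to every pathology of real instrument data.

## Known limitations and non-goals

- No transmission-line, Gerischer, finite-length-diffusion or inductive
  elements; no bounded Warburg.
- No Bayesian posterior sampling or simultaneous multi-spectrum fitting.
- The lin-KK stage is a validity test only; it does not attempt regularized
  recovery of the distribution of relaxation times.
- Phase-peak locations computed from the reference circuit parameters need
  not match phase peaks quoted from measured instrument data: the simulated
  CP peak sits at 0.16 Hz (dense-grid value), and the SPI low-frequency
  Nyquist branch only reaches its 45° Warburg asymptote below the C2/W
  admittance crossover near 0.03 Hz, i.e. on grids extending below the
  default 0.01 Hz floor. Tests pin these behaviours with dense-grid oracles.
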