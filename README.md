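# eiskit

Equivalent-circuit analysis of electrochemical impedance spectroscopy (EIS)
data: circuit simulation, complex nonlinear least-squares (CNLS) fitting with
modulus weighting, linear Kramers–Kronig validity testing, and the derived
interfacial descriptors electrochemists compare across electrodes.

The package was built around the characterisation of carbon-paste electrodes
bulk-modified with plant extracts — a bare carbon-paste electrode (CP) and
electrodes carrying beetroot (BET) and spinach (SPI) extracts — where the
interface is described by three equivalent circuits:

```
CP    R1 + (R2||CPE)                         one depressed semicircle
BET   R1 + (R2||C1) + (R3||C2) + (R4||C3)    three interfacial relaxations
SPI   R1 + (C1||(R2 + (C2||W)))              blocking film + diffusion
```

with R1 the solution resistance, R2 the charge-transfer resistance R_ct, CPE
a constant phase element Z = 1/(Y0(jω)ⁿ), and W a semi-infinite Warburg
element Z = 1/(W√(jω)). Fitting minimises

    S(p) = Σᵢ |Zᵢ|⁻² [ (Z′ᵢ − Ẑ′ᵢ)² + (Z″ᵢ − Ẑ″ᵢ)² ],  χ² = S/(2N − p)

and spectra are screened beforehand with a linear Kramers–Kronig test (a
fixed-τ Voigt chain fitted by linear least squares; pass when all χ²
components < 10⁻⁶ with no systematic residuals). From the fitted parameters
the package derives the effective double-layer capacitance (Brug relation
C_dl = [Y0(R_s⁻¹+R_ct⁻¹)ⁿ⁻¹]^(1/n), capacitance sums for multi-RC films),
time constants τ = RC, characteristic frequencies f_max = 1/(2πτ), and
Nyquist/Bode features. A synthetic-spectrum generator (proportional noise,
optional nonstationary drift) stands in for instrument data, so the whole
pipeline is testable end to end. See `docs/methods.md` for conventions and
numerical details.

Audience: electrochemists and analytical chemists who want a scriptable,
tested alternative to vendor fitting software, and developers who need
reproducible EIS fixtures.

## Worked example

```python
from eiskit import AnalysisConfig, GenerationSpec, run_pipeline

report = run_pipeline(AnalysisConfig(generation=GenerationSpec(circuit="CP")))
print(report["fit"]["parameters"]["R2"]["value"])   # 694000.0000000006
print(report["fit"]["parameters"]["n"]["value"])    # 0.669
print(report["fit"]["chi2"]["total"])               # 1.37e-31
print(report["kramers_kronig"]["verdict"])          # pass
print(report["derived"]["cdl"])                     # {'method': 'brug', 'unit': 'F',
                                                    #  'value': 5.2974928838e-06}
```

A noiseless 61-point spectrum (10 kHz → 0.01 Hz) is generated from the CP
reference circuit, validated (Kramers–Kronig χ² ≈ 10⁻²³, far below the 10⁻⁶
bound), and refitted from heuristic seeds: the charge-transfer resistance
(6.94 × 10⁵ Ω) and CPE exponent (0.669) are recovered to machine precision
with χ² at the numerical floor. The Brug capacitance of this interface
evaluates to 5.30 µF. The same run from a shell:

```sh
eiskit report --electrode CP --out-dir results/cp
eiskit simulate --electrode SPI --noise 0.005 --seed 7 --out spi.csv
eiskit validate spi.csv
eiskit fit spi.csv --circuit "R1 + (C1||(R2 + (C2||W)))"
```

Every CLI report is JSON on stdout; `report` also writes a bundle
(`report.json`, `nyquist.csv`, `bode.csv`, `kk_residuals.csv`).

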