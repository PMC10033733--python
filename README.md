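# qclpas

Simulation and analysis of quantum-cascade-laser (QCL) photoacoustic spectra
for breath-gas analysis, built around a mid-infrared sensor that quantifies
acetone and ethanol in a synthetic breath matrix (water, CO2, synthetic air)
by sweeping the laser's high-level drive current over 8263–8270 nm
(~1210–1209 cm⁻¹).

## Who this is for

Developers and users of amplitude-modulated photoacoustic trace-gas sensors
who need to: simulate magnitude-vs-current spectra from component absorption
cross-sections; normalize recorded spectra against the optical-power
envelope; quantify mixtures by linear unmixing; characterize sensitivity,
detection limits, Allan-deviation stability and NNEA; and fit / error-attribute
the forward model of their instrument.

## The model

A photoacoustic spectrum is the lock-in magnitude `pa(I)` recorded at each
high-level current `I` (350–495 mA, 1 mA steps).  The forward model is

```
pa(I) = q(I) · ⟨P_ν̃(I), Σ_c A_ν̃(c)⟩ + b(I)
```

where `P_ν̃(I)` is the (unit-area) laser emission line at the current-dependent
center `ν̃(I) = t0 + t1·I` scaled by the optical power `P0(I)`, `A_ν̃(c)` the
absorption-coefficient spectrum of component `c` (cross-section × number
density), `q(I) = d0 + d1·I` an amplification factor lumping the cell constant
`C_cell = (γ−1)(Q/f_res)·L_R/(2V_R)` and detection gains, and
`b(I) = c0 + c1·I + c2·I²` the analyte-independent background.  The spectrum
inner product is evaluated per current (trapezoidal quadrature), mirroring how
the instrument only ever samples the swept emission centers.

Around this core the package implements:

* **Scaling** — `U_scale(I) = U_meas(I) / b_scale(I)` with
  `b_scale(I) = U_BS(I)/U_BS(495 mA) ∈ (0,1]`, removing the optical-power
  envelope from measured spectra.
* **Acoustics** — resonance shifts `f_res = f_res,BS + κ_H2O·X_H2O −
  κ_CO2·X_CO2` (5049 Hz, +5.4 Hz/%v-H2O, −15.0 Hz/%v-CO2), the inverse giving
  the CO2 content of a sample from a measured resonance; multiplicative
  compensation `U/(1 − X_CO2·b_CO2)` of the dry-CO2 signal loss.
* **Metrics** — Pearson/Spearman spectral similarity, non-overlapping Allan
  deviation, linear calibration with 3σ detection limits, and
  `NNEA = LoD·N_A·σ(ν̃)·P0 / (SNR·√ENBW·V_mol)`.
* **Unmixing** — least-squares concentration estimation of mixture spectra
  against single-component references (down to two selected currents for
  water + acetone).
* **Model fitting** — nonlinear least squares over a campaign of spectra with
  covariance-based error attribution, cross-checked by an affine-invariant
  ensemble sampler (emcee), plus base-spectrum corrections (global tank
  factor, smooth local shape adaptation).
* **Synthetic data** — a component library emulating the relevant shapes
  (water doublet at 1209.25/1209.77 cm⁻¹, ethanol feature at 1210.0 cm⁻¹ on a
  pedestal, a nearly flat acetone continuum, zero CO2 absorption) with
  amplitudes calibrated to the instrument's published sensitivities, so every
  analysis is testable without spectral-database downloads.

## Worked example

```python
import numpy as np
from qclpas.instrument import default_tuning, default_power, default_acoustics, \
    MatrixComposition, infer_co2, resonance_frequency
from qclpas.preprocess import scaling_curve, scale_by_background
from qclpas.synthetic import default_forward_params, default_scenarios, \
    make_campaign, make_component_library
from qclpas.unmix import build_design_matrix, unmix

tuning, power, acoustics = default_tuning(), default_power(), default_acoustics()
params = default_forward_params(power)
library = make_component_library()

# simulate the default campaign (background, singles, sums, synthetic breath)
spectra = {s.label: s for s in make_campaign(
    default_scenarios(base_seed=1), library, tuning, power, params,
    acoustics=acoustics)}

# CO2 content of the breath scenario from its stamped resonance frequency
breath = spectra["breath"]
x_co2 = infer_co2(breath.f_res_pre, breath.matrix.x_h2o, acoustics)
print(f"inferred CO2: {x_co2:.2f} %v")          # inferred CO2: 3.00 %v

# two-current water/acetone unmixing of a humidified acetone mixture
curve = scaling_curve(spectra["background"])
refs = {"water": (scale_by_background(spectra["water"], curve), 0.9),
        "acetone": (scale_by_background(spectra["acetone"], curve), 2.0)}
mix = scale_by_background(spectra["humid-acetone"], curve)
design = build_design_matrix(refs, np.array([448.0, 478.0]), background=36.0)
result = unmix(mix, design)
print({k: round(v, 3) for k, v in result.concentrations.items()})
# {'water': 0.878, 'acetone': 3.919}  (set values: 0.89 %v, 3.92 ppmv)
```

The inferred CO2 equals the scenario's set 3 %v because trace analytes do not
shift the resonance; the unmixing recovers the set water and acetone contents
from just two sweep points despite the overlapping water absorption.

There is also a CLI for file-based pipelines:

```sh
qclpas fixtures --seed 1 --out campaign/
qclpas scale --background campaign/spectrum_background.txt \
             --input campaign/spectrum_water.txt --out scaled_water.txt
qclpas similarity campaign/spectrum_breath.txt campaign/spectrum_ethanol+water.txt
```

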