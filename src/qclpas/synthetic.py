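"""Synthetic component library, measurement campaigns and time series.

Everything here is a *synthetic emulation* of the measured system, built so
the rest of the package is testable without any spectral-database download:

* water contributes a doublet of lines at 1209.25 and 1209.77 cm^-1 (the
  stronger one at 1209.25, which is why the water peak of a scaled spectrum
  sits near 485 mA);
* ethanol contributes an almost flat pedestal with one broad feature at
  1210.0 cm^-1;
* acetone is a nearly flat, gently sloping continuum over the whole sweep;
* CO2 has no absorption in the emission range at all — it acts on the
  spectra only through the acoustics (resonance shift, dry damping).

Amplitudes are free calibration constants chosen once so that the default
instrument settings reproduce sensitivities of the right order
(~64 uV/ppmv acetone, ~7.8 uV/ppmv ethanol, ~42.7 uV/%v water at the
calibration currents); shapes and relative scales are emulated, absolute
database magnitudes are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import (
    CELL_PRESSURE_PA,
    CELL_TEMPERATURE_K,
    ForwardModelParams,
    PASpectrum,
    add_noise,
    simulate_pa_spectrum,
)
from .instrument import (
    AcousticCoefficients,
    InstrumentError,
    MatrixComposition,
    PowerModel,
    SWEEP_MAX_MA,
    SWEEP_MIN_MA,
    TuningModel,
    default_acoustics,
    default_power,
    default_tuning,
    optical_power,
    resonance_frequency,
)
from .spectral import (
    CrossSection,
    GasComponent,
    SpectralError,
    SpectralLine,
    WavenumberGrid,
    voigt_cross_section,
)

__all__ = [
    "ScenarioSpec",
    "make_component_library",
    "make_campaign",
    "make_timeseries",
    "default_sweep",
    "default_grid",
    "default_forward_params",
    "default_scenarios",
    "components_for_matrix",
    "WATER_LINES",
    "NOISE_SIGMA_RAW_UV",
    "NOISE_SIGMA_SPECTRUM_UV",
    "BACKGROUND_UV",
]

# Water doublet: centers fixed by the observed peaks; the 1209.25 cm^-1 line
# is the stronger one.  Intensities reproduce the measured 42.7 uV/%v-H2O
# sensitivity at 485 mA under the default instrument.
WATER_LINES = (
    SpectralLine(center=1209.25, intensity=1.80e-24,
                 lorentz_hwhm=0.040, doppler_hwhm=0.002),
    SpectralLine(center=1209.77, intensity=1.26e-24,
                 lorentz_hwhm=0.040, doppler_hwhm=0.002),
)

# Continuum scales (cm^2/molecule); see module docstring for provenance.
ACETONE_SIGMA0 = 1.948e-19      # at 1209.225 cm^-1 (the 490 mA probe point)
ACETONE_SLOPE = 0.03            # relative change per cm^-1, rising with nu
ETHANOL_PEDESTAL = 2.370e-20
ETHANOL_PEAK_CENTER = 1210.0
ETHANOL_PEAK_SIGMA0 = 1.2e-20   # extra peak amplitude on top of the pedestal
ETHANOL_PEAK_FWHM = 0.30

BACKGROUND_UV = 36.0            # scaled background level at the reference current

# Raw lock-in sample noise: chosen so a 20 s / 5 Hz blank average has a
# 3 sigma level of ~93 nV (3 * sigma / sqrt(100) = 0.0932 uV).
NOISE_SIGMA_RAW_UV = 0.31067
# Each recorded spectrum point is itself a 16 s / 5 Hz (80-sample) average.
NOISE_SIGMA_SPECTRUM_UV = float(NOISE_SIGMA_RAW_UV / np.sqrt(80.0))

# Amplification q(I) = d0 + d1*I calibrated so the acetone sensitivity at
# 490 mA is 64.1 uV/ppmv under the default power curve (q varies ~10% over
# the sweep).
_D0 = 74821471.9021666
_D1 = 72818.95075636654


@dataclass(frozen=True)
class ScenarioSpec:
    """One planned measurement: a gas-matrix state, sweep, noise and seed."""

    matrix: MatrixComposition
    label: str
    seed: int
    noise_sigma_uv: float = NOISE_SIGMA_SPECTRUM_UV
    sweep: np.ndarray | None = None

    def __post_init__(self):
        if self.seed is None:
            raise InstrumentError("scenario seed is mandatory")
        if self.noise_sigma_uv < 0:
            raise InstrumentError("noise sigma must be >= 0")
        if self.sweep is not None:
            s = np.asarray(self.sweep, dtype=float)
            if np.any(s < SWEEP_MIN_MA) or np.any(s > SWEEP_MAX_MA):
                raise InstrumentError("sweep outside instrument bounds")
            object.__setattr__(self, "sweep", s)


def default_sweep() -> np.ndarray:
    """The 146-point high-level current sweep, 350-495 mA in 1 mA steps."""
    return np.arange(SWEEP_MIN_MA, SWEEP_MAX_MA + 1.0)


def default_grid(step: float = 0.002) -> WavenumberGrid:
    """Wavenumber grid spanning the component library and the sweep."""
    return WavenumberGrid.uniform(1208.9, 1210.4, step)


def default_forward_params(power: PowerModel | None = None) -> ForwardModelParams:
    """Background proportional to optical power (36 uV at the 495 mA
    reference) plus the calibrated amplification."""
    power = power or default_power()
    scale = BACKGROUND_UV / optical_power(SWEEP_MAX_MA, power)
    return ForwardModelParams(c0=scale * power.p0, c1=scale * power.p1,
                              c2=scale * power.p2, d0=_D0, d1=_D1)


def make_component_library(grid: WavenumberGrid | None = None) -> dict[str, CrossSection]:
    """Synthetic cross-section basis spectra for water, ethanol, acetone, CO2."""
    grid = grid or default_grid()
    lo, hi = grid.span
    if lo > 1209.0 or hi < 1210.3:
        raise SpectralError("grid must span at least 1209.0-1210.3 cm^-1")
    x = grid.values

    water = voigt_cross_section(list(WATER_LINES), grid)
    water = CrossSection(grid=grid, sigma=water.sigma, species="water")

    acetone_sigma = ACETONE_SIGMA0 * (1.0 + ACETONE_SLOPE * (x - 1209.225))
    acetone = CrossSection(grid=grid, sigma=acetone_sigma, species="acetone")

    sg = ETHANOL_PEAK_FWHM / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    ethanol_sigma = ETHANOL_PEDESTAL + ETHANOL_PEAK_SIGMA0 * np.exp(
        -0.5 * ((x - ETHANOL_PEAK_CENTER) / sg) ** 2)
    ethanol = CrossSection(grid=grid, sigma=ethanol_sigma, species="ethanol")

    co2 = CrossSection(grid=grid, sigma=np.zeros_like(x), species="co2")
    return {"water": water, "ethanol": ethanol, "acetone": acetone, "co2": co2}


def components_for_matrix(matrix: MatrixComposition,
                          library: dict[str, CrossSection]) -> list[GasComponent]:
    """Translate a matrix composition into forward-model components."""
    comps = []
    if matrix.x_h2o > 0:
        comps.append(GasComponent("water", matrix.x_h2o / 100.0, library["water"]))
    if matrix.x_co2 > 0:
        comps.append(GasComponent("co2", matrix.x_co2 / 100.0, library["co2"]))
    for name, ppmv in sorted(matrix.analytes.items()):
        if ppmv > 0:
            comps.append(GasComponent(name, ppmv * 1e-6, library[name]))
    return comps


def default_scenarios(base_seed: int = 20230316,
                      noise_sigma_uv: float = NOISE_SIGMA_SPECTRUM_UV) -> list[ScenarioSpec]:
    """The default campaign plan: background, singles (7.9 ppmv ethanol,
    2.0 ppmv acetone, 0.9 %v H2O), pairwise sums, a full synthetic breath
    with 3.0 %v CO2, plus dry-CO2 / humid-CO2 / humid-analyte states."""
    def m(x_co2=0.0, x_h2o=0.0, **analytes):
        return MatrixComposition(x_co2=x_co2, x_h2o=x_h2o, analytes=analytes)

    plan = [
        ("background", m()),
        ("ethanol", m(ethanol=7.9)),
        ("acetone", m(acetone=2.0)),
        ("water", m(x_h2o=0.9)),
        ("ethanol+water", m(x_h2o=0.9, ethanol=7.9)),
        ("ethanol+acetone", m(ethanol=7.9, acetone=2.0)),
        ("breath", m(x_co2=3.0, x_h2o=0.9, ethanol=7.9, acetone=2.0)),
        ("dry-co2", m(x_co2=3.0)),
        ("humid-co2", m(x_co2=3.0, x_h2o=0.89)),
        ("humid-acetone", m(x_h2o=0.89, acetone=3.92)),
    ]
    return [ScenarioSpec(matrix=mx, label=lbl, seed=base_seed + k,
                         noise_sigma_uv=noise_sigma_uv)
            for k, (lbl, mx) in enumerate(plan)]


def make_campaign(scenarios: list[ScenarioSpec],
                  library: dict[str, CrossSection] | None = None,
                  tuning: TuningModel | None = None,
                  power: PowerModel | None = None,
                  params: ForwardModelParams | None = None,
                  acoustics: AcousticCoefficients | None = None,
                  grid: WavenumberGrid | None = None) -> list[PASpectrum]:
    """Simulate one photoacoustic spectrum per scenario.

    Each spectrum carries its matrix metadata and identical pre/post
    resonance frequencies from the acoustic model.  Dry CO2 scenarios have
    the acoustic damping (1 - X_CO2 * b_CO2) applied to the magnitudes, which
    the dry-CO2 compensation then inverts exactly.  Identical seeds give a
    bit-identical campaign.
    """
    tuning = tuning or default_tuning()
    power = power or default_power()
    params = params or default_forward_params(power)
    acoustics = acoustics or default_acoustics()
    library = library or make_component_library(grid or default_grid())
    out = []
    for sc in scenarios:
        sweep = sc.sweep if sc.sweep is not None else default_sweep()
        comps = components_for_matrix(sc.matrix, library)
        f_res = resonance_frequency(sc.matrix, acoustics)
        spec = simulate_pa_spectrum(comps, tuning, power, params, sweep,
                                    grid=grid, matrix=sc.matrix, f_res=f_res,
                                    label=sc.label)
        if sc.matrix.is_dry and sc.matrix.x_co2 > 0:
            spec = spec.with_magnitudes(
                spec.magnitudes * (1.0 - sc.matrix.x_co2 * acoustics.b_co2))
        if sc.noise_sigma_uv > 0:
            spec = add_noise(spec, sc.noise_sigma_uv, sc.seed)
        out.append(spec)
    return out


def make_timeseries(level_uv: float, sigma_uv: float, rate_hz: float,
                    duration_s: float, seed: int) -> np.ndarray:
    """Constant signal level plus white Gaussian noise, seeded."""
    n = int(round(rate_hz * duration_s))
    if n < 2:
        raise InstrumentError("duration * rate must give at least 2 samples")
    if sigma_uv < 0:
        raise InstrumentError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    return level_uv + rng.normal(0.0, sigma_uv, n)
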