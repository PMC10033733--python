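"""QCL and photoacoustic-cell models.

The distributed-feedback QCL is driven by a square-modulated current; the
high-level (on-phase) current ``I`` in mA is the sweep variable.  Increasing
``I`` red-shifts the emission (wavelength grows, wavenumber falls) and raises
the mean optical power, which follows a second-order polynomial above the
laser threshold.

The acoustic side models the first longitudinal resonance of the cell:
its frequency shifts linearly with the CO2 and H2O content of the gas matrix
(CO2 lowers it, water raises it), which is what allows the CO2 content of a
sample to be inferred from a measured resonance frequency.  In dry mixtures
CO2 additionally damps the signal (mostly through the Q-factor); that loss is
compensated multiplicatively.  The cell constant ties (gamma - 1), Q/f_res and
the resonator geometry together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import SpectralError, WavenumberGrid, nm_to_wavenumber

__all__ = [
    "InstrumentError",
    "TuningModel",
    "PowerModel",
    "MatrixComposition",
    "AcousticState",
    "AcousticCoefficients",
    "current_to_wavenumber",
    "optical_power",
    "emission_spectrum",
    "resonance_frequency",
    "infer_co2",
    "compensate_dry_co2",
    "compensate_matrix",
    "quality_factor",
    "mixture_gamma",
    "cell_constant",
    "cell_constant_relative_change",
    "default_tuning",
    "default_power",
    "default_acoustics",
    "SWEEP_MIN_MA",
    "SWEEP_MAX_MA",
    "R_GAS",
    "CP_SA",
    "CP_CO2",
    "CP_H2O",
]


class InstrumentError(ValueError):
    """Invalid instrument configuration or out-of-range input."""


SWEEP_MIN_MA = 350.0
SWEEP_MAX_MA = 495.0

R_GAS = 8.314462618  # J/(mol K)

# Molar heat capacities at constant pressure, J/(mol K), used by mixture_gamma.
# CP_SA is the effective value for dry synthetic air (80% N2 / 20% O2),
# calibrated once so that gamma(dry SA) = 1.3995, the cell's reference state;
# CO2 and H2O (vapor) use literature values near 300 K.
CP_SA = 29.125
CP_CO2 = 37.1
CP_H2O = 33.6


@dataclass(frozen=True)
class TuningModel:
    """Current -> emission-center map nu(I) = t0 + t1 I + t2 I^2 (cm^-1, mA).

    ``emission_fwhm`` is the FWHM of the (Gaussian) emission lineshape in
    cm^-1.  The map must be strictly monotone over the sweep.
    """

    t0: float
    t1: float
    t2: float = 0.0
    emission_fwhm: float = 0.005
    sweep: tuple[float, float] = (SWEEP_MIN_MA, SWEEP_MAX_MA)

    def __post_init__(self):
        if self.emission_fwhm <= 0:
            raise InstrumentError("emission FWHM must be positive")
        lo, hi = self.sweep
        if not lo < hi:
            raise InstrumentError("sweep bounds must satisfy lo < hi")
        grid = np.linspace(lo, hi, 256)
        d = self.t1 + 2.0 * self.t2 * grid
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InstrumentError("tuning must be strictly monotone over the sweep")


@dataclass(frozen=True)
class PowerModel:
    """Mean optical power P0(I) = p0 + p1 I + p2 I^2 (W) above threshold, 0 below.

    Continuity at the threshold requires p0 + p1 I_th + p2 I_th^2 = 0; the
    ``from_shape`` constructor enforces this by solving for p0.
    """

    threshold: float
    p0: float
    p1: float
    p2: float = 0.0

    def __post_init__(self):
        if self.threshold < 0:
            raise InstrumentError("threshold current must be >= 0")
        val = self.p0 + self.p1 * self.threshold + self.p2 * self.threshold**2
        if abs(val) > 1e-9:
            raise InstrumentError(
                f"power model discontinuous at threshold (P(I_th) = {val:.3g} W != 0)")

    @classmethod
    def from_shape(cls, threshold: float, p1: float, p2: float = 0.0) -> "PowerModel":
        p0 = -(p1 * threshold + p2 * threshold**2)
        return cls(threshold=threshold, p0=p0, p1=p1, p2=p2)


@dataclass(frozen=True)
class MatrixComposition:
    """Bulk matrix state: CO2 and H2O in %v, trace analytes in ppmv."""

    x_co2: float = 0.0
    x_h2o: float = 0.0
    analytes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.x_co2 < 0 or self.x_h2o < 0:
            raise InstrumentError("CO2/H2O fractions must be >= 0")
        if self.x_co2 + self.x_h2o > 100:
            raise InstrumentError("CO2 + H2O cannot exceed 100 %v")
        if any(v < 0 for v in self.analytes.values()):
            raise InstrumentError("analyte mixing ratios must be >= 0")

    @property
    def is_dry(self) -> bool:
        return self.x_h2o == 0.0


@dataclass(frozen=True)
class AcousticState:
    """One acoustic operating point of the cell."""

    f_res: float            # Hz
    q: float                # dimensionless
    gamma: float            # heat-capacity ratio
    l_r: float = 0.031      # resonator length, m
    v_r: float = 3.90e-7    # resonator volume, m^3 (4 mm bore x 31 mm)
    t_cell: float = 35.0    # deg C

    def __post_init__(self):
        if self.f_res <= 0 or self.q <= 0:
            raise InstrumentError("f_res and Q must be positive")
        if self.gamma <= 1:
            raise InstrumentError("gamma must exceed 1")
        if self.l_r <= 0 or self.v_r <= 0:
            raise InstrumentError("resonator geometry must be positive")


@dataclass(frozen=True)
class AcousticCoefficients:
    """Linear resonance-shift and damping coefficients of the breath matrix.

    f_res_bs: resonance of the analyte-free dry synthetic-air background, Hz.
    kappa_h2o: resonance rise per %v water (stored positive), Hz/%v.
    kappa_co2: resonance drop per %v CO2 (stored positive, applied with a
        minus sign), Hz/%v.
    b_co2: fractional photoacoustic signal loss per %v CO2 in *dry* mixtures.
    q_coeff_dry_co2: fractional Q loss per %v CO2 in dry mixtures.
    q_bs: Q of the background state.
    """

    f_res_bs: float = 5049.0
    kappa_h2o: float = 5.4
    kappa_co2: float = 15.0
    b_co2: float = 0.0083
    q_coeff_dry_co2: float = 0.01
    q_bs: float = 37.8
    # Q of humid mixtures does not follow a simple law; values per CO2 band
    # (nearest of 0/3/5 %v), seeded from measured humid operating points.
    q_humid_lookup: tuple[tuple[float, float], ...] = (
        (0.0, 37.95), (3.0, 38.08), (5.0, 38.15))

    def __post_init__(self):
        for name in ("kappa_h2o", "kappa_co2", "b_co2", "q_coeff_dry_co2"):
            if getattr(self, name) < 0:
                raise InstrumentError(f"{name} must be stored as a magnitude >= 0")


def default_tuning() -> TuningModel:
    """Linear tuning through (350 mA, 1e7/8263 cm^-1) and (495 mA, 1e7/8270 cm^-1)."""
    nu_lo_i = nm_to_wavenumber(8263.0)   # at 350 mA
    nu_hi_i = nm_to_wavenumber(8270.0)   # at 495 mA
    t1 = (nu_hi_i - nu_lo_i) / (SWEEP_MAX_MA - SWEEP_MIN_MA)
    t0 = nu_lo_i - t1 * SWEEP_MIN_MA
    return TuningModel(t0=t0, t1=t1, t2=0.0)


def default_power() -> PowerModel:
    """Quadratic power curve above the 250 mA threshold, calibrated so the
    sweep-mean power over 350-495 mA equals 80 mW."""
    threshold = 250.0
    p2 = 1.0e-6  # W/mA^2, gentle super-linearity
    currents = np.arange(SWEEP_MIN_MA, SWEEP_MAX_MA + 1.0)
    x = currents - threshold
    # solve mean(p1*x + p2*x^2) = 0.080 W for p1
    p1 = (0.080 - p2 * np.mean(x**2)) / np.mean(x)
    # convert from (I - threshold) form to plain polynomial coefficients
    return PowerModel(threshold=threshold,
                      p0=-(p1 * threshold) + p2 * threshold**2,
                      p1=p1 - 2.0 * p2 * threshold,
                      p2=p2)


def default_acoustics() -> AcousticCoefficients:
    return AcousticCoefficients()


def current_to_wavenumber(current: float | np.ndarray, tuning: TuningModel) -> float | np.ndarray:
    """Emission-center wavenumber (cm^-1) at high-level current I (mA)."""
    lo, hi = tuning.sweep
    arr = np.asarray(current, dtype=float)
    if np.any(arr < lo) or np.any(arr > hi):
        raise InstrumentError(f"current outside sweep range [{lo}, {hi}] mA")
    out = tuning.t0 + tuning.t1 * arr + tuning.t2 * arr**2
    return float(out) if np.ndim(current) == 0 else out


def optical_power(current: float | np.ndarray, power: PowerModel) -> float | np.ndarray:
    """Mean optical power in W; 0 at or below threshold, quadratic above."""
    arr = np.asarray(current, dtype=float)
    if np.any(arr < 0):
        raise InstrumentError("current must be >= 0")
    val = power.p0 + power.p1 * arr + power.p2 * arr**2
    out = np.where(arr <= power.threshold, 0.0, val)
    return float(out) if np.ndim(current) == 0 else out


def emission_spectrum(current: float, tuning: TuningModel,
                      grid: WavenumberGrid) -> np.ndarray:
    """Normalized laser emission lineshape sampled on ``grid``.

    Gaussian centred at ``current_to_wavenumber(current)`` with the tuning
    model's FWHM, numerically normalized to unit trapezoidal area.  In the
    limit FWHM -> grid spacing the profile degenerates to a point mass on the
    grid point nearest the center.
    """
    center = current_to_wavenumber(current, tuning)
    lo, hi = grid.span
    if not lo <= center <= hi:
        raise InstrumentError(
            f"emission center {center:.4f} cm^-1 outside grid span [{lo:.4f}, {hi:.4f}]")
    x = grid.values
    step = np.min(np.diff(x))
    if tuning.emission_fwhm <= step:
        # delta limit: all mass on the nearest grid point
        prof = np.zeros_like(x)
        i = int(np.argmin(np.abs(x - center)))
        prof[i] = 1.0
        area = np.trapezoid(prof, x)
        if area == 0.0:  # center on an endpoint of a 2-point grid edge case
            prof[i] = 2.0 / step
            return prof
        return prof / area
    sg = tuning.emission_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    prof = np.exp(-0.5 * ((x - center) / sg) ** 2)
    area = np.trapezoid(prof, x)
    return prof / area


# ---------------------------------------------------------------------------
# acoustic model


def resonance_frequency(matrix: MatrixComposition,
                        coeffs: AcousticCoefficients) -> float:
    """f_res = f_res_BS + kappa_H2O * X_H2O - kappa_CO2 * X_CO2 (trace analytes
    leave the resonance unchanged)."""
    return coeffs.f_res_bs + coeffs.kappa_h2o * matrix.x_h2o - coeffs.kappa_co2 * matrix.x_co2


def infer_co2(f_meas: float, x_h2o: float,
              coeffs: AcousticCoefficients) -> float:
    """Invert the resonance shift for the CO2 content in %v.

    X_CO2 = (f_res_BS - f_meas + X_H2O kappa_H2O) / kappa_CO2: the known
    water-induced rise is credited back before attributing the remaining
    deficit to CO2, which makes this the exact inverse of
    :func:`resonance_frequency`.  The result may be negative; callers compare
    it against the CO2 detection limit.
    """
    if f_meas <= 0:
        raise InstrumentError("measured resonance frequency must be positive")
    if x_h2o < 0:
        raise InstrumentError("water content must be >= 0")
    if coeffs.kappa_co2 == 0:
        raise InstrumentError("kappa_co2 = 0: CO2 inversion is not configured")
    return (coeffs.f_res_bs - f_meas + x_h2o * coeffs.kappa_h2o) / coeffs.kappa_co2


def compensate_dry_co2(magnitude_uv: float | np.ndarray, x_co2: float,
                       coeffs: AcousticCoefficients) -> float | np.ndarray:
    """Undo the dry-CO2 signal damping: U / (1 - X_CO2 * b_CO2).

    Only meaningful for dry mixtures; humid mixtures do not show the loss.
    """
    loss = x_co2 * coeffs.b_co2
    if loss >= 1.0:
        raise InstrumentError("X_CO2 * b_CO2 >= 1: compensation undefined")
    return np.asarray(magnitude_uv, dtype=float) / (1.0 - loss) \
        if np.ndim(magnitude_uv) else magnitude_uv / (1.0 - loss)


def compensate_matrix(magnitude_uv, matrix: MatrixComposition,
                      coeffs: AcousticCoefficients):
    """Apply the dry-CO2 compensation when the matrix is dry, else pass through
    (humidity removes the CO2 damping)."""
    if matrix.is_dry and matrix.x_co2 > 0:
        return compensate_dry_co2(magnitude_uv, matrix.x_co2, coeffs)
    return magnitude_uv


def quality_factor(matrix: MatrixComposition,
                   coeffs: AcousticCoefficients) -> float:
    """Q-factor for a matrix: linear loss with CO2 when dry, banded lookup
    when humid (no functional form is available for the humid recovery)."""
    if matrix.is_dry:
        return coeffs.q_bs * (1.0 - coeffs.q_coeff_dry_co2 * matrix.x_co2)
    bands = np.array([b for b, _ in coeffs.q_humid_lookup])
    values = np.array([v for _, v in coeffs.q_humid_lookup])
    return float(values[np.argmin(np.abs(bands - matrix.x_co2))])


def mixture_gamma(matrix: MatrixComposition) -> float:
    """Heat-capacity ratio of the matrix from mole-fraction-weighted molar Cp.

    The balance gas is dry synthetic air; CO2 and H2O displace it.  Trace
    analytes (ppmv) are ignored.  gamma = Cp / (Cp - R).
    """
    x_co2 = matrix.x_co2 / 100.0
    x_h2o = matrix.x_h2o / 100.0
    x_air = 1.0 - x_co2 - x_h2o
    cp = x_air * CP_SA + x_co2 * CP_CO2 + x_h2o * CP_H2O
    return cp / (cp - R_GAS)


def cell_constant(state: AcousticState) -> float:
    """Cell constant C = (gamma - 1) * (Q / f_res) * L_R / (2 V_R), in s/m^2
    up to the fixed microphone/electronics factor."""
    return (state.gamma - 1.0) * (state.q / state.f_res) * state.l_r / (2.0 * state.v_r)


def cell_constant_relative_change(state: AcousticState,
                                  reference: AcousticState) -> float:
    """Relative cell-constant change vs a reference state, in percent.

    Geometry (L_R, V_R) cancels, so only (gamma-1) Q / f_res matters.
    """
    def core(s: AcousticState) -> float:
        return (s.gamma - 1.0) * s.q / s.f_res

    return (core(state) / core(reference) - 1.0) * 100.0
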