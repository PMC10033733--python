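"""Forward simulation of amplitude-modulated photoacoustic spectra.

A photoacoustic spectrum is recorded by sweeping the high-level laser current
I: at each step the emission sits at a slightly different wavenumber, so the
magnitude trace U(I) samples the absorption of the gas matrix through the
instrument.  The simulated magnitude at each current is

    pa(I) = q(I) * P0(I) * <E_I, sum_c alpha_c> + b(I)

where E_I is the unit-area laser emission lineshape at current I, alpha_c the
absorption coefficient spectrum of component c, q(I) = d0 + d1*I an
amplification factor lumping the cell constant, microphone and lock-in gains,
P0(I) the mean optical power, and b(I) = c0 + c1*I + c2*I^2 the
analyte-independent background.  The "convolution" with the laser line is
evaluated as a per-current inner product (trapezoidal quadrature) because only
the swept centers are ever needed.  The relaxation efficiency is assumed
constant over the narrow emission range and is folded into q.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .instrument import (
    InstrumentError,
    MatrixComposition,
    PowerModel,
    TuningModel,
    current_to_wavenumber,
    optical_power,
)
from .spectral import GasComponent, SpectralError, WavenumberGrid, number_density, resample

__all__ = [
    "ForwardModelParams",
    "PASpectrum",
    "background_signal",
    "amplification",
    "simulate_pa_spectrum",
    "add_noise",
    "component_responses",
    "sweep_grid",
    "read_campaign_file",
    "write_campaign_file",
    "RESONANCE_DRIFT_TOL_HZ",
    "CELL_TEMPERATURE_K",
]

RESONANCE_DRIFT_TOL_HZ = 1.0
CELL_TEMPERATURE_K = 308.15   # 35 degC measuring cell
CELL_PRESSURE_PA = 101325.0   # ambient operation


@dataclass(frozen=True)
class ForwardModelParams:
    """Free parameters of the forward model.

    c0/c1/c2: background polynomial in I (uV, uV/mA, uV/mA^2).
    d0/d1: amplification q(I) = d0 + d1*I in uV per (W cm^-1).
    eps_relax: relaxation efficiency, constant by assumption and degenerate
        with the amplification; kept explicit for bookkeeping only.
    """

    c0: float = 36.0
    c1: float = 0.0
    c2: float = 0.0
    d0: float = 0.0
    d1: float = 0.0
    eps_relax: float = 1.0


@dataclass(frozen=True)
class PASpectrum:
    """Photoacoustic magnitude (uV) versus high-level current (mA).

    Carries the gas-matrix metadata and the resonance frequencies measured
    (or stamped, for simulations) before and after the sweep; a drift above
    ``RESONANCE_DRIFT_TOL_HZ`` means the cell detuned during recording.
    """

    currents: np.ndarray
    magnitudes: np.ndarray
    matrix: MatrixComposition = field(default_factory=MatrixComposition)
    f_res_pre: float = float("nan")
    f_res_post: float = float("nan")
    label: str = ""
    scaled: bool = False
    reference_current: float | None = None
    seed: int | None = None

    def __post_init__(self):
        c = np.asarray(self.currents, dtype=float)
        m = np.asarray(self.magnitudes, dtype=float)
        if c.shape != m.shape or c.ndim != 1 or c.size == 0:
            raise InstrumentError("currents and magnitudes must be equal-length 1-D arrays")
        if not np.all(np.isfinite(m)):
            raise InstrumentError("magnitudes must be finite")
        object.__setattr__(self, "currents", c)
        object.__setattr__(self, "magnitudes", m)

    @property
    def resonance_drift_hz(self) -> float:
        return abs(self.f_res_pre - self.f_res_post)

    def resonance_ok(self, tol_hz: float = RESONANCE_DRIFT_TOL_HZ) -> bool:
        if np.isnan(self.f_res_pre) or np.isnan(self.f_res_post):
            return True  # no resonance bookkeeping recorded
        return self.resonance_drift_hz <= tol_hz

    def with_magnitudes(self, magnitudes: np.ndarray, **meta) -> "PASpectrum":
        return replace(self, magnitudes=np.asarray(magnitudes, dtype=float), **meta)


def background_signal(current: float | np.ndarray,
                      params: ForwardModelParams) -> float | np.ndarray:
    """Analyte-independent background b(I) = c0 + c1*I + c2*I^2 in uV."""
    arr = np.asarray(current, dtype=float)
    out = params.c0 + params.c1 * arr + params.c2 * arr**2
    return float(out) if np.ndim(current) == 0 else out


def amplification(current: float | np.ndarray,
                  params: ForwardModelParams) -> float | np.ndarray:
    """q(I) = eps_relax * (d0 + d1*I) in uV per (W cm^-1)."""
    arr = np.asarray(current, dtype=float)
    out = params.eps_relax * (params.d0 + params.d1 * arr)
    return float(out) if np.ndim(current) == 0 else out


def sweep_grid(tuning: TuningModel, currents: np.ndarray,
               step: float = 0.002, margin: float = 0.05) -> WavenumberGrid:
    """Uniform wavenumber grid covering the swept emission centers plus a
    margin for the lineshape tails."""
    centers = current_to_wavenumber(np.asarray(currents, dtype=float), tuning)
    lo = float(np.min(centers)) - margin
    hi = float(np.max(centers)) + margin
    return WavenumberGrid.uniform(lo, hi, step)


def _emission_matrix(currents: np.ndarray, tuning: TuningModel,
                     grid: WavenumberGrid) -> np.ndarray:
    """Row-stacked unit-area emission lineshapes, one row per current."""
    x = grid.values
    centers = current_to_wavenumber(currents, tuning)
    lo, hi = grid.span
    if np.min(centers) < lo or np.max(centers) > hi:
        raise InstrumentError("spectral grid does not cover the swept emission range")
    step = float(np.min(np.diff(x)))
    w = _trapezoid_weights(x)
    if tuning.emission_fwhm <= step:
        mat = np.zeros((centers.size, x.size))
        idx = np.argmin(np.abs(x[None, :] - centers[:, None]), axis=1)
        mat[np.arange(centers.size), idx] = 1.0
    else:
        sg = tuning.emission_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        mat = np.exp(-0.5 * ((x[None, :] - centers[:, None]) / sg) ** 2)
    areas = mat @ w
    return mat / areas[:, None]


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += dx / 2.0
    w[1:] += dx / 2.0
    return w


def component_responses(components: list[GasComponent], tuning: TuningModel,
                        currents: np.ndarray,
                        grid: WavenumberGrid | None = None,
                        temperature: float = CELL_TEMPERATURE_K,
                        pressure: float = CELL_PRESSURE_PA) -> np.ndarray:
    """Per-component inner products <E_I, alpha_c> over the sweep.

    Returns an array of shape (n_components, n_currents) in cm^-1.  This is
    the expensive part of the forward model; model fitting reuses it when the
    tuning is held fixed.
    """
    currents = np.asarray(currents, dtype=float)
    if grid is None:
        grid = sweep_grid(tuning, currents)
    emat = _emission_matrix(currents, tuning, grid)
    w = _trapezoid_weights(grid.values)
    rows = []
    for comp in components:
        xs = resample(comp.cross_section, grid)
        alpha = xs.sigma * number_density(comp.mole_fraction, temperature, pressure)
        rows.append(emat @ (w * alpha))
    return np.asarray(rows) if rows else np.zeros((0, currents.size))


def simulate_pa_spectrum(components: list[GasComponent], tuning: TuningModel,
                         power: PowerModel, params: ForwardModelParams,
                         currents: np.ndarray,
                         grid: WavenumberGrid | None = None,
                         matrix: MatrixComposition | None = None,
                         f_res: float = float("nan"),
                         label: str = "",
                         temperature: float = CELL_TEMPERATURE_K,
                         pressure: float = CELL_PRESSURE_PA) -> PASpectrum:
    """Simulate one photoacoustic spectrum over the current sweep.

    The magnitude is linear in each component's mixing ratio and additive
    across components (the experimental sum-spectrum property).  Simulated
    spectra stamp identical pre/post resonance frequencies.
    """
    currents = np.asarray(currents, dtype=float)
    resp = component_responses(components, tuning, currents, grid,
                               temperature, pressure)
    alpha_eff = resp.sum(axis=0) if resp.size else np.zeros(currents.size)
    mags = (amplification(currents, params) * optical_power(currents, power)
            * alpha_eff + background_signal(currents, params))
    return PASpectrum(currents=currents, magnitudes=mags,
                      matrix=matrix or MatrixComposition(),
                      f_res_pre=f_res, f_res_post=f_res, label=label)


def add_noise(spectrum: PASpectrum, sigma: float, seed: int) -> PASpectrum:
    """Additive i.i.d. Gaussian magnitude noise; identical seed, identical output."""
    if sigma < 0:
        raise InstrumentError("noise sigma must be >= 0")
    if sigma == 0:
        return spectrum
    rng = np.random.default_rng(seed)
    noisy = spectrum.magnitudes + rng.normal(0.0, sigma, spectrum.magnitudes.size)
    return spectrum.with_magnitudes(noisy, seed=seed)


# ---------------------------------------------------------------------------
# campaign file I/O
#
# Columnar text "current_mA magnitude_uV" preceded by a '#'-prefixed header
# block carrying the matrix composition, resonance bookkeeping, label and
# (for scaled spectra) the reference current.  Floats use repr precision so
# write -> read round-trips exactly.

_CAMPAIGN_MAGIC = "# qclpas-campaign v1"


def write_campaign_file(spectrum: PASpectrum, target) -> None:
    buf = io.StringIO()
    buf.write(_CAMPAIGN_MAGIC + "\n")
    buf.write(f"# label: {spectrum.label}\n")
    buf.write(f"# x_co2_percent: {float(spectrum.matrix.x_co2)!r}\n")
    buf.write(f"# x_h2o_percent: {float(spectrum.matrix.x_h2o)!r}\n")
    for name, ppmv in sorted(spectrum.matrix.analytes.items()):
        buf.write(f"# analyte: {name} {float(ppmv)!r}\n")
    buf.write(f"# f_res_pre_hz: {float(spectrum.f_res_pre)!r}\n")
    buf.write(f"# f_res_post_hz: {float(spectrum.f_res_post)!r}\n")
    buf.write(f"# scaled: {str(spectrum.scaled).lower()}\n")
    if spectrum.reference_current is not None:
        buf.write(f"# reference_current_ma: {float(spectrum.reference_current)!r}\n")
    if spectrum.seed is not None:
        buf.write(f"# seed: {spectrum.seed}\n")
    buf.write("# current_mA magnitude_uV\n")
    for c, m in zip(spectrum.currents, spectrum.magnitudes):
        buf.write(f"{float(c)!r} {float(m)!r}\n")
    if hasattr(target, "write"):
        target.write(buf.getvalue())
    else:
        with open(target, "w") as fh:
            fh.write(buf.getvalue())


def read_campaign_file(source) -> PASpectrum:
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = text.splitlines()
    if not lines or lines[0].strip() != _CAMPAIGN_MAGIC:
        raise InstrumentError("not a qclpas campaign file (missing magic header)")
    meta: dict[str, str] = {}
    analytes: dict[str, float] = {}
    rows: list[tuple[float, float]] = []
    for i, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*([\w]+):\s*(.*)$", line)
            if m and m.group(1) == "analyte":
                name, val = m.group(2).rsplit(" ", 1)
                analytes[name.strip()] = float(val)
            elif m:
                meta[m.group(1)] = m.group(2).strip()
            continue
        parts = line.split()
        if len(parts) != 2:
            raise InstrumentError(f"campaign file: expected 2 columns on line {i}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise InstrumentError(f"campaign file: non-numeric value on line {i}") from exc
    if not rows:
        raise InstrumentError("campaign file contains no data rows")
    arr = np.asarray(rows)
    matrix = MatrixComposition(x_co2=float(meta.get("x_co2_percent", 0.0)),
                               x_h2o=float(meta.get("x_h2o_percent", 0.0)),
                               analytes=analytes)
    ref = meta.get("reference_current_ma")
    seed = meta.get("seed")
    return PASpectrum(currents=arr[:, 0], magnitudes=arr[:, 1], matrix=matrix,
                      f_res_pre=float(meta.get("f_res_pre_hz", "nan")),
                      f_res_post=float(meta.get("f_res_post_hz", "nan")),
                      label=meta.get("label", ""),
                      scaled=meta.get("scaled", "false") == "true",
                      reference_current=float(ref) if ref is not None else None,
                      seed=int(seed) if seed is not None else None)
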