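"""Scaling and averaging of recorded photoacoustic spectra.

The raw magnitude trace follows the optical-power curve of the laser; because
the analyte-free background is itself proportional to optical power, dividing
a measured spectrum by the background shape (normalized to 1 at the maximum
sweep current) removes the power envelope exactly and yields a spectrum whose
shape is that of the underlying absorption.  Scaling amplifies noise where
the background is small (low currents), which is reported, not suppressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .forward import PASpectrum
from .instrument import InstrumentError

__all__ = [
    "ScalingCurve",
    "scaling_curve",
    "scale_by_background",
    "average_block",
    "enbw",
    "MIN_BSCALE_WARN",
]

MIN_BSCALE_WARN = 0.05

# ENBW of the lock-in's cascaded-RC low-pass, per filter roll-off,
# as a multiple of 1/tau.
_ENBW_FACTORS = {6: 1.0 / 4.0, 12: 1.0 / 8.0, 18: 3.0 / 32.0, 24: 5.0 / 64.0}


@dataclass(frozen=True)
class ScalingCurve:
    """Background-shape scaling coefficients b_scale(I) in (0, 1]."""

    currents: np.ndarray
    b_scale: np.ndarray
    reference_current: float

    def __post_init__(self):
        c = np.asarray(self.currents, dtype=float)
        b = np.asarray(self.b_scale, dtype=float)
        if c.shape != b.shape:
            raise InstrumentError("currents and b_scale lengths differ")
        if np.any(b <= 0) or np.any(b > 1.0 + 1e-12):
            raise InstrumentError("b_scale values must lie in (0, 1]")
        object.__setattr__(self, "currents", c)
        object.__setattr__(self, "b_scale", b)


def scaling_curve(background: PASpectrum, smooth: bool = False) -> ScalingCurve:
    """b_scale(I) = U_BS(I) / U_BS(I_max): the background trace normalized to
    1 at the maximum sweep current.

    With ``smooth=True`` a quadratic fit of the background replaces the raw
    samples before normalization (optional noise suppression).
    """
    u = background.magnitudes
    if np.any(u <= 0):
        raise InstrumentError("background magnitudes must be strictly positive")
    if smooth:
        coef = np.polynomial.polynomial.polyfit(background.currents, u, 2)
        u = np.polynomial.polynomial.polyval(background.currents, coef)
        if np.any(u <= 0):
            raise InstrumentError("smoothed background non-positive over the sweep")
    i_ref = int(np.argmax(background.currents))
    b = u / u[i_ref]
    b = np.minimum(b, 1.0)  # guard rounding at the reference point
    b[i_ref] = 1.0
    return ScalingCurve(currents=background.currents.copy(), b_scale=b,
                        reference_current=float(background.currents[i_ref]))


def scale_by_background(measured: PASpectrum, curve: ScalingCurve) -> PASpectrum:
    """Divide the measured magnitudes by b_scale(I), decoupling the spectrum
    from the optical-power envelope."""
    if measured.currents.shape != curve.currents.shape or \
            not np.allclose(measured.currents, curve.currents):
        raise InstrumentError("measured spectrum and scaling curve use different current axes")
    small = curve.b_scale < MIN_BSCALE_WARN
    if np.any(small):
        warnings.warn(
            f"{int(np.count_nonzero(small))} sweep points have b_scale < "
            f"{MIN_BSCALE_WARN}; scaled values there are noise-amplified",
            stacklevel=2)
    scaled = measured.magnitudes / curve.b_scale
    return replace(measured, magnitudes=scaled, scaled=True,
                   reference_current=curve.reference_current)


def average_block(samples: np.ndarray, rate: float, duration: float) -> tuple[float, float]:
    """Mean and sample standard deviation of the first ``rate * duration``
    lock-in samples (the per-point averaging applied to recorded spectra)."""
    if rate <= 0 or duration <= 0:
        raise InstrumentError("rate and duration must be positive")
    n = int(round(rate * duration))
    samples = np.asarray(samples, dtype=float)
    if n < 1 or samples.size < n:
        raise InstrumentError(
            f"need {n} samples ({duration} s at {rate} Hz), got {samples.size}")
    block = samples[:n]
    std = float(np.std(block, ddof=1)) if n > 1 else 0.0
    return float(np.mean(block)), std


def enbw(tau: float, rolloff_db_per_octave: int = 18) -> float:
    """Equivalent noise bandwidth (Hz) of a cascaded-RC lock-in low-pass with
    time constant ``tau`` (s): 1/(4 tau), 1/(8 tau), 3/(32 tau), 5/(64 tau)
    for 6/12/18/24 dB per octave."""
    if tau <= 0:
        raise InstrumentError("time constant must be positive")
    try:
        factor = _ENBW_FACTORS[int(rolloff_db_per_octave)]
    except (KeyError, ValueError):
        raise InstrumentError(
            f"unsupported roll-off {rolloff_db_per_octave}; choose one of 6/12/18/24 dB/oct"
        ) from None
    return factor / tau
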