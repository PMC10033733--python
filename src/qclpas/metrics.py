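"""Spectral-similarity, noise and sensor-performance metrics.

Spectra are compared as plain intensity vectors (the wavenumber axis is
discarded): the Pearson coefficient measures their linear relationship and
the Spearman coefficient the monotone (rank) relationship, which makes the
pair robust against background offsets that dominate RMSE-type measures.

Sensor performance follows the usual photoacoustic conventions: a linear
calibration (signal vs concentration), a 3-sigma noise level from a blank
series, the detection limit LoD = noise / sensitivity, the non-overlapping
Allan deviation as a function of averaging time (slope -1/2 on log-log axes
for white noise), and the normalized noise-equivalent absorption coefficient

    NNEA = LoD * N_A * sigma * P0 / (SNR * sqrt(ENBW) * V_mol)

in W cm^-1 Hz^-1/2, which normalizes the detection limit by optical power and
detection bandwidth for cross-system comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MetricsError",
    "SimilarityScore",
    "AllanCurve",
    "CalibrationResult",
    "pearson",
    "spearman",
    "similarity",
    "error_metrics",
    "allan_deviation",
    "calibrate",
    "nnea",
    "calibration_report",
    "AVOGADRO",
]

AVOGADRO = 6.02214076e23   # 1/mol
R_GAS = 8.314462618        # J/(mol K)


class MetricsError(ValueError):
    """Invalid metric input."""


@dataclass(frozen=True)
class SimilarityScore:
    pcc: float
    pcc_p: float
    scc: float
    scc_p: float
    n: int
    scc_used_midranks: bool = False

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.pcc <= 1.0 + 1e-12):
            raise MetricsError("PCC out of [-1, 1]")
        if not (-1.0 - 1e-12 <= self.scc <= 1.0 + 1e-12):
            raise MetricsError("SCC out of [-1, 1]")


@dataclass(frozen=True)
class AllanCurve:
    taus: np.ndarray        # averaging times, s
    deviations: np.ndarray  # same units as the input series
    rate: float             # sampling rate, Hz

    def loglog_slope(self) -> float:
        """Least-squares slope of log10(deviation) vs log10(tau); -1/2 for
        white noise."""
        mask = self.deviations > 0
        if np.count_nonzero(mask) < 2:
            raise MetricsError("need >= 2 positive deviations for a slope")
        return float(np.polyfit(np.log10(self.taus[mask]),
                                np.log10(self.deviations[mask]), 1)[0])


@dataclass(frozen=True)
class CalibrationResult:
    """Linear calibration summary for one analyte / time-constant pair."""

    sensitivity_uv_per_ppmv: float
    intercept_uv: float
    r_squared: float
    noise_3sigma_nv: float
    lod_3sigma_ppbv: float
    tau_s: float = float("nan")
    analyte: str = ""
    nnea_w_cm_hz: float = float("nan")


def _check_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MetricsError("inputs must be equal-length 1-D vectors")
    if x.size < min_n:
        raise MetricsError(f"need at least {min_n} points")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient with two-sided p-value (t, n-2 dof)."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MetricsError("correlation undefined for a constant vector")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def spearman(x, y) -> tuple[float, float, bool]:
    """Spearman rank correlation with p-value.

    Without ties this equals 1 - 6 sum(d_i^2) / (n (n^2 - 1)) exactly; with
    ties the Pearson coefficient of mid-ranks is used (the standard
    generalization).  Returns (scc, p, used_midranks).
    """
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MetricsError("correlation undefined for a constant vector")
    ties = (np.unique(x).size < x.size) or (np.unique(y).size < y.size)
    r = stats.spearmanr(x, y)
    return float(r.statistic), float(r.pvalue), ties


def similarity(x, y) -> SimilarityScore:
    """PCC and SCC of two intensity vectors in one record."""
    pcc, pcc_p = pearson(x, y)
    scc, scc_p, ties = spearman(x, y)
    return SimilarityScore(pcc=pcc, pcc_p=pcc_p, scc=scc, scc_p=scc_p,
                           n=int(np.asarray(x).size), scc_used_midranks=ties)


def error_metrics(truth, estimate) -> dict[str, float]:
    """MAE, RMSE and MAPE (percent, relative to ``truth``)."""
    a, b = _check_pair(truth, estimate, min_n=1)
    diff = b - a
    out = {"mae": float(np.mean(np.abs(diff))),
           "rmse": float(np.sqrt(np.mean(diff**2)))}
    if np.any(a == 0):
        raise MetricsError("MAPE undefined: reference contains zeros")
    out["mape_percent"] = float(np.mean(np.abs(diff / a)) * 100.0)
    return out


def allan_deviation(series, rate: float, taus) -> AllanCurve:
    """Non-overlapping Allan deviation of a magnitude time series.

    Each requested averaging time must be an integer multiple of the sample
    interval; taus with fewer than two complete bins are dropped with a
    warning.
    """
    series = np.asarray(series, dtype=float)
    if rate <= 0:
        raise MetricsError("sampling rate must be positive")
    kept_taus, devs = [], []
    for tau in np.asarray(taus, dtype=float):
        m = int(round(tau * rate))            # samples per bin
        if m < 1 or abs(m - tau * rate) > 1e-9:
            raise MetricsError(f"tau {tau} s is not a multiple of the sample interval")
        k = series.size // m                  # complete bins
        if k < 2:
            warnings.warn(f"tau {tau} s dropped: needs >= 2 bins of {m} samples",
                          stacklevel=2)
            continue
        means = series[:k * m].reshape(k, m).mean(axis=1)
        avar = 0.5 * np.mean(np.diff(means) ** 2)
        kept_taus.append(tau)
        devs.append(np.sqrt(avar))
    if not kept_taus:
        raise MetricsError("no tau had enough data")
    return AllanCurve(taus=np.asarray(kept_taus), deviations=np.asarray(devs),
                      rate=rate)


def calibrate(concentrations_ppmv, signals_uv, blank_noise_uv,
              tau_s: float = float("nan"), analyte: str = "",
              sigma_multiplier: float = 3.0) -> CalibrationResult:
    """Ordinary-least-squares calibration line plus blank-based detection limit.

    sensitivity = slope of signal vs concentration (uV/ppmv); the noise level
    is ``sigma_multiplier`` (default 3, the 3-sigma convention) times the
    standard deviation of the blank series; LoD = noise / sensitivity.
    """
    c = np.asarray(concentrations_ppmv, dtype=float)
    u = np.asarray(signals_uv, dtype=float)
    if c.shape != u.shape or c.size < 3:
        raise MetricsError("need >= 3 matched concentration/signal points")
    blank = np.asarray(blank_noise_uv, dtype=float)
    if blank.size < 2:
        raise MetricsError("need a blank series of >= 2 samples")
    res = stats.linregress(c, u)
    if res.slope <= 0:
        raise MetricsError("calibration failure: non-positive sensitivity")
    noise_uv = sigma_multiplier * float(np.std(blank, ddof=1))
    lod_ppmv = noise_uv / res.slope
    return CalibrationResult(
        sensitivity_uv_per_ppmv=float(res.slope),
        intercept_uv=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        noise_3sigma_nv=noise_uv * 1e3,
        lod_3sigma_ppbv=lod_ppmv * 1e3,
        tau_s=tau_s, analyte=analyte)


def nnea(lod_ppbv: float, sigma_xsec_cm2: float, p0_w: float,
         snr: float, enbw_hz: float,
         temperature_k: float = 308.15, pressure_pa: float = 101325.0) -> float:
    """Normalized noise-equivalent absorption coefficient in W cm^-1 Hz^-1/2.

    The LoD is converted to a number density through N_A / V_mol at the given
    conditions (ideal gas), multiplied by the analyte cross-section at the
    probe wavenumber and by the optical power, and normalized by the SNR
    convention of the LoD and the square root of the detection bandwidth.
    """
    for name, v in (("lod", lod_ppbv), ("sigma", sigma_xsec_cm2), ("P0", p0_w),
                    ("SNR", snr), ("ENBW", enbw_hz),
                    ("temperature", temperature_k), ("pressure", pressure_pa)):
        if v < 0 or (name not in ("lod",) and v == 0):
            raise MetricsError(f"{name} must be positive")
    v_mol_cm3 = R_GAS * temperature_k / pressure_pa * 1e6  # m^3 -> cm^3
    n_lod = lod_ppbv * 1e-9 * AVOGADRO / v_mol_cm3          # molecules / cm^3
    return n_lod * sigma_xsec_cm2 * p0_w / (snr * np.sqrt(enbw_hz))


def calibration_report(results: list[CalibrationResult]) -> str:
    """Delimited summary table (one row per analyte / time-constant pair)."""
    header = ("analyte\ttau_s\tsensitivity_uV_per_ppmv\tr_squared\t"
              "noise_3sigma_nV\tlod_3sigma_ppbv\tnnea_W_cm-1_Hz-0.5")
    rows = [header]
    for r in results:
        rows.append(f"{r.analyte}\t{r.tau_s:g}\t{r.sensitivity_uv_per_ppmv:.6g}\t"
                    f"{r.r_squared:.6f}\t{r.noise_3sigma_nv:.4g}\t"
                    f"{r.lod_3sigma_ppbv:.4g}\t{r.nnea_w_cm_hz:.4g}")
    return "\n".join(rows) + "\n"
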