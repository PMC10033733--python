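"""Multi-component concentration estimation from scaled spectra.

Because photoacoustic spectra of mixtures are additive in their components
above a shared background, a mixture spectrum can be unmixed by ordinary
least squares against per-unit-concentration reference spectra of the single
components.  A two-point version of this (one current on a water peak, one
off it) suffices to jointly recover the water and acetone content of a
humidified sample; the same machinery generalizes to any current selection
and component set.  Near-collinear reference shapes (e.g. the flat acetone
and ethanol continua) are surfaced through the design-matrix condition
number rather than silently pseudo-inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .forward import PASpectrum
from .instrument import InstrumentError

__all__ = [
    "UnmixError",
    "DesignMatrix",
    "UnmixResult",
    "select_currents",
    "build_design_matrix",
    "unmix",
    "COND_LIMIT",
]

COND_LIMIT = 1e8


class UnmixError(ValueError):
    """Invalid unmixing problem."""


@dataclass(frozen=True)
class DesignMatrix:
    """Reference responses per unit concentration at the selected currents.

    ``matrix`` has one row per current and one column per component; the
    background enters as a known per-current level (default) or as an extra
    free column when ``background_free``.
    """

    currents: np.ndarray
    components: tuple[str, ...]
    matrix: np.ndarray
    background_level: np.ndarray
    background_free: bool = False

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        c = np.asarray(self.currents, dtype=float)
        b = np.asarray(self.background_level, dtype=float)
        if m.shape != (c.size, len(self.components)):
            raise UnmixError("design matrix shape mismatch")
        if b.shape != c.shape:
            raise UnmixError("background level must match the current axis")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "currents", c)
        object.__setattr__(self, "background_level", b)

    def regression_matrix(self) -> np.ndarray:
        """The matrix actually regressed on: component columns, plus the
        background column when it is a free parameter."""
        if self.background_free:
            return np.column_stack([self.matrix, self.background_level])
        return self.matrix

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.regression_matrix()))


@dataclass(frozen=True)
class UnmixResult:
    concentrations: dict[str, float]
    residual_norm_uv: float
    condition_number: float
    stderr: dict[str, float] | None = None
    background_estimate: float | None = None
    mape_vs_truth_percent: float | None = None


def select_currents(reference: PASpectrum, strategy: str = "peak") -> np.ndarray:
    """Pick regression currents from a reference spectrum.

    "peak" returns the current of the magnitude maximum, "peak-and-trough"
    adds the minimum, "all" every current of the sweep.
    """
    if reference.currents.size == 0:
        raise UnmixError("empty reference spectrum")
    if strategy == "peak":
        return np.asarray([reference.currents[int(np.argmax(reference.magnitudes))]])
    if strategy == "peak-and-trough":
        hi = reference.currents[int(np.argmax(reference.magnitudes))]
        lo = reference.currents[int(np.argmin(reference.magnitudes))]
        return np.unique([hi, lo])
    if strategy == "all":
        return reference.currents.copy()
    raise UnmixError(f"unknown selection strategy {strategy!r}")


def _values_at(spectrum: PASpectrum, currents: np.ndarray) -> np.ndarray:
    """Exact lookup of magnitudes at the selected currents (no interpolation)."""
    out = np.empty(currents.size)
    for k, c in enumerate(np.asarray(currents, dtype=float)):
        idx = np.nonzero(np.isclose(spectrum.currents, c, rtol=0, atol=1e-9))[0]
        if idx.size != 1:
            raise UnmixError(f"reference does not cover current {c} mA")
        out[k] = spectrum.magnitudes[idx[0]]
    return out


def build_design_matrix(references: dict[str, tuple[PASpectrum, float]],
                        currents: np.ndarray,
                        background: PASpectrum | float,
                        background_free: bool = False) -> DesignMatrix:
    """Assemble the regression design from single-component references.

    ``references`` maps a component name to its (scaled) reference spectrum
    and its known concentration; each entry becomes a column of the scaled
    magnitude above background per unit concentration.  ``background`` is the
    (scaled) background spectrum or a constant level in uV.
    """
    currents = np.atleast_1d(np.asarray(currents, dtype=float))
    if currents.size == 0:
        raise UnmixError("no currents selected")
    if isinstance(background, PASpectrum):
        bg = _values_at(background, currents)
    else:
        bg = np.full(currents.size, float(background))
    cols, names = [], []
    for name, (spec, conc) in references.items():
        if conc <= 0:
            raise UnmixError(f"reference concentration for {name!r} must be > 0")
        cols.append((_values_at(spec, currents) - bg) / conc)
        names.append(name)
    design = DesignMatrix(currents=currents, components=tuple(names),
                          matrix=np.column_stack(cols),
                          background_level=bg, background_free=background_free)
    n_params = len(names) + (1 if background_free else 0)
    if currents.size < n_params:
        raise UnmixError(f"{currents.size} currents cannot determine {n_params} parameters")
    cond = design.condition_number()
    if cond > COND_LIMIT:
        raise UnmixError(
            f"ill-conditioned design (cond = {cond:.3g} > {COND_LIMIT:.0e}); "
            f"collinear columns among {_collinear_pair(design)}")
    return design


def _collinear_pair(design: DesignMatrix) -> tuple[str, ...]:
    m = design.regression_matrix()
    names = list(design.components) + (["background"] if design.background_free else [])
    norms = np.linalg.norm(m, axis=0)
    norms[norms == 0] = 1.0
    g = (m / norms).T @ (m / norms)
    np.fill_diagonal(g, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(g)), g.shape)
    return (names[i], names[j]) if len(names) > 1 else tuple(names)


def unmix(measured: PASpectrum, design: DesignMatrix,
          truth: dict[str, float] | None = None,
          nonnegative: bool = False,
          noise_sigma_uv: float | None = None) -> UnmixResult:
    """Least-squares concentration estimate of a measured (scaled) spectrum.

    Noiseless mixtures are recovered exactly.  With ``truth`` supplied the
    mean absolute percentage error across components is reported.  Standard
    errors use ``noise_sigma_uv`` when given, else the residual variance
    (requires more currents than parameters).
    """
    cond = design.condition_number()
    if cond > COND_LIMIT:
        raise UnmixError(f"ill-conditioned design (cond = {cond:.3g})")
    y = _values_at(measured, design.currents)
    x_mat = design.regression_matrix()
    rhs = y if design.background_free else y - design.background_level
    if nonnegative:
        theta, _ = nnls(x_mat, rhs)
    else:
        theta, *_ = np.linalg.lstsq(x_mat, rhs, rcond=None)
    resid = rhs - x_mat @ theta
    conc = {name: float(theta[k]) for k, name in enumerate(design.components)}
    bg_est = float(theta[-1] * 1.0) if design.background_free else None

    stderr = None
    dof = y.size - x_mat.shape[1]
    sigma2 = None
    if noise_sigma_uv is not None:
        sigma2 = noise_sigma_uv**2
    elif dof > 0:
        sigma2 = float(resid @ resid) / dof
    if sigma2 is not None:
        cov = sigma2 * np.linalg.inv(x_mat.T @ x_mat)
        se = np.sqrt(np.diag(cov))
        stderr = {name: float(se[k]) for k, name in enumerate(design.components)}

    mape = None
    if truth:
        errs = [abs(conc[n] - t) / abs(t) for n, t in truth.items() if t != 0]
        if errs:
            mape = float(np.mean(errs) * 100.0)
    return UnmixResult(concentrations=conc,
                       residual_norm_uv=float(np.linalg.norm(resid)),
                       condition_number=cond, stderr=stderr,
                       background_estimate=bg_est,
                       mape_vs_truth_percent=mape)
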