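"""Forward-model parameter estimation, error attribution and base-spectrum
correction.

The forward model has three parameter groups, each with a constant and a
linear-in-current term: the QCL transfer function (emission center vs
current, here t0/t1), the background polynomial (c0/c1) and the
amplification factor (d0/d1).  Fitting minimizes the summed squared
magnitude residuals over a campaign of spectra with known compositions;
parameter uncertainty comes from the residual-variance-scaled inverse
Gauss-Newton normal matrix and is cross-checked with an affine-invariant
ensemble sampler of the Gaussian likelihood under flat priors (for a model
linear in the checked parameters the two must agree).

Base-spectrum correction handles systematic reference-spectrum errors: a
global multiplicative factor (e.g. a gas-tank concentration error) and a
smooth local multiplicative curve over a wavenumber window (reference
spectra whose shape disagrees with the instrument in a limited region).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

import emcee

from .forward import (
    CELL_PRESSURE_PA,
    CELL_TEMPERATURE_K,
    ForwardModelParams,
    PASpectrum,
    background_signal,
    component_responses,
)
from .instrument import InstrumentError, PowerModel, TuningModel, optical_power
from .spectral import CrossSection, WavenumberGrid
from .synthetic import components_for_matrix

__all__ = [
    "FittingError",
    "IdentifiabilityError",
    "FitResult",
    "BaseSpectrumCorrection",
    "CampaignModel",
    "fit_forward_model",
    "parameter_relative_variance",
    "ensemble_check",
    "EnsembleSummary",
    "correct_base_spectrum",
    "fit_base_correction",
    "residual_spectrum",
    "CANONICAL_FREE_PARAMS",
]

# the canonical free set: constant+linear terms of background, amplification
# and transfer function (quadratic terms exist but stay fixed by default)
CANONICAL_FREE_PARAMS = ("c0", "c1", "d0", "d1", "t0", "t1")
_ALL_PARAMS = ("c0", "c1", "c2", "d0", "d1", "t0", "t1", "t2")


class FittingError(RuntimeError):
    """Fit failure (non-convergence, invalid setup)."""


class IdentifiabilityError(FittingError):
    """Singular normal matrix; carries the unidentifiable parameter names."""


@dataclass(frozen=True)
class FitResult:
    """Converged parameters with covariance and per-spectrum residuals."""

    parameters: dict[str, float]
    free_names: tuple[str, ...]
    covariance: np.ndarray
    residuals: list[np.ndarray]
    converged: bool
    cost: float
    noise_sigma_uv: float

    def params_object(self, tuning: TuningModel) -> tuple[ForwardModelParams, TuningModel]:
        p = self.parameters
        fwd = ForwardModelParams(c0=p["c0"], c1=p["c1"], c2=p["c2"],
                                 d0=p["d0"], d1=p["d1"])
        tun = TuningModel(t0=p["t0"], t1=p["t1"], t2=p["t2"],
                          emission_fwhm=tuning.emission_fwhm, sweep=tuning.sweep)
        return fwd, tun

    def standard_errors(self) -> dict[str, float]:
        se = np.sqrt(np.diag(self.covariance))
        return {n: float(se[i]) for i, n in enumerate(self.free_names)}


class CampaignModel:
    """Predicts a campaign of spectra from a forward-model parameter vector.

    When the transfer-function parameters are fixed, the expensive
    emission-times-absorption inner products are computed once and every
    prediction is a cheap linear-algebra evaluation; with free tuning the
    responses are recomputed per evaluation (with a one-deep cache keyed on
    the tuning values, which also serves finite-difference Jacobians).
    """

    def __init__(self, spectra: list[PASpectrum], library: dict[str, CrossSection],
                 tuning: TuningModel, power: PowerModel,
                 init: ForwardModelParams,
                 free: tuple[str, ...] = CANONICAL_FREE_PARAMS,
                 grid: WavenumberGrid | None = None,
                 temperature: float = CELL_TEMPERATURE_K,
                 pressure: float = CELL_PRESSURE_PA):
        unknown = set(free) - set(_ALL_PARAMS)
        if unknown:
            raise FittingError(f"unknown free parameters {sorted(unknown)}")
        self.spectra = spectra
        self.library = library
        self.tuning = tuning
        self.power = power
        self.grid = grid
        self.temperature = temperature
        self.pressure = pressure
        self.free = tuple(free)
        self.fixed = {"c0": init.c0, "c1": init.c1, "c2": init.c2,
                      "d0": init.d0, "d1": init.d1,
                      "t0": tuning.t0, "t1": tuning.t1, "t2": tuning.t2}
        self._components = [components_for_matrix(s.matrix, library) for s in spectra]
        self._p0 = [optical_power(s.currents, power) for s in spectra]
        self._cache_key: tuple | None = None
        self._cache_resp: list[np.ndarray] | None = None
        self.n_data = int(sum(s.currents.size for s in spectra))

    @property
    def x0(self) -> np.ndarray:
        return np.array([self.fixed[n] for n in self.free])

    def param_dict(self, theta: np.ndarray) -> dict[str, float]:
        d = dict(self.fixed)
        for n, v in zip(self.free, theta):
            d[n] = float(v)
        return d

    def _responses(self, t0: float, t1: float, t2: float) -> list[np.ndarray]:
        key = (t0, t1, t2)
        if key != self._cache_key:
            tun = TuningModel(t0=t0, t1=t1, t2=t2,
                              emission_fwhm=self.tuning.emission_fwhm,
                              sweep=self.tuning.sweep)
            self._cache_resp = [
                component_responses(c, tun, s.currents, self.grid,
                                    self.temperature, self.pressure).sum(axis=0)
                if c else np.zeros(s.currents.size)
                for c, s in zip(self._components, self.spectra)]
            self._cache_key = key
        return self._cache_resp

    def predict(self, theta: np.ndarray) -> list[np.ndarray]:
        p = self.param_dict(np.asarray(theta, dtype=float))
        resp = self._responses(p["t0"], p["t1"], p["t2"])
        out = []
        for s, r, p0 in zip(self.spectra, resp, self._p0):
            i = s.currents
            q = p["d0"] + p["d1"] * i
            bg = p["c0"] + p["c1"] * i + p["c2"] * i**2
            out.append(q * p0 * r + bg)
        return out

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        pred = self.predict(theta)
        return np.concatenate([pr - s.magnitudes for pr, s in zip(pred, self.spectra)])


def fit_forward_model(spectra: list[PASpectrum], library: dict[str, CrossSection],
                      tuning: TuningModel, power: PowerModel,
                      init: ForwardModelParams,
                      free: tuple[str, ...] = CANONICAL_FREE_PARAMS,
                      grid: WavenumberGrid | None = None,
                      x_scale: str | np.ndarray = "jac",
                      max_nfev: int | None = None) -> FitResult:
    """Nonlinear least squares over a campaign of known-composition spectra.

    Returns the converged parameters, the residual-variance-scaled
    covariance ``s^2 (J^T J)^{-1}``, and per-spectrum residuals.  A singular
    normal matrix raises :class:`IdentifiabilityError` naming the null-space
    parameters (e.g. transfer-function terms fitted against flat absorbers).
    """
    model = CampaignModel(spectra, library, tuning, power, init, free, grid)
    n_free = len(model.free)
    if model.n_data < n_free:
        raise FittingError(f"{model.n_data} data points cannot fit {n_free} parameters")
    res = least_squares(model.residuals, model.x0, x_scale=x_scale,
                        max_nfev=max_nfev, method="lm" if model.n_data > n_free else "trf")
    converged = bool(res.status > 0)
    jac = res.jac
    # identifiability on the column-normalized Jacobian (parameter scales
    # span many orders of magnitude)
    norms = np.linalg.norm(jac, axis=0)
    dead = norms == 0
    if np.any(dead):
        raise IdentifiabilityError(
            "singular normal matrix; unidentifiable parameters: "
            f"{[model.free[i] for i in np.nonzero(dead)[0]]}")
    jn = jac / norms
    u, sv, vt = np.linalg.svd(jn, full_matrices=False)
    if sv[-1] / sv[0] < 1e-10:
        null = vt[-1]
        bad = [model.free[i] for i in np.nonzero(np.abs(null) > 0.3)[0]]
        raise IdentifiabilityError(
            f"singular normal matrix; unidentifiable parameters: {bad or list(model.free)}")
    dof = max(model.n_data - n_free, 1)
    s2 = 2.0 * res.cost / dof
    cov_n = (vt.T / sv**2) @ vt * s2
    cov = cov_n / norms[:, None] / norms[None, :]
    if not converged:
        raise FittingError(f"fit did not converge: {res.message}")
    params = model.param_dict(res.x)
    per_spectrum = []
    pred = model.predict(res.x)
    for pr, s in zip(pred, spectra):
        per_spectrum.append(pr - s.magnitudes)
    return FitResult(parameters=params, free_names=model.free, covariance=cov,
                     residuals=per_spectrum, converged=converged,
                     cost=float(res.cost), noise_sigma_uv=float(np.sqrt(s2)))


def parameter_relative_variance(fit: FitResult,
                                zero_tol: float = 1e-12) -> dict[str, float]:
    """Diagonal of the covariance divided by the squared parameter values.

    Parameters indistinguishable from zero (below ``zero_tol`` of the
    parameter scale) get ``nan``: their relative variance is undefined.
    """
    var = np.diag(fit.covariance)
    scale = max(abs(v) for v in (fit.parameters[n] for n in fit.free_names))
    out = {}
    for i, name in enumerate(fit.free_names):
        val = fit.parameters[name]
        if abs(val) <= zero_tol * max(scale, 1.0):
            out[name] = float("nan")
        else:
            out[name] = float(var[i] / val**2)
    return out


@dataclass(frozen=True)
class EnsembleSummary:
    names: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray
    correlation: np.ndarray
    acceptance_fraction: float


def ensemble_check(model: CampaignModel, theta0: np.ndarray,
                   noise_sigma_uv: float, n_walkers: int = 32,
                   n_steps: int = 2000, seed: int = 0,
                   burn_frac: float = 0.25) -> EnsembleSummary:
    """Affine-invariant ensemble sampling of the Gaussian-likelihood posterior
    under flat priors; per-parameter mean/std and pairwise correlations.

    Identical seeds give identical chains.  An acceptance fraction below
    0.05 raises (the sampler never equilibrated).
    """
    theta0 = np.asarray(theta0, dtype=float)
    ndim = theta0.size
    if n_walkers < 2 * ndim:
        raise FittingError("need n_walkers >= 2 x free parameters")

    inv_two_var = 0.5 / noise_sigma_uv**2

    def log_prob(theta):
        try:
            r = model.residuals(theta)
        except ValueError:
            # parameter excursion outside the physical/spectral domain
            return -np.inf
        return -inv_two_var * float(r @ r)

    rng = np.random.default_rng(seed)
    scale = np.where(theta0 != 0, 1e-4 * np.abs(theta0), 1e-8)
    p0 = theta0 + scale * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    acc = float(np.mean(sampler.acceptance_fraction))
    if acc < 0.05:
        raise FittingError(f"sampler acceptance fraction {acc:.3f} < 0.05")
    chain = sampler.get_chain(discard=int(burn_frac * n_steps), flat=True)
    mean = chain.mean(axis=0)
    std = chain.std(axis=0, ddof=1)
    corr = np.corrcoef(chain, rowvar=False)
    return EnsembleSummary(names=model.free, mean=mean, std=std,
                           correlation=np.atleast_2d(corr),
                           acceptance_fraction=acc)


# ---------------------------------------------------------------------------
# base-spectrum correction


@dataclass(frozen=True)
class BaseSpectrumCorrection:
    """Global factor plus a smooth local multiplicative curve.

    ``window`` is a (lo, hi) wavenumber interval or None; inside the window
    the correction follows a cubic spline through ``knots``/``knot_values``
    with the boundary knots pinned to 1 (continuity at the window edges);
    outside it is exactly the global factor.
    """

    factor: float
    window: tuple[float, float] | None = None
    knots: np.ndarray | None = None
    knot_values: np.ndarray | None = None

    def __post_init__(self):
        if self.factor <= 0:
            raise InstrumentError("correction factor must be positive")
        if self.window is not None:
            lo, hi = self.window
            if not lo < hi:
                raise InstrumentError("window must satisfy lo < hi")
            if self.knots is not None:
                k = np.asarray(self.knots, dtype=float)
                v = np.asarray(self.knot_values, dtype=float)
                if k.shape != v.shape or k.size < 2:
                    raise InstrumentError("knots/knot_values mismatch")
                if np.any(v <= 0):
                    raise InstrumentError("correction curve must stay positive")
                object.__setattr__(self, "knots", k)
                object.__setattr__(self, "knot_values", v)

    def local_curve(self, nu: np.ndarray) -> np.ndarray:
        """The multiplicative curve evaluated at ``nu`` (1 outside the window)."""
        out = np.ones_like(np.asarray(nu, dtype=float))
        if self.window is None or self.knots is None:
            return out
        lo, hi = self.window
        inside = (nu >= lo) & (nu <= hi)
        if np.any(inside):
            spline = CubicSpline(self.knots, self.knot_values, bc_type="natural")
            out[inside] = spline(nu[inside])
        return out


def correct_base_spectrum(base: CrossSection,
                          correction: BaseSpectrumCorrection) -> CrossSection:
    """sigma' = sigma * factor * local_curve(nu); identity outside the window."""
    if correction.window is not None:
        lo, hi = correction.window
        g0, g1 = base.grid.span
        if lo < g0 or hi > g1:
            raise InstrumentError("correction window outside the base-spectrum span")
    curve = correction.local_curve(base.grid.values)
    sigma = base.sigma * correction.factor * curve
    return CrossSection(grid=base.grid, sigma=np.maximum(sigma, 0.0),
                        species=base.species)


def fit_base_correction(base: CrossSection, observed: CrossSection,
                        window: tuple[float, float],
                        n_knots: int = 5,
                        factor: float | None = None) -> BaseSpectrumCorrection:
    """Estimate a global factor and a local multiplicative spline curve that
    reconcile a reference base spectrum with an observed effective spectrum.

    The global factor is the median observed/base ratio outside the window
    (unless supplied, e.g. a known tank-concentration factor); the interior
    knot values of a ``n_knots``-knot natural cubic spline across the window
    are then solved by linear least squares on the windowed points, with the
    boundary knots pinned at 1.
    """
    if base.grid != observed.grid:
        raise InstrumentError("base and observed spectra must share a grid")
    lo, hi = window
    nu = base.grid.values
    inside = (nu >= lo) & (nu <= hi)
    outside = ~inside & (base.sigma > 0)
    if factor is None:
        if not np.any(outside):
            raise InstrumentError("no points outside the window to estimate the factor")
        factor = float(np.median(observed.sigma[outside] / base.sigma[outside]))
    if factor <= 0:
        raise InstrumentError("estimated factor non-positive")
    if n_knots < 3:
        raise InstrumentError("need at least 3 knots (2 boundary + 1 interior)")
    knots = np.linspace(lo, hi, n_knots)
    x = nu[inside]
    b = base.sigma[inside] * factor
    target = observed.sigma[inside]
    # curve(nu) is linear in the knot values: build the spline basis columns
    basis = np.empty((x.size, n_knots))
    for j in range(n_knots):
        e = np.zeros(n_knots)
        e[j] = 1.0
        basis[:, j] = CubicSpline(knots, e, bc_type="natural")(x)
    # boundary knots fixed at 1
    fixed = basis[:, [0, -1]] @ np.ones(2)
    design = basis[:, 1:-1] * b[:, None]
    rhs = target - b * fixed
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    values = np.concatenate([[1.0], sol, [1.0]])
    if np.any(values <= 0):
        raise FittingError("fitted correction curve went non-positive; "
                           "narrow the window or add knots")
    return BaseSpectrumCorrection(factor=factor, window=window,
                                  knots=knots, knot_values=values)


def residual_spectrum(simulated: PASpectrum, measured: PASpectrum,
                      concentration: float,
                      normalize_to: float = 1.0) -> np.ndarray:
    """(simulated - measured) / concentration * normalize_to, per current.

    Normalizing campaigns of different analyte concentration to a common
    mixing ratio makes systematic errors (e.g. a tank-concentration offset)
    directly comparable across measurements.
    """
    if simulated.currents.shape != measured.currents.shape or \
            not np.allclose(simulated.currents, measured.currents):
        raise InstrumentError("residual_spectrum needs a common current axis")
    if concentration <= 0:
        raise InstrumentError("known analyte concentration must be positive")
    return (simulated.magnitudes - measured.magnitudes) / concentration * normalize_to
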