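"""Absorption cross-sections and absorption-coefficient spectra on wavenumber grids.

The canonical spectral axis is wavenumber in cm^-1, strictly ascending.
Cross-sections are stored in cm^2/molecule, absorption coefficients in cm^-1
(HITRAN conventions).  Line-by-line synthesis uses a pseudo-Voigt profile
(Thompson-Cox-Hastings width rule) by default; the exact Voigt via the Faddeeva
function is available behind the same contract.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import voigt_profile

__all__ = [
    "BOLTZMANN_CGS",
    "KB",
    "T_REF",
    "P_REF",
    "WavenumberGrid",
    "SpectralLine",
    "CrossSection",
    "AbsorptionSpectrum",
    "GasComponent",
    "nm_to_wavenumber",
    "wavenumber_to_nm",
    "number_density",
    "voigt_cross_section",
    "absorption_coefficient",
    "sum_spectra",
    "resample",
    "read_cross_section_table",
    "write_cross_section_table",
    "read_line_list",
    "write_line_list",
]

KB = 1.380649e-23          # Boltzmann constant, J/K
BOLTZMANN_CGS = KB * 1e7   # erg/K (unused in SI path, kept for clarity)
T_REF = 296.0              # K, reference temperature (HITRAN convention)
P_REF = 101325.0           # Pa, reference pressure


class SpectralError(ValueError):
    """Invalid spectral input (grids, lines, tables)."""


def nm_to_wavenumber(lam_nm: float | np.ndarray) -> float | np.ndarray:
    """Vacuum wavelength in nm -> wavenumber in cm^-1."""
    return 1.0e7 / np.asarray(lam_nm, dtype=float) if np.ndim(lam_nm) else 1.0e7 / float(lam_nm)


def wavenumber_to_nm(nu_cm1: float | np.ndarray) -> float | np.ndarray:
    """Wavenumber in cm^-1 -> vacuum wavelength in nm."""
    return 1.0e7 / np.asarray(nu_cm1, dtype=float) if np.ndim(nu_cm1) else 1.0e7 / float(nu_cm1)


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly ascending wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise SpectralError("wavenumber grid needs at least 2 points")
        if not np.all(np.diff(v) > 0):
            raise SpectralError("wavenumber grid must be strictly ascending")
        object.__setattr__(self, "values", v)

    @classmethod
    def uniform(cls, start: float, stop: float, step: float) -> "WavenumberGrid":
        if step <= 0:
            raise SpectralError("grid step must be positive")
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberGrid) and np.array_equal(self.values, other.values)


@dataclass(frozen=True)
class SpectralLine:
    """One rovibrational line: center (cm^-1), integrated intensity
    (cm^-1/(molecule cm^-2)), and Lorentz/Doppler half-widths (HWHM, cm^-1)."""

    center: float
    intensity: float
    lorentz_hwhm: float
    doppler_hwhm: float

    def __post_init__(self):
        if self.intensity < 0:
            raise SpectralError("line intensity must be >= 0")
        if self.lorentz_hwhm < 0 or self.doppler_hwhm < 0:
            raise SpectralError("line widths must be >= 0")
        if self.lorentz_hwhm == 0 and self.doppler_hwhm == 0:
            raise SpectralError("at least one line width must be positive")


@dataclass(frozen=True)
class CrossSection:
    """Absorption cross-section sigma(nu) in cm^2/molecule for one species."""

    grid: WavenumberGrid
    sigma: np.ndarray
    species: str = ""

    def __post_init__(self):
        s = np.asarray(self.sigma, dtype=float)
        if s.shape != self.grid.values.shape:
            raise SpectralError("sigma and grid lengths differ")
        if np.any(s < 0):
            raise SpectralError("cross-section must be non-negative")
        object.__setattr__(self, "sigma", s)

    def value_at(self, nu: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation inside the grid span (no extrapolation)."""
        lo, hi = self.grid.span
        nu_arr = np.asarray(nu, dtype=float)
        if np.any(nu_arr < lo) or np.any(nu_arr > hi):
            raise SpectralError("wavenumber outside the cross-section span")
        out = np.interp(nu_arr, self.grid.values, self.sigma)
        return float(out) if np.ndim(nu) == 0 else out


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Absorption coefficient alpha(nu) in cm^-1 for one gas composition."""

    grid: WavenumberGrid
    alpha: np.ndarray
    label: str = ""

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float)
        if a.shape != self.grid.values.shape:
            raise SpectralError("alpha and grid lengths differ")
        if np.any(a < 0):
            raise SpectralError("absorption coefficient must be non-negative")
        object.__setattr__(self, "alpha", a)


@dataclass(frozen=True)
class GasComponent:
    """A species at a mixing ratio (dimensionless mole fraction) with its
    cross-section basis spectrum."""

    species: str
    mole_fraction: float
    cross_section: CrossSection

    def __post_init__(self):
        if not 0.0 <= self.mole_fraction <= 1.0:
            raise SpectralError("mole fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# line-by-line synthesis

# Thompson-Cox-Hastings pseudo-Voigt mixing polynomial
_TCH_F = (2.69269, 2.42843, 4.47163, 0.07842)
_ETA = (1.36603, -0.47719, 0.11116)


def _pseudo_voigt(dx: np.ndarray, fl: float, fg: float) -> np.ndarray:
    """Unit-area pseudo-Voigt of Lorentz FWHM fl and Gauss FWHM fg at offsets dx."""
    f = (fg**5 + _TCH_F[0] * fg**4 * fl + _TCH_F[1] * fg**3 * fl**2
         + _TCH_F[2] * fg**2 * fl**3 + _TCH_F[3] * fg * fl**4 + fl**5) ** 0.2
    q = fl / f
    eta = _ETA[0] * q + _ETA[1] * q**2 + _ETA[2] * q**3
    gam = f / 2.0
    lor = gam / (np.pi * (dx**2 + gam**2))
    sg = f / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gau = np.exp(-0.5 * (dx / sg) ** 2) / (sg * np.sqrt(2.0 * np.pi))
    return eta * lor + (1.0 - eta) * gau


def voigt_cross_section(lines: list[SpectralLine], grid: WavenumberGrid,
                        profile: str = "pseudo-voigt") -> CrossSection:
    """Synthesize sigma(nu) from a line list.

    Each line contributes an (approximately) unit-area profile scaled by its
    integrated intensity.  ``profile`` selects "pseudo-voigt" (default,
    Thompson-Cox-Hastings blend, < 1% profile error) or "voigt" (exact
    Faddeeva-based Voigt).
    """
    if not isinstance(grid, WavenumberGrid):
        raise SpectralError("grid must be a WavenumberGrid")
    if profile not in ("pseudo-voigt", "voigt"):
        raise SpectralError(f"unknown profile {profile!r}")
    sigma = np.zeros(len(grid))
    x = grid.values
    for ln in lines:
        dx = x - ln.center
        if profile == "voigt":
            sg = ln.doppler_hwhm / np.sqrt(2.0 * np.log(2.0))
            prof = voigt_profile(dx, sg, ln.lorentz_hwhm) if sg > 0 or ln.lorentz_hwhm > 0 else 0.0
        else:
            prof = _pseudo_voigt(dx, 2.0 * ln.lorentz_hwhm, 2.0 * ln.doppler_hwhm)
        sigma = sigma + ln.intensity * prof
    return CrossSection(grid=grid, sigma=sigma)


def number_density(mole_fraction: float, temperature: float = T_REF,
                   pressure: float = P_REF) -> float:
    """Species number density in molecules/cm^3 from the ideal-gas law."""
    if mole_fraction < 0:
        raise SpectralError("mole fraction must be >= 0")
    if temperature <= 0 or pressure <= 0:
        raise SpectralError("temperature and pressure must be positive")
    return mole_fraction * pressure / (KB * temperature) * 1e-6  # m^-3 -> cm^-3


def absorption_coefficient(xsec: CrossSection, mole_fraction: float,
                           temperature: float = T_REF,
                           pressure: float = P_REF,
                           label: str = "") -> AbsorptionSpectrum:
    """alpha(nu) = sigma(nu) * n, with n the ideal-gas number density of the
    species at the given conditions. Linear in mole_fraction."""
    n = number_density(mole_fraction, temperature, pressure)
    return AbsorptionSpectrum(grid=xsec.grid, alpha=xsec.sigma * n,
                              label=label or xsec.species)


def sum_spectra(spectra: list[AbsorptionSpectrum],
                grid: WavenumberGrid | None = None) -> AbsorptionSpectrum:
    """Pointwise sum of absorption spectra on a common grid (no resampling)."""
    if not spectra:
        if grid is None:
            raise SpectralError("empty spectrum list needs an explicit grid")
        return AbsorptionSpectrum(grid=grid, alpha=np.zeros(len(grid)), label="sum")
    g0 = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != g0:
            raise SpectralError("sum_spectra requires identical grids (no silent resampling)")
    total = np.sum([s.alpha for s in spectra], axis=0)
    return AbsorptionSpectrum(grid=g0, alpha=total, label="+".join(s.label for s in spectra))


def resample(spectrum: CrossSection | AbsorptionSpectrum,
             target: WavenumberGrid) -> CrossSection | AbsorptionSpectrum:
    """Linear interpolation onto ``target``, which must lie within the source span."""
    src = spectrum.grid
    lo, hi = src.span
    t0, t1 = target.span
    if t0 < lo or t1 > hi:
        raise SpectralError(
            f"target grid [{t0:.6g}, {t1:.6g}] extends beyond source span [{lo:.6g}, {hi:.6g}]")
    if isinstance(spectrum, CrossSection):
        y = np.interp(target.values, src.values, spectrum.sigma)
        return CrossSection(grid=target, sigma=y, species=spectrum.species)
    y = np.interp(target.values, src.values, spectrum.alpha)
    return AbsorptionSpectrum(grid=target, alpha=y, label=spectrum.label)


# ---------------------------------------------------------------------------
# text-table I/O
#
# Cross-section dialect: two numeric columns (wavenumber_cm1, sigma_cm2),
# whitespace- or comma-separated, '#'-prefixed comments.  Units fixed, not
# auto-detected.  Floats are written with repr precision so read(write(x)) is
# bit-stable.


def _parse_rows(text: str, ncols: int, what: str) -> np.ndarray:
    rows = []
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise SpectralError(f"{what}: non-numeric value on line {i}: {raw!r}") from exc
        if len(vals) != ncols:
            raise SpectralError(f"{what}: expected {ncols} columns on line {i}, got {len(vals)}")
        rows.append(vals)
    return np.asarray(rows, dtype=float)


def read_cross_section_table(source, species: str = "") -> CrossSection:
    """Read a two-column (wavenumber, cross-section) text table.

    ``source`` is a path or file-like object.  Rows are sorted ascending;
    duplicated wavenumbers are rejected.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    data = _parse_rows(text, 2, "cross-section table")
    if data.shape[0] < 2:
        raise SpectralError("cross-section table needs at least 2 rows")
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    if np.any(np.diff(data[:, 0]) == 0):
        raise SpectralError("cross-section table has duplicated wavenumbers")
    return CrossSection(grid=WavenumberGrid(data[:, 0]), sigma=data[:, 1], species=species)


def write_cross_section_table(xsec: CrossSection, target) -> None:
    """Write ``xsec`` in the two-column dialect (full float round-trip)."""
    buf = io.StringIO()
    buf.write("# wavenumber_cm1 sigma_cm2_per_molecule\n")
    if xsec.species:
        buf.write(f"# species: {xsec.species}\n")
    for nu, s in zip(xsec.grid.values, xsec.sigma):
        buf.write(f"{float(nu)!r} {float(s)!r}\n")
    if hasattr(target, "write"):
        target.write(buf.getvalue())
    else:
        with open(target, "w") as fh:
            fh.write(buf.getvalue())


_LINE_LIST_HEADER = "center_cm1 intensity lorentz_hwhm_cm1 doppler_hwhm_cm1"


def read_line_list(source) -> list[SpectralLine]:
    """Read a columnar line list with header
    ``center_cm1 intensity lorentz_hwhm_cm1 doppler_hwhm_cm1``."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    data = _parse_rows(text, 4, "line list")
    return [SpectralLine(*row) for row in data]


def write_line_list(lines: list[SpectralLine], target) -> None:
    buf = io.StringIO()
    buf.write(f"# {_LINE_LIST_HEADER}\n")
    for ln in lines:
        buf.write(f"{float(ln.center)!r} {float(ln.intensity)!r} "
                  f"{float(ln.lorentz_hwhm)!r} {float(ln.doppler_hwhm)!r}\n")
    if hasattr(target, "write"):
        target.write(buf.getvalue())
    else:
        with open(target, "w") as fh:
            fh.write(buf.getvalue())
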