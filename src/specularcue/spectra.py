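"""Spectral sampling, cone excitations and MacLeod-Boynton chromaticity.

This module is the colorimetric substrate for the rest of the package.  A
:class:`Spectrum` is a sampled spectral function on a strictly increasing
wavelength grid: an illuminant power distribution I(lambda), a surface
reflectance R(lambda) in [0, 1], or a reflected radiance.  Light reflected
from a glossy dielectric surface is modelled as the two-component mixture

    a * I(lambda) + b * I(lambda) * R(lambda)

where ``a`` scales the specular (interface) component, which carries the
illuminant spectrum unmodified, and ``b`` scales the diffuse (body)
component, which carries the illuminant filtered by the surface reflectance.
Cone excitations are trapezoid-rule inner products of radiance with the L,
M and S cone sensitivities, and chromaticity is expressed in the
MacLeod-Boynton diagram: l = L/(L+M), s = S/(L+M), with luminance L+M on a
third axis.  In that representation the mixture chromaticities of a glossy
surface lie on a line between the diffuse chromaticity and the illuminant
chromaticity, and lines from several surfaces under one illuminant converge
at the illuminant chromaticity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GRID",
    "Spectrum",
    "ConeExcitation",
    "Chromaticity",
    "ChromaticChange",
    "GridMismatchError",
    "cone_fundamentals",
    "resample_spectrum",
    "spectral_product",
    "mixture_spectrum",
    "cone_excitations",
    "macleod_boynton",
    "macleod_boynton_arrays",
    "chromatic_change",
    "equal_energy_white",
    "read_spectra_csv",
    "write_spectra_csv",
]

#: Default working wavelength grid, nm.  Adequate for the smooth
#: daylight-like illuminants and smooth reflectances used throughout.
DEFAULT_GRID = np.arange(400.0, 701.0, 10.0)

_WL_MIN, _WL_MAX = 380.0, 780.0

_ROLES = ("illuminant", "reflectance", "radiance", "sensitivity")


class GridMismatchError(ValueError):
    """Raised when two spectra combined in one operation have different grids."""


class UndefinedChromaticityError(ValueError):
    """Raised when L+M = 0 so the MacLeod-Boynton projection is undefined."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral function on a strictly increasing nm grid.

    Parameters
    ----------
    wavelengths:
        Strictly increasing wavelengths in nm, within [380, 780].
    values:
        Nonnegative samples.  If ``role == "reflectance"`` the samples must
        also be <= 1.
    role:
        One of ``illuminant``, ``reflectance``, ``radiance``, ``sensitivity``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    role: str = "radiance"
    name: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)
        if wl.ndim != 1 or v.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-D and congruent")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < _WL_MIN - 1e-9 or wl[-1] > _WL_MAX + 1e-9:
            raise ValueError(f"wavelengths must lie within [{_WL_MIN}, {_WL_MAX}] nm")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if np.any(v < -1e-12):
            raise ValueError("spectral values must be nonnegative")
        if self.role == "reflectance" and np.any(v > 1.0 + 1e-9):
            raise ValueError("reflectance values must be <= 1")

    # -- convenience -------------------------------------------------------
    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavelengths.shape == other.wavelengths.shape and np.allclose(
            self.wavelengths, other.wavelengths
        )

    def with_values(self, values, role: str | None = None, name: str | None = None) -> "Spectrum":
        return Spectrum(
            self.wavelengths,
            np.asarray(values, dtype=float),
            role if role is not None else self.role,
            name if name is not None else self.name,
        )

    def __mul__(self, k: float) -> "Spectrum":
        return self.with_values(self.values * float(k))

    __rmul__ = __mul__


@dataclass(frozen=True)
class ConeExcitation:
    """Linear L, M, S cone excitations (arbitrary linear units)."""

    L: float
    M: float
    S: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.M, self.S], dtype=float)


@dataclass(frozen=True)
class Chromaticity:
    """MacLeod-Boynton chromaticity: l = L/(L+M), s = S/(L+M), lum = L+M.

    The ordinate is named ``s_mb`` to avoid collision with the surface
    specularity parameter ``s`` used elsewhere in the package.
    """

    l_mb: float
    s_mb: float
    lum: float


@dataclass(frozen=True)
class ChromaticChange:
    """A displacement in the (l_mb, s_mb) plane as (direction, magnitude).

    ``direction`` is the angle of the displacement in radians, in (-pi, pi],
    measured anticlockwise from the +l_mb axis; ``magnitude`` is its
    Euclidean length (unitless).  A zero displacement has direction 0 by
    convention.
    """

    direction: float
    magnitude: float

    @property
    def vector(self) -> np.ndarray:
        return self.magnitude * np.array([np.cos(self.direction), np.sin(self.direction)])


# ---------------------------------------------------------------------------
# Cone fundamentals
# ---------------------------------------------------------------------------

# Smooth analytic cone sensitivity approximations: Gaussian profiles with
# peaks and widths chosen to mimic human 2-degree L, M, S spectral
# sensitivities.  Every quantity computed downstream depends only on the
# relative chromatic geometry these induce (scale invariance, mixture-line
# convergence, classifier separability), not on a particular standards
# tabulation; the normalization below pins the conventional anchor points.
_PEAKS = (565.0, 535.0, 445.0)
_WIDTHS = (52.0, 48.0, 28.0)

#: Conventional MacLeod-Boynton coordinates of equal-energy white: the L
#: and M scales are set so that l(EEW) = 0.665 with luminance L+M = 1 for a
#: unit-power equal-energy spectrum, and the S scale so that s(EEW) = 1.
_EEW_L = 0.665
_EEW_S = 1.0


def _raw_fundamentals(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    out = np.empty((3, grid.size))
    for i, (peak, width) in enumerate(zip(_PEAKS, _WIDTHS)):
        out[i] = np.exp(-0.5 * ((grid - peak) / width) ** 2)
    return out


def _fundamental_scales() -> np.ndarray:
    # Computed once on a fine grid so the scaling does not depend on the
    # caller's working grid.
    fine = np.arange(400.0, 700.5, 1.0)
    raw = _raw_fundamentals(fine)
    eew = np.trapezoid(raw, fine, axis=1)  # excitations for unit-power EEW
    kL = _EEW_L / eew[0]
    kM = (1.0 - _EEW_L) / eew[1]
    kS = _EEW_S / eew[2]
    return np.array([kL, kM, kS])


_SCALES = _fundamental_scales()


def cone_fundamentals(grid=None) -> tuple[Spectrum, Spectrum, Spectrum]:
    """L, M, S cone sensitivities resampled onto ``grid`` (default grid).

    Scaled so that a unit-power equal-energy spectrum has luminance
    L+M = 1, l_mb = 0.665 and s_mb = 1 (fixed by a regression test)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    raw = _raw_fundamentals(grid) * _SCALES[:, None]
    names = ("L", "M", "S")
    return tuple(
        Spectrum(grid, raw[i], role="sensitivity", name=names[i]) for i in range(3)
    )


def equal_energy_white(grid=None) -> Spectrum:
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    return Spectrum(grid, np.ones_like(grid), role="illuminant", name="EEW")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def resample_spectrum(spec: Spectrum, grid) -> Spectrum:
    """Linearly interpolate ``spec`` onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < spec.wavelengths[0] - 1e-9 or grid[-1] > spec.wavelengths[-1] + 1e-9:
        raise ValueError(
            "target grid extends outside the spectrum's support "
            f"[{spec.wavelengths[0]}, {spec.wavelengths[-1]}] nm"
        )
    vals = np.interp(grid, spec.wavelengths, spec.values)
    return Spectrum(grid, vals, role=spec.role, name=spec.name)


def _require_same_grid(*specs: Spectrum):
    for other in specs[1:]:
        if not specs[0].same_grid(other):
            raise GridMismatchError("spectra do not share a wavelength grid")


def spectral_product(I: Spectrum, R: Spectrum) -> Spectrum:
    """Pointwise product I(lambda) * R(lambda): the diffuse-component radiance."""
    _require_same_grid(I, R)
    return Spectrum(I.wavelengths, I.values * R.values, role="radiance")


def mixture_spectrum(I: Spectrum, R: Spectrum, a: float, b: float) -> Spectrum:
    """Two-component reflection: a*I + b*I*R with a, b >= 0.

    ``a`` scales the specular component (illuminant spectrum unmodified),
    ``b`` the diffuse component (illuminant filtered by the reflectance).
    """
    if a < 0 or b < 0:
        raise ValueError("mixture coefficients a, b must be nonnegative")
    _require_same_grid(I, R)
    vals = a * I.values + b * I.values * R.values
    return Spectrum(I.wavelengths, vals, role="radiance")


def cone_excitations(rad: Spectrum, fundamentals=None) -> ConeExcitation:
    """Trapezoid-rule inner product of a radiance with each cone sensitivity."""
    if fundamentals is None:
        fundamentals = cone_fundamentals(rad.wavelengths)
    _require_same_grid(rad, *fundamentals)
    lms = [
        float(np.trapezoid(rad.values * f.values, rad.wavelengths))
        for f in fundamentals
    ]
    return ConeExcitation(*lms)


def macleod_boynton(c: ConeExcitation) -> Chromaticity:
    """Project cone excitations into the MacLeod-Boynton diagram."""
    lm = c.L + c.M
    if lm <= 0:
        raise UndefinedChromaticityError("chromaticity undefined for L+M = 0")
    return Chromaticity(c.L / lm, c.S / lm, lm)


def macleod_boynton_arrays(L, M, S):
    """Vectorized MacLeod-Boynton projection for image-sized arrays.

    Returns (l_mb, s_mb, lum); entries with L+M <= 0 are NaN in the
    chromaticity planes and 0 in luminance (callers mask them)."""
    L, M, S = (np.asarray(x, dtype=float) for x in (L, M, S))
    lum = L + M
    with np.errstate(divide="ignore", invalid="ignore"):
        l_mb = np.where(lum > 0, L / lum, np.nan)
        s_mb = np.where(lum > 0, S / lum, np.nan)
    return l_mb, s_mb, np.where(lum > 0, lum, 0.0)


def chromaticity_of(rad: Spectrum, fundamentals=None) -> Chromaticity:
    """Convenience composition: macleod_boynton(cone_excitations(rad))."""
    return macleod_boynton(cone_excitations(rad, fundamentals))


def chromatic_change(before: Chromaticity, after: Chromaticity) -> ChromaticChange:
    """The displacement after - before in the (l_mb, s_mb) plane."""
    dl = after.l_mb - before.l_mb
    ds = after.s_mb - before.s_mb
    mag = float(np.hypot(dl, ds))
    direction = 0.0 if mag == 0 else float(np.arctan2(ds, dl))
    return ChromaticChange(direction, mag)


# ---------------------------------------------------------------------------
# Spectra I/O
# ---------------------------------------------------------------------------

def _sniff_read(path_or_buf) -> pd.DataFrame:
    """Tolerant CSV read: sniffs comma vs semicolon and a header row."""
    if isinstance(path_or_buf, (str, Path)):
        text = Path(path_or_buf).read_text()
    else:
        text = path_or_buf.read()
    first = text.splitlines()[0] if text else ""
    sep = ";" if first.count(";") > first.count(",") else ","
    # Header detection: a header row contains a field that is not a number.
    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in first.split(sep) if t.strip())
    return pd.read_csv(
        io.StringIO(text), sep=sep, header=0 if has_header else None,
        skipinitialspace=True,
    )


def read_spectra_csv(path, role: str = "illuminant", grid=None) -> dict[str, Spectrum]:
    """Read spectra from CSV.

    Accepts the canonical two-column layout ``wavelength_nm,value`` and the
    multi-column dialect of the supplementary spectra table (first column
    wavelengths, one named column per spectrum; comma or semicolon
    separated, header optional).  Returns a mapping name -> Spectrum; a
    headerless two-column file yields the single key ``"spectrum"``.  If
    ``grid`` is given, spectra are resampled onto it.
    """
    df = _sniff_read(path)
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    order = np.argsort(wl)
    out: dict[str, Spectrum] = {}
    for j, col in enumerate(df.columns[1:], start=1):
        name = str(col) if not isinstance(col, (int, np.integer)) else (
            "spectrum" if df.shape[1] == 2 else f"spectrum_{j}"
        )
        vals = df.iloc[:, j].to_numpy(dtype=float)
        spec = Spectrum(wl[order], vals[order], role=role, name=name)
        out[name] = resample_spectrum(spec, grid) if grid is not None else spec
    return out


def write_spectra_csv(path, spectra: dict[str, Spectrum]):
    """Write spectra as one wavelength column plus one named column each."""
    specs = list(spectra.values())
    _require_same_grid(*specs)
    cols = {"wavelength_nm": specs[0].wavelengths}
    cols.update({name: s.values for name, s in spectra.items()})
    pd.DataFrame(cols).to_csv(path, index=False)
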