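"""Synthetic inputs: daylight-like illuminant pairs, smooth reflectance
libraries, and simulated binary responses.

The experiment needs (i) two smooth illuminant spectra whose chromaticities
differ along a blue-yellow axis, emulating direct sunlight versus skylight;
(ii) a library of smooth surface reflectances in [0, 1] spanning several
hue directions, emulating databases of measured natural and man-made
surfaces; and (iii) per-trial binary classification responses from
observers with specified sensitivity and bias, in the same long-format
table the analysis stage consumes.  Everything here is deterministic given
its seed, so the full pipeline is testable offline; measured spectra
supplied as CSV can replace the generated ones at any point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .spectra import (
    DEFAULT_GRID,
    Spectrum,
    chromaticity_of,
)

__all__ = [
    "IlluminantGeneratorParams",
    "ReflectanceGeneratorParams",
    "SimulatedObserverParams",
    "generate_illuminant_pair",
    "generate_reflectance_library",
    "simulate_responses",
    "write_responses_csv",
]


# ---------------------------------------------------------------------------
# Illuminants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IlluminantGeneratorParams:
    """Two-basis smooth daylight model: broad warm + broad cool components.

    ``sun_warm/sun_cool`` and ``sky_warm/sky_cool`` weight the two basis
    functions for the sun-like and sky-like members of the pair.  Equal
    controls for both members give chromatically identical spectra.  The
    defaults yield a sun-like spectrum with higher l_mb and lower s_mb than
    the sky-like one (a blue-yellow separation), with roughly equal
    luminance under a neutral surface.
    """

    sun_warm: float = 1.0
    sun_cool: float = 0.45
    sky_warm: float = 0.42
    sky_cool: float = 1.0
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    seed: int = 0


def _warm_basis(grid):
    return 0.25 + np.exp(-0.5 * ((grid - 620.0) / 90.0) ** 2)


def _cool_basis(grid):
    return 0.25 + np.exp(-0.5 * ((grid - 455.0) / 70.0) ** 2)


def generate_illuminant_pair(params: IlluminantGeneratorParams | None = None):
    """Return (sun_like, sky_like) illuminant spectra.

    Deterministic given the params (the seed is carried for provenance
    only; the basis model has no sampling noise)."""
    p = params or IlluminantGeneratorParams()
    grid = np.asarray(p.grid, dtype=float)
    w, c = _warm_basis(grid), _cool_basis(grid)

    def mk(warm, cool, name):
        vals = warm * w + cool * c
        vals = vals / vals.mean()  # comparable overall power
        return Spectrum(grid, vals, role="illuminant", name=name)

    return mk(p.sun_warm, p.sun_cool, "sun_like"), mk(p.sky_warm, p.sky_cool, "sky_like")


# ---------------------------------------------------------------------------
# Reflectances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReflectanceGeneratorParams:
    """Low-order smooth reflectance model.

    Each reflectance is a mean level plus a few low-frequency cosine
    components over the working range; samples falling outside
    ``bounds`` anywhere are rejected and redrawn, so every library entry is
    a valid reflectance and remains smooth (adjacent-sample differences are
    bounded by the basis order).
    """

    size: int = 500
    n_basis: int = 4
    mean_range: tuple = (0.15, 0.65)
    coeff_scale: float = 0.22
    bounds: tuple = (0.02, 0.98)
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    seed: int = 0


def generate_reflectance_library(params: ReflectanceGeneratorParams | None = None):
    """Return a list of smooth reflectance spectra within [0, 1]."""
    p = params or ReflectanceGeneratorParams()
    rng = np.random.default_rng(p.seed)
    grid = np.asarray(p.grid, dtype=float)
    t = (grid - grid[0]) / (grid[-1] - grid[0])  # in [0, 1]
    basis = np.stack(
        [np.cos(np.pi * k * t) / k for k in range(1, p.n_basis + 1)]
    )  # (K, n_wl); 1/k roll-off keeps spectra smooth
    lo, hi = p.bounds
    out = []
    attempts = 0
    while len(out) < p.size:
        attempts += 1
        if attempts > 200 * p.size:
            raise RuntimeError("reflectance rejection sampling failed to converge")
        mean = rng.uniform(*p.mean_range)
        coeffs = rng.normal(scale=p.coeff_scale, size=p.n_basis)
        vals = mean + coeffs @ basis
        if vals.min() < lo or vals.max() > hi:
            continue
        out.append(
            Spectrum(grid, vals, role="reflectance", name=f"refl_{len(out):04d}")
        )
    return out


# ---------------------------------------------------------------------------
# Simulated responses
# ---------------------------------------------------------------------------

#: Canonical long-format response table columns.
RESPONSE_COLUMNS = (
    "observer", "object_type", "motion_condition", "specularity_level",
    "truth", "response",
)


@dataclass(frozen=True)
class SimulatedObserverParams:
    """Equal-variance Gaussian observer: per-cell true d' and ln(beta).

    ``dprime`` maps (motion_condition, specularity_level) -> true
    sensitivity (>= 0); ``ln_beta`` is the response bias (positive =
    tendency toward "reflectance" responses).  Keys absent from ``dprime``
    raise, so a schedule cell can never be silently simulated at an
    unspecified sensitivity.
    """

    dprime: dict
    ln_beta: float = 0.0
    observer: str = "sim"
    seed: int = 0


def _criterion(dprime: float, ln_beta: float) -> float:
    # ln beta = (z_F^2 - z_H^2)/2 with z_H = d' - c, z_F = -c  =>
    # c = ln_beta/d' + d'/2 (any c is bias-consistent when d' = 0).
    if dprime == 0.0:
        return 0.0 if ln_beta == 0.0 else np.sign(ln_beta) * np.inf
    return ln_beta / dprime + dprime / 2.0


def simulate_responses(schedule, params: SimulatedObserverParams,
                       object_type: str = "marbled") -> pd.DataFrame:
    """One response per schedule trial from the Gaussian SDT model.

    Illuminant-change trials are the signal class: the internal variable is
    N(d', 1) on signal trials and N(0, 1) on noise (reflectance) trials,
    and the observer responds "illuminant" when it exceeds the criterion
    implied by (d', ln beta).
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for trial in schedule.trials:
        key = (trial.motion_condition, trial.specularity_level)
        if key not in params.dprime:
            raise KeyError(f"no simulated d' specified for cell {key}")
        d = params.dprime[key]
        if d < 0:
            raise ValueError("specified d' must be nonnegative")
        c = _criterion(d, params.ln_beta)
        x = rng.normal(loc=d if trial.change_type == "illuminant" else 0.0)
        response = "illuminant" if x > c else "reflectance"
        rows.append({
            "observer": params.observer,
            "object_type": object_type,
            "motion_condition": trial.motion_condition,
            "specularity_level": trial.specularity_level,
            "truth": trial.change_type,
            "response": response,
        })
    return pd.DataFrame(rows, columns=list(RESPONSE_COLUMNS))


def write_responses_csv(path, table: pd.DataFrame):
    """Write a response table in the canonical CSV schema."""
    missing = set(RESPONSE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    table.loc[:, list(RESPONSE_COLUMNS)].to_csv(path, index=False)
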