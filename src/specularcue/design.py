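"""Trial-ensemble construction with cue silencing.

Each trial shows one of two change types: the illuminant spectrum changes
(I1 -> I2 or I2 -> I1, reflectance fixed) or the surface reflectance
changes (Ra -> Rb, illuminant fixed).  With only two illuminants, an
arbitrary choice of reflectance pairs would let an observer classify trials
purely from the direction and magnitude of the diffuse-component colour
change: changes off the blue-yellow axis would be more likely to be surface
changes.  To silence that cue, each illuminant-change trial is paired with
a reflectance pair whose diffuse chromatic change is as close as possible
in (direction, log magnitude, log-luminance ratio); after matching, the two
classes' diffuse-change distributions overlap and only the specular
component distinguishes them.  At zero specularity the task is then
impossible by design.

A session is 700 trials — 140 at each of five specularity levels, balanced
70/70 between the change types — divided into four blocks of 175.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import energy_distance

from .scene import MOTION_CONDITIONS, SPECULARITY_LEVELS
from .spectra import (
    ChromaticChange,
    Spectrum,
    chromatic_change,
    chromaticity_of,
    spectral_product,
)

__all__ = [
    "TrialSpec",
    "SessionSchedule",
    "MatchingError",
    "diffuse_change",
    "select_matched_pairs",
    "build_schedule",
    "schedule_to_frame",
    "schedule_from_frame",
]


class MatchingError(RuntimeError):
    """Raised when the reflectance library cannot supply matched pairs."""


@dataclass(frozen=True)
class TrialSpec:
    """Full recipe for one animation.

    Exactly one of the illuminant and the reflectance changes: for
    ``change_type == "illuminant"`` the reflectances are equal, and for
    ``change_type == "reflectance"`` the illuminants are equal.
    """

    change_type: str
    I_before: Spectrum
    I_after: Spectrum
    R_before: Spectrum
    R_after: Spectrum
    specularity_level: int = 0
    motion_condition: str = "NoMotion"
    rotation_sign: int = 1
    object_type: str = "marbled"
    seed: int = 0

    def __post_init__(self):
        if self.change_type not in ("illuminant", "reflectance"):
            raise ValueError(f"unknown change type {self.change_type!r}")
        if self.change_type == "illuminant" and self.R_before is not self.R_after:
            if not np.allclose(self.R_before.values, self.R_after.values):
                raise ValueError("reflectance must be fixed on illuminant-change trials")
        if self.change_type == "reflectance" and self.I_before is not self.I_after:
            if not np.allclose(self.I_before.values, self.I_after.values):
                raise ValueError("illuminant must be fixed on reflectance-change trials")
        if not 0 <= self.specularity_level < len(SPECULARITY_LEVELS):
            raise ValueError("specularity level index out of range")
        if self.motion_condition not in MOTION_CONDITIONS:
            raise ValueError(f"unknown motion condition {self.motion_condition!r}")
        if self.rotation_sign not in (-1, 1):
            raise ValueError("rotation sign must be +1 or -1")
        if self.object_type not in ("bumpy", "marbled"):
            raise ValueError(f"unknown object type {self.object_type!r}")

    @property
    def specularity(self) -> float:
        return SPECULARITY_LEVELS[self.specularity_level]


def diffuse_change(trial: TrialSpec) -> ChromaticChange:
    """Chromatic change of the diffuse component across the trial."""
    before = chromaticity_of(spectral_product(trial.I_before, trial.R_before))
    after = chromaticity_of(spectral_product(trial.I_after, trial.R_after))
    return chromatic_change(before, after)


def _diffuse_features(I0, R0, I1, R1) -> np.ndarray:
    """(direction, log10 magnitude, delta log10 luminance) of the diffuse change."""
    c0 = chromaticity_of(spectral_product(I0, R0))
    c1 = chromaticity_of(spectral_product(I1, R1))
    ch = chromatic_change(c0, c1)
    return np.array([
        ch.direction,
        np.log10(ch.magnitude + 1e-9),
        np.log10(c1.lum) - np.log10(c0.lum),
    ])


def _library_lms(library, illuminants) -> np.ndarray:
    """Cone excitations of I*R for every (illuminant, reflectance) combo.

    Returns an array of shape (n_illuminants, n_library, 3); one trapezoid
    integration per combination, vectorized over the library.
    """
    from .spectra import cone_fundamentals

    grid = library[0].wavelengths
    funds = np.stack([f.values for f in cone_fundamentals(grid)])  # (3, n_wl)
    V = np.stack([r.values for r in library])  # (n_lib, n_wl)
    out = np.empty((len(illuminants), len(library), 3))
    for i, I in enumerate(illuminants):
        W = I.values[None, :] * funds  # (3, n_wl)
        out[i] = np.trapezoid(V[:, None, :] * W[None, :, :], grid, axis=-1)
    return out


def _lms_features(lms0: np.ndarray, lms1: np.ndarray) -> np.ndarray:
    """Vectorized diffuse-change features from before/after LMS rows."""
    def chrom(lms):
        lum = lms[..., 0] + lms[..., 1]
        return lms[..., 0] / lum, lms[..., 2] / lum, lum

    l0, s0, u0 = chrom(lms0)
    l1, s1, u1 = chrom(lms1)
    dl, ds = l1 - l0, s1 - s0
    mag = np.hypot(dl, ds)
    return np.stack([
        np.arctan2(ds, dl),
        np.log10(mag + 1e-9),
        np.log10(u1) - np.log10(u0),
    ], axis=-1)


def _match_distances(target: np.ndarray, cands: np.ndarray,
                     weights=(1.0, 1.0, 1.0)) -> np.ndarray:
    dd = np.abs(cands[:, 0] - target[0])
    dd = np.minimum(dd, 2 * np.pi - dd)  # circular direction distance
    dm = cands[:, 1] - target[1]
    du = cands[:, 2] - target[2]
    w = np.asarray(weights)
    return np.sqrt((w[0] * dd) ** 2 + (w[1] * dm) ** 2 + (w[2] * du) ** 2)


def select_matched_pairs(library, illuminants, n_per_class: int, seed: int = 0,
                         n_candidates: int | None = None,
                         tolerance: float | None = None):
    """Pair illuminant-change trials with matched reflectance-change trials.

    For each illuminant-change trial (random reflectance, random change
    direction within the illuminant pair), the nearest unused candidate
    reflectance pair — in (direction, log magnitude, delta log luminance)
    of the diffuse change — is selected greedily.  The candidate pool is
    every ordered reflectance pair under either fixed illuminant when that
    space is no larger than ``n_candidates``, otherwise a random subsample
    of it; exhaustive pools give the tightest matches, which matters
    because a noiseless model observer can exploit arbitrarily small
    distributional mismatch.  Returns ``(illuminant_trials,
    reflectance_trials, diagnostics)`` where the diagnostics report
    per-coordinate two-sample energy distances between the classes and the
    worst per-pair match distance.

    Raises :class:`MatchingError`, listing the unmatched trials, when
    ``tolerance`` is given and some trial has no candidate within it.
    """
    if len(library) < 3:
        raise MatchingError("reflectance library too small to form pairs")
    rng = np.random.default_rng(seed)
    I1, I2 = illuminants
    n_exhaustive = 2 * len(library) * (len(library) - 1)
    if n_candidates is None:
        n_candidates = max(min(n_exhaustive, 600_000), 40 * n_per_class)

    lms = _library_lms(library, (I1, I2))  # (2, n_lib, 3)

    # --- illuminant-change trials ---------------------------------------
    refl_idx = rng.integers(0, len(library), size=n_per_class)
    flip = rng.random(n_per_class) < 0.5
    ill_trials = []
    for i in range(n_per_class):
        R = library[refl_idx[i]]
        Ia, Ib = (I2, I1) if flip[i] else (I1, I2)
        ill_trials.append(TrialSpec("illuminant", Ia, Ib, R, R))
    before_ill = np.where(flip[:, None], lms[1][refl_idx], lms[0][refl_idx])
    after_ill = np.where(flip[:, None], lms[0][refl_idx], lms[1][refl_idx])
    ill_feats = _lms_features(before_ill, after_ill)

    # --- candidate reflectance pairs ------------------------------------
    if n_candidates >= n_exhaustive:
        # every ordered pair under each fixed illuminant
        ga, gb = np.meshgrid(np.arange(len(library)), np.arange(len(library)),
                             indexing="ij")
        keep = ga.ravel() != gb.ravel()
        ra = np.tile(ga.ravel()[keep], 2)
        rb = np.tile(gb.ravel()[keep], 2)
        fixed_I = np.repeat([0, 1], keep.sum())
    else:
        ra = rng.integers(0, len(library), size=n_candidates)
        rb = rng.integers(0, len(library), size=n_candidates)
        keep = ra != rb
        ra, rb = ra[keep], rb[keep]
        fixed_I = (rng.random(ra.size) < 0.5).astype(int)  # index into (I1, I2)
    cand_feats = _lms_features(lms[fixed_I, ra], lms[fixed_I, rb])

    # --- greedy nearest-neighbour matching ------------------------------
    used = np.zeros(ra.size, dtype=bool)
    order = rng.permutation(n_per_class)
    refl_trials = [None] * n_per_class
    pair_dists = np.empty(n_per_class)
    unmatched = []
    for i in order:
        d = _match_distances(ill_feats[i], cand_feats)
        d[used] = np.inf
        j = int(np.argmin(d))
        if not np.isfinite(d[j]):
            raise MatchingError("candidate pool exhausted before matching completed")
        if tolerance is not None and d[j] > tolerance:
            unmatched.append((int(i), float(d[j])))
            continue
        used[j] = True
        pair_dists[i] = d[j]
        I = (I1, I2)[fixed_I[j]]
        refl_trials[i] = TrialSpec(
            "reflectance", I, I, library[ra[j]], library[rb[j]]
        )
    if unmatched:
        raise MatchingError(
            f"{len(unmatched)} trials had no reflectance pair within "
            f"tolerance {tolerance}: {unmatched[:10]}"
        )

    matched_feats = np.array([
        _diffuse_features(t.I_before, t.R_before, t.I_after, t.R_after)
        for t in refl_trials
    ])
    names = ("direction", "log_magnitude", "dlog_lum")
    diagnostics = {
        f"energy_distance_{n}": float(energy_distance(ill_feats[:, k], matched_feats[:, k]))
        for k, n in enumerate(names)
    }
    diagnostics["max_pair_distance"] = float(pair_dists.max())
    diagnostics["mean_pair_distance"] = float(pair_dists.mean())
    return ill_trials, refl_trials, diagnostics


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered trials plus block boundaries for one experimental session."""

    trials: tuple
    n_blocks: int = 4

    def __post_init__(self):
        if len(self.trials) % self.n_blocks:
            raise ValueError("trial count must divide evenly into blocks")
        object.__setattr__(self, "trials", tuple(self.trials))

    @property
    def block_size(self) -> int:
        return len(self.trials) // self.n_blocks

    def blocks(self):
        bs = self.block_size
        return [self.trials[k * bs:(k + 1) * bs] for k in range(self.n_blocks)]

    def validate_standard(self):
        """Assert the canonical session design: 700 trials, 140 per
        specularity level balanced 70/70 by change type, 4 blocks of 175."""
        if len(self.trials) != 700 or self.n_blocks != 4:
            raise ValueError("standard session is 700 trials in 4 blocks")
        for lvl in range(len(SPECULARITY_LEVELS)):
            cell = [t for t in self.trials if t.specularity_level == lvl]
            if len(cell) != 140:
                raise ValueError(f"level {lvl} has {len(cell)} trials, expected 140")
            n_ill = sum(t.change_type == "illuminant" for t in cell)
            if n_ill != 70:
                raise ValueError(f"level {lvl} unbalanced: {n_ill}/70 illuminant")


def build_schedule(ill_trials, refl_trials, motion_condition: str,
                   object_type: str, seed: int = 0,
                   n_levels: int = len(SPECULARITY_LEVELS),
                   n_blocks: int = 4) -> SessionSchedule:
    """Assemble a shuffled session from matched trial sets.

    The matched sets are interleaved across specularity levels pair-by-pair
    (so every level receives an equal number of matched illuminant /
    reflectance pairs), rotation signs are drawn uniformly at random per
    trial, and the whole session is shuffled.  With the default sizes
    (350 matched pairs) this realizes the canonical 700-trial design.
    """
    if len(ill_trials) != len(refl_trials):
        raise ValueError("matched sets must have equal size")
    if len(ill_trials) % n_levels:
        raise ValueError("matched-set size must divide evenly across levels")
    rng = np.random.default_rng(seed)
    trials = []
    for i, (ti, tr) in enumerate(zip(ill_trials, refl_trials)):
        lvl = i % n_levels
        for t in (ti, tr):
            trials.append(replace(
                t,
                specularity_level=lvl,
                motion_condition=motion_condition,
                object_type=object_type,
                rotation_sign=int(rng.choice([-1, 1])),
                seed=int(rng.integers(0, 2**31 - 1)),
            ))
    perm = rng.permutation(len(trials))
    return SessionSchedule(tuple(trials[k] for k in perm), n_blocks=n_blocks)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_CSV_COLUMNS = (
    "trial", "block", "change_type", "I_before", "I_after", "R_before",
    "R_after", "specularity_level", "specularity", "motion_condition",
    "rotation_sign", "object_type", "seed",
)


def schedule_to_frame(schedule: SessionSchedule) -> pd.DataFrame:
    """One row per trial; spectra referenced by name."""
    rows = []
    bs = schedule.block_size
    for k, t in enumerate(schedule.trials):
        rows.append({
            "trial": k,
            "block": k // bs,
            "change_type": t.change_type,
            "I_before": t.I_before.name,
            "I_after": t.I_after.name,
            "R_before": t.R_before.name,
            "R_after": t.R_after.name,
            "specularity_level": t.specularity_level,
            "specularity": t.specularity,
            "motion_condition": t.motion_condition,
            "rotation_sign": t.rotation_sign,
            "object_type": t.object_type,
            "seed": t.seed,
        })
    return pd.DataFrame(rows, columns=list(_CSV_COLUMNS))


def schedule_from_frame(df: pd.DataFrame, spectra: dict) -> SessionSchedule:
    """Rebuild a schedule from its frame plus a name -> Spectrum mapping."""
    n_blocks = int(df["block"].max()) + 1
    trials = []
    for _, r in df.sort_values("trial").iterrows():
        trials.append(TrialSpec(
            change_type=r["change_type"],
            I_before=spectra[r["I_before"]],
            I_after=spectra[r["I_after"]],
            R_before=spectra[r["R_before"]],
            R_after=spectra[r["R_after"]],
            specularity_level=int(r["specularity_level"]),
            motion_condition=r["motion_condition"],
            rotation_sign=int(r["rotation_sign"]),
            object_type=r["object_type"],
            seed=int(r["seed"]),
        ))
    return SessionSchedule(tuple(trials), n_blocks=n_blocks)
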