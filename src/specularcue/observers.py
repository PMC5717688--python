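"""Model observers: classify trials from a single image chromatic statistic.

A model observer has perfect colour discrimination and no internal noise;
its only limit is the overlap of the stimulus ensemble as seen through its
statistic.  Two statistics are implemented: the luminance-weighted mean
chromaticity of the brightest fraction of object pixels ("brightest
pixel"), and the luminance-weighted mean chromaticity of the whole object
("mean chromaticity" — the limiting case of the former with fraction 1).
For each trial the observer compares the statistic in the first and last
frames and feeds the change vector (delta l_mb, delta s_mb, delta log
luminance) to a two-class quadratic discriminant trained on an
independently generated labelled ensemble for the same specularity level
and condition (equal priors, ties broken toward "illuminant").  The rule
must be quadratic: both change directions occur for both classes, so the
class-conditional change vectors have coinciding means and differ only in
their covariance — the specular component damps the statistic's change on
reflectance trials — and the likelihood-ratio rule for zero-mean classes
is a comparison of quadratic forms, which no linear boundary can express.

Because specular highlights carry the illuminant chromaticity, the
brightest-pixel statistic tracks the illuminant increasingly well as
specularity grows, so its discriminability rises steeply with specularity;
the mean-chromaticity statistic dilutes the specular signal over the whole
object and rises much more slowly.  At zero specularity the matched design
leaves both statistics uninformative and performance sits at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

from .design import SessionSchedule, TrialSpec, select_matched_pairs, build_schedule
from .scene import (
    SPECULARITY_LEVELS,
    ChromaticityImage,
    SceneConfig,
    SceneState,
    ShadingMaps,
    SurfaceMaterial,
    TurbulenceField,
    final_state,
    render_chromaticity_image,
    render_shading_maps,
)
from .spectra import DEFAULT_GRID, Chromaticity, Spectrum, cone_fundamentals

__all__ = [
    "ObserverSpec",
    "TrainedObserver",
    "StimulusRenderer",
    "brightest_pixel_statistic",
    "mean_chromaticity_statistic",
    "classify_trial",
    "train_observer",
    "simulate_model_observer",
    "model_observer_experiment",
]

#: Default "brightest pixels" set: top 0.1% of on-mask pixels by luminance.
DEFAULT_BRIGHTEST_FRACTION = 1e-3


@dataclass(frozen=True)
class ObserverSpec:
    """Which statistic an observer reads, and its parameters."""

    statistic: str = "brightest_pixel"  # or "mean_chromaticity"
    brightest_fraction: float = DEFAULT_BRIGHTEST_FRACTION
    seed: int = 0

    def __post_init__(self):
        if self.statistic not in ("brightest_pixel", "mean_chromaticity"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if not 0.0 < self.brightest_fraction <= 1.0:
            raise ValueError("brightest_fraction must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Image statistics
# ---------------------------------------------------------------------------

def _weighted_stat(l_mb, s_mb, lum) -> Chromaticity:
    w = lum.sum()
    if w <= 0:
        raise ValueError("statistic undefined: selected pixels carry no luminance")
    return Chromaticity(
        float((l_mb * lum).sum() / w),
        float((s_mb * lum).sum() / w),
        float(lum.mean()),
    )


def brightest_pixel_statistic(frame: ChromaticityImage,
                              fraction: float = DEFAULT_BRIGHTEST_FRACTION) -> Chromaticity:
    """Luminance-weighted mean chromaticity of the brightest object pixels.

    Selects the top ``fraction`` of on-mask pixels by luminance (at least
    one pixel); ``fraction = 1`` reduces to the whole-image mean.
    """
    if not np.any(frame.mask):
        raise ValueError("empty object mask")
    lum = frame.lum[frame.mask]
    l_mb = frame.l_mb[frame.mask]
    s_mb = frame.s_mb[frame.mask]
    k = max(1, int(round(fraction * lum.size)))
    if k < lum.size:
        idx = np.argpartition(lum, -k)[-k:]
        lum, l_mb, s_mb = lum[idx], l_mb[idx], s_mb[idx]
    return _weighted_stat(l_mb, s_mb, lum)


def mean_chromaticity_statistic(frame: ChromaticityImage) -> Chromaticity:
    """Luminance-weighted mean chromaticity over all object pixels."""
    return brightest_pixel_statistic(frame, fraction=1.0)


def frame_statistic(frame: ChromaticityImage, spec: ObserverSpec) -> Chromaticity:
    if spec.statistic == "mean_chromaticity":
        return mean_chromaticity_statistic(frame)
    return brightest_pixel_statistic(frame, spec.brightest_fraction)


def change_vector(first: Chromaticity, last: Chromaticity) -> np.ndarray:
    """The decision feature: (delta l_mb, delta s_mb, delta log10 lum)."""
    return np.array([
        last.l_mb - first.l_mb,
        last.s_mb - first.s_mb,
        np.log10(last.lum) - np.log10(first.lum),
    ])


# ---------------------------------------------------------------------------
# Rendering service with map reuse
# ---------------------------------------------------------------------------

class StimulusRenderer:
    """Renders first/last frames for trials of one (object, condition) cell.

    Shading maps depend only on geometry — the object's relief or texture
    variant, the motion condition and the rotation sign — never on the
    spectra or the specularity level (the specular map scales linearly with
    specularity).  Maps are therefore cached per (variant, sign) at unit
    specularity and reused across all spectral trials and levels, which is
    what makes ensembles of thousands of trials cheap.  Texture/bump
    variants are drawn from a deterministic pool indexed by the trial seed.
    """

    def __init__(self, config: SceneConfig, object_type: str,
                 motion_condition: str, n_variants: int = 8,
                 base_seed: int = 0, bump_amplitude: float = 0.05):
        self.config = config
        self.object_type = object_type
        self.motion_condition = motion_condition
        self.n_variants = n_variants
        self.base_seed = base_seed
        self.bump_amplitude = bump_amplitude
        self._cache: dict = {}
        self._fundamentals = None

    def _material(self, variant: int, reflectance: Spectrum) -> SurfaceMaterial:
        seed = self.base_seed * 1000 + variant
        if self.object_type == "marbled":
            tex = TurbulenceField(seed=seed, octaves=3, base_freq=2.5)
            return SurfaceMaterial(reflectance, specularity=0.1, texture=tex)
        bump = TurbulenceField(seed=seed, octaves=3, base_freq=6.0,
                               amplitude=self.bump_amplitude)
        return SurfaceMaterial(reflectance, specularity=0.1, bump=bump)

    def _unit_maps(self, variant: int, sign: int):
        """(first, last) ShadingMaps with the specular map at unit scale."""
        key = (variant, sign)
        if key not in self._cache:
            # any reflectance works: maps are spectrum-independent
            grid = DEFAULT_GRID
            dummy = Spectrum(grid, np.full(grid.size, 0.5), role="reflectance")
            flat = Spectrum(grid, np.ones(grid.size), role="illuminant")
            mat = self._material(variant, dummy)
            probe = TrialSpec("illuminant", flat, flat, dummy, dummy,
                              motion_condition=self.motion_condition,
                              rotation_sign=sign)
            first = render_shading_maps(self.config, mat, SceneState())
            last = render_shading_maps(self.config, mat, final_state(probe))
            unit = []
            for m in (first, last):
                unit.append(ShadingMaps(a=m.a / mat.specularity, b=m.b, mask=m.mask))
            self._cache[key] = tuple(unit)
        return self._cache[key]

    def trial_frames(self, trial: TrialSpec):
        """ChromaticityImages of the first and last frames of ``trial``."""
        variant = trial.seed % self.n_variants
        first_u, last_u = self._unit_maps(variant, trial.rotation_sign)
        s = trial.specularity
        if self._fundamentals is None:
            self._fundamentals = cone_fundamentals(trial.I_before.wavelengths)
        f = render_chromaticity_image(
            ShadingMaps(first_u.a * s, first_u.b, first_u.mask),
            trial.I_before, trial.R_before, self._fundamentals)
        l = render_chromaticity_image(
            ShadingMaps(last_u.a * s, last_u.b, last_u.mask),
            trial.I_after, trial.R_after, self._fundamentals)
        return f, l

    def trial_feature(self, trial: TrialSpec, spec: ObserverSpec) -> np.ndarray:
        f, l = self.trial_frames(trial)
        return change_vector(frame_statistic(f, spec), frame_statistic(l, spec))


# ---------------------------------------------------------------------------
# Decision model
# ---------------------------------------------------------------------------

@dataclass
class TrainedObserver:
    """An :class:`ObserverSpec` plus its fitted discriminant."""

    spec: ObserverSpec
    model: QuadraticDiscriminantAnalysis

    def predict(self, feature: np.ndarray) -> str:
        score = float(self.model.decision_function(feature.reshape(1, -1))[0])
        # classes_ is ("illuminant", "reflectance"); positive scores favour
        # the second class, and exact ties resolve to "illuminant".
        return "reflectance" if score > 0 else "illuminant"


def train_observer(features: np.ndarray, labels, spec: ObserverSpec) -> TrainedObserver:
    """Fit the equal-prior quadratic discriminant on labelled change vectors.

    A small covariance regularizer keeps the fit stable when a class's
    change vectors are nearly collinear (for example at high specularity,
    where reflectance-trial changes collapse toward zero)."""
    labels = np.asarray(labels)
    if set(labels) != {"illuminant", "reflectance"}:
        raise ValueError("training labels must contain both classes")
    model = QuadraticDiscriminantAnalysis(priors=[0.5, 0.5], reg_param=1e-4)
    model.fit(np.asarray(features), labels)
    return TrainedObserver(spec, model)


def classify_trial(first_stat: Chromaticity, last_stat: Chromaticity,
                   observer: TrainedObserver) -> str:
    """Deterministic label from the statistic-change vector."""
    return observer.predict(change_vector(first_stat, last_stat))


# ---------------------------------------------------------------------------
# Ensemble simulation
# ---------------------------------------------------------------------------

def _ensemble_features(renderer: StimulusRenderer, trials, spec: ObserverSpec):
    X = np.array([renderer.trial_feature(t, spec) for t in trials])
    y = np.array([t.change_type for t in trials])
    return X, y


def simulate_model_observer(schedule: SessionSchedule, renderer: StimulusRenderer,
                            spec: ObserverSpec, trained_by_level: dict,
                            observer_name: str | None = None) -> pd.DataFrame:
    """One deterministic response per schedule trial.

    ``trained_by_level`` maps specularity level -> :class:`TrainedObserver`
    fitted on an ensemble disjoint from the schedule's trials.
    """
    rows = []
    name = observer_name or f"model_{spec.statistic}"
    for t in schedule.trials:
        if t.specularity_level not in trained_by_level:
            raise KeyError(f"no trained model for specularity level {t.specularity_level}")
        obs = trained_by_level[t.specularity_level]
        feature = renderer.trial_feature(t, spec)
        rows.append({
            "observer": name,
            "object_type": t.object_type,
            "motion_condition": t.motion_condition,
            "specularity_level": t.specularity_level,
            "truth": t.change_type,
            "response": obs.predict(feature),
        })
    return pd.DataFrame(rows)


def model_observer_experiment(illuminants, library, object_type: str,
                              motion_condition: str,
                              specs: tuple = (
                                  ObserverSpec("brightest_pixel"),
                                  ObserverSpec("mean_chromaticity"),
                              ),
                              *, config: SceneConfig | None = None,
                              n_train_per_class: int = 1000,
                              n_eval_per_class: int = 500,
                              levels=None, seed: int = 0) -> pd.DataFrame:
    """Train and evaluate model observers over the specularity levels.

    For each level and each observer statistic, a discriminant is trained
    on a matched ensemble generated with one seed and evaluated on a
    disjoint matched ensemble generated with another; the evaluation
    responses for all observers are returned as one long-format table.
    """
    config = config or SceneConfig()
    levels = list(range(len(SPECULARITY_LEVELS))) if levels is None else list(levels)
    renderer = StimulusRenderer(config, object_type, motion_condition,
                                base_seed=seed)
    rng = np.random.default_rng(seed)
    train_seed = int(rng.integers(0, 2**31 - 1))
    eval_seed = int(rng.integers(0, 2**31 - 1))

    def matched_trials(n, s):
        ill, refl, _ = select_matched_pairs(library, illuminants, n, seed=s)
        return ill, refl

    ill_tr, refl_tr = matched_trials(n_train_per_class, train_seed)
    ill_ev, refl_ev = matched_trials(n_eval_per_class, eval_seed)

    def assign(trials, lvl, s0):
        rng2 = np.random.default_rng(s0)
        return [dc_replace(t, specularity_level=lvl,
                           motion_condition=motion_condition,
                           object_type=object_type,
                           rotation_sign=int(rng2.choice([-1, 1])),
                           seed=int(rng2.integers(0, 2**31 - 1)))
                for t in trials]

    def features_all_specs(trials):
        """One frame render per trial, shared by every statistic."""
        out = {i: [] for i in range(len(specs))}
        labels = []
        for t in trials:
            f, l = renderer.trial_frames(t)
            for i, spec in enumerate(specs):
                out[i].append(change_vector(frame_statistic(f, spec),
                                            frame_statistic(l, spec)))
            labels.append(t.change_type)
        return {i: np.array(v) for i, v in out.items()}, np.array(labels)

    tables = []
    for lvl in levels:
        train = assign(ill_tr + refl_tr, lvl, train_seed + lvl)
        evals = assign(ill_ev + refl_ev, lvl, eval_seed + lvl)
        X_train, y_train = features_all_specs(train)
        X_eval, y_eval = features_all_specs(evals)
        for i, spec in enumerate(specs):
            obs = train_observer(X_train[i], y_train, spec)
            for feature, truth in zip(X_eval[i], y_eval):
                tables.append({
                    "observer": f"model_{spec.statistic}",
                    "object_type": object_type,
                    "motion_condition": motion_condition,
                    "specularity_level": lvl,
                    "truth": truth,
                    "response": obs.predict(feature),
                })
    return pd.DataFrame(tables)
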