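"""Analytic shading of glossy spheres under three point lights.

A single sphere floats in a void, lit by three equal-intensity directional
sources that all share one spectral power distribution I(lambda).  The
sphere either has a smooth surface with a marbled reflectance-intensity
pattern ("marbled") or a procedurally bumped surface with uniform
reflectance ("bumpy"); patterning and bumpiness never co-occur.  Shading is
computed analytically per pixel under orthographic projection — no
raytracing, shadows or inter-reflections — because the chromatic structure
of the task needs only the per-pixel two-component mixture

    radiance(pixel) = a * I + b * I * R

with ``b = texture * sum_j max(0, n . l_j)`` (Lambertian diffuse) and
``a = specularity * sum_j ward(n, l_j, v)`` (isotropic Ward lobe, roughness
alpha = 0.15).  The maps (a, b) fully determine the image for any choice of
spectra, which the rest of the package exploits: one geometry render serves
every spectral condition.

Motion conditions rotate exactly one of {image, object, lights} about the
visual axis (VA, the viewing direction) or the vertical axis perpendicular
to it (PA).  Rotating the object carries its surface-attached texture or
bump field with it; rotating the lights moves the highlights while the
surface pattern stays put; rotating the image is a rigid in-plane rotation
of the composite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import (
    Spectrum,
    cone_excitations,
    cone_fundamentals,
    macleod_boynton_arrays,
    mixture_spectrum,
)

__all__ = [
    "MOTION_CONDITIONS",
    "SceneConfig",
    "SurfaceMaterial",
    "SceneState",
    "ShadingMaps",
    "ChromaticityImage",
    "TurbulenceField",
    "marble_texture",
    "sphere_geometry",
    "shading_coefficients",
    "render_shading_maps",
    "render_chromaticity_image",
    "apply_motion",
    "animate_trial",
    "max_image_speed_va",
    "max_image_speed_pa",
]

#: The six motion conditions: two controls and four experimental.
MOTION_CONDITIONS = (
    "NoMotion",
    "ImageVA",
    "ObjectVA",
    "LightsVA",
    "ObjectPA",
    "LightsPA",
)

#: Five specularity levels: matte plus four logarithmically spaced values.
SPECULARITY_LEVELS = (0.0, 10 ** -2.5, 10 ** -2.0, 10 ** -1.5, 10 ** -1.0)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _sph_dir(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Unit vector from azimuth/elevation; +z toward the viewer, +y up."""
    az, el = np.radians(azimuth_deg), np.radians(elevation_deg)
    return np.array(
        [np.cos(el) * np.sin(az), np.sin(el), np.cos(el) * np.cos(az)]
    )


# Default light placement: three distinct directions in the front
# hemisphere (azimuth, elevation in degrees), equal intensity.
_DEFAULT_LIGHTS = ((-40.0, 25.0), (15.0, 50.0), (45.0, 10.0))


@dataclass(frozen=True)
class SceneConfig:
    """Viewing geometry and sampling for one rendered scene."""

    image_size: int = 128
    stimulus_extent_deg: float = 7.1
    sphere_angular_radius_deg: float = 3.55
    light_directions: tuple = tuple(_sph_dir(*ae) for ae in _DEFAULT_LIGHTS)
    view_direction: tuple = (0.0, 0.0, 1.0)
    frame_rate_hz: float = 60.0

    def __post_init__(self):
        if len(self.light_directions) != 3:
            raise ValueError("the scene is lit by exactly three light sources")
        if self.stimulus_extent_deg <= 0 or self.sphere_angular_radius_deg <= 0:
            raise ValueError("angular sizes must be positive")
        object.__setattr__(
            self, "light_directions", tuple(_unit(l) for l in self.light_directions)
        )
        object.__setattr__(self, "view_direction", tuple(_unit(self.view_direction)))


@dataclass(frozen=True)
class SurfaceMaterial:
    """Surface optics: reflectance spectrum, specularity and relief/pattern.

    ``specularity`` is the fraction of incident light reflected in the
    specular component (0 = matte; 0.1 is the glossiest level used).
    ``roughness`` is the Ward lobe width alpha.  ``texture`` (marble
    pattern) and ``bump`` (radial displacement field) are mutually
    exclusive.
    """

    reflectance: Spectrum
    specularity: float = 0.0
    roughness: float = 0.15
    texture: "TurbulenceField | None" = None
    bump: "TurbulenceField | None" = None

    def __post_init__(self):
        if not (0.0 <= self.specularity <= 0.1 + 1e-12):
            raise ValueError("specularity must lie in [0, 0.1]")
        if self.roughness <= 0:
            raise ValueError("roughness must be positive")
        if self.texture is not None and self.bump is not None:
            raise ValueError("patterning and bumpiness never co-occur on one object")


@dataclass(frozen=True)
class SceneState:
    """Current orientation of the object, the lights and the image plane."""

    object_rot: np.ndarray = field(default_factory=lambda: np.eye(3))
    lights_rot: np.ndarray = field(default_factory=lambda: np.eye(3))
    image_angle_deg: float = 0.0


@dataclass(frozen=True)
class ShadingMaps:
    """Per-pixel mixture coefficients for one scene state.

    ``a`` multiplies the specular component I, ``b`` the diffuse component
    I*R; both are zero off-mask.  Zero specularity forces ``a == 0``.
    """

    a: np.ndarray
    b: np.ndarray
    mask: np.ndarray


@dataclass(frozen=True)
class ChromaticityImage:
    """Per-pixel MacLeod-Boynton coordinates with an object mask.

    Off-mask (and radiance-free) pixels are flagged False in ``mask`` and
    carry NaN chromaticity, never silently propagated."""

    l_mb: np.ndarray
    s_mb: np.ndarray
    lum: np.ndarray
    mask: np.ndarray


# ---------------------------------------------------------------------------
# Procedural noise: band-limited trig value noise with analytic gradients
# ---------------------------------------------------------------------------

class TurbulenceField:
    """Smooth procedural noise on R^3 built from random cosine waves.

    ``value(p)`` sums octaves of band-limited value noise; the gradient is
    analytic, which the bumpy-sphere normals use.  ``turbulence(p)`` sums
    absolute octaves (the classic marble driver).  Deterministic given the
    seed, and evaluated in object coordinates so the field is rigidly
    attached to the surface.
    """

    def __init__(self, seed: int = 0, octaves: int = 3, base_freq: float = 2.5,
                 waves_per_octave: int = 8, amplitude: float = 1.0):
        rng = np.random.default_rng(seed)
        self.amplitude = float(amplitude)
        self._octaves = []
        for o in range(octaves):
            k = base_freq * (2.0 ** o)
            dirs = rng.normal(size=(waves_per_octave, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            phases = rng.uniform(0, 2 * np.pi, size=waves_per_octave)
            weight = 0.5 ** o
            self._octaves.append((k, dirs, phases, weight))
        # normalize so value() has unit-ish range
        self._norm = 1.0 / sum(w for *_, w in self._octaves)

    def value(self, points: np.ndarray) -> np.ndarray:
        """Signed noise in roughly [-1, 1] at points of shape (..., 3)."""
        acc = 0.0
        for k, dirs, phases, w in self._octaves:
            phase = k * points @ dirs.T + phases  # (..., W)
            acc = acc + w * np.cos(phase).mean(axis=-1)
        return self.amplitude * self._norm * acc

    def gradient(self, points: np.ndarray) -> np.ndarray:
        """Analytic gradient of :meth:`value`, shape (..., 3)."""
        acc = 0.0
        for k, dirs, phases, w in self._octaves:
            phase = k * points @ dirs.T + phases
            acc = acc + w * (-np.sin(phase)[..., None] * (k * dirs)).mean(axis=-2)
        return self.amplitude * self._norm * acc

    def turbulence(self, points: np.ndarray) -> np.ndarray:
        """Sum of absolute octaves, in [0, ~1]."""
        acc = 0.0
        for k, dirs, phases, w in self._octaves:
            phase = k * points @ dirs.T + phases
            acc = acc + w * np.abs(np.cos(phase).mean(axis=-1))
        return self.amplitude * self._norm * acc


def marble_texture(points: np.ndarray, noise: TurbulenceField,
                   stripe_freq: float = 4.0, turb_gain: float = 4.0,
                   lo: float = 0.3) -> np.ndarray:
    """Marble-like diffuse intensity scale in [lo, 1] at surface points.

    A sinusoidal banding along one object axis, phase-distorted by the
    turbulence field.  The pattern contrast is scaled by the field's
    amplitude (clipped to 1): zero amplitude gives a constant scale of 1,
    unit amplitude the full [lo, 1] range.  Deterministic given the
    field's seed, and attached to object coordinates.
    """
    contrast = min(1.0, abs(noise.amplitude))
    if contrast == 0.0:
        return np.ones(points.shape[:-1])
    phase = stripe_freq * points[..., 0] + turb_gain * noise.turbulence(points)
    band = 0.5 + 0.5 * np.sin(phase)
    return 1.0 - (1.0 - lo) * contrast * band


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _rot_z(angle_deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def _rot_y(angle_deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])


def sphere_geometry(config: SceneConfig, material: SurfaceMaterial,
                    state: SceneState):
    """Per-pixel surface normals, object-frame surface points and mask.

    The sphere has unit radius and fills the square image
    (half-width = image half-extent); projection is orthographic with the
    viewer along +z.  An in-plane image rotation is applied exactly by
    rotating the pixel sampling coordinates.  For bumpy spheres the radius
    field is ``rho = 1 + h`` with ``h`` the (object-attached) noise value,
    and the normal of the displaced surface is the analytic

        n  ∝  u - (I - u u^T) grad_h / rho

    with ``u`` the unit radial direction.  A zero-amplitude bump field
    reduces exactly to the smooth sphere.

    Returns ``(normals, points_obj, mask)``: normals in world coordinates
    (..., 3), surface points in object coordinates, and the boolean mask.
    """
    n_px = config.image_size
    # pixel centres in sphere units, x rightward, y downward (image
    # convention); world y is up, so flip the sign.
    half = 1.0
    coords = (np.arange(n_px) + 0.5) / n_px * 2 * half - half
    px, py = np.meshgrid(coords, coords)
    # positive VA rotation = anticlockwise in the displayed image: sample
    # the un-rotated scene at coordinates rotated clockwise.
    ang = np.radians(state.image_angle_deg)
    if ang != 0.0:
        c, s = np.cos(ang), np.sin(ang)
        px, py = c * px + s * py, -s * px + c * py
    x = px
    y = -py  # world up
    rr = x * x + y * y
    mask = rr <= 1.0
    z = np.sqrt(np.clip(1.0 - rr, 0.0, None))
    u = np.stack([x, y, z], axis=-1)  # unit radial dirs, world frame
    u[~mask] = 0.0

    # object-frame surface directions (texture/bump attach here)
    Robj = state.object_rot
    u_obj = u @ Robj  # == Robj.T applied to each row vector

    if material.bump is not None and material.bump.amplitude != 0.0:
        h = material.bump.value(u_obj)
        grad_obj = material.bump.gradient(u_obj)
        grad = grad_obj @ Robj.T  # back to world frame
        # tangential projection of the gradient
        gn = np.einsum("...i,...i->...", grad, u)[..., None]
        tang = grad - gn * u
        rho = 1.0 + h
        n = u - tang / rho[..., None]
        n /= np.linalg.norm(n, axis=-1, keepdims=True) + 1e-30
        points_obj = (rho[..., None]) * u_obj
    else:
        n = u
        points_obj = u_obj
    n = np.where(mask[..., None], n, 0.0)
    return n, points_obj, mask


def _ward_lobe(n, l, v, alpha):
    """Isotropic Ward specular term per pixel, already times cos(theta_i).

    BRDF = exp(-tan^2 theta_h / alpha^2) / (4 pi alpha^2 sqrt(cos_i cos_r));
    the returned quantity is BRDF * cos_i, the radiance factor for a unit
    directional source.  Zero wherever the light or viewer is below the
    local horizon.
    """
    h = _unit(np.asarray(l) + np.asarray(v))
    cos_h = np.clip(np.einsum("...i,i->...", n, h), 0.0, 1.0)
    cos_i = np.einsum("...i,i->...", n, np.asarray(l))
    cos_r = np.einsum("...i,i->...", n, np.asarray(v))
    lit = (cos_i > 1e-9) & (cos_r > 1e-9) & (cos_h > 1e-9)
    out = np.zeros(n.shape[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tan2 = (1.0 - cos_h**2) / np.maximum(cos_h**2, 1e-30)
        brdf = np.exp(-tan2 / alpha**2) / (
            4 * np.pi * alpha**2 * np.sqrt(np.maximum(cos_i * cos_r, 1e-30))
        )
        out = np.where(lit, brdf * cos_i, 0.0)
    return out


def shading_coefficients(geometry, material: SurfaceMaterial, lights,
                         view) -> ShadingMaps:
    """Per-pixel mixture coefficients (a, b) from geometry and material.

    ``b = texture_scale * sum_j max(0, n.l_j)`` and ``a = specularity * pi *
    sum_j ward(n, l_j, v)``; occluded lights contribute to neither term.
    The factor pi absorbed into the specular scale makes ``specularity``
    the ratio of specular to diffuse albedo against an energy-conserving
    Lambertian base (whose BRDF is rho/pi): with it, the glossiest level
    (0.1) yields highlight pixels dominated by the specular component, as
    a glossy dielectric shows.
    """
    normals, points_obj, mask = geometry
    view = _unit(view)
    b = np.zeros(mask.shape)
    a = np.zeros(mask.shape)
    for l in lights:
        l = _unit(l)
        cos_i = np.einsum("...i,i->...", normals, l)
        b += np.clip(cos_i, 0.0, None)
        if material.specularity > 0:
            a += _ward_lobe(normals, l, view, material.roughness)
    a *= material.specularity * np.pi
    if material.texture is not None:
        b *= marble_texture(points_obj, material.texture)
    a = np.where(mask, a, 0.0)
    b = np.where(mask, b, 0.0)
    return ShadingMaps(a=a, b=b, mask=mask)


def render_shading_maps(config: SceneConfig, material: SurfaceMaterial,
                        state: SceneState) -> ShadingMaps:
    """Geometry plus shading in one call (the common path)."""
    geom = sphere_geometry(config, material, state)
    lights = [state.lights_rot @ l for l in config.light_directions]
    return shading_coefficients(geom, material, lights, config.view_direction)


def render_chromaticity_image(maps: ShadingMaps, I: Spectrum, R: Spectrum,
                              fundamentals=None) -> ChromaticityImage:
    """Per-pixel chromaticity of the mixture a*I + b*I*R.

    Uses the linearity of cone excitations: LMS(pixel) = a * LMS(I) +
    b * LMS(I*R), identical to integrating the per-pixel spectrum.
    Pixels with zero total radiance are flagged off-mask, not NaN-poisoned.
    """
    if fundamentals is None:
        fundamentals = cone_fundamentals(I.wavelengths)
    lms_spec = cone_excitations(I, fundamentals).as_array()
    lms_diff = cone_excitations(
        I.with_values(I.values * R.values, role="radiance"), fundamentals
    ).as_array()
    L = maps.a * lms_spec[0] + maps.b * lms_diff[0]
    M = maps.a * lms_spec[1] + maps.b * lms_diff[1]
    S = maps.a * lms_spec[2] + maps.b * lms_diff[2]
    l_mb, s_mb, lum = macleod_boynton_arrays(L, M, S)
    ok = maps.mask & (lum > 0)
    return ChromaticityImage(l_mb=l_mb, s_mb=s_mb, lum=lum, mask=ok)


def recompose_pixel_spectrum(maps: ShadingMaps, I: Spectrum, R: Spectrum,
                             i: int, j: int) -> Spectrum:
    """Independent per-pixel spectral recomposition (testing / export path)."""
    return mixture_spectrum(I, R, float(maps.a[i, j]), float(maps.b[i, j]))


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------

def apply_motion(state: SceneState, condition: str, angle_deg: float) -> SceneState:
    """Rotate exactly one of {image, object, lights} by ``angle_deg``.

    VA rotations are about the visual (viewing) axis; PA rotations about
    the vertical axis perpendicular to it.  ``NoMotion`` is the identity.
    """
    if abs(angle_deg) > 30.0 + 1e-9:
        raise ValueError("rotation angle magnitude exceeds the 30 degree range")
    if condition == "NoMotion":
        return state
    if condition == "ImageVA":
        return replace(state, image_angle_deg=state.image_angle_deg + angle_deg)
    if condition == "ObjectVA":
        return replace(state, object_rot=_rot_z(angle_deg) @ state.object_rot)
    if condition == "LightsVA":
        return replace(state, lights_rot=_rot_z(angle_deg) @ state.lights_rot)
    if condition == "ObjectPA":
        return replace(state, object_rot=_rot_y(angle_deg) @ state.object_rot)
    if condition == "LightsPA":
        return replace(state, lights_rot=_rot_y(angle_deg) @ state.lights_rot)
    raise ValueError(f"unknown motion condition {condition!r}")


#: Animation timing: static lead-in, dynamic period, static tail (seconds).
STATIC_DURATION_S = 0.50
DYNAMIC_DURATION_S = 1.0 / 3.0  # 20 frames at 60 Hz; prints as 0.33 s
ROTATION_SPEED_DEG_S = 90.0


@dataclass(frozen=True)
class AnimationFrame:
    time_s: float
    state: SceneState
    I: Spectrum
    R: Spectrum


def animate_trial(trial, config: SceneConfig,
                  static_s: float = STATIC_DURATION_S,
                  dynamic_s: float = DYNAMIC_DURATION_S,
                  speed_deg_s: float = ROTATION_SPEED_DEG_S):
    """Frame sequence for one trial: static, simultaneous change, static.

    The spectral change (I1 -> I2 or R1 -> R2, linear in spectral space)
    and the rotation (constant speed, abrupt onset/offset) both span the
    dynamic period.  Total rotation must equal speed * duration within half
    a degree, otherwise the recipe is inconsistent.  Returns
    ``(frames, first_frame, last_frame)``.
    """
    total_angle = speed_deg_s * dynamic_s
    if abs(total_angle) > 30.0 + 0.5:
        raise ValueError(
            f"rotation {total_angle:.1f} deg inconsistent with the +/-30 deg design"
        )
    fps = config.frame_rate_hz
    n_static = round(static_s * fps)
    n_dyn = round(dynamic_s * fps)
    angle_per_frame = trial.rotation_sign * speed_deg_s / fps

    def lerp_spec(s0: Spectrum, s1: Spectrum, t: float) -> Spectrum:
        return s0.with_values((1 - t) * s0.values + t * s1.values)

    frames = []
    state = SceneState()
    t = 0.0
    for _ in range(n_static):
        frames.append(AnimationFrame(t, state, trial.I_before, trial.R_before))
        t += 1.0 / fps
    for k in range(1, n_dyn + 1):
        if trial.motion_condition != "NoMotion":
            state = apply_motion(state, trial.motion_condition, angle_per_frame)
        frac = k / n_dyn
        frames.append(AnimationFrame(
            t, state,
            lerp_spec(trial.I_before, trial.I_after, frac),
            lerp_spec(trial.R_before, trial.R_after, frac),
        ))
        t += 1.0 / fps
    for _ in range(n_static):
        frames.append(AnimationFrame(t, state, trial.I_after, trial.R_after))
        t += 1.0 / fps
    return frames, frames[0], frames[-1]


def final_state(trial, config: SceneConfig | None = None) -> SceneState:
    """The scene state after the dynamic period (no intermediate frames)."""
    angle = trial.rotation_sign * ROTATION_SPEED_DEG_S * DYNAMIC_DURATION_S
    return apply_motion(SceneState(), trial.motion_condition, angle)


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def max_image_speed_va(config: SceneConfig,
                       speed_deg_s: float = ROTATION_SPEED_DEG_S) -> float:
    """Max linear image speed (deg of visual angle / s) for VA rotations.

    A point at the sphere's outer edge traces a circle of angular radius
    equal to the sphere's angular radius; its linear speed is the rotation
    rate (in rad/s) times that radius.
    """
    omega = math.radians(speed_deg_s)
    return omega * config.sphere_angular_radius_deg


def max_image_speed_pa(config: SceneConfig,
                       speed_deg_s: float = ROTATION_SPEED_DEG_S) -> float:
    """Max lateral image speed across the sphere centre for PA rotations.

    Under orthographic projection a surface point at the front pole moves
    laterally at omega * R; expressed in visual angle that is omega (rad/s)
    times the sphere's angular radius.  (Perspective magnification of a
    near virtual camera would scale this up; this package reports its own
    orthographic value.)
    """
    omega = math.radians(speed_deg_s)
    return omega * config.sphere_angular_radius_deg


# ---------------------------------------------------------------------------
# Preview export
# ---------------------------------------------------------------------------

def preview_rgb(img: ChromaticityImage) -> np.ndarray:
    """8-bit pseudo-colour preview of a chromaticity image (display only).

    Maps (l_mb, s_mb, lum) to RGB by reconstructing LMS and applying a
    fixed LMS->RGB mixing matrix with a gamma of 1/2.2; not a calibrated
    rendering.
    """
    lum = np.where(img.mask, img.lum, 0.0)
    L = np.where(img.mask, img.l_mb, 0.0) * lum
    M = lum - L
    S = np.where(img.mask, img.s_mb, 0.0) * lum
    mix = np.array([[4.0, -3.0, 0.1], [-1.0, 2.0, -0.1], [0.0, -0.3, 1.3]])
    rgb = np.stack([L, M, S], axis=-1) @ mix.T
    rgb = np.clip(rgb, 0.0, None)
    peak = rgb.max() or 1.0
    rgb = (rgb / peak) ** (1 / 2.2)
    return (255 * rgb).astype(np.uint8)
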