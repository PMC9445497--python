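"""Synthetic multi-channel scenes with known latent components.

Scenes emulate the situation the correction is built for: an elliptical
"embryo" whose autofluorescence (AF) is a smooth, spatially varying field
appearing in both the primary and the red-shifted predictor channel in exact
linear proportion, plus an independent fluorophore component confined to the
primary channel (with optional proportional spillover into the predictor),
and an optional red fluorophore bleeding into the predictor channel.  AF
magnitude varies between samples over a roughly two-fold range, matching the
inter-sample variability seen in real embryos.  Per-pixel noise is additive
Gaussian with an optional signal-proportional (camera-like) variance term.

Every latent component is stored exactly alongside the rendered noisy
channels, so calibration, correction and quantification can be validated
end-to-end against ground truth.  All randomness flows from one explicit
seed; there is no global random state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError
from .image_io import ChannelStack
from .quantify import Contour

GFP_LAYOUTS = ("none", "uniform_cytoplasm", "membrane_band", "nuclear_void")


@dataclass
class SceneParams:
    """Generating parameters for one synthetic scene (or a cohort).

    The AF mapping between channels is ``G_af = m_true * A_af + c_true``
    (slopes dimensionless, ``c_true`` in primary-channel detector units).
    ``rfp_bleed_true`` is the proportional bleedthrough of the red fluorophore
    into the AF predictor channel (``A_rfp = rfp_bleed_true * R_rfp``); note
    that the three-channel regression consequently recovers a *negative*
    coefficient on R, ``m2 = -m_true * rfp_bleed_true``, since red signal in A
    mimics AF that is absent from the primary channel.  ``s_true`` is the
    fluorophore spillover slope into A (``A_gfp = s_true * G_gfp``).

    AF per sample: each scene draws its own mean AF level as
    ``af_base_level * af_fold_range ** U(-1/2, +1/2)``, giving the stated
    ~``af_fold_range``-fold spread between the dimmest and brightest samples;
    spatial texture is low-pass-filtered white noise with correlation length
    ``af_texture_scale`` (pixels) and relative amplitude
    ``af_texture_strength``.

    Noise: per-pixel sd is ``sqrt(noise_sd^2 + noise_poisson_gain * signal)``.
    """

    shape: tuple = (140, 200)
    ellipse_radii: tuple = (50.0, 80.0)   # (y, x) semi-axes, pixels
    ellipse_center: tuple | None = None   # defaults to the image center
    roi_margin: float = 15.0              # background ring included in the ROI;
                                          # wide enough to cover the blurred AF falloff

    m_true: float = 1.8
    c_true: float = 100.0
    rfp_bleed_true: float = 0.05
    s_true: float = 0.0

    af_base_level: float = 200.0
    af_fold_range: float = 2.0
    af_texture_scale: float = 8.0
    af_texture_strength: float = 0.2
    af_edge_softening: float = 3.0        # smooth AF falloff at the boundary, px
    af_void: bool = False                 # interior AF-exclusion blob
    af_void_depth: float = 0.6
    af_void_sigma: float = 12.0

    gfp_layout: str = "none"
    gfp_amplitude: float = 0.0
    gfp_band_width: float = 2.5           # membrane band Gaussian sigma, pixels
    nuclear_void_sigma: float = 15.0

    rfp_amplitude: float = 0.0
    include_rfp_channel: bool = False

    # second, independently varying AF source (punctate granules) with its
    # own A->G slope; exercises the known single-source limitation
    second_af_amplitude: float = 0.0
    second_af_slope: float = 0.5
    second_af_n_granules: int = 60
    second_af_sigma: float = 2.0

    noise_sd: float = 5.0
    noise_poisson_gain: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gfp_layout not in GFP_LAYOUTS:
            raise ParameterError(f"gfp_layout must be one of {GFP_LAYOUTS}, got {self.gfp_layout!r}")
        for name in ("gfp_amplitude", "rfp_amplitude", "af_base_level",
                     "noise_sd", "noise_poisson_gain", "second_af_amplitude"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.gfp_layout == "membrane_band" and self.gfp_band_width <= 0:
            raise ParameterError("membrane_band layout requires gfp_band_width > 0")
        if self.s_true * self.m_true >= 1.0:
            raise ParameterError("s_true * m_true must be < 1")
        if self.af_fold_range < 1.0:
            raise ParameterError("af_fold_range must be >= 1")

    @property
    def center(self) -> tuple[float, float]:
        if self.ellipse_center is not None:
            return tuple(self.ellipse_center)
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)


@dataclass
class SyntheticScene:
    """Rendered noisy channels plus the exact latent components."""

    stack: ChannelStack
    truth: dict = field(default_factory=dict)
    params: SceneParams | None = None
    af_level: float = float("nan")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _grids(shape, center):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    return yy - center[0], xx - center[1]


def ellipse_mask(params: SceneParams) -> np.ndarray:
    dy, dx = _grids(params.shape, params.center)
    ry, rx = params.ellipse_radii
    return (dy / ry) ** 2 + (dx / rx) ** 2 <= 1.0


def signed_boundary_distance(params: SceneParams) -> np.ndarray:
    """Per-pixel distance to the ellipse boundary, positive inside."""
    mask = ellipse_mask(params)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def ellipse_contour(params: SceneParams, n_vertices: int = 720) -> Contour:
    """Ground-truth membrane contour along the ellipse boundary.

    Winding is chosen so the enclosed ellipse counts as "inside" for
    cross-membrane linescans (positive distances point into the embryo).
    """
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    cy, cx = params.center
    ry, rx = params.ellipse_radii
    x = cx + rx * np.cos(t)
    y = cy + ry * np.sin(t)
    return Contour(np.column_stack([x, y]), closed=True)


# ---------------------------------------------------------------------------
# Latent components
# ---------------------------------------------------------------------------

def make_af_field(params: SceneParams, rng: np.random.Generator,
                  level: float | None = None) -> np.ndarray:
    """Latent AF image in predictor-channel units (A_af).

    A smooth positive random field — white noise low-pass filtered at
    ``af_texture_scale`` and rescaled so its embryo mean equals the sample's
    drawn AF level — restricted to the elliptical embryo (zero outside).  An
    optional central void emulates local AF exclusion by the pronuclei/
    spindle region.
    """
    if level is None:
        level = draw_af_level(params, rng)
    mask = ellipse_mask(params)
    if np.isinf(params.af_texture_scale) or params.af_texture_strength == 0:
        # limiting case: infinitely long correlation length = flat field
        profile = np.ones(params.shape)
    else:
        z = rng.standard_normal(params.shape)
        if params.af_texture_scale > 0:
            z = ndimage.gaussian_filter(z, params.af_texture_scale, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = z / sd
        profile = np.clip(1.0 + params.af_texture_strength * z, 0.05, None)
    if params.af_void:
        dy, dx = _grids(params.shape, params.center)
        blob = np.exp(-(dy ** 2 + dx ** 2) / (2 * params.af_void_sigma ** 2))
        profile = profile * (1.0 - params.af_void_depth * blob)
    support = mask.astype(np.float64)
    if params.af_edge_softening > 0:
        # AF falls off smoothly at the embryo boundary, as optics blur it
        support = ndimage.gaussian_filter(support, params.af_edge_softening,
                                          mode="constant")
    fld = profile * support
    inside_mean = fld[mask].mean()
    if inside_mean > 0:
        fld = fld * (level / inside_mean)
    return fld


def draw_af_level(params: SceneParams, rng: np.random.Generator) -> float:
    """One sample's mean AF level; log-uniform over the stated fold range."""
    return float(params.af_base_level
                 * params.af_fold_range ** rng.uniform(-0.5, 0.5))


def _gfp_component(params: SceneParams) -> np.ndarray:
    mask = ellipse_mask(params)
    amp = params.gfp_amplitude
    if params.gfp_layout == "none" or amp == 0:
        return np.zeros(params.shape)
    if params.gfp_layout == "uniform_cytoplasm":
        return amp * mask.astype(np.float64)
    if params.gfp_layout == "membrane_band":
        sd = signed_boundary_distance(params)
        return amp * np.exp(-(sd ** 2) / (2 * params.gfp_band_width ** 2))
    # nuclear_void: uniform cytoplasm with a central depletion
    dy, dx = _grids(params.shape, params.center)
    blob = np.exp(-(dy ** 2 + dx ** 2) / (2 * params.nuclear_void_sigma ** 2))
    return amp * mask * (1.0 - blob)


def _granule_component(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Punctate second AF source: Gaussian spots scattered in the embryo."""
    if params.second_af_amplitude == 0:
        return np.zeros(params.shape)
    cy, cx = params.center
    ry, rx = params.ellipse_radii
    img = np.zeros(params.shape)
    for _ in range(params.second_af_n_granules):
        # rejection-free draw inside the ellipse
        u, t = rng.uniform(0, 1), rng.uniform(0, 2 * np.pi)
        r = 0.9 * np.sqrt(u)
        py, px = cy + r * ry * np.sin(t), cx + r * rx * np.cos(t)
        iy, ix = int(round(py)), int(round(px))
        if 0 <= iy < params.shape[0] and 0 <= ix < params.shape[1]:
            img[iy, ix] += rng.uniform(0.5, 1.5)
    img = ndimage.gaussian_filter(img, params.second_af_sigma, mode="constant")
    peak = img.max()
    if peak > 0:
        img = img * (params.second_af_amplitude / peak)
    return img


def _add_noise(pre: np.ndarray, params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    if params.noise_sd == 0 and params.noise_poisson_gain == 0:
        return pre.copy()
    var = params.noise_sd ** 2 + params.noise_poisson_gain * np.clip(pre, 0, None)
    return pre + rng.standard_normal(pre.shape) * np.sqrt(var)


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------

def make_scene(
    params: SceneParams,
    rng: np.random.Generator | None = None,
    sample_id: str = "scene",
) -> SyntheticScene:
    """Render one scene and record its exact latent decomposition.

    Pre-noise channel identities (held exactly in ``truth``)::

        G = G_gfp + G_af (+ slope2 * A_af2)        G_af = m_true * A_af + c_true
        A = A_af + s_true * G_gfp + rfp_bleed_true * R_rfp (+ A_af2)
        R = R_rfp

    The ROI mask covers the embryo ellipse plus a ``roi_margin``-pixel
    background ring.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    level = draw_af_level(params, rng)
    a_af = make_af_field(params, rng, level=level)
    g_af = params.m_true * a_af + params.c_true
    g_gfp = _gfp_component(params)
    mask = ellipse_mask(params)
    r_rfp = params.rfp_amplitude * mask.astype(np.float64)
    a_gfp = params.s_true * g_gfp
    a_rfp = params.rfp_bleed_true * r_rfp
    a_af2 = _granule_component(params, rng)

    g_pre = g_gfp + g_af + params.second_af_slope * a_af2
    a_pre = a_af + a_gfp + a_rfp + a_af2
    r_pre = r_rfp

    g_obs = _add_noise(g_pre, params, rng)
    a_obs = _add_noise(a_pre, params, rng)
    with_rfp = params.include_rfp_channel or params.rfp_amplitude > 0
    r_obs = _add_noise(r_pre, params, rng) if with_rfp else None

    roi = signed_boundary_distance(params) >= -params.roi_margin
    truth = {
        "G_GFP": g_gfp, "G_AF": g_af, "A_AF": a_af,
        "A_GFP": a_gfp, "A_RFP": a_rfp, "R_RFP": r_rfp,
    }
    if params.second_af_amplitude > 0:
        truth["A_AF2"] = a_af2
    stack = ChannelStack(
        primary=g_obs,
        predictor_af=a_obs,
        predictor_rfp=r_obs,
        roi=roi,
        sample_id=sample_id,
        meta={"synthetic": True, "af_level": level, "bit_depth": None},
    )
    return SyntheticScene(stack=stack, truth=truth, params=params, af_level=level)


def make_cohort(
    params: SceneParams,
    n_samples: int,
    overrides: dict | None = None,
    per_scene: list[dict] | None = None,
) -> list[SyntheticScene]:
    """Independent scenes sharing the inter-channel truth.

    All scenes share ``m_true``/``c_true`` etc. but each draws its own AF
    level and texture.  Scene ``i`` is generated from a stream derived
    deterministically from ``(params.seed, i)``, so cohorts are reproducible
    and insensitive to how many scenes precede a given index.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    if per_scene is not None and len(per_scene) != n_samples:
        raise ParameterError("per_scene overrides must match n_samples")
    base = dataclasses.replace(params, **(overrides or {}))
    scenes = []
    for i in range(n_samples):
        p = dataclasses.replace(base, **(per_scene[i] if per_scene else {}))
        rng = np.random.default_rng(np.random.SeedSequence(entropy=p.seed, spawn_key=(i,)))
        scenes.append(make_scene(p, rng=rng, sample_id=f"scene_{i:03d}"))
    return scenes


# ---------------------------------------------------------------------------
# Disk export (used by the `simulate` CLI)
# ---------------------------------------------------------------------------

def write_scene(scene: SyntheticScene, out_dir, *, write_truth: bool = True) -> None:
    """Write a scene's channels, ROI and truth images as TIFFs plus a
    params JSON."""
    from .image_io import write_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = scene.stack.sample_id
    write_image(out / f"{sid}_primary.tif", scene.stack.primary)
    write_image(out / f"{sid}_predictor_af.tif", scene.stack.predictor_af)
    if scene.stack.has_rfp:
        write_image(out / f"{sid}_predictor_rfp.tif", scene.stack.predictor_rfp)
    write_image(out / f"{sid}_roi.tif", scene.stack.roi.astype(np.float32))
    if write_truth:
        for key, img in scene.truth.items():
            write_image(out / f"{sid}_truth_{key}.tif", img)
    doc = dataclasses.asdict(scene.params)
    doc["af_level_drawn"] = scene.af_level
    (out / f"{sid}_params.json").write_text(json.dumps(doc, indent=2) + "\n")
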