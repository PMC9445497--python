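"""Calibration of the inter-channel autofluorescence correction function.

The model
---------

Fluorescence observed in the primary (GFP) channel is an additive mixture of
true fluorophore signal and autofluorescence (AF)::

    G_obs = G_gfp + G_af

AF has a broad emission spectrum, so it is also captured in a red-shifted
predictor channel A where fluorophore contribution is negligible.  Treating AF
as a single spectral component, its contributions to the two channels are
linearly proportional::

    G_af = m * A_obs + c                       (two-channel)

With a co-expressed red fluorophore, A additionally contains bleedthrough
proportional to the dedicated red channel R, so AF in the primary channel
becomes a linear function of both predictors::

    G_af = m1 * A_obs + m2 * R_obs + c         (three-channel)

Coefficients are fitted by ordinary least squares on pixels pooled from
calibration samples in which all primary-channel signal is AF: unlabeled
samples for two-channel mode, red-only samples for three-channel mode.  The
intercept ``c`` absorbs constant background offsets between channels.

Pixels are Gaussian-filtered before pooling (default radius 2 px) to suppress
salt-and-pepper noise that would otherwise dilute the inter-channel
correlation; the filter radius is stored on the fitted model so correction can
apply the same smoothing to predictor channels.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .exceptions import (
    CollinearityError,
    ConfigurationError,
    DegeneratePredictorError,
    InsufficientDataError,
    ModelSchemaError,
    ParameterError,
    SpilloverError,
)
from .image_io import ChannelStack

logger = logging.getLogger("saibr")

#: Default Gaussian pre-filter radius (pixels).  One to two pixels is the
#: practical range; the larger end is the default for stability on noisy
#: cameras.
DEFAULT_GAUSSIAN_RADIUS = 2.0

#: Recommended minimum number of calibration samples (warn below this).
MIN_RECOMMENDED_SAMPLES = 3


# ---------------------------------------------------------------------------
# Gaussian pre-filter
# ---------------------------------------------------------------------------

def gaussian_prefilter(image: np.ndarray, radius: float) -> np.ndarray:
    """Smooth an image with a normalized Gaussian kernel of the given radius.

    ``radius`` is the Gaussian sigma in pixels; 0 is the identity.  Boundary
    handling is reflection, which avoids dark-edge artifacts that would bias
    pooled border pixels.
    """
    if radius < 0:
        raise ParameterError(f"Gaussian radius must be >= 0, got {radius}")
    image = np.asarray(image, dtype=np.float64)
    if radius == 0:
        return image
    return ndimage.gaussian_filter(image, sigma=radius, mode="reflect")


# ---------------------------------------------------------------------------
# Pixel pooling
# ---------------------------------------------------------------------------

@dataclass
class PixelPool:
    """ROI pixels pooled from calibration samples, with provenance.

    ``g``/``a``/``r`` hold primary, AF-predictor and (optionally) red-channel
    values; ``source`` labels each pixel with its sample_id.  ``radius`` is
    the Gaussian pre-filter radius the values were smoothed at.
    """

    g: np.ndarray
    a: np.ndarray
    r: np.ndarray | None = None
    source: np.ndarray | None = None
    radius: float = 0.0

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.float64).ravel()
        self.a = np.asarray(self.a, dtype=np.float64).ravel()
        if self.r is not None:
            self.r = np.asarray(self.r, dtype=np.float64).ravel()
        if self.source is None:
            self.source = np.zeros(self.g.size, dtype=object)
            self.source[:] = ""
        else:
            self.source = np.asarray(self.source, dtype=object).ravel()
        lengths = {self.g.size, self.a.size, self.source.size}
        if self.r is not None:
            lengths.add(self.r.size)
        if len(lengths) != 1:
            raise ConfigurationError(f"pool vectors have unequal lengths: {sorted(lengths)}")

    @property
    def n_pixels(self) -> int:
        return int(self.g.size)

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.source:
            seen.setdefault(str(s))
        return list(seen)

    def low_intensity_fraction(self, quantile: float = 0.2) -> float:
        """Fraction of pool pixels in the dim tail of the predictor channel.

        Calibration ROIs should include some sample-free background so the
        fitted line is anchored at low intensities; a very small value here
        suggests the ROIs cover only bright sample interior.
        """
        lo = np.min(self.a)
        hi = np.max(self.a)
        if hi == lo:
            return 1.0
        return float(np.mean(self.a < lo + quantile * (hi - lo)))


def build_pixel_pool(
    stacks: Sequence[ChannelStack],
    radius: float = DEFAULT_GAUSSIAN_RADIUS,
    *,
    require_rfp: bool = False,
    saturation_max: float | None = None,
) -> PixelPool:
    """Gaussian-filter each channel and pool ROI pixels across samples.

    Saturated pixels (any channel at the detector maximum, taken from
    ``saturation_max`` or each stack's declared bit depth) are excluded with a
    logged count — saturation breaks the linearity the fit relies on.
    """
    if len(stacks) == 0:
        raise InsufficientDataError("at least one calibration stack is required")
    if len(stacks) < MIN_RECOMMENDED_SAMPLES:
        logger.warning(
            "calibration pool built from %d sample(s); pooling from at least %d is recommended",
            len(stacks), MIN_RECOMMENDED_SAMPLES,
        )
    gs, as_, rs, src = [], [], [], []
    with_r = require_rfp or all(s.has_rfp for s in stacks)
    n_saturated = 0
    for stack in stacks:
        if require_rfp and not stack.has_rfp:
            raise ConfigurationError(
                f"sample {stack.sample_id!r} lacks the red predictor channel required "
                "for three-channel calibration"
            )
        keep = stack.roi
        sat_max = saturation_max
        if sat_max is None and stack.meta.get("bit_depth"):
            sat_max = float(2 ** stack.meta["bit_depth"] - 1)
        if sat_max is not None:
            unsat = np.ones(stack.shape, dtype=bool)
            for arr in stack.channels().values():
                unsat &= arr < sat_max
            n_saturated += int(np.count_nonzero(keep & ~unsat))
            keep = keep & unsat
        gs.append(gaussian_prefilter(stack.primary, radius)[keep])
        as_.append(gaussian_prefilter(stack.predictor_af, radius)[keep])
        if with_r and stack.has_rfp:
            rs.append(gaussian_prefilter(stack.predictor_rfp, radius)[keep])
        n = int(np.count_nonzero(keep))
        ids = np.zeros(n, dtype=object)
        ids[:] = stack.sample_id
        src.append(ids)
    if n_saturated:
        logger.info("excluded %d saturated pixel(s) from the calibration pool", n_saturated)
    return PixelPool(
        g=np.concatenate(gs),
        a=np.concatenate(as_),
        r=np.concatenate(rs) if with_r and rs else None,
        source=np.concatenate(src),
        radius=radius,
    )


# ---------------------------------------------------------------------------
# Fitted model container
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """Fitted inter-channel correction function.

    Two-channel mode: ``G_af = m * A + c``.  Three-channel mode:
    ``G_af = m1 * A + m2 * R + c``.  ``s`` is the optional fluorophore
    spillover slope into the AF predictor channel (absent by default);
    ``gaussian_radius`` is the pre-filter radius used during fitting and to
    be re-applied to predictor channels at correction time.
    """

    mode: str
    c: float
    m: float | None = None
    m1: float | None = None
    m2: float | None = None
    s: float | None = None
    gaussian_radius: float = DEFAULT_GAUSSIAN_RADIUS
    n_pixels: int = 0
    r_squared: float = float("nan")
    sample_ids: list = field(default_factory=list)
    per_sample: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("two_channel", "three_channel"):
            raise ConfigurationError(f"unknown calibration mode {self.mode!r}")
        if self.mode == "two_channel":
            if self.m is None or self.m1 is not None or self.m2 is not None:
                raise ConfigurationError("two_channel mode requires m and forbids m1/m2")
        else:
            if self.m1 is None or self.m2 is None or self.m is not None:
                raise ConfigurationError("three_channel mode requires m1 and m2 and forbids m")
        if self.s is not None and self.primary_slope * self.s >= 1.0:
            raise SpilloverError(
                f"spillover slope s={self.s} with predictor slope "
                f"{self.primary_slope} gives m*s >= 1; no corrected solution exists"
            )

    @property
    def primary_slope(self) -> float:
        """Slope on the AF predictor channel (``m`` or ``m1``)."""
        return float(self.m if self.mode == "two_channel" else self.m1)

    def coefficients(self) -> dict[str, float]:
        if self.mode == "two_channel":
            return {"m": self.m, "c": self.c}
        return {"m1": self.m1, "m2": self.m2, "c": self.c}

    def to_dict(self) -> dict:
        doc = {
            "mode": self.mode,
            "c": self.c,
            "s": self.s,
            "gaussian_radius": self.gaussian_radius,
            "n_pixels": self.n_pixels,
            "r_squared": self.r_squared,
            "sample_ids": list(self.sample_ids),
            "per_sample": list(self.per_sample),
            "diagnostics": dict(self.diagnostics),
        }
        if self.mode == "two_channel":
            doc["m"] = self.m
        else:
            doc["m1"] = self.m1
            doc["m2"] = self.m2
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "CalibrationModel":
        mode = doc.get("mode")
        if mode not in ("two_channel", "three_channel"):
            raise ModelSchemaError(f"unknown or missing mode: {mode!r}")
        required = ["c"] + (["m"] if mode == "two_channel" else ["m1", "m2"])
        missing = [k for k in required if doc.get(k) is None]
        if missing:
            raise ModelSchemaError(f"model document missing field(s) {missing} for mode {mode!r}")
        return cls(
            mode=mode,
            c=float(doc["c"]),
            m=float(doc["m"]) if mode == "two_channel" else None,
            m1=float(doc["m1"]) if mode == "three_channel" else None,
            m2=float(doc["m2"]) if mode == "three_channel" else None,
            s=None if doc.get("s") is None else float(doc["s"]),
            gaussian_radius=float(doc.get("gaussian_radius", DEFAULT_GAUSSIAN_RADIUS)),
            n_pixels=int(doc.get("n_pixels", 0)),
            r_squared=float(doc.get("r_squared", float("nan"))),
            sample_ids=list(doc.get("sample_ids", [])),
            per_sample=list(doc.get("per_sample", [])),
            diagnostics=dict(doc.get("diagnostics", {})),
        )


# ---------------------------------------------------------------------------
# Least-squares machinery
# ---------------------------------------------------------------------------

def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS via QR-based lstsq (numerically stable orthogonal decomposition).

    Returns (coefficients, R^2).  The design matrix includes the intercept
    column; the caller has already checked rank.
    """
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return beta, max(0.0, min(1.0, r2))


def _per_sample_diagnostics(pool: PixelPool) -> list[dict]:
    """Per-sample slope and R^2 of the two-channel line (diagnostic only).

    These are never applied; a single global fit is what correction uses.
    """
    out = []
    for sid in pool.sample_ids:
        sel = pool.source == sid
        a, g = pool.a[sel], pool.g[sel]
        if a.size < 3 or np.ptp(a) == 0:
            out.append({"sample_id": sid, "n_pixels": int(a.size),
                        "slope": None, "r_squared": None})
            continue
        beta, r2 = _ols(np.column_stack([a, np.ones_like(a)]), g)
        out.append({"sample_id": sid, "n_pixels": int(a.size),
                    "slope": float(beta[0]), "r_squared": r2})
    return out


def fit_two_channel(pool: PixelPool) -> CalibrationModel:
    """Fit ``g = m*a + c`` by ordinary least squares on a pooled pixel set.

    A single global intercept is shared across all pooled samples; per-sample
    slopes are reported as diagnostics only.
    """
    if pool.n_pixels < 3:
        raise InsufficientDataError(
            f"two-channel fit needs at least 3 observations, got {pool.n_pixels}"
        )
    if np.ptp(pool.a) == 0:
        raise DegeneratePredictorError("AF predictor has zero variance across the pool")
    design = np.column_stack([pool.a, np.ones(pool.n_pixels)])
    beta, r2 = _ols(design, pool.g)
    return CalibrationModel(
        mode="two_channel",
        m=float(beta[0]),
        c=float(beta[1]),
        gaussian_radius=pool.radius,
        n_pixels=pool.n_pixels,
        r_squared=r2,
        sample_ids=pool.sample_ids,
        per_sample=_per_sample_diagnostics(pool),
        diagnostics={"low_intensity_fraction": pool.low_intensity_fraction()},
    )


def fit_three_channel(pool: PixelPool) -> CalibrationModel:
    """Fit ``g = m1*a + m2*r + c`` by multiple linear regression.

    Calibration data must come from red-only samples so that all
    primary-channel signal is AF.
    """
    if pool.r is None:
        raise ConfigurationError("three-channel fit requires the red predictor channel")
    if pool.n_pixels < 4:
        raise InsufficientDataError(
            f"three-channel fit needs at least 4 observations, got {pool.n_pixels}"
        )
    if np.ptp(pool.a) == 0:
        raise CollinearityError("predictor 'a' (AF channel) is constant across the pool")
    if np.ptp(pool.r) == 0:
        raise CollinearityError("predictor 'r' (red channel) is constant across the pool")
    centered = np.column_stack([pool.a - pool.a.mean(), pool.r - pool.r.mean()])
    if np.linalg.matrix_rank(centered) < 2:
        raise CollinearityError(
            "predictor 'r' (red channel) is perfectly collinear with the AF channel"
        )
    design = np.column_stack([pool.a, pool.r, np.ones(pool.n_pixels)])
    beta, r2 = _ols(design, pool.g)
    return CalibrationModel(
        mode="three_channel",
        m1=float(beta[0]),
        m2=float(beta[1]),
        c=float(beta[2]),
        gaussian_radius=pool.radius,
        n_pixels=pool.n_pixels,
        r_squared=r2,
        sample_ids=pool.sample_ids,
        per_sample=_per_sample_diagnostics(pool),
        diagnostics={"low_intensity_fraction": pool.low_intensity_fraction()},
    )


def fit_whole_sample(
    stacks: Sequence[ChannelStack],
    mode: str = "two_channel",
) -> CalibrationModel:
    """Fit the same regression on whole-sample ROI means instead of pixels.

    Each observation is one sample's ROI-mean per channel (unfiltered — the
    mean needs no noise suppression).  Under the shared linear model the
    coefficients estimate the same quantities as the pixel-by-pixel fit and
    may be applied per pixel.
    """
    n_coef = 2 if mode == "two_channel" else 3
    if len(stacks) < n_coef + 1:
        raise InsufficientDataError(
            f"{mode} whole-sample fit needs at least {n_coef + 1} samples, got {len(stacks)}"
        )
    g = np.array([s.primary[s.roi].mean() for s in stacks])
    a = np.array([s.predictor_af[s.roi].mean() for s in stacks])
    ids = np.array([s.sample_id for s in stacks], dtype=object)
    r = None
    if mode == "three_channel":
        for s in stacks:
            if not s.has_rfp:
                raise ConfigurationError(
                    f"sample {s.sample_id!r} lacks the red channel required for three-channel mode"
                )
        r = np.array([s.predictor_rfp[s.roi].mean() for s in stacks])
    pool = PixelPool(g=g, a=a, r=r, source=ids, radius=0.0)
    fit = fit_two_channel if mode == "two_channel" else fit_three_channel
    model = fit(pool)
    model.diagnostics["observations"] = "whole_sample_means"
    return model


# ---------------------------------------------------------------------------
# Fluorophore spillover into the AF channel
# ---------------------------------------------------------------------------

def estimate_spillover(
    gfp_only_stacks: Sequence[ChannelStack],
    base_model: CalibrationModel,
    radius: float | None = None,
) -> CalibrationModel:
    """Estimate the fluorophore spillover slope ``s`` into the AF channel.

    The narrow fluorophore emission band leaks a small proportional fraction
    ``s`` of true signal into the AF predictor channel, inflating inferred AF.
    This two-pass estimator needs samples with strong fluorophore expression
    acquired under the base model's conditions:

    1. first-pass correction with the base model gives, per pixel,
       ``g1 = (1 - m*s) * G_gfp + noise``;
    2. the predictor channel carries ``a = a_af + s * G_gfp``, so regressing
       ``a`` on ``g1`` (intercept absorbing mean AF) gives a slope
       ``beta = s / (1 - m*s)``, solved for ``s = beta / (1 + beta*m)``.

    The estimator assumes the fluorophore distribution varies independently
    of the AF field within the ROI; structured fluorophore signal (membrane,
    nuclei) provides the contrast that identifies ``s``.  A negative estimate
    is truncated to 0 with a warning; ``m*s >= 1`` is unidentifiable.
    """
    if radius is None:
        radius = base_model.gaussian_radius
    m = base_model.primary_slope
    pool = build_pixel_pool(
        gfp_only_stacks, radius, require_rfp=base_model.mode == "three_channel"
    )
    if base_model.mode == "two_channel":
        g1 = pool.g - (m * pool.a + base_model.c)
    else:
        g1 = pool.g - (m * pool.a + base_model.m2 * pool.r + base_model.c)
    if np.ptp(g1) == 0:
        raise DegeneratePredictorError("corrected signal has zero variance; cannot estimate spillover")
    beta, _ = _ols(np.column_stack([g1, np.ones(g1.size)]), pool.a)
    b = float(beta[0])
    if b <= 0 or 1.0 + b * m <= 0:
        # implied spillover is negative (unphysical): no detectable leak,
        # e.g. weak fluorophore expression or a fluorophore-free sample
        _warnings.warn(
            f"estimated spillover is negative within noise (beta={b:.4g}); using s=0",
            stacklevel=2,
        )
        s = 0.0
    else:
        s = b / (1.0 + b * m)
    if m * s >= 1.0:
        raise SpilloverError(f"estimated m*s = {m * s} >= 1; corrected solution does not exist")
    out = replace(base_model, s=float(s))
    out.diagnostics = dict(base_model.diagnostics)
    out.diagnostics["spillover_n_pixels"] = pool.n_pixels
    return out


# ---------------------------------------------------------------------------
# Diagnostic export
# ---------------------------------------------------------------------------

def export_pool_sample(pool: PixelPool, path, fraction: float = 0.1, seed: int = 0) -> None:
    """Write a random subsample of the pool as a scatter-ready CSV.

    Default 10% of pixels — enough to see the inter-channel correlation
    without multi-million-row files.  The subsample is seeded for
    reproducibility.
    """
    import pandas as pd

    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    n = max(1, int(round(fraction * pool.n_pixels)))
    idx = rng.choice(pool.n_pixels, size=min(n, pool.n_pixels), replace=False)
    cols = {"sample_id": pool.source[idx], "a": pool.a[idx], "g": pool.g[idx]}
    if pool.r is not None:
        cols["r"] = pool.r[idx]
    pd.DataFrame(cols).to_csv(path, index=False)
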