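"""Image and model I/O.

Channel images and ROI masks are exchanged as TIFF (single- or multi-page);
fitted calibration models as versioned JSON documents.  All pixel data is
converted to double precision on load with **no rescaling**: the correction
regression is scale-covariant, and keeping raw detector units preserves the
comparability of the intercept ``c`` across samples.

Negative values produced by background subtraction or correction are retained
throughout — they are diagnostically meaningful (over-subtraction shows up as
negative signal).  Clipping at zero is offered only as a display-export option.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .exceptions import (
    ChannelGeometryError,
    ConfigurationError,
    DataError,
    ModelSchemaError,
    ModelVersionError,
)

logger = logging.getLogger("saibr")

#: Current schema version for serialized calibration models.
MODEL_SCHEMA_VERSION = 1

#: Channel tags used throughout the package.
CHANNEL_TAGS = ("primary", "predictor_af", "predictor_rfp")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ChannelStack:
    """Co-registered 2-D channel images for one sample.

    Parameters
    ----------
    primary
        Fluorophore-reporting channel (e.g. GFP: ex488/em~535), in raw
        detector units.
    predictor_af
        Red-shifted autofluorescence predictor channel acquired under the
        same excitation (e.g. ex488/em~630).
    predictor_rfp
        Optional red-fluorophore channel (red excitation), used as a second
        predictor in three-channel mode.
    roi
        Boolean region-of-interest mask.  ``None`` means the whole frame.
    sample_id
        Free-text label carried into pooled fits and summary tables.
    meta
        Free-form acquisition metadata (bit depth, source paths, history).
    """

    primary: np.ndarray
    predictor_af: np.ndarray
    predictor_rfp: np.ndarray | None = None
    roi: np.ndarray | None = None
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.primary = _as_image(self.primary, "primary")
        self.predictor_af = _as_image(self.predictor_af, "predictor_af")
        if self.predictor_rfp is not None:
            self.predictor_rfp = _as_image(self.predictor_rfp, "predictor_rfp")
        shape = self.primary.shape
        for tag in ("predictor_af", "predictor_rfp"):
            arr = getattr(self, tag)
            if arr is not None and arr.shape != shape:
                raise ChannelGeometryError(
                    f"channel {tag!r} has shape {arr.shape}, expected {shape}"
                )
        if self.roi is None:
            self.roi = np.ones(shape, dtype=bool)
        else:
            self.roi = np.asarray(self.roi) != 0
            if self.roi.shape != shape:
                raise ChannelGeometryError(
                    f"ROI mask has shape {self.roi.shape}, expected {shape}"
                )
        if not self.roi.any():
            raise DataError("ROI mask contains no pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.primary.shape

    @property
    def has_rfp(self) -> bool:
        return self.predictor_rfp is not None

    def channels(self) -> dict[str, np.ndarray]:
        """Present channels as a tag -> array mapping."""
        out = {"primary": self.primary, "predictor_af": self.predictor_af}
        if self.predictor_rfp is not None:
            out["predictor_rfp"] = self.predictor_rfp
        return out


@dataclass
class BackgroundFrame:
    """A no-sample field-of-view image subtracted from one channel."""

    image: np.ndarray
    channel_tag: str

    def __post_init__(self) -> None:
        if self.channel_tag not in CHANNEL_TAGS:
            raise ConfigurationError(
                f"unknown channel tag {self.channel_tag!r}; expected one of {CHANNEL_TAGS}"
            )
        self.image = _as_image(self.image, f"background[{self.channel_tag}]")


def _as_image(arr, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ChannelGeometryError(f"{name} must be a 2-D image, got ndim={arr.ndim}")
    if not np.isfinite(arr).all():
        raise DataError(f"{name} contains non-finite pixel values")
    return arr


# ---------------------------------------------------------------------------
# Image reading / writing
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read a single 2-D TIFF page as float64, raw detector units."""
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    return _as_image(arr, str(path))


def read_mask(path) -> np.ndarray:
    """Read an ROI mask image; any nonzero pixel counts as inside."""
    arr = tifffile.imread(str(path))
    return np.asarray(arr) != 0


def load_channel_stack(
    primary=None,
    predictor_af=None,
    predictor_rfp=None,
    roi=None,
    *,
    stack=None,
    channel_order: Sequence[str] | None = None,
    sample_id: str | None = None,
) -> ChannelStack:
    """Load a :class:`ChannelStack` from per-channel files or a multi-page TIFF.

    Either pass one file per channel (``primary``, ``predictor_af``, optional
    ``predictor_rfp``) or a multi-page ``stack`` together with an explicit
    ``channel_order`` naming the pages — the order is always declared by the
    caller, never guessed from metadata.
    """
    meta: dict = {}
    if stack is not None:
        if channel_order is None:
            raise ConfigurationError("a multi-page stack requires an explicit channel_order")
        pages = np.asarray(tifffile.imread(str(stack)))
        if pages.ndim == 2:
            pages = pages[None]
        if len(channel_order) > pages.shape[0]:
            raise ChannelGeometryError(
                f"channel_order names {len(channel_order)} pages but stack has {pages.shape[0]}"
            )
        by_tag = {tag: pages[i] for i, tag in enumerate(channel_order)}
        meta["source"] = {"stack": str(stack), "channel_order": list(channel_order)}
        meta["bit_depth"] = 8 * pages.dtype.itemsize if pages.dtype.kind in "iu" else None
        primary_arr = by_tag.get("primary")
        af_arr = by_tag.get("predictor_af")
        rfp_arr = by_tag.get("predictor_rfp")
        if primary_arr is None or af_arr is None:
            raise ConfigurationError("channel_order must include 'primary' and 'predictor_af'")
    else:
        if primary is None or predictor_af is None:
            raise ConfigurationError("primary and predictor_af files are required")
        primary_arr = tifffile.imread(str(primary))
        af_arr = tifffile.imread(str(predictor_af))
        rfp_arr = tifffile.imread(str(predictor_rfp)) if predictor_rfp is not None else None
        meta["source"] = {
            "primary": str(primary),
            "predictor_af": str(predictor_af),
            "predictor_rfp": str(predictor_rfp) if predictor_rfp is not None else None,
        }
        dt = np.asarray(primary_arr).dtype
        meta["bit_depth"] = 8 * dt.itemsize if dt.kind in "iu" else None

    roi_arr = read_mask(roi) if roi is not None else None
    if sample_id is None:
        src = primary if primary is not None else stack
        sample_id = Path(str(src)).stem
    return ChannelStack(
        primary=primary_arr,
        predictor_af=af_arr,
        predictor_rfp=rfp_arr,
        roi=roi_arr,
        sample_id=sample_id,
        meta=meta,
    )


def subtract_background(
    stack: ChannelStack,
    backgrounds: Mapping[str, BackgroundFrame | np.ndarray],
) -> ChannelStack:
    """Subtract per-channel background frames pixel-wise.

    Every channel present in ``stack`` must have a background; negative
    results are retained.  Returns a new stack; the operation is recorded in
    ``meta['background_subtracted']``.
    """
    frames: dict[str, np.ndarray] = {}
    for tag, bg in backgrounds.items():
        if isinstance(bg, BackgroundFrame):
            if bg.channel_tag != tag:
                raise ConfigurationError(
                    f"background tagged {bg.channel_tag!r} supplied under key {tag!r}"
                )
            frames[tag] = bg.image
        else:
            frames[tag] = _as_image(bg, f"background[{tag}]")
    channels = stack.channels()
    missing = set(channels) - set(frames)
    if missing:
        raise ConfigurationError(f"missing background frame(s) for channel(s): {sorted(missing)}")
    for tag, frame in frames.items():
        if tag in channels and frame.shape != stack.shape:
            raise ChannelGeometryError(
                f"background for {tag!r} has shape {frame.shape}, expected {stack.shape}"
            )
    new = {tag: channels[tag] - frames[tag] for tag in channels}
    meta = dict(stack.meta)
    meta["background_subtracted"] = True
    return ChannelStack(
        primary=new["primary"],
        predictor_af=new["predictor_af"],
        predictor_rfp=new.get("predictor_rfp"),
        roi=stack.roi.copy(),
        sample_id=stack.sample_id,
        meta=meta,
    )


def write_image(path, image: np.ndarray, *, clip_display: bool = False) -> None:
    """Write an image as signed 32-bit float TIFF.

    ``clip_display=True`` clips negatives at zero — for display exports only;
    quantification always uses the signed data.
    """
    out = np.asarray(image, dtype=np.float32)
    if clip_display:
        out = np.clip(out, 0.0, None)
    tifffile.imwrite(str(path), out)


def check_identical_conditions(stacks: Sequence[ChannelStack]) -> list[str]:
    """Warn (but never block) when acquisition conditions look inconsistent.

    Calibration and experimental images must be acquired under identical
    conditions for the fitted coefficients to transfer; differing image shape
    or bit depth is a red flag worth logging.
    """
    warnings: list[str] = []
    shapes = {s.shape for s in stacks}
    if len(shapes) > 1:
        warnings.append(f"images have differing shapes: {sorted(shapes)}")
    depths = {s.meta.get("bit_depth") for s in stacks if s.meta.get("bit_depth") is not None}
    if len(depths) > 1:
        warnings.append(f"images have differing bit depths: {sorted(depths)}")
    for w in warnings:
        logger.warning("acquisition-condition check: %s", w)
    return warnings


# ---------------------------------------------------------------------------
# Calibration-model serialization
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a fitted calibration model to versioned JSON."""
    doc = model.to_dict()
    doc["schema_version"] = MODEL_SCHEMA_VERSION
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_model(path):
    """Load a calibration model saved by :func:`save_model`.

    Raises
    ------
    ModelVersionError
        If the file declares a schema version newer than this package knows.
    ModelSchemaError
        If required fields for the declared mode are absent.
    """
    from .calibration import CalibrationModel

    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version is None:
        raise ModelSchemaError("model file lacks a schema_version field")
    if version > MODEL_SCHEMA_VERSION:
        raise ModelVersionError(
            f"model schema version {version} is newer than supported version "
            f"{MODEL_SCHEMA_VERSION}"
        )
    return CalibrationModel.from_dict(doc)
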