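"""Applying a fitted calibration model to experimental images.

Per pixel, the predictor channel(s) are Gaussian-filtered at the model's
stored radius and mapped through the fitted linear function to give the
inferred autofluorescence image AF*; subtracting AF* from the (unfiltered)
primary channel yields the true-fluorophore image.  Smoothing predictors only
suppresses the noise amplification inherent in combining pixel noise from
multiple channels while preserving primary-channel resolution; the
unfiltered-predictor behavior is available behind a flag.

Negative corrected values are retained — a large negative fraction is the
standard symptom of wrong-mode calibration (e.g. a two-channel model applied
to a sample whose red fluorophore bleeds into the AF channel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, gaussian_prefilter
from .exceptions import ConfigurationError, SaibrError, SpilloverError
from .image_io import ChannelStack

#: Negative-fraction threshold above which the over-correction report flags
#: a likely wrong-mode calibration.
OVERCORRECTION_THRESHOLD = 0.05


@dataclass
class CorrectionResult:
    """Inferred AF image and corrected (signed) true-fluorophore image."""

    inferred_af: np.ndarray
    corrected: np.ndarray
    negative_fraction: float
    roi_mean_corrected: float
    roi_mean_raw: float
    sample_id: str
    model_ref: dict
    roi: np.ndarray


def infer_af(
    model: CalibrationModel,
    stack: ChannelStack,
    *,
    filter_predictors: bool = True,
) -> np.ndarray:
    """Infer the per-pixel AF image AF* in primary-channel units.

    Two-channel: ``AF* = m * A + c``; three-channel:
    ``AF* = m1 * A + m2 * R + c``, with predictors smoothed at the model's
    stored Gaussian radius (unless ``filter_predictors=False``).
    """
    radius = model.gaussian_radius if filter_predictors else 0.0
    a = gaussian_prefilter(stack.predictor_af, radius)
    if model.mode == "two_channel":
        return model.m * a + model.c
    if not stack.has_rfp:
        raise ConfigurationError(
            f"three-channel model applied to sample {stack.sample_id!r} "
            "which lacks the red predictor channel"
        )
    r = gaussian_prefilter(stack.predictor_rfp, radius)
    return model.m1 * a + model.m2 * r + model.c


def correct(
    model: CalibrationModel,
    stack: ChannelStack,
    *,
    filter_predictors: bool = True,
    apply_spillover: bool = True,
) -> CorrectionResult:
    """Subtract inferred AF from the primary channel.

    ``corrected = primary - AF*`` pixel-wise; the primary channel is never
    filtered, so the decomposition ``primary - AF* = corrected`` is exact.
    When the model carries a spillover slope ``s`` (and ``apply_spillover``),
    the subtraction leaves ``(1 - m*s)`` of the true signal, so the result is
    rescaled by ``1 / (1 - m*s)`` — spillover is proportional to fluorophore
    signal and only rescales its magnitude.
    """
    af_star = infer_af(model, stack, filter_predictors=filter_predictors)
    corrected = stack.primary - af_star
    if model.s is not None and apply_spillover and model.s != 0:
        denom = 1.0 - model.primary_slope * model.s
        if denom <= 0:
            raise SpilloverError(
                f"1 - m*s = {denom} <= 0; spillover-compensated solution does not exist"
            )
        corrected = corrected / denom
    roi = stack.roi
    return CorrectionResult(
        inferred_af=af_star,
        corrected=corrected,
        negative_fraction=float(np.mean(corrected[roi] < 0)),
        roi_mean_corrected=float(corrected[roi].mean()),
        roi_mean_raw=float(stack.primary[roi].mean()),
        sample_id=stack.sample_id,
        model_ref={"mode": model.mode, **model.coefficients(),
                   "s": model.s, "gaussian_radius": model.gaussian_radius},
        roi=roi,
    )


def correct_batch(
    model: CalibrationModel,
    stacks: Sequence[ChannelStack],
    **kwargs,
) -> tuple[list[CorrectionResult | None], pd.DataFrame]:
    """Correct a list of samples, tolerating per-sample failures.

    Returns the results (``None`` where a sample failed) in input order and a
    tidy summary table with one row per sample including a status column.
    """
    results: list[CorrectionResult | None] = []
    rows = []
    for stack in stacks:
        try:
            res = correct(model, stack, **kwargs)
        except SaibrError as exc:
            results.append(None)
            rows.append({
                "sample_id": stack.sample_id, "status": "failed", "error": str(exc),
                "roi_mean_raw": float(stack.primary[stack.roi].mean()),
                "roi_mean_corrected": np.nan, "negative_fraction": np.nan,
            })
            continue
        results.append(res)
        rows.append({
            "sample_id": res.sample_id, "status": "ok", "error": "",
            "roi_mean_raw": res.roi_mean_raw,
            "roi_mean_corrected": res.roi_mean_corrected,
            "negative_fraction": res.negative_fraction,
        })
    columns = ["sample_id", "status", "error", "roi_mean_raw",
               "roi_mean_corrected", "negative_fraction"]
    return results, pd.DataFrame(rows, columns=columns)


def overcorrection_report(
    result: CorrectionResult,
    threshold: float = OVERCORRECTION_THRESHOLD,
) -> dict:
    """Summarize over-subtraction diagnostics for one corrected sample.

    A negative fraction above ``threshold`` flags likely wrong-mode
    calibration (e.g. two-channel correction of a red-fluorophore-expressing
    sample, where bleedthrough inflates inferred AF).
    """
    vals = result.corrected[result.roi]
    neg = vals[vals < 0]
    return {
        "sample_id": result.sample_id,
        "negative_fraction": result.negative_fraction,
        "mean_negative": float(neg.mean()) if neg.size else 0.0,
        "threshold": threshold,
        "flag": bool(result.negative_fraction > threshold),
    }


# ---------------------------------------------------------------------------
# Mean-AF-subtraction reference method
# ---------------------------------------------------------------------------

def mean_af_reference(unlabeled_stacks: Sequence[ChannelStack]) -> float:
    """Cohort-average primary-channel AF level from unlabeled samples.

    The baseline method subtracts this single scalar from every experimental
    sample's mean, ignoring per-sample and per-pixel AF variation.  It exists
    as a named reference for benchmarking, not as a recommended path.
    """
    if len(unlabeled_stacks) == 0:
        raise ConfigurationError("mean-AF reference needs at least one unlabeled sample")
    return float(np.mean([s.primary[s.roi].mean() for s in unlabeled_stacks]))


def mean_af_subtract(stacks: Sequence[ChannelStack], af_mean: float) -> np.ndarray:
    """Per-sample ROI means minus the scalar cohort AF level."""
    return np.array([s.primary[s.roi].mean() - af_mean for s in stacks])
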