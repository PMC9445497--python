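"""Downstream quantification: ROI means, c.o.v., cross-membrane profiles.

Coordinate convention (fixed for interpolation reproducibility): pixel centers
sit at integer coordinates, origin at the top-left pixel, x increases
rightwards (columns), y increases downwards (rows).  Contour vertices live in
the same frame.  All distances are in pixels; apply your own scale factor for
microns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import GeometryError, ParameterError


# ---------------------------------------------------------------------------
# Scalar summaries
# ---------------------------------------------------------------------------

def roi_mean(image: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of the image over a nonempty boolean mask."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask) != 0
    if image.shape != mask.shape:
        raise ParameterError(f"mask shape {mask.shape} != image shape {image.shape}")
    if not mask.any():
        raise ParameterError("mask selects no pixels")
    return float(image[mask].mean())


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise ParameterError("c.o.v. needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ParameterError("c.o.v. is undefined for zero-mean values")
    return float(values.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# Contours
# ---------------------------------------------------------------------------

@dataclass
class Contour:
    """Ordered sub-pixel vertices (x, y) tracing a membrane.

    ``closed=True`` joins the last vertex back to the first.  Winding decides
    the outward-normal orientation of linescans (see
    :func:`cross_membrane_profiles`); self-intersection is not checked.
    """

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ParameterError("contour vertices must be an (n, 2) array of (x, y)")
        n_min = 3 if self.closed else 2
        if self.vertices.shape[0] < n_min:
            raise ParameterError(f"contour needs at least {n_min} vertices")

    def signed_area(self) -> float:
        """Shoelace area in this frame (y down); sign encodes winding."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def contour_from_csv(path) -> Contour:
    """Read a contour from a 2-column (x, y) CSV."""
    arr = pd.read_csv(path).to_numpy(dtype=np.float64)
    return Contour(arr[:, :2])


def contour_to_csv(contour: Contour, path) -> None:
    pd.DataFrame(contour.vertices, columns=["x", "y"]).to_csv(path, index=False)


def _resample_by_arc_length(contour: Contour, spacing: float):
    """Piecewise-linear resampling at equal arc-length steps.

    Returns (points (n,2), tangents (n,2) unit, arc_positions (n,),
    total_length).
    """
    verts = contour.vertices
    if contour.closed:
        verts = np.vstack([verts, verts[:1]])
    seg = np.diff(verts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = float(cum[-1])
    if total == 0:
        raise ParameterError("contour has zero length")
    if contour.closed:
        positions = np.arange(0.0, total, spacing)
    else:
        positions = np.arange(0.0, total + 1e-9, spacing)
    x = np.interp(positions, cum, verts[:, 0])
    y = np.interp(positions, cum, verts[:, 1])
    points = np.column_stack([x, y])
    if contour.closed:
        nxt = np.roll(points, -1, axis=0)
        prv = np.roll(points, 1, axis=0)
        tan = nxt - prv
    else:
        tan = np.gradient(points, axis=0)
    norm = np.hypot(tan[:, 0], tan[:, 1])
    norm[norm == 0] = 1.0
    tan = tan / norm[:, None]
    return points, tan, positions, total


# ---------------------------------------------------------------------------
# Linescans
# ---------------------------------------------------------------------------

@dataclass
class LinescanSet:
    """Cross-membrane linescans at successive positions along a contour.

    ``scans[i, j]`` is the interpolated intensity of linescan ``i`` at signed
    distance ``distances[j]`` from the membrane (negative outside, positive
    inside).  ``arc_positions`` locate each linescan along the contour;
    ``n_dropped`` counts linescans discarded for leaving the image frame.
    """

    distances: np.ndarray
    scans: np.ndarray
    arc_positions: np.ndarray
    points: np.ndarray
    total_length: float
    closed: bool
    n_dropped: int = 0

    @property
    def n_lines(self) -> int:
        return int(self.scans.shape[0])


def cross_membrane_profiles(
    image: np.ndarray,
    contour: Contour,
    half_length: float = 25.0,
    spacing: float = 1.0,
    n_samples: int = 50,
) -> LinescanSet:
    """Sample intensity profiles perpendicular to a membrane contour.

    At each arc-length step of ``spacing`` pixels along the contour, the image
    is sampled at ``n_samples`` equally spaced positions spanning
    [-half_length, +half_length] along the local normal, using smooth cubic
    (bicubic spline) interpolation.  The outward direction is fixed by the
    contour winding, so distance is negative outside the enclosed region and
    positive inside.  Linescans with any sample outside the image frame are
    dropped, with a count.
    """
    image = np.asarray(image, dtype=np.float64)
    if half_length <= 0 or spacing <= 0 or n_samples < 2:
        raise ParameterError("half_length and spacing must be > 0, n_samples >= 2")
    points, tangents, positions, total = _resample_by_arc_length(contour, spacing)

    # Outward normal from winding: with y down, positive shoelace area means
    # the interior lies to the left of travel in screen terms, i.e. at
    # (-ty, tx); rotate the tangent accordingly.
    sign = 1.0 if contour.signed_area() > 0 else -1.0
    normals_out = sign * np.column_stack([tangents[:, 1], -tangents[:, 0]])

    distances = np.linspace(-half_length, half_length, n_samples)
    # position = point - d * n_out  (positive distance goes inward)
    sample_x = points[:, 0, None] - distances[None, :] * normals_out[:, 0, None]
    sample_y = points[:, 1, None] - distances[None, :] * normals_out[:, 1, None]

    in_bounds = (
        (sample_x >= 0) & (sample_x <= image.shape[1] - 1)
        & (sample_y >= 0) & (sample_y <= image.shape[0] - 1)
    ).all(axis=1)
    n_dropped = int(np.count_nonzero(~in_bounds))
    if not in_bounds.any():
        raise GeometryError("every linescan leaves the image frame; contour outside image?")

    coords = np.stack([sample_y[in_bounds].ravel(), sample_x[in_bounds].ravel()])
    vals = ndimage.map_coordinates(image, coords, order=3, mode="nearest")
    scans = vals.reshape(-1, n_samples)
    return LinescanSet(
        distances=distances,
        scans=scans,
        arc_positions=positions[in_bounds],
        points=points[in_bounds],
        total_length=total,
        closed=contour.closed,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Profile averaging
# ---------------------------------------------------------------------------

@dataclass
class MembraneProfile:
    """Averaged cross-membrane intensity profile, membrane at distance 0."""

    distance: np.ndarray
    mean_intensity: np.ndarray
    sd_intensity: np.ndarray
    n_lines: int
    arc_fraction: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance": self.distance,
            "mean": self.mean_intensity,
            "sd": self.sd_intensity,
            "n": self.n_lines,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(Path(path), index=False)


def average_profiles(
    linescans: LinescanSet,
    arc_fraction: float = 1.0,
    anchor=None,
) -> MembraneProfile:
    """Pointwise mean +/- sd over linescans from a contiguous contour arc.

    ``arc_fraction`` selects that fraction of the contour's total arc length,
    centered on the contour point nearest the user-supplied ``anchor`` (an
    (x, y) coordinate, e.g. the posterior pole).  Fraction 1 averages the
    whole circumference and needs no anchor.  No axis-detection heuristic is
    attempted: anchors are always explicit.
    """
    if not 0 < arc_fraction <= 1:
        raise ParameterError(f"arc_fraction must be in (0, 1], got {arc_fraction}")
    if arc_fraction < 1.0:
        if anchor is None:
            raise ParameterError("selecting a partial arc requires an anchor point")
        anchor = np.asarray(anchor, dtype=np.float64)
        d2 = np.sum((linescans.points - anchor[None, :]) ** 2, axis=1)
        a0 = linescans.arc_positions[int(np.argmin(d2))]
        half = arc_fraction * linescans.total_length / 2.0
        delta = np.abs(linescans.arc_positions - a0)
        if linescans.closed:
            delta = np.minimum(delta, linescans.total_length - delta)
        sel = delta <= half
    else:
        sel = np.ones(linescans.n_lines, dtype=bool)
    if not sel.any():
        raise ParameterError("arc selection contains no linescans")
    scans = linescans.scans[sel]
    return MembraneProfile(
        distance=linescans.distances.copy(),
        mean_intensity=scans.mean(axis=0),
        sd_intensity=scans.std(axis=0),
        n_lines=int(scans.shape[0]),
        arc_fraction=arc_fraction,
    )
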