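"""Second-moment ellipse fit of a binary mask.

Each mask is summarised by the ellipse that has the same centroid and the
same normalized central second moments as the set of foreground pixel
centers (unit point masses — the convention of standard region-property
implementations).  From the fit come the five static shape descriptors used
downstream: centroid, full major/minor axis lengths b and a, major-axis
orientation φ, elongation ε = 1 − a/b, and area.

Orientation is measured in degrees from +x (columns, rightward) toward +y
(rows, downward on screen) and reported modulo 180° — the axis is
undirected.  The fit is deterministic and parameter-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import TrackConfig
from .mask_io import MaskFrame

__all__ = ["ShapeState", "central_moments", "fit_second_moment_ellipse"]


@dataclass
class ShapeState:
    """Per-frame ellipse fit in physical units (µm, µm²)."""

    frame_index: int
    time_s: float
    centroid_x_um: float
    centroid_y_um: float
    #: full minor axis length a (µm); a <= b
    minor_axis_a_um: float
    #: full major axis length b (µm)
    major_axis_b_um: float
    #: major-axis orientation φ, degrees in [0, 180), from +x toward +y
    orientation_phi_deg: float
    #: elongation ε = 1 − a/b, in [0, 1)
    elongation_eps: float
    area_um2: float
    #: set when the mask was too small for meaningful second moments and the
    #: semi-axes were clamped to half a pixel
    degenerate: bool = False
    # Exact-translation bookkeeping: the centroid in pixels is
    # origin (integer bounding-box corner) + local part.  Displacements are
    # computed from this split so that integer translation of the masks
    # leaves every step descriptor bit-identical.
    origin_x_px: float = 0.0
    origin_y_px: float = 0.0
    centroid_x_px_local: float = math.nan
    centroid_y_px_local: float = math.nan


def central_moments(frame: MaskFrame) -> tuple[float, float, float, float, float, float]:
    """Zeroth and central second moments of the foreground pixel centers.

    Returns ``(m00, cx, cy, mu20, mu11, mu02)`` with the second moments
    normalized per pixel (divided by m00).  Coordinates are in pixels,
    x = column, y = row.
    """
    m00, x0, y0, cx_loc, cy_loc, mu20, mu11, mu02 = _anchored_moments(frame)
    return float(m00), x0 + cx_loc, y0 + cy_loc, mu20, mu11, mu02


def _anchored_moments(frame: MaskFrame):
    """Moments relative to the bounding-box corner (x0, y0).

    Working in local coordinates makes the second moments and the local
    centroid exactly invariant under integer translation of the mask; the
    absolute centroid is origin + local part.
    """
    ys, xs = np.nonzero(frame.pixels)
    m00 = xs.size
    if m00 == 0:
        raise ValueError(f"frame {frame.frame_index}: empty mask")
    x0 = int(xs.min())
    y0 = int(ys.min())
    xl = xs - x0
    yl = ys - y0
    cx_loc = xl.mean()
    cy_loc = yl.mean()
    dx = xl - cx_loc
    dy = yl - cy_loc
    mu20 = float(np.dot(dx, dx)) / m00
    mu02 = float(np.dot(dy, dy)) / m00
    mu11 = float(np.dot(dx, dy)) / m00
    return m00, float(x0), float(y0), float(cx_loc), float(cy_loc), mu20, mu11, mu02


def fit_second_moment_ellipse(frame: MaskFrame, config: TrackConfig) -> ShapeState:
    """Fit the ellipse of identical second moments to a binary mask.

    The covariance matrix [[mu20, mu11], [mu11, mu02]] has eigenvalues
    λ₁ ≥ λ₂; the full axis lengths are b = 4√λ₁ and a = 4√λ₂ (the ellipse of
    the same per-pixel second moments), and the major-axis orientation is
    φ = ½·atan2(2·mu11, mu20 − mu02) mapped into [0, 180).  Lengths, centroid
    and area are scaled to µm / µm² with the pixel calibration.

    A mask whose second moments vanish along an axis (single pixel, 1-pixel-
    wide line) would yield a zero axis; semi-axes are clamped to half a pixel
    and the frame flagged degenerate instead.
    """
    m00, x0, y0, cx_loc, cy_loc, mu20, mu11, mu02 = _anchored_moments(frame)
    cx = x0 + cx_loc
    cy = y0 + cy_loc
    # eigenvalues of the 2x2 covariance, closed form
    common = math.hypot(mu20 - mu02, 2.0 * mu11) / 2.0
    mean = (mu20 + mu02) / 2.0
    lam1 = mean + common
    lam2 = max(mean - common, 0.0)
    phi = 0.5 * math.degrees(math.atan2(2.0 * mu11, mu20 - mu02))
    phi %= 180.0

    semi_major = 2.0 * math.sqrt(lam1)
    semi_minor = 2.0 * math.sqrt(lam2)
    degenerate = semi_minor < 0.5 or semi_major < 0.5
    semi_major = max(semi_major, 0.5)
    semi_minor = max(semi_minor, 0.5)

    eps = 1.0 - semi_minor / semi_major
    px = frame.pixel_size_um
    return ShapeState(
        frame_index=frame.frame_index,
        time_s=frame.time_s,
        centroid_x_um=cx * px,
        centroid_y_um=cy * px,
        minor_axis_a_um=2.0 * semi_minor * px,
        major_axis_b_um=2.0 * semi_major * px,
        orientation_phi_deg=phi,
        elongation_eps=eps,
        area_um2=m00 * px * px,
        degenerate=degenerate,
        origin_x_px=x0,
        origin_y_px=y0,
        centroid_x_px_local=cx_loc,
        centroid_y_px_local=cy_loc,
    )
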