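"""Per-step kinematic descriptors: displacement, α, uMM, sMM and Δϕ.

Step n links frames n and n+1 (1-based).  For each step the module computes
the centroid displacement vector d(n) = centroid(n+1) − centroid(n), the
turning angle α(n) between d(n−1) and d(n), the unsigned morphomigrational
angle uMM(n) — the acute angle between the fitted major axis at frame n and
d(n) — and its signed counterpart sMM(n), positive when the displacement
lies on the same side of the major axis as at the first frame that defines a
side.  The major-axis re-orientation between consecutive frames is Δϕ(n)
("M.A. dynamics").

All signed angles use screen coordinates (x right, y down): a turn that
appears clockwise on screen is positive.  The fitted axis is undirected, so
a per-track direction is propagated along the sequence by requiring
consecutive direction vectors to have non-negative dot product; this bounds
Δϕ to [−90°, 90°] and makes "same side of the axis" well defined.  The
side-tracking sign rule is a reconstruction of the published sign behaviour
(see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .config import TrackConfig
from .geometry import ShapeState

__all__ = [
    "StepKinematics",
    "displacement",
    "signed_angle",
    "turning_angle",
    "propagate_axis_directions",
    "ma_dynamics",
    "umm_angle",
    "smm_angles",
    "compute_track",
    "resample_track",
]

#: relative cross-product magnitude below which the displacement is treated
#: as exactly parallel to the axis (side = 0)
_PARALLEL_TOL = 1e-12


@dataclass
class StepKinematics:
    """Descriptors of step n (frames n → n+1).  NaN marks undefined values."""

    frame_index: int
    dx_um: float
    dy_um: float
    displacement_um: float
    speed_um_s: float
    uMM_deg: float = math.nan
    sMM_deg: float = math.nan
    #: +1 / −1: side of the major axis the displacement falls on; 0 = on axis
    side: int = 0
    turning_alpha_deg: float = math.nan
    ma_dynamics_dphi_deg: float = math.nan
    #: propagated axis direction at frame n (unit vector)
    axis_dir: tuple[float, float] = (math.nan, math.nan)
    #: elongation at frame n (copied for convenience of the classifiers)
    elongation_eps: float = math.nan
    zero_displacement: bool = False
    low_elongation: bool = False
    no_reference_side: bool = False
    degenerate: bool = False

    @property
    def valid(self) -> bool:
        """True when the step has a usable displacement (uMM/sMM defined)."""
        return not self.zero_displacement


def displacement(
    shape_n: ShapeState, shape_n1: ShapeState, config: TrackConfig
) -> tuple[float, float, float, float, bool]:
    """Centroid displacement of one step.

    Returns ``(dx, dy, |d|, speed, zero_displacement)`` in µm and µm/s.
    Displacements below ``min_displacement_px`` pixels are flagged: sub-pixel
    centroid shifts are segmentation noise and would produce wild angles.
    """
    if not (
        math.isnan(shape_n.centroid_x_px_local)
        or math.isnan(shape_n1.centroid_x_px_local)
    ):
        # origin/local split: bit-identical under integer mask translation
        dx_px = (shape_n1.centroid_x_px_local - shape_n.centroid_x_px_local) + (
            shape_n1.origin_x_px - shape_n.origin_x_px
        )
        dy_px = (shape_n1.centroid_y_px_local - shape_n.centroid_y_px_local) + (
            shape_n1.origin_y_px - shape_n.origin_y_px
        )
        dx = dx_px * config.pixel_size_um
        dy = dy_px * config.pixel_size_um
    else:  # hand-built ShapeStates without pixel bookkeeping
        dx = shape_n1.centroid_x_um - shape_n.centroid_x_um
        dy = shape_n1.centroid_y_um - shape_n.centroid_y_um
    norm = math.hypot(dx, dy)
    speed = norm / config.frame_interval_s
    flagged = norm < config.min_displacement_px * config.pixel_size_um
    return dx, dy, norm, speed, flagged


def signed_angle(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Signed angle from p to q in degrees, in (−180, 180].

    Positive = the rotation from p to q appears clockwise on screen (y-down
    axes).  Both vectors must be nonzero; the caller flags zero vectors.
    """
    cross = p[0] * q[1] - p[1] * q[0]
    dot = p[0] * q[0] + p[1] * q[1]
    ang = math.degrees(math.atan2(cross, dot))
    if ang == -180.0:
        ang = 180.0
    return ang


def turning_angle(
    d_prev: tuple[float, float] | None, d_curr: tuple[float, float] | None
) -> float:
    """Turning angle α between consecutive displacement vectors.

    NaN when either displacement is missing/flagged (first step of a track,
    or a step adjacent to a zero-displacement step).
    """
    if d_prev is None or d_curr is None:
        return math.nan
    return signed_angle(d_prev, d_curr)


def propagate_axis_directions(orientations_phi_deg: list[float]) -> list[tuple[float, float]]:
    """Assign a continuous direction to the undirected major axis per frame.

    u₁ = (cos φ₁, sin φ₁); each subsequent uₙ is ±(cos φₙ, sin φₙ) with the
    sign chosen so uₙ·uₙ₋₁ ≥ 0.  An exact-perpendicular tie (dot = 0) is
    resolved so the step reads Δϕ = +90°.
    """
    dirs: list[tuple[float, float]] = []
    for i, phi in enumerate(orientations_phi_deg):
        r = math.radians(phi)
        u = (math.cos(r), math.sin(r))
        if i > 0:
            prev = dirs[-1]
            dot = prev[0] * u[0] + prev[1] * u[1]
            if dot < 0:
                u = (-u[0], -u[1])
            elif dot == 0:
                cross = prev[0] * u[1] - prev[1] * u[0]
                if cross < 0:  # pick the candidate giving +90, not −90
                    u = (-u[0], -u[1])
        dirs.append(u)
    return dirs


def ma_dynamics(
    u_n: tuple[float, float], u_n1: tuple[float, float], clockwise_positive: bool = True
) -> float:
    """Δϕ between consecutive propagated axis directions, in [−90, 90]."""
    dphi = signed_angle(u_n, u_n1)
    return dphi if clockwise_positive else -dphi


def umm_angle(u_n: tuple[float, float], d_n: tuple[float, float]) -> float:
    """Acute angle between the (undirected) major axis and the displacement.

    uMM = arccos(|u·d| / |d|) in degrees, in [0, 90]; invariant to flipping
    the axis direction.
    """
    norm = math.hypot(d_n[0], d_n[1])
    if norm == 0:
        return math.nan
    c = abs(u_n[0] * d_n[0] + u_n[1] * d_n[1]) / norm
    return math.degrees(math.acos(min(c, 1.0)))


def _side_of_axis(u: tuple[float, float], d: tuple[float, float]) -> int:
    """Which side of the axis the displacement falls on: +1, −1 or 0."""
    norm = math.hypot(d[0], d[1])
    if norm == 0:
        return 0
    cross = (u[0] * d[1] - u[1] * d[0]) / norm
    if abs(cross) < _PARALLEL_TOL:
        return 0
    return 1 if cross > 0 else -1


def smm_angles(steps: list[StepKinematics]) -> None:
    """Assign signed sMM values to a track of steps, in place.

    The reference side is the side at the first valid step whose displacement
    is not exactly on the axis; it is fixed once per track.  sMM = +uMM when
    the step's side equals the reference, −uMM when opposite, and +0 when the
    motion is exactly along the axis.  Valid steps before a reference exists
    are flagged ``no_reference_side`` and carry a positive sign.
    """
    reference = 0
    for step in steps:
        if not step.valid or math.isnan(step.uMM_deg):
            continue
        if reference == 0:
            if step.side != 0:
                reference = step.side
            else:
                step.no_reference_side = True
                step.sMM_deg = +step.uMM_deg
                continue
        if step.side == 0:
            step.sMM_deg = +step.uMM_deg  # motion exactly along the axis: +0 convention
        else:
            step.sMM_deg = step.uMM_deg if step.side == reference else -step.uMM_deg


def compute_track(shapes: list[ShapeState], config: TrackConfig) -> list[StepKinematics]:
    """Assemble all per-step descriptors for a fitted track.

    For N frames there are N−1 steps; sMM/uMM/Δϕ are defined on steps
    1..N−1, α on steps 2..N−1 (and never adjacent to a flagged
    zero-displacement step).
    """
    if len(shapes) < 2:
        raise ValueError(f"need >= 2 frames to compute a track, got {len(shapes)}")
    dirs = propagate_axis_directions([s.orientation_phi_deg for s in shapes])

    steps: list[StepKinematics] = []
    d_vectors: list[tuple[float, float] | None] = []
    for n in range(len(shapes) - 1):
        dx, dy, norm, speed, flagged = displacement(shapes[n], shapes[n + 1], config)
        u = dirs[n]
        step = StepKinematics(
            frame_index=shapes[n].frame_index,
            dx_um=dx,
            dy_um=dy,
            displacement_um=norm,
            speed_um_s=speed,
            axis_dir=u,
            elongation_eps=shapes[n].elongation_eps,
            zero_displacement=flagged,
            low_elongation=shapes[n].elongation_eps < config.low_elongation_cutoff
            or shapes[n].degenerate,
            degenerate=shapes[n].degenerate,
        )
        step.ma_dynamics_dphi_deg = ma_dynamics(
            u, dirs[n + 1], config.dphi_clockwise_positive
        )
        if not flagged:
            step.uMM_deg = umm_angle(u, (dx, dy))
            step.side = _side_of_axis(u, (dx, dy))
            d_vectors.append((dx, dy))
        else:
            d_vectors.append(None)
        steps.append(step)

    for n in range(1, len(steps)):
        steps[n].turning_alpha_deg = turning_angle(d_vectors[n - 1], d_vectors[n])

    smm_angles(steps)
    return steps


def resample_track(
    shapes: list[ShapeState], config: TrackConfig, k: int
) -> tuple[list[ShapeState], TrackConfig]:
    """Keep frames 1, 1+k, 1+2k, … and rescale the frame interval to k·dt.

    Useful for studying the interval dependence of the step-based
    descriptors.  Frame indices are renumbered consecutively; absolute times
    are preserved from the original frames.
    """
    if k < 1:
        raise ValueError(f"resampling factor must be a positive integer, got {k}")
    if k >= len(shapes):
        raise ValueError(
            f"resampling factor {k} leaves fewer than 2 of {len(shapes)} frames"
        )
    kept = [replace(s, frame_index=i + 1) for i, s in enumerate(shapes[::k])]
    new_config = replace(config, frame_interval_s=config.frame_interval_s * k)
    return kept, new_config
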