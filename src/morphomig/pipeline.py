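"""End-to-end track analysis: masks in, descriptor tables out.

Chains component selection, ellipse fitting, step kinematics, coarse-grain
labelling, behaviour annotation and per-track summarisation into one call,
and assembles the per-frame step table written by :mod:`morphomig.mask_io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .behaviours import BehaviourSegment, annotate, behaviour_census
from .classify import CoarseLabels, label_track
from .config import TrackConfig
from .geometry import ShapeState, fit_second_moment_ellipse
from .kinematics import StepKinematics, compute_track
from .mask_io import STEP_TABLE_COLUMNS, MaskFrame, select_component
from .summaries import TrackSummary, summarize_track

__all__ = ["TrackResult", "analyze_frames", "assemble_step_table"]


@dataclass
class TrackResult:
    """Everything computed for one mask sequence."""

    config: TrackConfig
    shapes: list[ShapeState]
    steps: list[StepKinematics]
    labels: list[CoarseLabels]
    behaviours: list[str]
    segments: list[BehaviourSegment]
    census: pd.DataFrame
    summary: TrackSummary
    table: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def analyze_frames(
    frames: list[MaskFrame],
    config: TrackConfig,
    component_policy: str = "largest",
) -> TrackResult:
    """Run the whole descriptor pipeline on a calibrated mask sequence.

    The single-cell contract is enforced first: each frame is reduced to one
    8-connected component (policy "largest", or "nearest" to the previous
    frame's centroid).
    """
    if len(frames) < 2:
        raise ValueError(f"need >= 2 frames, got {len(frames)}")
    times = [f.time_s for f in frames]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("frame times must be strictly increasing")

    shapes: list[ShapeState] = []
    prev_centroid_px: tuple[float, float] | None = None
    for frame in frames:
        selected = select_component(frame, component_policy, prev_centroid_px)
        shape = fit_second_moment_ellipse(selected, config)
        prev_centroid_px = (
            shape.centroid_x_um / config.pixel_size_um,
            shape.centroid_y_um / config.pixel_size_um,
        )
        shapes.append(shape)

    steps = compute_track(shapes, config)
    labels = label_track(steps, config)
    behaviours, segments = annotate(labels, steps, config)
    census = behaviour_census(segments, config.frame_interval_s)
    summary = summarize_track(steps)
    table = assemble_step_table(shapes, steps, labels, behaviours)
    return TrackResult(
        config=config,
        shapes=shapes,
        steps=steps,
        labels=labels,
        behaviours=behaviours,
        segments=segments,
        census=census,
        summary=summary,
        table=table,
    )


def assemble_step_table(
    shapes: list[ShapeState],
    steps: list[StepKinematics],
    labels: list[CoarseLabels] | None = None,
    behaviours: list[str] | None = None,
) -> pd.DataFrame:
    """Per-frame table with step n's values on frame n's row.

    The last frame has no outgoing step, so its step fields are empty; the
    turning angle is additionally empty on the first frame.  Works for a
    single-frame track (one row, all step fields empty).
    """
    rows = []
    for i, shape in enumerate(shapes):
        row: dict = {c: math.nan for c in STEP_TABLE_COLUMNS}
        row.update(
            frame=shape.frame_index,
            time_s=shape.time_s,
            centroid_x_um=shape.centroid_x_um,
            centroid_y_um=shape.centroid_y_um,
            area_um2=shape.area_um2,
            elongation=shape.elongation_eps,
            orientation_deg=shape.orientation_phi_deg,
            degenerate=shape.degenerate,
        )
        if i < len(steps):
            s = steps[i]
            row.update(
                displacement_um=s.displacement_um,
                speed_um_s=s.speed_um_s,
                uMM_deg=s.uMM_deg,
                sMM_deg=s.sMM_deg,
                turning_deg=s.turning_alpha_deg,
                ma_dynamics_deg=s.ma_dynamics_dphi_deg,
                side=s.side,
                zero_displacement=s.zero_displacement,
                low_elongation=s.low_elongation,
                no_reference_side=s.no_reference_side,
            )
            if labels is not None:
                lab = labels[i]
                row.update(
                    smm_label=lab.smm_label,
                    smm_sign=lab.smm_sign,
                    alpha_label=lab.alpha_label,
                    alpha_sign=lab.alpha_sign,
                    dphi_label=lab.dphi_label,
                    dphi_sign=lab.dphi_sign,
                    eps_label=lab.eps_label,
                )
            if behaviours is not None:
                row["behaviour"] = behaviours[i]
        rows.append(row)
    return pd.DataFrame(rows, columns=STEP_TABLE_COLUMNS)
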