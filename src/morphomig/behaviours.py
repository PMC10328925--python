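"""Rule-based annotation of named morphomigrational behaviours.

Translates the per-step coarse labels and sign patterns into named
behaviours (lateral/perpendicular/askew displacement, lateral U-turn,
gradual redirection, lateral/perpendicular stretching, rear retraction,
rounded-chaotic).  The published behaviour catalogue is verbal; the rules
here are one consistent quantitative encoding of it, with all thresholds in
:class:`morphomig.config.BehaviourRules` (see docs/methods.md for the
reasoning behind each default).

Rules fire per step in a fixed priority order, with the two stretching rules
evaluated over windows of consecutive steps first and their member steps
claimed at the window rule's priority.  A near-circular frame (low ε)
dominates everything: the major axis of an almost-circular shape orients
itself essentially at random, so the orientation-based labels carry no
information there.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import CoarseLabels
from .config import TrackConfig
from .kinematics import StepKinematics

__all__ = ["BEHAVIOUR_LABELS", "BehaviourSegment", "annotate", "behaviour_census"]

BEHAVIOUR_LABELS = [
    "LATERAL_DISPLACEMENT",
    "PERPENDICULAR_DISPLACEMENT",
    "ASKEW_DISPLACEMENT",
    "LATERAL_U_TURN",
    "GRADUAL_REDIRECTION",
    "LATERAL_STRETCHING",
    "PERPENDICULAR_STRETCHING",
    "REAR_RETRACTION",
    "ROUNDED_CHAOTIC",
    "UNCLASSIFIED",
]

_ALPHA_HIGH = {"high", "very_high"}
_DPHI_HIGH = {"high", "very_high"}
_SMM_LOW = {"very_low", "low"}
_SMM_HIGHISH = {"moderate", "high"}


@dataclass
class BehaviourSegment:
    """A maximal run of consecutive steps sharing one behaviour label."""

    label: str
    start_frame: int
    end_frame: int  # last frame touched by the segment's steps
    evidence: str

    @property
    def n_steps(self) -> int:
        return self.end_frame - self.start_frame


def _smm_sign_constant(
    labels: list[CoarseLabels], steps: list[StepKinematics], i: int, j: int, tol: float
) -> bool:
    """Sign constancy of sMM over steps i..j, tolerating flips near zero."""
    signs = {
        labels[k].smm_sign
        for k in range(i, j + 1)
        if labels[k].smm_sign is not None and abs(steps[k].sMM_deg) > tol
    }
    return len(signs) <= 1


def _smm_sign_changes(
    labels: list[CoarseLabels], steps: list[StepKinematics], i: int, j: int, tol: float
) -> int:
    """Number of adjacent sign flips of sMM over steps i..j (near-zero steps skipped)."""
    seq = [
        labels[k].smm_sign
        for k in range(i, j + 1)
        if labels[k].smm_sign is not None and abs(steps[k].sMM_deg) > tol
    ]
    return sum(1 for a, b in zip(seq, seq[1:]) if a != b)


def _runs(indices: list[bool]) -> list[tuple[int, int]]:
    """Maximal runs of True, as (first, last) index pairs."""
    runs = []
    start = None
    for i, flag in enumerate(indices):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(indices) - 1))
    return runs


def annotate(
    labels: list[CoarseLabels],
    steps: list[StepKinematics],
    config: TrackConfig,
) -> tuple[list[str], list[BehaviourSegment]]:
    """Assign one behaviour label per step and merge them into segments.

    Priority order (first match wins):

    1. ROUNDED_CHAOTIC — the frame's elongation band is low.
    2. REAR_RETRACTION — |sMM| jumps from very_low to high in one step while
       the turning angle stays low and Δϕ is high/very high at the jump (the
       shape re-orients between the two steps, so Δϕ is checked at the
       preceding step or the current one).
    3. LATERAL_U_TURN — movement along the axis with a high/very-high
       turning angle.
    4. PERPENDICULAR_STRETCHING — window of ≥ ``stretch_min_window`` steps
       of moderate/high sMM with at least one sign change and increasing ε.
    5. LATERAL_STRETCHING — window of ≥ ``stretch_min_window`` steps of
       very-low/low sMM containing ≥ ``lateral_stretch_min_alpha_high``
       high-turning steps, ε non-decreasing.
    6. GRADUAL_REDIRECTION — ≥ ``gradual_min_run`` consecutive steps of
       moderate sMM with constant sign and low/moderate turning angles of a
       consistent nonzero sign.
    7. PERPENDICULAR_DISPLACEMENT — high sMM, sign constant vs the previous
       step, low turning angle.
    8. ASKEW_DISPLACEMENT — moderate sMM, low turning angle.
    9. LATERAL_DISPLACEMENT — very-low/low sMM, low turning angle.

    Steps with undefined inputs that match no rule are UNCLASSIFIED.
    """
    if len(labels) != len(steps):
        raise ValueError("labels and steps must have equal length")
    n = len(steps)
    rules = config.rules
    tol = rules.smm_sign_tolerance_deg

    # -- window rules, precomputed over maximal runs --------------------
    perp_stretch = set()
    for i, j in _runs([lab.smm_label in _SMM_HIGHISH for lab in labels]):
        if j - i + 1 < rules.stretch_min_window:
            continue
        if _smm_sign_changes(labels, steps, i, j, tol) < 1:
            continue
        if steps[j].elongation_eps - steps[i].elongation_eps > rules.eps_tolerance:
            perp_stretch.update(range(i, j + 1))

    lat_stretch = set()
    for i, j in _runs([lab.smm_label in _SMM_LOW for lab in labels]):
        if j - i + 1 < rules.stretch_min_window:
            continue
        n_high = sum(1 for k in range(i, j + 1) if labels[k].alpha_label in _ALPHA_HIGH)
        if n_high < rules.lateral_stretch_min_alpha_high:
            continue
        if steps[j].elongation_eps >= steps[i].elongation_eps - rules.eps_tolerance:
            lat_stretch.update(range(i, j + 1))

    gradual = set()

    def _gradual_ok(k: int) -> bool:
        lab = labels[k]
        return (
            lab.smm_label == "moderate"
            and lab.alpha_label in {"low", "moderate"}
            and abs(steps[k].turning_alpha_deg) > rules.alpha_sign_min_deg
        )

    for i, j in _runs([_gradual_ok(k) for k in range(n)]):
        if j - i + 1 < rules.gradual_min_run:
            continue
        alpha_signs = {labels[k].alpha_sign for k in range(i, j + 1)}
        if len(alpha_signs) == 1 and _smm_sign_constant(labels, steps, i, j, tol):
            gradual.update(range(i, j + 1))

    # -- per-step priority ----------------------------------------------
    out: list[str] = []
    for k in range(n):
        lab = labels[k]
        prev = labels[k - 1] if k > 0 else None
        if lab.eps_label == "low":
            out.append("ROUNDED_CHAOTIC")
        elif (
            prev is not None
            and prev.smm_label == "very_low"
            and lab.smm_label == "high"
            and lab.alpha_label == "low"
            and (prev.dphi_label in _DPHI_HIGH or lab.dphi_label in _DPHI_HIGH)
        ):
            out.append("REAR_RETRACTION")
        elif lab.smm_label in _SMM_LOW and lab.alpha_label in _ALPHA_HIGH:
            out.append("LATERAL_U_TURN")
        elif k in perp_stretch:
            out.append("PERPENDICULAR_STRETCHING")
        elif k in lat_stretch:
            out.append("LATERAL_STRETCHING")
        elif k in gradual:
            out.append("GRADUAL_REDIRECTION")
        elif (
            lab.smm_label == "high"
            and lab.alpha_label == "low"
            and (
                prev is None
                or prev.smm_sign is None
                or prev.smm_sign == lab.smm_sign
                or abs(steps[k - 1].sMM_deg) <= tol
            )
        ):
            out.append("PERPENDICULAR_DISPLACEMENT")
        elif lab.smm_label == "moderate" and lab.alpha_label == "low":
            out.append("ASKEW_DISPLACEMENT")
        elif lab.smm_label in _SMM_LOW and lab.alpha_label == "low":
            out.append("LATERAL_DISPLACEMENT")
        else:
            out.append("UNCLASSIFIED")

    # -- merge consecutive same-label steps into segments ----------------
    segments: list[BehaviourSegment] = []
    for i, j in _label_runs(out):
        lab = labels[i]
        evidence = (
            f"smm={lab.smm_label},alpha={lab.alpha_label},"
            f"dphi={lab.dphi_label},eps={lab.eps_label}"
        )
        segments.append(
            BehaviourSegment(
                label=out[i],
                start_frame=steps[i].frame_index,
                end_frame=steps[j].frame_index + 1,
                evidence=evidence,
            )
        )
    return out, segments


def _label_runs(seq: list[str]) -> list[tuple[int, int]]:
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            runs.append((start, i - 1))
            start = i
    return runs


def behaviour_census(
    segments: list[BehaviourSegment], frame_interval_s: float
) -> pd.DataFrame:
    """Counts and durations per behaviour label.

    One row per label present, with the number of segments, total steps,
    and mean segment duration in steps and in seconds.
    """
    if not segments:
        return pd.DataFrame(
            columns=["behaviour", "n_segments", "total_steps", "mean_steps", "mean_s"]
        )
    rows = []
    by_label: dict[str, list[int]] = {}
    for seg in segments:
        by_label.setdefault(seg.label, []).append(seg.n_steps)
    for label in BEHAVIOUR_LABELS:
        if label not in by_label:
            continue
        durations = by_label[label]
        mean_steps = sum(durations) / len(durations)
        rows.append(
            {
                "behaviour": label,
                "n_segments": len(durations),
                "total_steps": sum(durations),
                "mean_steps": mean_steps,
                "mean_s": mean_steps * frame_interval_s,
            }
        )
    return pd.DataFrame(rows)
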