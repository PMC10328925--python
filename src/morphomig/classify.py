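"""Coarse-grain banding of descriptor values.

Maps each numeric descriptor (sMM, α, Δϕ, ε) onto a small set of categorical
labels (very_low / low / moderate / high / very_high) via a band table.  The
default table reproduces the published coarse-grain definitions exactly,
including the printed ≤/< inclusivities: the signed parameters are banded on
|v| (the negative and positive rows mirror each other) and the sign is
reported separately.  Labelling is memoryless — each value depends only on
itself and the band table, never on neighbouring frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import TrackConfig
from .kinematics import StepKinematics

__all__ = ["CoarseLabels", "DOMAINS", "classify", "classify_signed", "label_track"]

#: value domain per parameter (inclusive); signed parameters are symmetric
DOMAINS: dict[str, tuple[float, float]] = {
    "smm": (-90.0, 90.0),
    "alpha": (-180.0, 180.0),
    "dphi": (-90.0, 90.0),
    "eps": (0.0, 1.0),
}

_SIGNED = {"smm", "alpha", "dphi"}


@dataclass
class CoarseLabels:
    """Per-step categorical labels; None marks an undefined input."""

    frame_index: int
    smm_label: str | None = None
    smm_sign: str | None = None
    alpha_label: str | None = None
    alpha_sign: str | None = None
    dphi_label: str | None = None
    dphi_sign: str | None = None
    eps_label: str | None = None
    low_elongation: bool = False


def classify(
    value: float,
    parameter: str,
    bands: dict[str, list[tuple[str, float]]] | None = None,
) -> str:
    """Band label of a descriptor value.

    Signed parameters are classified on |value|.  Bands are
    lower-exclusive / upper-inclusive, with the lowest band including its
    lower domain edge, so every in-domain value receives exactly one label.
    """
    if bands is None:
        bands = TrackConfig(1.0, 1.0).bands
    if parameter not in DOMAINS:
        raise ValueError(f"unknown parameter {parameter!r}; expected one of {sorted(DOMAINS)}")
    lo, hi = DOMAINS[parameter]
    if math.isnan(value) or not (lo <= value <= hi):
        raise ValueError(f"{parameter} value {value} outside domain [{lo}, {hi}]")
    v = abs(value) if parameter in _SIGNED else value
    for label, upper in bands[parameter]:
        if v <= upper:
            return label
    raise ValueError(f"{parameter} value {value} not covered by band table")


def _sign(value: float) -> str:
    # +0 convention: a value of exactly zero carries a positive sign
    return "-" if value < 0 else "+"


def classify_signed(
    value: float,
    parameter: str,
    bands: dict[str, list[tuple[str, float]]] | None = None,
) -> tuple[str, str]:
    """Label and sign of a signed descriptor value."""
    return classify(value, parameter, bands), _sign(value)


def label_track(steps: list[StepKinematics], config: TrackConfig) -> list[CoarseLabels]:
    """Coarse labels for every step of a computed track.

    Undefined inputs (NaN) yield None labels; the per-step low-elongation
    flag is copied through so downstream rules can discount the
    orientation-based labels on near-circular frames.
    """
    out: list[CoarseLabels] = []
    for step in steps:
        lab = CoarseLabels(frame_index=step.frame_index, low_elongation=step.low_elongation)
        if not math.isnan(step.sMM_deg):
            lab.smm_label, lab.smm_sign = classify_signed(step.sMM_deg, "smm", config.bands)
        if not math.isnan(step.turning_alpha_deg):
            lab.alpha_label, lab.alpha_sign = classify_signed(
                step.turning_alpha_deg, "alpha", config.bands
            )
        if not math.isnan(step.ma_dynamics_dphi_deg):
            lab.dphi_label, lab.dphi_sign = classify_signed(
                step.ma_dynamics_dphi_deg, "dphi", config.bands
            )
        if not math.isnan(step.elongation_eps):
            lab.eps_label = classify(step.elongation_eps, "eps", config.bands)
        out.append(lab)
    return out
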