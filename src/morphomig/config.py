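"""Track-level configuration: calibration, thresholds, coarse-grain bands, rules.

A :class:`TrackConfig` carries everything that is not the mask pixels
themselves: the spatial calibration (µm per pixel), the temporal calibration
(seconds per frame), the validity thresholds, the coarse-grain band table that
maps descriptor values to categorical labels, and the thresholds of the
behaviour rule engine.  Configs are plain dataclasses serialisable to/from
YAML so a run is fully described by one small text file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

__all__ = ["BehaviourRules", "TrackConfig", "DEFAULT_BANDS"]


# Coarse-grain band tables.  Each entry is (label, upper_edge); a value v is
# assigned the first label with |v| <= upper_edge (lower bound exclusive,
# upper inclusive), which reproduces the printed inclusivities of the
# published band definitions exactly.  Signed parameters are banded on |v|
# with the sign reported separately, since the negative and positive rows of
# the table mirror each other with identical labels.
DEFAULT_BANDS: dict[str, list[tuple[str, float]]] = {
    "smm": [("very_low", 15.0), ("low", 45.0), ("moderate", 70.0), ("high", 90.0)],
    "alpha": [("low", 60.0), ("moderate", 90.0), ("high", 135.0), ("very_high", 180.0)],
    "dphi": [
        ("very_low", 10.0),
        ("low", 20.0),
        ("moderate", 45.0),
        ("high", 60.0),
        ("very_high", 90.0),
    ],
    "eps": [("low", 0.1), ("moderate", 0.6), ("high", 1.0)],
}


@dataclass
class BehaviourRules:
    """Thresholds of the behaviour rule engine.

    The published behaviour descriptions are verbal; these defaults are one
    consistent quantitative encoding (see docs/methods.md).
    """

    #: minimum window length (steps) for the two stretching rules
    stretch_min_window: int = 3
    #: minimum number of high/very-high turning-angle steps inside a
    #: lateral-stretching window
    lateral_stretch_min_alpha_high: int = 2
    #: minimum run length (steps) for gradual redirection
    gradual_min_run: int = 2
    #: sMM sign changes are tolerated in "constant sign" checks while
    #: |sMM| <= this value (sign is noise-dominated near zero)
    smm_sign_tolerance_deg: float = 15.0
    #: a turning-angle sign only counts as a consistent rotation direction
    #: (gradual redirection) when |alpha| exceeds this value
    alpha_sign_min_deg: float = 5.0
    #: slack allowed when testing elongation for "non-decreasing" over a
    #: window (absorbs rasterisation/segmentation jitter)
    eps_tolerance: float = 0.01


@dataclass
class TrackConfig:
    """Calibration and analysis parameters for one mask sequence."""

    #: physical size of one pixel, µm (> 0)
    pixel_size_um: float
    #: time between consecutive frames, seconds (> 0)
    frame_interval_s: float
    #: centroid displacements below this many pixels are flagged as
    #: zero-displacement (sub-quarter-pixel shifts are segmentation noise)
    min_displacement_px: float = 0.25
    #: elongation below this marks the orientation (hence sMM / Δϕ) as
    #: unreliable for a near-circular shape
    low_elongation_cutoff: float = 0.1
    #: handedness of Δϕ: True = clockwise-on-screen positive (same as α)
    dphi_clockwise_positive: bool = True
    #: coarse-grain band table, parameter -> [(label, upper_edge), ...]
    bands: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_BANDS.items()}
    )
    #: behaviour rule-engine thresholds
    rules: BehaviourRules = field(default_factory=BehaviourRules)

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not (self.frame_interval_s > 0):
            raise ValueError(
                f"frame_interval_s must be > 0, got {self.frame_interval_s}"
            )
        for name in ("min_displacement_px", "low_elongation_cutoff"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for param, table in self.bands.items():
            edges = [e for _, e in table]
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError(f"band edges for {param!r} must be increasing")

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["bands"] = {k: [[lbl, edge] for lbl, edge in v] for k, v in self.bands.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TrackConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = {
                k: [(str(lbl), float(edge)) for lbl, edge in v]
                for k, v in d["bands"].items()
            }
        if "rules" in d and isinstance(d["rules"], dict):
            d["rules"] = BehaviourRules(**d["rules"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrackConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)
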