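"""Per-track aggregation: means ± SD, histograms and paired-value tables.

Tracks are summarized independently (per-track semantics); means of the
signed descriptors are signed arithmetic means over valid (non-flagged)
steps, with the sample standard deviation, and the number of valid steps is
reported per descriptor.  Histograms default to 10° bins spanning each
descriptor's domain.  Paired tables (sMM vs α, sMM vs Δϕ, sMM vs ε) expose
the per-step scatter behind the summary, and absolute-value views support
behaviour-profile comparisons across cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import DOMAINS
from .kinematics import StepKinematics

__all__ = ["TrackSummary", "summarize_track", "compare_behaviour_profiles",
           "plot_histograms", "plot_smm_pairs"]

_HIST_PARAMS = ("smm", "alpha", "dphi")


@dataclass
class TrackSummary:
    """Signed means ± sample SD, valid-step counts, histograms, pair tables."""

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    n_valid: dict[str, int] = field(default_factory=dict)
    #: parameter -> (bin_edges, counts)
    histograms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    #: per-step paired values: sMM vs alpha / dphi / eps
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": p,
                "mean": self.mean.get(p, math.nan),
                "sd": self.sd.get(p, math.nan),
                "n_valid": self.n_valid.get(p, 0),
            }
            for p in ("smm", "alpha", "dphi", "eps")
        ]
        return pd.DataFrame(rows)


def _collect(steps: list[StepKinematics]) -> dict[str, np.ndarray]:
    def finite(values):
        arr = np.asarray(values, dtype=float)
        return arr[np.isfinite(arr)]

    return {
        "smm": finite([s.sMM_deg for s in steps]),
        "alpha": finite([s.turning_alpha_deg for s in steps]),
        "dphi": finite([s.ma_dynamics_dphi_deg for s in steps]),
        "eps": finite([s.elongation_eps for s in steps]),
    }


def summarize_track(steps: list[StepKinematics], bin_width_deg: float = 10.0) -> TrackSummary:
    """Aggregate one computed track.

    Undefined (NaN) step values are excluded; ``n_valid`` records how many
    steps entered each aggregate.  With zero valid steps the summary is
    empty (NaN mean/SD, n = 0); with one valid step the SD is undefined.
    """
    values = _collect(steps)
    out = TrackSummary()
    for p, arr in values.items():
        out.n_valid[p] = int(arr.size)
        out.mean[p] = float(arr.mean()) if arr.size else math.nan
        out.sd[p] = float(arr.std(ddof=1)) if arr.size > 1 else (
            0.0 if arr.size == 1 else math.nan
        )
    for p in _HIST_PARAMS:
        lo, hi = DOMAINS[p]
        edges = np.arange(lo, hi + bin_width_deg / 2, bin_width_deg)
        counts, edges = np.histogram(values[p], bins=edges)
        out.histograms[p] = (edges, counts)
    out.pairs = pd.DataFrame(
        {
            "frame": [s.frame_index for s in steps],
            "sMM_deg": [s.sMM_deg for s in steps],
            "turning_deg": [s.turning_alpha_deg for s in steps],
            "ma_dynamics_deg": [s.ma_dynamics_dphi_deg for s in steps],
            "elongation": [s.elongation_eps for s in steps],
        }
    )
    return out


def compare_behaviour_profiles(
    tracks: dict[str, tuple[list[StepKinematics], list[str]]]
) -> pd.DataFrame:
    """Long-format per-step profile table across annotated tracks.

    ``tracks`` maps a track name to ``(steps, per-step behaviour labels)``.
    One row per (track, frame, behaviour) with |sMM|, |α|, |Δϕ| and ε — the
    parallel-coordinates data for comparing how the same behaviour looks in
    different cells.  UNCLASSIFIED steps are kept so callers can filter.
    """
    rows = []
    for name, (steps, behaviours) in tracks.items():
        if len(steps) != len(behaviours):
            raise ValueError(f"track {name!r}: steps and behaviours differ in length")
        for step, beh in zip(steps, behaviours):
            rows.append(
                {
                    "track": name,
                    "frame": step.frame_index,
                    "behaviour": beh,
                    "abs_sMM_deg": abs(step.sMM_deg),
                    "abs_turning_deg": abs(step.turning_alpha_deg),
                    "abs_ma_dynamics_deg": abs(step.ma_dynamics_dphi_deg),
                    "elongation": step.elongation_eps,
                }
            )
    columns = [
        "track", "frame", "behaviour",
        "abs_sMM_deg", "abs_turning_deg", "abs_ma_dynamics_deg", "elongation",
    ]
    return pd.DataFrame(rows, columns=columns)


def plot_histograms(summary: TrackSummary, path) -> None:
    """Histogram panel (sMM, α, Δϕ) as a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    titles = {"smm": "sMM angle [deg]", "alpha": "turning angle [deg]",
              "dphi": "M.A. dynamics [deg]"}
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax, p in zip(axes, _HIST_PARAMS):
        edges, counts = summary.histograms[p]
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
               edgecolor="k", linewidth=0.3)
        ax.set_xlabel(titles[p])
        ax.set_ylabel("steps")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_smm_pairs(summary: TrackSummary, path) -> None:
    """sMM plotted against α, Δϕ and ε, as a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = summary.pairs
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax, (col, label) in zip(
        axes,
        [("turning_deg", "turning angle [deg]"),
         ("ma_dynamics_deg", "M.A. dynamics [deg]"),
         ("elongation", "elongation")],
    ):
        ax.scatter(pairs[col], pairs["sMM_deg"], s=12, alpha=0.7)
        ax.set_xlabel(label)
        ax.set_ylabel("sMM angle [deg]")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
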