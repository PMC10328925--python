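"""Reading and writing mask sequences and tabular results.

Input is a time-lapse sequence of binary masks of a single cell: either a
multi-page TIFF or a directory of lexicographically ordered single-page
images.  Any nonzero pixel is foreground, whatever the bit depth, which keeps
the reader compatible with masks exported from FIJI and similar tools.

Coordinate convention (used throughout the package): x is the column index
increasing rightward, y is the row index increasing downward — screen
coordinates, which anchor the clockwise-positive sign convention of the
angular descriptors.  Physical coordinates are pixel × pixel_size_um.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .config import TrackConfig

__all__ = [
    "MaskFrame",
    "read_mask_stack",
    "write_mask_stack",
    "select_component",
    "write_step_table",
    "read_step_table",
    "STEP_TABLE_COLUMNS",
]

#: 8-connectivity structuring element for component labelling
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp"}


@dataclass
class MaskFrame:
    """One binary frame of the sequence, with temporal/spatial calibration.

    ``pixels`` is a 2-D boolean array (rows × cols); ``frame_index`` is
    1-based; ``time_s`` is the absolute time of the frame.
    """

    pixels: np.ndarray
    frame_index: int
    time_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels) != 0
        if self.pixels.ndim != 2:
            raise ValueError(
                f"frame {self.frame_index}: mask must be 2-D, got shape "
                f"{self.pixels.shape}"
            )
        if self.frame_index < 1:
            raise ValueError(f"frame_index must be >= 1, got {self.frame_index}")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")


def _as_frames(pages: list[np.ndarray], config: TrackConfig, names: list[str]) -> list[MaskFrame]:
    shape = pages[0].shape
    frames: list[MaskFrame] = []
    for i, page in enumerate(pages):
        if page.ndim == 3:  # RGB(A) export of a mask: any nonzero channel
            page = page.reshape(page.shape[0], page.shape[1], -1).any(axis=2)
        if page.shape != shape:
            raise ValueError(
                f"inconsistent dimensions: {names[i]} has shape {page.shape}, "
                f"expected {shape}"
            )
        if not np.any(page):
            raise ValueError(f"frame {i + 1} ({names[i]}) contains no foreground pixels")
        frames.append(
            MaskFrame(
                pixels=page,
                frame_index=i + 1,
                time_s=i * config.frame_interval_s,
                pixel_size_um=config.pixel_size_um,
            )
        )
    return frames


def read_mask_stack(path: str | Path, config: TrackConfig) -> list[MaskFrame]:
    """Read a mask sequence from a multi-page TIFF or an image directory.

    Frames are returned in temporal order (page order, or lexicographic file
    name order for a directory) with ``time_s = (frame_index − 1) ×
    frame_interval_s``.  A frame with no foreground pixels aborts the read:
    the per-frame descriptor chain has no gap semantics.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise ValueError(f"no image files found in directory {path}")
        pages = []
        for f in files:
            try:
                pages.append(np.asarray(iio.imread(f)))
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise ValueError(f"could not read image {f}: {exc}") from exc
        return _as_frames(pages, config, [f.name for f in files])
    if not path.exists():
        raise FileNotFoundError(f"mask stack not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"could not read TIFF stack {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2-D pages, got shape {arr.shape}")
    if arr.shape[0] == 0:
        raise ValueError(f"{path}: empty stack")
    pages = [arr[i] for i in range(arr.shape[0])]
    names = [f"{path.name} page {i + 1}" for i in range(len(pages))]
    return _as_frames(pages, config, names)


def write_mask_stack(frames: list[MaskFrame], path: str | Path) -> None:
    """Write frames as a multi-page 8-bit TIFF (foreground = 255)."""
    stack = np.stack([f.pixels.astype(np.uint8) * 255 for f in frames])
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def select_component(
    frame: MaskFrame,
    policy: str = "largest",
    prev_centroid_px: tuple[float, float] | None = None,
) -> MaskFrame:
    """Retain exactly one 8-connected foreground component.

    policy "largest": keep the component with the most pixels; ties are
    broken toward the component whose first pixel in row-major scan order is
    smallest (lowest row, then column).  policy "nearest": keep the component
    whose centroid is nearest to ``prev_centroid_px`` (x, y in pixels); ties
    fall back to the "largest" rule.
    """
    labels, n = ndimage.label(frame.pixels, structure=_STRUCTURE_8)
    if n == 0:
        raise ValueError(f"frame {frame.frame_index}: no foreground component")
    if n == 1:
        return frame
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    if policy == "largest":
        best = int(np.argmax(sizes)) + 1  # argmax -> lowest label on ties;
        # labels are assigned in row-major scan order, so the lowest label is
        # the component with the first (row, col) pixel
    elif policy == "nearest":
        if prev_centroid_px is None:
            raise ValueError("policy 'nearest' requires the previous frame's centroid")
        cy, cx = zip(*ndimage.center_of_mass(frame.pixels, labels, range(1, n + 1)))
        px, py = prev_centroid_px
        d2 = (np.asarray(cx) - px) ** 2 + (np.asarray(cy) - py) ** 2
        order = np.lexsort((np.arange(n), -sizes, d2))  # distance, then size
        best = int(order[0]) + 1
    else:
        raise ValueError(f"unknown component policy {policy!r}")
    return replace(frame, pixels=labels == best)


#: stable column schema of the per-frame step table
STEP_TABLE_COLUMNS = [
    "frame",
    "time_s",
    "centroid_x_um",
    "centroid_y_um",
    "area_um2",
    "elongation",
    "orientation_deg",
    "displacement_um",
    "speed_um_s",
    "uMM_deg",
    "sMM_deg",
    "turning_deg",
    "ma_dynamics_deg",
    "side",
    "zero_displacement",
    "low_elongation",
    "no_reference_side",
    "degenerate",
    "smm_label",
    "smm_sign",
    "alpha_label",
    "alpha_sign",
    "dphi_label",
    "dphi_sign",
    "eps_label",
    "behaviour",
]


def write_step_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-frame step table as UTF-8 CSV.

    One row per frame; undefined edge values (sMM/Δϕ at the last frame, α at
    the first and last) are written as empty fields.  Floats are written with
    6 decimals so a round-trip read reproduces values to that precision.
    """
    missing = [c for c in STEP_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"step table is missing columns: {missing}")
    table.to_csv(
        Path(path),
        index=False,
        columns=STEP_TABLE_COLUMNS,
        float_format="%.6f",
        encoding="utf-8",
    )


def read_step_table(path: str | Path) -> pd.DataFrame:
    """Read a step table written by :func:`write_step_table`."""
    return pd.read_csv(Path(path), encoding="utf-8")
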