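"""Domain types for the imaging pipeline.

Conventions: coordinates are 0-based ``(row, col)`` pixel indices, ROI boxes
are half-open, intensities are single-precision floats on a 16-bit-like scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Tile:
    """One field acquired on the low-magnification grid."""

    pixels: np.ndarray              # 2-D intensity array
    grid_pos: tuple[int, int]       # (row_idx, col_idx) on the acquisition grid
    channel: str = "nuclei"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("Tile.pixels must be a non-empty 2-D array")


@dataclass
class SlideMosaic:
    """Stitched single-channel slide image."""

    pixels: np.ndarray
    tile_offsets: list[tuple[int, int]]
    pixel_size_um: float = 1.0


@dataclass
class ScaffoldDetection:
    centre: tuple[float, float]     # (row_px, col_px)
    radius_px: float
    score: float


@dataclass
class ROISet:
    scaffold_id: int
    centres: list[tuple[float, float]]
    roi_size_px: int


@dataclass
class ZStack:
    """Per-channel 3-D (plane, row, col) image stacks, planes aligned."""

    pixels: dict[str, np.ndarray]
    z_step_um: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        shapes = {self.pixels[c].shape for c in self.channel_names}
        if len(shapes) != 1:
            raise ValueError("all channels must share one (plane, row, col) shape")
        (shape,) = shapes
        if len(shape) != 3 or shape[0] < 1:
            raise ValueError("ZStack needs >=1 plane per channel")

    @property
    def n_planes(self) -> int:
        return self.pixels[self.channel_names[0]].shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[name]


@dataclass
class FocusSelection:
    plane_idx: int
    focus_scores: np.ndarray
    degenerate: bool = False        # all-constant stack: scores are all zero


@dataclass
class MicrotissueRecord:
    """One segmented microtissue with background-subtracted total intensity."""

    fov_id: str
    label: int
    area_px: int
    centroid: tuple[float, float]
    total_intensity: dict[str, float] = field(default_factory=dict)
    clamped: dict[str, bool] = field(default_factory=dict)


@dataclass
class FOVSummary:
    fov_id: str
    scaffold_id: str
    mean_intensity: dict[str, float]
    n_microtissues: int


@dataclass
class ScaffoldSummary:
    scaffold_id: str
    condition: str
    mean_intensity: dict[str, float]    # unweighted mean of FOV means
    n_fovs: int
    n_microtissues: int


@dataclass
class ConditionComparison:
    channel: str
    condition: str
    reference: str
    fold_change: float | None           # None when reference mean is zero
    percent_change: float | None        # 100 * (1 - cond/ref)
    p_value: float | None = None
    undefined_fold: bool = False
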