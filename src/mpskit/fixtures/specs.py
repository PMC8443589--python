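"""Validated generator specifications for all synthetic fixtures.

Every spec is a frozen-ish dataclass whose ``__post_init__`` enforces the
documented invariants, raising :class:`~mpskit.errors.ConfigurationError`
messages that name the offending field.  All randomness downstream derives
from the spec's ``seed`` through one named generator per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mpskit.errors import ConfigurationError

CHANNELS: tuple[str, ...] = ("nuclei", "cytoskeleton", "asma", "collagen1")


def default_roi_template(scaffold_radius_px: float, n: int = 8) -> list[tuple[float, float]]:
    """Ring of ``n`` ROI offsets at 55% of the scaffold radius.

    The real template geometry is instrument-defined; any fixed array shared
    across scaffolds satisfies the acquisition contract.
    """
    r = 0.55 * scaffold_radius_px
    out = []
    for i in range(n):
        theta = 2.0 * math.pi * i / n
        out.append((r * math.sin(theta), r * math.cos(theta)))
    return out


@dataclass
class SlideSpec:
    """Layout of a low-magnification nuclei-channel slide mosaic."""

    grid_rows: int = 2
    grid_cols: int = 2
    tile_size_px: int = 256
    overlap_frac: float = 0.1
    scaffold_centers: list[tuple[float, float]] = field(default_factory=list)
    scaffold_radius_px: float = 80.0
    rois_per_scaffold: int = 8
    roi_template: list[tuple[float, float]] | None = None
    fovs_per_scaffold: int = 8
    microtissues_per_fov_range: tuple[int, int] = (8, 12)
    microtissue_radius_px_range: tuple[float, float] = (8.0, 12.0)
    channel_names: tuple[str, ...] = CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("grid_rows/grid_cols must be >= 1")
        if self.tile_size_px < 8:
            raise ConfigurationError("tile_size_px must be >= 8")
        if not (0.0 <= self.overlap_frac < 0.5):
            raise ConfigurationError("overlap_frac must lie in [0, 0.5)")
        lo, hi = self.microtissues_per_fov_range
        if lo > hi:
            raise ConfigurationError(
                "microtissues_per_fov_range: min_count must be <= max_count"
            )
        rlo, rhi = self.microtissue_radius_px_range
        if rlo <= 0 or rlo > rhi:
            raise ConfigurationError("microtissue_radius_px_range must be positive and ordered")
        if self.roi_template is None:
            self.roi_template = default_roi_template(
                self.scaffold_radius_px, self.rois_per_scaffold
            )
        if len(self.roi_template) != self.rois_per_scaffold:
            raise ConfigurationError(
                "roi_template length must equal rois_per_scaffold "
                f"({len(self.roi_template)} != {self.rois_per_scaffold})"
            )
        nrow, ncol = self.mosaic_shape
        for i, (r, c) in enumerate(self.scaffold_centers):
            if not (
                self.scaffold_radius_px <= r <= nrow - 1 - self.scaffold_radius_px
                and self.scaffold_radius_px <= c <= ncol - 1 - self.scaffold_radius_px
            ):
                raise ConfigurationError(
                    f"scaffold_centers[{i}]: scaffold circle does not fit inside the mosaic"
                )

    @property
    def stride_px(self) -> int:
        return int(round(self.tile_size_px * (1.0 - self.overlap_frac)))

    @property
    def mosaic_shape(self) -> tuple[int, int]:
        return (
            self.stride_px * (self.grid_rows - 1) + self.tile_size_px,
            self.stride_px * (self.grid_cols - 1) + self.tile_size_px,
        )


@dataclass
class StackSpec:
    """One confocal Z-stack field of view with depth-dependent defocus."""

    n_planes: int = 25
    z_step_um: float = 5.0
    depth_um: float = 120.0
    in_focus_plane: int = 12
    defocus_sigma_per_plane_px: float = 1.5   # blur sigma = coeff * |plane - in_focus|
    condition_fold: dict[str, float] = field(default_factory=dict)
    background_level: float = 100.0
    noise_cv: float = 0.0
    fov_size_px: int = 192
    channel_names: tuple[str, ...] = CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ConfigurationError("n_planes must be >= 1")
        expected = (self.n_planes - 1) * self.z_step_um
        if not math.isclose(expected, self.depth_um, rel_tol=0, abs_tol=1e-9):
            raise ConfigurationError(
                "inconsistent stack geometry: (n_planes - 1) * z_step_um "
                f"= {expected} != depth_um = {self.depth_um}"
            )
        if not (0 <= self.in_focus_plane < self.n_planes):
            raise ConfigurationError("in_focus_plane must lie in [0, n_planes)")
        for ch, fold in self.condition_fold.items():
            if ch not in self.channel_names:
                raise ConfigurationError(f"condition_fold: unknown channel {ch!r}")
            if fold <= 0:
                raise ConfigurationError(f"condition_fold[{ch!r}] must be > 0")
        if self.defocus_sigma_per_plane_px < 0:
            raise ConfigurationError("defocus_sigma_per_plane_px must be >= 0")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.background_level < 0:
            raise ConfigurationError("background_level must be >= 0")


@dataclass
class DecaySpec:
    """First-order drug-elimination time course with multiplicative noise.

    Exactly one of ``k_per_h`` / ``t_half_h`` is required (they are mutually
    derivable via t_half = ln 2 / k); supplying both consistently is allowed.
    """

    c0_uM: float = 1.0
    k_per_h: float | None = None
    t_half_h: float | None = None
    sample_times_h: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 24.0, 30.0, 36.0, 42.0, 48.0)
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c0_uM <= 0:
            raise ConfigurationError("c0_uM must be > 0")
        if self.k_per_h is None and self.t_half_h is None:
            raise ConfigurationError("one of k_per_h / t_half_h is required")
        if self.k_per_h is None:
            if self.t_half_h <= 0:
                raise ConfigurationError("t_half_h must be > 0")
            self.k_per_h = math.log(2.0) / self.t_half_h
        elif self.t_half_h is None:
            if self.k_per_h < 0:
                raise ConfigurationError("k_per_h must be >= 0")
            self.t_half_h = math.log(2.0) / self.k_per_h if self.k_per_h > 0 else math.inf
        else:
            if self.k_per_h > 0 and not math.isclose(
                self.t_half_h, math.log(2.0) / self.k_per_h, rel_tol=1e-9
            ):
                raise ConfigurationError("k_per_h and t_half_h are inconsistent")
        times = np.asarray(self.sample_times_h, dtype=float)
        if times.size == 0 or times[0] < 0 or np.any(np.diff(times) <= 0):
            raise ConfigurationError(
                "sample_times_h must be non-negative and strictly increasing"
            )
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")


@dataclass
class ExprSpec:
    """Log2-scale expression matrix with group, plate and residual effects."""

    n_genes: int = 1000
    n_reps_per_group: int = 3
    groups: tuple[str, ...] = ("control", "nash")
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed log2fc
    batch_assignment: dict[str, str] | None = None            # sample -> plate label
    batch_sd: float = 0.0
    residual_sd: float = 0.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_reps_per_group < 1:
            raise ConfigurationError("n_genes and n_reps_per_group must be >= 1")
        if len(self.groups) < 2:
            raise ConfigurationError("at least two groups are required")
        if self.batch_sd < 0 or self.residual_sd < 0:
            raise ConfigurationError("batch_sd and residual_sd must be >= 0")
        universe = set(self.gene_ids())
        for g in self.de_genes:
            if g not in universe:
                raise ConfigurationError(f"de_genes: {g!r} is not in the gene universe")
        if self.batch_assignment is not None:
            samples = set(self.sample_ids())
            for s in self.batch_assignment:
                if s not in samples:
                    raise ConfigurationError(f"batch_assignment: unknown sample {s!r}")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def sample_ids(self) -> list[str]:
        return [
            f"{grp}_{r + 1}" for grp in self.groups for r in range(self.n_reps_per_group)
        ]


@dataclass
class PanelSpec:
    """Analyte-by-sample biomarker panel with per-analyte detection limits."""

    analytes: tuple[str, ...]
    group_means: dict[tuple[str, str], float]     # (analyte, group) -> concentration
    detection_limit: dict[str, float] = field(default_factory=dict)
    groups: tuple[str, ...] = ("control", "nash")
    n_reps_per_group: int = 3
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.analytes:
            raise ConfigurationError("analytes must be non-empty")
        for (a, g), m in self.group_means.items():
            if a not in self.analytes:
                raise ConfigurationError(f"group_means: unknown analyte {a!r}")
            if g not in self.groups:
                raise ConfigurationError(f"group_means: unknown group label {g!r}")
            if m < 0:
                raise ConfigurationError(f"group_means[({a!r}, {g!r})] must be >= 0")
        for a, d in self.detection_limit.items():
            if a not in self.analytes:
                raise ConfigurationError(f"detection_limit: unknown analyte {a!r}")
            if d < 0:
                raise ConfigurationError(f"detection_limit[{a!r}] must be >= 0")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
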