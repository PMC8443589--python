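"""Synthetic confocal Z-stacks with depth-dependent defocus.

The in-focus plane holds the sharp rendered scene; every other plane is the
same scene blurred with a Gaussian whose sigma grows linearly with the plane
distance, so any monotone sharpness metric peaks exactly at the configured
in-focus plane.  Gaussian blur conserves integrated intensity, which keeps
per-object truth valid at every plane (up to border losses).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from mpskit.fixtures.render import (
    CHANNEL_BASE_AMPLITUDE,
    GroundTruth,
    MicrotissueTruth,
    add_tapered_disk,
    lognormal_noise,
    sample_positions,
)
from mpskit.fixtures.specs import StackSpec
from mpskit.imaging.types import ZStack


@dataclasses.dataclass
class FOVLayout:
    """Object layout for one field of view: centres, radii and amplitudes."""

    fov_id: str
    centres: np.ndarray                      # (n, 2) float
    radii: np.ndarray                        # (n,) float
    amplitudes: list[dict[str, float]]       # per object, per channel


def sample_fov_layout(
    spec: StackSpec,
    count_range: tuple[int, int] = (8, 12),
    radius_range: tuple[float, float] = (8.0, 12.0),
    fov_id: str = "fov0",
    rng: np.random.Generator | None = None,
    amplitude_jitter: float = 0.3,
) -> FOVLayout:
    """Draw a microtissue layout: count uniform on the inclusive range,
    radii uniform, per-object amplitude = channel base x condition fold x
    Uniform(1 - jitter, 1 + jitter)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = int(rng.integers(count_range[0], count_range[1] + 1))
    radii = rng.uniform(radius_range[0], radius_range[1], size=n)
    centres = sample_positions(n, radii, (spec.fov_size_px, spec.fov_size_px), rng)
    amplitudes = []
    for _ in range(n):
        amps = {}
        for ch in spec.channel_names:
            base = CHANNEL_BASE_AMPLITUDE.get(ch, 1000.0)
            fold = spec.condition_fold.get(ch, 1.0)
            amps[ch] = base * fold * rng.uniform(1 - amplitude_jitter, 1 + amplitude_jitter)
        amplitudes.append(amps)
    return FOVLayout(fov_id=fov_id, centres=centres, radii=radii, amplitudes=amplitudes)


def gen_zstack(spec: StackSpec, layout: FOVLayout | None = None) -> tuple[ZStack, GroundTruth]:
    """Render a multi-channel Z-stack for one FOV and return it with truth.

    When ``layout`` is omitted one is sampled from the spec's seed with the
    default per-FOV count range.  Truth integrated intensities are the exact
    rendered background-free sums at the in-focus plane.
    """
    rng = np.random.default_rng(spec.seed)
    if layout is None:
        layout = sample_fov_layout(spec, rng=rng)

    shape = (spec.fov_size_px, spec.fov_size_px)
    scenes: dict[str, np.ndarray] = {}
    truth = GroundTruth(params=dataclasses.asdict(spec))
    per_object: list[dict[str, float]] = [dict() for _ in range(len(layout.radii))]

    for ch in spec.channel_names:
        scene = np.zeros(shape, dtype=np.float32)
        for i, ((r, c), rad, amps) in enumerate(
            zip(layout.centres, layout.radii, layout.amplitudes)
        ):
            per_object[i][ch] = add_tapered_disk(scene, (r, c), rad, amps[ch])
        scenes[ch] = scene

    for i, (centre, rad) in enumerate(zip(layout.centres, layout.radii)):
        truth.microtissues.append(
            MicrotissueTruth(
                fov_id=layout.fov_id,
                centre=(float(centre[0]), float(centre[1])),
                radius_px=float(rad),
                intensity=per_object[i],
            )
        )

    pixels: dict[str, np.ndarray] = {}
    for ch in spec.channel_names:
        stack = np.empty((spec.n_planes,) + shape, dtype=np.float32)
        for p in range(spec.n_planes):
            sigma = spec.defocus_sigma_per_plane_px * abs(p - spec.in_focus_plane)
            plane = scenes[ch] if sigma == 0 else gaussian_filter(scenes[ch], sigma=sigma)
            stack[p] = plane + spec.background_level
        if spec.noise_cv > 0:
            stack *= lognormal_noise(stack.shape, spec.noise_cv, rng)
        pixels[ch] = stack

    zstack = ZStack(
        pixels=pixels, z_step_um=spec.z_step_um, channel_names=tuple(spec.channel_names)
    )
    return zstack, truth


def gen_fov_stacks(
    spec: StackSpec,
    n_fovs: int,
    count_range: tuple[int, int] = (8, 12),
    radius_range: tuple[float, float] = (8.0, 12.0),
    fov_prefix: str = "fov",
) -> list[tuple[ZStack, GroundTruth]]:
    """Generate ``n_fovs`` independent FOV stacks from one seeded stream."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(n_fovs):
        layout = sample_fov_layout(
            spec, count_range, radius_range, fov_id=f"{fov_prefix}{i}", rng=rng
        )
        sub = dataclasses.replace(spec, seed=int(rng.integers(0, 2**31 - 1)))
        out.append(gen_zstack(sub, layout))
    return out
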