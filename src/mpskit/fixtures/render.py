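"""Low-level rendering primitives shared by the slide and stack generators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Per-channel base amplitudes on a 16-bit-like scale.  Disease folds multiply
# these for the marker channels.
CHANNEL_BASE_AMPLITUDE: dict[str, float] = {
    "nuclei": 20000.0,
    "cytoskeleton": 15000.0,
    "asma": 2000.0,
    "collagen1": 2000.0,
}

TAPER_SIGMA_PX = 1.5   # Gaussian edge taper of rendered disks


def add_tapered_disk(
    image: np.ndarray,
    centre: tuple[float, float],
    core_radius_px: float,
    amplitude: float,
    taper_sigma_px: float = TAPER_SIGMA_PX,
) -> float:
    """Add a Gaussian-tapered disk in place and return its integrated intensity.

    Profile: ``amplitude`` inside ``core_radius_px``, Gaussian falloff with
    ``taper_sigma_px`` beyond it.  The returned sum is the exact rendered
    (pre-noise, background-free) integrated intensity of the object.
    """
    r0, c0 = centre
    reach = int(np.ceil(core_radius_px + 4.0 * taper_sigma_px))
    rlo = max(0, int(np.floor(r0)) - reach)
    rhi = min(image.shape[0], int(np.ceil(r0)) + reach + 1)
    clo = max(0, int(np.floor(c0)) - reach)
    chi = min(image.shape[1], int(np.ceil(c0)) + reach + 1)
    rr, cc = np.meshgrid(
        np.arange(rlo, rhi, dtype=np.float32),
        np.arange(clo, chi, dtype=np.float32),
        indexing="ij",
    )
    d = np.hypot(rr - r0, cc - c0)
    excess = np.maximum(d - core_radius_px, 0.0)
    profile = amplitude * np.exp(-(excess**2) / (2.0 * taper_sigma_px**2))
    image[rlo:rhi, clo:chi] += profile
    return float(profile.sum())


def sample_positions(
    n: int,
    radii: np.ndarray,
    shape: tuple[int, int],
    rng: np.random.Generator,
    min_gap_px: float = 8.0,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample ``n`` non-overlapping disk centres inside ``shape``.

    Disks are kept ``min_gap_px`` apart edge-to-edge and clear of the image
    border so segmentation can recover each object individually.
    """
    centres: list[tuple[float, float]] = []
    margin = radii.max() + 4.0 * TAPER_SIGMA_PX + 2.0
    for i in range(n):
        for _ in range(max_tries):
            r = rng.uniform(margin, shape[0] - margin)
            c = rng.uniform(margin, shape[1] - margin)
            ok = all(
                np.hypot(r - rr, c - cc) >= radii[i] + radii[j] + min_gap_px
                for j, (rr, cc) in enumerate(centres)
            )
            if ok:
                centres.append((r, c))
                break
        else:  # pragma: no cover - defensive; defaults never saturate
            raise RuntimeError("could not place all objects without overlap")
    return np.asarray(centres, dtype=float)


def lognormal_noise(shape, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative lognormal noise field with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(shape, dtype=np.float32)
    sigma2 = np.log1p(cv**2)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=shape).astype(np.float32)


@dataclass
class MicrotissueTruth:
    fov_id: str
    centre: tuple[float, float]
    radius_px: float
    intensity: dict[str, float]   # per-channel integrated (background-free) sum


@dataclass
class GroundTruth:
    """Exhaustive record of everything a generator rendered."""

    microtissues: list[MicrotissueTruth] = field(default_factory=list)
    roi_centers: dict[int, list[tuple[float, float]]] = field(default_factory=dict)
    tile_offsets: list[tuple[int, int]] = field(default_factory=list)
    scaffold_centers: list[tuple[float, float]] = field(default_factory=list)
    scaffold_radius_px: float | None = None
    params: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "microtissues": [
                {
                    "fov_id": m.fov_id,
                    "centre": list(m.centre),
                    "radius_px": m.radius_px,
                    "intensity": m.intensity,
                }
                for m in self.microtissues
            ],
            "roi_centers": {
                str(k): [list(c) for c in v] for k, v in self.roi_centers.items()
            },
            "tile_offsets": [list(t) for t in self.tile_offsets],
            "scaffold_centers": [list(c) for c in self.scaffold_centers],
            "scaffold_radius_px": self.scaffold_radius_px,
            "params": self.params,
        }
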