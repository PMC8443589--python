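"""Synthetic low-magnification slide mosaics cut into overlapping tiles."""

from __future__ import annotations

import dataclasses

import numpy as np

from mpskit.fixtures.render import GroundTruth, MicrotissueTruth, add_tapered_disk
from mpskit.fixtures.specs import SlideSpec
from mpskit.imaging.types import Tile

SLIDE_BACKGROUND = 50.0
SCAFFOLD_BASE = 4000.0       # soft disk marking the scaffold footprint
NUCLEI_BLOB_AMP = 15000.0
N_BLOBS_PER_SCAFFOLD = 40


def gen_slide(spec: SlideSpec) -> tuple[list[Tile], GroundTruth]:
    """Render a nuclei-channel slide mosaic and cut it into grid tiles.

    Each scaffold is a soft-edged bright disk textured with small nuclei
    blobs.  Tiles are cut at the nominal grid offsets
    ``(r * stride, c * stride)`` with ``stride = round((1 - overlap) * tile)``;
    the ground truth records those offsets, the scaffold centres, the
    per-scaffold ROI centres and every rendered blob.
    """
    rng = np.random.default_rng(spec.seed)
    mosaic = np.full(spec.mosaic_shape, SLIDE_BACKGROUND, dtype=np.float32)

    truth = GroundTruth(
        scaffold_centers=[tuple(map(float, c)) for c in spec.scaffold_centers],
        scaffold_radius_px=float(spec.scaffold_radius_px),
        params=_jsonable_spec(spec),
    )

    for sidx, (sr, sc) in enumerate(spec.scaffold_centers):
        add_tapered_disk(
            mosaic, (sr, sc), spec.scaffold_radius_px, SCAFFOLD_BASE, taper_sigma_px=4.0
        )
        for _ in range(N_BLOBS_PER_SCAFFOLD):
            rho = spec.scaffold_radius_px * 0.85 * np.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * np.pi)
            centre = (sr + rho * np.sin(theta), sc + rho * np.cos(theta))
            amp = NUCLEI_BLOB_AMP * rng.uniform(0.7, 1.3)
            total = add_tapered_disk(mosaic, centre, 3.0, amp)
            truth.microtissues.append(
                MicrotissueTruth(
                    fov_id=f"scaffold{sidx}",
                    centre=(float(centre[0]), float(centre[1])),
                    radius_px=3.0,
                    intensity={"nuclei": total},
                )
            )
        truth.roi_centers[sidx] = [
            (float(sr + dr), float(sc + dc)) for dr, dc in spec.roi_template
        ]

    stride = spec.stride_px
    tiles: list[Tile] = []
    for r in range(spec.grid_rows):
        for c in range(spec.grid_cols):
            off = (r * stride, c * stride)
            patch = mosaic[
                off[0] : off[0] + spec.tile_size_px, off[1] : off[1] + spec.tile_size_px
            ].copy()
            tiles.append(Tile(pixels=patch, grid_pos=(r, c), channel="nuclei"))
            truth.tile_offsets.append(off)

    return tiles, truth


def _jsonable_spec(spec: SlideSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["scaffold_centers"] = [list(c) for c in d["scaffold_centers"]]
    d["roi_template"] = [list(t) for t in d["roi_template"]]
    return d
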