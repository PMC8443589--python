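"""File I/O for fixtures: TIFF + sidecar JSON, truth JSON, GMT, CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from mpskit.fixtures.render import GroundTruth
from mpskit.imaging.types import Tile, ZStack


def write_tiles(tiles: list[Tile], directory: str | Path) -> None:
    """Write one 16-bit TIFF per tile plus a sidecar JSON with grid metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = []
    for tile in tiles:
        name = f"tile_r{tile.grid_pos[0]:02d}_c{tile.grid_pos[1]:02d}.tif"
        tifffile.imwrite(
            directory / name, np.clip(tile.pixels, 0, 65535).astype(np.uint16)
        )
        meta.append({"file": name, "grid_pos": list(tile.grid_pos), "channel": tile.channel})
    (directory / "tiles.json").write_text(json.dumps(meta, indent=2))


def read_tiles(directory: str | Path) -> list[Tile]:
    directory = Path(directory)
    meta = json.loads((directory / "tiles.json").read_text())
    return [
        Tile(
            pixels=tifffile.imread(directory / m["file"]).astype(np.float32),
            grid_pos=tuple(m["grid_pos"]),
            channel=m["channel"],
        )
        for m in meta
    ]


def write_stack(stack: ZStack, path: str | Path) -> None:
    """Multi-page TIFF, plane-major then channel, with a sidecar JSON."""
    path = Path(path)
    arr = np.stack([stack.pixels[c] for c in stack.channel_names], axis=1)  # (plane, ch, r, c)
    tifffile.imwrite(
        path,
        np.clip(arr, 0, 65535).astype(np.uint16),
        photometric="minisblack",
        planarconfig="separate",
    )
    sidecar = {
        "order": "plane-major, then channel",
        "channel_names": list(stack.channel_names),
        "z_step_um": stack.z_step_um,
        "n_planes": stack.n_planes,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path) -> ZStack:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    arr = tifffile.imread(path).astype(np.float32)
    channels = sidecar["channel_names"]
    pixels = {c: arr[:, i] for i, c in enumerate(channels)}
    return ZStack(
        pixels=pixels, z_step_um=sidecar["z_step_um"], channel_names=tuple(channels)
    )


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_jsonable(), indent=2, default=float))


def write_gmt(sets: dict[str, dict[str, int]], path: str | Path) -> None:
    """GMT with an optional direction suffix per member (``GENE|+1``)."""
    lines = []
    for name, members in sets.items():
        cells = [name, ""]
        for gene, direction in members.items():
            cells.append(f"{gene}|{direction:+d}" if direction else gene)
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        cells = line.split("\t")
        members: dict[str, int] = {}
        for cell in cells[2:]:
            if "|" in cell:
                gene, direction = cell.rsplit("|", 1)
                members[gene] = int(direction)
            else:
                members[cell] = 0
        out[cells[0]] = members
    return out
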