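"""Shared fixtures: small seeded synthetic inputs, generated at test time."""

import numpy as np
import pytest

from mpskit.fixtures import SlideSpec, StackSpec, gen_slide, gen_zstack


@pytest.fixture(scope="session")
def slide_spec() -> SlideSpec:
    return SlideSpec(
        grid_rows=2,
        grid_cols=2,
        tile_size_px=256,
        overlap_frac=0.1,
        scaffold_centers=[(230.0, 230.0)],
        scaffold_radius_px=80.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def slide(slide_spec):
    return gen_slide(slide_spec)


@pytest.fixture(scope="session")
def two_scaffold_slide():
    spec = SlideSpec(
        grid_rows=2,
        grid_cols=3,
        tile_size_px=256,
        overlap_frac=0.1,
        scaffold_centers=[(120.0, 120.0), (350.0, 500.0)],
        scaffold_radius_px=80.0,
        seed=2,
    )
    return spec, gen_slide(spec)


@pytest.fixture(scope="session")
def stack_spec() -> StackSpec:
    return StackSpec(seed=3, condition_fold={"collagen1": 8.0})


@pytest.fixture(scope="session")
def fov_stack(stack_spec):
    return gen_zstack(stack_spec)


def match_records_to_truth(records, truth_microtissues, max_dist_px=5.0):
    """Pair segmentation records with truth objects by nearest centroid."""
    pairs = []
    unused = list(truth_microtissues)
    for rec in records:
        dists = [
            np.hypot(rec.centroid[0] - t.centre[0], rec.centroid[1] - t.centre[1])
            for t in unused
        ]
        i = int(np.argmin(dists))
        assert dists[i] <= max_dist_px, "no nearby truth object"
        pairs.append((rec, unused.pop(i)))
    return pairs
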