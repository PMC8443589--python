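"""Focus-plane selection on the nuclei channel of a Z-stack."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import laplace

from mpskit.errors import InputError
from mpskit.imaging.types import FocusSelection, ZStack


def select_focus(stack: ZStack, channel: str = "nuclei") -> FocusSelection:
    """Pick the sharpest plane: argmax of the variance of the Laplacian.

    Ties resolve to the lowest plane index.  An all-constant stack returns
    plane 0 with zero scores and the degenerate flag set.
    """
    if channel not in stack.channel_names:
        raise InputError(f"channel {channel!r} not present in stack")
    planes = stack.channel(channel).astype(np.float64)
    scores = np.array([laplace(p).var() for p in planes])
    if np.allclose(scores, 0.0):
        return FocusSelection(plane_idx=0, focus_scores=scores, degenerate=True)
    return FocusSelection(plane_idx=int(np.argmax(scores)), focus_scores=scores)
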