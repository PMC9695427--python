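"""Shared threshold-crossing semantics.

Both the colorimetric and conductometric endpoints are defined the same
way: the first sample at which a percent-scaled signal reaches a level
(default 90). Keeping a single implementation guarantees the two
pipelines cannot drift apart.
"""

from __future__ import annotations

import numpy as np

__all__ = ["first_crossing_index", "ceil_to_grid"]


def first_crossing_index(values, level: float) -> int | None:
    """Index of the first sample with ``values[i] >= level``.

    Returns ``None`` when the level is never reached. NaNs never cross.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be 1-D")
    hits = np.nonzero(v >= level)[0]
    return int(hits[0]) if hits.size else None


def ceil_to_grid(t: float, fps: float, t0_offset: float = 0.0) -> float:
    """Round a time up to the acquisition grid ``t0_offset + k/fps``.

    A value already on the grid is returned unchanged (up to float
    round-off in the k/fps representation).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    k = int(np.ceil((t - t0_offset) * fps - 1e-9))
    return t0_offset + max(k, 0) / fps
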