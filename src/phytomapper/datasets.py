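"""Small deterministic demonstration datasets.

The Y-shaped planar point cloud is the canonical Mapper worked example: with
the y-coordinate as the lens and 4 overlapping intervals, the Mapper graph
is a tree with a single degree-3 branch node; with the x-coordinate lens the
same points yield a different (path-shaped) graph.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["y_point_cloud"]


def y_point_cloud(
    step: float = 0.05,
    branch_y: float = 0.8,
    arm_slope: float = 2.0,
    y_max: float = 2.0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Deterministic "Y" in the plane.

    A vertical stem runs from (0, 0) to (0, ``branch_y``); two arms leave
    the branch point at +-``arm_slope`` horizontal units per vertical unit
    up to ``y_max``. Returns ``(points, y_lens, x_lens)`` where ``points``
    is a 2 x N DataFrame (rows ``x``/``y``, columns point ids) suitable for
    :func:`phytomapper.mapper.mapper_pipeline` with ``transform="none"`` and
    the Euclidean metric.
    """
    pts: list[tuple[float, float]] = []
    for y in np.arange(0.0, branch_y + 1e-9, step):
        pts.append((0.0, y))
    for y in np.arange(branch_y + step, y_max + 1e-9, step):
        dx = arm_slope * (y - branch_y)
        pts.append((-dx, y))
        pts.append((dx, y))
    ids = [f"p{i:03d}" for i in range(len(pts))]
    arr = np.array(pts).T  # 2 x N
    points = pd.DataFrame(arr, index=["x", "y"], columns=ids)
    y_lens = pd.Series(arr[1], index=ids, name="lens_value")
    x_lens = pd.Series(arr[0], index=ids, name="lens_value")
    return points, y_lens, x_lens
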