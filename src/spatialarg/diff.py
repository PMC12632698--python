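"""Spatial diff: compare node locations of two structurally identical ARGs.

The canonical use is comparing inferred ancestral locations against
simulated ground truth (or one inference method against another): both
ARGs must share the exact same node/edge tables, differing only in
their coordinates. The diff reports per-node displacement vectors,
Euclidean distances and midpoints, plus equal-width time-bin summaries
that expose how inference error grows moving back through time.

Distances are planar Euclidean in every CRS (a documented limitation
for lon/lat data).
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import SpatialARG


@dataclasses.dataclass
class NodeDiff:
    node_id: int
    time: float
    loc_a: Tuple[float, float]
    loc_b: Tuple[float, float]
    midpoint: Tuple[float, float]
    distance: float


@dataclasses.dataclass
class DiffResult:
    per_node: List[NodeDiff]
    n_unlocated: int  # nodes present but unlocated in at least one input
    max_time: float

    def distances(self) -> np.ndarray:
        return np.array([d.distance for d in self.per_node])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (
                d.node_id,
                d.time,
                d.loc_a[0],
                d.loc_a[1],
                d.loc_b[0],
                d.loc_b[1],
                d.midpoint[0],
                d.midpoint[1],
                d.distance,
            )
            for d in self.per_node
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "node_id",
                "time",
                "ax",
                "ay",
                "bx",
                "by",
                "mid_x",
                "mid_y",
                "distance",
            ],
        )


def _check_same_structure(a: SpatialARG, b: SpatialARG) -> None:
    ta, tb = a.ts.tables, b.ts.tables
    if ta.sequence_length != tb.sequence_length:
        raise ValidationError("sequence lengths differ")
    na, nb = ta.nodes, tb.nodes
    if len(na) != len(nb):
        raise ValidationError(f"node counts differ ({len(na)} vs {len(nb)})")
    same = (
        np.array_equal(na.time, nb.time)
        and np.array_equal(na.flags, nb.flags)
    )
    if not same:
        diff_rows = np.flatnonzero(
            (na.time != nb.time) | (na.flags != nb.flags)
        )
        raise ValidationError(
            f"node tables differ first at row {int(diff_rows[0])}"
        )
    ea, eb = ta.edges, tb.edges
    if len(ea) != len(eb):
        raise ValidationError(f"edge counts differ ({len(ea)} vs {len(eb)})")
    same = (
        np.array_equal(ea.left, eb.left)
        and np.array_equal(ea.right, eb.right)
        and np.array_equal(ea.parent, eb.parent)
        and np.array_equal(ea.child, eb.child)
    )
    if not same:
        diff_rows = np.flatnonzero(
            (ea.left != eb.left)
            | (ea.right != eb.right)
            | (ea.parent != eb.parent)
            | (ea.child != eb.child)
        )
        raise ValidationError(
            f"edge tables differ first at row {int(diff_rows[0])}"
        )


def spatial_diff(arg_a: SpatialARG, arg_b: SpatialARG) -> DiffResult:
    """Per-node displacement between two location assignments.

    Node and edge tables must be identical (location metadata aside);
    nodes missing a location in either input are excluded from the
    per-node list and counted in ``n_unlocated``.
    """
    _check_same_structure(arg_a, arg_b)
    if arg_a.locations is None or arg_b.locations is None:
        raise ValidationError("both ARGs must carry locations")
    times = arg_a.node_times
    per_node = []
    unlocated = 0
    for u in range(arg_a.num_nodes):
        la = arg_a.locations.get(u)
        lb = arg_b.locations.get(u)
        if la is None or lb is None:
            unlocated += 1
            continue
        dx, dy = lb[0] - la[0], lb[1] - la[1]
        per_node.append(
            NodeDiff(
                node_id=u,
                time=float(times[u]),
                loc_a=la,
                loc_b=lb,
                midpoint=((la[0] + lb[0]) / 2.0, (la[1] + lb[1]) / 2.0),
                distance=float(np.hypot(dx, dy)),
            )
        )
    max_time = float(times.max()) if len(times) else 0.0
    return DiffResult(per_node=per_node, n_unlocated=unlocated, max_time=max_time)


def diff_summary(diff: DiffResult, n_bins: int) -> pd.DataFrame:
    """Equal-width time-bin summary of displacement distances.

    Bins tile ``[0, max node time]``; per bin the count, mean, RMSE and
    maximum distance are reported (NaN statistics for empty bins). The
    node at exactly the maximum time falls in the last bin.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    top = diff.max_time if diff.max_time > 0 else 1.0
    edges = np.linspace(0.0, top, n_bins + 1)
    rows = []
    times = np.array([d.time for d in diff.per_node])
    dists = np.array([d.distance for d in diff.per_node])
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        if b == n_bins - 1:
            mask = (times >= lo) & (times <= hi)
        else:
            mask = (times >= lo) & (times < hi)
        d = dists[mask]
        rows.append(
            (
                lo,
                hi,
                int(mask.sum()),
                float(d.mean()) if len(d) else np.nan,
                float(np.sqrt((d**2).mean())) if len(d) else np.nan,
                float(d.max()) if len(d) else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["bin_left", "bin_right", "n", "mean", "rmse", "max"]
    )
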