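"""Deterministic 2D layout preparation.

Tips (sample nodes) are ordered left-to-right; internal nodes sit at
the mean rank of their descendant samples, with y following node time.
Each marginal tree has its own natural order (depth-first with a
min-descendant-id tie break); across trees a consensus is aggregated by
span-weighted Borda rank averaging. The number of edge crossings under
a given order is the layout quality metric.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ValidationError
from .model import CRS_CUSTOM, LocalTree, LocationTable, SpatialARG
from .subset_display import DisplayGraph
from .ts_io import extract_local_trees


@dataclasses.dataclass
class TipOrder:
    """A left-to-right permutation of sample node ids."""

    order: List[int]
    source: str  # "per_tree[l,r)" or "consensus"
    score: Optional[float] = None  # consensus: span-weighted Kendall distance

    def rank(self) -> Dict[int, int]:
        return {u: i for i, u in enumerate(self.order)}


def per_tree_tip_order(tree: LocalTree) -> TipOrder:
    """Depth-first tip order of one marginal tree.

    At every internal node, children are visited in increasing order of
    their minimum descendant sample id; root subtrees likewise. The
    traversal is fully deterministic.
    """
    n = len(tree.parent)
    children: Dict[int, List[int]] = {}
    in_tree = set(int(s) for s in tree.samples)
    for c in range(n):
        p = int(tree.parent[c])
        if p != -1:
            children.setdefault(p, []).append(c)
            in_tree.add(c)
            in_tree.add(p)

    min_desc: Dict[int, float] = {}

    def compute_min(u: int) -> float:
        if u in min_desc:
            return min_desc[u]
        best = float(u) if u in set(map(int, tree.samples)) else np.inf
        for c in children.get(u, []):
            best = min(best, compute_min(c))
        min_desc[u] = best
        return best

    sample_set = set(int(s) for s in tree.samples)
    roots = sorted(
        (u for u in in_tree if int(tree.parent[u]) == -1),
        key=lambda u: compute_min(u),
    )
    order: List[int] = []
    for root in roots:
        stack = [root]
        while stack:
            u = stack.pop()
            if u in sample_set:
                order.append(u)
            kids = sorted(children.get(u, []), key=compute_min, reverse=True)
            stack.extend(kids)
    # isolated samples (not attached in this tree) go last, by id
    for s in sorted(sample_set):
        if s not in order:
            order.append(s)
    left, right = tree.interval
    return TipOrder(order, source=f"per_tree[{left:g},{right:g})")


def kendall_distance(a: Sequence[int], b: Sequence[int]) -> int:
    """Number of discordant pairs between two permutations of one set."""
    pos_b = {u: i for i, u in enumerate(b)}
    seq = [pos_b[u] for u in a]
    count = 0
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            if seq[i] > seq[j]:
                count += 1
    return count


def consensus_tip_order(arg: SpatialARG) -> TipOrder:
    """Span-weighted Borda aggregation of per-tree tip orders.

    Each sample's Borda score is the span-weighted mean of its rank
    across marginal trees; the consensus sorts by score (ties broken by
    sample id). The ``score`` field reports the span-weighted sum of
    Kendall-tau distances between the consensus and each per-tree order.
    """
    trees = extract_local_trees(arg)
    if not trees:
        raise ValidationError("ARG has no local trees")
    L = arg.sequence_length
    samples = [int(s) for s in arg.samples]
    borda = {s: 0.0 for s in samples}
    per_orders = []
    for t in trees:
        order = per_tree_tip_order(t)
        per_orders.append((t.span / L, order))
        for r, s in enumerate(order.order):
            borda[s] += (t.span / L) * r
    consensus = sorted(samples, key=lambda s: (borda[s], s))
    kd = sum(w * kendall_distance(consensus, o.order) for w, o in per_orders)
    return TipOrder(consensus, source="consensus", score=float(kd))


def _segments_cross(
    p1: Tuple[float, float],
    p2: Tuple[float, float],
    q1: Tuple[float, float],
    q2: Tuple[float, float],
) -> bool:
    """True iff the open segments properly cross (shared endpoints and
    touching configurations excluded)."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(v) < 1e-12:
            return 0
        return 1 if v > 0 else -1

    for a, b in ((p1, q1), (p1, q2), (p2, q1), (p2, q2)):
        if a == b:
            return False
    d1 = orient(p1, p2, q1)
    d2 = orient(p1, p2, q2)
    d3 = orient(q1, q2, p1)
    d4 = orient(q1, q2, p2)
    return d1 * d2 < 0 and d3 * d4 < 0


def count_crossings(arg: SpatialARG, order: TipOrder) -> int:
    """Total edge crossings over all marginal trees under ``order``.

    Tips are placed at their order ranks on the x-axis, every internal
    node at the mean rank of its descendant samples in that tree, nodes
    at y = time, edges drawn as straight segments. Crossings are counted
    exactly per tree, excluding pairs that share an endpoint.
    """
    samples = set(int(s) for s in arg.samples)
    if sorted(order.order) != sorted(samples):
        raise ValidationError("tip order is not a permutation of the ARG's samples")
    rank = order.rank()
    times = arg.node_times
    total = 0
    for tree in extract_local_trees(arg):
        n = len(tree.parent)
        children: Dict[int, List[int]] = {}
        edges = []
        for c in range(n):
            p = int(tree.parent[c])
            if p != -1:
                children.setdefault(p, []).append(c)
                edges.append((p, c))
        xcoord: Dict[int, float] = {}

        def xpos(u: int) -> float:
            if u in xcoord:
                return xcoord[u]
            if u in samples and u not in children:
                x = float(rank[u])
            else:
                desc = _descendant_samples(u, children, samples)
                x = float(np.mean([rank[s] for s in desc])) if desc else float(
                    rank.get(u, 0)
                )
            xcoord[u] = x
            return x

        pts = {u: (xpos(u), float(times[u])) for e in edges for u in e}
        for (e1, e2) in itertools.combinations(edges, 2):
            if _segments_cross(pts[e1[0]], pts[e1[1]], pts[e2[0]], pts[e2[1]]):
                total += 1
    return total


def _descendant_samples(u, children, samples) -> List[int]:
    out = []
    stack = [u]
    while stack:
        v = stack.pop()
        if v in samples:
            out.append(v)
        stack.extend(children.get(v, []))
    return out


def layout_2d(
    arg_or_display: Union[SpatialARG, DisplayGraph], order: TipOrder
) -> LocationTable:
    """Deterministic (x = rank, y = time) coordinates.

    Samples sit at their order ranks; every other node at the mean rank
    of its descendant samples (via the ARG's full edge set, or the
    display graph's merged edges when one is given).
    """
    rank = order.rank()
    if isinstance(arg_or_display, DisplayGraph):
        dg = arg_or_display
        children: Dict[int, List[int]] = {}
        for e in dg.edges:
            children.setdefault(e.parent_display_id, []).append(e.child_display_id)
        sample_rank: Dict[int, float] = {}
        sample_ids = set()
        for dn in dg.nodes:
            if dn.kind == "sample":
                member_ranks = [rank[m] for m in dn.members if m in rank]
                if not member_ranks:
                    raise ValidationError(
                        f"display node {dn.display_id} has no ranked sample member"
                    )
                sample_rank[dn.display_id] = float(np.mean(member_ranks))
                sample_ids.add(dn.display_id)
        coords = {}
        for dn in dg.nodes:
            if dn.display_id in sample_rank:
                x = sample_rank[dn.display_id]
            else:
                desc = _descendant_samples(dn.display_id, children, sample_ids)
                x = float(np.mean([sample_rank[s] for s in desc])) if desc else 0.0
            coords[dn.display_id] = (x, dn.time)
        return LocationTable(coords, crs=CRS_CUSTOM)

    arg = arg_or_display
    samples = set(int(s) for s in arg.samples)
    if sorted(order.order) != sorted(samples):
        raise ValidationError("tip order is not a permutation of the ARG's samples")
    children: Dict[int, List[int]] = {}
    for e in arg.edges():
        kids = children.setdefault(int(e.parent), [])
        if int(e.child) not in kids:
            kids.append(int(e.child))
    times = arg.node_times
    coords = {}
    for u in range(arg.num_nodes):
        if u in samples:
            x = float(rank[u])
        else:
            desc = _descendant_samples(u, children, samples)
            x = float(np.mean([rank[s] for s in desc])) if desc else 0.0
        coords[u] = (x, float(times[u]))
    return LocationTable(coords, crs=CRS_CUSTOM)


def minimum_crossings_exhaustive(arg: SpatialARG) -> Tuple[int, TipOrder]:
    """Brute-force minimum crossing count over all tip permutations.

    Only feasible for small sample counts; used as the layout oracle.
    """
    samples = [int(s) for s in arg.samples]
    best = None
    best_order = None
    for perm in itertools.permutations(samples):
        order = TipOrder(list(perm), source="exhaustive")
        c = count_crossings(arg, order)
        if best is None or c < best:
            best, best_order = c, order
    return int(best), best_order
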