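"""Self-contained fixture generation.

Two generators live here:

* :func:`simulate_arg` — a minimal back-in-time Hudson coalescent with
  recombination. Lineages carry lists of ancestral segments; pairs
  coalesce at rate :math:`k(k-1)/2 \\cdot 1/(2N_e)` per generation and
  recombination strikes each lineage at rate ``recomb_rate`` per base
  pair of ancestral material it carries. Recombination events are
  recorded in full-ARG style: two parent nodes with consecutive ids,
  equal times and the recombination flag set, splitting the child's
  material at the breakpoint. The process stops once every genomic
  position has reached its MRCA.

* :func:`simulate_brownian_locations` — forward-in-time Brownian
  dispersal down the ARG: each root is placed uniformly in the unit
  square and every other node is displaced from its *primary* parent
  (the parent covering the largest genomic span; ties to the lower id)
  by independent Gaussian steps with per-axis variance
  :math:`\\sigma^2 \\Delta t`. A node has one location but possibly many
  parents across the genome, so the ground truth follows this single
  spanning tree — mirroring how spatially explicit forward simulators
  give each individual one birth location.

Both are exactly reproducible from their seed.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple

import numpy as np
import tskit

from .errors import NumericalError, StructuralError, ValidationError
from .model import (
    CRS_UNIT_GRID,
    RECOMB_NODE_FLAG,
    LocationTable,
    SpatialARG,
    arg_from_tables,
)

_MAX_EVENTS = 10**6


@dataclasses.dataclass
class SimConfig:
    """Parameters of the coalescent-with-recombination simulation.

    Attributes
    ----------
    n_samples
        Number of sampled haploid genomes (>= 2), all at time 0.
    sequence_length
        Genome length in base pairs (continuous coordinates).
    recomb_rate
        Recombination rate per base pair per generation.
    Ne
        Diploid effective population size; pairwise coalescence rate is
        1/(2 Ne) per generation, so E[TMRCA] for two samples is 2 Ne.
    dispersal_sigma
        Brownian dispersal scale, coordinate units per sqrt(generation).
    seed
        Random seed (all randomness flows from it).
    boundary
        ``"none"`` or ``"reflecting"`` (fold locations into the unit
        square).
    record_full_arg
        Record recombination-event nodes (two flagged parents per
        event). When False the same process runs but recombination
        nodes are not emitted as table rows.
    """

    n_samples: int = 10
    sequence_length: float = 1e4
    recomb_rate: float = 0.0
    Ne: float = 1.0
    dispersal_sigma: float = 0.05
    seed: int = 1
    boundary: str = "none"
    record_full_arg: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if self.sequence_length <= 0:
            raise ValidationError("sequence_length must be positive")
        if self.recomb_rate < 0 or self.Ne <= 0 or self.dispersal_sigma < 0:
            raise ValidationError("rates must be nonnegative and Ne positive")
        if self.boundary not in ("none", "reflecting"):
            raise ValidationError("boundary must be 'none' or 'reflecting'")


# A lineage is a list of half-open ancestral segments plus the node id
# that currently represents it in the recorded tables. All of a
# lineage's segments map to that one node, so full-ARG recombination
# records always share a single child.
@dataclasses.dataclass
class _Lineage:
    node: int
    segments: List[Tuple[float, float]]

    @property
    def material(self) -> float:
        return sum(r - l for l, r in self.segments)


def _merge_segments(a: List[Tuple[float, float]], b: List[Tuple[float, float]]):
    """Union of two segment lists, returning (union, overlaps)."""
    events = []
    for l, r in a:
        events.append((l, 0, +1))
        events.append((r, 0, -1))
    for l, r in b:
        events.append((l, 1, +1))
        events.append((r, 1, -1))
    events.sort()
    union, overlap = [], []
    depth = 0
    start = None
    o_start = None
    for pos, _, d in events:
        prev = depth
        depth += d
        if prev == 0 and depth > 0:
            start = pos
        if prev > 0 and depth == 0:
            union.append((start, pos))
        if prev < 2 and depth == 2:
            o_start = pos
        if prev == 2 and depth < 2:
            overlap.append((o_start, pos))
    # coalesce touching pieces
    out = []
    for l, r in union:
        if out and out[-1][1] == l:
            out[-1] = (out[-1][0], r)
        else:
            out.append((l, r))
    return [tuple(s) for s in out], overlap


class _CountMap:
    """Piecewise-constant count of lineages still carrying each interval.

    Once a position's count drops to 1 it has reached its MRCA and is
    removed from further ancestral material.
    """

    def __init__(self, L: float, n: int):
        self.pieces: List[List[float]] = [[0.0, L, float(n)]]

    def decrement(self, intervals: List[Tuple[float, float]]) -> List[Tuple[float, float]]:
        """Decrement counts over ``intervals``; return sub-intervals whose
        count reached 1 (newly at MRCA)."""
        done = []
        for l, r in intervals:
            new_pieces = []
            for pl, pr, c in self.pieces:
                if pr <= l or pl >= r:
                    new_pieces.append([pl, pr, c])
                    continue
                if pl < l:
                    new_pieces.append([pl, l, c])
                il, ir = max(pl, l), min(pr, r)
                new_pieces.append([il, ir, c - 1])
                if c - 1 == 1:
                    done.append((il, ir))
                if pr > r:
                    new_pieces.append([r, pr, c])
            self.pieces = new_pieces
        return done


def _subtract(segments, holes):
    """Segment list minus a list of holes."""
    out = []
    for l, r in segments:
        cur = [(l, r)]
        for hl, hr in holes:
            nxt = []
            for sl, sr in cur:
                if hr <= sl or hl >= sr:
                    nxt.append((sl, sr))
                    continue
                if sl < hl:
                    nxt.append((sl, hl))
                if sr > hr:
                    nxt.append((hr, sr))
            cur = nxt
        out.extend(cur)
    return [s for s in out if s[1] > s[0]]


def simulate_arg(config: SimConfig) -> SpatialARG:
    """Run the Hudson process and return the recorded SpatialARG.

    With ``recomb_rate = 0`` this is the plain Kingman coalescent: a
    single marginal tree with exactly ``2 n - 1`` nodes, and for two
    samples TMRCA is Exponential with mean ``2 Ne`` generations.
    """
    rng = np.random.default_rng(config.seed)
    L = float(config.sequence_length)
    n = config.n_samples

    tables = tskit.TableCollection(sequence_length=L)
    for _ in range(n):
        tables.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0.0)

    lineages = [_Lineage(i, [(0.0, L)]) for i in range(n)]
    counts = _CountMap(L, n)
    t = 0.0
    n_events = 0

    while lineages:
        k = len(lineages)
        materials = np.array([lin.material for lin in lineages])
        coal_rate = k * (k - 1) / 2.0 / (2.0 * config.Ne)
        recomb_rates = config.recomb_rate * materials
        total_recomb = recomb_rates.sum()
        total = coal_rate + total_recomb
        if total <= 0:
            raise StructuralError("event rate vanished before all MRCAs were reached")
        t += rng.exponential(1.0 / total)
        n_events += 1
        if n_events > _MAX_EVENTS:
            raise NumericalError(
                "more than 1e6 events; reduce recomb_rate or sequence_length"
            )
        if rng.random() < coal_rate / total:
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[int(i)], lineages[int(j)]
            u = tables.nodes.add_row(flags=0, time=t)
            for lin in (a, b):
                for l, r in lin.segments:
                    tables.edges.add_row(left=l, right=r, parent=u, child=lin.node)
            union, overlap = _merge_segments(a.segments, b.segments)
            finished = counts.decrement(overlap)
            remaining = _subtract(union, finished)
            survivors = [lin for lin in lineages if lin is not a and lin is not b]
            if remaining:
                survivors.append(_Lineage(u, remaining))
            lineages = survivors
        else:
            # pick lineage proportional to its ancestral material, then a
            # uniform breakpoint within that material
            probs = recomb_rates / total_recomb
            idx = int(rng.choice(k, p=probs))
            lin = lineages[idx]
            pos = rng.uniform(0, lin.material)
            acc = 0.0
            bp = None
            for l, r in lin.segments:
                if pos < acc + (r - l):
                    bp = l + (pos - acc)
                    break
                acc += r - l
            left_segs = [(l, min(r, bp)) for l, r in lin.segments if l < bp]
            right_segs = [(max(l, bp), r) for l, r in lin.segments if r > bp]
            left_segs = [s for s in left_segs if s[1] > s[0]]
            right_segs = [s for s in right_segs if s[1] > s[0]]
            if not left_segs or not right_segs:
                continue  # breakpoint at a segment boundary: no-op
            if config.record_full_arg:
                flag = RECOMB_NODE_FLAG
                u1 = tables.nodes.add_row(flags=flag, time=t)
                u2 = tables.nodes.add_row(flags=flag, time=t)
                for l, r in left_segs:
                    tables.edges.add_row(left=l, right=r, parent=u1, child=lin.node)
                for l, r in right_segs:
                    tables.edges.add_row(left=l, right=r, parent=u2, child=lin.node)
                new = [_Lineage(u1, left_segs), _Lineage(u2, right_segs)]
            else:
                new = [_Lineage(lin.node, left_segs), _Lineage(lin.node, right_segs)]
            lineages = [x for x in lineages if x is not lin] + new

    tables.sort()
    tables.edges.squash()
    tables.sort()
    return arg_from_tables(tables)


def _primary_parent(arg: SpatialARG) -> np.ndarray:
    """For each node, the parent covering the largest genomic span
    (ties to the lower parent id); -1 for roots."""
    span = {}
    for e in arg.edges():
        key = (int(e.child), int(e.parent))
        span[key] = span.get(key, 0.0) + (e.right - e.left)
    best = np.full(arg.num_nodes, -1, dtype=np.int64)
    best_span = np.zeros(arg.num_nodes)
    # iteration is sorted by (child, parent), so on a span tie the lower
    # parent id wins
    for (c, p), s in sorted(span.items()):
        if s > best_span[c]:
            best[c] = p
            best_span[c] = s
    return best


def simulate_brownian_locations(
    arg: SpatialARG,
    sigma: float,
    seed: int,
    boundary: str = "none",
) -> LocationTable:
    """Generate ground-truth node locations by Brownian dispersal.

    Roots are uniform in the unit square; each other node sits at its
    primary parent's location plus N(0, sigma^2 * dt) per axis, with dt
    the branch duration in generations. With ``boundary="reflecting"``
    coordinates are folded back into [0, 1].
    """
    if boundary not in ("none", "reflecting"):
        raise ValidationError("boundary must be 'none' or 'reflecting'")
    rng = np.random.default_rng(seed)
    times = arg.node_times
    # a node is a root iff it has no parent edge; isolated nodes are
    # treated as roots of their own (empty) subtree
    parent = _primary_parent(arg)
    order = np.argsort(times, kind="stable")[::-1]  # oldest first
    xy = np.zeros((arg.num_nodes, 2))
    for u in order:
        p = parent[u]
        if p == -1:
            xy[u] = rng.uniform(0.0, 1.0, size=2)
        else:
            dt = times[p] - times[u]
            if dt <= 0:
                raise StructuralError(
                    f"node {int(u)} has primary parent {int(p)} with no time gap"
                )
            xy[u] = xy[p] + rng.normal(0.0, sigma * np.sqrt(dt), size=2)
    if boundary == "reflecting":
        xy = _reflect_unit(xy)
    coords = {int(u): (float(xy[u, 0]), float(xy[u, 1])) for u in range(arg.num_nodes)}
    return LocationTable(coords, crs=CRS_UNIT_GRID)


def _reflect_unit(xy: np.ndarray) -> np.ndarray:
    """Fold coordinates into [0, 1] by reflection at the boundaries."""
    period = 2.0
    folded = np.mod(xy, period)
    return np.where(folded > 1.0, period - folded, folded)


def simulate_spatial_arg(config: SimConfig) -> SpatialARG:
    """Convenience: ARG plus Brownian ground-truth locations attached."""
    arg = simulate_arg(config)
    # independent stream for locations so topology is unchanged by sigma
    locs = simulate_brownian_locations(
        arg, config.dispersal_sigma, seed=config.seed + 1_000_003, boundary=config.boundary
    )
    return arg.with_locations(locs)
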