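"""Subsetting ARGs and building merged display graphs.

Three subsetting axes are offered: by sample set (simplification to the
ancestry of the retained samples), by genomic window (edge intersection
plus coordinate shift), and by time window (strict node removal or
clipping with interpolated boundary nodes).

The display graph collapses two kinds of node groups that clutter a
drawing: the two parent records of one recombination event, and pairs of
sample nodes that are two haplotypes of the same individual (identical
location, adjacent ids).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import tskit

from .errors import ValidationError
from .model import (
    RECOMB_NODE_FLAG,
    LocationTable,
    SpatialARG,
    arg_from_tables,
)


def subset_samples(
    arg: SpatialARG, sample_ids: Sequence[int]
) -> Tuple[SpatialARG, Dict[int, int]]:
    """Restrict the ARG to the ancestry of ``sample_ids``.

    Unary-through nodes are removed and the survivors renumbered
    contiguously in (time, old id) order. Returns the new ARG together
    with the old-to-new node id map; locations are carried over.
    TMRCAs among retained samples are preserved.
    """
    sample_ids = sorted({int(s) for s in sample_ids})
    if len(sample_ids) == 0:
        raise ValidationError("sample subset must be nonempty")
    if len(sample_ids) == 1:
        raise ValidationError(
            "a single-sample subset has no genealogy; provide >= 2 samples"
        )
    sample_set = set(int(s) for s in arg.samples)
    bad = [s for s in sample_ids if s not in sample_set]
    if bad:
        raise ValidationError(f"ids {bad} are not sample nodes of this ARG")

    new_ts, node_map = arg.ts.simplify(samples=sample_ids, map_nodes=True)
    # renumber contiguously, order-preserving by (time, old id)
    old_of_new = {}
    for old, new in enumerate(node_map):
        if new != tskit.NULL:
            old_of_new[int(new)] = old
    times = new_ts.nodes_time
    order = sorted(range(new_ts.num_nodes), key=lambda v: (times[v], old_of_new[v]))
    position = {v: i for i, v in enumerate(order)}
    tables = new_ts.dump_tables()
    tables.subset(np.array(order, dtype=np.int32), record_provenance=False)
    final_map = {
        old: position[int(new)] for old, new in enumerate(node_map) if new != tskit.NULL
    }

    locations = None
    if arg.locations is not None:
        locations = arg.locations.remapped(final_map)
    return arg_from_tables(tables, locations), final_map


def subset_genomic(arg: SpatialARG, left: float, right: float) -> SpatialARG:
    """Restrict to the genomic window ``[left, right)``.

    Edges are intersected with the window and shifted so the new
    sequence spans ``[0, right - left)``; marginal trees inside the
    window keep their exact topology (no simplification). Nodes no
    longer referenced by any edge are dropped; samples are always kept.
    """
    L = arg.sequence_length
    if not (0 <= left < right <= L):
        raise ValidationError(
            f"window [{left}, {right}) is degenerate or outside [0, {L})"
        )
    tables = arg.ts.dump_tables()
    tables.keep_intervals(np.array([[left, right]]), simplify=False, record_provenance=False)
    e = tables.edges
    tables.edges.set_columns(
        left=e.left - left,
        right=e.right - left,
        parent=e.parent,
        child=e.child,
    )
    if len(tables.sites) > 0:
        s = tables.sites
        tables.sites.set_columns(
            position=s.position - left,
            ancestral_state=s.ancestral_state,
            ancestral_state_offset=s.ancestral_state_offset,
        )
    tables.sequence_length = right - left
    referenced = set(int(x) for x in tables.edges.parent)
    referenced |= set(int(x) for x in tables.edges.child)
    referenced |= set(int(s) for s in arg.samples)
    keep = sorted(referenced)
    tables.sort()
    tables.subset(np.array(keep, dtype=np.int32), record_provenance=False)
    node_map = {old: i for i, old in enumerate(keep)}
    locations = arg.locations.remapped(node_map) if arg.locations is not None else None
    return arg_from_tables(tables, locations)


def subset_temporal(
    arg: SpatialARG, t_min: float, t_max: float, mode: str = "clip"
) -> SpatialARG:
    """Restrict to nodes (and edge portions) in the time window.

    ``strict``
        Nodes with time outside ``[t_min, t_max]`` are removed together
        with their incident edges; the result may be a forest. A window
        that excludes every sample is an error.
    ``clip`` (default)
        Edges crossing a bound are truncated by inserting a synthetic
        boundary node at the bound's time; when locations are present
        the boundary node is placed by linear interpolation between
        child and parent locations.
    """
    if not (0 <= t_min < t_max):
        raise ValidationError(f"time window [{t_min}, {t_max}] is degenerate")
    if mode not in ("strict", "clip"):
        raise ValidationError("mode must be 'strict' or 'clip'")

    times = arg.node_times
    flags = arg.node_flags
    in_window = (times >= t_min) & (times <= t_max)
    kept_old = [int(u) for u in np.flatnonzero(in_window)]

    if mode == "strict" and not any(arg.is_sample[u] for u in kept_old):
        raise ValidationError("strict time window excludes every sample node")

    boundary_nodes: Dict[Tuple[str, int, int], int] = {}
    new_edges: List[Tuple[int, int, float, float]] = []  # refs into records
    boundary_records = []

    loc = arg.locations

    def interp(c: int, p: int, t_b: float) -> Optional[Tuple[float, float]]:
        if loc is None or c not in loc or p not in loc:
            return None
        (xc, yc), (xp, yp) = loc[c], loc[p]
        f = (t_b - times[c]) / (times[p] - times[c])
        return (xc + f * (xp - xc), yc + f * (yp - yc))

    def boundary_ref(kind: str, p: int, c: int, t_b: float) -> int:
        key = (kind, p, c)
        if key not in boundary_nodes:
            idx = len(boundary_records)
            boundary_records.append((t_b, 1, idx, 0, (kind, p, c)))
            boundary_nodes[key] = idx
        return boundary_nodes[key]

    for e in arg.edges():
        p, c = int(e.parent), int(e.child)
        t_c, t_p = times[c], times[p]
        if mode == "strict":
            if in_window[p] and in_window[c]:
                new_edges.append((("old", p), ("old", c), e.left, e.right))
            continue
        if t_p <= t_min or t_c >= t_max:
            continue
        child_ref = ("old", c) if t_c >= t_min else ("low", boundary_ref("low", p, c, t_min))
        parent_ref = ("old", p) if t_p <= t_max else ("high", boundary_ref("high", p, c, t_max))
        new_edges.append((parent_ref, child_ref, e.left, e.right))

    # assemble node table: kept old nodes + boundary nodes, time-ordered
    entries = []
    for u in kept_old:
        entries.append((times[u], 0, u, ("old", u)))
    for key, idx in boundary_nodes.items():
        kind = key[0]
        t_b = t_min if kind == "low" else t_max
        entries.append((t_b, 1, idx, (kind, idx)))
    entries.sort(key=lambda r: (r[0], r[1], r[2]))

    tables = tskit.TableCollection(sequence_length=arg.sequence_length)
    ref_to_new: Dict[Tuple[str, int], int] = {}
    coords = {}
    boundary_key_of_idx = {idx: key for key, idx in boundary_nodes.items()}
    for t_u, kind_flag, _, ref in entries:
        if kind_flag == 0:
            u = ref[1]
            new = tables.nodes.add_row(flags=int(flags[u]), time=float(t_u))
            ref_to_new[("old", u)] = new
            if loc is not None and u in loc:
                coords[new] = loc[u]
        else:
            idx = ref[1]
            kindname, p, c = boundary_key_of_idx[idx]
            new = tables.nodes.add_row(flags=0, time=float(t_u))
            ref_to_new[(kindname, idx)] = new
            xy = interp(c, p, t_u)
            if xy is not None:
                coords[new] = xy
    for parent_ref, child_ref, l, r in new_edges:
        tables.edges.add_row(
            left=l, right=r, parent=ref_to_new[parent_ref], child=ref_to_new[child_ref]
        )
    tables.sort()
    locations = None
    if loc is not None and coords:
        locations = LocationTable(coords, crs=loc.crs)
    return arg_from_tables(tables, locations)


# ---------------------------------------------------------------------------
# Display graph


@dataclasses.dataclass
class DisplayNode:
    display_id: int
    members: Tuple[int, ...]
    time: float
    location: Optional[Tuple[float, float]]
    kind: str  # sample | internal | root


@dataclasses.dataclass
class DisplayEdge:
    parent_display_id: int
    child_display_id: int
    span: float  # total genomic span aggregated over member edges


@dataclasses.dataclass
class DisplayGraph:
    nodes: List[DisplayNode]
    edges: List[DisplayEdge]

    @property
    def member_map(self) -> Dict[int, int]:
        """node id -> display id."""
        out = {}
        for dn in self.nodes:
            for m in dn.members:
                out[m] = dn.display_id
        return out


def build_display_graph(arg: SpatialARG) -> DisplayGraph:
    """Collapse recombination pairs and same-individual haplotypes.

    A recombination event's two parent records (flagged, equal times,
    consecutive ids, sharing one identical child) become a single
    display node carrying both ids. Sample nodes at identical locations
    whose ids differ by exactly one are treated as two haplotypes of one
    individual and merged likewise. Display edges aggregate the genomic
    span of all member edges. ARGs without recombination flags (and with
    distinct sample locations) pass through unmerged.
    """
    n = arg.num_nodes
    times = arg.node_times
    is_rec = arg.is_recomb_event
    is_samp = arg.is_sample
    loc = arg.locations

    children_of: Dict[int, Set[int]] = {}
    for e in arg.edges():
        children_of.setdefault(int(e.parent), set()).add(int(e.child))

    group_of = np.arange(n)
    # recombination pairs: (u, u+1)
    u = 0
    while u < n - 1:
        if (
            is_rec[u]
            and is_rec[u + 1]
            and times[u] == times[u + 1]
            and group_of[u] == u
            and children_of.get(u) is not None
            and children_of.get(u) == children_of.get(u + 1)
            and len(children_of[u]) == 1
        ):
            group_of[u + 1] = u
            u += 2
        else:
            u += 1
    # haplotype pairs among samples: adjacent ids, same location and time
    if loc is not None:
        u = 0
        while u < n - 1:
            if (
                is_samp[u]
                and is_samp[u + 1]
                and group_of[u] == u
                and group_of[u + 1] == u + 1
                and times[u] == times[u + 1]
                and u in loc
                and (u + 1) in loc
                and loc[u] == loc[u + 1]
            ):
                group_of[u + 1] = u
                u += 2
            else:
                u += 1

    members: Dict[int, List[int]] = {}
    for v in range(n):
        members.setdefault(int(group_of[v]), []).append(v)
    reps = sorted(members, key=lambda r: (times[r], r))
    display_id = {r: i for i, r in enumerate(reps)}

    # aggregate edge spans between groups
    span: Dict[Tuple[int, int], float] = {}
    has_parent = set()
    for e in arg.edges():
        gp = display_id[int(group_of[int(e.parent)])]
        gc = display_id[int(group_of[int(e.child)])]
        if gp == gc:
            continue
        span[(gp, gc)] = span.get((gp, gc), 0.0) + (e.right - e.left)
        has_parent.add(gc)

    nodes = []
    for r in reps:
        mem = tuple(members[r])
        did = display_id[r]
        if any(is_samp[m] for m in mem):
            kind = "sample"
        elif did not in has_parent:
            kind = "root"
        else:
            kind = "internal"
        location = loc[r] if (loc is not None and r in loc) else None
        nodes.append(DisplayNode(did, mem, float(times[r]), location, kind))
    edges = [DisplayEdge(p, c, s) for (p, c), s in sorted(span.items())]
    return DisplayGraph(nodes, edges)
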