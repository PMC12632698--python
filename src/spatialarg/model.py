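"""Core data model: spatial ancestral recombination graphs.

A :class:`SpatialARG` is a succinct tree sequence (node/edge tables,
wrapped as an immutable :class:`tskit.TreeSequence`) plus an optional
table of per-node 2D locations and a coordinate-reference-system tag.
Times are in generations before present; genomic coordinates are 0-based
half-open floats in base pairs, following the tree-sequence convention.

Recombination-event nodes are flagged with :data:`RECOMB_NODE_FLAG`, the
same flag bit msprime uses for full-ARG recombination records, so ARGs
simulated elsewhere interoperate.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterator, Mapping, Optional, Tuple

import numpy as np
import tskit

from .errors import StructuralError, ValidationError

#: Node flag marking one parent of a recombination event (msprime's
#: ``NODE_IS_RE_EVENT`` bit).
RECOMB_NODE_FLAG = 1 << 17

#: Valid coordinate-reference-system tags.
CRS_UNIT_GRID = "unit_grid"
CRS_LONLAT = "lonlat"
CRS_CUSTOM = "custom"
VALID_CRS = (CRS_UNIT_GRID, CRS_LONLAT, CRS_CUSTOM)


@dataclasses.dataclass
class LocationTable:
    """Mapping of node id to planar (x, y) coordinates with a CRS tag."""

    coords: Dict[int, Tuple[float, float]]
    crs: str = CRS_CUSTOM

    def __post_init__(self) -> None:
        if self.crs not in VALID_CRS:
            raise ValidationError(f"unknown CRS tag {self.crs!r}; expected one of {VALID_CRS}")
        for node, (x, y) in self.coords.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValidationError(f"non-finite coordinate for node {node}: ({x}, {y})")
        if self.crs == CRS_LONLAT:
            for node, (x, y) in self.coords.items():
                if not (-180.0 <= x <= 180.0 and -90.0 <= y <= 90.0):
                    raise ValidationError(
                        f"node {node} coordinate ({x}, {y}) outside lon/lat range"
                    )

    def __len__(self) -> int:
        return len(self.coords)

    def __contains__(self, node: int) -> bool:
        return int(node) in self.coords

    def __getitem__(self, node: int) -> Tuple[float, float]:
        return self.coords[int(node)]

    def items(self) -> Iterator[Tuple[int, Tuple[float, float]]]:
        return iter(sorted(self.coords.items()))

    def get(self, node: int, default=None):
        return self.coords.get(int(node), default)

    def as_array(self, node_ids) -> np.ndarray:
        """Return an (n, 2) float array of coordinates for ``node_ids``."""
        return np.array([self.coords[int(u)] for u in node_ids], dtype=float)

    def remapped(self, node_map: Mapping[int, int]) -> "LocationTable":
        """New table with ids translated through ``node_map``; ids absent
        from the map are dropped."""
        coords = {
            int(node_map[u]): xy for u, xy in self.coords.items() if u in node_map
        }
        return LocationTable(coords, crs=self.crs)

    def copy(self) -> "LocationTable":
        return LocationTable(dict(self.coords), crs=self.crs)


@dataclasses.dataclass
class LocalTree:
    """One genomic interval's marginal tree as a parent array.

    ``parent[c]`` gives the parent node id of ``c`` in this tree, or -1
    for roots and for nodes absent from the tree.
    """

    interval: Tuple[float, float]
    parent: np.ndarray
    samples: np.ndarray

    @property
    def span(self) -> float:
        return self.interval[1] - self.interval[0]

    def children_of(self, u: int) -> np.ndarray:
        return np.flatnonzero(self.parent == u)


class SpatialARG:
    """An ancestral recombination graph with optional node locations.

    Parameters
    ----------
    ts
        The underlying succinct tree sequence.
    locations
        Optional per-node coordinates. When present, every sample node
        must be located (internal nodes may be unlocated).
    """

    def __init__(self, ts: tskit.TreeSequence, locations: Optional[LocationTable] = None):
        self.ts = ts
        self.locations = locations
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def num_nodes(self) -> int:
        return self.ts.num_nodes

    @property
    def num_edges(self) -> int:
        return self.ts.num_edges

    @property
    def sequence_length(self) -> float:
        return self.ts.sequence_length

    @property
    def node_times(self) -> np.ndarray:
        return self.ts.nodes_time

    @property
    def node_flags(self) -> np.ndarray:
        return self.ts.nodes_flags

    @property
    def is_sample(self) -> np.ndarray:
        return (self.ts.nodes_flags & tskit.NODE_IS_SAMPLE) != 0

    @property
    def is_recomb_event(self) -> np.ndarray:
        return (self.ts.nodes_flags & RECOMB_NODE_FLAG) != 0

    @property
    def samples(self) -> np.ndarray:
        return self.ts.samples()

    @property
    def crs(self) -> Optional[str]:
        return self.locations.crs if self.locations is not None else None

    def edges(self):
        """Iterate over tskit edges (parent, child, left, right)."""
        return self.ts.edges()

    def edge_arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        t = self.ts.tables
        return (
            t.edges.parent.astype(int),
            t.edges.child.astype(int),
            t.edges.left.copy(),
            t.edges.right.copy(),
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants, raising ValidationError."""
        validate_tables(self.ts.tables)
        if self.locations is not None:
            missing = [int(s) for s in self.samples if s not in self.locations]
            if missing:
                raise ValidationError(
                    f"locations present but sample nodes {missing} are unlocated"
                )
            bad = [u for u in self.locations.coords if u >= self.num_nodes or u < 0]
            if bad:
                raise ValidationError(f"location entries for nonexistent nodes {sorted(bad)}")

    # -- convenience -----------------------------------------------------
    def with_locations(self, locations: Optional[LocationTable]) -> "SpatialARG":
        return SpatialARG(self.ts, locations)

    def __repr__(self) -> str:  # pragma: no cover
        loc = f", {len(self.locations)} located" if self.locations else ""
        return (
            f"SpatialARG({self.num_nodes} nodes, {self.num_edges} edges, "
            f"L={self.sequence_length:g}{loc}, crs={self.crs})"
        )


def validate_tables(tables: tskit.TableCollection) -> None:
    """Validate node/edge invariants with informative messages."""
    times = tables.nodes.time
    n = len(times)
    L = tables.sequence_length
    parent = tables.edges.parent
    child = tables.edges.child
    left = tables.edges.left
    right = tables.edges.right
    if len(parent):
        if parent.max() >= n or child.max() >= n or min(parent.min(), child.min()) < 0:
            raise ValidationError("edge references a node id outside the node table")
        bad = np.flatnonzero(times[parent] <= times[child])
        if len(bad):
            e = int(bad[0])
            raise ValidationError(
                f"edge {e}: parent {int(parent[e])} (time {times[parent[e]]}) "
                f"not strictly older than child {int(child[e])} (time {times[child[e]]})"
            )
        bad = np.flatnonzero(~((0 <= left) & (left < right) & (right <= L)))
        if len(bad):
            e = int(bad[0])
            raise ValidationError(
                f"edge {e}: interval [{left[e]}, {right[e]}) invalid for "
                f"sequence length {L}"
            )


def arg_from_tables(
    tables: tskit.TableCollection,
    locations: Optional[LocationTable] = None,
) -> SpatialARG:
    """Sort tables, build the tree sequence, and wrap as a SpatialARG."""
    tables = tables.copy()
    validate_tables(tables)
    tables.sort()
    tables.build_index()
    return SpatialARG(tables.tree_sequence(), locations)
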