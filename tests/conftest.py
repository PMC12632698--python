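"""Shared fixtures: small hand-built ARGs and simulated ones."""

import numpy as np
import pytest
import tskit

from spatialarg import (
    LocationTable,
    SimConfig,
    SpatialARG,
    arg_from_tables,
    simulate_spatial_arg,
)


def build_arg(nodes, edges, sequence_length=1.0, locations=None, crs="unit_grid"):
    """Construct a SpatialARG from plain lists.

    nodes: list of (time, flags) — flags 1 marks a sample.
    edges: list of (parent, child, left, right).
    locations: optional {node_id: (x, y)}.
    """
    tables = tskit.TableCollection(sequence_length=sequence_length)
    for time, flags in nodes:
        tables.nodes.add_row(flags=flags, time=time)
    for parent, child, left, right in edges:
        tables.edges.add_row(left=left, right=right, parent=parent, child=child)
    loc = LocationTable(dict(locations), crs=crs) if locations is not None else None
    return arg_from_tables(tables, loc)


S = tskit.NODE_IS_SAMPLE


@pytest.fixture
def cherry():
    """Two samples at t=0 joined by a root at t=10, located on a line."""
    return build_arg(
        nodes=[(0, S), (0, S), (10, 0)],
        edges=[(2, 0, 0, 10), (2, 1, 0, 10)],
        sequence_length=10,
        locations={0: (0.0, 0.0), 1: (8.0, 0.0), 2: (4.0, 0.0)},
    )


@pytest.fixture
def two_tree_pair():
    """Two samples, breakpoint at L/2; TMRCA 1 on the left, 3 on the right."""
    return build_arg(
        nodes=[(0, S), (0, S), (1, 0), (3, 0)],
        edges=[
            (2, 0, 0.0, 0.5),
            (2, 1, 0.0, 0.5),
            (3, 0, 0.5, 1.0),
            (3, 1, 0.5, 1.0),
        ],
        sequence_length=1.0,
    )


@pytest.fixture
def caterpillar():
    """((a,b),c) with a=(0,0), b=(2,0), c=(8,0)."""
    return build_arg(
        nodes=[(0, S), (0, S), (0, S), (1, 0), (2, 0)],
        edges=[(3, 0, 0, 1), (3, 1, 0, 1), (4, 3, 0, 1), (4, 2, 0, 1)],
        locations={0: (0.0, 0.0), 1: (2.0, 0.0), 2: (8.0, 0.0)},
    )


@pytest.fixture
def cherry_pairs_4tip():
    """Two cherries (0,2) and (1,3) under one root."""
    return build_arg(
        nodes=[(0, S), (0, S), (0, S), (0, S), (1, 0), (1, 0), (2, 0)],
        edges=[
            (4, 0, 0, 1),
            (4, 2, 0, 1),
            (5, 1, 0, 1),
            (5, 3, 0, 1),
            (6, 4, 0, 1),
            (6, 5, 0, 1),
        ],
    )


@pytest.fixture
def balanced_4tip():
    """Balanced 4-tip tree with tips on a rectangle, for midpoint checks."""
    return build_arg(
        nodes=[(0, S), (0, S), (0, S), (0, S), (1, 0), (1, 0), (2, 0)],
        edges=[
            (4, 0, 0, 1),
            (4, 1, 0, 1),
            (5, 2, 0, 1),
            (5, 3, 0, 1),
            (6, 4, 0, 1),
            (6, 5, 0, 1),
        ],
        locations={
            0: (0.0, 0.0),
            1: (0.0, 2.0),
            2: (4.0, 0.0),
            3: (4.0, 2.0),
            4: (0.0, 1.0),
            5: (4.0, 1.0),
            6: (2.0, 1.0),
        },
    )


@pytest.fixture
def unequal_branch():
    """One parent, two children with branch lengths 1 and 3 at x=0 and 4."""
    return build_arg(
        nodes=[(0, S), (2, S), (3, 0)],
        edges=[(2, 1, 0, 1), (2, 0, 0, 1)],
        locations={0: (4.0, 0.0), 1: (0.0, 0.0)},
    )


def sim_spatial(seed, n_samples=20, sequence_length=1000.0, recomb_rate=7.5e-4,
                Ne=0.5, sigma=0.05):
    """Simulated ARG with Brownian ground-truth locations attached."""
    return simulate_spatial_arg(
        SimConfig(
            n_samples=n_samples,
            sequence_length=sequence_length,
            recomb_rate=recomb_rate,
            Ne=Ne,
            dispersal_sigma=sigma,
            seed=seed,
        )
    )


@pytest.fixture
def sim_arg():
    return sim_spatial(seed=42)


@pytest.fixture
def samples_only(sim_arg):
    """The same ARG with only sample locations retained."""
    coords = {int(s): sim_arg.locations[int(s)] for s in sim_arg.samples}
    return sim_arg.with_locations(
        LocationTable(coords, crs=sim_arg.locations.crs)
    )
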