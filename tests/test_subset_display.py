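"""Sample/genomic/temporal subsetting and display-graph merging."""

import numpy as np
import pytest

from spatialarg import (
    LocationTable,
    build_display_graph,
    extract_local_trees,
    subset_genomic,
    subset_samples,
    subset_temporal,
)
from spatialarg.errors import ValidationError

from conftest import build_arg, sim_spatial, S


def _topologies(arg):
    """Per-tree sets of sample splits (topology fingerprint)."""
    out = []
    for tree in extract_local_trees(arg):
        splits = set()
        samples = set(int(s) for s in tree.samples)
        for u in range(len(tree.parent)):
            desc = set()
            stack = [u]
            while stack:
                v = stack.pop()
                if v in samples:
                    desc.add(v)
                stack.extend(np.flatnonzero(tree.parent == v).tolist())
            if 1 < len(desc) < len(samples):
                splits.add(frozenset(desc))
        out.append(splits)
    return out


class TestSubsetSamples:
    def test_all_samples_keeps_topologies(self, sim_arg):
        sub, node_map = subset_samples(sim_arg, list(sim_arg.samples))
        # sample ids are preserved under the (time, old id) renumbering
        relabeled = [
            {frozenset(node_map[s] for s in split) for split in tree}
            for tree in _topologies(sim_arg)
        ]
        assert relabeled == _topologies(sub)

    def test_pair_subset_root_time_is_tmrca(self, sim_arg):
        rho0 = sim_spatial(seed=5, recomb_rate=0.0)
        tree = extract_local_trees(rho0)[0]
        a, b = int(rho0.samples[0]), int(rho0.samples[3])
        # oracle: walk up from both tips to the common ancestor
        anc = {}
        u = a
        while u != -1:
            anc[u] = True
            u = int(tree.parent[u])
        u = b
        while u not in anc:
            u = int(tree.parent[u])
        tmrca = rho0.node_times[u]
        sub, _ = subset_samples(rho0, [a, b])
        assert sub.num_nodes == 3
        assert sub.node_times.max() == pytest.approx(tmrca)

    def test_idempotent(self, sim_arg):
        keep = list(sim_arg.samples[:5])
        once, m1 = subset_samples(sim_arg, keep)
        twice, m2 = subset_samples(once, [m1[s] for s in keep])
        assert once.num_nodes == twice.num_nodes
        assert np.array_equal(once.ts.tables.edges.left, twice.ts.tables.edges.left)
        assert np.array_equal(once.ts.tables.edges.parent, twice.ts.tables.edges.parent)

    def test_locations_carried_over(self, sim_arg):
        keep = list(sim_arg.samples[:3])
        sub, node_map = subset_samples(sim_arg, keep)
        for s in keep:
            assert sub.locations[node_map[s]] == sim_arg.locations[s]

    def test_single_sample_rejected(self, sim_arg):
        with pytest.raises(ValidationError):
            subset_samples(sim_arg, [int(sim_arg.samples[0])])

    def test_non_sample_id_rejected(self, sim_arg):
        internal = int(np.flatnonzero(~sim_arg.is_sample)[0])
        with pytest.raises(ValidationError):
            subset_samples(sim_arg, [int(sim_arg.samples[0]), internal])


class TestSubsetGenomic:
    def test_full_window_identity(self, sim_arg):
        sub = subset_genomic(sim_arg, 0, sim_arg.sequence_length)
        ta, tb = sim_arg.ts.tables, sub.ts.tables
        assert np.array_equal(ta.edges.left, tb.edges.left)
        assert np.array_equal(ta.edges.right, tb.edges.right)
        assert np.array_equal(ta.nodes.time, tb.nodes.time)

    def test_window_of_one_tree(self, two_tree_pair):
        sub = subset_genomic(two_tree_pair, 0.0, 0.5)
        trees = extract_local_trees(sub)
        assert len(trees) == 1
        assert sub.sequence_length == 0.5
        # left tree had TMRCA 1
        assert sub.node_times.max() == pytest.approx(1.0)

    def test_window_straddling_breakpoint(self, two_tree_pair):
        sub = subset_genomic(two_tree_pair, 0.25, 0.75)
        trees = extract_local_trees(sub)
        assert len(trees) == 2
        assert [t.interval for t in trees] == [(0.0, 0.25), (0.25, 0.5)]

    @pytest.mark.parametrize("frac", [(0.0, 0.3), (0.2, 0.9)])
    def test_window_trees_match_original(self, sim_arg, frac):
        L = sim_arg.sequence_length
        left, right = frac[0] * L, frac[1] * L
        sub = subset_genomic(sim_arg, left, right)
        original = [
            t
            for t in extract_local_trees(sim_arg)
            if t.interval[1] > left and t.interval[0] < right
        ]
        assert len(extract_local_trees(sub)) == len(original)

    def test_degenerate_window_rejected(self, sim_arg):
        with pytest.raises(ValidationError):
            subset_genomic(sim_arg, 5.0, 5.0)


class TestSubsetTemporal:
    def test_full_window_identity(self, sim_arg):
        top = float(sim_arg.node_times.max())
        sub = subset_temporal(sim_arg, 0, top + 1, mode="clip")
        assert sub.num_nodes == sim_arg.num_nodes
        assert sub.num_edges == sim_arg.num_edges

    def test_clip_cherry_interpolation(self, cherry):
        sub = subset_temporal(cherry, 0, 4, mode="clip")
        # two boundary nodes at time 4, located 4/10 along each edge
        boundary = np.flatnonzero(sub.node_times == 4.0)
        assert len(boundary) == 2
        locs = sorted(sub.locations[int(u)] for u in boundary)
        assert locs[0] == pytest.approx((1.6, 0.0))
        assert locs[1] == pytest.approx((6.4, 0.0))

    def test_strict_cherry_gives_isolated_samples(self, cherry):
        sub = subset_temporal(cherry, 0, 4, mode="strict")
        assert sub.num_nodes == 2
        assert sub.num_edges == 0
        assert sub.is_sample.all()

    def test_clip_conserves_edge_spans_and_boundary_times(self, sim_arg):
        t_max = float(np.median(sim_arg.node_times[~sim_arg.is_sample]))
        sub = subset_temporal(sim_arg, 0, t_max, mode="clip")
        total_before = sum(
            e.right - e.left
            for e in sim_arg.edges()
            if sim_arg.node_times[e.child] < t_max
        )
        total_after = sum(e.right - e.left for e in sub.edges())
        assert total_after == pytest.approx(total_before)
        new_top = sub.node_times.max()
        assert new_top <= t_max

    def test_strict_excluding_all_samples_rejected(self, cherry):
        with pytest.raises(ValidationError):
            subset_temporal(cherry, 5, 20, mode="strict")


class TestDisplayGraph:
    def test_recombination_pair_merged(self):
        arg = build_arg(
            nodes=[(0, S), (0, S), (1, 0), (2, 1 << 17), (2, 1 << 17), (3, 0)],
            edges=[
                (2, 0, 0, 1),
                (2, 1, 0, 1),
                (3, 2, 0, 0.5),
                (4, 2, 0.5, 1),
                (5, 3, 0, 0.5),
                (5, 4, 0.5, 1),
            ],
        )
        dg = build_display_graph(arg)
        merged = [dn for dn in dg.nodes if len(dn.members) > 1]
        assert len(merged) == 1
        assert merged[0].members == (3, 4)
        # the two half-span edges to the shared child aggregate to span 1
        child_display = dg.member_map[2]
        spans = [
            e.span
            for e in dg.edges
            if e.parent_display_id == merged[0].display_id
            and e.child_display_id == child_display
        ]
        assert spans == [pytest.approx(1.0)]

    def test_same_location_adjacent_samples_merged(self):
        arg = build_arg(
            nodes=[(0, S), (0, S), (0, S), (1, 0)],
            edges=[(3, 0, 0, 1), (3, 1, 0, 1), (3, 2, 0, 1)],
            locations={
                0: (0.3, 0.7),
                1: (0.3, 0.7),
                2: (0.9, 0.1),
                3: (0.5, 0.5),
            },
        )
        dg = build_display_graph(arg)
        merged = [dn for dn in dg.nodes if len(dn.members) > 1]
        assert len(merged) == 1
        assert merged[0].members == (0, 1)
        assert merged[0].kind == "sample"

    def test_plain_arg_passes_through(self, balanced_4tip):
        dg = build_display_graph(balanced_4tip)
        assert all(len(dn.members) == 1 for dn in dg.nodes)
        assert len(dg.nodes) == balanced_4tip.num_nodes

    @pytest.mark.parametrize("seed", [4, 13])
    def test_members_partition_and_span_conserved(self, seed):
        arg = sim_spatial(seed=seed)
        dg = build_display_graph(arg)
        members = sorted(m for dn in dg.nodes for m in dn.members)
        assert members == list(range(arg.num_nodes))
        for dn in dg.nodes:
            assert len({arg.node_times[m] for m in dn.members}) == 1
        inter_group = sum(
            e.right - e.left
            for e in arg.edges()
            if dg.member_map[int(e.parent)] != dg.member_map[int(e.child)]
        )
        assert sum(e.span for e in dg.edges) == pytest.approx(inter_group)
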