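"""BFS shortest pathways, trajectory statistics, routes, and occupancy maps."""

import itertools

import numpy as np
import pytest

from confwire.hbond_graph import HBondGraph, HBondParams
from confwire.pathway_search import (
    classify_route,
    occupancy_map,
    scan_trajectory,
    shortest_water_path,
    write_opendx,
)
from confwire.structio import AtomRecord, Structure, Trajectory
from confwire.synthetic_data import WireSystemSpec, make_wire_trajectory


def graph_from_edges(nodes, edges, seed, bulk):
    return HBondGraph(tuple(nodes), frozenset(tuple(sorted(e)) for e in edges),
                      frozenset(seed), frozenset(bulk))


def enumerate_shortest(graph):
    """Exhaustive simple-path enumeration oracle (small graphs only)."""
    best = None
    adj = {n: set(graph.adjacency.get(n, ())) for n in graph.water_nodes}

    def extend(path):
        nonlocal best
        if best is not None and len(path) >= len(best):
            return
        if path[-1] in graph.bulk_nodes:
            best = list(path)
            return
        for nb in sorted(adj[path[-1]]):
            if nb not in path:
                extend(path + [nb])

    for start in sorted(graph.seed_adjacent):
        extend([start])
    return best


def random_graph(rng, n_nodes, p_edge=0.15, n_seed=2, n_bulk=2):
    nodes = list(range(n_nodes))
    edges = [e for e in itertools.combinations(nodes, 2) if rng.random() < p_edge]
    seed = rng.choice(nodes, size=min(n_seed, n_nodes), replace=False)
    bulk = rng.choice(nodes, size=min(n_bulk, n_nodes), replace=False)
    return graph_from_edges(nodes, edges, seed.tolist(), bulk.tolist())


class TestShortestPath:
    def test_disconnected_returns_none(self):
        g = graph_from_edges([1, 2, 3, 4], [], [1], [4])
        assert shortest_water_path(g) is None

    def test_branched_graph_prefers_short_chain(self):
        # seed -> 1-2-3-4 -> bulk and seed -> 1-5-6-7-8-9 -> bulk
        edges = [(1, 2), (2, 3), (3, 4), (1, 5), (5, 6), (6, 7), (7, 8), (8, 9)]
        g = graph_from_edges(range(1, 10), edges, [1], [4, 9])
        path = shortest_water_path(g)
        assert path.waters == (1, 2, 3, 4)
        assert path.n_w == 4
        assert enumerate_shortest(g) == list(path.waters)

    def test_seed_water_in_bulk_gives_single_water_path(self):
        g = graph_from_edges([7, 8], [(7, 8)], [7], [7])
        path = shortest_water_path(g)
        assert path.waters == (7,) and path.n_w == 1

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            g = random_graph(rng, int(rng.integers(2, 12)))
            path = shortest_water_path(g)
            oracle = enumerate_shortest(g)
            if oracle is None:
                assert path is None
            else:
                assert path.n_w == len(oracle)

    def test_matches_networkx_on_large_graphs(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(23)
        for _ in range(30):
            g = random_graph(rng, 300, p_edge=0.01, n_seed=4, n_bulk=4)
            path = shortest_water_path(g)
            gx = g.to_networkx()
            gx.add_node("SEED")
            for s in g.seed_adjacent:
                gx.add_edge("SEED", s)
            lengths = {
                b: nx.shortest_path_length(gx, "SEED", b)
                for b in g.bulk_nodes
                if nx.has_path(gx, "SEED", b)
            }
            if not lengths:
                assert path is None
            else:
                assert path.n_w == min(lengths.values())

    def test_minimality_witness(self):
        """Dropping any path water disconnects or lengthens the pathway."""
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 20:
            g = random_graph(rng, 40, p_edge=0.08, n_seed=3, n_bulk=3)
            path = shortest_water_path(g)
            if path is None or path.n_w < 2:
                continue
            checked += 1
            for drop in path.waters:
                nodes = [n for n in g.water_nodes if n != drop]
                edges = [e for e in g.edges if drop not in e]
                sub = graph_from_edges(nodes, edges,
                                       set(g.seed_adjacent) - {drop},
                                       set(g.bulk_nodes) - {drop})
                shorter = shortest_water_path(sub)
                assert shorter is None or shorter.n_w >= path.n_w


class TestScanTrajectory:
    def test_always_connected_chain(self):
        traj, truth = make_wire_trajectory(WireSystemSpec(n_frames=20, p_connect=1.0, chain_length=5, rng_seed=1))
        stats = scan_trajectory(traj, HBondParams())
        assert stats.f_path == 1.0
        assert stats.histogram_nw == {5: 20}

    def test_never_connected(self):
        traj, truth = make_wire_trajectory(WireSystemSpec(n_frames=10, p_connect=0.0, rng_seed=2))
        stats = scan_trajectory(traj, HBondParams())
        assert stats.f_path == 0.0
        assert stats.histogram_nw == {}

    def test_fpath_matches_planted_binomial_draw(self):
        spec = WireSystemSpec(n_frames=500, p_connect=0.4, rng_seed=3)
        traj, truth = make_wire_trajectory(spec)
        stats = scan_trajectory(traj, HBondParams())
        assert np.array_equal(stats.present, truth)
        assert stats.f_path == pytest.approx(truth.mean())
        # detector output stays inside the exact binomial 99% interval around p
        from scipy.stats import binom

        lo, hi = binom.ppf([0.005, 0.995], 500, 0.4) / 500
        assert lo <= stats.f_path <= hi

    def test_fpath_invariant_under_frame_reordering(self):
        spec = WireSystemSpec(n_frames=60, p_connect=0.5, rng_seed=4)
        traj, truth = make_wire_trajectory(spec)
        stats = scan_trajectory(traj, HBondParams())
        perm = np.random.default_rng(0).permutation(60)
        shuffled = Trajectory(traj.topology, traj.frames[perm])
        stats2 = scan_trajectory(shuffled, HBondParams())
        assert stats2.f_path == stats.f_path
        assert sum(stats.histogram_nw.values()) == int(stats.present.sum())

    def test_empty_water_trajectory(self, gln_toy):
        frames = np.repeat(gln_toy.coords[None], 10, axis=0)
        traj = Trajectory(gln_toy, frames)
        stats = scan_trajectory(traj, HBondParams())
        assert stats.f_path == 0.0 and stats.histogram_nw == {}


class TestClassifyRoute:
    def _frame(self):
        # markers: GLN 113 side chain at (0, 3, -14); GLU 202 at (0, 12, -14)
        atoms = [
            AtomRecord(1, "OE1", "O", "GLN", 148, "A", (0.0, 0.0, -10.0)),
            AtomRecord(2, "NE2", "N", "GLN", 113, "A", (0.0, 3.0, -14.0)),
            AtomRecord(3, "OE1", "O", "GLU", 202, "A", (0.0, 12.0, -14.0)),
        ]
        from conftest import make_water

        atoms += make_water(1, (0.0, 0.0, -13.0), (0.0, 0.0, -13.96), serial0=4)
        atoms += make_water(2, (0.0, 0.0, -15.7), (0.0, 0.0, -16.66), serial0=6)
        return Structure(atoms)

    def test_nearest_marker_wins(self):
        s = self._frame()
        from confwire.pathway_search import WaterPathway

        path = WaterPathway(0, (3, 5))  # the two water oxygens
        rl = classify_route(path, s, s.coords, {"inner": "resid 113", "interfacial": "resid 202"})
        assert rl.label == "inner"
        assert rl.marker_distances["inner"] < rl.marker_distances["interfacial"]

    def test_ceiling_gives_other(self):
        s = self._frame()
        from confwire.pathway_search import WaterPathway

        path = WaterPathway(0, (3, 5))
        rl = classify_route(path, s, s.coords, {"interfacial": "resid 202"}, ceiling=6.0)
        assert rl.label == "other"

    def test_tie_breaks_by_name(self):
        s = self._frame()
        from confwire.pathway_search import WaterPathway

        path = WaterPathway(0, (3,))
        # two markers at identical distance from the path water
        rl = classify_route(path, s, s.coords, {"b_marker": "resid 113", "a_marker": "resid 113"})
        assert rl.label == "a_marker"

    def test_empty_path_rejected(self):
        s = self._frame()
        from confwire.pathway_search import WaterPathway

        with pytest.raises(ValueError):
            classify_route(WaterPathway(0, ()), s, s.coords, {"m": "resid 113"})


class TestOccupancyMap:
    def test_immobile_water_full_occupancy(self):
        from conftest import make_water

        atoms = make_water(1, (1.0, 1.0, 1.0), (1.96, 1.0, 1.0))
        s = Structure(atoms)
        traj = Trajectory(s, np.repeat(s.coords[None], 10, axis=0))
        grid = occupancy_map(traj, ((0, 0, 0), (4, 4, 4)), voxel=2.0)
        occ = grid.occupancy
        assert occ[0, 0, 0] == 1.0
        assert occ.sum() == 1.0

    def test_uniform_random_fill_fraction(self):
        from conftest import make_water

        rng = np.random.default_rng(8)
        n_w, n_frames, box = 30, 200, 10.0
        atoms = []
        for i in range(n_w):
            atoms += make_water(i + 1, (0, 0, 0), serial0=i + 1)
        s = Structure(atoms)
        frames = rng.uniform(0, box, (n_frames, n_w, 3))
        traj = Trajectory(s, frames)
        grid = occupancy_map(traj, ((0, 0, 0), (box, box, box)), voxel=2.0)
        n_vox = grid.counts.size
        expected = 1.0 - (1.0 - 1.0 / n_vox) ** n_w
        assert grid.occupancy.mean() == pytest.approx(expected, rel=0.05)

    def test_default_isovalue(self):
        from conftest import make_water

        s = Structure(make_water(1, (1, 1, 1)))
        traj = Trajectory(s, s.coords[None])
        grid = occupancy_map(traj, ((0, 0, 0), (2, 2, 2)), voxel=1.0)
        assert grid.isovalue == 0.35

    def test_opendx_export_parses(self, tmp_path):
        from conftest import make_water

        s = Structure(make_water(1, (1, 1, 1)))
        traj = Trajectory(s, s.coords[None])
        grid = occupancy_map(traj, ((0, 0, 0), (4, 4, 4)), voxel=2.0)
        out = tmp_path / "grid.dx"
        write_opendx(grid, str(out))
        text = out.read_text()
        assert "gridpositions counts 2 2 2" in text
        values = []
        in_data = False
        for line in text.splitlines():
            if line.startswith("object 3"):
                in_data = True
                continue
            if in_data and line.startswith("attribute"):
                break
            if in_data:
                values += [float(v) for v in line.split()]
        assert len(values) == 8 and sum(values) == pytest.approx(1.0)
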