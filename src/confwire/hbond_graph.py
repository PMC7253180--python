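"""Per-frame hydrogen-bond connectivity graphs over water molecules.

For one trajectory frame the graph has one node per water molecule (keyed by
its oxygen atom index), an edge wherever two waters satisfy the geometric
hydrogen-bond criterion, a set of seed-adjacent waters (oxygen within the
seed cutoff of any seed atom, e.g. the OE1/NE2 amide atoms of the external
glutamine), and a set of bulk waters (oxygen below the intracellular bulk
z-plane).

Two hydrogen-bond definitions are supported:

* ``H-acceptor`` (default): any hydrogen of either water within ``d_hb``
  (default 2.5 Å) of the partner oxygen — the standard inexpensive geometric
  proxy for an O–H···O bond.
* ``O-O``: oxygen–oxygen distance within ``d_oo`` (default 3.5 Å), used for
  hydrogen-free inputs. Waters lacking hydrogens fall back to this criterion
  automatically.

No angular criterion is applied. Protein–water hydrogen bonds are not graph
edges; seed attachment uses the separate oxygen-to-seed-atom cutoff.
Periodic boundary conditions are ignored by default (pathways of interest
lie in the protein interior); a minimum-image option exists for synthetic
boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import Selection, Structure, WATER_RESNAMES, resolve_selection

DEFAULT_D_HB = 2.5  # Å, hydrogen-to-acceptor-oxygen cutoff
DEFAULT_D_SEED = 3.5  # Å, seed-atom-to-water-oxygen cutoff
DEFAULT_Z_BULK = -15.0  # Å, waters below this z belong to intracellular bulk
DEFAULT_D_OO = 3.5  # Å, oxygen-oxygen fallback cutoff


@dataclass(frozen=True)
class HBondParams:
    """Geometric parameters of the water-wire detector."""

    d_hb: float = DEFAULT_D_HB
    d_seed: float = DEFAULT_D_SEED
    z_bulk: float = DEFAULT_Z_BULK
    seed_selection: str = "resid 148 and name OE1 NE2"
    hbond_definition: str = "H-acceptor"  # or "O-O"
    d_oo: float = DEFAULT_D_OO
    minimum_image: bool = False
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.d_hb <= 0 or self.d_seed <= 0 or self.d_oo <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not np.isfinite(self.z_bulk):
            raise ValueError("z_bulk must be finite")
        if self.hbond_definition not in ("H-acceptor", "O-O"):
            raise ValueError(f"unknown hbond_definition {self.hbond_definition!r}")
        if self.minimum_image and self.box is None:
            raise ValueError("minimum_image requires a box")


@dataclass(frozen=True)
class WaterMolecule:
    """A water: oxygen atom index plus (possibly empty) hydrogen indices."""

    o_index: int
    h_indices: tuple[int, ...]


@dataclass
class HBondGraph:
    """Undirected H-bond graph over waters with seed/bulk annotations.

    Nodes are oxygen atom indices. ``adjacency`` maps each node to its
    sorted neighbor list; ``edges`` is the set of unordered pairs.
    """

    water_nodes: tuple[int, ...]
    edges: frozenset[tuple[int, int]]
    seed_adjacent: frozenset[int]
    bulk_nodes: frozenset[int]
    adjacency: Mapping[int, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodes = set(self.water_nodes)
        if not (self.seed_adjacent <= nodes and self.bulk_nodes <= nodes):
            raise ValueError("seed_adjacent and bulk_nodes must be subsets of water_nodes")
        if self.adjacency:
            adj = {n: tuple(sorted(nb)) for n, nb in self.adjacency.items()}
        else:
            tmp: dict[int, list[int]] = {n: [] for n in self.water_nodes}
            for a, b in self.edges:
                if a == b:
                    raise ValueError("self-edges are not allowed")
                tmp[a].append(b)
                tmp[b].append(a)
            adj = {n: tuple(sorted(v)) for n, v in tmp.items()}
        self.adjacency = adj

    def to_networkx(self):
        """Export as a networkx.Graph (nodes = oxygen indices)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.water_nodes)
        g.add_edges_from(self.edges)
        return g


def identify_waters(structure: Structure) -> list[WaterMolecule]:
    """Group water atoms into molecules by (chain, resid).

    Water residues are those named HOH/WAT/TIP3. The oxygen is the atom
    whose element is O (or whose name starts with O); hydrogens are the
    rest with element H.
    """
    groups: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.resname.upper() in WATER_RESNAMES:
            groups.setdefault((a.chain, a.resid), []).append(i)
    waters = []
    for key in sorted(groups):
        idxs = groups[key]
        o = [i for i in idxs if structure.atoms[i].element.upper() == "O"]
        h = [i for i in idxs if structure.atoms[i].element.upper() == "H"]
        if not o:
            continue
        waters.append(WaterMolecule(o[0], tuple(h)))
    return waters


def _pair_disp(a: np.ndarray, b: np.ndarray, params: HBondParams) -> np.ndarray:
    d = a - b
    if params.minimum_image:
        box = np.asarray(params.box, dtype=float)
        d -= box * np.round(d / box)
    return d


def waters_hydrogen_bonded(
    coords: np.ndarray,
    water_i: WaterMolecule,
    water_j: WaterMolecule,
    d_hb: float = DEFAULT_D_HB,
    params: HBondParams | None = None,
) -> bool:
    """True iff two waters are hydrogen bonded under the geometric criterion.

    With hydrogens present: any H of either water within ``d_hb`` of the
    partner's oxygen. Without hydrogens (on either side): O–O distance
    within the fallback cutoff.
    """
    if water_i.o_index == water_j.o_index:
        raise ValueError("cannot test a water against itself")
    params = params or HBondParams(d_hb=d_hb)
    use_oo = params.hbond_definition == "O-O" or not (water_i.h_indices and water_j.h_indices)
    if use_oo:
        d = _pair_disp(coords[water_i.o_index], coords[water_j.o_index], params)
        return bool(np.linalg.norm(d) <= params.d_oo)
    for donor, acceptor in ((water_i, water_j), (water_j, water_i)):
        for h in donor.h_indices:
            d = _pair_disp(coords[h], coords[acceptor.o_index], params)
            if np.linalg.norm(d) <= params.d_hb:
                return True
    return False


def build_water_graph(
    structure: Structure,
    coords: np.ndarray | None = None,
    params: HBondParams | None = None,
) -> HBondGraph:
    """Build the frame's H-bond graph over waters with seed/bulk annotation.

    Uses a KD-tree neighbor search whose edge set equals the all-pairs
    definition. A frame without waters yields a valid empty graph. The seed
    selection must resolve to at least one atom.
    """
    params = params or HBondParams()
    coords = structure.coords if coords is None else np.asarray(coords, dtype=float)
    seed_sel = resolve_selection(structure, params.seed_selection)
    if len(seed_sel) == 0:
        raise ValueError(f"seed selection {params.seed_selection!r} matched no atoms")
    waters = identify_waters(structure)
    if not waters:
        return HBondGraph((), frozenset(), frozenset(), frozenset())

    o_idx = np.array([w.o_index for w in waters])
    o_pos = coords[o_idx]
    boxsize = params.box if params.minimum_image else None

    pairs: set[tuple[int, int]] = set()
    all_have_h = all(w.h_indices for w in waters)
    if params.hbond_definition == "H-acceptor" and all_have_h:
        h_idx = np.concatenate([np.array(w.h_indices, dtype=int) for w in waters])
        h_owner = np.concatenate(
            [np.full(len(w.h_indices), wi, dtype=int) for wi, w in enumerate(waters)]
        )
        h_pos = coords[h_idx]
        if boxsize is not None:
            o_tree = cKDTree(np.mod(o_pos, boxsize), boxsize=boxsize)
            h_query = np.mod(h_pos, boxsize)
        else:
            o_tree = cKDTree(o_pos)
            h_query = h_pos
        for hi, neighbors in enumerate(o_tree.query_ball_point(h_query, params.d_hb)):
            wi = h_owner[hi]
            for wj in neighbors:
                if wj != wi:
                    pairs.add((min(wi, wj), max(wi, wj)))
    else:
        # O-O criterion (chosen or forced by hydrogen-free waters)
        cutoff = params.d_oo
        if boxsize is not None:
            tree = cKDTree(np.mod(o_pos, boxsize), boxsize=boxsize)
        else:
            tree = cKDTree(o_pos)
        for wi, wj in tree.query_pairs(cutoff):
            pairs.add((min(wi, wj), max(wi, wj)))
        if params.hbond_definition == "H-acceptor" and not all_have_h:
            # mixed topologies: waters with hydrogens still use H-acceptor
            refined = set()
            for wi, wj in pairs:
                if waters_hydrogen_bonded(coords, waters[wi], waters[wj], params=params):
                    refined.add((wi, wj))
            pairs = refined

    edges = frozenset(
        (int(o_idx[a]), int(o_idx[b])) if o_idx[a] < o_idx[b] else (int(o_idx[b]), int(o_idx[a]))
        for a, b in pairs
    )

    seed_pos = coords[list(seed_sel.indices)]
    if boxsize is not None:
        seed_tree = cKDTree(np.mod(seed_pos, boxsize), boxsize=boxsize)
        o_query = np.mod(o_pos, boxsize)
    else:
        seed_tree = cKDTree(seed_pos)
        o_query = o_pos
    near_seed = seed_tree.query_ball_point(o_query, params.d_seed)
    seed_adjacent = frozenset(int(o_idx[i]) for i, hits in enumerate(near_seed) if hits)

    bulk_nodes = frozenset(int(o) for o, pos in zip(o_idx, o_pos) if pos[2] < params.z_bulk)

    return HBondGraph(
        tuple(int(i) for i in o_idx),
        edges,
        seed_adjacent,
        bulk_nodes,
    )
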