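"""Shortest hydrogen-bonded water pathways from seed to bulk, per frame.

The search runs breadth-first from a virtual seed node attached to all
seed-adjacent waters and stops at the first water below the bulk z-plane,
so the returned chain has the minimal number of water molecules (path
length is counted in waters, equivalently O–H hops plus one; the
seed→first-water and last-water→bulk attachments are not counted).
Expansion order is deterministic (ascending oxygen atom index), which fixes
the tie-break among equal-length pathways.

Aggregation over a trajectory yields the per-frame presence series, the
occurrence fraction ``f_path`` (frames with a pathway / frames analyzed)
and the path-length histogram. Route classification labels each pathway by
the marker residue whose side chain comes closest to any path water, and
occupancy maps voxelize the fraction of frames in which each cell contains
at least one water oxygen (exported as OpenDX text, default contour
isovalue 0.35).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hbond_graph import HBondGraph, HBondParams, build_water_graph, identify_waters
from .structio import Selection, Structure, Trajectory, resolve_selection

logger = logging.getLogger(__name__)

DEFAULT_ISOVALUE = 0.35
DEFAULT_ROUTE_CEILING = 6.0  # Å


@dataclass(frozen=True)
class WaterPathway:
    """An ordered seed-to-bulk water chain found in one frame."""

    frame_index: int
    waters: tuple[int, ...]  # oxygen atom indices, seed-adjacent first

    @property
    def n_w(self) -> int:
        return len(self.waters)


@dataclass
class PathwayStats:
    """Per-frame pathway presence and aggregate occurrence statistics."""

    present: np.ndarray  # (n_frames,) bool
    paths: list[WaterPathway]
    route_labels: list[str] | None = None

    @property
    def n_frames(self) -> int:
        return int(self.present.size)

    @property
    def f_path(self) -> float:
        """Occurrence fraction: frames with a pathway / frames analyzed."""
        return float(self.present.mean()) if self.present.size else 0.0

    @property
    def histogram_nw(self) -> dict[int, int]:
        """Mapping path length (waters) -> number of frames."""
        hist: dict[int, int] = {}
        for p in self.paths:
            hist[p.n_w] = hist.get(p.n_w, 0) + 1
        return dict(sorted(hist.items()))

    def nw_mean_sd(self) -> tuple[float, float]:
        """Descriptive mean and SD of the path-length distribution."""
        if not self.paths:
            return (float("nan"), float("nan"))
        nw = np.array([p.n_w for p in self.paths], dtype=float)
        return float(nw.mean()), float(nw.std(ddof=1)) if nw.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-frame table: frame, present, N_w, route."""
        nw = np.full(self.n_frames, -1, dtype=int)
        route = np.full(self.n_frames, "", dtype=object)
        by_frame = {p.frame_index: i for i, p in enumerate(self.paths)}
        for f, i in by_frame.items():
            nw[f] = self.paths[i].n_w
            if self.route_labels is not None:
                route[f] = self.route_labels[i]
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "present": self.present.astype(bool),
                "N_w": nw,
                "route": route,
            }
        )

    def route_fractions(self) -> dict[str, dict[str, float]]:
        """Route shares under both denominators: pathway instances and frames.

        Which denominator a route percentage refers to is a reporting choice;
        both are returned so either convention can be quoted.
        """
        if self.route_labels is None or not self.paths:
            return {}
        counts: dict[str, int] = {}
        for lab in self.route_labels:
            counts[lab] = counts.get(lab, 0) + 1
        return {
            lab: {
                "of_pathways": c / len(self.paths),
                "of_frames": c / self.n_frames,
            }
            for lab, c in sorted(counts.items())
        }


@dataclass(frozen=True)
class RouteLabel:
    """Route classification of one pathway with its marker distances."""

    label: str
    marker_distances: Mapping[str, float]


@dataclass
class DensityGrid:
    """Voxelized water-occupancy map (presence mode: ≤1 count/voxel/frame)."""

    origin: np.ndarray  # (3,) Å
    voxel: float  # Å edge length
    counts: np.ndarray  # (nx, ny, nz) int
    n_frames: int
    isovalue: float = DEFAULT_ISOVALUE

    @property
    def occupancy(self) -> np.ndarray:
        """Per-voxel fraction of frames with at least one water oxygen."""
        return self.counts / max(self.n_frames, 1)


# ---------------------------------------------------------------------------
# BFS


def shortest_water_path(graph: HBondGraph, frame_index: int = 0) -> WaterPathway | None:
    """Breadth-first search for the minimal seed-to-bulk water chain.

    Returns the pathway with the smallest number of waters reaching any bulk
    node, or ``None`` when seed and bulk are disconnected. Among equal-length
    paths the first discovered under ascending-oxygen-index expansion is
    returned, making the result reproducible. A seed-adjacent water that is
    itself a bulk node yields a single-water pathway.
    """
    if not graph.seed_adjacent or not graph.bulk_nodes:
        return None
    parent: dict[int, int | None] = {}
    queue: deque[int] = deque()
    for node in sorted(graph.seed_adjacent):
        parent[node] = None
        queue.append(node)
    while queue:
        node = queue.popleft()
        if node in graph.bulk_nodes:
            chain = [node]
            while parent[chain[-1]] is not None:
                chain.append(parent[chain[-1]])  # type: ignore[arg-type]
            return WaterPathway(frame_index, tuple(reversed(chain)))
        for nb in graph.adjacency.get(node, ()):
            if nb not in parent:
                parent[nb] = node
                queue.append(nb)
    return None


def scan_trajectory(
    traj: Trajectory,
    params: HBondParams | None = None,
    frame_range: tuple[int, int] | None = None,
    frame_mask: np.ndarray | None = None,
    markers: Mapping[str, str] | None = None,
    route_ceiling: float = DEFAULT_ROUTE_CEILING,
    progress_every: int = 0,
) -> PathwayStats:
    """Detect the shortest water pathway in every frame of a trajectory.

    ``frame_range`` restricts analysis to ``[start, stop)``; ``frame_mask``
    (boolean per retained frame) further subsets frames, e.g. to one
    rotameric cluster. When ``markers`` (label -> selection expression) is
    given, each found pathway is route-classified. Errors in a frame are
    re-raised with the frame index in the message.
    """
    params = params or HBondParams()
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    start, stop = frame_range if frame_range is not None else (0, traj.n_frames)
    indices = np.arange(start, stop)
    if frame_mask is not None:
        mask = np.asarray(frame_mask, dtype=bool)
        if mask.size != indices.size:
            raise ValueError(f"frame_mask length {mask.size} != {indices.size} analyzed frames")
        indices = indices[mask]

    present = np.zeros(indices.size, dtype=bool)
    paths: list[WaterPathway] = []
    labels: list[str] = [] if markers else None  # type: ignore[assignment]
    for k, f in enumerate(indices):
        try:
            graph = build_water_graph(traj.topology, traj.frames[f], params)
            path = shortest_water_path(graph, frame_index=int(f))
        except Exception as exc:
            raise type(exc)(f"frame {f}: {exc}") from exc
        if path is not None:
            present[k] = True
            paths.append(path)
            if markers:
                rl = classify_route(
                    path, traj.topology, traj.frames[f], markers, ceiling=route_ceiling
                )
                labels.append(rl.label)
        if progress_every and (k + 1) % progress_every == 0:
            logger.info("scanned %d/%d frames, %d pathways", k + 1, indices.size, len(paths))
    return PathwayStats(present=present, paths=paths, route_labels=labels)


def classify_route(
    path: WaterPathway,
    topology: Structure,
    coords: np.ndarray,
    markers: Mapping[str, str | Selection],
    ceiling: float = DEFAULT_ROUTE_CEILING,
) -> RouteLabel:
    """Label a pathway by the nearest marker residue side chain.

    The label is the marker attaining the smallest minimum distance between
    its atoms and any path-water oxygen; ``other`` if no marker comes within
    ``ceiling`` Å. Ties (to 1e-9 Å) break deterministically by marker name
    order and are logged.
    """
    if not markers:
        raise ValueError("classify_route requires at least one marker")
    if not path.waters:
        raise ValueError("cannot classify an empty pathway")
    coords = np.asarray(coords, dtype=float)
    water_pos = coords[list(path.waters)]
    dists: dict[str, float] = {}
    for label in sorted(markers):
        sel = markers[label]
        if isinstance(sel, str):
            sel = resolve_selection(topology, sel)
        if len(sel) == 0:
            raise ValueError(f"marker {label!r} selects no atoms")
        marker_pos = coords[list(sel.indices)]
        diff = water_pos[:, None, :] - marker_pos[None, :, :]
        dists[label] = float(np.sqrt((diff**2).sum(axis=2)).min())
    best = min(dists, key=lambda k: (dists[k], k))
    near_ties = [k for k in dists if k != best and abs(dists[k] - dists[best]) <= 1e-9]
    if near_ties:
        logger.info(
            "route tie at frame %d between %s and %s; choosing %r by name order",
            path.frame_index,
            best,
            near_ties,
            best,
        )
    if dists[best] > ceiling:
        return RouteLabel("other", dists)
    return RouteLabel(best, dists)


# ---------------------------------------------------------------------------
# Occupancy map


def occupancy_map(
    traj: Trajectory,
    region: tuple[Sequence[float], Sequence[float]],
    voxel: float,
    isovalue: float = DEFAULT_ISOVALUE,
    frame_mask: np.ndarray | None = None,
) -> DensityGrid:
    """Fraction of frames with ≥1 water oxygen per voxel of an axis-aligned box.

    ``region`` is ``(lower_corner, upper_corner)`` in Å. A region containing
    no coordinates yields an all-zero grid with a logged warning.
    """
    if voxel <= 0:
        raise ValueError("voxel edge must be positive")
    lo = np.asarray(region[0], dtype=float)
    hi = np.asarray(region[1], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("region upper corner must exceed lower corner on every axis")
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)

    o_idx = np.array([w.o_index for w in identify_waters(traj.topology)], dtype=int)
    counts = np.zeros(tuple(shape), dtype=np.int64)
    frame_ids = np.arange(traj.n_frames)
    if frame_mask is not None:
        frame_ids = frame_ids[np.asarray(frame_mask, dtype=bool)]
    if o_idx.size:
        for f in frame_ids:
            pos = traj.frames[f][o_idx]
            cell = np.floor((pos - lo) / voxel).astype(int)
            inside = np.all((cell >= 0) & (cell < shape), axis=1)
            if not np.any(inside):
                continue
            occupied = np.unique(cell[inside], axis=0)
            counts[occupied[:, 0], occupied[:, 1], occupied[:, 2]] += 1
    grid = DensityGrid(lo, float(voxel), counts, n_frames=len(frame_ids), isovalue=isovalue)
    if grid.counts.sum() == 0:
        logger.warning("occupancy region contains no water oxygens in any analyzed frame")
    return grid


def write_opendx(grid: DensityGrid, path: str) -> None:
    """Export an occupancy grid as OpenDX scalar text (for VMD/PyMOL)."""
    nx, ny, nz = grid.counts.shape
    occ = grid.occupancy
    with open(path, "w") as fh:
        fh.write(f"# water occupancy map, isovalue {grid.isovalue}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {grid.origin[0]:.4f} {grid.origin[1]:.4f} {grid.origin[2]:.4f}\n")
        fh.write(f"delta {grid.voxel:.4f} 0 0\n")
        fh.write(f"delta 0 {grid.voxel:.4f} 0\n")
        fh.write(f"delta 0 0 {grid.voxel:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {occ.size} data follows\n")
        flat = occ.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6f}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
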