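"""Side-chain dihedral (χ) time series and rotamer clustering.

χ angles are signed dihedrals in degrees, wrapped to (−180, 180]. Clustering
runs k-means on the unit-circle embedding (sin, cos of each χ), which makes
the metric continuous across the ±180° seam: a single angular mode straddling
the seam is never split into two clusters. Cluster labels are renumbered by
descending population and cluster centers are circular means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .structio import Structure, Trajectory

# Standard side-chain χ atom quadruples (N–CA–CB–... chains), per residue type.
CHI_DEFINITIONS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


@dataclass
class ChiSeries:
    """Per-frame χ1..χk vectors for one residue, degrees in (−180, 180]."""

    resid: int
    chi: np.ndarray  # (n_frames, k)

    @property
    def n_frames(self) -> int:
        return self.chi.shape[0]

    @property
    def n_chi(self) -> int:
        return self.chi.shape[1]


@dataclass
class ClusterResult:
    """Rotamer clustering: per-frame labels, circular-mean centers, populations."""

    labels: np.ndarray  # (n_frames,) int, 0-based, ordered by descending population
    centers: np.ndarray  # (K, k) degrees
    populations: np.ndarray  # (K,) frame fractions, sums to 1

    @property
    def k(self) -> int:
        return self.centers.shape[0]


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle(s) in degrees, vectorized over leading axes.

    Zero for a cis (eclipsed) arrangement, ±180 for trans; sign follows the
    right-hand rule about the p1→p2 axis (IUPAC convention).
    """
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def wrap_angle(deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap degrees into (−180, 180]."""
    wrapped = -np.mod(-np.asarray(deg) + 180.0, 360.0) + 180.0
    return wrapped if np.ndim(deg) else float(wrapped)


def circular_mean(deg: np.ndarray, axis: int = 0) -> np.ndarray | float:
    """Circular mean of angles in degrees, in (−180, 180]."""
    rad = np.radians(deg)
    mean = np.degrees(np.arctan2(np.sin(rad).mean(axis=axis), np.cos(rad).mean(axis=axis)))
    return wrap_angle(mean)


def chi_angles(
    traj: Trajectory,
    resid: int,
    chain: str | None = None,
    definitions: dict[str, list[tuple[str, str, str, str]]] | None = None,
) -> ChiSeries:
    """Extract the χ-angle time series for one residue across a trajectory.

    A missing atom raises a descriptive ``ValueError`` naming it.
    """
    definitions = definitions or CHI_DEFINITIONS
    atoms = {
        a.name: i
        for i, a in enumerate(traj.topology.atoms)
        if a.resid == resid and (chain is None or a.chain == chain)
    }
    resnames = {
        a.resname for a in traj.topology.atoms if a.resid == resid and (chain is None or a.chain == chain)
    }
    if not resnames:
        raise ValueError(f"residue {resid} not found in topology")
    resname = sorted(resnames)[0]
    quads = definitions.get(resname.upper())
    if not quads:
        raise ValueError(f"no χ definitions for residue type {resname!r}")
    cols = []
    for quad in quads:
        idx = []
        for name in quad:
            if name not in atoms:
                raise ValueError(f"residue {resname} {resid} is missing atom {name!r} required for χ")
            idx.append(atoms[name])
        p = traj.frames[:, idx, :]  # (n_frames, 4, 3)
        cols.append(dihedral(p[:, 0], p[:, 1], p[:, 2], p[:, 3]))
    return ChiSeries(resid, np.stack(cols, axis=1))


def cluster_conformers(
    series: ChiSeries,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterResult:
    """k-means rotamer clustering on the (sin, cos) embedding of the χ vector.

    Deterministic for a given ``seed``. Labels are renumbered so cluster 0 is
    the most populated; centers are per-cluster circular means of each χ.
    Raises ``ValueError`` when there are fewer frames than clusters.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if series.n_frames < k:
        raise ValueError(f"cannot form {k} clusters from {series.n_frames} frames")
    rad = np.radians(series.chi)
    embed = np.concatenate([np.sin(rad), np.cos(rad)], axis=1)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(embed)
    counts = np.bincount(raw, minlength=k)
    order = np.argsort(-counts, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]
    centers = np.stack(
        [circular_mean(series.chi[labels == c], axis=0) for c in range(k)]
    ).reshape(k, series.n_chi)
    populations = np.bincount(labels, minlength=k) / series.n_frames
    return ClusterResult(labels, centers, populations)
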