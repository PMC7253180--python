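"""Conformational comparison of structure pairs.

Difference distance matrices (DDMs) compare two conformations through the
change in every Cα–Cα distance, which makes them independent of how the two
structures are superposed — the property that motivates their use alongside
per-residue displacement profiles, which *do* depend on an alignment choice.
Superposition is least-squares rigid-body (Kabsch, proper rotation only),
by default on the helix B/F/G/I core segments of the CLC-ec1 numbering
(residues 35–47, 153–164, 174–190, 215–223), which stay put between the
conformations being compared. Inverted-repeat RMSD compares the two
structurally homologous halves (Helices B–I vs J–Q) within and across
structures via a residue correspondence table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structio import Structure

logger = logging.getLogger(__name__)

# Core helix segments that superpose well between conformations (CLC-ec1
# numbering): helices B, F, G and I.
DEFAULT_ALIGN_SUBSET: tuple[tuple[int, int], ...] = ((35, 47), (153, 164), (174, 190), (215, 223))


@dataclass
class DistanceMatrix:
    """Symmetric Cα–Cα distance matrix over an ordered residue list."""

    resids: tuple[int, ...]
    d: np.ndarray  # (n, n) Å

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.resids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} residues")


@dataclass
class DifferenceDistanceMatrix:
    """Signed per-pair distance change D_A − D_B between two conformations."""

    resids: tuple[int, ...]
    delta: np.ndarray  # (n, n) Å, signed
    helix_annotation: Mapping[int, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.delta, index=list(self.resids), columns=list(self.resids))


@dataclass
class SuperpositionResult:
    """Rigid-body fit of mobile onto reference over an alignment subset."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd_fit: float  # Å over the alignment subset
    per_residue_delta: pd.Series  # Å displacement per common residue after the fit

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RepeatDefinition:
    """The two inverted-topology repeats and their residue correspondence."""

    repeat1: tuple[tuple[int, int], ...]  # helices B–I
    repeat2: tuple[tuple[int, int], ...]  # helices J–Q
    correspondence: tuple[tuple[int, int], ...]  # (resid in repeat1, resid in repeat2)

    def __post_init__(self) -> None:
        r1 = {r for lo, hi in self.repeat1 for r in range(lo, hi + 1)}
        r2 = {r for lo, hi in self.repeat2 for r in range(lo, hi + 1)}
        for a, b in self.correspondence:
            if a not in r1 or b not in r2:
                raise ValueError(f"correspondence pair ({a}, {b}) outside the repeat ranges")


# ---------------------------------------------------------------------------
# Packaged annotation tables


def helix_annotation() -> dict[int, str]:
    """Residue → helix letter (A..R) table for CLC-ec1 numbering.

    Loaded from the packaged, user-editable TSV. Residues outside any helix
    are absent from the mapping.
    """
    mapping: dict[int, str] = {}
    text = resources.files("confwire.data").joinpath("clc_ec1_helices.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        helix, lo, hi = line.split("\t")
        for r in range(int(lo), int(hi) + 1):
            mapping[r] = helix
    return mapping


def default_repeats() -> RepeatDefinition:
    """Default inverted-repeat definition with a 1:1 range-order correspondence.

    The residue pairing between the repeats is a curated default (editable by
    replacing the packaged table); results that depend on it should be read
    as correspondence-dependent.
    """
    text = resources.files("confwire.data").joinpath("clc_ec1_repeats.tsv").read_text()
    r1: list[tuple[int, int]] = []
    r2: list[tuple[int, int]] = []
    pairs: list[tuple[int, int]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        which, lo1, hi1, lo2, hi2 = line.split("\t")
        a = (int(lo1), int(hi1))
        b = (int(lo2), int(hi2))
        if a[1] - a[0] != b[1] - b[0]:
            raise ValueError(f"paired segments {a} and {b} have unequal lengths")
        r1.append(a)
        r2.append(b)
        pairs.extend(zip(range(a[0], a[1] + 1), range(b[0], b[1] + 1)))
    return RepeatDefinition(tuple(r1), tuple(r2), tuple(pairs))


# ---------------------------------------------------------------------------
# Distance matrices


def _ca_map(structure: Structure, chain: str | None = None) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    for a in structure.atoms:
        if a.name == "CA" and (chain is None or a.chain == chain):
            out.setdefault(a.resid, np.asarray(a.xyz, dtype=float))
    return out


def ca_distance_matrix(
    structure: Structure,
    resids: Sequence[int] | None = None,
    chain: str | None = None,
) -> DistanceMatrix:
    """All-pairs Cα–Cα Euclidean distances over the listed residues.

    Defaults to every residue with a Cα. A listed residue lacking a Cα
    raises ``ValueError`` naming it.
    """
    ca = _ca_map(structure, chain)
    if resids is None:
        resids = sorted(ca)
    missing = [r for r in resids if r not in ca]
    if missing:
        raise ValueError(f"residues without a CA atom: {missing}")
    pts = np.stack([ca[r] for r in resids])
    return DistanceMatrix(tuple(int(r) for r in resids), cdist(pts, pts))


def difference_matrix(
    a: DistanceMatrix,
    b: DistanceMatrix,
    helix_only: bool = False,
) -> DifferenceDistanceMatrix:
    """Elementwise D_A − D_B (signed). Resid lists must match exactly.

    ``helix_only`` restricts the output to residues annotated as helical in
    the packaged table.
    """
    if a.resids != b.resids:
        only_a = sorted(set(a.resids) - set(b.resids))
        only_b = sorted(set(b.resids) - set(a.resids))
        raise ValueError(
            f"residue lists differ (only in A: {only_a[:10]}, only in B: {only_b[:10]})"
        )
    annotation = helix_annotation()
    resids = a.resids
    delta = a.d - b.d
    if helix_only:
        keep = [i for i, r in enumerate(resids) if r in annotation]
        resids = tuple(resids[i] for i in keep)
        delta = delta[np.ix_(keep, keep)]
    return DifferenceDistanceMatrix(resids, delta, {r: annotation[r] for r in resids if r in annotation})


# ---------------------------------------------------------------------------
# Kabsch superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of point set ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1) enforced via the SVD sign correction. Requires ≥3
    non-collinear points; degenerate input raises ``ValueError``.
    """
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if p.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    if np.linalg.matrix_rank(pc, tol=1e-8) < 2:
        raise ValueError("alignment points are collinear; the fit is degenerate")
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    trans = q.mean(axis=0) - p.mean(axis=0) @ rot.T
    fitted = p @ rot.T + trans
    rmsd = float(np.sqrt(((fitted - q) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def _subset_resids(subset: Sequence[tuple[int, int]] | Sequence[int]) -> list[int]:
    resids: list[int] = []
    for item in subset:
        if isinstance(item, (tuple, list)):
            lo, hi = item
            resids.extend(range(int(lo), int(hi) + 1))
        else:
            resids.append(int(item))
    return resids


def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    subset: Sequence[tuple[int, int]] | Sequence[int] = DEFAULT_ALIGN_SUBSET,
    chain: str | None = None,
) -> SuperpositionResult:
    """Superpose ``mobile`` onto ``reference`` on a Cα subset.

    The fit uses only the subset residues; ``per_residue_delta`` reports the
    post-fit Cα displacement of every residue common to both structures.
    """
    ca_m = _ca_map(mobile, chain)
    ca_r = _ca_map(reference, chain)
    wanted = [r for r in _subset_resids(subset) if r in ca_m and r in ca_r]
    if len(wanted) < 3:
        raise ValueError(f"alignment subset resolves to only {len(wanted)} shared Cα")
    rot, trans, rmsd = kabsch(
        np.stack([ca_m[r] for r in wanted]), np.stack([ca_r[r] for r in wanted])
    )
    common = sorted(set(ca_m) & set(ca_r))
    moved = np.stack([ca_m[r] for r in common]) @ rot.T + trans
    ref = np.stack([ca_r[r] for r in common])
    delta = pd.Series(np.linalg.norm(moved - ref, axis=1), index=common, name="delta_A")
    return SuperpositionResult(rot, trans, rmsd, delta)


def repeat_rmsd(
    structure_a: Structure,
    structure_b: Structure,
    repeats: RepeatDefinition | None = None,
    chain: str | None = None,
) -> pd.DataFrame:
    """Kabsch RMSD table over the inverted repeats.

    Rows: R1_A_vs_R1_B, R2_A_vs_R2_B (same repeat across structures, direct
    residue identity) and R1_vs_R2_in_A / R1_vs_R2_in_B (inverted repeats
    within one structure, via the correspondence table).
    """
    repeats = repeats or default_repeats()
    ca_a = _ca_map(structure_a, chain)
    ca_b = _ca_map(structure_b, chain)

    def _pts(ca: Mapping[int, np.ndarray], resids: Sequence[int]) -> np.ndarray:
        missing = [r for r in resids if r not in ca]
        if missing:
            raise ValueError(f"repeat correspondence cannot resolve residues {missing[:10]}")
        return np.stack([ca[r] for r in resids])

    r1 = _subset_resids(repeats.repeat1)
    r2 = _subset_resids(repeats.repeat2)
    c1 = [a for a, _ in repeats.correspondence]
    c2 = [b for _, b in repeats.correspondence]

    rows = {}
    rows["R1_A_vs_R1_B"] = kabsch(_pts(ca_a, r1), _pts(ca_b, r1))[2]
    rows["R2_A_vs_R2_B"] = kabsch(_pts(ca_a, r2), _pts(ca_b, r2))[2]
    rows["R1_vs_R2_in_A"] = kabsch(_pts(ca_a, c1), _pts(ca_a, c2))[2]
    rows["R1_vs_R2_in_B"] = kabsch(_pts(ca_b, c1), _pts(ca_b, c2))[2]
    return pd.DataFrame({"rmsd_A": rows.values()}, index=list(rows))
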