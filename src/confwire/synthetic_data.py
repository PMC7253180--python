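"""Synthetic inputs with planted ground truth for every analysis stage.

Three generators:

* :func:`make_wire_trajectory` — toy trajectories of a glutamine-like seed
  residue, an explicit water chain running from the seed down to the
  intracellular bulk slab, and non-bridging noise waters. Each frame is
  connected with probability ``p_connect``; broken frames displace one chain
  water beyond every cutoff, so the per-frame ground truth is exact.
* :func:`make_structure_pair` — idealized Cα-only helical chains where a
  chosen residue subset is rigidly displaced and the whole second copy is
  then re-posed by a random rigid transform; per-residue displacement truth
  is returned.
* :func:`make_deer_dataset` — four-/five-pulse dipolar traces from a known
  model with additive Gaussian noise.

Planted chains satisfy the detector's geometric criteria with a construction
margin of at least 0.2 Å so detection never rides a cutoff boundary; noise
waters are kept ≥5 Å from the chain and from each other so they can never
bridge. Hydrogens are placed explicitly along chain O→O vectors (O–H
0.96 Å), exercising the hydrogen-acceptor criterion rather than the O–O
fallback. All generators are deterministic under a fixed ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .deer import (
    DeerModel,
    DipolarSignal,
    FIVE_PULSE,
    FOUR_PULSE,
    GaussianPr,
    simulate_signal,
)
from .structio import AtomRecord, Structure, Trajectory


class GenerationError(RuntimeError):
    """Raised when a synthetic system cannot be packed within its box."""


@dataclass(frozen=True)
class WireSystemSpec:
    """Geometry and statistics of a planted water-wire system."""

    n_frames: int = 300
    p_connect: float = 0.5
    chain_length: int = 5
    o_o_spacing: float = 2.7  # Å
    z_bulk: float = -15.0  # Å, bulk slab lies below this plane
    n_noise_waters: int = 20
    n_bulk_waters: int = 8
    seed_offset: float = 3.0  # Å, seed atom to first chain oxygen (cutoff 3.5)
    margin: float = 0.5  # Å, clearance below the bulk plane for the last oxygen
    box_halfwidth: float = 12.0  # Å, lateral extent for noise waters
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_connect <= 1.0):
            raise ValueError("p_connect must be in [0, 1]")
        if self.chain_length < 2:
            raise ValueError("chain_length must be at least 2")
        if self.o_o_spacing >= 3.5:
            raise ValueError("o_o_spacing must stay below the O-O fallback cutoff")


@dataclass(frozen=True)
class MotionPairSpec:
    """A structure pair differing by a rigid displacement of a residue subset."""

    n_residues: int = 100
    moved_subset: tuple[tuple[int, int], ...] = ((50, 60),)
    displacement: tuple[float, float, float] = (3.0, 0.0, 0.0)
    global_transform: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in self.moved_subset:
            if not (1 <= lo <= hi <= self.n_residues):
                raise ValueError(f"moved range ({lo}, {hi}) outside 1..{self.n_residues}")


@dataclass(frozen=True)
class DeerTruthSpec:
    """Ground-truth model and sampling for synthetic DEER datasets."""

    model: DeerModel = field(
        default_factory=lambda: DeerModel(
            GaussianPr(35.0, 2.0), lam=0.3, k_bg=0.05, eta=0.25, t_shift=2.6
        )
    )
    t_max: float = 3.0  # µs
    n_points: int = 200
    noise_sd: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 50:
            raise ValueError("n_points must be at least 50")


# ---------------------------------------------------------------------------
# Water-wire trajectories

OH_LENGTH = 0.96  # Å

_SEED_RESID = 148


def _chain_positions(spec: WireSystemSpec) -> tuple[np.ndarray, np.ndarray]:
    """(seed atom position, intact chain oxygen positions) for the planted wire.

    The chain descends along −z with the last oxygen ``margin`` below the
    bulk plane and the first oxygen ``seed_offset`` below the seed atom.
    """
    last_z = spec.z_bulk - spec.margin
    first_z = last_z + (spec.chain_length - 1) * spec.o_o_spacing
    seed_pos = np.array([0.0, 0.0, first_z + spec.seed_offset])
    zs = first_z - np.arange(spec.chain_length) * spec.o_o_spacing
    chain = np.stack([np.zeros_like(zs), np.zeros_like(zs), zs], axis=1)
    return seed_pos, chain


def _water_atoms(o_pos: np.ndarray, h1: np.ndarray, h2: np.ndarray, resid: int, serial0: int) -> list[AtomRecord]:
    return [
        AtomRecord(serial0, "OH2", "O", "TIP3", resid, "W", tuple(o_pos)),
        AtomRecord(serial0 + 1, "H1", "H", "TIP3", resid, "W", tuple(h1)),
        AtomRecord(serial0 + 2, "H2", "H", "TIP3", resid, "W", tuple(h2)),
    ]


def make_wire_trajectory(spec: WireSystemSpec) -> tuple[Trajectory, np.ndarray]:
    """Generate a trajectory with a planted seed-to-bulk water wire.

    Returns ``(trajectory, truth)`` where ``truth[f]`` is True iff the chain
    is intact in frame ``f``. Connected frames contain a hydrogen-bonded
    chain from within ``seed_offset`` of the seed amide atoms to an oxygen
    below the bulk plane; broken frames displace one chain water to a
    parking position far from everything. Noise waters jitter slightly
    around fixed positions that keep ≥5 Å from the chain, the parking spot,
    the seed, and each other.
    """
    rng = np.random.default_rng(spec.rng_seed)
    seed_pos, chain = _chain_positions(spec)

    # Seed residue: glutamine-like amide with OE1/NE2 flanking the chain head.
    seed_atoms = [
        AtomRecord(1, "CD", "C", "GLN", _SEED_RESID, "A", tuple(seed_pos + np.array([0.0, 1.2, 0.6]))),
        AtomRecord(2, "OE1", "O", "GLN", _SEED_RESID, "A", tuple(seed_pos)),
        AtomRecord(3, "NE2", "N", "GLN", _SEED_RESID, "A", tuple(seed_pos + np.array([1.3, 1.8, 0.4]))),
    ]

    parking = np.array([spec.box_halfwidth + 18.0, 0.0, (chain[0, 2] + chain[-1, 2]) / 2.0])

    # Fixed noise-water sites, rejection-sampled with a 5 Å exclusion radius.
    exclusion = np.vstack([chain, seed_pos[None, :], parking[None, :]])
    noise_sites: list[np.ndarray] = []
    z_lo, z_hi = spec.z_bulk + 1.5, seed_pos[2] + 2.0
    max_tries = 20000
    tries = 0
    while len(noise_sites) < spec.n_noise_waters:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not pack {spec.n_noise_waters} noise waters with 5 Å spacing "
                f"in a ±{spec.box_halfwidth} Å box"
            )
        cand = np.array(
            [
                rng.uniform(-spec.box_halfwidth, spec.box_halfwidth),
                rng.uniform(-spec.box_halfwidth, spec.box_halfwidth),
                rng.uniform(z_lo, z_hi),
            ]
        )
        pool = exclusion if not noise_sites else np.vstack([exclusion, np.stack(noise_sites)])
        if np.min(np.linalg.norm(pool - cand, axis=1)) >= 5.0:
            noise_sites.append(cand)

    # Bulk slab waters below the plane, likewise non-bridging.
    bulk_sites: list[np.ndarray] = []
    tries = 0
    while len(bulk_sites) < spec.n_bulk_waters:
        tries += 1
        if tries > max_tries:
            raise GenerationError("could not pack bulk slab waters")
        cand = np.array(
            [
                rng.uniform(-spec.box_halfwidth, spec.box_halfwidth),
                rng.uniform(-spec.box_halfwidth, spec.box_halfwidth),
                rng.uniform(spec.z_bulk - 8.0, spec.z_bulk - 2.0),
            ]
        )
        pool = np.vstack(
            [exclusion]
            + ([np.stack(noise_sites)] if noise_sites else [])
            + ([np.stack(bulk_sites)] if bulk_sites else [])
        )
        if np.min(np.linalg.norm(pool - cand, axis=1)) >= 5.0:
            bulk_sites.append(cand)

    def chain_waters(positions: np.ndarray, serial0: int, resid0: int) -> list[AtomRecord]:
        atoms: list[AtomRecord] = []
        for i, o in enumerate(positions):
            if i + 1 < len(positions):
                direction = positions[i + 1] - o
            else:
                direction = np.array([0.0, 0.0, -1.0])
            direction = direction / np.linalg.norm(direction)
            h1 = o + OH_LENGTH * direction  # donates along the chain
            h2 = o + OH_LENGTH * np.array([1.0, 0.0, 0.0])
            atoms.extend(_water_atoms(o, h1, h2, resid0 + i, serial0 + 3 * i))
        return atoms

    def free_waters(sites: Sequence[np.ndarray], serial0: int, resid0: int, rng_: np.random.Generator) -> list[AtomRecord]:
        atoms: list[AtomRecord] = []
        for i, o in enumerate(sites):
            u = rng_.normal(size=3)
            u /= np.linalg.norm(u)
            v = rng_.normal(size=3)
            v -= v @ u * u
            v /= np.linalg.norm(v)
            atoms.extend(
                _water_atoms(o, o + OH_LENGTH * u, o + OH_LENGTH * v, resid0 + i, serial0 + 3 * i)
            )
        return atoms

    topo_atoms = list(seed_atoms)
    topo_atoms += chain_waters(chain, serial0=4, resid0=1)
    n_chain_atoms = 3 * spec.chain_length
    topo_atoms += free_waters(noise_sites, serial0=4 + n_chain_atoms, resid0=1 + spec.chain_length, rng_=rng)
    topo_atoms += free_waters(
        bulk_sites,
        serial0=4 + n_chain_atoms + 3 * spec.n_noise_waters,
        resid0=1 + spec.chain_length + spec.n_noise_waters,
        rng_=rng,
    )
    topology = Structure(topo_atoms)
    base = topology.coords

    truth = rng.random(spec.n_frames) < spec.p_connect
    frames = np.empty((spec.n_frames, base.shape[0], 3))
    chain_atom0 = 3  # first chain-water atom index (O of water 1)
    for f in range(spec.n_frames):
        coords = base.copy()
        # jitter noise and bulk waters (±0.2 Å keeps every exclusion margin)
        jstart = 3 + n_chain_atoms
        coords[jstart:] += rng.uniform(-0.2, 0.2, size=coords[jstart:].shape)
        if not truth[f]:
            # break the wire: park one chain water (O and both H) far away
            broken = int(rng.integers(0, spec.chain_length))
            a0 = chain_atom0 + 3 * broken
            shift = parking - coords[a0]
            coords[a0 : a0 + 3] += shift
        frames[f] = coords
    return Trajectory(topology, frames), truth


# ---------------------------------------------------------------------------
# Structure pairs with planted motion


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR-based, det = +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_structure_pair(spec: MotionPairSpec) -> tuple[Structure, Structure, dict[int, float]]:
    """Cα-only helical chain pair with a planted rigid subset displacement.

    Copy B equals copy A with ``moved_subset`` residues translated by
    ``displacement`` and (optionally) the whole copy re-posed by a random
    rigid transform. The returned truth maps resid → planted displacement
    magnitude (Å) in the un-posed frame.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_residues
    # idealized alpha-helical Cα trace: 2.3 Å radius, 100°/residue, 1.5 Å rise
    idx = np.arange(n)
    theta = np.radians(100.0 * idx)
    coords_a = np.stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * idx], axis=1
    )
    moved = np.zeros(n, dtype=bool)
    for lo, hi in spec.moved_subset:
        moved[lo - 1 : hi] = True
    disp = np.asarray(spec.displacement, dtype=float)
    coords_b = coords_a.copy()
    coords_b[moved] += disp
    if spec.global_transform:
        rot = random_rotation(rng)
        trans = rng.uniform(-20, 20, size=3)
        coords_b = coords_b @ rot.T + trans

    def build(coords: np.ndarray) -> Structure:
        atoms = [
            AtomRecord(i + 1, "CA", "C", "ALA", i + 1, "A", tuple(c)) for i, c in enumerate(coords)
        ]
        return Structure(atoms)

    truth = {int(i + 1): (float(np.linalg.norm(disp)) if moved[i] else 0.0) for i in idx}
    return build(coords_a), build(coords_b), truth


# ---------------------------------------------------------------------------
# DEER datasets


def make_deer_dataset(
    spec: DeerTruthSpec,
) -> tuple[DipolarSignal, DipolarSignal, DeerModel]:
    """Noisy four- and five-pulse traces from a known model.

    Both traces share the truth model; noise is additive i.i.d. Gaussian
    with SD ``noise_sd``. Deterministic under ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    t4 = np.linspace(-0.1, spec.t_max, spec.n_points)
    t5 = np.linspace(-0.1, spec.t_max, spec.n_points)
    clean4 = simulate_signal(spec.model, t4, FOUR_PULSE)
    clean5 = simulate_signal(spec.model, t5, FIVE_PULSE)
    v4 = clean4.v + rng.normal(0.0, spec.noise_sd, size=t4.size)
    v5 = clean5.v + rng.normal(0.0, spec.noise_sd, size=t5.size)
    return (
        DipolarSignal(t4, v4, FOUR_PULSE),
        DipolarSignal(t5, v5, FIVE_PULSE),
        spec.model,
    )
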