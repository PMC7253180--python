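"""Shared fixtures: small hand-built structures and synthetic systems."""

from __future__ import annotations

import numpy as np
import pytest

from confwire.structio import AtomRecord, Structure


def make_water(resid: int, o: tuple, h1: tuple | None = None, h2: tuple | None = None, serial0: int = 1):
    """Atoms of one TIP3-style water; hydrogens optional."""
    atoms = [AtomRecord(serial0, "OH2", "O", "HOH", resid, "W", tuple(map(float, o)))]
    if h1 is not None:
        atoms.append(AtomRecord(serial0 + 1, "H1", "H", "HOH", resid, "W", tuple(map(float, h1))))
    if h2 is not None:
        atoms.append(AtomRecord(serial0 + 2, "H2", "H", "HOH", resid, "W", tuple(map(float, h2))))
    return atoms


@pytest.fixture
def gln_toy() -> Structure:
    """Two-residue toy with a GLN 148 bearing OE1/NE2 and backbone CAs."""
    atoms = [
        AtomRecord(1, "CA", "C", "GLN", 148, "A", (0.0, 0.0, 0.0)),
        AtomRecord(2, "OE1", "O", "GLN", 148, "A", (1.0, 1.0, 0.0)),
        AtomRecord(3, "NE2", "N", "GLN", 148, "A", (1.5, -0.5, 0.5)),
        AtomRecord(4, "CA", "C", "ALA", 149, "A", (3.8, 0.0, 0.0)),
    ]
    return Structure(atoms)


def random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random proper rotation + translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-15.0, 15.0, size=3)
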