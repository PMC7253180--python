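"""Structure and trajectory I/O, atom selections, and basic geometric measurements.

Coordinates are in Å throughout. Structures are assumed to be membrane-aligned:
the membrane normal is the z axis and the membrane center sits at z = 0, the
frame in which the intracellular bulk-water criterion (z below a threshold)
is meaningful. Atom indices are 0-based internally; author residue numbering
(``resid``) is preserved.

PDB reading is fixed-column (ATOM/HETATM/MODEL/ENDMDL/TER). Alternate
locations other than blank or 'A' are dropped; insertion codes are rejected
with a clear error. A simple ``frames-xyz`` trajectory dialect is also
supported: a header line ``natoms nframes`` followed by per-frame blocks of
``name x y z`` lines (``#`` comments allowed anywhere).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3"})

MEMBRANE_NOTE = "membrane normal along z, membrane center at z = 0"


class PDBFormatError(ValueError):
    """Raised when a PDB or frames-xyz file cannot be parsed."""


class SelectionError(ValueError):
    """Raised when a selection expression does not parse."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus Å coordinates."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    xyz: tuple[float, float, float]

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resid, self.name)


@dataclass
class Structure:
    """An ordered collection of atoms in a membrane-aligned frame."""

    atoms: list[AtomRecord]
    frame_origin_note: str = MEMBRANE_NOTE

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Structure must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Å."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate shape {coords.shape} does not match atom count {len(self.atoms)}")
        atoms = [replace(a, xyz=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, self.frame_origin_note)


@dataclass
class Trajectory:
    """Shared topology plus ordered coordinate frames (Å), optional times (ns)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frames shape {self.frames.shape} inconsistent with topology of {len(self.topology)} atoms"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class Selection:
    """A resolved atom selection: the expression and its 0-based indices."""

    expression: str
    indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# PDB I/O


def _parse_atom_line(line: str, serial_fallback: int) -> AtomRecord:
    altloc = line[16:17]
    if altloc not in (" ", "A"):
        return None  # type: ignore[return-value]
    icode = line[26:27]
    if icode != " ":
        raise PDBFormatError(f"insertion codes are not supported (got {icode!r} in line: {line.rstrip()})")
    name = line[12:16].strip()
    resname = line[17:21].strip()
    chain = line[21:22].strip() or "A"
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = serial_fallback
    try:
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBFormatError(f"malformed ATOM/HETATM record: {line.rstrip()}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
        raise PDBFormatError(f"non-finite coordinates in line: {line.rstrip()}")
    return AtomRecord(serial, name, element, resname, resid, chain, (x, y, z))


def _guess_element(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in {"CL", "NA", "MG", "ZN", "FE", "BR", "CA"}:
        # two-letter element only when the atom name is exactly that ion
        if name.strip().upper() in {"CL", "NA", "MG", "ZN", "FE", "BR"}:
            return name.strip().capitalize()
    return stripped[:1].upper() if stripped else "X"


def read_pdb(path: str | Path) -> Structure:
    """Read the first MODEL of a PDB file into a :class:`Structure`.

    Alternate locations other than blank/'A' are dropped. Raises
    :class:`PDBFormatError` if no atoms are parsed, :class:`OSError` if the
    file is unreadable.
    """
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "ENDMDL":
                break
            if rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, serial_fallback=len(atoms) + 1)
                if atom is not None:
                    atoms.append(atom)
    if not atoms:
        raise PDBFormatError(f"no ATOM/HETATM records parsed from {path}")
    return Structure(atoms)


def write_pdb(structure: Structure, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write a structure as fixed-column PDB (coordinates to 3 decimals)."""
    with open(path, "w") as fh:
        for text in header_lines:
            fh.write(f"REMARK   1 {text}\n")
        _write_model(fh, structure.atoms, structure.coords)
        fh.write("END\n")


def _write_model(fh, atoms: Sequence[AtomRecord], coords: np.ndarray) -> None:
    for a, (x, y, z) in zip(atoms, coords):
        record = "HETATM" if a.resname in WATER_RESNAMES else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        fh.write(
            f"{record}{a.serial:>5d} {name:<4s} {a.resname:<4s}"
            f"{a.chain:1s}{a.resid:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
        )


def read_trajectory(path: str | Path, dialect: str = "multi-model-pdb") -> Trajectory:
    """Read a multi-frame trajectory.

    ``dialect`` is either ``multi-model-pdb`` (MODEL/ENDMDL blocks sharing one
    topology) or ``frames-xyz`` (header ``natoms nframes`` then per-frame
    blocks of ``name x y z``). Frames with inconsistent atom counts raise
    :class:`PDBFormatError`.
    """
    if dialect == "multi-model-pdb":
        return _read_multimodel_pdb(path)
    if dialect == "frames-xyz":
        return _read_frames_xyz(path)
    raise ValueError(f"unknown trajectory dialect: {dialect!r}")


def _read_multimodel_pdb(path: str | Path) -> Trajectory:
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] | None = None
    saw_model_kw = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model_kw = True
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    if saw_model_kw:
                        continue
                    current = []
                atom = _parse_atom_line(line, serial_fallback=len(current) + 1)
                if atom is not None:
                    current.append(atom)
    if current:
        models.append(current)
    if not models or not models[0]:
        raise PDBFormatError(f"no frames parsed from {path}")
    n = len(models[0])
    for i, m in enumerate(models):
        if len(m) != n:
            raise PDBFormatError(f"frame {i} has {len(m)} atoms, expected {n}")
    topology = Structure(models[0])
    frames = np.array([[a.xyz for a in m] for m in models], dtype=float)
    return Trajectory(topology, frames)


def _read_frames_xyz(path: str | Path) -> Trajectory:
    tokens_per_line: list[list[str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                tokens_per_line.append(line.split())
    if not tokens_per_line:
        raise PDBFormatError(f"empty frames-xyz file: {path}")
    header = tokens_per_line[0]
    if len(header) != 2:
        raise PDBFormatError("frames-xyz header must be 'natoms nframes'")
    natoms, nframes = int(header[0]), int(header[1])
    body = tokens_per_line[1:]
    if len(body) != natoms * nframes:
        raise PDBFormatError(
            f"frames-xyz body has {len(body)} atom lines, expected {natoms}x{nframes}"
        )
    names = [t[0] for t in body[:natoms]]
    frames = np.empty((nframes, natoms, 3), dtype=float)
    for f in range(nframes):
        for i in range(natoms):
            t = body[f * natoms + i]
            if len(t) != 4:
                raise PDBFormatError(f"bad frames-xyz atom line: {' '.join(t)}")
            if t[0] != names[i]:
                raise PDBFormatError(
                    f"frame {f}: atom {i} name {t[0]!r} differs from frame 0 name {names[i]!r}"
                )
            frames[f, i] = [float(v) for v in t[1:4]]
    # frames-xyz carries no residue information: atoms become one UNK residue
    # each, with water-like names (OW/HW) mapped to HOH when so prefixed.
    atoms = []
    for i, name in enumerate(names):
        resname = "HOH" if name.upper().startswith(("OW", "HW")) else "UNK"
        atoms.append(
            AtomRecord(i + 1, name, _guess_element(name), resname, i + 1, "A", tuple(frames[0, i]))
        )
    return Trajectory(Structure(atoms), frames)


def write_frames_xyz(traj: Trajectory, path: str | Path, header_comments: Iterable[str] = ()) -> None:
    """Write a trajectory in the frames-xyz dialect."""
    with open(path, "w") as fh:
        for text in header_comments:
            fh.write(f"# {text}\n")
        fh.write(f"{len(traj.topology)} {traj.n_frames}\n")
        names = [a.name for a in traj.topology.atoms]
        for f in range(traj.n_frames):
            fh.write(f"# frame {f}\n")
            for name, (x, y, z) in zip(names, traj.frames[f]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-MODEL PDB."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL {f + 1:>8d}\n")
            _write_model(fh, traj.topology.atoms, traj.frames[f])
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selection mini-language
#
# Grammar:  expr   := term ('or' term)*
#           term   := factor ('and' factor)*
#           factor := '(' expr ')' | 'not' factor | clause
#           clause := keyword value+       (keyword in chain/resid/resname/
#                                           name/element; resid values may be
#                                           ranges 'a:b', inclusive)

_KEYWORDS = ("chain", "resid", "resname", "name", "element")
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _SelParser:
    def __init__(self, expression: str):
        self.tokens = _TOKEN_RE.findall(expression)
        self.pos = 0
        self.expression = expression

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selection: {self.expression!r}")
        self.pos += 1
        return tok

    def parse(self, structure: Structure) -> np.ndarray:
        mask = self.expr(structure)
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens from {self.peek()!r} in {self.expression!r}")
        return mask

    def expr(self, s: Structure) -> np.ndarray:
        mask = self.term(s)
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.term(s)
        return mask

    def term(self, s: Structure) -> np.ndarray:
        mask = self.factor(s)
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.factor(s)
        return mask

    def factor(self, s: Structure) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selection: {self.expression!r}")
        if tok == "(":
            self.next()
            mask = self.expr(s)
            if self.next() != ")":
                raise SelectionError(f"unbalanced parentheses in {self.expression!r}")
            return mask
        if tok.lower() == "not":
            self.next()
            return ~self.factor(s)
        return self.clause(s)

    def clause(self, s: Structure) -> np.ndarray:
        kw = self.next().lower()
        if kw not in _KEYWORDS:
            raise SelectionError(f"unknown selection keyword {kw!r} in {self.expression!r}")
        values: list[str] = []
        while True:
            tok = self.peek()
            if tok is None or tok in ("(", ")") or tok.lower() in ("and", "or", "not") or tok.lower() in _KEYWORDS:
                break
            values.append(self.next())
        if not values:
            raise SelectionError(f"keyword {kw!r} requires at least one value in {self.expression!r}")
        mask = np.zeros(len(s), dtype=bool)
        if kw == "resid":
            wanted: set[int] = set()
            for v in values:
                if ":" in v:
                    lo, hi = v.split(":", 1)
                    try:
                        wanted.update(range(int(lo), int(hi) + 1))
                    except ValueError as exc:
                        raise SelectionError(f"bad resid range {v!r}") from exc
                else:
                    try:
                        wanted.add(int(v))
                    except ValueError as exc:
                        raise SelectionError(f"bad resid value {v!r}") from exc
            for i, a in enumerate(s.atoms):
                mask[i] = a.resid in wanted
        else:
            upper = {v.upper() for v in values}
            attr = {"chain": "chain", "resname": "resname", "name": "name", "element": "element"}[kw]
            for i, a in enumerate(s.atoms):
                mask[i] = getattr(a, attr).upper() in upper
        return mask


def resolve_selection(structure: Structure, expression: str) -> Selection:
    """Resolve a selection expression against a structure.

    Deterministic and order-preserving (indices ascend in atom order). An
    empty result is allowed; a syntax error raises :class:`SelectionError`.
    """
    mask = _SelParser(expression).parse(structure)
    return Selection(expression, tuple(int(i) for i in np.flatnonzero(mask)))


# ---------------------------------------------------------------------------
# Measurements


def atom_distance(
    structure: Structure,
    sel_a: Selection | str,
    sel_b: Selection | str,
    mode: str = "min",
) -> float:
    """Distance in Å between two selections.

    ``mode='min'`` gives the minimum pairwise distance; ``mode='centroid'``
    the distance between unweighted centroids. Empty selections raise
    ``ValueError``.
    """
    if isinstance(sel_a, str):
        sel_a = resolve_selection(structure, sel_a)
    if isinstance(sel_b, str):
        sel_b = resolve_selection(structure, sel_b)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("atom_distance requires non-empty selections")
    coords = structure.coords
    a = coords[list(sel_a.indices)]
    b = coords[list(sel_b.indices)]
    if mode == "min":
        diff = a[:, None, :] - b[None, :, :]
        return float(np.sqrt((diff**2).sum(axis=2)).min())
    if mode == "centroid":
        return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    raise ValueError(f"unknown mode {mode!r}; use 'min' or 'centroid'")
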