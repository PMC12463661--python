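"""Atomic configurations, extended-XYZ reading/writing, and neighbor lists.

The on-disk format is a pinned extended-XYZ dialect: a ``Lattice`` key with
nine row-major cell components, a ``Properties`` string of the form
``species:S:1:pos:R:3[:forces:R:3]``, an optional scalar ``energy`` (eV) and a
``pbc="T/F T/F T/F"`` flag triple.  All coordinates are Cartesian Angstrom;
forces are eV/Angstrom.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomicConfiguration",
    "NeighborList",
    "ExtXYZError",
    "read_extxyz",
    "write_extxyz",
    "build_neighbor_list",
]


class ExtXYZError(ValueError):
    """Raised for malformed extended-XYZ content."""


@dataclass
class AtomicConfiguration:
    """A single atomic structure, optionally labeled with energy and forces.

    Parameters
    ----------
    positions : (N, 3) float array, Angstrom.
    species : sequence of N chemical symbols.
    cell : optional (3, 3) float array of row lattice vectors, Angstrom.
    pbc : three booleans; any True requires a non-singular cell.
    energy : optional total energy label, eV.
    forces : optional (N, 3) force labels, eV/Angstrom.
    """

    positions: np.ndarray
    species: tuple[str, ...]
    cell: np.ndarray | None = None
    pbc: tuple[bool, bool, bool] = (False, False, False)
    energy: float | None = None
    forces: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = tuple(str(s) for s in self.species)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be (N, 3), got {self.positions.shape}")
        n = self.positions.shape[0]
        if n < 1:
            raise ValueError("a configuration needs at least one atom")
        if len(self.species) != n:
            raise ValueError(f"{len(self.species)} species for {n} atoms")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float)
            if self.cell.shape != (3, 3):
                raise ValueError("cell must be 3x3")
        self.pbc = tuple(bool(p) for p in self.pbc)
        if len(self.pbc) != 3:
            raise ValueError("pbc needs exactly three flags")
        if any(self.pbc):
            if self.cell is None:
                raise ValueError("periodic configuration without a cell")
            if abs(np.linalg.det(self.cell)) <= 0.0:
                raise ValueError("periodic configuration with singular cell")
        if self.energy is not None:
            self.energy = float(self.energy)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != (n, 3):
                raise ValueError(f"forces must be ({n}, 3), got {self.forces.shape}")
            if not np.all(np.isfinite(self.forces)):
                raise ValueError("non-finite forces")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "AtomicConfiguration":
        return AtomicConfiguration(
            positions=self.positions.copy(),
            species=self.species,
            cell=None if self.cell is None else self.cell.copy(),
            pbc=self.pbc,
            energy=self.energy,
            forces=None if self.forces is None else self.forces.copy(),
        )


@dataclass
class NeighborList:
    """Directed neighbor pairs within a distance cutoff.

    ``displacements[p]`` points from atom ``centers[p]`` to the (possibly
    periodic image of) atom ``neighbors[p]``; ``distances[p]`` is its norm.
    Pairs are double counted: (i, j) and (j, i) are both present.
    """

    centers: np.ndarray
    neighbors: np.ndarray
    displacements: np.ndarray
    distances: np.ndarray
    cutoff: float

    @property
    def n_pairs(self) -> int:
        return self.centers.shape[0]


# ---------------------------------------------------------------------------
# extended-XYZ I/O
# ---------------------------------------------------------------------------

_KEYVAL_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(comment: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KEYVAL_RE.finditer(comment)}


def _parse_properties(props: str, frame: int) -> list[tuple[str, str, int]]:
    toks = props.split(":")
    if len(toks) % 3 != 0:
        raise ExtXYZError(f"frame {frame}: malformed Properties string {props!r}")
    out = []
    for i in range(0, len(toks), 3):
        name, kind, ncol = toks[i], toks[i + 1], toks[i + 2]
        try:
            out.append((name, kind, int(ncol)))
        except ValueError as exc:
            raise ExtXYZError(f"frame {frame}: bad column count in {props!r}") from exc
    return out


def read_extxyz(path: str | Path) -> list[AtomicConfiguration]:
    """Read every frame of an extended-XYZ file.

    Raises :class:`ExtXYZError` naming the frame index on any structural
    problem (atom-count mismatch, missing ``Properties``, non-numeric fields).
    """
    lines = Path(path).read_text().splitlines()
    configs: list[AtomicConfiguration] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ExtXYZError(f"frame {frame}: bad atom-count line {lines[i]!r}") from exc
        if i + 1 >= len(lines):
            raise ExtXYZError(f"frame {frame}: missing comment line")
        keyvals = _parse_comment(lines[i + 1])
        if "Properties" not in keyvals:
            raise ExtXYZError(f"frame {frame}: missing Properties key")
        columns = _parse_properties(keyvals["Properties"], frame)
        atom_lines = lines[i + 2 : i + 2 + n]
        if len(atom_lines) < n or any(not ln.strip() for ln in atom_lines):
            raise ExtXYZError(f"frame {frame}: expected {n} atom lines")

        ncols = sum(c for _, _, c in columns)
        species: list[str] = []
        pos = np.empty((n, 3))
        forces = None
        for a, ln in enumerate(atom_lines):
            fields = ln.split()
            if len(fields) != ncols:
                raise ExtXYZError(
                    f"frame {frame}: atom line {a} has {len(fields)} fields, expected {ncols}")
            off = 0
            for name, kind, c in columns:
                chunk = fields[off : off + c]
                off += c
                if name == "species":
                    species.append(chunk[0])
                elif name in ("pos", "forces"):
                    try:
                        vals = [float(x) for x in chunk]
                    except ValueError as exc:
                        raise ExtXYZError(
                            f"frame {frame}: non-numeric {name} entry on atom {a}") from exc
                    if name == "pos":
                        pos[a] = vals
                    else:
                        if forces is None:
                            forces = np.empty((n, 3))
                        forces[a] = vals
        if len(species) != n:
            raise ExtXYZError(f"frame {frame}: Properties lacks a species column")

        cell = None
        if "Lattice" in keyvals:
            try:
                cell = np.array([float(x) for x in keyvals["Lattice"].split()]).reshape(3, 3)
            except ValueError as exc:
                raise ExtXYZError(f"frame {frame}: bad Lattice") from exc
        pbc = (False, False, False)
        if "pbc" in keyvals:
            flags = keyvals["pbc"].split()
            pbc = tuple(f.upper() in ("T", "TRUE") for f in flags)
        energy = None
        if "energy" in keyvals:
            try:
                energy = float(keyvals["energy"])
            except ValueError as exc:
                raise ExtXYZError(f"frame {frame}: bad energy value") from exc
        configs.append(AtomicConfiguration(pos, species, cell=cell, pbc=pbc,
                                           energy=energy, forces=forces))
        i += 2 + n
        frame += 1
    return configs


def _fmt(x: float) -> str:
    # shortest representation that round-trips the float64 exactly
    return repr(float(x))


def write_extxyz(configs: Iterable[AtomicConfiguration], path: str | Path) -> None:
    """Write configurations in the dialect accepted by :func:`read_extxyz`."""
    out: list[str] = []
    for cfg in configs:
        has_forces = cfg.forces is not None
        props = "species:S:1:pos:R:3" + (":forces:R:3" if has_forces else "")
        keys = []
        if cfg.cell is not None:
            keys.append('Lattice="' + " ".join(_fmt(x) for x in cfg.cell.ravel()) + '"')
        keys.append(f"Properties={props}")
        if cfg.energy is not None:
            keys.append(f"energy={_fmt(cfg.energy)}")
        keys.append('pbc="' + " ".join("T" if p else "F" for p in cfg.pbc) + '"')
        out.append(str(cfg.n_atoms))
        out.append(" ".join(keys))
        for a in range(cfg.n_atoms):
            fields = [cfg.species[a]] + [_fmt(x) for x in cfg.positions[a]]
            if has_forces:
                fields += [_fmt(x) for x in cfg.forces[a]]
            out.append(" ".join(fields))
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# neighbor lists
# ---------------------------------------------------------------------------

def build_neighbor_list(config: AtomicConfiguration, cutoff: float) -> NeighborList:
    """All directed pairs with 0 < distance <= cutoff, including periodic images.

    Periodic directions are handled by explicit image enumeration over the
    minimal shell count whose plane spacing covers the cutoff, which is correct
    for triclinic cells and for cutoffs larger than half the box.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = config.positions
    n = config.n_atoms

    if any(config.pbc):
        cell = config.cell
        if abs(np.linalg.det(cell)) <= 0.0:
            raise ValueError("singular cell with periodic boundary conditions")
        inv = np.linalg.inv(cell)
        # plane spacing along axis i is 1/||column i of cell^-1||
        reps = [
            int(math.ceil(cutoff * np.linalg.norm(inv[:, i]))) if config.pbc[i] else 0
            for i in range(3)
        ]
        shifts = np.array([
            (sx, sy, sz)
            for sx in range(-reps[0], reps[0] + 1)
            for sy in range(-reps[1], reps[1] + 1)
            for sz in range(-reps[2], reps[2] + 1)
        ], dtype=float)
        offsets = shifts @ cell  # (S, 3)
    else:
        offsets = np.zeros((1, 3))

    # displacement from atom i to image of atom j: pos[j] + offset - pos[i]
    disp = pos[None, :, None, :] + offsets[None, None, :, :] - pos[:, None, None, :]
    dist = np.linalg.norm(disp, axis=-1)  # (N, N, S)
    mask = (dist > 0.0) & (dist <= cutoff)
    ii, jj, ss = np.nonzero(mask)
    return NeighborList(
        centers=ii.astype(np.intp),
        neighbors=jj.astype(np.intp),
        displacements=disp[ii, jj, ss],
        distances=dist[ii, jj, ss],
        cutoff=float(cutoff),
    )
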