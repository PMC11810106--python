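"""Structures, trajectories, text time series and atom selections.

This module owns the in-memory containers every analysis stage consumes
(:class:`Structure`, :class:`Trajectory`, :class:`AtomGroup`) and the plain
text formats they are exchanged in: PDB for coordinates (single- and
multi-model), XVG-dialect whitespace tables for time series.  Coordinates are
converted to nm at the parsing boundary; PDB files are read and written
through biotite.

Binary trajectory formats (XTC/DCD) are deliberately not a hard dependency;
:func:`trajectory_from_arrays` is the adapter entry point for callers that
read them with mdtraj or MDAnalysis themselves.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .units import ANGSTROM_PER_NM, NM_PER_ANGSTROM

__all__ = [
    "AtomMeta",
    "Structure",
    "Trajectory",
    "AtomGroup",
    "GroupRole",
    "ParseError",
    "SelectionError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "trajectory_from_arrays",
    "read_timeseries",
    "write_timeseries",
    "select",
]


class ParseError(ValueError):
    """A file could not be parsed; carries a line number when known."""


class SelectionError(ValueError):
    """A selection expression is invalid or matches nothing."""


class GroupRole(str, enum.Enum):
    ARG_GUANIDINIUM = "ARG_GUANIDINIUM"
    PAM_NB = "PAM_NB"
    PAM_BB = "PAM_BB"
    NONPAM = "NONPAM"
    DOMAIN = "DOMAIN"
    OTHER = "OTHER"


@dataclass(frozen=True)
class AtomMeta:
    """Per-atom metadata; ``index`` is 0-based and contiguous."""

    index: int
    name: str
    residue_number: int
    residue_name: str
    chain: str
    mass: float
    charge: float | None = None

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.index} ({self.name}): mass must be > 0")


@dataclass
class Structure:
    """A set of atoms with one coordinate triple each (nm)."""

    atoms: list[AtomMeta]
    coords: np.ndarray  # (A, 3) nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise ValueError("atom indices must be contiguous from 0")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology; times in ps with uniform step."""

    structure: Structure
    frames: np.ndarray  # (F, A, 3) nm
    times: np.ndarray  # (F,) ps

    _DT_RTOL = 1e-6

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, A, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != self.structure.n_atoms:
            raise ValueError("frame atom count does not match topology")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times length does not match frame count")
        if self.n_frames > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=self._DT_RTOL, atol=1e-9):
                raise ValueError("time step must be uniform")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def dt(self) -> float:
        """Time step in ps (0.0 for a single-frame trajectory)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])


@dataclass
class AtomGroup:
    """A named, validated set of atom indices on a bound structure."""

    label: str
    indices: np.ndarray
    role: GroupRole = GroupRole.OTHER
    structure: Structure | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if idx.size == 0:
            raise SelectionError(f"atom group {self.label!r} is empty")
        if self.structure is not None:
            if idx.min() < 0 or idx.max() >= self.structure.n_atoms:
                raise SelectionError(
                    f"atom group {self.label!r} has indices outside the structure"
                )
        self.indices = idx

    def __len__(self) -> int:
        return self.indices.size

    def masses(self) -> np.ndarray:
        if self.structure is None:
            raise ValueError("group is not bound to a structure")
        return self.structure.masses[self.indices]


# --------------------------------------------------------------------------
# PDB reading / writing (biotite-backed)
# --------------------------------------------------------------------------

_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "NI", "CO", "SE", "CD",
    "HG", "MO", "LI", "AL", "SI",
}


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name.

    Biomolecular atom names (CA, CB, N7, OP1, HH11...) start with the
    element symbol; only a short list of genuine two-letter elements (ion
    names like CL, MG) is treated as such.
    """
    stripped = name.strip().lstrip("0123456789'\"*")
    if not stripped:
        return "C"
    if stripped.upper() in _TWO_LETTER_ELEMENTS:
        return stripped.capitalize()
    first = stripped[0].upper()
    return first if first.isalpha() else "C"


def _masses_for(elements: Iterable[str], names: Iterable[str]) -> np.ndarray:
    import biotite.structure.info as info

    cache: dict[str, float] = {}
    out = []
    for el, name in zip(elements, names):
        key = el.strip().capitalize() or _element_from_name(name)
        if key not in cache:
            try:
                m = info.mass(key)
            except KeyError:
                m = None
            if m is None or m <= 0:
                try:
                    m = info.mass(_element_from_name(name))
                except KeyError:
                    m = None
            cache[key] = float(m) if m else 12.011
        out.append(cache[key])
    return np.array(out, dtype=float)


def _locate_bad_atom_line(path: Path) -> int | None:
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except (ValueError, IndexError):
                    return ln
    return None


def _atom_array_to_structure(arr) -> Structure:
    elements = getattr(arr, "element", [""] * arr.array_length())
    masses = _masses_for(elements, arr.atom_name)
    charges = getattr(arr, "charge", None)
    atoms = [
        AtomMeta(
            index=i,
            name=str(arr.atom_name[i]),
            residue_number=int(arr.res_id[i]),
            residue_name=str(arr.res_name[i]),
            chain=str(arr.chain_id[i]),
            mass=masses[i],
            charge=float(charges[i]) if charges is not None else None,
        )
        for i in range(arr.array_length())
    ]
    if hasattr(arr, "stack_depth"):
        coords = np.asarray(arr.coord[0]) * NM_PER_ANGSTROM
    else:
        coords = np.asarray(arr.coord) * NM_PER_ANGSTROM
    return Structure(atoms=atoms, coords=coords)


def read_structure(path: str | Path, dialect: str = "pdb", model: int = 1) -> Structure:
    """Read one model of a PDB file into a :class:`Structure` (nm).

    Alternate locations are resolved to the highest-occupancy variant;
    insertion codes and author residue numbering are kept verbatim.
    """
    path = Path(path)
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=model, altloc="occupancy")
    except Exception as exc:  # biotite raises various error types
        ln = _locate_bad_atom_line(path)
        if ln is not None:
            raise ParseError(f"{path}: malformed ATOM/HETATM record at line {ln}") from exc
        raise ParseError(f"{path}: {exc}") from exc
    if arr.array_length() == 0:
        raise ParseError(f"{path}: model {model} contains no atoms")
    return _atom_array_to_structure(arr)


def read_trajectory(path: str | Path, dt: float = 1.0, t0: float = 0.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory; frame times are ``t0 + i*dt`` ps."""
    path = Path(path)
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(altloc="occupancy")
    except Exception as exc:
        ln = _locate_bad_atom_line(path)
        if ln is not None:
            raise ParseError(f"{path}: malformed ATOM/HETATM record at line {ln}") from exc
        raise ParseError(f"{path}: {exc}") from exc
    if stack.array_length() == 0 or stack.stack_depth() == 0:
        raise ParseError(f"{path}: no atoms/models found")
    structure = _atom_array_to_structure(stack[0])
    frames = np.asarray(stack.coord) * NM_PER_ANGSTROM
    times = t0 + dt * np.arange(frames.shape[0])
    return Trajectory(structure=structure, frames=frames, times=times)


def _structure_to_atom_array(structure: Structure, coords_nm: np.ndarray):
    import biotite.structure as struc

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords_nm) * ANGSTROM_PER_NM
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.res_id = np.array([a.residue_number for a in structure.atoms])
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.chain_id = np.array([a.chain for a in structure.atoms])
    arr.element = np.array([_element_from_name(a.name) for a in structure.atoms])
    return arr


def write_structure(structure: Structure, path: str | Path) -> None:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_structure_to_atom_array(structure, structure.coords))
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (times are not stored)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arrays = [
        _structure_to_atom_array(traj.structure, traj.frames[i])
        for i in range(traj.n_frames)
    ]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def trajectory_from_arrays(
    structure: Structure, frames: np.ndarray, dt: float, t0: float = 0.0
) -> Trajectory:
    """Adapter entry point for externally read (e.g. binary) trajectories."""
    frames = np.asarray(frames, dtype=float)
    times = t0 + dt * np.arange(frames.shape[0])
    return Trajectory(structure=structure, frames=frames, times=times)


# --------------------------------------------------------------------------
# XVG-dialect time series
# --------------------------------------------------------------------------


def read_timeseries(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a whitespace-delimited (time, value...) table.

    Lines starting with '#' or '@' are ignored (XVG dialect).  Returns
    ``(times, values)``; ``values`` is 1-D for two-column files, else 2-D
    with one column per value series.
    """
    path = Path(path)
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            fields = s.split()
            try:
                row = [float(x) for x in fields]
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric field at line {ln}") from exc
            if width is None:
                width = len(row)
                if width < 2:
                    raise ParseError(f"{path}: need at least two columns (line {ln})")
            elif len(row) != width:
                raise ParseError(f"{path}: ragged row at line {ln}")
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    data = np.array(rows, dtype=float)
    times = data[:, 0]
    if np.any(np.diff(times) <= 0):
        raise ParseError(f"{path}: times are not strictly increasing")
    values = data[:, 1] if data.shape[1] == 2 else data[:, 1:]
    return times, values


def write_timeseries(
    path: str | Path,
    times: np.ndarray,
    values: np.ndarray,
    header: str | None = None,
) -> None:
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    cols = values.reshape(len(times), -1)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for t, row in zip(times, cols):
            fh.write(f"{t:.10g} " + " ".join(f"{v:.10g}" for v in row) + "\n")


# --------------------------------------------------------------------------
# Selection expressions
# --------------------------------------------------------------------------
#
# Grammar (case-insensitive keywords):
#   expr     := or_term
#   or_term  := and_term ('or' and_term)*
#   and_term := unary ('and' unary)*
#   unary    := 'not' unary | '(' expr ')' | primary
#   primary  := 'resid' range+ | 'name' WORD+ | 'chain' WORD+
#             | 'resname' WORD+ | 'all'
#   range    := INT ['to' INT]

_KEYWORDS = {"and", "or", "not", "resid", "name", "chain", "resname", "all", "to", "(", ")"}


def _tokenize(expr: str) -> list[str]:
    out = []
    for tok in expr.replace("(", " ( ").replace(")", " ) ").split():
        out.append(tok)
    return out


class _SelParser:
    def __init__(self, tokens: list[str], structure: Structure):
        self.toks = tokens
        self.pos = 0
        self.s = structure

    def peek(self) -> str | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_term()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def or_term(self) -> np.ndarray:
        mask = self.and_term()
        while (p := self.peek()) is not None and p.lower() == "or":
            self.take()
            mask = mask | self.and_term()
        return mask

    def and_term(self) -> np.ndarray:
        mask = self.unary()
        while (p := self.peek()) is not None and p.lower() == "and":
            self.take()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        p = self.peek()
        if p is None:
            raise SelectionError("unexpected end of selection expression")
        if p.lower() == "not":
            self.take()
            return ~self.unary()
        if p == "(":
            self.take()
            mask = self.or_term()
            if self.take() != ")":
                raise SelectionError("missing closing parenthesis")
            return mask
        return self.primary()

    def _values(self) -> list[str]:
        vals = []
        while (p := self.peek()) is not None and p.lower() not in _KEYWORDS:
            vals.append(self.take())
        if not vals:
            raise SelectionError("keyword expects at least one value")
        return vals

    def primary(self) -> np.ndarray:
        kw = self.take().lower()
        atoms = self.s.atoms
        if kw == "all":
            return np.ones(len(atoms), dtype=bool)
        if kw == "resid":
            wanted: set[int] = set()
            items = self._values_with_ranges()
            for lo, hi in items:
                wanted.update(range(lo, hi + 1))
            return np.array([a.residue_number in wanted for a in atoms])
        if kw == "name":
            names = {v.upper() for v in self._values()}
            return np.array([a.name.upper() in names for a in atoms])
        if kw == "resname":
            names = {v.upper() for v in self._values()}
            return np.array([a.residue_name.upper() in names for a in atoms])
        if kw == "chain":
            chains = set(self._values())
            return np.array([a.chain in chains for a in atoms])
        raise SelectionError(f"unknown selection keyword {kw!r}")

    def _values_with_ranges(self) -> list[tuple[int, int]]:
        items: list[tuple[int, int]] = []
        while (p := self.peek()) is not None and p.lower() not in _KEYWORDS:
            try:
                lo = int(self.take())
            except ValueError as exc:
                raise SelectionError("resid expects integers") from exc
            hi = lo
            if (q := self.peek()) is not None and q.lower() == "to":
                self.take()
                try:
                    hi = int(self.take())
                except ValueError as exc:
                    raise SelectionError("resid range needs an integer bound") from exc
            items.append((lo, hi))
        if not items:
            raise SelectionError("resid expects at least one value")
        return items


def select(
    structure: Structure,
    expr: str,
    label: str | None = None,
    role: GroupRole = GroupRole.OTHER,
) -> AtomGroup:
    """Resolve a selection expression to an :class:`AtomGroup`.

    Supports residue ranges (``resid 3``, ``resid 1 to 10``), atom-name and
    residue-name lists, chain filters, ``and``/``or``/``not`` and parentheses.
    Raises :class:`SelectionError` if nothing matches.
    """
    mask = _SelParser(_tokenize(expr), structure).parse()
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise SelectionError(f"selection {expr!r} matches no atoms")
    return AtomGroup(label=label or expr, indices=idx, role=role, structure=structure)
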