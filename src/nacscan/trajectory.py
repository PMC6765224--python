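"""Data model and I/O for multi-frame atomic trajectories.

The in-memory model is deliberately small: an ordered list of frames, each an
ordered list of :class:`AtomRecord`, with a rigid topology across frames
(identical atom count and identical ``(residue_seq, atom_name)`` ordering).
Coordinates are in Angstrom throughout.

Supported on-disk dialects are multi-model PDB (``MODEL``/``ENDMDL`` blocks;
a file without ``MODEL`` records is read as a single frame) and concatenated
GRO frames.  Both readers report malformed lines by line number and refuse
trajectories whose atom count changes between frames.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "Selection",
    "ParseError",
    "TopologyError",
    "read_multimodel_pdb",
    "read_gro_sequence",
    "write_multimodel_pdb",
    "select_atoms",
    "infer_element",
]


class ParseError(ValueError):
    """A line of a trajectory file could not be interpreted."""


class TopologyError(ValueError):
    """Frames of one trajectory disagree on atom count or atom identity order."""


# Two-letter element symbols that occur in biomolecular PDB files and could be
# confused with a one-letter element followed by a greek-position letter.
_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "SE", "NI", "CD",
}


def infer_element(atom_name: str) -> str:
    """Infer the chemical element from a PDB atom name.

    Standard PDB semantics: digits may precede the element letter (``1HB``),
    and names are left-padded so that one-letter elements start in the second
    column of the four-character field.  For the plain four-character names we
    handle here the robust heuristic is: strip leading digits, take the first
    letter, upper-cased.  Two-letter ions/halides are only recognised when the
    full stripped name equals the symbol (``CL``, ``NA``...), so ``CA`` the
    alpha-carbon stays carbon in amino-acid context (callers selecting metal
    ions should set the element explicitly).
    """
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if stripped.upper() in _TWO_LETTER_ELEMENTS and len(atom_name.strip()) <= 2:
        return stripped.upper().capitalize()
    return stripped[0].upper()


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame: identity plus a position in Angstrom."""

    atom_serial: int
    atom_name: str
    residue_name: str
    residue_seq: int
    chain_id: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if not self.element:
            object.__setattr__(self, "element", infer_element(self.atom_name))

    @property
    def identity(self) -> tuple[int, str]:
        return (self.residue_seq, self.atom_name)


@dataclass
class Frame:
    """A single trajectory frame: ordered atoms and an optional orthorhombic box."""

    index: int
    atoms: list[AtomRecord]
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("frame index must be >= 0")
        if not self.atoms:
            raise ValueError("frame must contain at least one atom")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or not np.all(self.box > 0):
                raise ValueError("box must be three positive lengths")

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        return np.array([a.position for a in self.atoms])

    def identity_order(self) -> tuple[tuple[int, str], ...]:
        return tuple(a.identity for a in self.atoms)


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one rigid topology."""

    frames: list[Frame]
    source: str = "<memory>"
    stride: int = 1

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        ref = self.frames[0].identity_order()
        for fr in self.frames[1:]:
            if len(fr.atoms) != len(ref):
                raise TopologyError(
                    f"frame {fr.index}: atom count {len(fr.atoms)} differs from "
                    f"frame {self.frames[0].index} ({len(ref)})"
                )
            if fr.identity_order() != ref:
                raise TopologyError(
                    f"frame {fr.index}: (residue_seq, atom_name) ordering differs "
                    "from first frame"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0].atoms)


@dataclass(frozen=True)
class Selection:
    """Predicate over atom identity fields.

    ``None`` fields match anything; set fields restrict to membership.  A
    selection referencing names absent from the trajectory resolves to the
    empty set rather than erroring.
    """

    residue_names: frozenset[str] | None = None
    residue_seqs: frozenset[int] | None = None
    atom_names: frozenset[str] | None = None
    chain_ids: frozenset[str] | None = None

    @classmethod
    def of(
        cls,
        residue_names: Iterable[str] | str | None = None,
        residue_seqs: Iterable[int] | int | None = None,
        atom_names: Iterable[str] | str | None = None,
        chain_ids: Iterable[str] | str | None = None,
    ) -> "Selection":
        def norm(v, scalar_types):
            if v is None:
                return None
            if isinstance(v, scalar_types):
                return frozenset([v])
            return frozenset(v)

        return cls(
            residue_names=norm(residue_names, str),
            residue_seqs=norm(residue_seqs, int),
            atom_names=norm(atom_names, str),
            chain_ids=norm(chain_ids, str),
        )

    def matches(self, atom: AtomRecord) -> bool:
        if self.residue_names is not None and atom.residue_name not in self.residue_names:
            return False
        if self.residue_seqs is not None and atom.residue_seq not in self.residue_seqs:
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.chain_ids is not None and atom.chain_id not in self.chain_ids:
            return False
        return True


def select_atoms(traj: Trajectory, sel: Selection) -> tuple[int, ...]:
    """Resolve a selection against the trajectory topology.

    The topology is rigid, so resolution uses the first frame; the returned
    index tuple is ascending and identical on repeated calls.
    """
    return tuple(i for i, atom in enumerate(traj.frames[0].atoms) if sel.matches(atom))


# ---------------------------------------------------------------------------
# multi-model PDB

_PDB_RECORD = re.compile(r"^(ATOM  |HETATM)")


def _parse_pdb_atom_line(line: str, lineno: int) -> AtomRecord:
    # Fixed PDB columns (1-based): serial 7-11, name 13-16, resName 18-20,
    # chainID 22, resSeq 23-26, x 31-38, y 39-46, z 47-54, element 77-78.
    if len(line.rstrip("\n")) < 54:
        raise ParseError(f"line {lineno}: ATOM/HETATM record shorter than coordinate columns")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip()
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed ATOM/HETATM record ({exc})") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    try:
        return AtomRecord(
            atom_serial=serial,
            atom_name=name,
            residue_name=resname,
            residue_seq=resseq,
            chain_id=chain,
            element=element,
            position=np.array([x, y, z]),
        )
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    Each ``MODEL``/``ENDMDL`` block becomes one frame, in file order.  A file
    with no ``MODEL`` records is a single-frame trajectory.  ``CRYST1``
    records, when present, set the orthorhombic box.
    """
    path = Path(path)
    frames: list[Frame] = []
    current: list[AtomRecord] | None = None
    box: np.ndarray | None = None
    saw_model = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: malformed CRYST1 record") from exc
            elif rec == "MODEL ":
                saw_model = True
                if current:
                    frames.append(Frame(index=len(frames), atoms=current, box=box))
                current = []
            elif rec == "ENDMDL":
                if current:
                    frames.append(Frame(index=len(frames), atoms=current, box=box))
                current = None
            elif _PDB_RECORD.match(line):
                atom = _parse_pdb_atom_line(line, lineno)
                if current is None:
                    if saw_model:
                        raise ParseError(
                            f"line {lineno}: ATOM record outside MODEL/ENDMDL block"
                        )
                    current = []
                current.append(atom)

    if current:
        frames.append(Frame(index=len(frames), atoms=current, box=box))
    if not frames:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    try:
        return Trajectory(frames=frames, source=str(path))
    except TopologyError as exc:
        raise TopologyError(f"{path}: {exc}") from exc


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB (coordinates to 3 decimals)."""
    path = Path(path)
    with open(path, "w") as fh:
        first = traj.frames[0]
        if first.box is not None:
            bx, by, bz = first.box
            fh.write(f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}  90.00  90.00  90.00 P 1           1\n")
        for frame in traj.frames:
            fh.write(f"MODEL     {frame.index + 1:4d}\n")
            for atom in frame.atoms:
                name = atom.atom_name
                # standard PDB name justification: 1-letter elements start in
                # column 14 unless the name is 4 characters long
                if len(name) < 4 and len(atom.element) == 1:
                    name_field = f" {name:<3s}"
                else:
                    name_field = f"{name:<4s}"
                x, y, z = atom.position
                fh.write(
                    f"ATOM  {atom.atom_serial:5d} {name_field} {atom.residue_name:<3s} "
                    f"{atom.chain_id or ' ':1s}{atom.residue_seq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                    f"{atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# concatenated GRO frames (optional dialect, same Trajectory contract)

def read_gro_sequence(path: str | Path) -> Trajectory:
    """Read concatenated fixed-atom-count GRO frames as a trajectory.

    GRO stores nanometres; positions are converted to Angstrom.  Residue and
    atom names follow GRO fixed columns; chain id is blank (GRO has none).
    """
    path = Path(path)
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title_line = i
        try:
            n_atoms = int(lines[i + 1])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"line {title_line + 2}: expected GRO atom count") from exc
        atoms: list[AtomRecord] = []
        for j in range(n_atoms):
            lineno = i + 2 + j
            if lineno >= len(lines):
                raise ParseError(f"line {lineno + 1}: truncated GRO frame")
            line = lines[lineno]
            try:
                resseq = int(line[0:5])
                resname = line[5:10].strip()
                name = line[10:15].strip()
                serial = int(line[15:20])
                x = float(line[20:28]) * 10.0
                y = float(line[28:36]) * 10.0
                z = float(line[36:44]) * 10.0
            except ValueError as exc:
                raise ParseError(f"line {lineno + 1}: malformed GRO atom line ({exc})") from exc
            atoms.append(
                AtomRecord(
                    atom_serial=serial,
                    atom_name=name,
                    residue_name=resname,
                    residue_seq=resseq,
                    chain_id="",
                    element="",
                    position=np.array([x, y, z]),
                )
            )
        box_lineno = i + 2 + n_atoms
        if box_lineno >= len(lines):
            raise ParseError(f"line {box_lineno + 1}: missing GRO box line")
        box_fields = lines[box_lineno].split()
        box = None
        if len(box_fields) >= 3:
            bx, by, bz = (float(v) * 10.0 for v in box_fields[:3])
            if bx > 0 and by > 0 and bz > 0:
                box = np.array([bx, by, bz])
        frames.append(Frame(index=len(frames), atoms=atoms, box=box))
        i = box_lineno + 1
    if not frames:
        raise ParseError(f"{path}: no GRO frames found")
    try:
        return Trajectory(frames=frames, source=str(path))
    except TopologyError as exc:
        raise TopologyError(f"{path}: {exc}") from exc
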