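"""Multi-model PDB input/output and atom selection.

Conformational ensembles are exchanged as fixed-column PDB files with one
``MODEL``/``ENDMDL`` block per frame (a single implicit model is also
accepted).  The in-memory representation is an :class:`Ensemble`: an ordered
topology of :class:`AtomRecord` plus an ``F x A x 3`` coordinate tensor in
Angstrom.  Analyses address atoms through :class:`Selection` objects resolved
by :func:`select_atoms` from conjunctive filters (chain, residue ranges,
atom names, residue names, polymer/hetero class).

Only the multi-model PDB dialect is supported; binary trajectory formats are
out of scope for desk-scale ensembles.  Insertion codes are rejected and only
the first alternate location of an atom is kept, since silently mishandling
either corrupts downstream selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import (
    AmbiguousAtomError,
    EmptySelectionError,
    FormatOverflowError,
    ParseError,
    StructureInconsistencyError,
    ValidationError,
)

POLYMER = "polymer"
HETERO = "hetero"


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology, shared by every frame."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    element: str = ""
    record_class: str = POLYMER

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValidationError(
                f"residue_number must be >= 1, got {self.residue_number} "
                f"for atom {self.atom_name}"
            )
        if self.record_class not in (POLYMER, HETERO):
            raise ValidationError(f"unknown record_class {self.record_class!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


@dataclass
class Ensemble:
    """An ordered topology plus an F x A x 3 coordinate tensor (Angstrom)."""

    topology: list[AtomRecord]
    coordinates: np.ndarray
    frame_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValidationError(
                f"coordinates must be F x A x 3, got shape {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise ValidationError("ensemble needs at least one frame")
        if self.coordinates.shape[1] != len(self.topology):
            raise ValidationError(
                f"coordinate tensor has {self.coordinates.shape[1]} atoms per "
                f"frame but topology lists {len(self.topology)}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("coordinates contain non-finite values")
        keys = [a.key for a in self.topology]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, int, str]] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate atom key in topology: {dup}")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> "Ensemble":
        """Single-frame view (copy) of frame ``i``."""
        return Ensemble(self.topology, self.coordinates[i : i + 1].copy())

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.topology:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out


@dataclass(frozen=True)
class SelectionExpression:
    """Conjunction of filters; ``None`` means the filter is inactive.

    ``hetero`` selects record class: ``True`` -> HETATM only, ``False`` ->
    ATOM only, ``None`` -> both.
    """

    chain: str | None = None
    resnum_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: frozenset[str] | None = None
    residue_names: frozenset[str] | None = None
    hetero: bool | None = None

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain is not None and atom.chain_id != self.chain:
            return False
        if self.resnum_ranges is not None and not any(
            lo <= atom.residue_number <= hi for lo, hi in self.resnum_ranges
        ):
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.residue_names is not None and atom.residue_name not in self.residue_names:
            return False
        if self.hetero is not None:
            want = HETERO if self.hetero else POLYMER
            if atom.record_class != want:
                return False
        return True


@dataclass(frozen=True)
class Selection:
    """A resolved selection: the expression plus strictly increasing indices."""

    expression: SelectionExpression
    resolved_indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.resolved_indices)

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(self.resolved_indices, dtype=int)


def select_atoms(ensemble: Ensemble, expression: SelectionExpression) -> Selection:
    """Resolve ``expression`` on the ensemble topology.

    Raises :class:`EmptySelectionError` when nothing matches; the message
    distinguishes an unknown chain from an otherwise empty match.
    """
    idx = tuple(
        i for i, atom in enumerate(ensemble.topology) if expression.matches(atom)
    )
    if not idx:
        if expression.chain is not None and expression.chain not in ensemble.chains():
            raise EmptySelectionError(
                f"chain {expression.chain!r} not present; topology has chains "
                f"{ensemble.chains()}"
            )
        raise EmptySelectionError(f"selection matched no atoms: {expression}")
    return Selection(expression=expression, resolved_indices=idx)


def select_single_atom(ensemble: Ensemble, expression: SelectionExpression) -> Selection:
    """Like :func:`select_atoms` but requires exactly one match."""
    sel = select_atoms(ensemble, expression)
    if len(sel) != 1:
        matches = [ensemble.topology[i] for i in sel.resolved_indices]
        names = ", ".join(
            f"{a.chain_id}/{a.residue_name}{a.residue_number}/{a.atom_name}"
            for a in matches
        )
        raise AmbiguousAtomError(
            f"selection must resolve to exactly one atom, matched {len(sel)}: {names}"
        )
    return sel


def parse_selection(text: str) -> SelectionExpression:
    """Parse the CLI mini-language, e.g. ``"resname FAD, atom N5, hetero"``.

    Comma-separated clauses: ``chain X``, ``resname NAME[+NAME...]``,
    ``atom NAME[+NAME...]``, ``resnum LO-HI[+LO-HI...]``, ``polymer``,
    ``hetero``.
    """
    chain = None
    resnum_ranges = None
    atom_names = None
    residue_names = None
    hetero = None
    for clause in (c.strip() for c in text.split(",") if c.strip()):
        parts = clause.split(None, 1)
        key = parts[0].lower()
        if key == "hetero" and len(parts) == 1:
            hetero = True
        elif key == "polymer" and len(parts) == 1:
            hetero = False
        elif key == "chain" and len(parts) == 2:
            chain = parts[1]
        elif key in ("atom", "name") and len(parts) == 2:
            atom_names = frozenset(parts[1].split("+"))
        elif key == "resname" and len(parts) == 2:
            residue_names = frozenset(parts[1].split("+"))
        elif key == "resnum" and len(parts) == 2:
            resnum_ranges = parse_residue_ranges(parts[1])
        else:
            raise ValidationError(f"cannot parse selection clause {clause!r}")
    return SelectionExpression(
        chain=chain,
        resnum_ranges=resnum_ranges,
        atom_names=atom_names,
        residue_names=residue_names,
        hetero=hetero,
    )


def parse_residue_ranges(text: str) -> tuple[tuple[int, int], ...]:
    """Parse ``"153-157+177-188"`` (also accepts commas) into inclusive ranges."""
    out: list[tuple[int, int]] = []
    for token in text.replace(",", "+").split("+"):
        token = token.strip()
        if not token:
            continue
        if "-" in token:
            lo_s, hi_s = token.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(token)
        if lo > hi:
            raise ValidationError(f"range {token!r} has start > end")
        out.append((lo, hi))
    if not out:
        raise ValidationError(f"no residue ranges in {text!r}")
    return tuple(out)


# --- PDB fixed-column reading/writing -------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray, str]:
    record_class = HETERO if line.startswith("HETATM") else POLYMER
    line = line.rstrip("\n").ljust(80)
    icode = line[26]
    if icode not in (" ", ""):
        raise ParseError(f"line {lineno}: insertion code {icode!r} not supported")
    altloc = line[16]
    try:
        serial = int(line[6:11])
        resnum = int(line[22:26])
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])], dtype=float
        )
    except ValueError as exc:
        raise ParseError(f"line {lineno}: unparseable numeric field ({exc})") from exc
    atom = AtomRecord(
        serial=serial,
        atom_name=line[12:16].strip(),
        residue_name=line[17:20].strip(),
        chain_id=line[21].strip() or " ",
        residue_number=resnum,
        element=line[76:78].strip(),
        record_class=record_class,
    )
    return atom, xyz, altloc.strip()


def read_multimodel_pdb(path: str | Path) -> Ensemble:
    """Read a MODEL/ENDMDL multi-model PDB file into an :class:`Ensemble`.

    The topology is taken from the first model; later models must list the
    same atoms in the same order or a
    :class:`StructureInconsistencyError` naming the offending model is raised.
    Files without MODEL records are read as a single implicit model.
    """
    path = Path(path)
    frames: list[list[np.ndarray]] = []
    per_frame_atoms: list[list[AtomRecord]] = []
    model_numbers: list[str] = []
    current_atoms: list[AtomRecord] | None = None
    current_xyz: list[np.ndarray] | None = None
    current_keys: set[tuple[str, int, str]] = set()
    saw_model = False

    def open_model(label: str) -> None:
        nonlocal current_atoms, current_xyz, current_keys
        current_atoms, current_xyz, current_keys = [], [], set()
        model_numbers.append(label)

    def close_model() -> None:
        nonlocal current_atoms, current_xyz
        if current_atoms is not None:
            per_frame_atoms.append(current_atoms)
            frames.append(current_xyz)  # type: ignore[arg-type]
        current_atoms, current_xyz = None, None

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("MODEL"):
                if current_atoms is not None:
                    close_model()
                saw_model = True
                open_model(line[10:14].strip() or str(len(model_numbers) + 1))
            elif line.startswith("ENDMDL"):
                close_model()
            elif line.startswith(("ATOM  ", "HETATM")):
                if current_atoms is None:
                    if saw_model:
                        raise ParseError(
                            f"line {lineno}: atom record outside MODEL/ENDMDL block"
                        )
                    open_model("1")
                atom, xyz, altloc = _parse_atom_line(line, lineno)
                if atom.key in current_keys:
                    if altloc:
                        continue  # keep first altloc only
                    raise ParseError(
                        f"line {lineno}: duplicate atom {atom.key} within one model"
                    )
                current_keys.add(atom.key)
                current_atoms.append(atom)
                current_xyz.append(xyz)  # type: ignore[union-attr]
    close_model()

    if not frames:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    topology = per_frame_atoms[0]
    for m, atoms in enumerate(per_frame_atoms[1:], start=2):
        label = model_numbers[m - 1] if m - 1 < len(model_numbers) else str(m)
        if len(atoms) != len(topology):
            raise StructureInconsistencyError(
                f"model {label} has {len(atoms)} atoms, first model has "
                f"{len(topology)}"
            )
        for a, b in zip(topology, atoms):
            if a.key != b.key:
                raise StructureInconsistencyError(
                    f"model {label}: atom {b.key} does not match first-model "
                    f"atom {a.key} at the same position"
                )
    coords = np.stack([np.array(f) for f in frames])
    return Ensemble(topology=topology, coordinates=coords)


def _format_atom_line(atom: AtomRecord, xyz: np.ndarray) -> str:
    record = "HETATM" if atom.record_class == HETERO else "ATOM  "
    name = atom.atom_name
    # PDB convention: names of <4 chars start in column 14 unless 2-char element
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    fields = []
    for v in xyz:
        s = f"{v:8.3f}"
        if len(s) > 8:
            raise FormatOverflowError(
                f"coordinate {v} overflows the 8-column PDB field"
            )
        fields.append(s)
    return (
        f"{record}{atom.serial % 100000:5d} {name_field}"
        f" {atom.residue_name:>3.3s} {atom.chain_id:1.1s}"
        f"{atom.residue_number % 10000:4d}    "
        f"{fields[0]}{fields[1]}{fields[2]}"
        f"{1.0:6.2f}{0.0:6.2f}          {atom.element:>2.2s}"
    )


def write_multimodel_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write the ensemble as MODEL/ENDMDL blocks, 3-decimal fixed columns.

    The output round-trips through :func:`read_multimodel_pdb` exactly on
    topology and to 3 decimals on coordinates (the PDB column precision).
    """
    if np.any(np.abs(ensemble.coordinates) >= 10000):
        raise FormatOverflowError("coordinate magnitude >= 10000 A overflows PDB columns")
    path = Path(path)
    with open(path, "w") as handle:
        for f in range(ensemble.n_frames):
            handle.write(f"MODEL     {f + 1:4d}\n")
            for atom, xyz in zip(ensemble.topology, ensemble.coordinates[f]):
                handle.write(_format_atom_line(atom, xyz) + "\n")
            handle.write("ENDMDL\n")
        handle.write("END\n")


def concatenate(ensembles: Sequence[Ensemble]) -> Ensemble:
    """Concatenate frames of ensembles sharing one topology."""
    if not ensembles:
        raise ValidationError("nothing to concatenate")
    first = ensembles[0]
    for e in ensembles[1:]:
        if [a.key for a in e.topology] != [a.key for a in first.topology]:
            raise StructureInconsistencyError(
                "cannot concatenate ensembles with different topologies"
            )
    return Ensemble(
        topology=first.topology,
        coordinates=np.concatenate([e.coordinates for e in ensembles], axis=0),
    )
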