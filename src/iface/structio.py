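"""Structure data model and PDB reading/writing.

The in-memory model is a thin chain → residue → atom hierarchy with
coordinates in Å, designed for the needs of docked-pose ensemble analysis:
author residue numbering (with insertion codes) is preserved, altloc
duplicates are resolved deterministically at read time, hydrogens are kept
but flagged by element so downstream selections can exclude them, and
MODEL-delimited multi-model files are exploded into separate structures in
file order.

Parsing is delegated to gemmi; writing emits fixed-column PDB records
directly so the round-trip contract (atom count, names, numbering, chain
ids, coordinates to 3 decimals) is under this module's control.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
from Bio.SeqUtils import seq1

from .errors import CongruenceError, InputError, ParseError

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Trajectory",
    "ResidueKey",
    "read_pdb",
    "read_models",
    "write_pdb",
    "chain_sequence",
    "read_trajectory",
]

#: (chain_id, author residue number, insertion code) — the residue identity
#: used throughout the package.
ResidueKey = tuple[str, int, str]


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise InputError(f"atom {self.name!r}: coord must be 3 finite components")
        if not 0.0 <= self.occupancy <= 1.0:
            raise InputError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name3: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.icode)

    @property
    def is_hetero(self) -> bool:
        """True when every atom came from a HETATM record."""
        return bool(self.atoms) and all(a.is_hetero for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source: str = ""

    def residues(self, chain_id: str | None = None) -> Iterator[Residue]:
        if chain_id is not None:
            if chain_id not in self.chains:
                raise LookupError(f"structure {self.id!r} has no chain {chain_id!r}")
            yield from self.chains[chain_id]
        else:
            for residues in self.chains.values():
                yield from residues

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def coords(self) -> np.ndarray:
        """All atom coordinates, shape (n_atoms, 3), in hierarchy order."""
        return np.array([a.coord for _, a in self.atoms()], dtype=float).reshape(-1, 3)

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """Copy of this structure with every atom coordinate replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise CongruenceError(
                f"coordinate array shape {coords.shape} incompatible with {self.n_atoms} atoms"
            )
        out = Structure(id=id or self.id, source=self.source)
        i = 0
        for cid, residues in self.chains.items():
            new_res = []
            for res in residues:
                new_atoms = []
                for atom in res.atoms:
                    new_atoms.append(
                        Atom(atom.name, atom.element, coords[i].copy(), atom.occupancy,
                             atom.altloc, atom.is_hetero)
                    )
                    i += 1
                new_res.append(Residue(res.chain_id, res.number, res.icode, res.name3, new_atoms))
            out.chains[cid] = new_res
        return out

    def atom_mask(
        self,
        chains: Iterable[str] | None = None,
        atom_names: Iterable[str] | None = None,
        heavy_only: bool = False,
        include_hetero: bool = True,
    ) -> np.ndarray:
        """Boolean mask over the flat atom order selecting a subset of atoms."""
        chain_set = set(chains) if chains is not None else None
        name_set = set(atom_names) if atom_names is not None else None
        mask = []
        for res, atom in self.atoms():
            keep = True
            if chain_set is not None and res.chain_id not in chain_set:
                keep = False
            if name_set is not None and atom.name not in name_set:
                keep = False
            if heavy_only and atom.is_hydrogen:
                keep = False
            if not include_hetero and atom.is_hetero:
                keep = False
            mask.append(keep)
        return np.array(mask, dtype=bool)

    def atom_residue_keys(self) -> list[ResidueKey]:
        """Residue key of every atom in flat order (parallel to coords())."""
        return [res.key for res, _ in self.atoms()]


@dataclass
class Trajectory:
    """Topology plus ordered coordinate frames with a fixed time step (ps)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    dt: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise InputError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise CongruenceError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if not self.dt > 0:
            raise InputError(f"dt must be positive, got {self.dt}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps (frame index × dt)."""
        return np.arange(self.n_frames, dtype=float) * self.dt


# ---------------------------------------------------------------------------
# reading


def _validate_coordinate_columns(path: str | os.PathLike) -> int:
    """Check ATOM/HETATM coordinate fields parse as floats; return record count.

    gemmi silently coerces malformed coordinate fields to 0, so the contract
    "parse error naming the line number" is enforced here with a cheap scan.
    """
    n_records = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n_records += 1
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}: non-numeric coordinate "
                            f"field {fieldtxt!r}"
                        ) from None
    return n_records


def _resolve_altlocs(atoms: list[Atom], policy: str) -> list[Atom]:
    seen: dict[str, list[Atom]] = {}
    for atom in atoms:
        seen.setdefault(atom.name, []).append(atom)
    resolved = []
    for name, group in seen.items():
        if len(group) == 1:
            resolved.append(group[0])
        elif policy == "keep-first":
            resolved.append(group[0])
        elif policy == "highest-occupancy":
            # ties broken alphabetically by altloc id
            resolved.append(min(group, key=lambda a: (-a.occupancy, a.altloc)))
        else:
            raise InputError(f"unknown altloc policy {policy!r}")
    return resolved


def _convert_model(model: gemmi.Model, label: str, source: str, altloc_policy: str) -> Structure:
    out = Structure(id=label, source=source)
    for chain in model:
        residues = []
        for res in chain:
            is_het = res.het_flag == "H"
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(float(a.occ), 0.0), 1.0),
                    altloc=a.altloc if a.altloc else "",
                    is_hetero=is_het,
                )
                for a in res
            ]
            atoms = _resolve_altlocs(atoms, altloc_policy)
            residues.append(
                Residue(
                    chain_id=chain.name,
                    number=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    name3=res.name,
                    atoms=atoms,
                )
            )
        if chain.name in out.chains:
            out.chains[chain.name].extend(residues)
        else:
            out.chains[chain.name] = residues
    return out


def read_models(
    path: str | os.PathLike, altloc_policy: str = "highest-occupancy"
) -> list[Structure]:
    """Read a PDB file, exploding MODEL-delimited entries into one Structure each."""
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    n_records = _validate_coordinate_columns(path)
    if n_records == 0:
        raise InputError(f"{path}: no ATOM/HETATM records (empty structure)")
    st = gemmi.read_pdb(str(path))
    base = os.path.splitext(os.path.basename(str(path)))[0]
    structures = []
    for i, model in enumerate(st):
        label = base if len(st) == 1 else f"{base}#{i}"
        structures.append(_convert_model(model, label, str(path), altloc_policy))
    return structures


def read_pdb(path: str | os.PathLike, altloc_policy: str = "highest-occupancy") -> Structure:
    """Read the first (or only) model of a PDB file into a Structure."""
    return read_models(path, altloc_policy=altloc_policy)[0]


# ---------------------------------------------------------------------------
# writing


def _format_atom_name(name: str) -> str:
    # Names of 1-3 characters start in column 14, 4-character names in column 13.
    return f"{name:>4}" if len(name) >= 4 else f" {name:<3}"


def _pdb_record_lines(s: Structure) -> list[str]:
    if s.n_atoms == 0:
        raise InputError("refusing to write an empty structure")
    for cid in s.chains:
        if len(cid) != 1:
            raise InputError(f"chain id {cid!r} does not fit the 1-character PDB column")
    serial = 0
    lines = []
    for cid, residues in s.chains.items():
        last = None
        for res in residues:
            for atom in res.atoms:
                serial += 1
                record = "HETATM" if atom.is_hetero else "ATOM  "
                lines.append(
                    f"{record}{serial:>5} {_format_atom_name(atom.name)}"
                    f"{atom.altloc or ' '}{res.name3:>3} {cid}{res.number:>4}"
                    f"{res.icode or ' '}   "
                    f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2}"
                )
            last = res
        if last is not None:
            serial += 1
            lines.append(
                f"TER   {serial:>5}      {last.name3:>3} {cid}{last.number:>4}"
                f"{last.icode or ' '}"
            )
    return lines


def write_pdb(s: Structure, path: str | os.PathLike) -> None:
    """Write a Structure as fixed-column PDB ATOM/HETATM records.

    Coordinates are written to 3 decimals; a TER record separates chains and
    the file ends with END.
    """
    lines = _pdb_record_lines(s) + ["END"]
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def write_models(structures: Sequence[Structure], path: str | os.PathLike) -> None:
    """Write several structures as a MODEL-delimited multi-model PDB file."""
    if not structures:
        raise InputError("no structures to write")
    lines: list[str] = []
    for i, s in enumerate(structures, start=1):
        lines.append(f"MODEL     {i:>4}")
        lines.extend(_pdb_record_lines(s))
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# sequences and trajectories


def chain_sequence(s: Structure, chain_id: str) -> str:
    """One-letter sequence of a chain; unknown names map to X, HETATM-only skipped."""
    if chain_id not in s.chains:
        raise LookupError(f"structure {s.id!r} has no chain {chain_id!r}")
    letters = []
    for res in s.chains[chain_id]:
        if res.is_hetero:
            continue
        one = seq1(res.name3.capitalize(), undef_code="X")
        letters.append(one if one.isalpha() else "X")
    return "".join(letters)


def read_trajectory(paths: Sequence[str | os.PathLike], dt: float) -> Trajectory:
    """Assemble ordered single-model PDB frame files into a Trajectory."""
    if not paths:
        raise InputError("need at least one frame file")
    topology = read_pdb(paths[0])
    n_atoms = topology.n_atoms
    frames = [topology.coords()]
    for i, path in enumerate(paths[1:], start=1):
        frame = read_pdb(path)
        if frame.n_atoms != n_atoms:
            raise CongruenceError(
                f"frame {i} ({path}) has {frame.n_atoms} atoms, expected {n_atoms}"
            )
        frames.append(frame.coords())
    return Trajectory(topology=topology, frames=np.stack(frames), dt=dt)
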