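"""Strict PDB-subset I/O and the internal coordinate model.

Every analysis module consumes the :class:`Structure` / :class:`Trajectory`
containers defined here.  Author (PDB) residue numbering is preserved verbatim
throughout the package, so user-facing labels like ``A126`` match the
literature; no re-indexing ever happens.

Supported format: fixed-column PDB (ATOM, HETATM, SSBOND, MODEL/ENDMDL, TER,
END).  Multi-model PDB doubles as the trajectory carrier.  mmCIF, gzip and
binary trajectory formats are out of scope.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
from Bio.SeqUtils import seq1

__all__ = [
    "Atom",
    "Residue",
    "SSBond",
    "Structure",
    "Trajectory",
    "PDBParseError",
    "EmptyStructureError",
    "CongruenceError",
    "read_pdb",
    "write_pdb",
    "read_multimodel",
    "write_multimodel",
]


class PDBParseError(ValueError):
    """Malformed fixed-column record; message carries the 1-based line number."""


class EmptyStructureError(ValueError):
    """A file yielded zero ATOM records."""


class CongruenceError(ValueError):
    """Models of a multi-model file disagree in atom count/order."""


# one-letter codes for residue labels ("A126"); unknown residues fall back to X
def _one_letter(resname: str) -> str:
    return seq1(resname) or "X"


@dataclass
class Atom:
    """A single atom: PDB name, element, coordinates (Å), B-factor (Å²)."""

    name: str
    element: str
    coords: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.bfactor < 0:
            raise ValueError(f"atom {self.name!r}: negative B-factor")


@dataclass
class Residue:
    """A residue keyed by (chain, author seq number, insertion code)."""

    chain: str
    seqnum: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seqnum, self.icode)

    @property
    def label(self) -> str:
        """One-letter-code label in author numbering, e.g. ``A126``."""
        return f"{_one_letter(self.name)}{self.seqnum}{self.icode.strip()}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has(self, name: str) -> bool:
        return self.atom(name) is not None

    @property
    def heavy_coords(self) -> np.ndarray:
        xyz = [a.coords for a in self.atoms if a.element != "H"]
        return np.array(xyz) if xyz else np.empty((0, 3))


@dataclass
class SSBond:
    """An SSBOND header record (two cysteine references, optional Sγ–Sγ length)."""

    chain1: str
    seq1: int
    icode1: str
    chain2: str
    seq2: int
    icode2: str
    length: float | None = None


@dataclass
class Structure:
    """Ordered residues grouped by chain, plus any SSBOND header records."""

    label: str = ""
    residues: list[Residue] = field(default_factory=list)
    ssbonds: list[SSBond] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues:
            if r.key in seen:
                raise ValueError(f"duplicate residue key {r.key}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain not in out:
                out.append(r.chain)
        return out

    def get(self, chain: str, seqnum: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.chain == chain and r.seqnum == seqnum and r.icode.strip() == icode.strip():
                return r
        return None

    def find_label(self, label: str) -> Residue | None:
        """Resolve a label like ``S133`` or ``A:S133`` (chain-qualified)."""
        chain = None
        if ":" in label:
            chain, label = label.split(":", 1)
        for r in self.residues:
            if r.label == label and (chain is None or r.chain == chain):
                return r
        return None

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def coords(self, atom_name: str | None = None) -> np.ndarray:
        """Stacked coordinates, optionally restricted to one atom name (e.g. CA)."""
        if atom_name is None:
            return np.array([a.coords for a in self.atoms])
        out = []
        for r in self.residues:
            a = r.atom(atom_name)
            if a is not None:
                out.append(a.coords)
        return np.array(out)

    def ca_coords(self) -> np.ndarray:
        return self.coords("CA")


@dataclass
class Trajectory:
    """A topology plus ordered coordinate frames with strictly increasing times (ps)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,) ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        n_atoms = len(self.topology.atoms)
        if self.frames.ndim != 3 or self.frames.shape[1] != n_atoms:
            raise CongruenceError(
                f"frames have {self.frames.shape[1] if self.frames.ndim == 3 else '?'} atoms, "
                f"topology has {n_atoms}"
            )
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame time stamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def atom_index(self, atom_name: str) -> np.ndarray:
        """Flat indices of a named atom across residues (for Cα selections)."""
        idx, k = [], 0
        for r in self.topology.residues:
            for a in r.atoms:
                if a.name == atom_name:
                    idx.append(k)
                k += 1
        return np.array(idx, dtype=int)


# --------------------------------------------------------------------------
# parsing


def _parse_float(line: str, lo: int, hi: int, what: str, lineno: int) -> float:
    text = line[lo:hi].strip()
    try:
        return float(text)
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad {what} field {text!r}") from exc


def _parse_int(line: str, lo: int, hi: int, what: str, lineno: int) -> int:
    text = line[lo:hi].strip()
    try:
        return int(text)
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad {what} field {text!r}") from exc


def _parse_atom_line(line: str, lineno: int):
    line = line.rstrip("\n").ljust(80)
    name = line[12:16].strip()
    if not name:
        raise PDBParseError(f"line {lineno}: empty atom name")
    altloc = line[16]
    resname = line[17:20].strip()
    chain = line[21]
    seqnum = _parse_int(line, 22, 26, "residue number", lineno)
    icode = line[26].strip()
    x = _parse_float(line, 30, 38, "x", lineno)
    y = _parse_float(line, 38, 46, "y", lineno)
    z = _parse_float(line, 46, 54, "z", lineno)
    occ_text = line[54:60].strip()
    occupancy = float(occ_text) if occ_text else 1.0
    b_text = line[60:66].strip()
    bfactor = float(b_text) if b_text else 0.0
    element = line[76:78].strip() or name[0]
    atom = Atom(name=name, element=element, coords=np.array([x, y, z]),
                bfactor=max(bfactor, 0.0), occupancy=occupancy)
    return (chain, seqnum, icode, resname), altloc, atom


def _parse_ssbond_line(line: str, lineno: int) -> SSBond:
    line = line.rstrip("\n").ljust(80)
    chain1 = line[15].strip()
    s1 = _parse_int(line, 17, 21, "SSBOND residue 1", lineno)
    i1 = line[21].strip()
    chain2 = line[29].strip()
    s2 = _parse_int(line, 31, 35, "SSBOND residue 2", lineno)
    i2 = line[35].strip()
    length_text = line[73:78].strip()
    length = float(length_text) if length_text else None
    return SSBond(chain1, s1, i1, chain2, s2, i2, length)


def _assemble(records, ssbonds, label: str) -> Structure:
    """Group parsed atom records into residues, resolving altlocs."""
    residues: dict[tuple, Residue] = {}
    order: list[tuple] = []
    # altloc policy: keep highest occupancy, ties -> first encountered
    best: dict[tuple, tuple[float, int]] = {}
    for n, (reskey, altloc, atom) in enumerate(records):
        akey = (reskey, atom.name)
        if reskey not in residues:
            residues[reskey] = Residue(chain=reskey[0], seqnum=reskey[1],
                                       icode=reskey[2], name=reskey[3])
            order.append(reskey)
        res = residues[reskey]
        if altloc.strip() == "" or akey not in best:
            if akey in best and altloc.strip() == "":
                continue  # duplicate plain atom name: keep first
            best[akey] = (atom.occupancy, len(res.atoms))
            res.atoms.append(atom)
        else:
            prev_occ, pos = best[akey]
            if atom.occupancy > prev_occ:
                res.atoms[pos] = atom
                best[akey] = (atom.occupancy, pos)
    return Structure(label=label, residues=[residues[k] for k in order], ssbonds=ssbonds)


def read_pdb(source: str | TextIO, label: str = "", include_hetatm: bool = False) -> Structure:
    """Parse a (single-model) PDB text into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer (ties:
    first encountered).  HETATM records are skipped unless *include_hetatm*.
    SSBOND header records are captured.  Only the first MODEL of a multi-model
    file is read; use :func:`read_multimodel` for trajectories.
    """
    stream = io.StringIO(source) if isinstance(source, str) else source
    records, ssbonds = [], []
    in_model = 0
    for lineno, line in enumerate(stream, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model += 1
            if in_model > 1:
                break
        elif rec == "ATOM" or (rec == "HETATM" and include_hetatm):
            records.append(_parse_atom_line(line, lineno))
        elif rec == "SSBOND":
            ssbonds.append(_parse_ssbond_line(line, lineno))
        elif rec == "END":
            break
    if not records:
        raise EmptyStructureError("no ATOM records found")
    return _assemble(records, ssbonds, label)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise ValueError(f"atom name {name!r} exceeds the 4-character PDB field")
    # names of <=3 chars with 1-char elements start in column 14
    if len(name) < 4 and len(element) < 2:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure) -> str:
    """Serialize a :class:`Structure` to PDB text.

    Coordinates are written to 3 decimals and B-factors to 2, so a
    parse-write-parse round trip is exact at that precision.  Atom serials
    above 99999 wrap back to 1 (documented wrap policy).
    """
    if not structure.residues:
        raise EmptyStructureError("cannot write an empty structure")
    lines: list[str] = []
    for b in structure.ssbonds:
        lines.append(
            "SSBOND {ser:>3d} CYS {c1:1s} {s1:>4d}{i1:1s}   CYS {c2:1s} {s2:>4d}{i2:1s}"
            "{pad:>36s}{length}".format(
                ser=len(lines) + 1, c1=b.chain1 or " ", s1=b.seq1, i1=b.icode1 or " ",
                c2=b.chain2 or " ", s2=b.seq2, i2=b.icode2 or " ", pad="",
                length=f"{b.length:6.2f}" if b.length is not None else "",
            ).rstrip()
        )
    serial = 0
    prev_chain = None
    for res in structure.residues:
        if prev_chain is not None and res.chain != prev_chain:
            lines.append("TER")
        prev_chain = res.chain
        for atom in res.atoms:
            serial = serial % 99999 + 1
            x, y, z = atom.coords
            lines.append(
                "ATOM  {ser:>5d} {name} {res:<3s} {chain:1s}{seq:>4d}{icode:1s}   "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}".format(
                    ser=serial, name=_format_atom_name(atom.name, atom.element),
                    res=res.name, chain=res.chain or " ", seq=res.seqnum,
                    icode=res.icode or " ", x=x, y=y, z=z,
                    occ=atom.occupancy, b=atom.bfactor, el=atom.element,
                )
            )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_multimodel(source: str | TextIO, label: str = "",
                    dt_ps: float = 1.0) -> Trajectory:
    """Parse a MODEL/ENDMDL multi-model PDB into a :class:`Trajectory`.

    The topology is taken from the first model; every later model must list
    the same atoms in the same order.  Frame times default to ``0, dt_ps,
    2*dt_ps, ...``.
    """
    stream = io.StringIO(source) if isinstance(source, str) else source
    models: list[list] = []
    current: list | None = None
    ssbonds: list[SSBond] = []
    saw_model_record = False
    for lineno, line in enumerate(stream, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current is not None and saw_model_record:
                raise PDBParseError(f"line {lineno}: MODEL record without ENDMDL")
            saw_model_record = True
            current = []
        elif rec == "ENDMDL":
            if current is not None:
                models.append(current)
            current = None
        elif rec == "ATOM":
            if current is None:
                if saw_model_record:
                    raise PDBParseError(f"line {lineno}: ATOM outside MODEL block")
                current = []  # tolerate a model-less single structure
            current.append(_parse_atom_line(line, lineno))
        elif rec == "SSBOND":
            ssbonds.append(_parse_ssbond_line(line, lineno))
    if current:
        models.append(current)
    if not models:
        raise EmptyStructureError("no models found")
    topology = _assemble(models[0], ssbonds, label)
    n_atoms = len(topology.atoms)
    frames = np.empty((len(models), n_atoms, 3))
    for m, records in enumerate(models):
        if len(records) != n_atoms:
            raise CongruenceError(
                f"model {m + 1} has {len(records)} atoms, expected {n_atoms}"
            )
        for k, (_, _, atom) in enumerate(records):
            frames[m, k] = atom.coords
    times = np.arange(len(models), dtype=float) * dt_ps
    return Trajectory(topology=topology, frames=frames, times=times)


def write_multimodel(trajectory: Trajectory) -> str:
    """Serialize a trajectory as a MODEL/ENDMDL multi-model PDB."""
    chunks: list[str] = []
    topo = trajectory.topology
    flat_atoms = topo.atoms
    saved = [a.coords.copy() for a in flat_atoms]
    try:
        for m, frame in enumerate(trajectory.frames, start=1):
            for atom, xyz in zip(flat_atoms, frame):
                atom.coords = np.asarray(xyz, dtype=float)
            chunks.append(f"MODEL {m:>8d}")
            body = write_pdb(topo).rstrip("\n").split("\n")
            chunks.extend(line for line in body if not line.startswith(("END", "SSBOND")))
            chunks.append("ENDMDL")
    finally:
        for atom, xyz in zip(flat_atoms, saved):
            atom.coords = xyz
    chunks.append("END")
    return "\n".join(chunks) + "\n"
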