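"""Structure I/O: PDB files under IO profiles, CHARMM DCD trajectories.

An :class:`IOProfile` bundles the flags that fine-tune import behaviour:
whether nonconforming records abort the import or are skipped with a
warning, whether HETATM records are read, and which connectivity processor
runs afterwards.  The default profile is strict: the import aborts, citing
the line number, on the first malformed record — the recommended setting
for automated pipelines.

DCD trajectories can be read fully into memory or lazily: in lazy mode only
the header is parsed up front and frames are fetched from disk on demand
through per-frame file offsets, with a small LRU cache.  Both modes return
bit-identical coordinates for any frame index.
"""

from __future__ import annotations

import struct
from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import conop
from .mol import Atom, Entity, EntityView, Residue, _guess_element

__all__ = [
    "IOProfile",
    "DEFAULT_PROFILE",
    "TOLERANT_PROFILE",
    "PDBParseError",
    "PDBWriteError",
    "DCDError",
    "Trajectory",
    "read_pdb",
    "write_pdb",
    "read_dcd",
    "write_dcd",
    "frame_positions",
    "apply_frame",
]


@dataclass(frozen=True)
class IOProfile:
    """Flags fine-tuning structure import and post-processing."""
    strict: bool = True
    process_connectivity: str = "rule_based"   # rule_based | heuristic | none
    fault_tolerant: bool = False
    read_hetatms: bool = True


DEFAULT_PROFILE = IOProfile()
TOLERANT_PROFILE = IOProfile(strict=False, fault_tolerant=True)


class PDBParseError(Exception):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class PDBWriteError(Exception):
    pass


class DCDError(Exception):
    pass


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

@dataclass
class _RawAtom:
    line_no: int
    serial: int
    name: str
    alt_loc: str
    res_name: str
    chain: str
    res_seq: int
    icode: str
    pos: tuple
    occupancy: float
    b_factor: float
    element: str
    charge: float
    is_hetatm: bool
    aniso_b: Optional[np.ndarray] = None


def _parse_atom_record(line: str, line_no: int) -> _RawAtom:
    if len(line) < 54:
        raise PDBParseError("ATOM/HETATM record shorter than coordinate fields",
                            line_no)
    line = line.ljust(80)

    def _float(lo, hi, what):
        text = line[lo:hi].strip()
        try:
            return float(text)
        except ValueError:
            raise PDBParseError(f"non-numeric {what} field {text!r}", line_no) from None

    def _int(lo, hi, what):
        text = line[lo:hi].strip()
        try:
            return int(text)
        except ValueError:
            raise PDBParseError(f"non-numeric {what} field {text!r}", line_no) from None

    name = line[12:16].strip()
    if not name:
        raise PDBParseError("empty atom name", line_no)
    occ_text = line[54:60].strip()
    b_text = line[60:66].strip()
    charge_text = line[78:80].strip()
    charge = 0.0
    if charge_text:
        try:
            if charge_text[-1] in "+-":
                charge = float(charge_text[-1] + charge_text[:-1])
            else:
                charge = float(charge_text)
        except ValueError:
            raise PDBParseError(f"malformed charge field {charge_text!r}",
                                line_no) from None
    element = line[76:78].strip().upper()
    return _RawAtom(
        line_no=line_no,
        serial=_int(6, 11, "serial"),
        name=name,
        alt_loc=line[16].strip(),
        res_name=line[17:20].strip(),
        chain=line[21].strip() or "_",
        res_seq=_int(22, 26, "residue number"),
        icode=line[26].strip(),
        pos=(_float(30, 38, "x"), _float(38, 46, "y"), _float(46, 54, "z")),
        occupancy=_float(54, 60, "occupancy") if occ_text else 1.0,
        b_factor=_float(60, 66, "B factor") if b_text else 0.0,
        element=element or _guess_element(name),
        charge=charge,
        is_hetatm=line.startswith("HETATM"),
    )


def read_pdb(path, profile: IOProfile = DEFAULT_PROFILE):
    """Read a PDB file (first MODEL only) into an entity.

    Alternate locations are resolved to the highest occupancy, ties to the
    lowest alt-loc letter.  Returns ``(entity, diagnostics)``, where the
    diagnostics come from connectivity processing plus any records skipped
    under a fault-tolerant profile.
    """
    raw_atoms: list[_RawAtom] = []
    by_serial: dict[int, _RawAtom] = {}
    diags = conop.Diagnostics()
    in_first_model = True
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                if not in_first_model:
                    continue
                try:
                    raw = _parse_atom_record(line.rstrip("\n"), line_no)
                except PDBParseError as exc:
                    if profile.fault_tolerant:
                        diags.add("warning", f"line {line_no}", "bad_record",
                                  str(exc))
                        continue
                    raise
                if raw.is_hetatm and not profile.read_hetatms:
                    continue
                raw_atoms.append(raw)
                by_serial[raw.serial] = raw
            elif rec == "ANISOU" and in_first_model:
                try:
                    serial = int(line[6:11])
                    u = [int(line[28 + 7 * k:35 + 7 * k]) for k in range(6)]
                except ValueError:
                    continue
                if serial in by_serial:
                    u11, u22, u33, u12, u13, u23 = (v / 1e4 for v in u)
                    by_serial[serial].aniso_b = np.array(
                        [[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])
            elif rec.startswith("ENDMDL"):
                in_first_model = False
            elif rec.startswith("END"):
                break

    entity = _assemble_entity(raw_atoms, Path(path).stem)
    if profile.process_connectivity == "rule_based":
        conn = conop.rule_based_process(entity, strict=profile.strict)
        diags.records.extend(conn.records)
    elif profile.process_connectivity == "heuristic":
        conop.heuristic_process(entity)
    return entity, diags


def _assemble_entity(raw_atoms: list[_RawAtom], name: str) -> Entity:
    # alt-loc resolution: per residue+atom-name keep highest occupancy,
    # ties broken by the lowest alt-loc letter ('' sorts lowest)
    best: "OrderedDict[tuple, _RawAtom]" = OrderedDict()
    for raw in raw_atoms:
        key = (raw.chain, raw.res_seq, raw.icode, raw.name)
        prev = best.get(key)
        if prev is None:
            best[key] = raw
        elif (raw.occupancy > prev.occupancy or
              (raw.occupancy == prev.occupancy and raw.alt_loc < prev.alt_loc)):
            best[key] = raw

    entity = Entity(name)
    for raw in best.values():
        chain = entity.find_chain(raw.chain) or entity.add_chain(raw.chain)
        res = chain.find_residue(raw.res_seq, raw.icode)
        if res is None:
            res = chain.add_residue(Residue(raw.res_name, raw.res_seq, raw.icode))
        res.add_atom(Atom(raw.name, raw.element, raw.pos, raw.occupancy,
                          raw.b_factor, raw.aniso_b, raw.charge, raw.is_hetatm))
    return entity


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def write_pdb(entity_or_view, path) -> None:
    """Write an entity or view as fixed-column PDB v3.3 ATOM/HETATM records.

    A strict-profile read of the output reproduces chains, residues, atoms
    and positions to three decimals.  Over-long names and out-of-range
    coordinates raise :class:`PDBWriteError`.
    """
    is_view = isinstance(entity_or_view, EntityView)
    lines = []
    serial = 0
    chains = entity_or_view.chains
    for chain in chains:
        cname = chain.name
        if len(cname) > 1:
            raise PDBWriteError(f"chain name {cname!r} exceeds one character")
        for res in chain.residues:
            if len(res.name) > 3:
                raise PDBWriteError(f"residue name {res.name!r} exceeds field width")
            if not (-999 <= res.number <= 9999):
                raise PDBWriteError(f"residue number {res.number} overflows field")
            for atom in res.atoms:
                serial += 1
                a = atom.handle if is_view else atom
                if len(a.name) > 4:
                    raise PDBWriteError(f"atom name {a.name!r} exceeds field width")
                x, y, z = a.pos
                for c in (x, y, z):
                    if not (-999.999 <= c <= 9999.999):
                        raise PDBWriteError(f"coordinate {c} overflows field")
                if len(a.name) >= 4 or len(a.element) >= 2:
                    name_field = a.name.ljust(4)
                else:
                    name_field = (" " + a.name).ljust(4)
                charge_field = "  "
                if a.charge:
                    mag = int(round(abs(a.charge)))
                    if mag:
                        charge_field = f"{mag}{'+' if a.charge > 0 else '-'}"
                lines.append(
                    f"{'HETATM' if a.is_hetatm else 'ATOM  '}"
                    f"{serial:5d} {name_field}{'':1s}{res.name:>3s} {cname:1s}"
                    f"{res.number:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                    f"          {a.element:>2s}{charge_field}"
                )
        lines.append(f"TER   {serial + 1:5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# DCD trajectories
# ---------------------------------------------------------------------------

class Trajectory:
    """Frames of coordinates over a fixed topology.

    ``mode`` is ``in_memory`` (all strided frames resident) or ``lazy``
    (frames fetched from disk on demand through an LRU cache of
    ``cache_size`` frames; ``fetch_count`` counts actual disk reads).
    """

    def __init__(self, topology: Entity, mode: str, stride: int,
                 source=None, frames: Optional[np.ndarray] = None,
                 reader: Optional["_DCDReader"] = None, cache_size: int = 16):
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.topology = topology
        self.mode = mode
        self.stride = stride
        self.source = source
        self._frames = frames
        self._reader = reader
        self.cache_size = cache_size
        self._cache: "OrderedDict[int, np.ndarray]" = OrderedDict()
        self.fetch_count = 0
        if mode == "in_memory":
            self.frame_count = len(frames)
        else:
            self.frame_count = (reader.n_frames + stride - 1) // stride

    @property
    def atom_count(self) -> int:
        return self.topology.atom_count

    def positions(self, i: int) -> np.ndarray:
        """Coordinates of frame ``i`` (after striding), shape (n_atoms, 3) Å."""
        if not 0 <= i < self.frame_count:
            raise IndexError(f"frame index {i} out of range [0, {self.frame_count})")
        if self.mode == "in_memory":
            return self._frames[i]
        if i in self._cache:
            self._cache.move_to_end(i)
            return self._cache[i]
        frame = self._reader.read_frame(i * self.stride)
        self.fetch_count += 1
        self._cache[i] = frame
        if len(self._cache) > self.cache_size:
            self._cache.popitem(last=False)
        return frame

    @property
    def resident_frames(self) -> int:
        return len(self._frames) if self.mode == "in_memory" else len(self._cache)

    def apply(self, i: int, entity: Optional[Entity] = None) -> None:
        apply_frame(self, i, entity)


def frame_positions(traj: Trajectory, i: int) -> np.ndarray:
    return traj.positions(i)


def apply_frame(traj: Trajectory, i: int, entity: Optional[Entity] = None) -> None:
    """Set entity atom positions to frame ``i``; views reflect the change."""
    entity = entity if entity is not None else traj.topology
    coords = traj.positions(i)
    atoms = list(entity.atoms)
    if len(atoms) != coords.shape[0]:
        raise ValueError("entity atom count does not match trajectory")
    for atom, xyz in zip(atoms, coords):
        atom.pos = xyz


class _DCDReader:
    """CHARMM-dialect DCD: 4-byte Fortran record markers, 'CORD' magic,
    single-precision coordinates, optional unit-cell block (honoured and
    ignored); endianness detected from the first record marker."""

    def __init__(self, path):
        self.path = Path(path)
        with open(self.path, "rb") as fh:
            header = fh.read(4)
            if len(header) < 4:
                raise DCDError("truncated DCD header")
            if struct.unpack("<i", header)[0] == 84:
                self.endian = "<"
            elif struct.unpack(">i", header)[0] == 84:
                self.endian = ">"
            else:
                raise DCDError("bad record marker: not a CHARMM DCD file")
            magic = fh.read(4)
            if magic != b"CORD":
                raise DCDError(f"magic-number mismatch: {magic!r} != b'CORD'")
            icntrl = struct.unpack(self.endian + "20i", fh.read(80))
            if struct.unpack(self.endian + "i", fh.read(4))[0] != 84:
                raise DCDError("corrupt header record")
            self.n_frames = icntrl[0]
            self.has_unitcell = icntrl[10] != 0
            # title block
            (tlen,) = struct.unpack(self.endian + "i", fh.read(4))
            fh.seek(tlen, 1)
            fh.read(4)
            # natoms block
            if struct.unpack(self.endian + "i", fh.read(4))[0] != 4:
                raise DCDError("corrupt atom-count record")
            (self.n_atoms,) = struct.unpack(self.endian + "i", fh.read(4))
            fh.read(4)
            self.data_start = fh.tell()
        cell = 56 if self.has_unitcell else 0
        coord_rec = 8 + 4 * self.n_atoms
        self.frame_size = cell + 3 * coord_rec
        size = self.path.stat().st_size
        avail = (size - self.data_start) // self.frame_size
        if avail < self.n_frames:
            self.n_frames = avail      # header may over-promise; trust the file

    def read_frame(self, i: int) -> np.ndarray:
        if not 0 <= i < self.n_frames:
            raise DCDError(f"frame {i} out of range")
        dtype = np.dtype(self.endian + "f4")
        with open(self.path, "rb") as fh:
            fh.seek(self.data_start + i * self.frame_size)
            if self.has_unitcell:
                fh.seek(56, 1)
            out = np.empty((3, self.n_atoms), dtype=np.float64)
            for axis in range(3):
                marker = fh.read(4)
                if len(marker) < 4:
                    raise DCDError(f"truncated frame {i}")
                (n,) = struct.unpack(self.endian + "i", marker)
                if n != 4 * self.n_atoms:
                    raise DCDError(f"frame {i}: bad coordinate record size")
                buf = fh.read(4 * self.n_atoms)
                if len(buf) < 4 * self.n_atoms:
                    raise DCDError(f"truncated frame {i}")
                out[axis] = np.frombuffer(buf, dtype=dtype)
                fh.read(4)
        return out.T.copy()


def read_dcd(path, topology: Entity, mode: str = "in_memory",
             stride: int = 1, cache_size: int = 16) -> Trajectory:
    """Read a CHARMM DCD file against a topology entity.

    ``mode='in_memory'`` loads every strided frame up front;
    ``mode='lazy'`` parses the header only and fetches frames on demand.
    The DCD atom count must match the topology atom count.
    """
    if mode not in ("in_memory", "lazy"):
        raise ValueError(f"unknown mode {mode!r}")
    reader = _DCDReader(path)
    n_top = topology.atom_count
    if reader.n_atoms != n_top:
        raise DCDError(
            f"atom-count mismatch: DCD has {reader.n_atoms}, topology {n_top}")
    if mode == "lazy":
        return Trajectory(topology, "lazy", stride, source=Path(path),
                          reader=reader, cache_size=cache_size)
    frames = np.stack([reader.read_frame(i)
                       for i in range(0, reader.n_frames, stride)]) \
        if reader.n_frames else np.empty((0, reader.n_atoms, 3))
    return Trajectory(topology, "in_memory", stride, source=Path(path),
                      frames=frames)


def write_dcd(path, coordinates: np.ndarray) -> None:
    """Minimal CHARMM DCD writer for test fixtures (little-endian, no cell).

    ``coordinates`` has shape (n_frames, n_atoms, 3) in Å.
    """
    coords = np.asarray(coordinates, dtype=np.float32)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
    n_frames, n_atoms, _ = coords.shape
    icntrl = [0] * 20
    icntrl[0] = n_frames
    icntrl[1] = 1          # first step
    icntrl[2] = 1          # save frequency
    icntrl[3] = n_frames
    icntrl[19] = 24        # CHARMM version stamp
    with open(path, "wb") as fh:
        def rec(payload: bytes):
            fh.write(struct.pack("<i", len(payload)))
            fh.write(payload)
            fh.write(struct.pack("<i", len(payload)))

        rec(b"CORD" + struct.pack("<20i", *icntrl))
        title = b"* molkit fixture trajectory".ljust(80)
        rec(struct.pack("<i", 1) + title)
        rec(struct.pack("<i", n_atoms))
        for f in range(n_frames):
            for axis in range(3):
                rec(coords[f, :, axis].astype("<f4").tobytes())
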