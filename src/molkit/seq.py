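"""Gapped sequences, alignments, gap-list index mapping, structure attachment.

A :class:`SequenceHandle` stores a one-letter-code string in which ``-``
marks gaps, plus a run-length *gap list* of ``(start, length)`` entries.
Mapping between an alignment position and the residue index only traverses
the gap list, never the sequence itself, so the cost is proportional to the
number of gaps — usually far smaller than the sequence length.  The number
of gap entries inspected is counted in ``map_stats`` so the bound is
testable.

A structure can be attached to its matching sequence; the gap-list mapping
then resolves alignment positions directly to residues of the attached
view.  Attachment validates that non-gap codes equal the view's one-letter
codes position-wise, with ``X`` matching anything.

Positions and residue indices are 0-based; ``offset`` (default 0) is the
index of the sequence's first residue within the full molecule sequence.
Input is case-insensitive and stored uppercase; ``.`` is accepted as a gap
on input and normalised to ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import AlignIO, SeqIO

from .mol import EntityView

__all__ = [
    "SequenceError",
    "SequenceHandle",
    "AlignmentHandle",
    "SequenceList",
    "create_sequence",
    "pos_to_residue_index",
    "residue_index_to_pos",
    "attach_view",
    "residue_at_pos",
    "read_sequences",
    "write_sequences",
    "read_alignment",
    "write_alignment",
]

_GAP = "-"
_VALID = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ") | {_GAP}


class SequenceError(Exception):
    pass


def _gap_list_of(string: str) -> list[tuple[int, int]]:
    gaps = []
    start = None
    for i, c in enumerate(string):
        if c == _GAP:
            if start is None:
                start = i
        elif start is not None:
            gaps.append((start, i - start))
            start = None
    if start is not None:
        gaps.append((start, len(string) - start))
    return gaps


@dataclass
class _MapStats:
    entries_inspected: int = 0

    def reset(self):
        self.entries_inspected = 0


class SequenceHandle:
    """A named, possibly gapped sequence with an optional attached structure."""

    def __init__(self, name: str, string: str, offset: int = 0,
                 pir_type: str = "P1", description: str = ""):
        self.name = name
        self.offset = int(offset)
        self.pir_type = pir_type
        self.description = description
        self.attached_view: Optional[EntityView] = None
        self._residues: list = []
        self.map_stats = _MapStats()
        self._set_string(string)

    # -- string / gap list -------------------------------------------------

    def _set_string(self, string: str) -> None:
        norm = string.upper().replace(".", _GAP)
        bad = set(norm) - _VALID
        if bad:
            raise SequenceError(
                f"sequence {self.name!r}: illegal character(s) "
                f"{', '.join(map(repr, sorted(bad)))}")
        self._string = norm
        self.gap_list = _gap_list_of(norm)

    @property
    def string(self) -> str:
        return self._string

    def __len__(self) -> int:
        return len(self._string)

    def __getitem__(self, pos: int) -> str:
        return self._string[pos]

    @property
    def gapless(self) -> str:
        return self._string.replace(_GAP, "")

    @property
    def non_gap_count(self) -> int:
        return len(self._string) - sum(n for _, n in self.gap_list)

    # -- mapping -----------------------------------------------------------

    def pos_to_residue_index(self, pos: int) -> Optional[int]:
        """Residue index at alignment position ``pos``; None on a gap.

        Traverses only the gap list: cost is bounded by the number of gap
        runs, not by ``pos``.
        """
        if not 0 <= pos < len(self._string):
            raise IndexError(f"position {pos} out of range [0, {len(self)})")
        gaps_before = 0
        for start, length in self.gap_list:
            self.map_stats.entries_inspected += 1
            if start > pos:
                break
            if pos < start + length:
                return None
            gaps_before += length
        return self.offset + pos - gaps_before

    def residue_index_to_pos(self, index: int) -> int:
        """Alignment position of residue ``index``; inverse of
        :meth:`pos_to_residue_index` on non-gap positions."""
        if not self.offset <= index < self.offset + self.non_gap_count:
            raise IndexError(
                f"residue index {index} out of range "
                f"[{self.offset}, {self.offset + self.non_gap_count})")
        pos = index - self.offset
        for start, length in self.gap_list:
            self.map_stats.entries_inspected += 1
            if start <= pos:
                pos += length
            else:
                break
        return pos

    # -- structure attachment ----------------------------------------------

    def attach_view(self, view: EntityView) -> None:
        residues = list(view.residues)
        if len(residues) != self.non_gap_count:
            raise SequenceError(
                f"cannot attach: view has {len(residues)} residues, sequence "
                f"{self.name!r} has {self.non_gap_count} non-gap characters")
        idx = 0
        for pos, code in enumerate(self._string):
            if code == _GAP:
                continue
            rcode = residues[idx].one_letter_code
            if code != rcode and code != "X" and rcode != "X":
                raise SequenceError(
                    f"code mismatch at position {pos}: sequence has {code!r}, "
                    f"residue {residues[idx].qualified_name} has {rcode!r}")
            idx += 1
        self.attached_view = view
        self._residues = residues

    def residue_at_pos(self, pos: int):
        """Residue of the attached view at alignment position ``pos``."""
        if self.attached_view is None:
            raise SequenceError(f"sequence {self.name!r} has no attached view")
        idx = self.pos_to_residue_index(pos)
        if idx is None:
            return None
        return self._residues[idx - self.offset]

    def copy(self) -> "SequenceHandle":
        dup = SequenceHandle(self.name, self._string, self.offset,
                             self.pir_type, self.description)
        return dup

    def __repr__(self):
        return f"<SequenceHandle {self.name!r} len={len(self)}>"


def create_sequence(name: str, string: str, offset: int = 0) -> SequenceHandle:
    return SequenceHandle(name, string, offset)


# module-level forms of the mapping ops

def pos_to_residue_index(seq: SequenceHandle, pos: int) -> Optional[int]:
    return seq.pos_to_residue_index(pos)


def residue_index_to_pos(seq: SequenceHandle, index: int) -> int:
    return seq.residue_index_to_pos(index)


def attach_view(seq: SequenceHandle, view: EntityView) -> None:
    seq.attach_view(view)


def residue_at_pos(seq: SequenceHandle, pos: int):
    return seq.residue_at_pos(pos)


class SequenceList:
    """Ordered sequences with unconstrained lengths."""

    def __init__(self, sequences: Iterable[SequenceHandle] = ()):
        self.sequences = list(sequences)

    def append(self, seq: SequenceHandle):
        self.sequences.append(seq)

    def __len__(self):
        return len(self.sequences)

    def __getitem__(self, i):
        return self.sequences[i]

    def __iter__(self):
        return iter(self.sequences)

    def find(self, name: str) -> Optional[SequenceHandle]:
        for s in self.sequences:
            if s.name == name:
                return s
        return None


class AlignmentHandle:
    """Sequences of equal length related by an alignment; column-wise edits."""

    def __init__(self, sequences: Iterable[SequenceHandle]):
        seqs = list(sequences)
        if not seqs:
            raise SequenceError("an alignment needs at least one sequence")
        length = len(seqs[0])
        for s in seqs:
            if len(s) != length:
                raise SequenceError(
                    f"sequence {s.name!r} has length {len(s)}, expected {length}")
        self.sequences = seqs

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self):
        return len(self.sequences)

    def __getitem__(self, i) -> SequenceHandle:
        return self.sequences[i]

    def __iter__(self):
        return iter(self.sequences)

    def find(self, name: str) -> Optional[SequenceHandle]:
        for s in self.sequences:
            if s.name == name:
                return s
        return None

    def column(self, pos: int) -> list[str]:
        if not 0 <= pos < self.length:
            raise IndexError(f"column {pos} out of range [0, {self.length})")
        return [s[pos] for s in self.sequences]

    def insert_gap_column(self, pos: int) -> None:
        if not 0 <= pos <= self.length:
            raise IndexError(f"column {pos} out of range [0, {self.length}]")
        for s in self.sequences:
            s._set_string(s.string[:pos] + _GAP + s.string[pos:])

    def remove_column(self, pos: int, force: bool = False) -> None:
        col = self.column(pos)
        if not force and any(c != _GAP for c in col):
            raise SequenceError(
                f"column {pos} contains non-gap characters; pass force=True")
        for s in self.sequences:
            s._set_string(s.string[:pos] + s.string[pos + 1:])

    def __repr__(self):
        return f"<AlignmentHandle {len(self)} seqs × {self.length} cols>"


# ---------------------------------------------------------------------------
# File I/O — FASTA and ClustalW through Biopython, PIR hand-rolled so the
# two-letter sequence-type code round-trips.
# ---------------------------------------------------------------------------

def _check_unique(names):
    seen = set()
    for n in names:
        if n in seen:
            raise SequenceError(f"duplicate sequence name {n!r}")
        seen.add(n)


def _read_pir(path) -> list[SequenceHandle]:
    seqs = []
    name = pir_type = desc = None
    chunks: list[str] = []

    def flush():
        if name is not None:
            string = "".join(chunks).replace("*", "")
            seqs.append(SequenceHandle(name, string, pir_type=pir_type,
                                       description=desc))

    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            flush()
            header = line[1:]
            if len(header) < 3 or header[2] != ";":
                raise SequenceError(f"malformed PIR header {line!r}")
            pir_type, name = header[:2], header[3:].strip()
            desc, chunks = None, []
        elif name is not None and desc is None:
            desc = line.strip()
        elif name is not None:
            chunks.append(line.strip())
    flush()
    return seqs


def _write_pir(seqs, path) -> None:
    lines = []
    for s in seqs:
        lines.append(f">{s.pir_type};{s.name}")
        lines.append(s.description or s.name)
        for i in range(0, len(s.string), 60):
            lines.append(s.string[i:i + 60])
        lines[-1] += "*"
    Path(path).write_text("\n".join(lines) + "\n")


def read_sequences(path, fmt: str = "fasta") -> SequenceList:
    """Read a FASTA or PIR file into a :class:`SequenceList`."""
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        seqs = [SequenceHandle(r.id, str(r.seq), description=r.description)
                for r in records]
    elif fmt == "pir":
        seqs = _read_pir(path)
    else:
        raise SequenceError(f"unsupported sequence format {fmt!r}")
    _check_unique(s.name for s in seqs)
    return SequenceList(seqs)


def write_sequences(seqs, path, fmt: str = "fasta") -> None:
    """Write sequences (any iterable of handles) as FASTA or PIR."""
    seqs = list(seqs)
    if fmt == "fasta":
        lines = []
        for s in seqs:
            lines.append(f">{s.name}")
            for i in range(0, len(s.string), 60):
                lines.append(s.string[i:i + 60])
        Path(path).write_text("\n".join(lines) + "\n")
    elif fmt == "pir":
        _write_pir(seqs, path)
    else:
        raise SequenceError(f"unsupported sequence format {fmt!r}")


def read_alignment(path, fmt: str = "fasta") -> AlignmentHandle:
    """Read an alignment from FASTA, ClustalW (``clustal``) or PIR.

    ClustalW blocks are concatenated per sequence; ragged blocks raise
    :class:`SequenceError`.
    """
    if fmt == "clustal":
        try:
            aln = AlignIO.read(str(path), "clustal")
        except (ValueError, AssertionError) as exc:
            raise SequenceError(f"malformed ClustalW file: {exc}") from exc
        seqs = [SequenceHandle(r.id, str(r.seq)) for r in aln]
    elif fmt in ("fasta", "pir"):
        seqs = list(read_sequences(path, fmt))
    else:
        raise SequenceError(f"unsupported alignment format {fmt!r}")
    _check_unique(s.name for s in seqs)
    return AlignmentHandle(seqs)


def write_alignment(aln: AlignmentHandle, path, fmt: str = "fasta") -> None:
    write_sequences(aln, path, fmt)
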