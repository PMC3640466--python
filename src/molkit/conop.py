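"""Connectivity and topology: rule-based and heuristic bond builders.

The rule-based builder connects atoms according to per-residue bond tables
from a compound library (the bundled one covers the 20 standard amino acids,
the 8 standard nucleotides, water and haem).  Deviations from the library —
unknown residues, unknown or missing atoms — are collected as diagnostics
and, under strict processing, raised as errors.  The heuristic builder is a
quick-and-dirty alternative for structures with loose naming conventions:
known residues go through the same lookup tables, anything else is connected
whenever the interatomic distance does not exceed the sum of covalent radii
plus a tolerance, with hydrogens limited to a single bond.

Inter-residue links use a distance criterion: a peptide bond C(i)–N(i+1) or
a phosphodiester bond O3'(i)–P(i+1) is created between consecutive residues
of a chain when the distance is at most ``INTER_RESIDUE_CUTOFF`` (2.5 Å).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .mol import Atom, Entity

__all__ = [
    "CompoundEntry",
    "CompoundLibrary",
    "Diagnostic",
    "Diagnostics",
    "ConopError",
    "load_compound_library",
    "default_compound_library",
    "rule_based_process",
    "heuristic_process",
    "COVALENT_RADII",
    "COVALENT_TOLERANCE",
    "INTER_RESIDUE_CUTOFF",
]

# Conventional single-bond covalent radii (Å); the default covers anything
# exotic generously so the heuristic over- rather than under-connects.
COVALENT_RADII = {
    "H": 0.31, "C": 0.77, "N": 0.71, "O": 0.66,
    "S": 1.05, "P": 1.07, "FE": 1.32,
}
DEFAULT_COVALENT_RADIUS = 1.5
COVALENT_TOLERANCE = 0.4
INTER_RESIDUE_CUTOFF = 2.5


class ConopError(Exception):
    """Malformed compound library, or strict processing hit an unknown."""


@dataclass(frozen=True)
class CompoundEntry:
    name: str
    one_letter: str
    chem_class: str            # amino_acid | nucleotide | ligand | water
    atoms: dict                # atom name -> element
    bonds: tuple               # ((name_a, name_b), ...)


class CompoundLibrary:
    def __init__(self, entries: dict[str, CompoundEntry]):
        self.entries = entries

    def get(self, residue_name: str) -> Optional[CompoundEntry]:
        return self.entries.get(residue_name)

    def __contains__(self, residue_name: str) -> bool:
        return residue_name in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Diagnostic:
    severity: str              # warning | error
    residue: str               # residue locator, e.g. "A.ALA1"
    kind: str                  # unknown_residue | unknown_atom | missing_atom
    message: str


@dataclass
class Diagnostics:
    records: list = field(default_factory=list)

    def add(self, severity, residue, kind, message):
        self.records.append(Diagnostic(severity, residue, kind, message))

    def of_kind(self, kind: str) -> list:
        return [r for r in self.records if r.kind == kind]

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def load_compound_library(path) -> CompoundLibrary:
    """Load a compound library from the repo's JSON table format.

    The format is a JSON object mapping 3-letter residue codes to entries
    with ``one_letter``, ``chem_class``, ``atoms`` (name → element) and
    ``bonds`` (pairs of declared atom names).  A bond referencing an
    undeclared atom is a load error; an empty object is a valid empty
    library.
    """
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConopError(f"cannot load compound library {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConopError("compound library must be a JSON object")
    entries = {}
    for code, entry in raw.items():
        try:
            atoms = dict(entry["atoms"])
            bonds = tuple((a, b) for a, b in entry["bonds"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConopError(f"malformed entry {code!r}: {exc}") from exc
        for a, b in bonds:
            if a not in atoms or b not in atoms:
                raise ConopError(
                    f"entry {code!r}: bond {a}-{b} references undeclared atom")
        entries[code] = CompoundEntry(
            code, entry.get("one_letter", "X"),
            entry.get("chem_class", "ligand"), atoms, bonds)
    return CompoundLibrary(entries)


_DEFAULT_LIB: Optional[CompoundLibrary] = None


def default_compound_library() -> CompoundLibrary:
    """The bundled library (standard amino acids, nucleotides, HOH, HEM)."""
    global _DEFAULT_LIB
    if _DEFAULT_LIB is None:
        path = resources.files("molkit.data") / "compounds.json"
        _DEFAULT_LIB = load_compound_library(path)
    return _DEFAULT_LIB


def _dist(a: Atom, b: Atom) -> float:
    d = a.pos - b.pos
    return float(np.sqrt(d @ d))


def rule_based_process(entity: Entity, library: Optional[CompoundLibrary] = None,
                       strict: bool = False) -> Diagnostics:
    """Derive bonds and residue metadata from library rules; mutates the entity.

    Intra-residue bonds are exactly the library's bond list restricted to
    the atoms actually present; consecutive residues get a peptide or
    phosphodiester bond when the distance criterion holds.  One-letter codes
    and chemical classes are assigned from the library.  With ``strict``,
    the first unknown residue or unknown atom raises :class:`ConopError`;
    otherwise unknowns stay unbonded and are reported as diagnostics.
    Idempotent: re-running adds no bonds and repeats the same diagnostics.
    """
    if library is None:
        library = default_compound_library()
    diags = Diagnostics()
    for chain in entity.chains:
        for res in chain.residues:
            entry = library.get(res.name)
            if entry is None:
                msg = f"unknown residue {res.name!r}"
                if strict:
                    raise ConopError(f"{res.qualified_name}: {msg}")
                diags.add("warning", res.qualified_name, "unknown_residue", msg)
                continue
            res.one_letter_code = entry.one_letter
            res.chem_class = entry.chem_class
            res.is_protein = entry.chem_class == "amino_acid"
            present = {a.name: a for a in res.atoms}
            for a in res.atoms:
                if a.name not in entry.atoms:
                    msg = f"unknown atom {a.name!r} in {res.name}"
                    if strict:
                        raise ConopError(f"{res.qualified_name}: {msg}")
                    diags.add("warning", res.qualified_name, "unknown_atom", msg)
                elif not a.element:
                    a.element = entry.atoms[a.name]
            for name, _elem in entry.atoms.items():
                # terminal/alternative atoms are legitimately absent
                if name not in present and name not in ("OXT", "OP1", "OP2", "P"):
                    diags.add("warning", res.qualified_name, "missing_atom",
                              f"missing atom {name!r} of {res.name}")
            for a_name, b_name in entry.bonds:
                a, b = present.get(a_name), present.get(b_name)
                if a is not None and b is not None:
                    entity.connect(a, b)
        # inter-residue links between consecutive residues in list order
        for prev, nxt in zip(chain.residues, chain.residues[1:]):
            _link_consecutive(entity, library, prev, nxt)
    return diags


def _link_consecutive(entity, library, prev, nxt) -> None:
    e_prev, e_nxt = library.get(prev.name), library.get(nxt.name)
    if e_prev is None or e_nxt is None:
        return
    if e_prev.chem_class == "amino_acid" and e_nxt.chem_class == "amino_acid":
        pair = (prev.find_atom("C"), nxt.find_atom("N"))
    elif e_prev.chem_class == "nucleotide" and e_nxt.chem_class == "nucleotide":
        pair = (prev.find_atom("O3'"), nxt.find_atom("P"))
    else:
        return
    a, b = pair
    if a is not None and b is not None and _dist(a, b) <= INTER_RESIDUE_CUTOFF:
        entity.connect(a, b)


def covalent_radius(element: str) -> float:
    return COVALENT_RADII.get(element.upper(), DEFAULT_COVALENT_RADIUS)


def heuristic_process(entity: Entity,
                      library: Optional[CompoundLibrary] = None) -> Entity:
    """Best-effort connectivity without diagnostics; mutates and returns entity.

    Residues known to the lookup tables are bonded exactly like in
    :func:`rule_based_process`; all other residues fall back to the
    distance rule ``|a-b| ≤ r_cov(a) + r_cov(b) + 0.4 Å`` over all atom
    pairs, with each hydrogen restricted to one bond (its nearest heavy
    atom within range).
    """
    if library is None:
        library = default_compound_library()
    for chain in entity.chains:
        for res in chain.residues:
            entry = library.get(res.name)
            if entry is not None:
                present = {a.name: a for a in res.atoms}
                res.one_letter_code = entry.one_letter
                res.chem_class = entry.chem_class
                res.is_protein = entry.chem_class == "amino_acid"
                for a in res.atoms:
                    if not a.element and a.name in entry.atoms:
                        a.element = entry.atoms[a.name]
                for a_name, b_name in entry.bonds:
                    a, b = present.get(a_name), present.get(b_name)
                    if a is not None and b is not None:
                        entity.connect(a, b)
            else:
                _distance_connect(entity, res.atoms)
        for prev, nxt in zip(chain.residues, chain.residues[1:]):
            _link_consecutive(entity, library, prev, nxt)
    return entity


def _distance_connect(entity: Entity, atoms) -> None:
    from .mol import SpatialGrid, _guess_element

    for a in atoms:
        if not a.element:
            a.element = _guess_element(a.name)
    heavy = [a for a in atoms if a.element.upper() != "H"]
    max_reach = 2.0 * max((covalent_radius(a.element) for a in atoms),
                          default=1.0) + COVALENT_TOLERANCE
    grid = SpatialGrid(heavy, max_reach)
    for a in atoms:
        limit_a = covalent_radius(a.element)
        if a.element.upper() == "H":
            # one bond only: nearest heavy atom within range
            best, best_d = None, None
            for b in grid.query(a.pos, max_reach):
                d = _dist(a, b)
                if d <= limit_a + covalent_radius(b.element) + COVALENT_TOLERANCE:
                    if best is None or d < best_d:
                        best, best_d = b, d
            if best is not None:
                entity.connect(a, best)
            continue
        for b in grid.query(a.pos, max_reach):
            if b is a or id(b) < id(a):   # emit each heavy pair once
                continue
            if _dist(a, b) <= limit_a + covalent_radius(b.element) + COVALENT_TOLERANCE:
                entity.connect(a, b)
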