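"""Molecular entity data model: handles, views, generic properties, spatial search.

A molecular structure is owned by a single :class:`Entity` (the *handle*),
organised as a tree of chains, residues and atoms, with bonds stored at the
entity level.  An :class:`EntityView` is a non-copying subset of a handle: it
holds references into the handle hierarchy, so coordinate changes on the
handle are immediately visible through every view.  Deleting handle atoms
invalidates dependent views; this is enforced with a generation counter.

Positions are in ångströms in a right-handed Cartesian frame.  Residue
numbers follow PDB convention (1-based, may be negative, insertion codes
honoured).  Generic-property keys are case-sensitive and values are strictly
typed: reading a key through the wrong typed accessor raises, no silent
coercion.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Entity",
    "Chain",
    "Residue",
    "Atom",
    "Bond",
    "EntityView",
    "ChainView",
    "ResidueView",
    "AtomView",
    "GenericPropError",
    "StaleViewError",
    "build_entity",
    "create_view",
    "find_within",
]


class GenericPropError(Exception):
    """Missing generic-property key or typed-accessor mismatch."""


class StaleViewError(Exception):
    """The underlying entity was structurally modified after view creation."""


_MISSING = object()

_PROP_TYPES = (str, float, int, bool)


class GenericPropContainer:
    """Typed key-value annotations shared by all structural elements.

    Values are restricted to ``str``/``float``/``int``/``bool``.  ``bool`` is
    checked before ``int`` so the two never alias.
    """

    __slots__ = ("_props",)

    def __init__(self):
        self._props: dict[str, object] = {}

    def set_prop(self, key: str, value) -> None:
        if not isinstance(key, str):
            raise GenericPropError("property keys must be strings")
        if not isinstance(value, _PROP_TYPES) or isinstance(value, type):
            raise GenericPropError(
                f"unsupported property type {type(value).__name__!r} for key {key!r}"
            )
        self._props[key] = value

    def get_prop(self, key: str, default=_MISSING):
        try:
            return self._props[key]
        except KeyError:
            if default is _MISSING:
                raise GenericPropError(f"no generic property {key!r}") from None
            return default

    def has_prop(self, key: str) -> bool:
        return key in self._props

    def _get_typed(self, key: str, typ, type_name: str, default):
        if key not in self._props:
            if default is _MISSING:
                raise GenericPropError(f"no generic property {key!r}")
            return default
        value = self._props[key]
        if typ is bool or typ is int:
            ok = type(value) is typ
        else:
            ok = isinstance(value, typ) and type(value) is not bool
        if not ok:
            raise GenericPropError(
                f"property {key!r} holds {type(value).__name__}, not {type_name}"
            )
        return value

    def get_float(self, key: str, default=_MISSING) -> float:
        # ints are not silently widened to float
        return self._get_typed(key, float, "float", default)

    def get_int(self, key: str, default=_MISSING) -> int:
        return self._get_typed(key, int, "int", default)

    def get_str(self, key: str, default=_MISSING) -> str:
        return self._get_typed(key, str, "str", default)

    def get_bool(self, key: str, default=_MISSING) -> bool:
        return self._get_typed(key, bool, "bool", default)

    @property
    def prop_keys(self):
        return self._props.keys()


class Atom(GenericPropContainer):
    __slots__ = (
        "name", "element", "_pos", "occupancy", "b_factor", "aniso_b",
        "charge", "is_hetatm", "residue",
    )

    def __init__(self, name: str, element: str = "", pos=(0.0, 0.0, 0.0),
                 occupancy: float = 1.0, b_factor: float = 0.0,
                 aniso_b=None, charge: float = 0.0, is_hetatm: bool = False):
        super().__init__()
        pos = np.asarray(pos, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {name!r}: position must be a finite 3-vector")
        self.name = name
        self.element = element
        self._pos = pos
        self.occupancy = float(occupancy)
        self.b_factor = float(b_factor)
        self.aniso_b = None if aniso_b is None else np.asarray(aniso_b, dtype=float)
        self.charge = float(charge)
        self.is_hetatm = bool(is_hetatm)
        self.residue: Optional[Residue] = None

    @property
    def pos(self) -> np.ndarray:
        return self._pos

    @pos.setter
    def pos(self, value) -> None:
        value = np.asarray(value, dtype=float)
        if value.shape != (3,) or not np.all(np.isfinite(value)):
            raise ValueError("position must be a finite 3-vector")
        self._pos = value

    @property
    def qualified_name(self) -> str:
        res = self.residue
        if res is None:
            return self.name
        return f"{res.qualified_name}.{self.name}"

    @property
    def bonds(self) -> list["Bond"]:
        ent = self.entity
        if ent is None:
            return []
        return [b for b in ent.bonds if b.atom_a is self or b.atom_b is self]

    @property
    def entity(self) -> Optional["Entity"]:
        if self.residue is None or self.residue.chain is None:
            return None
        return self.residue.chain.entity

    def __repr__(self):
        return f"<Atom {self.qualified_name}>"


class Residue(GenericPropContainer):
    __slots__ = ("name", "number", "insertion_code", "one_letter_code",
                 "is_protein", "chem_class", "atoms", "chain")

    def __init__(self, name: str, number: int, insertion_code: str = "",
                 one_letter_code: str = "X", is_protein: bool = False):
        super().__init__()
        if len(insertion_code) > 1:
            raise ValueError("insertion code is a single character or empty")
        self.name = name
        self.number = int(number)
        self.insertion_code = insertion_code
        self.one_letter_code = one_letter_code
        self.is_protein = bool(is_protein)
        self.chem_class: str = "unknown"
        self.atoms: list[Atom] = []
        self.chain: Optional[Chain] = None

    @property
    def num_key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    @property
    def qualified_name(self) -> str:
        cname = self.chain.name if self.chain is not None else "?"
        return f"{cname}.{self.name}{self.number}{self.insertion_code}"

    def add_atom(self, atom: Atom) -> Atom:
        if any(a.name == atom.name for a in self.atoms):
            raise ValueError(
                f"duplicate atom name {atom.name!r} in residue {self.qualified_name}")
        atom.residue = self
        self.atoms.append(atom)
        return atom

    def find_atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __repr__(self):
        return f"<Residue {self.qualified_name}>"


class Chain(GenericPropContainer):
    __slots__ = ("name", "residues", "entity")

    def __init__(self, name: str):
        super().__init__()
        self.name = name
        self.residues: list[Residue] = []
        self.entity: Optional[Entity] = None

    def add_residue(self, residue: Residue) -> Residue:
        if any(r.num_key == residue.num_key for r in self.residues):
            raise ValueError(
                f"duplicate residue number {residue.number}{residue.insertion_code!r} "
                f"in chain {self.name!r}")
        residue.chain = self
        self.residues.append(residue)
        return residue

    def find_residue(self, number: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        return None

    @property
    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    def __repr__(self):
        return f"<Chain {self.name}>"


class Bond:
    __slots__ = ("atom_a", "atom_b", "order")

    def __init__(self, atom_a: Atom, atom_b: Atom, order: int = 1):
        if atom_a is atom_b:
            raise ValueError("a bond needs two distinct atoms")
        self.atom_a = atom_a
        self.atom_b = atom_b
        self.order = int(order)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.atom_a.pos - self.atom_b.pos))

    def key(self) -> frozenset:
        return frozenset((id(self.atom_a), id(self.atom_b)))

    def __repr__(self):
        return f"<Bond {self.atom_a.qualified_name}-{self.atom_b.qualified_name}>"


class Entity(GenericPropContainer):
    """Root handle owning the chain/residue/atom tree and the bond list."""

    __slots__ = ("name", "chains", "bonds", "_bond_keys", "_generation")

    def __init__(self, name: str = ""):
        super().__init__()
        self.name = name
        self.chains: list[Chain] = []
        self.bonds: list[Bond] = []
        self._bond_keys: set[frozenset] = set()
        self._generation = 0

    # -- construction -----------------------------------------------------

    def add_chain(self, name: str) -> Chain:
        if any(c.name == name for c in self.chains):
            raise ValueError(f"duplicate chain name {name!r}")
        chain = Chain(name)
        chain.entity = self
        self.chains.append(chain)
        return chain

    def find_chain(self, name: str) -> Optional[Chain]:
        for c in self.chains:
            if c.name == name:
                return c
        return None

    def connect(self, atom_a: Atom, atom_b: Atom, order: int = 1) -> Optional[Bond]:
        """Add a bond; no-op if the unordered pair is already bonded."""
        if atom_a.entity is not self or atom_b.entity is not self:
            raise ValueError("both bond endpoints must belong to this entity")
        bond = Bond(atom_a, atom_b, order)
        k = bond.key()
        if k in self._bond_keys:
            return None
        self._bond_keys.add(k)
        self.bonds.append(bond)
        return bond

    def delete_bonds(self) -> None:
        self.bonds.clear()
        self._bond_keys.clear()

    def delete_atoms(self, atoms: Iterable[Atom]) -> None:
        """Remove atoms (and their bonds); bumps the generation counter,
        invalidating all existing views."""
        doomed = set(map(id, atoms))
        if not doomed:
            return
        for chain in self.chains:
            for res in chain.residues:
                res.atoms = [a for a in res.atoms if id(a) not in doomed]
        self.bonds = [b for b in self.bonds
                      if id(b.atom_a) not in doomed and id(b.atom_b) not in doomed]
        self._bond_keys = {b.key() for b in self.bonds}
        self._generation += 1

    # -- traversal --------------------------------------------------------

    @property
    def residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    @property
    def atoms(self) -> Iterator[Atom]:
        for c in self.chains:
            for r in c.residues:
                yield from r.atoms

    @property
    def atom_count(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    @property
    def residue_count(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def chain_count(self) -> int:
        return len(self.chains)

    @property
    def bond_count(self) -> int:
        return len(self.bonds)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def handle(self) -> "Entity":
        return self

    def __repr__(self):
        return (f"<Entity {self.name!r}: {self.chain_count} chains, "
                f"{self.residue_count} residues, {self.atom_count} atoms>")


# ---------------------------------------------------------------------------
# Views
# ---------------------------------------------------------------------------

class _ViewElement:
    """Mixin delegating generic properties to the wrapped handle element."""

    __slots__ = ()

    @property
    def handle(self):
        return self._handle

    def set_prop(self, key, value):
        self._handle.set_prop(key, value)

    def get_prop(self, key, default=_MISSING):
        return self._handle.get_prop(key, default)

    def has_prop(self, key):
        return self._handle.has_prop(key)

    def get_float(self, key, default=_MISSING):
        return self._handle.get_float(key, default)

    def get_int(self, key, default=_MISSING):
        return self._handle.get_int(key, default)

    def get_str(self, key, default=_MISSING):
        return self._handle.get_str(key, default)

    def get_bool(self, key, default=_MISSING):
        return self._handle.get_bool(key, default)


class AtomView(_ViewElement):
    __slots__ = ("_handle", "residue_view", "_root")

    def __init__(self, handle: Atom, residue_view: "ResidueView", root: "EntityView"):
        self._handle = handle
        self.residue_view = residue_view
        self._root = root

    def _check(self):
        self._root._check_fresh()

    @property
    def pos(self) -> np.ndarray:
        self._check()
        return self._handle.pos

    @property
    def name(self):
        return self._handle.name

    @property
    def element(self):
        return self._handle.element

    @property
    def occupancy(self):
        return self._handle.occupancy

    @property
    def b_factor(self):
        return self._handle.b_factor

    @property
    def charge(self):
        return self._handle.charge

    @property
    def is_hetatm(self):
        return self._handle.is_hetatm

    @property
    def qualified_name(self):
        return self._handle.qualified_name

    def __repr__(self):
        return f"<AtomView {self._handle.qualified_name}>"


class ResidueView(_ViewElement):
    __slots__ = ("_handle", "chain_view", "atoms")

    def __init__(self, handle: Residue, chain_view: "ChainView"):
        self._handle = handle
        self.chain_view = chain_view
        self.atoms: list[AtomView] = []

    @property
    def name(self):
        return self._handle.name

    @property
    def number(self):
        return self._handle.number

    @property
    def insertion_code(self):
        return self._handle.insertion_code

    @property
    def one_letter_code(self):
        return self._handle.one_letter_code

    @property
    def is_protein(self):
        return self._handle.is_protein

    @property
    def qualified_name(self):
        return self._handle.qualified_name

    def find_atom(self, name: str) -> Optional[AtomView]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __repr__(self):
        return f"<ResidueView {self._handle.qualified_name}>"


class ChainView(_ViewElement):
    __slots__ = ("_handle", "residues")

    def __init__(self, handle: Chain):
        self._handle = handle
        self.residues: list[ResidueView] = []

    @property
    def name(self):
        return self._handle.name

    def __repr__(self):
        return f"<ChainView {self._handle.name}>"


class EntityView(_ViewElement):
    """Subset of an entity referencing (not copying) handle data.

    Invariants: every view atom's parent residue is in the view, every view
    residue's parent chain is in the view, and a bond is included only when
    both endpoint atoms are.  The view is tied to the handle's structural
    generation: deleting handle atoms makes the view stale.
    """

    __slots__ = ("_handle", "chains", "bonds", "_atom_ids", "_generation")

    def __init__(self, handle: Entity):
        self._handle = handle
        self.chains: list[ChainView] = []
        self.bonds: list[Bond] = []
        self._atom_ids: set[int] = set()
        self._generation = handle._generation

    def _check_fresh(self):
        if self._generation != self._handle._generation:
            raise StaleViewError(
                "the underlying entity was structurally modified; recreate the view")

    # -- traversal --------------------------------------------------------

    @property
    def entity(self) -> Entity:
        return self._handle

    @property
    def residues(self) -> Iterator[ResidueView]:
        self._check_fresh()
        for c in self.chains:
            yield from c.residues

    @property
    def atoms(self) -> Iterator[AtomView]:
        self._check_fresh()
        for c in self.chains:
            for r in c.residues:
                yield from r.atoms

    @property
    def atom_count(self) -> int:
        return len(self._atom_ids)

    @property
    def residue_count(self) -> int:
        self._check_fresh()
        return sum(len(c.residues) for c in self.chains)

    @property
    def chain_count(self) -> int:
        return len(self.chains)

    @property
    def bond_count(self) -> int:
        return len(self.bonds)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float).reshape(-1, 3)

    def handle_atoms(self) -> Iterator[Atom]:
        for a in self.atoms:
            yield a.handle

    def contains_atom(self, atom: Atom) -> bool:
        return id(atom) in self._atom_ids

    def find_chain(self, name: str) -> Optional[ChainView]:
        for c in self.chains:
            if c.name == name:
                return c
        return None

    def __repr__(self):
        return (f"<EntityView of {self._handle.name!r}: {self.chain_count} chains, "
                f"{self.residue_count} residues, {self.atom_count} atoms>")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_entity(spec, name: str = "") -> Entity:
    """Construct an entity from a nested chain/residue/atom description.

    ``spec`` is a sequence of chain dicts::

        [{"name": "A",
          "residues": [{"name": "ALA", "number": 1, "insertion_code": "",
                        "one_letter_code": "A",
                        "atoms": [{"name": "CA", "element": "C",
                                   "pos": (0, 0, 0), ...}, ...]}, ...]}, ...]

    Bonds are left empty; connectivity is derived afterwards (see
    :mod:`molkit.conop`).  Uniqueness invariants are enforced and violations
    raise ``ValueError``.
    """
    ent = Entity(name)
    for cspec in spec:
        chain = ent.add_chain(cspec["name"])
        for rspec in cspec.get("residues", ()):
            res = Residue(
                rspec["name"], rspec["number"],
                rspec.get("insertion_code", ""),
                rspec.get("one_letter_code", "X"),
                rspec.get("is_protein", False),
            )
            chain.add_residue(res)
            for aspec in rspec.get("atoms", ()):
                res.add_atom(Atom(
                    aspec["name"],
                    aspec.get("element", _guess_element(aspec["name"])),
                    aspec.get("pos", (0.0, 0.0, 0.0)),
                    aspec.get("occupancy", 1.0),
                    aspec.get("b_factor", 0.0),
                    aspec.get("aniso_b"),
                    aspec.get("charge", 0.0),
                    aspec.get("is_hetatm", False),
                ))
    return ent


def _guess_element(atom_name: str) -> str:
    """Leading alphabetic characters of a PDB-style atom name."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if len(stripped) >= 2 and stripped[:2].upper() in ("FE", "CL", "BR", "ZN",
                                                       "MG", "MN", "NA", "CU"):
        return stripped[:2].upper()
    return stripped[0].upper()


def create_view(entity, atoms: Iterable) -> EntityView:
    """Build the minimal view of ``entity`` containing exactly ``atoms``.

    ``atoms`` may contain :class:`Atom` handles or :class:`AtomView` items;
    parents are pulled in automatically and bonds are kept iff both endpoints
    are included.  Atoms from a different entity raise ``ValueError``.
    """
    handle = entity.handle if isinstance(entity, EntityView) else entity
    atom_handles: list[Atom] = []
    seen: set[int] = set()
    for a in atoms:
        h = a.handle if isinstance(a, AtomView) else a
        if h.entity is not handle:
            raise ValueError(f"atom {h!r} does not belong to entity {handle.name!r}")
        if id(h) not in seen:
            seen.add(id(h))
            atom_handles.append(h)

    view = EntityView(handle)
    view._atom_ids = seen
    chain_views: dict[int, ChainView] = {}
    res_views: dict[int, ResidueView] = {}
    # iterate in handle order so view order is deterministic
    for chain in handle.chains:
        cv = None
        for res in chain.residues:
            rv = None
            for atom in res.atoms:
                if id(atom) not in seen:
                    continue
                if cv is None:
                    cv = ChainView(chain)
                    chain_views[id(chain)] = cv
                    view.chains.append(cv)
                if rv is None:
                    rv = ResidueView(res, cv)
                    res_views[id(res)] = rv
                    cv.residues.append(rv)
                rv.atoms.append(AtomView(atom, rv, view))
    view.bonds = [b for b in handle.bonds
                  if id(b.atom_a) in seen and id(b.atom_b) in seen]
    return view


def view_from_residues(entity, residues: Iterable) -> EntityView:
    """View containing all atoms of the given residues."""
    atoms = []
    for r in residues:
        rh = r.handle if isinstance(r, ResidueView) else r
        atoms.extend(rh.atoms)
    return create_view(entity, atoms)


# ---------------------------------------------------------------------------
# Spatial search
# ---------------------------------------------------------------------------

class SpatialGrid:
    """Uniform-grid binning of atoms; cell size equals the query radius."""

    def __init__(self, atoms: Sequence[Atom], cell: float):
        self.cell = max(cell, 1e-6)
        self.cells: dict[tuple[int, int, int], list[Atom]] = {}
        for a in atoms:
            key = tuple(int(math.floor(c / self.cell)) for c in a.pos)
            self.cells.setdefault(key, []).append(a)

    def query(self, center, radius: float) -> list[Atom]:
        center = np.asarray(center, dtype=float)
        r2 = radius * radius
        lo = [int(math.floor((c - radius) / self.cell)) for c in center]
        hi = [int(math.floor((c + radius) / self.cell)) for c in center]
        out = []
        for i in range(lo[0], hi[0] + 1):
            for j in range(lo[1], hi[1] + 1):
                for k in range(lo[2], hi[2] + 1):
                    for a in self.cells.get((i, j, k), ()):
                        d = a.pos - center
                        if float(d @ d) <= r2:
                            out.append(a)
        return out


def find_within(entity_or_view, center, radius: float) -> set[Atom]:
    """Atoms of ``entity_or_view`` within ``radius`` Å of ``center``.

    The contract is exhaustive (Euclidean distance ≤ radius); the
    implementation bins atoms on a uniform grid with the radius as cell size.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if isinstance(entity_or_view, EntityView):
        atoms = [a.handle for a in entity_or_view.atoms]
    else:
        atoms = list(entity_or_view.atoms)
    grid = SpatialGrid(atoms, radius if radius > 0 else 1.0)
    return set(grid.query(center, radius))
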