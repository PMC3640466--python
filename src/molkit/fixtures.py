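"""Synthetic fixtures: ideal helices, random entities, trajectories, maps.

Everything the test surface needs is generated deterministically from a
seed — no downloads, no bundled binaries.  The helix builder places an
ideal poly-alanine α-helix (rise 1.5 Å, 100°/residue, i.e. backbone
torsions φ = −57°, ψ = −47°, ω = 180°) from standard internal coordinates;
trajectories are written as CHARMM DCD files with either an analytic
sinusoidal rigid translation (closed-form centroid for oracle tests) or a
Brownian walk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mol import Atom, Entity, Residue
from .structio import write_dcd

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "make_polyala_helix",
    "make_dipeptide",
    "make_point_cloud",
    "make_random_entity",
    "make_trajectory",
    "TrajectoryDescriptor",
    "random_query",
]


@dataclass(frozen=True)
class FixtureSpec:
    kind: str            # helix | dipeptide | point_cloud | trajectory | density
    n: int = 10
    seed: int = 0
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("fixture size n must be >= 1")


# ideal backbone internal coordinates (Å, degrees)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
         "CA-CB": 1.521}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
          "CA-C-O": 120.8, "C-CA-CB": 110.1}
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF: position of atom D given A-B-C, |CD|, angle BCD, torsion ABCD."""
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_polyala_helix(n_residues: int, seed: int = 0,
                       noise_sigma: float = 0.0, chain_name: str = "A") -> Entity:
    """Ideal poly-ALA α-helix: chain A, N/CA/C/O/CB per residue.

    Deterministic per seed; ``noise_sigma`` adds isotropic Gaussian jitter.
    Consecutive Cα–Cα distances come out at ≈3.8 Å and the C(i)–N(i+1)
    distance at 1.33 Å, so rule-based processing finds n−1 peptide bonds.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    ent = Entity("polyala_helix")
    chain = ent.add_chain(chain_name)
    prev = None        # (N, CA, C) coordinates of the previous residue
    for i in range(n_residues):
        if prev is None:
            n_pos = np.zeros(3)
            ca_pos = np.array([_BOND["N-CA"], 0.0, 0.0])
            ang = np.deg2rad(_ANGLE["N-CA-C"])
            c_pos = ca_pos + _BOND["CA-C"] * np.array(
                [-np.cos(ang), np.sin(ang), 0.0])
        else:
            n_prev, ca_prev, c_prev = prev
            n_pos = _place(n_prev, ca_prev, c_prev,
                           _BOND["C-N"], _ANGLE["CA-C-N"], _PSI)
            ca_pos = _place(ca_prev, c_prev, n_pos,
                            _BOND["N-CA"], _ANGLE["C-N-CA"], _OMEGA)
            c_pos = _place(c_prev, n_pos, ca_pos,
                           _BOND["CA-C"], _ANGLE["N-CA-C"], _PHI)
        o_pos = _place(n_pos, ca_pos, c_pos,
                       _BOND["C-O"], _ANGLE["CA-C-O"], _PSI + 180.0)
        cb_pos = _place(n_pos, c_pos, ca_pos,
                        _BOND["CA-CB"], _ANGLE["C-CA-CB"], 122.6)
        res = chain.add_residue(Residue("ALA", i + 1, one_letter_code="A",
                                        is_protein=True))
        for name, pos in (("N", n_pos), ("CA", ca_pos), ("C", c_pos),
                          ("O", o_pos), ("CB", cb_pos)):
            res.add_atom(Atom(name, name[0], pos))
        prev = (n_pos, ca_pos, c_pos)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        for atom in ent.atoms:
            atom.pos = atom.pos + rng.normal(0.0, noise_sigma, 3)
    return ent


def make_dipeptide(seed: int = 0) -> Entity:
    """ALA–GLY dipeptide with ideal geometry (from the helix builder)."""
    ent = make_polyala_helix(2, seed)
    res2 = ent.chains[0].residues[1]
    res2.name = "GLY"
    res2.one_letter_code = "G"
    cb = res2.find_atom("CB")
    ent.delete_atoms([cb])
    return ent


_ELEMENTS = ("C", "N", "O", "S", "FE")


def make_point_cloud(n_atoms: int, seed: int = 0, box: float = 20.0,
                     res_name: str = "UNK") -> Entity:
    """Unknown-residue point cloud for heuristic-connectivity tests."""
    rng = np.random.default_rng(seed)
    ent = Entity("cloud")
    chain = ent.add_chain("A")
    res = chain.add_residue(Residue(res_name, 1))
    for i in range(n_atoms):
        elem = _ELEMENTS[rng.integers(len(_ELEMENTS))]
        res.add_atom(Atom(f"{elem}{i + 1}", elem, rng.uniform(0.0, box, 3)))
    return ent


_RES_POOL = (
    ("ALA", "A", False), ("GLY", "G", False), ("SER", "S", False),
    ("HOH", "X", True), ("HEM", "X", True), ("LIG", "X", True),
)
_ATOM_POOL = ("N", "CA", "C", "O", "CB", "OG", "FE", "S1")


def make_random_entity(seed: int = 0, n_chains: int = 2, n_residues: int = 8,
                       n_atoms: int = 4, box: float = 30.0,
                       with_props: bool = True) -> Entity:
    """Random entity exercising every queryable property.

    Chains A, B, …; residue names drawn from a pool that mixes polymer and
    hetero compounds; occupancies, B factors, charges and a few generic
    properties (``ga:score``, ``gr:conservation``, ``gc:weight``) are
    randomised so selection oracles have something to chew on.
    """
    rng = np.random.default_rng(seed)
    ent = Entity(f"random{seed}")
    for ci in range(n_chains):
        chain = ent.add_chain(chr(ord("A") + ci))
        if with_props and rng.random() < 0.7:
            chain.set_prop("weight", float(np.round(rng.random(), 3)))
        for ri in range(n_residues):
            name, olc, het = _RES_POOL[rng.integers(len(_RES_POOL))]
            res = chain.add_residue(
                Residue(name, ri + 1, one_letter_code=olc, is_protein=not het))
            if with_props and rng.random() < 0.5:
                res.set_prop("conservation", float(np.round(rng.random(), 3)))
            k = int(rng.integers(1, n_atoms + 1))
            used = rng.permutation(len(_ATOM_POOL))[:k]
            for ai in used:
                aname = _ATOM_POOL[ai]
                atom = res.add_atom(Atom(
                    aname, aname[0] if aname != "FE" else "FE",
                    rng.uniform(0.0, box, 3),
                    occupancy=float(np.round(rng.uniform(0.2, 1.0), 2)),
                    b_factor=float(np.round(rng.uniform(5.0, 80.0), 2)),
                    charge=float(rng.integers(-1, 2)),
                    is_hetatm=het))
                if with_props and rng.random() < 0.4:
                    atom.set_prop("score", float(np.round(rng.random(), 3)))
    return ent


@dataclass(frozen=True)
class TrajectoryDescriptor:
    """Closed-form description of a generated trajectory."""
    motion: str
    n_frames: int
    amplitude: float
    base_centroid: tuple

    def centroid(self, frame: int) -> np.ndarray:
        """Analytic centroid of a sinusoid trajectory at a frame index."""
        if self.motion != "sinusoid":
            raise ValueError("closed-form centroid only for sinusoid motion")
        dx = self.amplitude * np.sin(2.0 * np.pi * frame / self.n_frames)
        return np.asarray(self.base_centroid) + np.array([dx, 0.0, 0.0])


def make_trajectory(entity: Entity, n_frames: int, path,
                    motion: str = "sinusoid", seed: int = 0,
                    amplitude: float = 1.0) -> TrajectoryDescriptor:
    """Write a DCD for ``entity``; sinusoid mode is a rigid x-translation
    with analytic per-frame centroid, brownian mode a seeded random walk."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    base = entity.positions
    frames = np.empty((n_frames, base.shape[0], 3), dtype=np.float32)
    if motion == "sinusoid":
        for t in range(n_frames):
            dx = amplitude * np.sin(2.0 * np.pi * t / n_frames)
            frames[t] = base + np.array([dx, 0.0, 0.0])
    elif motion == "brownian":
        rng = np.random.default_rng(seed)
        coords = base.copy()
        for t in range(n_frames):
            coords = coords + rng.normal(0.0, 0.1, coords.shape)
            frames[t] = coords
    else:
        raise ValueError(f"unknown motion {motion!r}")
    write_dcd(path, frames)
    return TrajectoryDescriptor(motion, n_frames, amplitude,
                                tuple(base.mean(axis=0)))


def make_fixture(spec: FixtureSpec, path=None):
    """Dispatch on :class:`FixtureSpec`; trajectory/density need helpers."""
    if spec.kind == "helix":
        return make_polyala_helix(spec.n, spec.seed, spec.noise_sigma)
    if spec.kind == "dipeptide":
        return make_dipeptide(spec.seed)
    if spec.kind == "point_cloud":
        return make_point_cloud(spec.n, spec.seed)
    if spec.kind == "trajectory":
        ent = make_polyala_helix(max(spec.n // 10, 2), spec.seed)
        if path is None:
            raise ValueError("trajectory fixture needs an output path")
        return make_trajectory(ent, spec.n, path, seed=spec.seed)
    if spec.kind == "density":
        from .img import DensityParams, entity_to_density
        from .mol import create_view
        ent = make_polyala_helix(spec.n, spec.seed)
        view = create_view(ent, ent.atoms)
        img = entity_to_density(view, DensityParams())
        if spec.noise_sigma > 0:
            rng = np.random.default_rng(spec.seed)
            img.data = img.data + rng.normal(0.0, spec.noise_sigma,
                                             img.data.shape)
        return img
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Random query strings (for oracle-equivalence suites)
# ---------------------------------------------------------------------------

def random_query(rng, depth: int = 2, allow_within: bool = True) -> str:
    """Random selection string from the full dialect."""
    if depth <= 0 or rng.random() < 0.35:
        return _random_predicate(rng, allow_within)
    roll = rng.random()
    if roll < 0.35:
        return (f"{random_query(rng, depth - 1, allow_within)} and "
                f"{random_query(rng, depth - 1, allow_within)}")
    if roll < 0.7:
        return (f"{random_query(rng, depth - 1, allow_within)} or "
                f"{random_query(rng, depth - 1, allow_within)}")
    if roll < 0.85:
        return f"not {random_query(rng, depth - 1, allow_within)}"
    return f"({random_query(rng, depth - 1, allow_within)})"


def _random_predicate(rng, allow_within: bool) -> str:
    choices = ["aname", "rname", "rnum", "cname", "ele", "occ", "abfac",
               "ishetatm", "charge", "gr", "ga"]
    if allow_within:
        choices.append("within")
    prop = choices[rng.integers(len(choices))]
    if prop == "within":
        radius = round(float(rng.uniform(2.0, 8.0)), 1)
        sub = _random_predicate(rng, allow_within=False)
        return f"{radius} <> [{sub}]"
    if prop == "aname":
        names = rng.permutation(["CA", "CB", "N", "O", "FE"])[
            :rng.integers(1, 3)]
        return f"aname={','.join(names)}"
    if prop == "rname":
        op = "=" if rng.random() < 0.7 else "!="
        return f"rname{op}{['ALA', 'HOH', 'HEM', 'GLY'][rng.integers(4)]}"
    if prop == "rnum":
        lo = int(rng.integers(1, 8))
        if rng.random() < 0.5:
            return f"rnum={lo}:{lo + int(rng.integers(0, 5))}"
        return f"rnum{['=', '<', '>', '<=', '>=', '!='][rng.integers(6)]}{lo}"
    if prop == "cname":
        return f"cname={'AB'[rng.integers(2)]}"
    if prop == "ele":
        return f"ele={['C', 'N', 'O', 'FE'][rng.integers(4)]}"
    if prop == "occ":
        return f"occ{['<', '>', '<=', '>='][rng.integers(4)]}" \
               f"{round(float(rng.uniform(0.2, 1.0)), 2)}"
    if prop == "abfac":
        return f"abfac{['<', '>'][rng.integers(2)]}" \
               f"{round(float(rng.uniform(10.0, 70.0)), 1)}"
    if prop == "ishetatm":
        return f"ishetatm={['true', 'false'][rng.integers(2)]}"
    if prop == "charge":
        return f"charge{['=', '!=', '>='][rng.integers(3)]}" \
               f"{int(rng.integers(-1, 2))}"
    if prop == "gr":
        return f"gr:conservation{['>', '<'][rng.integers(2)]}" \
               f"{round(float(rng.uniform(0.0, 1.0)), 2)}"
    return f"ga:score{['>', '<'][rng.integers(2)]}" \
           f"{round(float(rng.uniform(0.0, 1.0)), 2)}"
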