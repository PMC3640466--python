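"""Least-squares superposition, RMSD and alignment-guided annotation transfer.

Superposition uses the Kabsch algorithm: centre both point sets, take the
SVD of the covariance matrix and correct for reflection by flipping the
sign of the smallest singular vector when the determinant is negative, so
the result is always a proper rotation.  Atom correspondence is positional
— the i-th atom of the mobile view is paired with the i-th atom of the
reference view, whatever their names.  Any two equally sized views can be
superposed: ligand atoms, binding-site side chains, Cα traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mol import EntityView
from .query import select
from .seq import AlignmentHandle, SequenceHandle

__all__ = [
    "SuperpositionResult",
    "superpose",
    "rmsd",
    "transfer_annotation",
]


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray      # 3×3 proper rotation (det = +1)
    translation: np.ndarray   # 3-vector Å; maps mobile -> reference frame
    rmsd: float               # Å, after applying the transform
    atom_count: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _coords(view) -> np.ndarray:
    return np.asarray(view.positions, dtype=float)


def superpose(mobile: EntityView, reference: EntityView,
              apply: bool = False) -> SuperpositionResult:
    """Rotation/translation minimising the RMSD of mobile onto reference.

    Correspondence is iteration order; both views need the same atom count,
    at least 3.  With ``apply=True`` every atom of the mobile view's
    underlying entity is transformed in place (views reflect the change).
    A degenerate (collinear) reference is allowed but warned about — the
    rotation is then not unique.
    """
    P = _coords(mobile)
    Q = _coords(reference)
    if P.shape != Q.shape:
        raise ValueError(
            f"atom-count mismatch: mobile {P.shape[0]}, reference {Q.shape[0]}")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    sv = np.linalg.svd(Q0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        warnings.warn("reference atoms are (near-)collinear; "
                      "the superposition is not unique", stacklevel=2)
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rms = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    result = SuperpositionResult(R, t, rms, n)
    if apply:
        for atom in mobile.entity.atoms:
            atom.pos = R @ atom.pos + t
    return result


def rmsd(view_a, view_b, transform: Optional[SuperpositionResult] = None) -> float:
    """Positional RMSD in Å; ``transform`` (if given) is applied to ``view_a``."""
    A = _coords(view_a)
    B = _coords(view_b)
    if A.shape != B.shape:
        raise ValueError(f"atom-count mismatch: {A.shape[0]} vs {B.shape[0]}")
    if transform is not None:
        A = transform.transform(A)
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def transfer_annotation(src_seq: SequenceHandle, dst_seq: SequenceHandle,
                        aln: AlignmentHandle, selection: str,
                        prop_key: str) -> int:
    """Copy a residue-level annotation across an alignment.

    Every residue of ``src_seq``'s attached view matching ``selection``
    (e.g. binding-site residues found with a ``within`` query) marks the
    aligned residue of ``dst_seq`` — if that column is not a gap — with the
    generic property ``prop_key = True`` on the residue handle.  Returns
    the number of destination residues annotated.
    """
    for s in (src_seq, dst_seq):
        if s not in aln.sequences:
            raise ValueError(f"sequence {s.name!r} is not part of the alignment")
        if s.attached_view is None:
            raise ValueError(f"sequence {s.name!r} has no attached structure")
    matched = select(src_seq.attached_view, selection)
    matched_ids = {id(r.handle) for r in matched.residues}
    count = 0
    src_residues = list(src_seq.attached_view.residues)
    for idx, res in enumerate(src_residues):
        if id(res.handle) not in matched_ids:
            continue
        pos = src_seq.residue_index_to_pos(src_seq.offset + idx)
        dst_res = dst_seq.residue_at_pos(pos)
        if dst_res is None:
            continue
        handle = dst_res.handle if hasattr(dst_res, "handle") else dst_res
        handle.set_prop(prop_key, True)
        count += 1
    return count
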