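"""Pairwise sequence alignment (global and local, affine gaps) and
per-column conservation.

Both aligners use the three-matrix affine-gap dynamic programme (Gotoh):
a gap of length L costs ``gap_open + (L-1)*gap_extend``, both negative.
Traceback ties are broken deterministically: diagonal, then up (gap in the
second sequence), then left.  The default scoring scheme is BLOSUM62 with
gap open −10 and extend −1.

Conservation follows the pairwise physico-chemical similarity idea: for
each column, the mean over unordered sequence pairs of a similarity in
[0, 1]; any pair involving a gap contributes 0, so an all-gap column scores
0 and a column of identical non-gap residues scores exactly 1.  The
similarity matrix is derived from BLOSUM62 (see :func:`similarity`) and is
pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Union

from Bio.Align import substitution_matrices

from .seq import AlignmentHandle, SequenceError, SequenceHandle

__all__ = [
    "AlignError",
    "ScoringScheme",
    "PairwiseAlignmentResult",
    "load_matrix",
    "global_align",
    "local_align",
    "rescore",
    "sequence_identity",
    "conservation",
    "similarity",
]

_GAP = "-"
_NEG_INF = float("-inf")


class AlignError(Exception):
    pass


def _matrix_to_dict(m) -> dict:
    alphabet = m.alphabet
    return {(a, b): int(m[a, b]) for a in alphabet for b in alphabet}


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both negative)."""
    matrix: tuple            # hashable ((pair, score), ...) mapping
    gap_open: int = -10
    gap_extend: int = -1

    def __post_init__(self):
        if self.gap_extend < self.gap_open:
            raise AlignError("gap_extend must not penalize more than gap_open")
        d = dict(self.matrix)
        for (a, b), s in d.items():
            if d.get((b, a), s) != s:
                raise AlignError(f"substitution matrix asymmetric at ({a},{b})")

    @property
    def _lookup(self) -> dict:
        return dict(self.matrix)

    def score(self, a: str, b: str) -> int:
        d = self._lookup
        try:
            return d[(a, b)]
        except KeyError:
            try:
                return d[(b, a)]
            except KeyError:
                raise AlignError(f"no substitution score for pair ({a},{b})") \
                    from None

    @classmethod
    def from_dict(cls, matrix: dict, gap_open: int = -10,
                  gap_extend: int = -1) -> "ScoringScheme":
        return cls(tuple(sorted(matrix.items())), gap_open, gap_extend)

    @classmethod
    def blosum62(cls, gap_open: int = -10, gap_extend: int = -1) -> "ScoringScheme":
        return cls.from_dict(_matrix_to_dict(_blosum62()), gap_open, gap_extend)

    @classmethod
    def simple(cls, match: int = 1, mismatch: int = -1, gap_open: int = -2,
               gap_extend: int = -1,
               alphabet: str = "ACDEFGHIKLMNPQRSTVWYXU") -> "ScoringScheme":
        m = {(a, b): (match if a == b else mismatch)
             for a in alphabet for b in alphabet}
        return cls.from_dict(m, gap_open, gap_extend)


@lru_cache(maxsize=None)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


def load_matrix(path) -> dict:
    """Load an NCBI-format substitution matrix file into a pair->score dict."""
    return _matrix_to_dict(substitution_matrices.read(str(path)))


@dataclass
class PairwiseAlignmentResult:
    alignment: AlignmentHandle
    score: int
    identity: float          # percentage over both-non-gap columns


def _as_string(seq) -> tuple[str, str]:
    if isinstance(seq, SequenceHandle):
        name, s = seq.name, seq.string
    else:
        name, s = "", str(seq).upper()
    if _GAP in s or "." in s:
        raise AlignError("input sequences must be ungapped")
    if not s:
        raise AlignError("cannot align an empty sequence")
    return name, s


def _dp(s1: str, s2: str, scheme: ScoringScheme, local: bool):
    n, m = len(s1), len(s2)
    go, ge = scheme.gap_open, scheme.gap_extend
    sub = scheme.score
    # M: diagonal end; X: gap in s2 (vertical); Y: gap in s1 (horizontal)
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    if not local:
        for i in range(1, n + 1):
            X[i][0] = go + (i - 1) * ge
        for j in range(1, m + 1):
            Y[0][j] = go + (j - 1) * ge
    else:
        for i in range(n + 1):
            M[i][0] = 0
        for j in range(m + 1):
            M[0][j] = 0
    for i in range(1, n + 1):
        c1 = s1[i - 1]
        for j in range(1, m + 1):
            s = sub(c1, s2[j - 1])
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            M[i][j] = max(diag, 0) if local else diag
            X[i][j] = max(M[i - 1][j] + go, X[i - 1][j] + ge, Y[i - 1][j] + go)
            Y[i][j] = max(M[i][j - 1] + go, Y[i][j - 1] + ge, X[i][j - 1] + go)
    return M, X, Y


def _traceback(s1, s2, scheme, M, X, Y, i, j, state, stop_at_zero):
    """Walk back from (i, j, state); ties prefer diagonal, then up, then left."""
    go, ge = scheme.gap_open, scheme.gap_extend
    a1, a2 = [], []
    while i > 0 or j > 0:
        if state == "M":
            if stop_at_zero and M[i][j] == 0:
                break
            if i == 0 or j == 0:
                # only reachable in global mode along an edge
                state = "X" if j == 0 else "Y"
                continue
            s = scheme.score(s1[i - 1], s2[j - 1])
            target = M[i][j] - s
            if M[i - 1][j - 1] == target:
                nstate = "M"
            elif X[i - 1][j - 1] == target:
                nstate = "X"
            else:
                nstate = "Y"
            a1.append(s1[i - 1])
            a2.append(s2[j - 1])
            i, j, state = i - 1, j - 1, nstate
        elif state == "X":
            if X[i][j] == M[i - 1][j] + go:
                nstate = "M"
            elif X[i][j] == X[i - 1][j] + ge:
                nstate = "X"
            else:
                nstate = "Y"
            a1.append(s1[i - 1])
            a2.append(_GAP)
            i, state = i - 1, nstate
        else:
            if Y[i][j] == M[i][j - 1] + go:
                nstate = "M"
            elif Y[i][j] == Y[i][j - 1] + ge:
                nstate = "Y"
            else:
                nstate = "X"
            a2.append(s2[j - 1])
            a1.append(_GAP)
            j, state = j - 1, nstate
    return "".join(reversed(a1)), "".join(reversed(a2)), i, j


def _result(name1, name2, r1, r2, off1, off2, score) -> PairwiseAlignmentResult:
    sh1 = SequenceHandle(name1 or "seq1", r1, offset=off1)
    sh2 = SequenceHandle(name2 or "seq2", r2, offset=off2)
    aln = AlignmentHandle([sh1, sh2])
    try:
        ident = sequence_identity(aln)
    except AlignError:        # no both-non-gap column (all-gap optimum)
        ident = 0.0
    return PairwiseAlignmentResult(aln, int(score), ident)


def global_align(seq1, seq2,
                 scheme: Optional[ScoringScheme] = None) -> PairwiseAlignmentResult:
    """Optimal global (Needleman–Wunsch) alignment under affine gaps."""
    scheme = scheme or ScoringScheme.blosum62()
    name1, s1 = _as_string(seq1)
    name2, s2 = _as_string(seq2)
    M, X, Y = _dp(s1, s2, scheme, local=False)
    n, m = len(s1), len(s2)
    end_scores = {"M": M[n][m], "X": X[n][m], "Y": Y[n][m]}
    state = max(("M", "X", "Y"), key=lambda k: end_scores[k])
    score = end_scores[state]
    r1, r2, _, _ = _traceback(s1, s2, scheme, M, X, Y, n, m, state, False)
    return _result(name1, name2, r1, r2, 0, 0, score)


def local_align(seq1, seq2,
                scheme: Optional[ScoringScheme] = None) -> PairwiseAlignmentResult:
    """Optimal local (Smith–Waterman) alignment; score floored at 0.

    On no positive-scoring region the result is an empty alignment with
    score 0.  Start offsets of the aligned region are reported through the
    sequence offsets.
    """
    scheme = scheme or ScoringScheme.blosum62()
    name1, s1 = _as_string(seq1)
    name2, s2 = _as_string(seq2)
    M, X, Y = _dp(s1, s2, scheme, local=True)
    best, bi, bj = 0, 0, 0
    for i in range(len(s1) + 1):
        row = M[i]
        for j in range(len(s2) + 1):
            if row[j] > best:
                best, bi, bj = row[j], i, j
    if best == 0:
        sh1 = SequenceHandle(name1 or "seq1", "")
        sh2 = SequenceHandle(name2 or "seq2", "")
        return PairwiseAlignmentResult(AlignmentHandle([sh1, sh2]), 0, 0.0)
    r1, r2, i0, j0 = _traceback(s1, s2, scheme, M, X, Y, bi, bj, "M", True)
    return _result(name1, name2, r1, r2, i0, j0, best)


def rescore(aln: AlignmentHandle, scheme: ScoringScheme) -> int:
    """Score an emitted 2-sequence alignment under a scheme (affine gaps)."""
    if len(aln) != 2:
        raise AlignError("rescore needs a 2-sequence alignment")
    s1, s2 = aln[0].string, aln[1].string
    score = 0
    gap1 = gap2 = False
    for a, b in zip(s1, s2):
        if a == _GAP and b == _GAP:
            raise AlignError("column with two gaps")
        if a == _GAP:
            score += scheme.gap_extend if gap1 else scheme.gap_open
            gap1, gap2 = True, False
        elif b == _GAP:
            score += scheme.gap_extend if gap2 else scheme.gap_open
            gap2, gap1 = True, False
        else:
            score += scheme.score(a, b)
            gap1 = gap2 = False
    return score


def sequence_identity(aln: AlignmentHandle) -> float:
    """Percentage of identical columns among both-non-gap columns."""
    if len(aln) != 2:
        raise AlignError("sequence identity is defined for 2-sequence alignments")
    s1, s2 = aln[0].string, aln[1].string
    aligned = same = 0
    for a, b in zip(s1, s2):
        if a != _GAP and b != _GAP:
            aligned += 1
            if a == b:
                same += 1
    if aligned == 0:
        raise AlignError("alignment has no aligned (both non-gap) columns")
    return 100.0 * same / aligned


@lru_cache(maxsize=None)
def _similarity_table() -> dict:
    """Similarity in [0,1] from BLOSUM62: shifted score over the shifted
    mean of the two self-scores — exactly 1 on the diagonal."""
    m = _blosum62()
    d = _matrix_to_dict(m)
    lo = min(d.values())
    sim = {}
    for (a, b), s in d.items():
        denom = (d[(a, a)] + d[(b, b)]) / 2.0 - lo
        sim[(a, b)] = min(max((s - lo) / denom, 0.0), 1.0) if denom > 0 else 0.0
    return sim


def similarity(a: str, b: str, table: Optional[dict] = None) -> float:
    """Pairwise residue similarity in [0, 1]; 1 iff ``a == b``."""
    table = table if table is not None else _similarity_table()
    try:
        return table[(a, b)]
    except KeyError:
        try:
            return table[(b, a)]
        except KeyError:
            return 0.0


def conservation(aln: AlignmentHandle, normalized: bool = True,
                 table: Optional[dict] = None) -> list[float]:
    """Per-column conservation: mean pairwise similarity over sequence pairs.

    Pairs involving a gap contribute 0 (``normalized``) or the matrix
    minimum (raw mode).  Requires at least two sequences.
    """
    if len(aln) < 2:
        raise AlignError("conservation needs an alignment of >= 2 sequences")
    nseq = len(aln)
    npairs = nseq * (nseq - 1) // 2
    raw = _matrix_to_dict(_blosum62())
    lo = min(raw.values())
    scores = []
    for pos in range(aln.length):
        col = aln.column(pos)
        total = 0.0
        for i in range(nseq):
            for j in range(i + 1, nseq):
                a, b = col[i], col[j]
                if a == _GAP or b == _GAP:
                    total += 0.0 if normalized else lo
                elif normalized:
                    total += similarity(a, b, table)
                else:
                    total += raw.get((a, b), raw.get((b, a), lo))
        scores.append(total / npairs)
    return scores
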