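"""Pairwise global alignment, distance matrices, and progressive MSA.

Pairwise alignment is affine-gap global alignment (Needleman-Wunsch/Gotoh)
under BLOSUM62 with the conventional -11 open / -1 extend penalties, where
"open" is the score of the first gap position.  The multiple alignment is a
single progressive pass: a UPGMA guide tree built from pairwise identity
distances is traversed post-order, and at each internal node the two child
profiles are aligned by dynamic programming on mean-of-pairs column scores,
with a gap scoring 0 against any residue inside the mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import phylogeny
from .seqio import ALPHABET, SequenceRecord

_NEG = -1e30

# profile alphabet: 20 residues + X + gap
_SYMBOLS = "ACDEFGHIKLMNPQRSTVWYX-"
_SYM_INDEX = {c: i for i, c in enumerate(_SYMBOLS)}
_GAP_IDX = _SYM_INDEX["-"]


def _default_matrix():
    return substitution_matrices.load("BLOSUM62")


@dataclass
class AlignmentParams:
    """Scoring parameters for global and profile alignment.

    ``gap_open`` is the score of the first position of a gap and
    ``gap_extend`` of each subsequent position; both negative, with
    ``gap_open <= gap_extend < 0``.
    """

    substitution_matrix: object = field(default_factory=_default_matrix)
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")

    def score_table(self) -> np.ndarray:
        """Dense score table over the profile alphabet; gap rows/cols are 0."""
        table = np.zeros((len(_SYMBOLS), len(_SYMBOLS)))
        mat = self.substitution_matrix
        for a in _SYMBOLS[:-1]:
            for b in _SYMBOLS[:-1]:
                table[_SYM_INDEX[a], _SYM_INDEX[b]] = mat[a, b]
        return table


class AlignmentError(ValueError):
    pass


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = params.substitution_matrix
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def global_align(
    a: str, b: str, params: AlignmentParams | None = None
) -> tuple[float, str, str]:
    """Optimal affine-gap global alignment of two residue strings.

    Returns (score, gapped_a, gapped_b); the gapped strings realize the
    returned score.  Terminal gaps are penalized like internal gaps.
    """
    params = params or AlignmentParams()
    if not a or not b:
        raise AlignmentError("global_align requires non-empty sequences")
    for s in (a, b):
        bad = set(s) - ALPHABET
        if bad:
            raise AlignmentError(f"residues outside alphabet: {sorted(bad)}")
    aligner = _make_aligner(params)
    aln = aligner.align(a, b)[0]
    return float(aln.score), str(aln[0]), str(aln[1])


@dataclass
class ColumnMap:
    """Bidirectional map between alignment columns and 1-based positions."""

    row_id: str
    col_to_pos: dict[int, int]
    pos_to_col: dict[int, int]

    def position(self, col: int) -> int:
        return self.col_to_pos[col]

    def column(self, pos: int) -> int:
        return self.pos_to_col[pos]


@dataclass
class AlignmentMatrix:
    """A gapped multiple alignment: equal-length rows over residues + '-'."""

    row_ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids in alignment")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, row_id: str) -> str:
        return self.rows[self.row_ids.index(row_id)]

    def degapped(self, row_id: str) -> str:
        return self.row(row_id).replace("-", "")

    def column(self, col: int) -> str:
        return "".join(r[col] for r in self.rows)

    def column_map(self, row_id: str) -> ColumnMap:
        """Total, invertible map between non-gap columns and residue positions."""
        row = self.row(row_id)
        col_to_pos: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(row):
            if ch != "-":
                pos += 1
                col_to_pos[col] = pos
        return ColumnMap(
            row_id=row_id,
            col_to_pos=col_to_pos,
            pos_to_col={p: c for c, p in col_to_pos.items()},
        )

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.row_ids, self.rows):
                fh.write(f">{rid}\n")
                for i in range(0, len(row), width):
                    fh.write(row[i : i + width] + "\n")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "AlignmentMatrix":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(row_ids=ids, rows=rows)


def distance_matrix(
    records: Sequence[SequenceRecord], params: AlignmentParams | None = None
) -> phylogeny.DistanceMatrix:
    """All-pairs (1 - identity) distances from global alignments."""
    from .seqio import pairwise_identity

    if len(records) < 2:
        raise ValueError("distance_matrix requires at least two records")
    params = params or AlignmentParams()
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - pairwise_identity(records[i], records[j], params)
    return phylogeny.DistanceMatrix(ids=[r.id for r in records], d=d)


def build_guide_tree(D: phylogeny.DistanceMatrix) -> phylogeny.TreeNode:
    """Guide tree for progressive alignment; same UPGMA as the phylogeny."""
    return phylogeny.upgma(D)


# ---------------------------------------------------------------------------
# profile-profile dynamic programming


class _Profile:
    __slots__ = ("ids", "rows", "counts")

    def __init__(self, ids: list[str], rows: list[str]):
        self.ids = ids
        self.rows = rows
        arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
        arr = arr.reshape(len(rows), -1)
        lut = np.zeros(128, dtype=np.int64)
        for ch, idx in _SYM_INDEX.items():
            lut[ord(ch)] = idx
        idxs = lut[arr]  # (n_rows, n_cols)
        n_cols = idxs.shape[1]
        counts = np.zeros((n_cols, len(_SYMBOLS)))
        for r in range(idxs.shape[0]):
            np.add.at(counts, (np.arange(n_cols), idxs[r]), 1.0)
        self.counts = counts


def _profile_dp(S: np.ndarray, go: float, ge: float) -> list[str]:
    """Affine-gap DP over a precomputed column-pair score matrix.

    Returns the traceback as a list of moves 'D' (column pair), 'U' (column
    from the first profile vs gap), 'L' (gap vs column from the second).
    Tie-breaking prefers diagonal, then up, then left.
    """
    n1, n2 = S.shape
    M = np.full((n1 + 1, n2 + 1), _NEG)
    X = np.full((n1 + 1, n2 + 1), _NEG)  # gap in second profile (move U)
    Y = np.full((n1 + 1, n2 + 1), _NEG)  # gap in first profile (move L)
    M[0, 0] = 0.0
    if n1:
        X[1:, 0] = go + ge * np.arange(n1)
    if n2:
        Y[0, 1:] = go + ge * np.arange(n2)
    cols = np.arange(n2 + 1)
    for i in range(1, n1 + 1):
        X[i, :] = np.maximum.reduce(
            [M[i - 1, :] + go, X[i - 1, :] + ge, Y[i - 1, :] + go]
        )
        best_prev = np.maximum.reduce([M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]])
        M[i, 1:] = S[i - 1, :] + best_prev
        M[i, 0] = _NEG
        # Y[i, j] = max_{k<j} (max(M,X)[i,k] + go + ge*(j-1-k)): running max
        Z = np.maximum(M[i, :], X[i, :])
        W = Z - ge * cols
        run = np.maximum.accumulate(W[:-1])
        Y[i, 1:] = run + go + ge * (cols[1:] - 1)
        Y[i, 0] = _NEG
    # traceback
    moves: list[str] = []
    i, j = n1, n2
    order = ("M", "X", "Y")
    vals = {"M": M, "X": X, "Y": Y}
    state = max(order, key=lambda s: (vals[s][i, j], -order.index(s)))

    def close(a: float, b: float) -> bool:
        return abs(a - b) <= 1e-6 * (1.0 + abs(b))

    while i > 0 or j > 0:
        if i == 0:
            moves.append("L")
            j -= 1
            continue
        if j == 0:
            moves.append("U")
            i -= 1
            continue
        if state == "M":
            moves.append("D")
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            for s in order:
                if close(vals[s][i, j], target):
                    state = s
                    break
        elif state == "X":
            moves.append("U")
            target = X[i, j]
            cands = [("M", M[i - 1, j] + go), ("X", X[i - 1, j] + ge), ("Y", Y[i - 1, j] + go)]
            i -= 1
            state = next((s for s, v in cands if close(v, target)), "M")
        else:  # Y
            moves.append("L")
            target = Y[i, j]
            cands = [("M", M[i, j - 1] + go), ("X", X[i, j - 1] + go), ("Y", Y[i, j - 1] + ge)]
            j -= 1
            state = next((s for s, v in cands if close(v, target)), "M")
    moves.reverse()
    return moves


def _merge(a: _Profile, b: _Profile, params: AlignmentParams, table: np.ndarray) -> _Profile:
    # mean-of-pairs column score; gaps contribute 0 through the zeroed table
    denom = len(a.rows) * len(b.rows)
    S = (a.counts @ table @ b.counts.T) / denom
    moves = _profile_dp(S, params.gap_open, params.gap_extend)
    rows_a = [[] for _ in a.rows]
    rows_b = [[] for _ in b.rows]
    ia = ib = 0
    for mv in moves:
        if mv == "D":
            for k, row in enumerate(a.rows):
                rows_a[k].append(row[ia])
            for k, row in enumerate(b.rows):
                rows_b[k].append(row[ib])
            ia += 1
            ib += 1
        elif mv == "U":
            for k, row in enumerate(a.rows):
                rows_a[k].append(row[ia])
            for k in range(len(b.rows)):
                rows_b[k].append("-")
            ia += 1
        else:
            for k in range(len(a.rows)):
                rows_a[k].append("-")
            for k, row in enumerate(b.rows):
                rows_b[k].append(row[ib])
            ib += 1
    merged_rows = ["".join(r) for r in rows_a] + ["".join(r) for r in rows_b]
    return _Profile(ids=a.ids + b.ids, rows=merged_rows)


def progressive_msa(
    records: Sequence[SequenceRecord],
    guide: phylogeny.TreeNode,
    params: AlignmentParams | None = None,
) -> AlignmentMatrix:
    """Progressive multiple alignment along a guide tree.

    Row order follows the leaf order of the guide tree; de-gapping any row
    reproduces the corresponding input sequence exactly.
    """
    params = params or AlignmentParams()
    by_id = {r.id: r for r in records}
    leaf_ids = guide.leaf_labels()
    if sorted(leaf_ids) != sorted(by_id):
        raise AlignmentError(
            "guide tree leaves do not match record ids: "
            f"{sorted(set(leaf_ids) ^ set(by_id))}"
        )
    table = params.score_table()

    def build(node: phylogeny.TreeNode) -> _Profile:
        if node.is_leaf:
            return _Profile(ids=[node.label], rows=[by_id[node.label].residues])
        left, right = (build(c) for c in node.children)
        return _merge(left, right, params, table)

    prof = build(guide)
    return AlignmentMatrix(row_ids=prof.ids, rows=prof.rows)
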