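"""Global (Needleman-Wunsch) alignment with affine gap penalties.

The aligner is the three-state Gotoh dynamic program: state M ends in a
substitution column, state X in a gap in the second sequence (a residue of
``a`` over ``-``), state Y in a gap in the first.  A gap of length L costs
``gap_open + (L - 1) * gap_extend``, terminal gaps included (true global
alignment, no free end gaps).  With ``gap_open == gap_extend`` the model
collapses to classical linear-gap Needleman-Wunsch.

Traceback is deterministic: ties are resolved preferring the diagonal
(substitution) move, then the vertical (gap in ``b``), then the horizontal
move, so repeated runs are bit-identical.  The optimal *score* is
unaffected by tie order.

Percent identity and percent similarity are computed over the full gapped
alignment length: identity counts columns with identical residues,
similarity counts columns whose residue pair is identical or has a positive
substitution score.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

_NEG = -1e30  # effectively -infinity inside the DP


class AlignmentError(ValueError):
    """Raised for sequences the chosen substitution matrix cannot score."""


# ---------------------------------------------------------------------------
# substitution matrices


@lru_cache(maxsize=None)
def load_matrix(name_or_path: str):
    """A substitution matrix by standard name (BLOSUM62, PAM250, ...) or
    from an NCBI-format matrix file."""
    try:
        return substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        pass
    path = Path(name_or_path)
    if path.exists():
        return substitution_matrices.read(str(path))
    raise AlignmentError(
        f"unknown substitution matrix {name_or_path!r}; choose one of "
        f"{', '.join(substitution_matrices.load())} or give a matrix file"
    )


def simple_matrix(match: float, mismatch: float, alphabet: str = "ACDEFGHIKLMNPQRSTVWY"):
    """A uniform match/mismatch matrix, mainly for small worked examples."""
    m = substitution_matrices.Array(alphabet, dims=2)
    arr = np.asarray(m)
    arr[:] = mismatch
    np.fill_diagonal(arr, match)
    return m


@dataclass(frozen=True, eq=False)
class AlignmentParams:
    """Alignment knobs: substitution matrix and affine gap penalties.

    ``matrix`` is a standard matrix name, a path to an NCBI-format matrix
    file, or a ``substitution_matrices.Array``.  Both gap penalties are
    negative, with ``gap_open <= gap_extend < 0``.
    """

    matrix: object = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError(
                f"require gap_open <= gap_extend < 0, got "
                f"({self.gap_open}, {self.gap_extend})"
            )

    def resolve_matrix(self):
        if isinstance(self.matrix, str):
            return load_matrix(self.matrix)
        return self.matrix


def encode(seq: str, alphabet: str) -> np.ndarray:
    """Map residues to matrix row indices; unknown residues are an error."""
    index = {c: i for i, c in enumerate(alphabet)}
    try:
        return np.array([index[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise AlignmentError(
            f"residue {exc.args[0]!r} is not in the substitution matrix "
            f"alphabet {alphabet!r}"
        ) from None


# ---------------------------------------------------------------------------
# DP kernel


@njit(cache=True)
def _gotoh_fill(a, b, S, go, ge):  # pragma: no cover - exercised via wrapper
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = S[ai, b[j - 1]]
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = s + best

            x = M[i - 1, j] + go
            if X[i - 1, j] + ge > x:
                x = X[i - 1, j] + ge
            if Y[i - 1, j] + go > x:
                x = Y[i - 1, j] + go
            X[i, j] = x

            y = M[i, j - 1] + go
            if Y[i, j - 1] + ge > y:
                y = Y[i, j - 1] + ge
            if X[i, j - 1] + go > y:
                y = X[i, j - 1] + go
            Y[i, j] = y
    return M, X, Y


_STATE_ORDER = ("M", "X", "Y")  # diagonal > up (gap in b) > left (gap in a)
_TOL = 1e-6


def _traceback(a: str, b: str, M, X, Y, go: float, ge: float):
    n, m = len(a), len(b)
    i, j = n, m
    scores = {"M": M[n, m], "X": X[n, m], "Y": Y[n, m]}
    best = max(scores.values())
    state = next(s for s in _STATE_ORDER if scores[s] >= best - _TOL)
    cols_a: list[str] = []
    cols_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            prev = {"M": M[i - 1, j - 1], "X": X[i - 1, j - 1], "Y": Y[i - 1, j - 1]}
            want = max(prev.values())
            state = next(s for s in _STATE_ORDER if prev[s] >= want - _TOL)
            i -= 1
            j -= 1
        elif state == "X":
            cols_a.append(a[i - 1])
            cols_b.append("-")
            prev = {
                "M": M[i - 1, j] + go,
                "X": X[i - 1, j] + ge,
                "Y": Y[i - 1, j] + go,
            }
            state = next(s for s in _STATE_ORDER if prev[s] >= X[i, j] - _TOL)
            i -= 1
        else:  # Y
            cols_a.append("-")
            cols_b.append(b[j - 1])
            prev = {
                "M": M[i, j - 1] + go,
                "Y": Y[i, j - 1] + ge,
                "X": X[i, j - 1] + go,
            }
            state = next(s for s in _STATE_ORDER if prev[s] >= Y[i, j] - _TOL)
            j -= 1
    return "".join(reversed(cols_a)), "".join(reversed(cols_b))


# ---------------------------------------------------------------------------
# public surface


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal global alignment and its column statistics."""

    score: float
    aligned_a: str
    aligned_b: str
    identity_pct: float
    similarity_pct: float


def _column_stats(aligned_a: str, aligned_b: str, matrix) -> tuple[float, float]:
    length = len(aligned_a)
    ident = 0
    simil = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            ident += 1
            simil += 1
        elif matrix[ca, cb] > 0:
            simil += 1
    return 100.0 * ident / length, 100.0 * simil / length


def global_align(seq_a: str, seq_b: str, params: AlignmentParams | None = None) -> AlignmentResult:
    """Optimal global alignment of two amino-acid sequences.

    Returns the maximum affine-gap score together with one deterministic
    optimal alignment and its percent identity / similarity.
    """
    params = params or AlignmentParams()
    if not seq_a or not seq_b:
        raise AlignmentError("cannot align an empty sequence")
    matrix = params.resolve_matrix()
    alphabet = str(matrix.alphabet)
    S = np.asarray(matrix, dtype=np.float64)
    ea = encode(seq_a, alphabet)
    eb = encode(seq_b, alphabet)
    M, X, Y = _gotoh_fill(ea, eb, S, float(params.gap_open), float(params.gap_extend))
    score = float(max(M[-1, -1], X[-1, -1], Y[-1, -1]))
    aligned_a, aligned_b = _traceback(seq_a, seq_b, M, X, Y, params.gap_open, params.gap_extend)
    identity, similarity_ = _column_stats(aligned_a, aligned_b, matrix)
    return AlignmentResult(score, aligned_a, aligned_b, identity, similarity_)


def align_score(seq_a: str, seq_b: str, params: AlignmentParams | None = None) -> float:
    """Optimal global score only (no traceback)."""
    return global_align(seq_a, seq_b, params).score


def similarity(rec_a, rec_b, params: AlignmentParams | None = None, mode: str = "identity") -> float:
    """Pairwise percent identity or similarity of two protein records.

    ``mode`` selects the statistic: ``identity`` (default, identical
    columns over full alignment length) or ``similarity`` (columns with a
    positive substitution score).  Symmetric in its arguments.
    """
    if mode not in ("identity", "similarity"):
        raise ValueError(f"mode must be 'identity' or 'similarity', got {mode!r}")
    result = global_align(rec_a.sequence, rec_b.sequence, params)
    return result.identity_pct if mode == "identity" else result.similarity_pct
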