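"""Affine-gap global (Needleman–Wunsch/Gotoh) alignment.

The gap model is affine with the convention that a gap of length ``L`` costs
``open + (L - 1) * extend`` (the opening position itself is charged only the
opening penalty). Some engines instead charge ``open + L * extend``; pass
``charge_extend_on_open=True`` to :class:`GapModel` for that convention when
cross-comparing with such tools.

The dynamic program is the standard three-state recurrence (match state plus
one insertion state per sequence), with terminal gaps penalized (true global
semantics). Traceback ties are broken deterministically in the order
diagonal > gap-in-b (consume ``a``) > gap-in-a (consume ``b``).

The same machinery aligns two profiles given a precomputed column-vs-column
score table (used by the progressive MSA aligner).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .matrices import SubstitutionMatrix

_NEG = -1e30  # effective -infinity that stays finite under +/-


@dataclass(frozen=True)
class GapModel:
    """Affine gap penalties (both non-negative, subtracted from the score)."""

    open_penalty: float
    extend_penalty: float
    charge_extend_on_open: bool = False

    def __post_init__(self) -> None:
        if self.open_penalty < 0 or self.extend_penalty < 0:
            raise ValueError("gap penalties must be non-negative")

    @property
    def open_cost(self) -> float:
        """Cost charged at the first position of a gap."""
        if self.charge_extend_on_open:
            return self.open_penalty + self.extend_penalty
        return self.open_penalty


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    aligned_a: str
    aligned_b: str

    @property
    def columns(self) -> int:
        return len(self.aligned_a)


def _dp_matrices(S: np.ndarray, gap_open: float, gap_ext: float):
    """Fill the three Gotoh state matrices for a column score table *S* (m x n).

    ``M[i, j]``: best score ending with column (a_i, b_j); ``X``: ending with
    a_i over a gap; ``Y``: ending with a gap over b_j. Row-wise vectorized;
    the in-row Y recurrence is solved with a prefix-max scan.
    """
    m, n = S.shape
    M = np.full((m + 1, n + 1), _NEG)
    X = np.full((m + 1, n + 1), _NEG)
    Y = np.full((m + 1, n + 1), _NEG)
    M[0, 0] = 0.0
    if n >= 1:
        Y[0, 1:] = -gap_open - gap_ext * np.arange(n)
    if m >= 1:
        X[1:, 0] = -gap_open - gap_ext * np.arange(m)
    for i in range(1, m + 1):
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - gap_open,
            X[i - 1, 1:] - gap_ext,
        )
        prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = S[i - 1, :] + prev
        # Y[i, j] = max(H[i, j-1] - open, Y[i, j-1] - ext) with H = max(M, X):
        # substitute U[j] = Y[i, j] + j*ext and take a running maximum.
        H = np.maximum(M[i, :-1], X[i, :-1])
        # (Y[i, 0] is -inf for i >= 1, so the scan over V alone suffices.)
        V = H + np.arange(n) * gap_ext - gap_open + gap_ext
        U = np.maximum.accumulate(V)
        Y[i, 1:] = U - np.arange(1, n + 1) * gap_ext
    return M, X, Y


def _traceback(S, M, X, Y, gap_open, gap_ext):
    """Recover one optimal path; ties broken diagonal > gap-in-b > gap-in-a."""
    m, n = S.shape
    i, j = m, n
    # state 0 = M (diagonal), 1 = X (gap in b), 2 = Y (gap in a)
    end_scores = (M[m, n], X[m, n], Y[m, n])
    state = int(np.argmax(end_scores))  # argmax returns the first max: M > X > Y
    ops: list[int] = []
    while i > 0 or j > 0:
        if i == 0:
            ops.append(2)
            j -= 1
            continue
        if j == 0:
            ops.append(1)
            i -= 1
            continue
        if state == 0:
            ops.append(0)
            base = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand, val in ((0, M[i, j]), (1, X[i, j]), (2, Y[i, j])):
                if np.isclose(val, base, rtol=0, atol=1e-6):
                    state = cand
                    break
        elif state == 1:
            ops.append(1)
            target = X[i, j]
            i -= 1
            if np.isclose(M[i, j] - gap_open, target, rtol=0, atol=1e-6):
                state = 0
            elif np.isclose(X[i, j] - gap_ext, target, rtol=0, atol=1e-6):
                state = 1
            else:
                state = 2
        else:
            ops.append(2)
            target = Y[i, j]
            j -= 1
            if np.isclose(M[i, j] - gap_open, target, rtol=0, atol=1e-6):
                state = 0
            elif np.isclose(X[i, j] - gap_open, target, rtol=0, atol=1e-6):
                state = 1
            else:
                state = 2
    ops.reverse()
    return ops


def align_score_table(S: np.ndarray, gaps: GapModel):
    """Align two position sequences given their column score table.

    Returns ``(score, ops)`` where *ops* is the optimal column sequence:
    0 = aligned pair, 1 = position of the first axis over a gap, 2 = gap over
    a position of the second axis.
    """
    S = np.asarray(S, dtype=float)
    gap_open, gap_ext = gaps.open_cost, gaps.extend_penalty
    M, X, Y = _dp_matrices(S, gap_open, gap_ext)
    m, n = S.shape
    score = float(max(M[m, n], X[m, n], Y[m, n]))
    ops = _traceback(S, M, X, Y, gap_open, gap_ext)
    return score, ops


def global_align(
    seq_a: str, seq_b: str, matrix: SubstitutionMatrix, gaps: GapModel
) -> AlignmentResult:
    """Optimal global alignment of two sequences under (matrix, gaps)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    try:
        ia = np.array([matrix.index(c) for c in seq_a])
    except KeyError:
        bad = next(k for k, c in enumerate(seq_a) if c not in matrix.alphabet)
        raise ValueError(
            f"seq_a[{bad}] = {seq_a[bad]!r} not in matrix alphabet"
        ) from None
    try:
        ib = np.array([matrix.index(c) for c in seq_b])
    except KeyError:
        bad = next(k for k, c in enumerate(seq_b) if c not in matrix.alphabet)
        raise ValueError(
            f"seq_b[{bad}] = {seq_b[bad]!r} not in matrix alphabet"
        ) from None
    S = matrix.scores[np.ix_(ia, ib)]
    score, ops = align_score_table(S, gaps)
    out_a, out_b = [], []
    i = j = 0
    for op in ops:
        if op == 0:
            out_a.append(seq_a[i])
            out_b.append(seq_b[j])
            i += 1
            j += 1
        elif op == 1:
            out_a.append(seq_a[i])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(seq_b[j])
            j += 1
    return AlignmentResult(score=score, aligned_a="".join(out_a), aligned_b="".join(out_b))


def integer_scale(
    matrix: SubstitutionMatrix, gaps: GapModel, max_factor: int = 64
) -> tuple[SubstitutionMatrix, GapModel, int]:
    """Smallest positive integer factor making scores and penalties integral.

    Alignment scores under the scaled parameters equal the unscaled scores
    times the factor exactly, which lets integer-only engines run fractional
    penalties (the gap-extension grid uses 0.5 steps).
    """
    values = list(matrix.scores.ravel()) + [gaps.open_penalty, gaps.extend_penalty]
    factor = 1
    for v in values:
        frac = Fraction(v).limit_denominator(max_factor)
        if abs(float(frac) - v) > 1e-9:
            raise ValueError(f"value {v!r} not representable with denominator <= {max_factor}")
        factor = factor * frac.denominator // np.gcd(factor, frac.denominator)
        if factor > max_factor:
            raise ValueError("no integer scaling factor <= %d" % max_factor)
    scaled_matrix = SubstitutionMatrix(
        name=f"{matrix.name} x{factor}",
        scores=np.round(matrix.scores * factor),
        alphabet=matrix.alphabet,
    )
    scaled_gaps = GapModel(
        open_penalty=round(gaps.open_penalty * factor),
        extend_penalty=round(gaps.extend_penalty * factor),
        charge_extend_on_open=gaps.charge_extend_on_open,
    )
    return scaled_matrix, scaled_gaps, int(factor)
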