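"""MSA benchmarking: Q/TC scoring, alignment statistics, progressive realignment,
and exhaustive gap-penalty grid search.

Benchmarking follows the strip-and-realign protocol: reference alignments are
stripped of gaps, realigned under a candidate (matrix, gap penalties), and the
result compared back to the reference with two standard metrics:

* Q-score (sum-of-pairs score): the fraction of residue pairs co-aligned in
  the reference that the test alignment also co-aligns. Permissive.
* TC-score (total column score): the fraction of reference columns whose
  exact residue content (including the gap pattern) recurs as a column of
  the test alignment. Stringent; TC <= Q always.

The built-in realigner is a progressive aligner (UPGMA guide tree on
pairwise-identity distances, profile-profile alignment with sum-of-pairs
column scoring); an external aligner callable can be injected anywhere a
realignment happens.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .align import GapModel, align_score_table, global_align
from .matrices import CANONICAL_ALPHABET, SubstitutionMatrix

GAP = "-"


@dataclass(frozen=True)
class MultipleAlignment:
    """Rectangular gapped alignment with per-row identifiers."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 sequences")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        width = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(f"ragged alignment: row {rid!r} has length {len(row)}")
            if set(row) <= {GAP}:
                raise ValueError(f"row {rid!r} is all gaps")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class MsaStats:
    n_sequences: int
    mean_pairwise_identity: float
    mean_sequence_length: float
    match_rate: float
    mismatch_rate: float
    gap_rate: float


@dataclass
class GridResult:
    """Exhaustive gap-penalty search output."""

    cells: list[dict]
    best_q: tuple[float, float]
    best_tc: tuple[float, float]


def read_msa(source) -> MultipleAlignment:
    """Read an aligned FASTA or Stockholm file (format sniffed from content).

    Gap characters '.' and '-' are normalized to '-', sequences upper-cased.
    """
    from Bio import AlignIO

    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = source
    fmt = "stockholm" if text.lstrip().startswith("# STOCKHOLM") else "fasta"
    try:
        aln = AlignIO.read(io.StringIO(text), fmt)
    except ValueError as exc:
        raise ValueError(f"cannot parse alignment: {exc}") from None
    ids = tuple(rec.id for rec in aln)
    rows = tuple(str(rec.seq).upper().replace(".", GAP) for rec in aln)
    return MultipleAlignment(ids=ids, rows=rows)


def strip_gaps(msa: MultipleAlignment) -> list[tuple[str, str]]:
    """Ungapped (id, sequence) pairs, order preserved."""
    return [(rid, row.replace(GAP, "")) for rid, row in zip(msa.ids, msa.rows)]


# ---------------------------------------------------------------------------
# Q / TC scoring


def _residue_index_table(msa: MultipleAlignment) -> list[list[int | None]]:
    """Per row: residue index at each column, None at gaps."""
    table = []
    for row in msa.rows:
        k = 0
        out: list[int | None] = []
        for c in row:
            if c == GAP:
                out.append(None)
            else:
                out.append(k)
                k += 1
        table.append(out)
    return table


def _check_same_sequences(test: MultipleAlignment, ref: MultipleAlignment) -> list[int]:
    """Map ref row order to test row indices, verifying stripped content."""
    test_map = {rid: i for i, rid in enumerate(test.ids)}
    order = []
    for rid, seq in strip_gaps(ref):
        if rid not in test_map:
            raise ValueError(f"sequence {rid!r} missing from test alignment")
        i = test_map[rid]
        if test.rows[i].replace(GAP, "") != seq:
            raise ValueError(f"sequence content mismatch for {rid!r}")
        order.append(i)
    return order


def _aligned_pairs(msa: MultipleAlignment, row_order: Sequence[int]) -> set:
    """All co-aligned residue pairs {((row_pos, res_idx), (row_pos, res_idx))}."""
    table = _residue_index_table(msa)
    pairs = set()
    n = len(row_order)
    for col in range(msa.n_columns):
        occupied = [
            (r, table[row_order[r]][col])
            for r in range(n)
            if table[row_order[r]][col] is not None
        ]
        for (r1, k1), (r2, k2) in itertools.combinations(occupied, 2):
            pairs.add(((r1, k1), (r2, k2)))
    return pairs


def q_score(test: MultipleAlignment, ref: MultipleAlignment) -> float:
    """Fraction of reference residue pairs recovered by the test alignment."""
    order = _check_same_sequences(test, ref)
    ref_pairs = _aligned_pairs(ref, list(range(ref.n_sequences)))
    if not ref_pairs:
        return 1.0
    test_pairs = _aligned_pairs(test, order)
    return len(ref_pairs & test_pairs) / len(ref_pairs)


def tc_score(test: MultipleAlignment, ref: MultipleAlignment) -> float:
    """Fraction of reference columns reproduced exactly (gap pattern included).

    Columns of the reference that are entirely gaps are excluded from the
    denominator.
    """
    order = _check_same_sequences(test, ref)
    ref_table = _residue_index_table(ref)
    test_table = _residue_index_table(test)
    test_columns = {
        tuple(test_table[i][col] for i in order) for col in range(test.n_columns)
    }
    n_ref = 0
    n_hit = 0
    for col in range(ref.n_columns):
        key = tuple(ref_table[r][col] for r in range(ref.n_sequences))
        if all(k is None for k in key):
            continue
        n_ref += 1
        if key in test_columns:
            n_hit += 1
    if n_ref == 0:
        return 1.0
    return n_hit / n_ref


def msa_stats(msa: MultipleAlignment, identity_sample: int | None = None) -> MsaStats:
    """Match/mismatch/gap rates, identity, and length summary of one MSA.

    Rates are over all within-column sequence pairs: a pair of residues is a
    match (identical) or mismatch; a residue against a gap is a gap pair;
    gap–gap pairs are ignored. The three rates sum to one.

    Mean pairwise identity is computed by global alignment of the stripped
    sequences (BLOSUM62, gap open 10 / extend 1); *identity_sample* caps the
    number of row pairs used (all pairs when None; 0 skips the computation
    and reports NaN, useful for very long alignments).
    """
    from .structures import sequence_identity

    match = mismatch = gap = 0
    for col in range(msa.n_columns):
        column = [row[col] for row in msa.rows]
        for x, y in itertools.combinations(column, 2):
            if x == GAP and y == GAP:
                continue
            if x == GAP or y == GAP:
                gap += 1
            elif x == y:
                match += 1
            else:
                mismatch += 1
    total = match + mismatch + gap
    if total == 0:
        raise ValueError("alignment has no residue pairs")
    seqs = [s for _, s in strip_gaps(msa)]
    row_pairs = list(itertools.combinations(range(len(seqs)), 2))
    if identity_sample is not None and len(row_pairs) > identity_sample:
        rng = np.random.default_rng(0)
        idx = rng.choice(len(row_pairs), size=identity_sample, replace=False)
        row_pairs = [row_pairs[i] for i in sorted(idx)]
    if not row_pairs:
        identities = [float("nan")]
    else:
        identities = [sequence_identity(seqs[i], seqs[j]) for i, j in row_pairs]
    return MsaStats(
        n_sequences=msa.n_sequences,
        mean_pairwise_identity=float(np.mean(identities)),
        mean_sequence_length=float(np.mean([len(s) for s in seqs])),
        match_rate=match / total,
        mismatch_rate=mismatch / total,
        gap_rate=gap / total,
    )


# ---------------------------------------------------------------------------
# Progressive alignment


def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    """Residue count vectors (columns x 20); gaps contribute nothing."""
    idx = {a: i for i, a in enumerate(CANONICAL_ALPHABET)}
    counts = np.zeros((len(rows[0]), len(CANONICAL_ALPHABET)))
    for row in rows:
        for col, c in enumerate(row):
            if c != GAP:
                counts[col, idx[c]] += 1
    return counts


def _align_profiles(
    rows_a: Sequence[str], rows_b: Sequence[str], matrix: SubstitutionMatrix, gaps: GapModel
) -> tuple[list[str], list[str]]:
    """Profile–profile alignment with sum-of-pairs column scoring."""
    CA = _profile_counts(rows_a)
    CB = _profile_counts(rows_b)
    S = CA @ matrix.scores @ CB.T
    _, ops = align_score_table(S, gaps)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for op in ops:
        if op in (0, 1):
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            i += 1
        else:
            for r in out_a:
                r.append(GAP)
        if op in (0, 2):
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
            j += 1
        else:
            for r in out_b:
                r.append(GAP)
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_align(
    seqs: Sequence[str],
    matrix: SubstitutionMatrix,
    gaps: GapModel,
    ids: Sequence[str] | None = None,
) -> MultipleAlignment:
    """Progressive MSA: UPGMA guide tree on identity distances, then
    profile–profile merges in tree order. Deterministic for a fixed input order."""
    from scipy.cluster.hierarchy import linkage

    from .structures import sequence_identity

    n = len(seqs)
    if n < 2:
        raise ValueError("progressive alignment needs >= 2 sequences")
    if ids is None:
        ids = tuple(f"seq{i}" for i in range(n))
    if n == 2:
        result = global_align(seqs[0], seqs[1], matrix, gaps)
        return MultipleAlignment(ids=tuple(ids), rows=(result.aligned_a, result.aligned_b))
    dist = []
    for i, j in itertools.combinations(range(n), 2):
        dist.append(1.0 - sequence_identity(seqs[i], seqs[j]))
    Z = linkage(np.asarray(dist), method="average")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)
    }
    for k, (a, b, _, _) in enumerate(Z):
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        new_a, new_b = _align_profiles(rows_a, rows_b, matrix, gaps)
        clusters[n + k] = (ids_a + ids_b, new_a + new_b)
    order, rows = clusters[n + len(Z) - 1]
    # restore the input row order
    by_index = {idx: row for idx, row in zip(order, rows)}
    return MultipleAlignment(
        ids=tuple(ids), rows=tuple(by_index[i] for i in range(n))
    )


# ---------------------------------------------------------------------------
# Gap-penalty grid search


def realign(
    ref: MultipleAlignment,
    matrix: SubstitutionMatrix,
    gaps: GapModel,
    aligner: Callable | None = None,
) -> MultipleAlignment:
    """Strip a reference alignment and realign it under (matrix, gaps)."""
    stripped = strip_gaps(ref)
    ids = [rid for rid, _ in stripped]
    seqs = [s for _, s in stripped]
    if aligner is not None:
        return aligner(seqs, ids, matrix, gaps)
    return progressive_align(seqs, matrix, gaps, ids=ids)


def gap_grid_search(
    references: Sequence[MultipleAlignment],
    matrix: SubstitutionMatrix,
    gop_range: Sequence[float] = tuple(np.arange(0.0, 10.5, 1.0)),
    gep_range: Sequence[float] = tuple(np.arange(0.0, 5.5, 0.5)),
    aligner: Callable | None = None,
) -> GridResult:
    """Exhaustive (GOP, GEP) search maximizing mean Q and mean TC.

    Every reference is stripped and realigned at every grid cell. Ties are
    broken toward the smaller GOP, then the smaller GEP.
    """
    if not references:
        raise ValueError("need at least one reference alignment")
    gop_range = list(gop_range)
    gep_range = list(gep_range)
    if not gop_range or not gep_range:
        raise ValueError("empty penalty range")
    cells = []
    for gop in gop_range:
        for gep in gep_range:
            gaps = GapModel(open_penalty=float(gop), extend_penalty=float(gep))
            qs, tcs = [], []
            for ref in references:
                test = realign(ref, matrix, gaps, aligner=aligner)
                qs.append(q_score(test, ref))
                tcs.append(tc_score(test, ref))
            cells.append(
                {
                    "gop": float(gop),
                    "gep": float(gep),
                    "mean_q": float(np.mean(qs)),
                    "mean_tc": float(np.mean(tcs)),
                }
            )
    # max by score; ties toward smaller (gop, gep) — minimize the key tuple
    best_q = min(cells, key=lambda c: (-c["mean_q"], c["gop"], c["gep"]))
    best_tc = min(cells, key=lambda c: (-c["mean_tc"], c["gop"], c["gep"]))
    return GridResult(
        cells=cells,
        best_q=(best_q["gop"], best_q["gep"]),
        best_tc=(best_tc["gop"], best_tc["gep"]),
    )
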