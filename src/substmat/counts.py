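"""Weighted substitution counting and half-bit log-odds estimation.

This is the matrix-construction core. Substitution observations come from
ungapped pairwise alignments (one observation per aligned column). Families
contribute equally regardless of size: each family ``k`` with ``n_k`` members
has ``C(n_k, 2)`` pairs, and every pair is weighted by

    w_k = 2 / (n_k (n_k - 1)) = 1 / C(n_k, 2),

so a family's pairs jointly carry the mass of a single alignment. The weighted
frequencies f_ij are then turned into scores with the classical BLOSUM
log-odds recipe: normalize the 210 unique-pair masses to probabilities q_ij,
derive residue marginals p_i, form expected pair frequencies e_ii = p_i**2 and
e_ij = 2 p_i p_j, and score

    s_ij = round( 2 * log2(q_ij / e_ij) )

in half-bit units (the factor 2 is 1/scale_bits with the default 0.5 bits per
score unit).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .matrices import CANONICAL_ALPHABET, SubstitutionMatrix

_N = len(CANONICAL_ALPHABET)
_AA_INDEX = {a: i for i, a in enumerate(CANONICAL_ALPHABET)}


@dataclass(frozen=True)
class UngappedPairBlock:
    """Equal-length gap-free aligned sequence pair from one family."""

    family_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("pair block sequences must have equal length")
        if len(self.seq_a) < 1:
            raise ValueError("pair block must have at least one column")
        for seq in (self.seq_a, self.seq_b):
            bad = next((c for c in seq if c not in _AA_INDEX), None)
            if bad is not None:
                raise ValueError(f"invalid residue {bad!r} in pair block (gaps not allowed)")

    @property
    def length(self) -> int:
        return len(self.seq_a)


@dataclass(frozen=True)
class FamilyWeighting:
    """Per-pair weight for a family of ``n_members`` proteins."""

    family_id: str
    n_members: int
    weight: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError(
                f"family {self.family_id!r}: need >= 2 members to form pairs"
            )
        object.__setattr__(
            self, "weight", 2.0 / (self.n_members * (self.n_members - 1))
        )


def family_weight(n_members: int, family_id: str = "family") -> FamilyWeighting:
    """Weighting factor w = 2 / (n (n-1)) for a family of *n_members*."""
    return FamilyWeighting(family_id=family_id, n_members=n_members)


@dataclass
class WeightedCounts:
    """Symmetric table of family-weighted substitution frequencies f_ij.

    ``f[i, j] == f[j, i]`` holds the mass of the unordered pair {i, j}; the
    total is the sum over unique entries (diagonal plus upper triangle).
    """

    f: np.ndarray
    n_families: int = 0

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (_N, _N):
            raise ValueError(f"counts table must be {_N}x{_N}")
        if (self.f < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.f, self.f.T):
            raise ValueError("counts table must be symmetric")

    @property
    def total(self) -> float:
        iu = np.triu_indices(_N)
        return float(self.f[iu].sum())

    def __add__(self, other: "WeightedCounts") -> "WeightedCounts":
        return WeightedCounts(
            f=self.f + other.f, n_families=self.n_families + other.n_families
        )


@dataclass(frozen=True)
class LogOddsParams:
    """Scoring parameters for the log-odds step.

    scale_bits : bits per score unit; 0.5 gives half-bit scores (factor 2).
    pseudocount : fraction of the total mass added to every unique cell
        before normalization, keeping log-odds finite on sparse data. 0
        raises on empty cells.
    rounding : "nearest-integer" (half away from zero) or "none".
    """

    scale_bits: float = 0.5
    pseudocount: float = 1e-6
    rounding: str = "nearest-integer"

    def __post_init__(self) -> None:
        if self.scale_bits <= 0:
            raise ValueError("scale_bits must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.rounding not in ("nearest-integer", "none"):
            raise ValueError("rounding must be 'nearest-integer' or 'none'")


def count_substitutions(
    blocks: Iterable[UngappedPairBlock],
    weights: Mapping[str, FamilyWeighting],
) -> WeightedCounts:
    """Accumulate weighted unordered-pair masses over aligned columns.

    Each column (x, y) of a block from family k adds w_k to f_{xy}; the total
    over unique entries equals sum over blocks of length * w_k.
    """
    f = np.zeros((_N, _N))
    families = set()
    for block in blocks:
        if block.family_id not in weights:
            raise KeyError(f"no weighting for family {block.family_id!r}")
        w = weights[block.family_id].weight
        families.add(block.family_id)
        for x, y in zip(block.seq_a, block.seq_b):
            i, j = _AA_INDEX[x], _AA_INDEX[y]
            f[i, j] += w
            if i != j:
                f[j, i] += w
    return WeightedCounts(f=f, n_families=len(families))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def estimate_log_odds(
    counts: WeightedCounts, params: LogOddsParams = LogOddsParams(), name: str = "estimated"
) -> SubstitutionMatrix:
    """BLOSUM-style half-bit log-odds matrix from weighted counts.

    Residues with no observed mass at all are left out of the normalization;
    their rows and columns are zero in the output. A zero cell between two
    observed residues requires a positive pseudocount.
    """
    total = counts.total
    if total <= 0:
        raise ValueError("empty counts: total weighted mass is zero")
    observed = np.where(counts.f.sum(axis=0) > 0)[0]
    k = len(observed)
    sub = counts.f[np.ix_(observed, observed)]
    iu = np.triu_indices(k)
    q = sub[iu] + params.pseudocount * total
    if (q <= 0).any():
        bad = int(np.argmax(q <= 0))
        pair = (
            CANONICAL_ALPHABET[observed[iu[0][bad]]],
            CANONICAL_ALPHABET[observed[iu[1][bad]]],
        )
        raise ValueError(
            f"zero observed frequency for pair {pair} with pseudocount 0; "
            "set a positive pseudocount"
        )
    q = q / q.sum()
    Q = np.zeros((k, k))
    Q[iu] = q
    Q = Q + np.triu(Q, 1).T  # symmetric, unordered mass mirrored
    p = np.diag(Q) + (Q.sum(axis=1) - np.diag(Q)) / 2.0
    e = 2.0 * np.outer(p, p)
    np.fill_diagonal(e, p**2)
    sub_scores = (1.0 / params.scale_bits) * np.log2(Q / e)
    scores = np.zeros((_N, _N))
    scores[np.ix_(observed, observed)] = sub_scores
    if params.rounding == "nearest-integer":
        scores = _round_half_away(scores)
    return SubstitutionMatrix(name=name, scores=scores)


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class FamilyMember:
    member_id: str
    sequence: str
    chain: object | None = None  # StructureChain when structure mode is used


@dataclass
class Family:
    family_id: str
    members: list[FamilyMember]


@dataclass
class BuildReport:
    """Bookkeeping for one end-to-end matrix build."""

    n_families_input: int = 0
    n_families_used: int = 0
    pairs_generated: int = 0
    pairs_filtered_identity: int = 0
    pairs_aligned: int = 0
    counts_total: float = 0.0


def _default_pair_block(
    family: Family,
    a: FamilyMember,
    b: FamilyMember,
    proximity_threshold: float,
) -> UngappedPairBlock | None:
    """Structure route when both members carry chains, else column pairing.

    Sequence-only members must have equal lengths (columns pair up directly,
    as for families simulated column-wise); otherwise supply a custom
    ``block_provider``.
    """
    if a.chain is not None and b.chain is not None:
        from .structures import extract_correspondences, pair_block_from_correspondence

        corr = extract_correspondences(
            a.chain, b.chain, proximity_threshold=proximity_threshold
        )
        if not corr.pairs:
            return None
        return pair_block_from_correspondence(a.chain, b.chain, corr, family.family_id)
    if len(a.sequence) != len(b.sequence):
        raise ValueError(
            f"members {a.member_id!r}/{b.member_id!r} have unequal lengths and no "
            "structures; supply a block_provider"
        )
    return UngappedPairBlock(family.family_id, a.sequence, b.sequence)


def family_counts(
    family: Family,
    identity_threshold: float = 0.62,
    proximity_threshold: float = 5.0,
    block_provider: Callable | None = None,
) -> tuple[WeightedCounts | None, BuildReport]:
    """Weighted counts contributed by a single family (None if no pair survives)."""
    from .structures import sequence_identity

    report = BuildReport(n_families_input=1)
    members = family.members
    if len(members) < 2:
        warnings.warn(
            f"family {family.family_id!r} has < 2 members; skipped", stacklevel=2
        )
        return None, report
    weighting = family_weight(len(members), family.family_id)
    blocks = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            report.pairs_generated += 1
            ident = sequence_identity(members[i].sequence, members[j].sequence)
            if ident > identity_threshold:
                report.pairs_filtered_identity += 1
                continue
            if block_provider is not None:
                block = block_provider(family, members[i], members[j])
            else:
                block = _default_pair_block(
                    family, members[i], members[j], proximity_threshold
                )
            if block is not None:
                blocks.append(block)
                report.pairs_aligned += 1
    if not blocks:
        return None, report
    counts = count_substitutions(blocks, {family.family_id: weighting})
    report.n_families_used = 1
    report.counts_total = counts.total
    return counts, report


def build_matrix(
    families: Sequence[Family],
    identity_threshold: float = 0.62,
    proximity_threshold: float = 5.0,
    params: LogOddsParams = LogOddsParams(),
    block_provider: Callable | None = None,
    name: str = "built",
) -> tuple[SubstitutionMatrix, BuildReport]:
    """Full pipeline: pair enumeration, identity filter, counting, log-odds.

    Within each family all member pairs are generated; pairs with global
    sequence identity strictly above *identity_threshold* are dropped; the
    rest yield ungapped blocks (via structural correspondence when members
    carry chains). Families whose pairs are all filtered contribute nothing
    and do not count toward K.
    """
    total = WeightedCounts(f=np.zeros((_N, _N)))
    report = BuildReport()
    for family in families:
        counts, fr = family_counts(
            family, identity_threshold, proximity_threshold, block_provider
        )
        report.n_families_input += fr.n_families_input
        report.pairs_generated += fr.pairs_generated
        report.pairs_filtered_identity += fr.pairs_filtered_identity
        report.pairs_aligned += fr.pairs_aligned
        if counts is not None:
            total = total + counts
            report.n_families_used += 1
    if total.total <= 0:
        raise ValueError("empty counts: no pairs survived filtering")
    report.counts_total = total.total
    matrix = estimate_log_odds(total, params, name=name)
    return matrix, report


def convergence_curve(
    families: Sequence[Family],
    subset_sizes: Sequence[int],
    replicates: int = 50,
    seed: int = 0,
    identity_threshold: float = 0.62,
    proximity_threshold: float = 5.0,
    params: LogOddsParams = LogOddsParams(),
    block_provider: Callable | None = None,
):
    """Total |difference| to the full-data matrix versus family-subset size.

    For each size, draws ``replicates`` uniform random subsets of families,
    rebuilds the matrix, and sums absolute differences over the 210 unique
    entries against the full-data matrix. Returns a list of records
    ``{"size", "mean", "std"}``. Per-family counts are computed once and
    reused across subsets (the estimator is additive over families).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    per_family = []
    for family in families:
        counts, _ = family_counts(
            family, identity_threshold, proximity_threshold, block_provider
        )
        if counts is not None:
            per_family.append(counts)
    K = len(per_family)
    if K == 0:
        raise ValueError("empty counts: no family contributes pairs")
    for size in subset_sizes:
        if not 1 <= size <= K:
            raise ValueError(f"subset size {size} outside [1, {K}]")
    full = estimate_log_odds(_sum_counts(per_family), params)
    iu = np.triu_indices(_N)
    rng = np.random.default_rng(seed)
    records = []
    for size in subset_sizes:
        diffs = []
        for _ in range(replicates):
            idx = rng.choice(K, size=size, replace=False)
            sub = estimate_log_odds(_sum_counts([per_family[i] for i in idx]), params)
            diffs.append(float(np.abs(sub.scores[iu] - full.scores[iu]).sum()))
        records.append(
            {"size": int(size), "mean": float(np.mean(diffs)), "std": float(np.std(diffs))}
        )
    return records


def _sum_counts(counts_list: Sequence[WeightedCounts]) -> WeightedCounts:
    f = np.zeros((_N, _N))
    for c in counts_list:
        f = f + c.f
    return WeightedCounts(f=f, n_families=len(counts_list))
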