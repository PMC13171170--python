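"""Structural residue correspondences by rigid superposition.

Substitution observations are read off pairs of 3D chains: after rigid
superposition, residues whose alpha-carbons are mutual nearest neighbors
within a proximity cutoff are taken as corresponding, pruned to a strictly
monotone (sequential) subset, and emitted as an ungapped pair block.

The superposition/re-pairing loop is iterated to a fixed point:

1. seed pairing from a global sequence alignment under the identity (1/0)
   unit matrix — deliberately matrix-agnostic so the structure stage does not
   depend on the substitution matrix being estimated;
2. Kabsch least-squares superposition on the current pairs;
3. re-pair as mutual nearest alpha-carbon neighbors within the cutoff and
   keep the longest strictly-increasing subset (ties to smaller distances).

External correspondences (from any structural aligner) can be imported as
TSV and used instead of the built-in scheme.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .align import GapModel, global_align
from .counts import UngappedPairBlock
from .matrices import CANONICAL_ALPHABET, SubstitutionMatrix, load_standard, unit_matrix

logger = logging.getLogger(__name__)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parents
    "MSE": "M", "SEC": "C", "PYL": "K",
}


@dataclass(frozen=True)
class StructureChain:
    """Ordered residues of one chain, each with an alpha-carbon coordinate (Å)."""

    chain_id: str
    sequence: str
    coords: np.ndarray
    author_numbers: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (len(self.sequence), 3):
            raise ValueError("coords must be (length, 3) matching the sequence")
        if len(self.sequence) < 3:
            raise ValueError("chain needs >= 3 residues for superposition")
        if not np.isfinite(coords).all():
            raise ValueError("coordinates must be finite")
        bad = set(self.sequence) - set(CANONICAL_ALPHABET)
        if bad:
            raise ValueError(f"non-canonical residues in chain: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation mapping one point set onto another."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass(frozen=True)
class Correspondence:
    """Strictly monotone list of 0-based residue index pairs."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple((int(a), int(b)) for a, b in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]):
            if a2 <= a1 or b2 <= b1:
                raise ValueError("correspondence indices must be strictly increasing")
        if pairs and (pairs[0][0] < 0 or pairs[0][1] < 0):
            raise ValueError("indices must be non-negative")

    def __len__(self) -> int:
        return len(self.pairs)

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        arr = np.asarray(self.pairs, dtype=int)
        return arr[:, 0], arr[:, 1]


# ---------------------------------------------------------------------------
# I/O


def read_chain(path, chain_id: str | None = None) -> StructureChain:
    """Read one chain's alpha-carbon trace from a PDB or mmCIF file.

    Residues without an alpha-carbon or with a residue name that cannot be
    mapped to a canonical amino acid are dropped (logged at WARNING level).
    """
    import biotite.structure as struc

    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".cif", ".mmcif", ".pdbx"):
        from biotite.structure.io.pdbx import CIFFile, get_structure

        atoms = get_structure(CIFFile.read(path), model=1)
    else:
        from biotite.structure.io.pdb import PDBFile

        atoms = PDBFile.read(path).get_structure(model=1)
    atoms = atoms[struc.filter_amino_acids(atoms)]
    chains = sorted(set(atoms.chain_id))
    if chain_id is None:
        if len(chains) != 1:
            raise ValueError(f"file has chains {chains}; specify one")
        chain_id = chains[0]
    if chain_id not in chains:
        raise ValueError(f"chain {chain_id!r} not found (have {chains})")
    atoms = atoms[atoms.chain_id == chain_id]
    seq, coords, numbers = [], [], []
    for res_id in np.unique(atoms.res_id):
        res = atoms[atoms.res_id == res_id]
        name = str(res.res_name[0])
        ca = res[res.atom_name == "CA"]
        code = _THREE_TO_ONE.get(name)
        if len(ca) == 0:
            logger.warning("residue %s%d lacks CA; dropped", name, res_id)
            continue
        if code is None:
            logger.warning("non-canonical residue %s%d dropped", name, res_id)
            continue
        seq.append(code)
        coords.append(ca.coord[0])
        numbers.append(int(res_id))
    if len(seq) < 3:
        raise ValueError(f"chain {chain_id!r}: fewer than 3 usable residues")
    return StructureChain(
        chain_id=chain_id,
        sequence="".join(seq),
        coords=np.asarray(coords, dtype=float),
        author_numbers=tuple(numbers),
    )


def write_correspondence_tsv(
    corr: Correspondence, path, distances: np.ndarray | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write("index_a\tindex_b\tdistance\n")
        for k, (a, b) in enumerate(corr.pairs):
            d = "" if distances is None else f"{distances[k]:.4f}"
            fh.write(f"{a}\t{b}\t{d}\n")


def read_correspondence_tsv(path) -> Correspondence:
    """Import externally computed correspondences (index_a, index_b[, distance])."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("index_a"):
                continue
            fields = line.split("\t")
            pairs.append((int(fields[0]), int(fields[1])))
    return Correspondence(pairs=tuple(pairs))


# ---------------------------------------------------------------------------
# Superposition


def kabsch_superpose(
    chain_a: StructureChain, chain_b: StructureChain, pairs: Correspondence
) -> RigidTransform:
    """Least-squares optimal rigid superposition of chain_b onto chain_a.

    Closed-form Kabsch solution via SVD, with the usual determinant
    correction so the rotation is proper. Rank-deficient (collinear) point
    sets are handled by the same SVD path (the optimum is then non-unique;
    a warning is logged).
    """
    ia, ib = pairs.indices()
    if len(ia) < 3:
        raise ValueError("superposition needs >= 3 pairs")
    P = chain_b.coords[ib]  # moving
    Q = chain_a.coords[ia]  # fixed
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-10 * max(S[0], 1.0):
        logger.warning("degenerate (collinear) point set in superposition")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd)


def _longest_monotone_subset(pairs: list[tuple[int, int, float]]) -> list[tuple[int, int]]:
    """Longest strictly-increasing (in both indices) subset; ties by distance.

    *pairs* are (index_a, index_b, distance) with unique index_a. Classic
    O(n^2) longest-increasing-subsequence on index_b after sorting by
    index_a, preferring smaller total distance among equal-length chains.
    """
    pairs = sorted(pairs)
    n = len(pairs)
    if n == 0:
        return []
    best_len = [1] * n
    best_dist = [p[2] for p in pairs]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if pairs[j][0] < pairs[i][0] and pairs[j][1] < pairs[i][1]:
                cand_len = best_len[j] + 1
                cand_dist = best_dist[j] + pairs[i][2]
                if cand_len > best_len[i] or (
                    cand_len == best_len[i] and cand_dist < best_dist[i]
                ):
                    best_len[i] = cand_len
                    best_dist[i] = cand_dist
                    prev[i] = j
    end = max(range(n), key=lambda i: (best_len[i], -best_dist[i]))
    out = []
    while end != -1:
        out.append((pairs[end][0], pairs[end][1]))
        end = prev[end]
    return out[::-1]


_SEED_GAPS = GapModel(open_penalty=1.0, extend_penalty=0.5)


def _seed_pairs(chain_a: StructureChain, chain_b: StructureChain) -> list[tuple[int, int]]:
    """Initial pairing from a sequence alignment under the identity matrix."""
    result = global_align(chain_a.sequence, chain_b.sequence, unit_matrix(1, 0), _SEED_GAPS)
    pairs = []
    i = j = 0
    for ca, cb in zip(result.aligned_a, result.aligned_b):
        if ca != "-" and cb != "-":
            pairs.append((i, j))
        if ca != "-":
            i += 1
        if cb != "-":
            j += 1
    if len(pairs) < 3:
        # fall back to aligning the leading index ranges
        m = min(chain_a.length, chain_b.length)
        pairs = [(k, k) for k in range(m)]
    return pairs


def extract_correspondences(
    chain_a: StructureChain,
    chain_b: StructureChain,
    proximity_threshold: float = 5.0,
    max_iters: int = 20,
) -> Correspondence:
    """Iterative superposition/re-pairing correspondence extraction.

    Returns the final (possibly empty) strictly monotone correspondence of
    mutual nearest alpha-carbon neighbors within *proximity_threshold* Å.
    """
    current = _seed_pairs(chain_a, chain_b)
    for _ in range(max_iters):
        if len(current) < 3:
            return Correspondence(pairs=())
        transform = kabsch_superpose(chain_a, chain_b, Correspondence(tuple(current)))
        moved_b = transform.apply(chain_b.coords)
        tree_a = cKDTree(chain_a.coords)
        tree_b = cKDTree(moved_b)
        d_ab, nn_ab = tree_b.query(chain_a.coords)  # for each a: nearest b
        d_ba, nn_ba = tree_a.query(moved_b)  # for each b: nearest a
        cand = [
            (ia, int(nn_ab[ia]), float(d_ab[ia]))
            for ia in range(chain_a.length)
            if d_ab[ia] <= proximity_threshold and nn_ba[nn_ab[ia]] == ia
        ]
        new = _longest_monotone_subset(cand)
        if new == current:
            break
        current = new
    if len(current) < 3:
        return Correspondence(pairs=())
    return Correspondence(pairs=tuple(current))


def pair_block_from_correspondence(
    chain_a: StructureChain,
    chain_b: StructureChain,
    corr: Correspondence,
    family_id: str,
) -> UngappedPairBlock:
    """Ungapped pair block of the residue codes at corresponding positions."""
    if not corr.pairs:
        raise ValueError("empty correspondence")
    ia, ib = corr.indices()
    seq_a = "".join(chain_a.sequence[i] for i in ia)
    seq_b = "".join(chain_b.sequence[j] for j in ib)
    return UngappedPairBlock(family_id=family_id, seq_a=seq_a, seq_b=seq_b)


# ---------------------------------------------------------------------------
# Sequence identity

_IDENTITY_GAPS = GapModel(open_penalty=10.0, extend_penalty=1.0)
_identity_matrix_cache: dict[str, SubstitutionMatrix] = {}


def sequence_identity(
    seq_a: str,
    seq_b: str,
    matrix: SubstitutionMatrix | None = None,
    gaps: GapModel = _IDENTITY_GAPS,
) -> float:
    """Global-alignment sequence identity (BLOSUM62, gap open 10 / extend 1).

    Identity = identical aligned columns / total alignment columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if matrix is None:
        matrix = _identity_matrix_cache.setdefault("BLOSUM62", load_standard("BLOSUM62"))
    result = global_align(seq_a, seq_b, matrix, gaps)
    same = sum(
        1 for x, y in zip(result.aligned_a, result.aligned_b) if x == y and x != "-"
    )
    return same / result.columns
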