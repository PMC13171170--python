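"""Seeded generators for synthetic fixtures with known ground truth.

Every generator is a pure function of its parameters and a seed. Four kinds
of fixture are produced:

* sequence families drawn from a known substitution process, whose analytic
  half-bit log-odds matrix is available in closed form (for estimator
  parameter-recovery tests);
* toy 3D chain pairs on a helical backbone with a planted deletion, noise and
  rigid motion, with the true residue correspondence recorded;
* gapped reference alignments with their ungapped sequences (for Q/TC and
  realignment tests);
* labeled Gaussian score sets and vector clusters (for ROC/PR and
  nearest-neighbor retrieval tests).

The substitution process is parameterized directly at the level of the joint
per-column pair distribution: divergence ``d`` interpolates between identity
(d = 0, every pair conserved) and independence (d = 1, pairs drawn from the
product of marginals),

    Q = (1 - d) * diag(p) + d * p p^T,

which keeps the implied log-odds in closed form with no rate-matrix
exponentials. Members of a family are drawn conditionally independent given a
common ancestor column; two members then follow the same family of joint
distributions with effective pair divergence ``d(2 - d)``, and it is that
pair-level process whose analytic log-odds the family records as its truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counts import Family, FamilyMember, UngappedPairBlock
from .matrices import CANONICAL_ALPHABET, SubstitutionMatrix
from .msa import GAP, MultipleAlignment
from .structures import Correspondence, StructureChain

_N = len(CANONICAL_ALPHABET)


def skewed_frequencies() -> np.ndarray:
    """A mildly skewed stationary distribution (catches marginal-handling bugs)."""
    w = np.linspace(1.0, 3.5, _N)
    return w / w.sum()


@dataclass(frozen=True)
class SubstitutionProcess:
    """Joint per-column pair distribution with tunable divergence."""

    stationary: np.ndarray = field(default_factory=lambda: np.full(_N, 1.0 / _N))
    divergence: float = 0.3

    def __post_init__(self) -> None:
        p = np.asarray(self.stationary, dtype=float)
        object.__setattr__(self, "stationary", p)
        if p.shape != (_N,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("stationary must be a length-20 probability vector")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")

    @property
    def joint(self) -> np.ndarray:
        """Ordered-pair joint distribution Q (20 x 20, sums to 1, marginals p)."""
        p, d = self.stationary, self.divergence
        return (1.0 - d) * np.diag(p) + d * np.outer(p, p)

    def conditional(self) -> np.ndarray:
        """P(child = y | parent = x) rows; rows sum to 1 where p_x > 0."""
        p, d = self.stationary, self.divergence
        return (1.0 - d) * np.eye(_N) + d * np.tile(p, (_N, 1))

    def pair_process(self) -> "SubstitutionProcess":
        """Process governing two children of a common ancestor: d -> d(2-d)."""
        d = self.divergence
        return SubstitutionProcess(self.stationary, d * (2.0 - d))

    def expected_identity(self) -> float:
        return float(np.trace(self.joint))

    def analytic_log_odds(
        self, scale_bits: float = 0.5, rounding: bool = True
    ) -> SubstitutionMatrix:
        """Closed-form half-bit log-odds implied by the joint distribution.

        Unordered-pair probabilities are q_ii = Q_ii and q_ij = 2 Q_ij;
        expected frequencies come from the marginals p: e_ii = p_i^2,
        e_ij = 2 p_i p_j; the score is (1/scale_bits) * log2(q/e).
        """
        Q = self.joint
        p = self.stationary
        if (p <= 0).any() or self.divergence == 0.0:
            raise ValueError("log-odds undefined: zero cells in the joint")
        e = np.outer(p, p)
        scores = (1.0 / scale_bits) * np.log2(Q / e)
        if rounding:
            scores = np.sign(scores) * np.floor(np.abs(scores) + 0.5)
        return SubstitutionMatrix(name=f"analytic d={self.divergence:g}", scores=scores)


@dataclass
class ToyFamily:
    """A simulated family plus the ground truth needed by recovery tests."""

    family: Family
    process: SubstitutionProcess
    pair_process: SubstitutionProcess
    ancestor: str


def _draw_sequence(rng: np.random.Generator, probs: np.ndarray, length: int) -> np.ndarray:
    return rng.choice(_N, size=length, p=probs)


def simulate_family(
    n_members: int,
    length: int,
    process: SubstitutionProcess = SubstitutionProcess(),
    seed: int = 0,
    family_id: str = "fam",
) -> ToyFamily:
    """Draw a family of sequences column-wise from the substitution process.

    An ancestor is drawn from the stationary distribution; each member's
    residue at a column is drawn from the conditional given the ancestor,
    independently across members. All members have equal length (columns pair
    up directly as ungapped blocks).
    """
    if n_members < 2 or length < 1:
        raise ValueError("need n_members >= 2 and length >= 1")
    rng = np.random.default_rng(seed)
    cond = process.conditional()
    ancestor = _draw_sequence(rng, process.stationary, length)
    cum = np.cumsum(cond[ancestor], axis=1)
    members = []
    for m in range(n_members):
        u = rng.random(length)
        residues = np.minimum((u[:, None] > cum).sum(axis=1), _N - 1)
        seq = "".join(CANONICAL_ALPHABET[k] for k in residues)
        members.append(FamilyMember(member_id=f"{family_id}_m{m}", sequence=seq))
    return ToyFamily(
        family=Family(family_id=family_id, members=members),
        process=process,
        pair_process=process.pair_process(),
        ancestor="".join(CANONICAL_ALPHABET[k] for k in ancestor),
    )


def simulate_families(
    n_families: int,
    n_members: int,
    length: int,
    process: SubstitutionProcess = SubstitutionProcess(),
    seed: int = 0,
) -> list[ToyFamily]:
    """Independent families sharing one process (seeds derived from *seed*)."""
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_families)
    return [
        simulate_family(n_members, length, process, seed=int(s), family_id=f"fam{k}")
        for k, s in enumerate(child)
    ]


# ---------------------------------------------------------------------------
# Toy structures

_CA_SPACING = 3.8  # consecutive alpha-carbon distance, Å


def _helix_coords(length: int) -> np.ndarray:
    """Idealized helical CA trace rescaled to exactly 3.8 Å spacing."""
    t = np.deg2rad(100.0) * np.arange(length)
    coords = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(length)])
    spacing = np.linalg.norm(coords[1] - coords[0])
    return coords * (_CA_SPACING / spacing)


def simulate_structure_pair(
    length: int = 60,
    deletion_run: int = 5,
    coordinate_noise_sd: float = 0.5,
    seed: int = 0,
    deletion_start: int | None = None,
) -> tuple[StructureChain, StructureChain, Correspondence]:
    """A helical chain and a perturbed homolog with known correspondence.

    The homolog deletes a contiguous run of residues, adds isotropic Gaussian
    coordinate noise, and is moved by a random rigid transform. The returned
    correspondence maps surviving base-chain residues to homolog positions.
    """
    if deletion_run >= length:
        raise ValueError("deletion_run must be smaller than length")
    rng = np.random.default_rng(seed)
    seq = "".join(CANONICAL_ALPHABET[k] for k in rng.integers(0, _N, size=length))
    coords = _helix_coords(length)
    chain_a = StructureChain(chain_id="A", sequence=seq, coords=coords)

    if deletion_run > 0:
        start = (
            int(rng.integers(1, length - deletion_run))
            if deletion_start is None
            else deletion_start
        )
        keep = [i for i in range(length) if not start <= i < start + deletion_run]
    else:
        keep = list(range(length))
    coords_b = coords[keep] + coordinate_noise_sd * rng.standard_normal((len(keep), 3))
    # random proper rotation from a normalized quaternion
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    coords_b = coords_b @ R.T + rng.uniform(-20, 20, size=3)
    chain_b = StructureChain(
        chain_id="B", sequence="".join(seq[i] for i in keep), coords=coords_b
    )
    truth = Correspondence(pairs=tuple((i, k) for k, i in enumerate(keep)))
    return chain_a, chain_b, truth


def write_chain_pdb(chain: StructureChain, path) -> None:
    """Write a CA-only PDB rendering of a toy chain."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    one_to_three = {v: k for k, v in {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
        "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
        "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
        "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    }.items()}
    atoms = struc.AtomArray(chain.length)
    atoms.coord = chain.coords.astype(np.float32)
    atoms.chain_id = np.full(chain.length, chain.chain_id)
    atoms.res_id = np.arange(1, chain.length + 1)
    atoms.res_name = np.array([one_to_three[c] for c in chain.sequence])
    atoms.atom_name = np.full(chain.length, "CA")
    atoms.element = np.full(chain.length, "C")
    atoms.hetero = np.zeros(chain.length, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(path)


def write_chain_cif(chain: StructureChain, path) -> None:
    """Write a CA-only mmCIF rendering of a toy chain."""
    import biotite.structure as struc
    from biotite.structure.io.pdbx import CIFFile, set_structure

    # reuse the PDB atom construction
    import tempfile, os

    with tempfile.NamedTemporaryFile(suffix=".pdb", delete=False) as tmp:
        tmp_path = tmp.name
    try:
        write_chain_pdb(chain, tmp_path)
        from biotite.structure.io.pdb import PDBFile

        atoms = PDBFile.read(tmp_path).get_structure(model=1)
    finally:
        os.unlink(tmp_path)
    cif = CIFFile()
    set_structure(cif, atoms)
    cif.write(path)


# ---------------------------------------------------------------------------
# Reference MSAs


def simulate_reference_msa(
    n: int,
    length: int,
    gap_rate: float,
    process: SubstitutionProcess = SubstitutionProcess(),
    seed: int = 0,
) -> tuple[MultipleAlignment, list[str]]:
    """A ground-truth alignment: process-drawn columns with per-cell gaps.

    Gaps replace residues independently per cell with probability *gap_rate*;
    rows that would lose every residue keep their first column. Returns the
    truth alignment and the ungapped sequences (row order preserved).
    """
    if not 0.0 <= gap_rate < 1.0:
        raise ValueError("gap_rate must lie in [0, 1)")
    fam = simulate_family(n, length, process, seed=seed, family_id="msa")
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31 - 1))
    rows = []
    for member in fam.family.members:
        gaps = rng.random(length) < gap_rate
        if gaps.all():
            gaps[0] = False
        rows.append(
            "".join(GAP if g else c for g, c in zip(gaps, member.sequence))
        )
    msa = MultipleAlignment(
        ids=tuple(m.member_id for m in fam.family.members), rows=tuple(rows)
    )
    stripped = [row.replace(GAP, "") for row in rows]
    return msa, stripped


# ---------------------------------------------------------------------------
# Labeled scores and vectors


def simulate_labeled_scores(
    n_pos: int, n_neg: int, separation: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian score populations: positives N(separation, 1), negatives N(0, 1)."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one score per class")
    rng = np.random.default_rng(seed)
    scores = np.concatenate(
        [separation + rng.standard_normal(n_pos), rng.standard_normal(n_neg)]
    )
    flags = np.concatenate([np.ones(n_pos, dtype=bool), np.zeros(n_neg, dtype=bool)])
    return scores, flags


def simulate_vectors(
    n_per_label: int,
    labels: list[str],
    cluster_sd: float,
    seed: int = 0,
    dim: int = 8,
    center_scale: float = 5.0,
):
    """Isotropic Gaussian clusters, one per label, at scale *center_scale*."""
    from .homology import VectorDataset

    if n_per_label < 1 or not labels:
        raise ValueError("need at least one vector per label")
    rng = np.random.default_rng(seed)
    centers = center_scale * rng.standard_normal((len(labels), dim))
    ids, vecs, labs = [], [], []
    for c, label in enumerate(labels):
        for k in range(n_per_label):
            ids.append(f"{label}_{k}")
            vecs.append(centers[c] + cluster_sd * rng.standard_normal(dim))
            labs.append(label)
    return VectorDataset(ids=tuple(ids), vectors=np.asarray(vecs), labels=tuple(labs))
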