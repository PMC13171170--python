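"""Substitution-matrix data model, I/O, embedded standard tables, and comparison statistics.

A substitution matrix is a symmetric table of log-odds scores over the 20
canonical amino acids. This module provides the :class:`SubstitutionMatrix`
container, readers/writers for the NCBI/EMBOSS whitespace table format,
embedded copies of the standard BLOSUM45/62/80 and PAM120/250 tables, and the
statistics used to compare matrices with each other:

* Pearson correlation of two matrices (vectorized over all 400 entries by
  default, or over the 210 unique entries of the upper triangle),
* "evolutionary distance" |mean(diagonal) / mean(off-diagonal)|, a scalar
  proxy for the divergence regime a matrix targets,
* the fraction of identical unique entries between two integer matrices,
* a 2-component PCA embedding of a collection of matrices.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

#: Canonical amino-acid alphabet, in the fixed order used by NCBI matrices.
CANONICAL_ALPHABET: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

#: Extended residue codes dropped on load (ambiguity codes and the stop column).
EXTENDED_CODES = frozenset("BZXJUO*")

#: Names of the standard matrices embedded with the package.
STANDARD_MATRICES = ("BLOSUM45", "BLOSUM62", "BLOSUM80", "PAM120", "PAM250")


class MatrixFormatError(ValueError):
    """Raised for malformed matrix files (missing residues, bad rows)."""


class MatrixSymmetryError(ValueError):
    """Raised when a loaded matrix is not symmetric."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric score table over the canonical amino-acid alphabet.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"BLOSUM62"``.
    scores : numpy.ndarray
        Square symmetric array of shape ``(20, 20)`` indexed by
        :data:`CANONICAL_ALPHABET` order.
    alphabet : tuple of str
        Ordered residue codes; defaults to the canonical 20.
    """

    name: str
    scores: np.ndarray
    alphabet: tuple[str, ...] = CANONICAL_ALPHABET

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        n = len(self.alphabet)
        if len(set(self.alphabet)) != n:
            raise ValueError("alphabet entries must be unique")
        unknown = set(self.alphabet) - set(CANONICAL_ALPHABET)
        if unknown:
            raise ValueError(f"non-canonical residues in alphabet: {sorted(unknown)}")
        if scores.shape != (n, n):
            raise ValueError(f"scores must be {n}x{n}, got {scores.shape}")
        if not np.isfinite(scores).all():
            raise ValueError("scores must be finite")
        bad = np.argwhere(scores != scores.T)
        if bad.size:
            i, j = bad[0]
            raise MatrixSymmetryError(
                f"matrix {self.name!r} is asymmetric at "
                f"({self.alphabet[i]},{self.alphabet[j]}): "
                f"{scores[i, j]} != {scores[j, i]}"
            )

    @property
    def integer_valued(self) -> bool:
        return bool(np.all(self.scores == np.round(self.scores)))

    @property
    def size(self) -> int:
        return len(self.alphabet)

    def index(self, residue: str) -> int:
        try:
            return self.alphabet.index(residue)
        except ValueError:
            raise KeyError(f"residue {residue!r} not in matrix alphabet") from None

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.scores[self.index(a), self.index(b)])

    def unique_entries(self) -> np.ndarray:
        """The 210 upper-triangle entries (diagonal included), row-major."""
        iu = np.triu_indices(self.size)
        return self.scores[iu]

    def with_name(self, name: str) -> "SubstitutionMatrix":
        return SubstitutionMatrix(name=name, scores=self.scores, alphabet=self.alphabet)


@dataclass(frozen=True)
class MatrixSummary:
    """One comparison row: distance regime plus similarity to a reference."""

    name: str
    evo_dist: float | None
    corr_to_reference: float | None = None
    identical_fraction: float | None = None


# ---------------------------------------------------------------------------
# I/O


def parse_matrix(text: str, name: str = "matrix") -> SubstitutionMatrix:
    """Parse an NCBI-style whitespace matrix table.

    Comment lines start with ``#``. The first data row is the header of
    residue codes; each following row is a residue label and one score per
    header column. Extended codes (B, Z, X, *, ...) are dropped; the result is
    restricted to the canonical 20 residues in canonical order.
    """
    rows: dict[str, list[float]] = {}
    header: list[str] | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if header is None:
            header = [f.upper() for f in fields]
            continue
        label = fields[0].upper()
        values = fields[1:]
        if len(values) < len(header):
            raise MatrixFormatError(
                f"line {lineno}: row {label!r} has {len(values)} values, "
                f"expected {len(header)}"
            )
        try:
            rows[label] = [float(v) for v in values[: len(header)]]
        except ValueError as exc:
            raise MatrixFormatError(f"line {lineno}: {exc}") from None
    if header is None or not rows:
        raise MatrixFormatError("no matrix table found")
    missing = [a for a in CANONICAL_ALPHABET if a not in rows or a not in header]
    if missing:
        raise MatrixFormatError(f"missing canonical residues: {missing}")
    col = {a: header.index(a) for a in CANONICAL_ALPHABET}
    scores = np.array(
        [[rows[a][col[b]] for b in CANONICAL_ALPHABET] for a in CANONICAL_ALPHABET]
    )
    # Symmetry check happens in the constructor and names the offending pair.
    return SubstitutionMatrix(name=name, scores=scores)


def load_matrix(source, name: str | None = None) -> SubstitutionMatrix:
    """Load a matrix from a path, file object, or raw table text."""
    if hasattr(source, "read"):
        text = source.read()
        label = name or getattr(source, "name", "matrix")
    elif isinstance(source, (str, os.PathLike)) and (
        isinstance(source, os.PathLike) or "\n" not in source
    ):
        with open(source) as fh:
            text = fh.read()
        label = name or os.path.splitext(os.path.basename(os.fspath(source)))[0]
    else:
        text = source
        label = name or "matrix"
    return parse_matrix(text, name=label)


def write_matrix(matrix: SubstitutionMatrix, path=None) -> str:
    """Render a matrix as NCBI-style text (and optionally write it to *path*).

    Integer matrices round-trip bit-exactly through :func:`load_matrix`;
    non-integer matrices are rendered with 4 decimals.
    """
    integer = matrix.integer_valued
    fmt = (lambda v: "%4d" % int(round(v))) if integer else (lambda v: "%9.4f" % v)
    lines = [f"# {matrix.name}", "   " + "  ".join(matrix.alphabet)]
    for i, a in enumerate(matrix.alphabet):
        lines.append(a + " " + " ".join(fmt(v) for v in matrix.scores[i]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_standard(name: str) -> SubstitutionMatrix:
    """Load one of the embedded standard matrices (see :data:`STANDARD_MATRICES`).

    BLOSUM tables are the NCBI integer versions; BLOSUM80 is the half-bit
    scaling (the variant distributed with BLAST), not the 1/3-bit one.
    """
    key = name.upper()
    if key not in STANDARD_MATRICES:
        raise KeyError(f"unknown standard matrix {name!r}; have {STANDARD_MATRICES}")
    text = resources.files("substmat.data").joinpath(f"{key}.txt").read_text()
    return parse_matrix(text, name=key)


def unit_matrix(match: float, mismatch: float) -> SubstitutionMatrix:
    """Baseline matrix: *match* on the diagonal, *mismatch* elsewhere.

    ``unit_matrix(5, 0)`` and ``unit_matrix(5, -1)`` are the conventional
    "no substitution information" baselines whose match score is in line with
    the average diagonal of the standard matrices.
    """
    n = len(CANONICAL_ALPHABET)
    scores = np.full((n, n), float(mismatch))
    np.fill_diagonal(scores, float(match))
    return SubstitutionMatrix(name=f"unit {match:g}/{mismatch:g}", scores=scores)


# ---------------------------------------------------------------------------
# Statistics


def _check_common_alphabet(a: SubstitutionMatrix, b: SubstitutionMatrix) -> None:
    if a.alphabet != b.alphabet:
        raise ValueError(f"alphabet mismatch between {a.name!r} and {b.name!r}")


def _vectorize(m: SubstitutionMatrix, vectorization: str) -> np.ndarray:
    if vectorization == "full":
        return m.scores.ravel()
    if vectorization == "unique":
        return m.unique_entries()
    raise ValueError(f"vectorization must be 'full' or 'unique', got {vectorization!r}")


def pearson_correlation(
    a: SubstitutionMatrix, b: SubstitutionMatrix, vectorization: str = "full"
) -> float:
    """Pearson correlation of two matrices.

    With ``vectorization="full"`` (default) all 400 entries enter the
    correlation, matching a whole-matrix ``numpy.corrcoef`` call; with
    ``"unique"`` only the 210 upper-triangle entries do.
    """
    _check_common_alphabet(a, b)
    va, vb = _vectorize(a, vectorization), _vectorize(b, vectorization)
    for v, m in ((va, a), (vb, b)):
        if np.ptp(v) == 0:
            raise ValueError(f"correlation undefined: matrix {m.name!r} is constant")
    return float(np.corrcoef(va, vb)[0, 1])


def evolutionary_distance(m: SubstitutionMatrix) -> float | None:
    """|mean(diagonal) / mean(off-diagonal)|, or None when undefined.

    Invariant to uniform positive rescaling. A zero mean off-diagonal (e.g.
    the 5/0 unit matrix) leaves the ratio undefined.
    """
    diag = float(np.mean(np.diag(m.scores)))
    n = m.size
    off = float((m.scores.sum() - np.trace(m.scores)) / (n * (n - 1)))
    if off == 0.0:
        return None
    return abs(diag / off)


def identical_fraction(a: SubstitutionMatrix, b: SubstitutionMatrix) -> float:
    """Fraction of the 210 unique entries that agree between two integer matrices."""
    _check_common_alphabet(a, b)
    if not (a.integer_valued and b.integer_valued):
        raise ValueError("identical_fraction is defined for integer matrices only")
    ua, ub = a.unique_entries(), b.unique_entries()
    return float(np.mean(np.round(ua) == np.round(ub)))


def matrix_pca(matrices: Sequence[SubstitutionMatrix]):
    """Project matrices (as 210-d unique-entry vectors) onto two principal components.

    Returns ``(coordinates, explained_variance_ratio)`` where *coordinates*
    has one row per matrix and *explained_variance_ratio* the (non-increasing)
    variance fractions of the two components.
    """
    from sklearn.decomposition import PCA

    if len(matrices) < 2:
        raise ValueError("matrix_pca requires at least 2 matrices")
    alph = matrices[0].alphabet
    for m in matrices[1:]:
        if m.alphabet != alph:
            raise ValueError("matrix_pca requires a common alphabet")
    X = np.stack([m.unique_entries() for m in matrices])
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_


def summarize(
    m: SubstitutionMatrix,
    reference: SubstitutionMatrix | None = None,
    vectorization: str = "full",
) -> MatrixSummary:
    """Comparison-table row for *m*, optionally against a reference matrix."""
    corr = ident = None
    if reference is not None:
        corr = pearson_correlation(m, reference, vectorization)
        if m.integer_valued and reference.integer_valued:
            ident = identical_fraction(m, reference)
    return MatrixSummary(
        name=m.name,
        evo_dist=evolutionary_distance(m),
        corr_to_reference=corr,
        identical_fraction=ident,
    )
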