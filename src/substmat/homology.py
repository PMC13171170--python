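"""Remote-homology benchmarking: all-vs-all alignment scores, ROC/PR AUC, and
nearest-neighbor retrieval on precomputed per-sequence vectors.

The homology task is binary: does a pair of domains belong to the same
superfamily? Every unordered sequence pair is scored by global alignment, the
same/different-superfamily flag is the label, and the separation of the two
score populations is summarized as the area under the ROC curve (equivalently,
the probability that a random positive pair outscores a random negative pair,
ties at half credit) and the area under the precision–recall curve (step-wise
average-precision integration).

Sequence embeddings enter only as precomputed numeric vectors: retrieval is
exact nearest-neighbor under Euclidean (L2) distance, and retrieval quality is
a micro-averaged one-vs-rest AUC over binarized labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import GapModel, global_align, integer_scale
from .matrices import SubstitutionMatrix


@dataclass(frozen=True)
class LabeledDataset:
    """Sequences with superfamily labels."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.sequences) == len(self.labels)):
            raise ValueError("ids, sequences and labels must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dupes = {i for i in self.ids if self.ids.count(i) > 1}
            raise ValueError(f"duplicate ids: {sorted(dupes)}")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class VectorDataset:
    """Precomputed numeric vectors (one per entry) with labels."""

    ids: tuple[str, ...]
    vectors: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", vectors)
        if vectors.ndim != 2 or vectors.shape[1] == 0:
            raise ValueError("vectors must be a non-empty 2D array")
        if vectors.shape[0] != len(self.ids) or len(self.ids) != len(self.labels):
            raise ValueError("ids, vectors and labels must agree in length")
        if not np.isfinite(vectors).all():
            raise ValueError("vectors must be finite")


def all_vs_all_scores(
    data: LabeledDataset, matrix: SubstitutionMatrix, gaps: GapModel
) -> pd.DataFrame:
    """Global-alignment score for every unordered pair, with same-label flags.

    Fractional gap penalties are integer-scaled for the alignment and the
    scores divided back, so reported scores are on the input scale.
    """
    if data.n < 2:
        raise ValueError("need at least 2 sequences")
    factor = 1
    work_matrix, work_gaps = matrix, gaps
    if (gaps.open_penalty != int(gaps.open_penalty)) or (
        gaps.extend_penalty != int(gaps.extend_penalty)
    ):
        work_matrix, work_gaps, factor = integer_scale(matrix, gaps)
    rows = []
    for i, j in itertools.combinations(range(data.n), 2):
        score = global_align(
            data.sequences[i], data.sequences[j], work_matrix, work_gaps
        ).score / factor
        rows.append(
            {
                "id_a": data.ids[i],
                "id_b": data.ids[j],
                "score": score,
                "same_superfamily": data.labels[i] == data.labels[j],
            }
        )
    return pd.DataFrame(rows)


def _check_two_classes(flags: np.ndarray) -> None:
    if flags.all() or not flags.any():
        raise ValueError("AUC undefined: need both positive and negative flags")


def roc_auc(scores, flags) -> float:
    """ROC AUC: P(random positive outscores random negative), ties half credit."""
    from sklearn.metrics import roc_auc_score

    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    _check_two_classes(flags)
    return float(roc_auc_score(flags, scores))


def pr_auc(scores, flags) -> float:
    """Precision–recall AUC by step-wise (average precision) integration."""
    from sklearn.metrics import average_precision_score

    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    _check_two_classes(flags)
    return float(average_precision_score(flags, scores))


def nn_retrieval_auc(data: VectorDataset) -> tuple[pd.DataFrame, float]:
    """Exact L2 nearest-neighbor retrieval and micro-averaged one-vs-rest AUC.

    Each entry retrieves its nearest neighbor (self excluded); the per-class
    retrieval score is the indicator that the retrieved neighbor carries that
    class label. Micro OvR AUC is computed over the binarized label matrix.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.neighbors import NearestNeighbors

    n = len(data.ids)
    if n < 2:
        raise ValueError("need at least 2 entries")
    classes = sorted(set(data.labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 distinct labels")
    nn = NearestNeighbors(n_neighbors=2, metric="euclidean").fit(data.vectors)
    _, idx = nn.kneighbors(data.vectors)
    neighbor = np.where(idx[:, 0] == np.arange(n), idx[:, 1], idx[:, 0])
    labels = np.asarray(data.labels)
    nn_labels = labels[neighbor]
    y_true = (labels[:, None] == np.asarray(classes)[None, :]).astype(int)
    y_score = (nn_labels[:, None] == np.asarray(classes)[None, :]).astype(float)
    auc = float(roc_auc_score(y_true, y_score, average="micro"))
    table = pd.DataFrame(
        {
            "id": data.ids,
            "label": labels,
            "nn_id": [data.ids[k] for k in neighbor],
            "nn_label": nn_labels,
            "hit": labels == nn_labels,
        }
    )
    return table, auc


def read_vector_tsv(vector_path, label_path) -> VectorDataset:
    """Load vectors (id, v1..vd) and labels (id, label) from TSV files."""
    vec = pd.read_csv(vector_path, sep="\t", header=None, index_col=0)
    lab = pd.read_csv(label_path, sep="\t", header=None, index_col=0)
    lab = lab.loc[vec.index]
    return VectorDataset(
        ids=tuple(str(i) for i in vec.index),
        vectors=vec.to_numpy(dtype=float),
        labels=tuple(str(v) for v in lab.iloc[:, 0]),
    )
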