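"""Core labelled containers shared across the package.

The method operates on three kinds of objects: a binary miRNA x disease
association matrix, per-disease ancestor DAGs (MeSH-style), and labelled
symmetric similarity matrices in [0, 1].  All are thin dataclasses around
numpy arrays plus ordered id lists, validated on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import LabelMismatchError, ValidationError

#: Roles a similarity matrix can play in the pipeline.  SS1/SS2 are the two
#: DAG-based disease semantic models, KD/KM the Gaussian interaction-profile
#: kernels, FS the externally supplied miRNA functional similarity, SD/SM the
#: integrated disease/miRNA similarities.
SIMILARITY_ROLES = ("SS1", "SS2", "KD", "KM", "FS", "SD", "SM")


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate {what} ids")
    if not ids:
        raise ValidationError(f"empty {what} id list")
    return ids


@dataclass
class AssociationData:
    """Binary association matrix A (rows = miRNAs, columns = diseases)."""

    mirna_ids: list[str]
    disease_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValidationError(
                f"association matrix shape {self.A.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.disease_ids)} diseases"
            )
        if not np.isin(self.A, (0, 1)).all():
            raise ValidationError("association matrix entries must be 0 or 1")
        self.A = self.A.astype(np.int8)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def pairs(self) -> list[tuple[str, str]]:
        """Known (miRNA, disease) pairs in row-major order."""
        return [
            (self.mirna_ids[i], self.disease_ids[j])
            for i, j in zip(*np.nonzero(self.A))
        ]

    def mask_pairs(self, index_pairs: Iterable[tuple[int, int]]) -> "AssociationData":
        """Copy with the given (row, col) cells zeroed (training matrix of a CV fold)."""
        A = self.A.copy()
        for i, j in index_pairs:
            A[i, j] = 0
        return AssociationData(list(self.mirna_ids), list(self.disease_ids), A)


@dataclass(frozen=True)
class DiseaseDAG:
    """One disease's ancestor DAG: the disease, its ancestor terms, and the
    parent->child edges among them.  Every node must be the target or one of
    its ancestors, i.e. reach the target along directed edges."""

    target: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(self.edges))
        if self.target not in self.nodes:
            raise ValidationError(
                f"disease {self.target!r}: target term missing from its own DAG"
            )
        for parent, child in self.edges:
            if parent not in self.nodes or child not in self.nodes:
                raise ValidationError(
                    f"disease {self.target!r}: edge ({parent!r} -> {child!r}) "
                    "references a term outside the node set"
                )
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError(f"disease {self.target!r}: DAG contains a cycle")
        reachable = nx.ancestors(g, self.target) | {self.target}
        stranded = self.nodes - reachable
        if stranded:
            raise ValidationError(
                f"disease {self.target!r}: terms {sorted(stranded)} have no "
                "directed path to the target"
            )

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def children(self, node: str) -> set[str]:
        return {c for p, c in self.edges if p == node}


@dataclass
class SemanticContributions:
    """Per-term contributions to one disease's semantic value.

    ``model=1`` is the decay model (target contributes 1, each ancestor a
    fraction of its best child's contribution); ``model=2`` is the
    information-content model (rarer terms contribute more)."""

    model: int
    per_node: dict[str, float]
    total: float = field(init=False)

    def __post_init__(self) -> None:
        if self.model not in (1, 2):
            raise ValidationError("semantic model must be 1 or 2")
        vals = np.array(list(self.per_node.values()), dtype=float)
        if vals.size == 0 or not np.isfinite(vals).all() or (vals < 0).any():
            raise ValidationError("semantic contributions must be finite and >= 0")
        self.total = float(vals.sum())


@dataclass
class SimilarityMatrix:
    """Labelled symmetric similarity in [0, 1] with a per-pair coverage mask.

    ``coverage`` marks pairs where the role's primary source is defined
    (e.g. both diseases have a DAG for SS1/SS2, the pair appears in the
    functional-similarity input for FS).  Uncovered cells hold 0 and are
    candidates for a fallback during integration."""

    labels: list[str]
    values: np.ndarray
    role: str
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = _check_unique(self.labels, "similarity")
        if self.role not in SIMILARITY_ROLES:
            raise ValidationError(f"unknown similarity role {self.role!r}")
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValidationError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{k} labels"
            )
        if self.coverage is None:
            self.coverage = np.ones((k, k), dtype=bool)
        self.coverage = np.asarray(self.coverage, dtype=bool)
        if self.coverage.shape != (k, k):
            raise ValidationError("coverage mask shape mismatch")
        if not (self.coverage == self.coverage.T).all():
            raise ValidationError("coverage mask must be symmetric")
        if not np.isfinite(self.values).all():
            raise ValidationError("similarity values must be finite")
        vals = np.where(self.coverage, self.values, 0.0)
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError("similarity values must lie in [0, 1]")
        if np.abs(vals - vals.T).max() > 1e-8:
            raise ValidationError("similarity matrix is not symmetric")
        self.values = vals

    @property
    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def check_labels(self, labels: Sequence[str], what: str = "axis") -> None:
        if list(labels) != self.labels:
            raise LabelMismatchError(
                f"{self.role} labels do not match the {what} labels"
            )

    def reindex(self, labels: Sequence[str]) -> "SimilarityMatrix":
        """Re-order/extend to a new label list; labels absent from this
        matrix become uncovered rows/columns."""
        labels = list(labels)
        k = len(labels)
        values = np.zeros((k, k))
        coverage = np.zeros((k, k), dtype=bool)
        pos = self.index
        present = [(i, pos[lab]) for i, lab in enumerate(labels) if lab in pos]
        if present:
            new_idx, old_idx = map(np.array, zip(*present))
            values[np.ix_(new_idx, new_idx)] = self.values[np.ix_(old_idx, old_idx)]
            coverage[np.ix_(new_idx, new_idx)] = self.coverage[np.ix_(old_idx, old_idx)]
        return SimilarityMatrix(labels, values, self.role, coverage)


@dataclass
class AugmentedAdjacency:
    """Similarity-augmented weighted association matrix (A' or A'').

    Known associations keep weight exactly 1; a zero cell gains the largest
    similarity of a sufficiently similar neighbour that carries a known
    association on the relevant axis.  Degrees are those of the augmented
    bipartite network under the configured degree mode."""

    values: np.ndarray
    side: str  # "mirna_augmented" | "disease_augmented"
    threshold: float
    mirna_degrees: np.ndarray
    disease_degrees: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in ("mirna_augmented", "disease_augmented"):
            raise ValidationError(f"unknown augmentation side {self.side!r}")
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValidationError("augmented adjacency cells must lie in [0, 1]")
        self.mirna_degrees = np.asarray(self.mirna_degrees, dtype=float)
        self.disease_degrees = np.asarray(self.disease_degrees, dtype=float)


@dataclass
class ResourceVector:
    """Per-node heat resources at one stage of the two-pass conduction."""

    entity_axis: str  # "mirnas" | "diseases"
    values: np.ndarray
    stage: str  # "initial" | "forward" | "biased_back"

    def __post_init__(self) -> None:
        if self.entity_axis not in ("mirnas", "diseases"):
            raise ValidationError(f"unknown entity axis {self.entity_axis!r}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValidationError("resources must be finite and nonnegative")


@dataclass
class ScoreMatrix:
    """Pairwise association scores S (rows = miRNAs, columns = diseases)."""

    mirna_ids: list[str]
    disease_ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValidationError("score matrix shape does not match id lists")
        if not np.isfinite(self.S).all():
            raise ValidationError("scores must be finite")


@dataclass
class CVResult:
    """Cross-validation outcome: held-out ranks, rank-based ROC points, AUC."""

    method: str  # "loocv" | "kfold"
    k: int | None
    seed: int | None
    test_ranks: list[tuple[str, str, float]]
    roc_points: list[tuple[float, float]]
    auc: float


DagCorpus = Mapping[str, DiseaseDAG]
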