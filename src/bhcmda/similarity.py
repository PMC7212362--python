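"""Similarity construction.

Disease similarity comes from MeSH-style ancestor DAGs under two semantic
models, miRNA similarity from an externally supplied functional-similarity
matrix; both are backed by Gaussian interaction-profile (GIP) kernels
computed from the binary association matrix wherever the primary source is
undefined.

Semantic model 1 scores each term of a disease's DAG by decayed proximity:
the disease itself contributes 1 and every ancestor contributes
``semantic_delta`` times its best child's contribution.  Semantic model 2
scores a term by its information content across the DAG corpus,
``-ln(n_DAGs_containing_term / n_diseases)``, so rare (specific) terms
weigh more.  Either way the similarity of two diseases is the summed
contribution of their shared terms relative to their total semantic values.

The GIP kernel between two entities is ``exp(-gamma * ||p_a - p_b||^2)``
on their binary association profiles, with the bandwidth ``gamma``
normalised by the mean squared profile norm of the axis.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .config import RunConfig
from .datatypes import (
    AssociationData,
    DagCorpus,
    DiseaseDAG,
    SemanticContributions,
    SimilarityMatrix,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)


def semantic_contributions_model1(
    dag: DiseaseDAG, semantic_delta: float = 0.5
) -> SemanticContributions:
    """Decay-model contributions of each term of ``dag`` to its disease.

    Computed in reverse topological order (terms closer to the target
    first); the target contributes 1 and each ancestor
    ``semantic_delta * max(child contributions)``."""
    if not 0.0 < semantic_delta < 1.0:
        raise ValidationError("semantic_delta must lie in (0, 1)")
    per_node: dict[str, float] = {}
    # Edges run parent -> child, so a topological order lists ancestors
    # before descendants; walk it backwards to fill children first.
    for node in reversed(list(nx.topological_sort(dag.graph()))):
        if node == dag.target:
            per_node[node] = 1.0
        else:
            kids = dag.children(node)
            if not kids:
                raise ValidationError(
                    f"disease {dag.target!r}: term {node!r} has no path to target"
                )
            per_node[node] = semantic_delta * max(per_node[c] for c in kids)
    return SemanticContributions(model=1, per_node=per_node)


def semantic_contributions_model2(
    dag: DiseaseDAG, dag_corpus: DagCorpus
) -> SemanticContributions:
    """Information-content contributions of each term of ``dag``, relative
    to the corpus: ``-ln(n_DAGs_containing_term / n_diseases)``."""
    if not dag_corpus:
        raise ValidationError("empty DAG corpus")
    n = len(dag_corpus)
    per_node: dict[str, float] = {}
    for node in dag.nodes:
        count = sum(1 for other in dag_corpus.values() if node in other.nodes)
        if count == 0:
            raise ValidationError(
                f"term {node!r} of disease {dag.target!r} absent from the corpus"
            )
        per_node[node] = -math.log(count / n)
    return SemanticContributions(model=2, per_node=per_node)


def _pairwise_semantic(
    dags: DagCorpus,
    contribs: Mapping[str, SemanticContributions],
    labels: Sequence[str],
    role: str,
) -> SimilarityMatrix:
    k = len(labels)
    values = np.zeros((k, k))
    coverage = np.zeros((k, k), dtype=bool)
    warned = False
    for i, di in enumerate(labels):
        if di not in dags:
            continue
        ci = contribs[di]
        for j in range(i, k):
            dj = labels[j]
            if dj not in dags:
                continue
            cj = contribs[dj]
            coverage[i, j] = coverage[j, i] = True
            denom = ci.total + cj.total
            if denom == 0.0:
                if not warned:
                    logger.warning(
                        "%s: zero total semantic value for pair (%s, %s); "
                        "similarity set to 0", role, di, dj)
                    warned = True
                continue
            shared = dags[di].nodes & dags[dj].nodes
            num = sum(ci.per_node[t] + cj.per_node[t] for t in shared)
            values[i, j] = values[j, i] = num / denom
    return SimilarityMatrix(list(labels), values, role, coverage)


def semantic_similarity_model1(
    dags: DagCorpus,
    semantic_delta: float = 0.5,
    labels: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Decay-model disease similarity over a DAG corpus.

    ``labels`` may extend beyond the corpus; pairs lacking a DAG on either
    side are uncovered (similarity source undefined)."""
    if not dags:
        raise ValidationError("empty DAG corpus")
    labels = list(labels) if labels is not None else list(dags)
    contribs = {d: semantic_contributions_model1(g, semantic_delta)
                for d, g in dags.items()}
    return _pairwise_semantic(dags, contribs, labels, "SS1")


def semantic_similarity_model2(
    dags: DagCorpus, labels: Sequence[str] | None = None
) -> SimilarityMatrix:
    """Information-content disease similarity over a DAG corpus."""
    if not dags:
        raise ValidationError("empty DAG corpus")
    labels = list(labels) if labels is not None else list(dags)
    contribs = {d: semantic_contributions_model2(g, dags) for d, g in dags.items()}
    return _pairwise_semantic(dags, contribs, labels, "SS2")


def gip_kernel(
    assoc: AssociationData, axis: str, bandwidth_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over one axis of the association
    matrix.

    Disease profiles are columns of A, miRNA profiles rows.  The bandwidth
    is ``bandwidth_prime`` divided by the mean squared profile norm of the
    axis's own entities."""
    if bandwidth_prime <= 0:
        raise ValidationError("bandwidth_prime must be > 0")
    if axis == "diseases":
        profiles = assoc.A.T.astype(float)
        labels = assoc.disease_ids
        role = "KD"
    elif axis == "mirnas":
        profiles = assoc.A.astype(float)
        labels = assoc.mirna_ids
        role = "KM"
    else:
        raise ValidationError(f"unknown axis {axis!r}")
    mean_sq_norm = float((profiles ** 2).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise ValidationError("empty interaction profile: association matrix is all-zero")
    gamma = bandwidth_prime / mean_sq_norm
    values = squareform(np.exp(-gamma * pdist(profiles, "sqeuclidean")))
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(labels), values, role)


def integrate_disease_similarity(
    ss1: SimilarityMatrix, ss2: SimilarityMatrix, kd: SimilarityMatrix
) -> SimilarityMatrix:
    """Integrated disease similarity: the mean of the two semantic models
    where both diseases have a DAG, the GIP kernel otherwise."""
    if ss1.labels != ss2.labels or ss1.labels != kd.labels:
        raise ValidationError("SS1/SS2/KD label sets differ")
    semantic = ss1.coverage & ss2.coverage
    values = np.where(semantic, (ss1.values + ss2.values) / 2.0, kd.values)
    return SimilarityMatrix(list(ss1.labels), values, "SD")


def integrate_mirna_similarity(
    fs: SimilarityMatrix, km: SimilarityMatrix
) -> SimilarityMatrix:
    """Integrated miRNA similarity: functional similarity where supplied,
    the GIP kernel otherwise."""
    if fs.labels != km.labels:
        raise ValidationError("FS/KM label sets differ")
    values = np.where(fs.coverage, fs.values, km.values)
    return SimilarityMatrix(list(fs.labels), values, "SM")


def build_similarities(
    assoc: AssociationData,
    dags: DagCorpus | None,
    fs: SimilarityMatrix | None,
    cfg: RunConfig,
    ss1: SimilarityMatrix | None = None,
    ss2: SimilarityMatrix | None = None,
) -> dict[str, SimilarityMatrix]:
    """Compute the full similarity stack (SS1, SS2, KD, KM, SD, SM) for one
    association matrix.

    The semantic matrices do not depend on A and may be passed in
    precomputed (``ss1``/``ss2``); when ``dags`` is absent the disease
    similarity falls back to the kernel everywhere, likewise ``fs`` for the
    miRNA side."""
    dlabels, mlabels = assoc.disease_ids, assoc.mirna_ids
    if ss1 is None or ss2 is None:
        if dags:
            ss1 = semantic_similarity_model1(dags, cfg.semantic_delta, dlabels)
            ss2 = semantic_similarity_model2(dags, dlabels)
        else:
            empty = np.zeros((len(dlabels),) * 2)
            ss1 = SimilarityMatrix(list(dlabels), empty, "SS1", empty.astype(bool))
            ss2 = SimilarityMatrix(list(dlabels), empty, "SS2", empty.astype(bool))
    else:
        ss1.check_labels(dlabels, "disease")
        ss2.check_labels(dlabels, "disease")
    kd = gip_kernel(assoc, "diseases", cfg.gip_bandwidth_d)
    km = gip_kernel(assoc, "mirnas", cfg.gip_bandwidth_m)
    if fs is None:
        empty = np.zeros((len(mlabels),) * 2)
        fs = SimilarityMatrix(list(mlabels), empty, "FS", empty.astype(bool))
    else:
        fs = fs if fs.labels == list(mlabels) else fs.reindex(mlabels)
    sd = integrate_disease_similarity(ss1, ss2, kd)
    sm = integrate_mirna_similarity(fs, km)
    return {"SS1": ss1, "SS2": ss2, "KD": kd, "KM": km, "FS": fs, "SD": sd, "SM": sm}
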