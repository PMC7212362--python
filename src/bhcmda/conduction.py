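"""Two-pass biased heat conduction on similarity-augmented bipartite networks.

The method scores miRNA-disease pairs in two symmetric passes.  Each pass
first augments the binary association matrix with weighted edges: a zero
cell (m_i, d_j) gains the similarity of the most similar neighbour (a
miRNA for the miRNA-augmented network A', a disease for the
disease-augmented network A'') that both exceeds the pass's threshold and
carries a known association completing the pair.  Heat then flows twice
across the augmented bipartite network: every source node starts with one
unit of resource which it splits over its edges in proportion to edge
weight over source degree, and the return pass is additionally damped by
``degree^gamma`` of the receiving node — the bias that favours low-degree
(unpopular) nodes.  The final score of a pair is the mean of the miRNA's
resource after the A' pass and the disease's resource after the A'' pass.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .datatypes import (
    AssociationData,
    AugmentedAdjacency,
    ResourceVector,
    ScoreMatrix,
    SimilarityMatrix,
)
from .errors import ValidationError


def _degrees(values: np.ndarray, degree_mode: str) -> tuple[np.ndarray, np.ndarray]:
    if degree_mode == "binary":
        return ((values > 0).sum(axis=1).astype(float),
                (values > 0).sum(axis=0).astype(float))
    if degree_mode == "weighted":
        return values.sum(axis=1), values.sum(axis=0)
    raise ValidationError(f"unknown degree_mode {degree_mode!r}")


def augment_adjacency(
    assoc: AssociationData,
    sim: SimilarityMatrix,
    threshold: float,
    side: str,
    degree_mode: str = "binary",
) -> AugmentedAdjacency:
    """Build the weighted association matrix A' (``side="mirna_augmented"``,
    similarity over miRNAs) or A'' (``side="disease_augmented"``,
    similarity over diseases).

    Known associations stay exactly 1.  A zero cell (i, j) becomes the
    largest similarity ``sim(i, t) > threshold`` over miRNAs t associated
    with d_j (A'), respectively ``sim(j, t) > threshold`` over diseases t
    associated with m_i (A''); 0 if no such neighbour exists.  The
    similarity comparison is strict."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("augmentation threshold must lie in [0, 1]")
    A = assoc.A.astype(float)
    n, q = A.shape
    W = np.where(sim.values > threshold, sim.values, 0.0)
    out = np.zeros_like(A)
    if side == "mirna_augmented":
        sim.check_labels(assoc.mirna_ids, "miRNA")
        for j in range(q):
            carriers = A[:, j] > 0
            if carriers.any():
                out[:, j] = W[:, carriers].max(axis=1)
    elif side == "disease_augmented":
        sim.check_labels(assoc.disease_ids, "disease")
        for i in range(n):
            carriers = A[i, :] > 0
            if carriers.any():
                out[i, :] = W[:, carriers].max(axis=1)
    else:
        raise ValidationError(f"unknown augmentation side {side!r}")
    out = np.where(A == 1, 1.0, out)
    mdeg, ddeg = _degrees(out, degree_mode)
    return AugmentedAdjacency(out, side, threshold, mdeg, ddeg)


def forward_conduction(adj: AugmentedAdjacency, from_axis: str) -> ResourceVector:
    """First conduction pass: every ``from_axis`` node starts with one unit
    of resource and sends ``weight / degree(source)`` along each edge.
    Zero-degree sources hold no spreadable resource and are skipped."""
    if from_axis == "mirnas":
        deg = adj.mirna_degrees
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        received = adj.values.T @ inv
        return ResourceVector("diseases", received, "forward")
    if from_axis == "diseases":
        deg = adj.disease_degrees
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        received = adj.values @ inv
        return ResourceVector("mirnas", received, "forward")
    raise ValidationError(f"unknown axis {from_axis!r}")


def biased_back_conduction(
    adj: AugmentedAdjacency, forward: ResourceVector, gamma: float
) -> ResourceVector:
    """Return pass: each target node collects ``weight * resource / degree``
    from the opposite axis and the total is damped by
    ``degree(target) ** gamma`` — the degree bias.  ``gamma=0`` recovers
    plain heat conduction.  Zero-degree nodes send and receive nothing."""
    if gamma < 0:
        raise ValidationError("gamma must be >= 0")
    if forward.stage != "forward":
        raise ValidationError("biased back-conduction needs a forward resource vector")
    if forward.entity_axis == "diseases":
        sdeg, tdeg = adj.disease_degrees, adj.mirna_degrees
        spread = np.divide(forward.values, sdeg,
                           out=np.zeros_like(sdeg), where=sdeg > 0)
        total = adj.values @ spread
        axis = "mirnas"
    elif forward.entity_axis == "mirnas":
        sdeg, tdeg = adj.mirna_degrees, adj.disease_degrees
        spread = np.divide(forward.values, sdeg,
                           out=np.zeros_like(sdeg), where=sdeg > 0)
        total = adj.values.T @ spread
        axis = "diseases"
    else:
        raise ValidationError(f"unknown axis {forward.entity_axis!r}")
    damp = np.divide(1.0, tdeg ** gamma, out=np.zeros_like(tdeg), where=tdeg > 0)
    return ResourceVector(axis, damp * total, "biased_back")


def bhc_scores(
    assoc: AssociationData,
    sm: SimilarityMatrix,
    sd: SimilarityMatrix,
    cfg: RunConfig,
) -> ScoreMatrix:
    """Full two-pass scoring.

    Pass 1 (miRNA-augmented network A', threshold ``delta``): heat flows
    miRNAs -> diseases -> miRNAs, giving each miRNA a resource f'(m).
    Pass 2 (disease-augmented network A'', threshold ``eta``): heat flows
    diseases -> miRNAs -> diseases, giving each disease f''(d).  The score
    of pair (i, j) is ``(f'(m_i) + f''(d_j)) / 2``."""
    a_m = augment_adjacency(assoc, sm, cfg.delta, "mirna_augmented", cfg.degree_mode)
    fwd_d = forward_conduction(a_m, "mirnas")
    f_m = biased_back_conduction(a_m, fwd_d, cfg.gamma)

    a_d = augment_adjacency(assoc, sd, cfg.eta, "disease_augmented", cfg.degree_mode)
    fwd_m = forward_conduction(a_d, "diseases")
    f_d = biased_back_conduction(a_d, fwd_m, cfg.gamma)

    S = (f_m.values[:, None] + f_d.values[None, :]) / 2.0
    return ScoreMatrix(list(assoc.mirna_ids), list(assoc.disease_ids), S)
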