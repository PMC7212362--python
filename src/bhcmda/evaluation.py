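"""Cross-validation and ranking evaluation.

Known associations are held out (one at a time for LOOCV, in seeded
near-equal groups for k-fold), the model is rebuilt on the training matrix
and the held-out pair is ranked globally against every pair with no known
association ("candidate" pairs).  Ties get half credit (midranks), so the
pooled AUC is the Mann-Whitney probability that a held-out association
outscores a random candidate pair.

By default the Gaussian kernels and the integrated similarities are refit
from the training matrix of each fold so no information about the held-out
cell leaks through them; ``refit_similarity=False`` computes them once
from the full matrix (faster, and the likelier protocol of the original
study).  The DAG-based semantic similarities and the supplied functional
similarity do not derive from the association matrix and are never refit.
"""

from __future__ import annotations

import numpy as np
from sklearn import metrics as _skmetrics

from .config import RunConfig
from .conduction import bhc_scores
from .datatypes import (
    AssociationData,
    CVResult,
    DagCorpus,
    ScoreMatrix,
    SimilarityMatrix,
)
from .errors import ValidationError
from .similarity import (
    build_similarities,
    semantic_similarity_model1,
    semantic_similarity_model2,
)


def auc_from_ranks(
    positive_scores, candidate_scores
) -> tuple[list[tuple[float, float]], float]:
    """ROC points and AUC for positives ranked against one shared candidate
    pool.

    The curve sweeps all distinct score thresholds (TPR = fraction of
    positives above, FPR = fraction of candidates above) and the area is
    the trapezoidal integral, which equals the Mann-Whitney statistic with
    midrank tie handling."""
    pos = np.asarray(positive_scores, dtype=float)
    cand = np.asarray(candidate_scores, dtype=float)
    if pos.size == 0 or cand.size == 0:
        raise ValidationError("positive and candidate score lists must be nonempty")
    y = np.concatenate([np.ones(pos.size), np.zeros(cand.size)])
    s = np.concatenate([pos, cand])
    fpr, tpr, _ = _skmetrics.roc_curve(y, s, drop_intermediate=False)
    auc = float(_skmetrics.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def _roc_from_normalized_ranks(
    p: np.ndarray,
) -> tuple[list[tuple[float, float]], float]:
    """Rank-based ROC for pooled CV: each held-out pair contributes the
    fraction ``p`` of its fold's candidates ranked above it (ties half).
    At rank threshold t the FPR is t by construction and the TPR is the
    fraction of held-out pairs with p <= t; the AUC is mean(1 - p)."""
    auc = float(np.mean(1.0 - p))
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    for t in np.unique(p):
        tpr = float(np.mean(p <= t))
        if points[-1] != (float(t), tpr):
            points.append((float(t), float(np.mean(p < t))))
            points.append((float(t), tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points, auc


def _normalized_rank(pos_score: float, cand_scores: np.ndarray) -> tuple[float, float]:
    """(fraction of candidates above, midrank) of one held-out pair."""
    better = int((cand_scores > pos_score).sum())
    ties = int((cand_scores == pos_score).sum())
    frac_above = (better + 0.5 * ties) / cand_scores.size
    midrank = 1.0 + better + 0.5 * ties
    return frac_above, midrank


class _FoldScorer:
    """Rebuilds similarities (per configured refit policy) and scores one
    training matrix."""

    def __init__(
        self,
        assoc: AssociationData,
        cfg: RunConfig,
        dags: DagCorpus | None = None,
        fs: SimilarityMatrix | None = None,
        sd: SimilarityMatrix | None = None,
        sm: SimilarityMatrix | None = None,
    ) -> None:
        self.assoc = assoc
        self.cfg = cfg
        self.dags = dags
        self.fs = fs.reindex(assoc.mirna_ids) if fs is not None else None
        # Semantic similarities are association-independent side information:
        # compute once, reuse in every fold.
        self.ss1 = self.ss2 = None
        if dags:
            self.ss1 = semantic_similarity_model1(
                dags, cfg.semantic_delta, assoc.disease_ids)
            self.ss2 = semantic_similarity_model2(dags, assoc.disease_ids)
        if sd is not None:
            sd.check_labels(assoc.disease_ids, "disease")
        if sm is not None:
            sm.check_labels(assoc.mirna_ids, "miRNA")
        # Explicitly supplied SD/SM are treated as fold-independent inputs.
        self._fixed_sd, self._fixed_sm = sd, sm
        if not cfg.refit_similarity and (sd is None or sm is None):
            sims = build_similarities(assoc, dags, fs, cfg, self.ss1, self.ss2)
            self._fixed_sd = sd if sd is not None else sims["SD"]
            self._fixed_sm = sm if sm is not None else sims["SM"]

    def score(self, training: AssociationData) -> ScoreMatrix:
        sd, sm = self._fixed_sd, self._fixed_sm
        if sd is None or sm is None:
            sims = build_similarities(
                training, self.dags, self.fs, self.cfg, self.ss1, self.ss2)
            sd = sd if sd is not None else sims["SD"]
            sm = sm if sm is not None else sims["SM"]
        return bhc_scores(training, sm, sd, self.cfg)


def _pooled_cv(
    assoc: AssociationData,
    folds: list[np.ndarray],
    scorer: _FoldScorer,
    method: str,
    k: int | None,
    seed: int | None,
    candidate_scope: str = "global",
) -> CVResult:
    if candidate_scope not in ("global", "local"):
        raise ValidationError(f"unknown candidate scope {candidate_scope!r}")
    candidate_mask = assoc.A == 0
    ranks: list[tuple[str, str, float]] = []
    fracs: list[float] = []
    for fold in folds:
        training = assoc.mask_pairs(fold)
        scores = scorer.score(training)
        cand = scores.S[candidate_mask]
        for i, j in fold:
            if candidate_scope == "local":
                cand = scores.S[candidate_mask[:, j], j]
            frac, midrank = _normalized_rank(scores.S[i, j], cand)
            fracs.append(frac)
            ranks.append((assoc.mirna_ids[i], assoc.disease_ids[j], midrank))
    points, auc = _roc_from_normalized_ranks(np.asarray(fracs))
    return CVResult(method, k, seed, ranks, points, auc)


def loocv(
    assoc: AssociationData,
    cfg: RunConfig,
    dags: DagCorpus | None = None,
    fs: SimilarityMatrix | None = None,
    sd: SimilarityMatrix | None = None,
    sm: SimilarityMatrix | None = None,
    candidate_scope: str = "global",
) -> CVResult:
    """Leave-one-out cross-validation over the known associations.

    ``candidate_scope="global"`` ranks each held-out pair against every
    unknown pair in the matrix; ``"local"`` restricts candidates to the
    held-out pair's own disease."""
    positives = np.argwhere(assoc.A == 1)
    if positives.shape[0] == 0:
        raise ValidationError("no known associations")
    if positives.shape[0] < 2:
        raise ValidationError("need at least 2 known associations for LOOCV")
    scorer = _FoldScorer(assoc, cfg, dags, fs, sd, sm)
    folds = [positives[i:i + 1] for i in range(positives.shape[0])]
    return _pooled_cv(assoc, folds, scorer, "loocv", None, None, candidate_scope)


def kfold_cv(
    assoc: AssociationData,
    k: int,
    seed: int,
    cfg: RunConfig,
    dags: DagCorpus | None = None,
    fs: SimilarityMatrix | None = None,
    sd: SimilarityMatrix | None = None,
    sm: SimilarityMatrix | None = None,
    candidate_scope: str = "global",
) -> CVResult:
    """k-fold cross-validation: a seeded random partition of the known
    associations into k near-equal disjoint groups, each masked in turn."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    positives = np.argwhere(assoc.A == 1)
    if positives.shape[0] == 0:
        raise ValidationError("no known associations")
    if k > positives.shape[0]:
        raise ValidationError(
            f"k={k} exceeds the number of known associations ({positives.shape[0]})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(positives.shape[0])
    folds = [positives[idx] for idx in np.array_split(perm, k)]
    scorer = _FoldScorer(assoc, cfg, dags, fs, sd, sm)
    return _pooled_cv(assoc, folds, scorer, "kfold", k, seed, candidate_scope)


def top_k(
    scores: ScoreMatrix,
    assoc: AssociationData,
    disease_id: str,
    k: int,
) -> list[tuple[str, float]]:
    """The k best-scoring candidate miRNAs for one disease, known
    associations excluded, ties broken by miRNA id."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if disease_id not in scores.disease_ids:
        raise ValidationError(f"unknown disease id {disease_id!r}")
    if (assoc.mirna_ids != scores.mirna_ids
            or assoc.disease_ids != scores.disease_ids):
        raise ValidationError("score and association labels do not match")
    j = scores.disease_ids.index(disease_id)
    candidates = [
        (scores.mirna_ids[i], float(scores.S[i, j]))
        for i in range(scores.S.shape[0])
        if assoc.A[i, j] == 0
    ]
    candidates.sort(key=lambda ms: (-ms[1], ms[0]))
    return candidates[:k]
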