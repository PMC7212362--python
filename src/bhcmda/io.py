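"""Readers and writers for the package's plain-TSV exchange formats.

Three formats are defined:

* **association list** — two tab-separated columns ``mirna_id  disease_id``,
  one known association per line; lines starting with ``#`` are comments.
* **DAG table** — three columns ``target_disease  node  parent``; an empty
  parent field marks a root of that disease's ancestor DAG.
* **square similarity matrix** — a header row of labels, then one labelled
  row per entity.  Empty cells mark pairs where the similarity is undefined
  (uncovered); they trigger the kernel fallback during integration.

Score matrices are exchanged long-format:
``mirna_id  disease_id  score  known_flag``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import AssociationData, DiseaseDAG, ScoreMatrix, SimilarityMatrix
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


def _data_lines(path: str | Path):
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    with open(p) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_associations(path: str | Path) -> AssociationData:
    """Parse a miRNA-disease association pair list into a binary matrix.

    Ids are ordered by first appearance; duplicate pairs collapse to a
    single cell with a logged warning."""
    mirna_ids: list[str] = []
    disease_ids: list[str] = []
    mpos: dict[str, int] = {}
    dpos: dict[str, int] = {}
    pairs: list[tuple[int, int]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(
                f"{path}: line {lineno}: expected at least 2 tab-separated "
                f"fields (mirna_id, disease_id)"
            )
        m, d = fields[0].strip(), fields[1].strip()
        if (m, d) in seen:
            logger.warning("%s: line %d: duplicate pair (%s, %s) ignored",
                           path, lineno, m, d)
            continue
        seen.add((m, d))
        if m not in mpos:
            mpos[m] = len(mirna_ids)
            mirna_ids.append(m)
        if d not in dpos:
            dpos[d] = len(disease_ids)
            disease_ids.append(d)
        pairs.append((mpos[m], dpos[d]))
    if not pairs:
        raise ParseError(f"{path}: no associations")
    A = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.int8)
    for i, j in pairs:
        A[i, j] = 1
    return AssociationData(mirna_ids, disease_ids, A)


def write_associations(assoc: AssociationData, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#mirna_id\tdisease_id\n")
        for m, d in assoc.pairs():
            fh.write(f"{m}\t{d}\n")


def read_dag_file(path: str | Path) -> dict[str, DiseaseDAG]:
    """Parse a DAG table into one validated :class:`DiseaseDAG` per target
    disease.  Cycles or stranded terms raise a validation error naming the
    disease."""
    nodes: dict[str, set[str]] = {}
    edges: dict[str, set[tuple[str, str]]] = {}
    order: list[str] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(
                f"{path}: line {lineno}: expected (target_disease, node, parent)"
            )
        target = fields[0].strip()
        node = fields[1].strip()
        parent = fields[2].strip() if len(fields) > 2 else ""
        if not target or not node:
            raise ParseError(
                f"{path}: line {lineno}: empty target or node field"
            )
        if target not in nodes:
            nodes[target] = set()
            edges[target] = set()
            order.append(target)
        nodes[target].add(node)
        if parent:
            nodes[target].add(parent)
            edges[target].add((parent, node))
    if not order:
        raise ParseError(f"{path}: no DAG rows")
    return {t: DiseaseDAG(t, frozenset(nodes[t]), frozenset(edges[t])) for t in order}


def write_dag_file(dags: Mapping[str, DiseaseDAG], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#target_disease\tnode\tparent\n")
        for target, dag in dags.items():
            parents: dict[str, list[str]] = {n: [] for n in dag.nodes}
            for parent, child in sorted(dag.edges):
                parents[child].append(parent)
            for node in sorted(dag.nodes):
                if parents[node]:
                    for parent in parents[node]:
                        fh.write(f"{target}\t{node}\t{parent}\n")
                else:
                    fh.write(f"{target}\t{node}\t\n")


def read_similarity_tsv(path: str | Path, role: str = "FS") -> SimilarityMatrix:
    """Read a square labelled similarity matrix.

    Row and column labels must agree; asymmetry beyond 1e-8 is an error.
    Values outside [0, 1] by at most 1e-6 are clipped with a warning,
    larger excursions are an error.  Empty cells become uncovered pairs."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    try:
        df = pd.read_csv(p, sep="\t", index_col=0, comment=None)
    except Exception as exc:  # pandas raises many flavours on malformed input
        raise ParseError(f"{p}: cannot parse similarity table: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise ValidationError(
            f"{p}: similarity table is not square ({df.shape[0]} rows x "
            f"{df.shape[1]} columns)"
        )
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise ValidationError(f"{p}: row labels do not match column labels")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{p}: non-numeric similarity cell: {exc}") from exc
    coverage = ~np.isnan(values)
    if not (coverage == coverage.T).all():
        raise ValidationError(f"{p}: asymmetric pattern of empty cells")
    values = np.where(coverage, values, 0.0)
    lo, hi = values.min(), values.max()
    if lo < -1e-6 or hi > 1 + 1e-6:
        raise ValidationError(
            f"{p}: similarity values outside [0, 1] (min {lo}, max {hi})"
        )
    if lo < 0 or hi > 1:
        logger.warning("%s: values outside [0, 1] by <= 1e-6 clipped", p)
        values = np.clip(values, 0.0, 1.0)
    return SimilarityMatrix(rows, values, role, coverage)


def write_similarity_tsv(sim: SimilarityMatrix, path: str | Path) -> None:
    values = np.where(sim.coverage, sim.values, np.nan)
    df = pd.DataFrame(values, index=sim.labels, columns=sim.labels)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="")


def write_scores_tsv(
    scores: ScoreMatrix,
    path: str | Path,
    assoc: AssociationData | None = None,
) -> None:
    """Write scores long-format, grouped by disease (column order), rows
    within a disease by descending score and ties by miRNA id.  The
    known_flag column is 1 where ``assoc`` marks a known association."""
    if assoc is not None:
        if (assoc.mirna_ids != scores.mirna_ids
                or assoc.disease_ids != scores.disease_ids):
            raise ValidationError("score and association labels do not match")
        known = assoc.A
    else:
        known = np.zeros(scores.S.shape, dtype=np.int8)
    with open(path, "w") as fh:
        fh.write("#mirna_id\tdisease_id\tscore\tknown_flag\n")
        for j, d in enumerate(scores.disease_ids):
            col = scores.S[:, j]
            order = sorted(range(len(col)),
                           key=lambda i: (-col[i], scores.mirna_ids[i]))
            for i in order:
                fh.write(
                    f"{scores.mirna_ids[i]}\t{d}\t{_FLOAT_FMT % col[i]}\t{known[i, j]}\n"
                )


def read_scores_tsv(path: str | Path) -> tuple[ScoreMatrix, np.ndarray]:
    """Read a long-format score table back into a matrix plus known-flag
    matrix.  Ids are ordered by first appearance."""
    mirna_ids: list[str] = []
    disease_ids: list[str] = []
    mpos: dict[str, int] = {}
    dpos: dict[str, int] = {}
    rows: list[tuple[int, int, float, int]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(
                f"{path}: line {lineno}: expected "
                "(mirna_id, disease_id, score, known_flag)"
            )
        m, d, s, k = (f.strip() for f in fields[:4])
        if m not in mpos:
            mpos[m] = len(mirna_ids)
            mirna_ids.append(m)
        if d not in dpos:
            dpos[d] = len(disease_ids)
            disease_ids.append(d)
        try:
            rows.append((mpos[m], dpos[d], float(s), int(k)))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if not rows:
        raise ParseError(f"{path}: no score rows")
    S = np.full((len(mirna_ids), len(disease_ids)), np.nan)
    known = np.zeros(S.shape, dtype=np.int8)
    for i, j, s, k in rows:
        S[i, j] = s
        known[i, j] = k
    if np.isnan(S).any():
        raise ValidationError(f"{path}: score table does not cover all pairs")
    return ScoreMatrix(mirna_ids, disease_ids, S), known
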