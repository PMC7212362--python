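# Methods

## Model

The package scores unobserved miRNA–disease pairs by two-pass heat
conduction on a bipartite graph whose edge set is the known association
matrix `A` (`n` miRNAs × `q` diseases) *augmented* with
similarity-derived weighted edges.

### Similarity stack

* **Semantic model 1 (decay).** Each disease is described by an ancestor
  DAG. The disease's own term contributes 1; an ancestor contributes
  `Δ × max(contributions of its children in the DAG)`, evaluated in
  reverse topological order. The similarity of two diseases is
  `Σ_{t shared} (c_i(t) + c_j(t)) / (V_i + V_j)` where `V` is the sum of
  a disease's contributions.
* **Semantic model 2 (information content).** A term contributes
  `−ln(m_t / N)` where `m_t` is the number of corpus DAGs containing the
  term and `N` the corpus size, so terms shared by every disease carry no
  information and rare (specific) terms dominate. Same ratio form as
  model 1. A corpus of one disease makes every total zero; such pairs are
  defined as similarity 0 with a logged warning.
* **Gaussian interaction-profile kernels.** `exp(−γ ‖p_a − p_b‖²)` on
  binary association profiles (matrix rows for miRNAs, columns for
  diseases), with `γ = γ′ / mean(‖p‖²)` over the axis's own entities.
  An all-zero matrix leaves the bandwidth undefined and is an error.
* **Integration.** Disease similarity `SD` is the plain mean of the two
  semantic models wherever *both* diseases have a DAG (tracked by an
  explicit coverage mask, not by whether the value is positive), else the
  kernel `KD`. miRNA similarity `SM` is the supplied functional
  similarity where defined, else `KM`. On disk, undefined similarity
  cells are empty cells in the square TSV.

### Augmentation and conduction

For the miRNA-augmented network `A′` with threshold `δ`: a known cell is
exactly 1 and is never overwritten; a zero cell `(i, j)` gains the
largest `SM(i, t)` over miRNAs `t` that carry the association `(t, j)`
and satisfy `SM(i, t) > δ` (strict), else 0. The disease-augmented `A″`
with threshold `η` mirrors this with neighbour diseases of `d_j`
associated with `m_i`.

Conduction: every source node starts with one unit of resource and
spreads `w_e / d(source)` along each incident edge; the return pass sums
`w_e f / d(source)` into each target and damps the total by
`d(target)^γ`. `γ = 0` is plain heat conduction; small positive `γ`
biases the ranking toward low-degree nodes. The score of pair `(i, j)`
is the mean of the miRNA's resource from the `A′` pass and the disease's
resource from the `A″` pass.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `delta` | 0.29 | miRNA-side augmentation threshold (dimensionless similarity) |
| `eta` | 0.13 | disease-side augmentation threshold |
| `gamma` | 0.001 | degree-bias exponent of the return pass |
| `semantic_delta` | 0.5 | per-generation decay of semantic model 1 |
| `gip_bandwidth_d/m` | 1.0 | kernel bandwidth numerators γ′ |
| `degree_mode` | binary | node degree = count of nonzero incident edges; `weighted` sums weights |
| `refit_similarity` | true | rebuild kernels/integration from each fold's training matrix |

`delta`, `eta` and `gamma` are the values published with the method
(tuned on the HMDD corpus). The semantic decay 0.5 and unit kernel
bandwidths are the conventional choices in this literature; neither was
stated with the method. Natural log is used for information content —
the ratio form of the similarity makes the base unobservable.

## Numerical and design choices

* **Degree of a weighted node.** The augmented networks are weighted but
  the method's origin is an unweighted recommender graph, so the default
  degree is the count of nonzero incident edges; a weighted-degree mode
  is provided.
* **Zero-degree nodes** (legal in CV folds) send and receive nothing
  rather than raising on division by zero.
* **Profile orientation.** Disease profiles are columns of `A` and miRNA
  profiles rows, consistent with `A` being miRNA × disease.
* **Ranking protocol.** Cross-validation ranks each held-out association
  against every pair with no known association in the full matrix
  (global candidates); a per-disease local ranking mode exists
  (`candidate_scope="local"`). Ties get midrank credit, making the
  pooled AUC a Mann–Whitney statistic; `auc_from_ranks` additionally
  returns the threshold-swept ROC polyline, whose trapezoidal area
  equals that statistic to machine precision.
* **Refit policy.** Kernels and the integrated `SD`/`SM` are rebuilt from
  each fold's training matrix by default, so nothing about the held-out
  cell leaks through them; `refit_similarity=False` computes them once
  from the full matrix (faster, and likelier the original protocol).
  DAG-based similarities and the supplied functional similarity do not
  derive from `A` and are never refit.
* **Ties in output files** are broken by miRNA id so writes are
  deterministic; floats are written at 12 significant digits.

## Synthetic data

The generator plants the method's premise as aligned blocks: miRNAs and
diseases are partitioned into matched groups; associations are
`Bernoulli(p_in = 0.3)` within a matched group and
`Bernoulli(p_out = 0.02)` outside (60 × 40, 4 blocks by default);
functional similarity is 0.8 within miRNA blocks and 0.1 across, plus
symmetric Gaussian noise (sd 0.05), clipped to `[0, 1]`, with a random
10 % of pairs left undefined to exercise the kernel fallback; each
block owns ancestor chains under a global root (depth 3, 2 chains per
block), so same-block diseases share non-root ancestors. Sizes were
chosen so a full leave-one-out run with per-fold refits completes in
seconds on one CPU.

What the generator does *not* emulate: heavy-tailed degree
distributions. Real association catalogues are dominated by hub miRNAs
and well-studied diseases with dozens to hundreds of annotations, while
the block design gives every node a near-identical binomial degree.
This matters for interpreting evaluation results, below.

## Known limitations

With uniform initial resources (every source node starts at 1, as the
method specifies), the final score `S(i,j) = (f′(m_i) + f″(d_j))/2` is
*additive in per-node quantities*: within any one disease, candidate
miRNAs are ordered purely by `f′(m)`, identically across diseases. The
method therefore cannot express pair-level interactions — which miRNA
goes with which disease — beyond what the augmentation bakes into the
node resources; its cross-validated ranking power comes from node-degree
heterogeneity (well-connected nodes accumulate more heat and also
account for more held-out positives). Two consequences, both measured by
the test suite and `scripts/acceptance.py` rather than asserted from
theory alone:

* On the homogeneous planted-block synthetic data the leave-one-out AUC
  stays near chance (≈ 0.48 mean over 10 seeds) even though the planted
  block signal is strong, because block membership is a pair-level
  interaction invisible to an additive score, and masking the held-out
  edge slightly *lowers* the test pair's two node resources relative to
  untouched candidates. The permutation-null AUC (≈ 0.47–0.50) is
  statistically indistinguishable from the planted condition.
* On matrices with heavy-tailed degrees the same code climbs well above
  chance, consistent with the strong results reported for this family of
  methods on real catalogues, where hubs dominate.

Scores are comparable across the matrix but are heat resources, not
probabilities; only their ranking is meaningful. The pair-list
association format cannot represent entities with no associations, so
isolated entities present in a generator specification drop out of a
write/read round trip.
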