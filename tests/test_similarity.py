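import math

import numpy as np
import pytest

from bhcmda import (
    AssociationData,
    DiseaseDAG,
    ValidationError,
    gip_kernel,
    integrate_disease_similarity,
    integrate_mirna_similarity,
    semantic_contributions_model1,
    semantic_contributions_model2,
    semantic_similarity_model1,
    semantic_similarity_model2,
)
from conftest import make_sim, random_assoc
from naive_bhc import naive_gip


def chain_dag(target, depth):
    """root -> a1 -> ... -> target chain of the given edge count."""
    nodes = [f"a{k}" for k in range(depth)] + [target]
    edges = set(zip(nodes[:-1], nodes[1:]))
    return DiseaseDAG(target, set(nodes), edges)


class TestSemanticModel1:
    def test_single_node_dag_contributes_one(self):
        dag = DiseaseDAG("d1", {"d1"}, set())
        c = semantic_contributions_model1(dag, 0.5)
        assert c.per_node == {"d1": 1.0} and c.total == 1.0

    def test_chain_decays_by_delta(self):
        dag = DiseaseDAG("d1", {"d1", "r"}, {("r", "d1")})
        c = semantic_contributions_model1(dag, 0.5)
        assert c.per_node == {"d1": 1.0, "r": 0.5}
        assert c.total == pytest.approx(1.5)

    def test_diamond_takes_max_over_children(self):
        dag = DiseaseDAG(
            "d1", {"d1", "a", "b", "r"},
            {("r", "a"), ("r", "b"), ("a", "d1"), ("b", "d1")},
        )
        c = semantic_contributions_model1(dag, 0.5)
        assert c.per_node == {"d1": 1.0, "a": 0.5, "b": 0.5, "r": 0.25}
        assert c.total == pytest.approx(2.25)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_delta_outside_open_interval_rejected(self, bad):
        dag = DiseaseDAG("d1", {"d1"}, set())
        with pytest.raises(ValidationError):
            semantic_contributions_model1(dag, bad)


class TestSemanticSimilarityModel1:
    def test_self_similarity_is_one(self, shared_root_dags):
        ss1 = semantic_similarity_model1(shared_root_dags, 0.5)
        assert np.allclose(np.diag(ss1.values), 1.0)

    def test_shared_root_pair(self, shared_root_dags):
        ss1 = semantic_similarity_model1(shared_root_dags, 0.5)
        assert ss1.values[0, 1] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_disjoint_dags_score_zero(self):
        dags = {
            "d1": DiseaseDAG("d1", {"d1", "r1"}, {("r1", "d1")}),
            "d2": DiseaseDAG("d2", {"d2", "r2"}, {("r2", "d2")}),
        }
        ss1 = semantic_similarity_model1(dags, 0.5)
        assert ss1.values[0, 1] == 0.0

    def test_missing_dag_makes_pair_uncovered(self, shared_root_dags):
        ss1 = semantic_similarity_model1(
            shared_root_dags, 0.5, labels=["d1", "d2", "d3"]
        )
        assert ss1.coverage[0, 1]
        assert not ss1.coverage[0, 2] and not ss1.coverage[2, 2]

    def test_adding_a_shared_ancestor_never_decreases_similarity(self):
        """Enlarging the shared part of two DAGs is monotone for model 1."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            da = chain_dag("dA", int(rng.integers(1, 4)))
            db = chain_dag("dB", int(rng.integers(1, 4)))
            base = semantic_similarity_model1({"dA": da, "dB": db}, 0.5)
            grown = {
                "dA": DiseaseDAG("dA", da.nodes | {"shared_root"},
                                 da.edges | {("shared_root", next(iter(
                                     {n for n in da.nodes if not any(
                                         c == n for _, c in da.edges)})))}),
                "dB": DiseaseDAG("dB", db.nodes | {"shared_root"},
                                 db.edges | {("shared_root", next(iter(
                                     {n for n in db.nodes if not any(
                                         c == n for _, c in db.edges)})))}),
            }
            ss = semantic_similarity_model1(grown, 0.5)
            assert ss.values[0, 1] >= base.values[0, 1] - 1e-12


class TestSemanticModel2:
    def test_corpus_counts_give_information_content(self, shared_root_dags):
        c = semantic_contributions_model2(
            shared_root_dags["d1"], shared_root_dags)
        assert c.per_node["r"] == 0.0
        assert c.per_node["d1"] == pytest.approx(math.log(2.0), abs=1e-12)

    def test_single_dag_corpus_is_degenerate(self):
        dag = DiseaseDAG("d1", {"d1", "r"}, {("r", "d1")})
        c = semantic_contributions_model2(dag, {"d1": dag})
        assert c.total == 0.0

    def test_ubiquitous_term_contributes_zero(self, shared_root_dags):
        for d, dag in shared_root_dags.items():
            c = semantic_contributions_model2(dag, shared_root_dags)
            assert c.per_node["r"] == 0.0

    def test_shared_root_pair_scores_zero(self, shared_root_dags):
        ss2 = semantic_similarity_model2(shared_root_dags)
        assert ss2.values[0, 1] == 0.0

    def test_self_similarity_is_one_when_total_positive(self, shared_root_dags):
        ss2 = semantic_similarity_model2(shared_root_dags)
        assert np.allclose(np.diag(ss2.values), 1.0)

    def test_degenerate_corpus_pair_is_zero_with_warning(self, caplog):
        dag = DiseaseDAG("d1", {"d1"}, set())
        with caplog.at_level("WARNING"):
            ss2 = semantic_similarity_model2({"d1": dag})
        assert ss2.values[0, 0] == 0.0
        assert any("zero total" in r.message for r in caplog.records)


class TestGipKernel:
    def test_printed_toy_profiles(self, toy_assoc):
        # disease profiles (1,1,0) and (1,0,1): mean sq norm 2, K = e^-1
        kd = gip_kernel(toy_assoc, "diseases", 1.0)
        assert kd.values[0, 1] == pytest.approx(math.exp(-1.0), abs=1e-12)
        assert np.allclose(np.diag(kd.values), 1.0)

    def test_identical_profiles_have_unit_similarity(self):
        assoc = AssociationData(["m1", "m2"], ["d1"], np.array([[1], [1]]))
        km = gip_kernel(assoc, "mirnas", 1.0)
        assert km.values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_orthogonal_unit_profiles_closed_form(self, k):
        """k diseases with one private association each: off-diagonal
        kernel is exp(-2 * bandwidth_prime)."""
        assoc = AssociationData(
            [f"m{i}" for i in range(k)], [f"d{j}" for j in range(k)], np.eye(k, dtype=int)
        )
        bp = 0.7
        kd = gip_kernel(assoc, "diseases", bp)
        off = kd.values[~np.eye(k, dtype=bool)]
        assert np.allclose(off, math.exp(-2.0 * bp), atol=1e-12)

    def test_matches_bruteforce_loop_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            assoc = random_assoc(rng, 10, 10)
            for axis, prof in (("diseases", assoc.A.T), ("mirnas", assoc.A)):
                got = gip_kernel(assoc, axis, 1.3).values
                want = naive_gip(prof.astype(float), 1.3)
                assert np.abs(got - want).max() < 1e-12

    def test_vanishing_bandwidth_gives_all_ones(self, toy_assoc):
        kd = gip_kernel(toy_assoc, "diseases", 1e-9)
        assert np.allclose(kd.values, 1.0, atol=1e-6)

    def test_all_zero_matrix_is_an_error(self):
        assoc = AssociationData(["m1"], ["d1"], np.array([[1]]))
        assoc.A[0, 0] = 0  # bypass constructor check deliberately
        with pytest.raises(ValidationError, match="empty interaction profile"):
            gip_kernel(assoc, "diseases", 1.0)


class TestIntegration:
    def test_semantic_pairs_average_the_two_models(self):
        labels = ["d1", "d2"]
        ss1 = make_sim(labels, [[1, 0.4], [0.4, 1]], "SS1")
        ss2 = make_sim(labels, [[1, 0.2], [0.2, 1]], "SS2")
        kd = make_sim(labels, [[1, 0.7], [0.7, 1]], "KD")
        sd = integrate_disease_similarity(ss1, ss2, kd)
        assert sd.values[0, 1] == pytest.approx(0.3)

    def test_uncovered_pairs_fall_back_to_kernel(self):
        labels = ["d1", "d2"]
        cov = np.array([[True, False], [False, True]])
        ss1 = make_sim(labels, [[1, 0], [0, 1]], "SS1", cov)
        ss2 = make_sim(labels, [[1, 0], [0, 1]], "SS2", cov)
        kd = make_sim(labels, [[1, 0.7], [0.7, 1]], "KD")
        sd = integrate_disease_similarity(ss1, ss2, kd)
        assert sd.values[0, 1] == pytest.approx(0.7)
        assert np.allclose(np.diag(sd.values), 1.0)

    def test_mirna_side_prefers_functional_similarity(self):
        labels = ["m1", "m2"]
        fs = make_sim(labels, [[1, 0.55], [0.55, 1]], "FS")
        km = make_sim(labels, [[1, 0.8], [0.8, 1]], "KM")
        assert integrate_mirna_similarity(fs, km).values[0, 1] == pytest.approx(0.55)
        fs_uncov = make_sim(labels, [[1, 0], [0, 1]], "FS",
                            np.array([[True, False], [False, True]]))
        assert integrate_mirna_similarity(fs_uncov, km).values[0, 1] == pytest.approx(0.8)

    def test_label_mismatch_rejected(self):
        fs = make_sim(["m1", "m2"], [[1, 0.5], [0.5, 1]], "FS")
        km = make_sim(["m1", "mX"], [[1, 0.5], [0.5, 1]], "KM")
        with pytest.raises(ValidationError):
            integrate_mirna_similarity(fs, km)


def test_similarity_outputs_are_symmetric_unit_diagonal_in_range():
    """Invariant sweep over randomized inputs for every similarity role."""
    from bhcmda import RunConfig, build_similarities
    from bhcmda.simulate import (
        SyntheticSpec, gen_associations, gen_dag_corpus, gen_functional_similarity,
    )

    for seed in range(3):
        spec = SyntheticSpec(n_mirnas=15, n_diseases=10, n_blocks=3, seed=seed)
        sims = build_similarities(
            gen_associations(spec), gen_dag_corpus(spec),
            gen_functional_similarity(spec), RunConfig(),
        )
        for role, sim in sims.items():
            assert np.abs(sim.values - sim.values.T).max() < 1e-12, role
            assert sim.values.min() >= 0.0 and sim.values.max() <= 1.0, role
            if role in ("KD", "KM", "SD", "SM"):
                assert np.allclose(np.diag(sim.values), 1.0), role
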