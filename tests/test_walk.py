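import numpy as np
import pytest

from drwgo.semantics import lin_term_similarity, structure_ic
from drwgo.walk import (
    downward_rwr,
    drw_likelihood,
    filtered_similarity,
    stationary_profiles,
    transition_matrix,
)

from conftest import make_random_dag


def unit_sim(t1, t2):
    return 1.0


def dense_walk_oracle(W, dag, t, eta, iterations):
    """Brute-force dense |T| x |T| iteration of the walk update."""
    dense = W.matrix.toarray()
    n = len(W.terms)
    e = np.zeros(n)
    e[W.index[t]] = 1.0
    r = e.copy()
    for _ in range(iterations):
        r = eta * (dense.T @ r) + (1 - eta) * e
    return {term: r[W.index[term]] for term in W.terms}


class TestFilteredSimilarity:
    def test_non_edge_pair_zero(self, chain_dag):
        assert filtered_similarity(chain_dag, unit_sim, "c1", "c0") == 0.0

    def test_edge_pair_passes_through(self, chain_dag):
        sim = lambda a, b: 0.8
        assert filtered_similarity(chain_dag, sim, "c0", "c1") == 0.8

    def test_grandparent_to_grandchild_zero(self, chain_dag):
        # no transition between non-adjacent ancestor/descendant pairs
        assert filtered_similarity(chain_dag, unit_sim, "c0", "c2") == 0.0


class TestTransitionMatrix:
    def test_single_parent_child_weight_one(self, chain_dag):
        W = transition_matrix(chain_dag, lambda a, b: 0.37)
        assert W.weight("c0", "c1") == pytest.approx(1.0)
        assert W.weight("c1", "c2") == pytest.approx(1.0)

    def test_two_parent_normalization(self, diamond_dag):
        sims = {("d1", "d3"): 0.2, ("d2", "d3"): 0.6}
        sim = lambda a, b: sims.get((a, b), 0.5)
        W = transition_matrix(diamond_dag, sim)
        assert W.weight("d1", "d3") == pytest.approx(0.25)
        assert W.weight("d2", "d3") == pytest.approx(0.75)

    def test_equal_weights_give_uniform_over_parents(self, diamond_dag):
        W = transition_matrix(diamond_dag, unit_sim)
        assert W.weight("d1", "d3") == pytest.approx(0.5)
        assert W.weight("d2", "d3") == pytest.approx(0.5)

    def test_root_column_zero(self, diamond_dag):
        W = transition_matrix(diamond_dag, unit_sim)
        col = W.matrix[:, W.index["d0"]].toarray()
        assert np.all(col == 0)

    def test_zero_similarity_falls_back_to_uniform(self, diamond_dag, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            W = transition_matrix(diamond_dag, lambda a, b: 0.0)
        assert "fallback" in caplog.text
        assert W.weight("d1", "d3") == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_nonroot_columns_sum_to_one(self, seed):
        dag = make_random_dag(seed)
        sim = lin_term_similarity(dag, structure_ic(dag))
        W = transition_matrix(dag, sim)
        sums = np.asarray(W.matrix.sum(axis=0)).ravel()
        for t in dag.terms:
            j = W.index[t]
            if dag.parents(t):
                assert sums[j] == pytest.approx(1.0, abs=1e-12)
            else:
                assert sums[j] == 0.0


class TestDownwardRwr:
    def test_start_term_holds_one_minus_eta(self, chain_dag):
        W = transition_matrix(chain_dag, unit_sim)
        for s in range(1, 5):
            prof = downward_rwr(W, chain_dag, "c0", eta=0.5, iterations=s)
            assert prof.probs["c0"] == pytest.approx(0.5)

    @pytest.mark.parametrize("eta", [0.25, 0.5, 0.75])
    def test_chain_closed_form(self, chain_dag, eta):
        # converged profile at distance d equals (1 - eta) * eta^d
        W = transition_matrix(chain_dag, unit_sim)
        prof = downward_rwr(W, chain_dag, "c0", eta=eta, iterations=50)
        for d, term in enumerate(["c0", "c1", "c2"]):
            assert prof.probs[term] == pytest.approx((1 - eta) * eta**d, abs=1e-10)

    def test_default_chain_values(self, chain_dag):
        W = transition_matrix(chain_dag, unit_sim)
        prof = downward_rwr(W, chain_dag, "c0")
        assert prof.probs == pytest.approx({"c0": 0.5, "c1": 0.25, "c2": 0.125})

    def test_eta_zero_collapses_to_start_vector(self, chain_dag):
        W = transition_matrix(chain_dag, unit_sim)
        prof = downward_rwr(W, chain_dag, "c0", eta=0.0, iterations=10)
        assert prof.probs == pytest.approx({"c0": 1.0, "c1": 0.0, "c2": 0.0})

    def test_leaf_start(self, chain_dag):
        W = transition_matrix(chain_dag, unit_sim)
        prof = downward_rwr(W, chain_dag, "c2", eta=0.5, iterations=1)
        assert prof.probs == pytest.approx({"c2": 0.5})

    def test_parameter_validation(self, chain_dag):
        W = transition_matrix(chain_dag, unit_sim)
        with pytest.raises(ValueError):
            downward_rwr(W, chain_dag, "c0", eta=1.5)
        with pytest.raises(ValueError):
            downward_rwr(W, chain_dag, "c0", iterations=0)

    def test_support_confined_to_start_and_descendants(self, diamond_dag):
        W = transition_matrix(diamond_dag, unit_sim)
        prof = downward_rwr(W, diamond_dag, "d1")
        assert set(prof.probs) == {"d1", "d3"}

    def test_monotone_decay_along_chain(self, chain_dag):
        W = transition_matrix(chain_dag, unit_sim)
        prof = downward_rwr(W, chain_dag, "c0")
        assert prof.probs["c1"] > prof.probs["c2"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_oracle_on_random_dags(self, seed):
        dag = make_random_dag(seed, n_terms=40, max_parents=3)
        sim = lin_term_similarity(dag, structure_ic(dag))
        W = transition_matrix(dag, sim)
        for t in sorted(dag.terms)[::7]:
            prof = downward_rwr(W, dag, t, eta=0.5, iterations=10)
            oracle = dense_walk_oracle(W, dag, t, eta=0.5, iterations=10)
            support = {t} | dag.descendants(t)
            for term in dag.terms:
                got = prof.probs.get(term, 0.0)
                assert abs(got - oracle[term]) <= 1e-10
                if term not in support:
                    assert oracle[term] == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_values_in_unit_interval(self, seed):
        dag = make_random_dag(seed)
        W = transition_matrix(dag, lin_term_similarity(dag, structure_ic(dag)))
        for t in sorted(dag.terms)[:10]:
            prof = downward_rwr(W, dag, t)
            assert all(0.0 <= v <= 1.0 for v in prof.probs.values())


class TestStationaryProfiles:
    def test_empty_starts(self, chain_dag):
        W = transition_matrix(chain_dag, unit_sim)
        assert stationary_profiles(W, chain_dag, set()) == {}

    def test_single_start_matches_direct_call(self, chain_dag):
        W = transition_matrix(chain_dag, unit_sim)
        profs = stationary_profiles(W, chain_dag, {"c0"})
        assert profs["c0"].probs == downward_rwr(W, chain_dag, "c0").probs

    def test_disjoint_subtrees_have_disjoint_support(self):
        from drwgo.ontology import OntologyDag

        dag = OntologyDag(
            ["r", "a", "a1", "b", "b1"],
            [("r", "a"), ("r", "b"), ("a", "a1"), ("b", "b1")],
        )
        W = transition_matrix(dag, unit_sim)
        profs = stationary_profiles(W, dag, {"a", "b"})
        assert set(profs["a"].probs) & set(profs["b"].probs) == set()


class TestDrwLikelihood:
    def chain_profiles(self, chain_dag):
        W = transition_matrix(chain_dag, unit_sim)
        return stationary_profiles(W, chain_dag, {"c0", "c1", "c2"})

    def test_chain_example_by_hand(self, chain_dag):
        # profile of c0: {c0: .5, c1: .25, c2: .125}; off-start nonzeros
        # {.25, .125} -> theta = .1875; only c1 survives the cutoff
        profiles = self.chain_profiles(chain_dag)
        row = drw_likelihood(profiles, {"c0"}, {"c0", "c1", "c2"})
        assert row.theta == pytest.approx(0.1875)
        assert row.scores.get("c1") == pytest.approx(0.25)
        assert row.scores.get("c2", 0.0) == 0.0

    def test_full_universe_annotation_yields_empty_row(self, chain_dag):
        profiles = self.chain_profiles(chain_dag)
        row = drw_likelihood(profiles, {"c0", "c1", "c2"}, {"c0", "c1", "c2"})
        assert row.scores == {}

    def test_empty_term_set(self, chain_dag):
        row = drw_likelihood({}, set(), {"c0"})
        assert row.scores == {} and row.theta == 0.0

    def test_second_kind_term_scores_positive(self, chain_dag):
        # c2 annotated to nobody is still scored when its ancestors are:
        # pooled nonzeros {.25, .125, .25} -> theta ~ .2083 < R(c1, c2) = .25
        profiles = self.chain_profiles(chain_dag)
        row = drw_likelihood(profiles, {"c0", "c1"}, {"c0", "c1", "c2"})
        assert row.scores.get("c2", 0.0) > 0.0

    def test_strict_threshold_filters_single_uniform_entry(self, chain_dag):
        # one pooled off-start entry equals theta; strict '>' removes it
        profiles = self.chain_profiles(chain_dag)
        row = drw_likelihood(profiles, {"c1"}, {"c0", "c1", "c2"})
        assert row.scores == {}
        assert row.theta == pytest.approx(0.25)

    def test_invariant_to_enumeration_order(self, diamond_dag):
        W = transition_matrix(diamond_dag, unit_sim)
        profiles = stationary_profiles(W, diamond_dag, {"d0", "d1", "d2"})
        universe = {"d0", "d1", "d2", "d3"}
        a = drw_likelihood(profiles, {"d0", "d1", "d2"}, universe)
        b = drw_likelihood(profiles, {"d2", "d1", "d0"}, universe)
        assert a.scores == b.scores and a.theta == b.theta
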