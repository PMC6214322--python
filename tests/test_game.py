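"""The coalitional game, its Shapley value (oracle and closed form), and weights."""

import random
import warnings
from fractions import Fraction

import pytest

from shapcoex.fixtures import random_network
from shapcoex.game import (
    cluster_count_weights,
    coalition_value,
    keygene_weights,
    read_weights_tsv,
    shapley_bruteforce,
    shapley_closed_form,
    uniform_weights,
    write_scores_tsv,
    write_weights_tsv,
)
from shapcoex.graph import Network


def path_abc():
    return Network(edges=[("a", "b"), ("b", "c")])


class TestCoalitionValue:
    def test_empty_coalition_is_zero(self, fig1):
        assert coalition_value(fig1, uniform_weights(fig1), set()) == 0

    def test_hub_coalition_covers_closed_neighborhood(self, fig1):
        # {hub} plus its 5 branch neighbours, uniform weights
        assert coalition_value(fig1, uniform_weights(fig1), {"1"}) == 6

    def test_grand_coalition_is_total_weight(self, fig2):
        k = {i: float(j) for j, i in enumerate(fig2.nodes)}
        assert coalition_value(fig2, k, set(fig2.nodes)) == pytest.approx(sum(k.values()))

    def test_unknown_member_errors(self, fig1):
        with pytest.raises(KeyError):
            coalition_value(fig1, uniform_weights(fig1), {"zz"})


class TestBruteforceOracle:
    def test_path_by_permutation_enumeration(self):
        # all 6 orders of (a,b,c) enumerated by hand give (5/6, 4/3, 5/6)
        g = path_abc()
        rho = shapley_bruteforce(g, uniform_weights(g))
        assert rho == {"a": Fraction(5, 6), "b": Fraction(4, 3), "c": Fraction(5, 6)}

    def test_single_node_gets_its_own_weight(self):
        g = Network(nodes=["a"])
        assert shapley_bruteforce(g, {"a": 7}) == {"a": Fraction(7)}

    def test_size_guard(self):
        g = random_network(13, 0.3, seed=0)
        with pytest.raises(ValueError, match="closed"):
            shapley_bruteforce(g, uniform_weights(g))

    def test_clique_plus_hub_matches_closed_form(self, fig2):
        sub = fig2.subgraph({"1", "2", "5", "6", "7"})
        k = uniform_weights(sub)
        assert shapley_bruteforce(sub, k) == shapley_closed_form(sub, k, exact=True)


class TestClosedForm:
    def test_star_of_stars_exact_fractions(self, fig1):
        rho = shapley_closed_form(fig1, uniform_weights(fig1), exact=True)
        assert rho["1"] == Fraction(35, 30)
        for branch in ("2", "3", "4", "5", "6"):
            assert rho[branch] == Fraction(56, 30)
        for leaf in (str(i) for i in range(7, 22)):
            assert rho[leaf] == Fraction(21, 30)

    def test_clique_flower_values(self, fig2):
        rho = shapley_closed_form(fig2, uniform_weights(fig2))
        assert rho["1"] == pytest.approx(0.85)
        for connector in ("2", "3", "4"):
            assert rho[connector] == pytest.approx(1.20)
        for member in (str(i) for i in range(5, 14)):
            assert rho[member] == pytest.approx(0.95)

    def test_edgeless_graph_returns_weights(self):
        g = Network(nodes=["a", "b"])
        assert shapley_closed_form(g, {"a": 2.5, "b": -1.0}) == {"a": 2.5, "b": -1.0}

    def test_missing_weight_errors_naming_node(self, fig1):
        with pytest.raises(KeyError, match="21"):
            shapley_closed_form(fig1, {i: 1 for i in fig1.nodes if i != "21"})


def random_case(trial: int):
    rng = random.Random(trial)
    n = rng.randint(2, 9)
    g = random_network(n, rng.choice([0.2, 0.5, 0.8]), seed=10_000 + trial)
    k = {i: Fraction(rng.randint(0, 200), 100) for i in g.nodes}
    return g, k


class TestAxioms:
    """The four characterizing axioms plus linearity, on random graphs."""

    cases = [random_case(t) for t in range(25)]

    @pytest.mark.parametrize("trial", range(25))
    def test_oracle_equivalence_exact(self, trial):
        g, k = self.cases[trial]
        assert shapley_bruteforce(g, k) == shapley_closed_form(g, k, exact=True)

    @pytest.mark.parametrize("trial", range(25))
    def test_efficiency(self, trial):
        g, k = self.cases[trial]
        rho = shapley_closed_form(g, k, exact=True)
        assert sum(rho.values()) == sum(k[i] for i in g.nodes)

    def test_symmetry_for_twin_nodes(self):
        # x and y share weight and the same neighbour set {a, b}
        g = Network(edges=[("x", "a"), ("x", "b"), ("y", "a"), ("y", "b"), ("a", "b")])
        k = {"x": 3, "y": 3, "a": 1, "b": 5}
        rho = shapley_closed_form(g, k, exact=True)
        assert rho["x"] == rho["y"]

    @pytest.mark.parametrize("trial", range(10))
    def test_dummy_isolated_node_keeps_its_weight(self, trial):
        g, k = self.cases[trial]
        g2 = Network(nodes=list(g.nodes) + ["solo"], edges=g.edges)
        k2 = dict(k, solo=Fraction(17, 4))
        rho = shapley_closed_form(g2, k2, exact=True)
        assert rho["solo"] == Fraction(17, 4)

    @pytest.mark.parametrize("trial", range(10))
    def test_star_additivity(self, trial):
        # raising k_i by delta raises rho_j by delta/(d_i+1) exactly on N_i ∪ {i}
        g, k = self.cases[trial]
        i = g.nodes[trial % g.n_nodes]
        delta = Fraction(7, 3)
        k2 = dict(k)
        k2[i] = k2[i] + delta
        before = shapley_closed_form(g, k, exact=True)
        after = shapley_closed_form(g, k2, exact=True)
        bump = delta / (g.degree(i) + 1)
        star = g.neighbors(i) | {i}
        for j in g.nodes:
            assert after[j] - before[j] == (bump if j in star else 0)

    @pytest.mark.parametrize("trial", range(10))
    def test_linearity_in_weights(self, trial):
        g, k = self.cases[trial]
        rng = random.Random(1000 + trial)
        k2 = {i: Fraction(rng.randint(-100, 100), 50) for i in g.nodes}
        a, b = Fraction(2, 3), Fraction(-5, 7)
        mixed = {i: a * k[i] + b * k2[i] for i in g.nodes}
        r1 = shapley_closed_form(g, k, exact=True)
        r2 = shapley_closed_form(g, k2, exact=True)
        rm = shapley_closed_form(g, mixed, exact=True)
        assert all(rm[i] == a * r1[i] + b * r2[i] for i in g.nodes)


class TestWeightSchemes:
    def test_uniform(self, fig1):
        k = uniform_weights(fig1)
        assert sum(k.values()) == 21
        assert uniform_weights(Network()) == {}

    def test_keygene_indicator(self, fig1):
        k = keygene_weights(fig1, {"1"})
        rho = shapley_closed_form(fig1, k, exact=True)
        for i in ("1", "2", "3", "4", "5", "6"):
            assert rho[i] == Fraction(1, 6)
        assert rho["7"] == 0

    def test_keygene_empty_and_full(self, fig2):
        assert set(keygene_weights(fig2, set()).values()) == {0}
        assert keygene_weights(fig2, set(fig2.nodes)) == uniform_weights(fig2)

    def test_keygene_missing_ids_warn_or_raise(self, fig2):
        with pytest.warns(UserWarning, match="GENEX"):
            keygene_weights(fig2, {"1", "GENEX"})
        with pytest.raises(KeyError, match="GENEX"):
            keygene_weights(fig2, {"GENEX"}, strict=True)

    def test_cluster_counts(self, fig2):
        clusters = [{"2", "5", "6", "7"}, {"5", "8"}]
        k = cluster_count_weights(fig2, clusters)
        assert k["5"] == 2 and k["2"] == 1 and k["13"] == 0

    def test_disjoint_cover_equals_uniform(self, fig2):
        cover = [{"1", "2", "3", "4"}, set(str(i) for i in range(5, 14))]
        assert cluster_count_weights(fig2, cover) == uniform_weights(fig2)

    def test_cluster_member_outside_network_warns(self, fig2):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cluster_count_weights(fig2, [{"1", "NOPE"}])
        assert any("NOPE" in str(w.message) for w in caught)


class TestWeightScoreIO:
    def test_weights_round_trip(self, tmp_path, fig2):
        k = {i: float(j) for j, i in enumerate(fig2.nodes)}
        p = tmp_path / "w.tsv"
        write_weights_tsv(k, p)
        assert read_weights_tsv(p) == k

    def test_scores_tsv_has_min_ranks_for_ties(self, tmp_path):
        p = tmp_path / "s.tsv"
        write_scores_tsv({"a": 3.0, "b": 2.0, "c": 2.0, "d": 1.0}, p)
        rows = [line.split("\t") for line in p.read_text().splitlines()[1:]]
        ranks = {gene: int(rank) for gene, _, rank in rows}
        assert ranks == {"a": 1, "b": 2, "c": 2, "d": 4}
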