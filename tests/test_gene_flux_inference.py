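import itertools

import numpy as np
import pytest
from scipy.stats import binom

from geneflux.gene_flux_inference import (
    BDIModel,
    FitSettings,
    BranchEventPosteriors,
    count_events,
    fit_model,
    log_likelihood,
    posterior_events,
    stationary_distribution,
    transition_matrix,
)
from geneflux.phyletic import PhyleticMatrix
from geneflux.synthetic_data import _evolve_family
from geneflux.trees import parse_newick


# -- independent oracles ---------------------------------------------------


def brute_force_loglik(model, matrix, tree):
    """Exhaustive sum over all internal-node state assignments."""
    prior = stationary_distribution(model)
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    T = {id(n): transition_matrix(model, n.length) for n in nodes if n.parent is not None}
    S = model.n_max + 1
    col = {g: j for j, g in enumerate(matrix.genome_ids)}

    def scenario_prob(f, leaf_value):
        total = 0.0
        for assign in itertools.product(range(S), repeat=len(internal)):
            st = {id(n): a for n, a in zip(internal, assign)}
            p = prior[st[id(tree.root)]]
            for n in nodes:
                if n.parent is None:
                    continue
                child = st[id(n)] if not n.is_leaf else leaf_value(f, n)
                p *= T[id(n)][st[id(n.parent)], child]
            total += p
        return total

    lik = np.array([
        scenario_prob(f, lambda f_, n: matrix.counts[f_, col[n.name]])
        for f in range(matrix.n_families)
    ])
    p_absent = scenario_prob(0, lambda f_, n: 0)
    return float(np.log(lik).sum() - len(lik) * np.log1p(-p_absent))


def brute_force_posteriors(model, matrix, tree):
    """Exhaustive joint posteriors of the four events and root presence."""
    prior = stationary_distribution(model)
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    T = {id(n): transition_matrix(model, n.length) for n in nodes if n.parent is not None}
    S = model.n_max + 1
    col = {g: j for j, g in enumerate(matrix.genome_ids)}
    edges = tree.edges()
    out = []
    for f in range(matrix.n_families):
        pg = np.zeros(len(edges))
        pl = np.zeros(len(edges))
        pe = np.zeros(len(edges))
        pr = np.zeros(len(edges))
        proot = 0.0
        Z = 0.0
        for assign in itertools.product(range(S), repeat=len(internal)):
            st = {id(n): a for n, a in zip(internal, assign)}
            for n in nodes:
                if n.is_leaf:
                    st[id(n)] = matrix.counts[f, col[n.name]]
            p = prior[st[id(tree.root)]]
            for n in nodes:
                if n.parent is not None:
                    p *= T[id(n)][st[id(n.parent)], st[id(n)]]
            Z += p
            if st[id(tree.root)] >= 1:
                proot += p
            for k, e in enumerate(edges):
                i, j = st[id(e.parent)], st[id(e)]
                if i == 0 and j >= 1:
                    pg[k] += p
                elif i >= 1 and j == 0:
                    pl[k] += p
                elif i >= 1 and j > i:
                    pe[k] += p
                elif j >= 1 and j < i:
                    pr[k] += p
        out.append((pg / Z, pl / Z, pe / Z, pr / Z, proot / Z))
    return out


# -- transition matrix -----------------------------------------------------


class TestTransitionMatrix:
    def test_t_zero_identity(self):
        m = BDIModel(kappa=1.0, lam=0.5, mu=2.0, n_max=4)
        assert np.array_equal(transition_matrix(m, 0.0), np.eye(5))

    def test_negative_t_error(self):
        m = BDIModel(kappa=1.0, lam=0.5, mu=2.0, n_max=4)
        with pytest.raises(ValueError):
            transition_matrix(m, -0.1)

    def test_row_stochastic(self):
        m = BDIModel(kappa=2.0, lam=1.0, mu=3.0, n_max=8)
        P = transition_matrix(m, 0.7)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert P.min() >= 0

    def test_pure_death_closed_form(self):
        # kappa = lambda = 0: each copy survives independently with prob e^{-mu t}
        mu, t = 1.3, 0.6
        m = BDIModel(kappa=0.0, lam=0.0, mu=mu, n_max=6)
        P = transition_matrix(m, t)
        s = np.exp(-mu * t)
        for n in range(7):
            for k in range(7):
                assert P[n, k] == pytest.approx(binom.pmf(k, n, s), abs=1e-9)

    def test_against_gillespie_oracle(self):
        # the simulator's event-by-event engine is the independent oracle
        kappa, lam, mu, t = 1.5, 0.8, 2.0, 0.5
        model = BDIModel(kappa=kappa, lam=lam, mu=mu, n_max=12)
        P = transition_matrix(model, t)
        rng = np.random.default_rng(42)
        n_traj = 40_000
        for n0 in (0, 1, 3):
            ends = np.array([
                _evolve_family(rng, n0, t, kappa, lam, mu)[0] for n in range(n_traj)
            ])
            for k in range(model.n_max + 1):
                phat = np.mean(ends == k)
                se = np.sqrt(max(phat * (1 - phat), 1e-9) / n_traj)
                assert abs(phat - P[n0, k]) <= 3 * se + 1e-4


# -- likelihood ------------------------------------------------------------


TREES_4 = [
    "((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.6);",
    "(((A:0.2,B:0.2):0.2,C:0.4):0.1,D:0.5);",
    "(A:0.4,(B:0.3,(C:0.2,D:0.2):0.1):0.1);",
]


class TestLikelihood:
    @pytest.mark.parametrize("newick", TREES_4)
    @pytest.mark.parametrize("params", [(0.4, 0.3, 0.9), (1.2, 0.05, 0.5)])
    def test_pruning_equals_enumeration(self, newick, params):
        tree = parse_newick(newick)
        matrix = PhyleticMatrix(
            ["f1", "f2", "f3"], ["A", "B", "C", "D"],
            np.array([[1, 0, 2, 1], [0, 0, 0, 1], [3, 1, 0, 0]]),
        )
        model = BDIModel(*params, n_max=3)
        assert log_likelihood(model, matrix, tree) == pytest.approx(
            brute_force_loglik(model, matrix, tree), abs=1e-10
        )

    def test_two_leaf_enumeration(self):
        tree = parse_newick("(A:0.4,B:0.2);")
        matrix = PhyleticMatrix(["f1", "f2"], ["A", "B"], np.array([[1, 0], [2, 2]]))
        model = BDIModel(kappa=0.7, lam=0.2, mu=1.1, n_max=3)
        assert log_likelihood(model, matrix, tree) == pytest.approx(
            brute_force_loglik(model, matrix, tree), abs=1e-10
        )

    def test_n_max_exceeded_error(self):
        tree = parse_newick("(A:0.1,B:0.1);")
        matrix = PhyleticMatrix(["f1"], ["A", "B"], np.array([[5, 1]]))
        model = BDIModel(kappa=1.0, lam=0.1, mu=1.0, n_max=3)
        with pytest.raises(ValueError, match="n_max"):
            log_likelihood(model, matrix, tree)


class TestFitModel:
    def test_toy_loglik_matches_enumeration_at_fit(self):
        tree = parse_newick("((A:0.3,B:0.5):0.2,C:0.4);")
        matrix = PhyleticMatrix(["f1", "f2"], ["A", "B", "C"],
                                np.array([[1, 0, 1], [2, 1, 0]]))
        model = fit_model(matrix, tree, FitSettings(n_max=3, n_starts=2, max_iter=400))
        assert model.log_likelihood == pytest.approx(
            brute_force_loglik(model, matrix, tree), abs=1e-8
        )

    def test_no_loss_limit(self):
        # every family in every genome at copy 1: mu driven to the lower bound
        tree = parse_newick("((A:0.05,B:0.05):0.02,C:0.07);")
        matrix = PhyleticMatrix(
            [f"f{i}" for i in range(10)], ["A", "B", "C"], np.ones((10, 3), dtype=int)
        )
        model = fit_model(matrix, tree, FitSettings(n_starts=2))
        assert model.mu < 1e-2

    def test_empty_matrix_error(self):
        tree = parse_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError):
            fit_model(PhyleticMatrix([], ["A", "B"], np.zeros((0, 2), dtype=int)), tree)


# -- posteriors ------------------------------------------------------------


class TestPosteriorEvents:
    def test_enumeration_oracle_three_leaf(self):
        tree = parse_newick("((A:0.3,B:0.5):0.2,C:0.4);")
        matrix = PhyleticMatrix(["f1", "f2", "f3"], ["A", "B", "C"],
                                np.array([[1, 0, 2], [0, 1, 0], [2, 2, 1]]))
        model = BDIModel(kappa=0.4, lam=0.3, mu=0.9, n_max=2)
        post = posterior_events(model, matrix, tree)
        for f, (pg, pl, pe, pr, proot) in enumerate(brute_force_posteriors(model, matrix, tree)):
            np.testing.assert_allclose(post.p_gain[f], pg, atol=1e-10)
            np.testing.assert_allclose(post.p_loss[f], pl, atol=1e-10)
            np.testing.assert_allclose(post.p_expansion[f], pe, atol=1e-10)
            np.testing.assert_allclose(post.p_reduction[f], pr, atol=1e-10)
            assert post.p_root_present[f] == pytest.approx(proot, abs=1e-10)

    def test_singleton_limit(self):
        # shallow 10-leaf tree, family in one leaf only: gain on that branch
        from geneflux.synthetic_data import generate_tree

        tree = generate_tree(10, 0.002, seed=1)
        leaves = tree.leaf_labels()
        counts = np.zeros((1, 10), dtype=int)
        counts[0, 3] = 1
        counts = np.vstack([counts, np.ones((1, 10), dtype=int)])  # anchor family
        matrix = PhyleticMatrix(["single", "anchor"], leaves, counts)
        model = BDIModel(kappa=5.0, lam=1.0, mu=20.0, n_max=3)
        post = posterior_events(model, matrix, tree)
        target = leaves[3]
        k = next(k for k, e in enumerate(tree.edges()) if e.name == target)
        assert post.p_gain[0, k] == pytest.approx(1.0, abs=0.05)
        others = np.delete(post.p_gain[0], k)
        assert others.max() < 0.05

    def test_universal_family_root_present(self):
        from geneflux.synthetic_data import generate_tree

        tree = generate_tree(10, 0.002, seed=2)
        matrix = PhyleticMatrix(["u"], tree.leaf_labels(), np.ones((1, 10), dtype=int))
        model = BDIModel(kappa=5.0, lam=1.0, mu=20.0, n_max=3)
        post = posterior_events(model, matrix, tree)
        assert post.p_root_present[0] > 0.99

    def test_order_invariance(self, small_sim):
        tree, _, matrix, _ = small_sim
        sub = PhyleticMatrix(matrix.family_ids[:40], matrix.genome_ids,
                             matrix.counts[:40])
        model = BDIModel(kappa=9.0 * 800 / 800, lam=2.4, mu=9.0, n_max=int(sub.counts.max()) + 3)
        post = posterior_events(model, sub, tree)
        rng = np.random.default_rng(5)
        rp = rng.permutation(sub.n_families)
        cp = rng.permutation(sub.n_genomes)
        shuffled = PhyleticMatrix([sub.family_ids[i] for i in rp],
                                  [sub.genome_ids[j] for j in cp],
                                  sub.counts[np.ix_(rp, cp)])
        post2 = posterior_events(model, shuffled, tree)
        np.testing.assert_allclose(post2.p_gain, post.p_gain[rp], atol=1e-9)
        np.testing.assert_allclose(post2.p_root_present, post.p_root_present[rp], atol=1e-9)


class TestCountEvents:
    def _empty_posteriors(self, n_fam=2, n_edges=3):
        z = np.zeros((n_fam, n_edges))
        return BranchEventPosteriors(
            family_ids=[f"f{i}" for i in range(n_fam)],
            branch_lengths=np.full(n_edges, 0.1),
            is_terminal=np.array([True, True, False]),
            p_gain=z.copy(), p_loss=z.copy(), p_expansion=z.copy(), p_reduction=z.copy(),
            p_root_present=np.zeros(n_fam),
            presence_counts=np.array([1, 2]),
        )

    def test_all_zero(self):
        totals = count_events(self._empty_posteriors())
        assert all(v == 0 for v in totals.totals.values())

    def test_single_gain(self):
        post = self._empty_posteriors()
        post.p_gain[0, 1] = 1.0
        totals = count_events(post)
        assert totals.totals["gain"] == pytest.approx(1.0)
        assert totals.gains[1] == pytest.approx(1.0)
        # family 0 is a singleton and edge 1 is terminal: excluded
        assert totals.gains_excl_singletons[1] == pytest.approx(0.0)

    def test_expected_gains_near_truth_at_shallow_depth(self, small_sim):
        tree, config, matrix, truth = small_sim
        model = fit_model(matrix, tree, FitSettings(n_starts=2))
        post = posterior_events(model, matrix, tree)
        totals = count_events(post)
        true_gains = truth.totals()["gain"]
        assert abs(totals.totals["gain"] - true_gains) / true_gains < 0.25
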