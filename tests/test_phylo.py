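"""Tree structure, Newick I/O, grafting/pruning, Brownian root states."""
import dendropy
import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal

from paleomet.phylo import (
    GraftSpec,
    NewickError,
    TreeError,
    brownian_rate,
    brownian_root_state,
    graft_fossil,
    prune_tip,
    prune_tips,
    read_newick,
)

from conftest import random_tree


def dendropy_tip_distances(newick):
    """Independent path-sum oracle for pairwise tip distances."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(taxa)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return D, labels


def sorted_distances(tree):
    D, labels = tree.tip_distances()
    order = np.argsort(labels)
    return D[np.ix_(order, order)], sorted(labels)


class TestNewick:
    def test_three_tip_example(self, three_tip_tree):
        t = three_tip_tree
        assert sorted(t.tip_labels()) == ["A", "B", "C"]
        depths = t.depths()
        assert depths[t.find("A")] == pytest.approx(2.0)
        assert t.age == pytest.approx(2.0)

    def test_single_tip_rejected(self):
        with pytest.raises(NewickError, match="2 tips"):
            read_newick("(A:1);")

    @pytest.mark.parametrize("text", ["((A:1,B:1:1,C:2);", "(A:1,B:1", "not a tree"])
    def test_malformed_input_names_position(self, text):
        with pytest.raises(NewickError):
            read_newick(text)

    def test_missing_branch_length_is_explicit_error(self):
        with pytest.raises(NewickError, match="branch length"):
            read_newick("((A:1,B),C:2);")

    def test_quoted_labels_round_trip(self):
        t = read_newick("(('sp. A':1,'B (cf.)':1):1,C:2);")
        assert "sp. A" in t.tip_labels()
        again = read_newick(t.write_newick())
        assert sorted(again.tip_labels()) == sorted(t.tip_labels())

    def test_round_trip_preserves_distances_on_random_trees(self, rng):
        for _ in range(50):
            t = random_tree(rng, int(rng.integers(4, 33)))
            nwk = t.write_newick()
            back = read_newick(nwk)
            D1, l1 = sorted_distances(back)
            D2, l2 = dendropy_tip_distances(nwk)
            assert l1 == l2
            np.testing.assert_allclose(D1, D2, atol=1e-9)


class TestGraft:
    def test_midpoint_graft_splits_edge(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        # C's terminal edge spans times [0, 2]; attach at its midpoint
        g = graft_fossil(
            t, GraftSpec("F", attach="C", attach_time=1.0, stem_length=0.5,
                         tip_age=0.5)
        )
        ages = g.tip_ages()
        assert ages["F"] == pytest.approx(0.5)
        D, labels = g.tip_distances()
        i, j = labels.index("C"), labels.index("F")
        assert D[i, j] == pytest.approx(1.0 + 0.5)

    def test_zero_stem_twin(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        g = graft_fossil(
            t, GraftSpec("F", attach="A", attach_time=0.0, stem_length=0.0)
        )
        D, labels = g.tip_distances()
        assert D[labels.index("A"), labels.index("F")] == pytest.approx(0.0)

    def test_attach_time_outside_edge_span(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(TreeError, match="outside edge span"):
            graft_fossil(t, GraftSpec("F", attach="A", attach_time=1.7))

    def test_inconsistent_declared_age(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(TreeError, match="inconsistent"):
            graft_fossil(
                t, GraftSpec("F", attach="C", attach_time=1.0,
                             stem_length=0.25, tip_age=0.5)
            )

    def test_random_grafts_preserve_existing_distances(self, rng):
        for _ in range(100):
            t = random_tree(rng, int(rng.integers(4, 17)))
            D0, labels0 = sorted_distances(t)
            # pick a random non-root edge and position within it
            edges = t.edge_ids()
            child = int(edges[rng.integers(len(edges))])
            depth = t.depths()
            lo, hi = depth[t.parent[child]], depth[child]
            pos = float(rng.uniform(lo, hi))
            spec = GraftSpec(
                "FOSSIL", attach=child, attach_time=t.age - pos,
                stem_length=float(rng.uniform(0, 5)),
            )
            g = graft_fossil(t, spec)
            Dg, labelsg = g.tip_distances()
            idx = [labelsg.index(lab) for lab in labels0]
            np.testing.assert_allclose(Dg[np.ix_(idx, idx)], D0, atol=1e-9)

    def test_prune_then_graft_round_trips_distances(self, rng):
        for _ in range(30):
            t = random_tree(rng, int(rng.integers(5, 15)))
            D0, labels0 = sorted_distances(t)
            victim = t.tip_labels()[int(rng.integers(t.n_tips))]
            pruned, spec = prune_tip(t, victim)
            assert victim not in pruned.tip_labels()
            back = graft_fossil(pruned, spec)
            D1, labels1 = sorted_distances(back)
            assert labels1 == labels0
            np.testing.assert_allclose(D1, D0, atol=1e-9)

    def test_prune_tips_specs_valid_on_final_tree(self, rng):
        t = random_tree(rng, 12)
        victims = t.tip_labels()[:3]
        pruned, specs = prune_tips(t, victims)
        D0, labels0 = sorted_distances(t)
        for lab in victims:
            g = graft_fossil(pruned, specs[lab])
            Dg, labelsg = sorted_distances(g)
            keep = [labelsg.index(x) for x in labels0 if x in labelsg]
            src = [labels0.index(x) for x in labels0 if x in labelsg]
            np.testing.assert_allclose(
                Dg[np.ix_(keep, keep)], D0[np.ix_(src, src)], atol=1e-9
            )


class TestBrownianRootState:
    def test_constant_tips_return_constant(self, three_tip_tree):
        assert brownian_root_state(three_tip_tree, {"A": 3.2, "B": 3.2, "C": 3.2}) == 3.2

    def test_two_tip_symmetry(self):
        t = read_newick("(A:1,B:1);")
        assert brownian_root_state(t, {"A": 0.8, "B": 1.0}) == pytest.approx(0.9)

    def test_star_tree_is_arithmetic_mean(self):
        t = read_newick("(A:2,B:2,C:2,D:2);")
        vals = {"A": 1.0, "B": 4.0, "C": -2.0, "D": 0.5}
        assert brownian_root_state(t, vals) == pytest.approx(np.mean(list(vals.values())))

    def test_missing_tip_value_errors(self, three_tip_tree):
        with pytest.raises(TreeError, match="missing"):
            brownian_root_state(three_tip_tree, {"A": 1.0, "B": 2.0})

    def test_matches_numerical_likelihood_maximum(self, rng):
        """Brute-force oracle: maximize the Brownian MVN likelihood over the
        root state at fixed (profiled-out irrelevant) rate."""
        for _ in range(10):
            t = random_tree(rng, int(rng.integers(4, 12)))
            C, labels = t.brownian_covariance()
            y = rng.normal(0.0, 1.0, len(labels))
            vals = dict(zip(labels, y))

            def nll(mu):
                return -multivariate_normal.logpdf(y, mean=np.full(len(y), mu), cov=C)

            res = minimize_scalar(nll, method="brent", options={"xtol": 1e-13})
            # nll is quadratic in mu: one parabolic-vertex step is exact
            x, d = float(res.x), 1e-3
            f0, f1, f2 = nll(x - d), nll(x), nll(x + d)
            vertex = x - d * (f2 - f0) / (2.0 * (f2 - 2.0 * f1 + f0))
            assert brownian_root_state(t, vals) == pytest.approx(vertex, abs=1e-8)

    def test_invariant_to_tip_ordering(self, rng):
        t = random_tree(rng, 8)
        labels = t.tip_labels()
        y = rng.normal(size=len(labels))
        vals = dict(zip(labels, y))
        shuffled = dict(reversed(list(vals.items())))
        assert brownian_root_state(t, vals) == pytest.approx(
            brownian_root_state(t, shuffled), rel=1e-12
        )

    def test_covariance_is_psd(self, rng):
        for _ in range(20):
            t = random_tree(rng, int(rng.integers(3, 20)))
            C, _ = t.brownian_covariance()
            np.testing.assert_allclose(C, C.T, atol=1e-12)
            assert np.linalg.eigvalsh(C).min() >= -1e-9

    def test_rate_recovers_simulated_rate(self, rng):
        """GLS rate estimate is unbiased for noiseless Brownian tips."""
        from paleomet.simulate import SimulationConfig, simulate_traits

        cfg = SimulationConfig(n_tips=24, noise_sd=0.0, rate_mmr=0.004,
                               correlation=0.0, seed=3)
        rates = []
        for _ in range(120):
            t = random_tree(rng, 24)
            traits = simulate_traits(t, cfg, rng)
            rates.append(brownian_rate(t, traits["log_mmr_mi"].to_dict()))
        assert np.mean(rates) == pytest.approx(0.004, rel=0.15)
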