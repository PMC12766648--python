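"""Perfect-phylogeny imputation, tree building, coalescent fit, RRS, k-means."""

import numpy as np
import pandas as pd
import pytest

from clonetrace import SimConfig, simulate_population
from clonetrace.lineage import (
    MCMCSettings,
    build_tree,
    compute_rrs,
    fit_coalescent_too,
    generations_to_pmw,
    impute_perfect_phylogeny,
    is_compatible,
    kmeans_dispersion,
)
from clonetrace.trees import LineageTree


def brute_force_min_cost(posterior, site_mf=None, tol=0.25):
    """Independent oracle: enumerate every flip set, keep the cheapest
    compatible matrix."""
    call = (posterior >= 0.5).astype(int)
    n = posterior.size
    best_cost, best = np.inf, None
    for mask in range(2**n):
        flips = np.array([(mask >> k) & 1 for k in range(n)]).reshape(posterior.shape)
        M = np.where(flips, 1 - call, call)
        if not is_compatible(M):
            continue
        if site_mf is not None and np.any(np.abs(M.mean(0) - site_mf) > tol):
            continue
        cost = float(np.abs(posterior - M)[M != call].sum())
        if cost < best_cost:
            best_cost, best = cost, M
    return best_cost, best


class TestCompatibility:
    def test_four_gamete_rule(self):
        assert is_compatible([[1, 1], [1, 0], [0, 0]])
        assert not is_compatible([[1, 1], [1, 0], [0, 1]])


class TestImputation:
    def test_compatible_matrix_unchanged(self):
        post = pd.DataFrame([[0.9, 0.9], [0.9, 0.1], [0.1, 0.1]])
        im = impute_perfect_phylogeny(post)
        assert im.n_changed == 0
        assert im.cost == 0.0

    def test_three_pattern_single_flip(self):
        post = pd.DataFrame([[0.9, 0.95], [0.9, 0.1], [0.1, 0.9]])
        im = impute_perfect_phylogeny(post)
        oracle_cost, _ = brute_force_min_cost(post.values)
        assert im.cost == pytest.approx(oracle_cost)
        assert is_compatible(im.genotypes.values)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        post = rng.uniform(0.05, 0.95, size=(4, 3))
        im = impute_perfect_phylogeny(pd.DataFrame(post))
        oracle_cost, _ = brute_force_min_cost(post)
        assert im.cost == pytest.approx(oracle_cost)
        assert is_compatible(im.genotypes.values)

    def test_mf_constraint_respected(self):
        rng = np.random.default_rng(3)
        post = rng.uniform(0.05, 0.95, size=(4, 3))
        mf = pd.Series([0.5, 0.25, 0.25])
        im = impute_perfect_phylogeny(pd.DataFrame(post), site_mf=mf, mf_tolerance=0.3)
        oracle_cost, _ = brute_force_min_cost(post, mf.values, 0.3)
        assert im.cost == pytest.approx(oracle_cost)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_greedy_flips_are_mostly_true_errors(self, seed):
        # generator truth (20 sites x 200 cells) with 5% genotyping noise:
        # at least 90% of the entries the imputation flips are true errors
        pop = simulate_population(SimConfig(tracked_lineages=200, seed=seed))
        mm = pop.mutations
        panel = list(
            mm[(mm["true_mf"] > 0.05) & (mm["true_mf"] < 0.9)]["mutation_id"][:20]
        )
        truth = np.zeros((200, len(panel)), dtype=int)
        for j, mut in enumerate(panel):
            truth[pop.carriers[mut], j] = 1
        rng = np.random.default_rng(seed)
        noise = rng.random(truth.shape) < 0.05
        obs = np.where(noise, 1 - truth, truth)
        post = pd.DataFrame(np.where(obs == 1, 0.95, 0.05), columns=panel)
        im = impute_perfect_phylogeny(post, max_exact_sites=0)
        changed = im.changed.values
        assert changed.sum() > 0
        true_error = obs != truth
        precision = (changed & true_error).sum() / changed.sum()
        assert precision >= 0.9


class TestBuildTree:
    def test_single_site_cherry(self):
        g = pd.DataFrame(
            [[1], [1], [0], [0]], index=["c1", "c2", "c3", "c4"], columns=["s1"]
        )
        tree = build_tree(g)
        # parsimony score = number of placed sites
        assert tree.edge_mutation_count.sum() == 1
        carriers = tree.leaves_under(tree.variant_edges()["s1"])
        assert [tree.leaf_ids[i] for i in carriers] == ["c1", "c2"]

    def test_nested_containment(self):
        g = pd.DataFrame(
            {"A": [1, 1, 1, 0], "B": [1, 1, 0, 0]},
            index=["c1", "c2", "c3", "c4"],
        )
        tree = build_tree(g)
        edges = tree.variant_edges()
        # B's branch lies below A's
        v = edges["B"]
        anc = []
        while v >= 0:
            anc.append(v)
            v = tree.parent[v]
        assert edges["A"] in anc[1:]

    def test_incompatible_matrix_rejected(self):
        with pytest.raises(ValueError):
            build_tree(pd.DataFrame([[1, 1], [1, 0], [0, 1]]))

    def test_noiseless_recovery_rf_zero(self):
        pop = simulate_population(SimConfig(tracked_lineages=40, seed=30))
        genotypes = pd.DataFrame(
            0,
            index=pop.cells["cell_id"],
            columns=pop.mutations["mutation_id"],
        )
        for mut, idx in pop.carriers.items():
            genotypes.iloc[idx, genotypes.columns.get_loc(mut)] = 1
        built = build_tree(genotypes)
        truth = pop.tree.collapse_unsupported()
        assert built.rf_distance(truth) == 0


class TestPMW:
    def test_anchors(self):
        assert generations_to_pmw(0.0) == 0.0
        assert generations_to_pmw(13.0) == pytest.approx(8.0)
        assert generations_to_pmw(26.0) == pytest.approx(16.0)

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert generations_to_pmw(40.0) == pytest.approx(16.0)

    def test_bad_table_rejected(self):
        bad = pd.DataFrame({"week": [0, 1], "population": [10, 10]})
        with pytest.raises(ValueError):
            generations_to_pmw(1.0, bad)


class TestCoalescent:
    def test_star_tree_no_mutations_times_near_zero(self):
        n = 6
        parent = np.concatenate([np.full(n, n), [-1]])
        tree = LineageTree(parent=parent, leaf_ids=[f"c{i}" for i in range(n)])
        fit = fit_coalescent_too(
            tree,
            mcmc=MCMCSettings(chains=2, draws=300, warmup=200, check_convergence=False),
            seed=0,
        )
        # with no mutations the prior dominates: coalescences pile up at the
        # earliest generations the (binarized) topology allows
        assert (np.sort(fit.node_times["time_median"]) <= np.arange(2, 12, 2)).all()
        assert fit.params["mu"].median() < 1.0
        assert len(fit.too) == 0

    def test_recovery_and_too_monotonicity(self):
        pop = simulate_population(SimConfig(tracked_lineages=30, seed=203))
        tree = pop.lineage_tree()
        fit = fit_coalescent_too(
            tree,
            mcmc=MCMCSettings(chains=2, draws=500, warmup=300, rhat_threshold=1.2),
            seed=3,
        )
        su = fit.summary()
        assert su["N_ci90"][0] <= 2**26 <= su["N_ci90"][1]
        assert su["mu_ci90"][1] > 2.0  # posterior mass near the true rate
        # TOO monotone down every lineage
        too = fit.too.set_index("variant")["too_median"]
        edges = tree.variant_edges()
        for v1, n1 in edges.items():
            v = int(tree.parent[n1])
            while v >= 0:
                for v2, n2 in edges.items():
                    if n2 == v:
                        assert too[v2] <= too[v1]
                v = int(tree.parent[v])

    def test_nonmixing_raises(self):
        pop = simulate_population(SimConfig(tracked_lineages=25, seed=204))
        with pytest.raises(RuntimeError, match="R-hat"):
            fit_coalescent_too(
                pop.lineage_tree(),
                mcmc=MCMCSettings(chains=4, draws=20, warmup=0, rhat_threshold=1.0),
                seed=0,
            )


class TestRRS:
    def _tree(self):
        parent = np.array([6, 6, 6, 7, 7, 7, 8, 8, -1])
        return LineageTree(
            parent=parent,
            leaf_ids=[f"c{i}" for i in range(6)],
            edge_mutation_count=np.array([1.0, 1, 1, 1, 1, 1, 3, 3, 0]),
        )

    def test_subtree_segregation_gives_rrs_above_one(self):
        regions = {f"c{i}": ("R1" if i < 3 else "R2") for i in range(6)}
        r = compute_rrs(self._tree(), regions, n_boot=300, seed=0)
        assert r.rrs > 1.0
        assert r.ci[0] > 1.0

    def test_exchangeable_labels_cover_one(self):
        rng = np.random.default_rng(1)
        parent = np.concatenate([np.repeat(np.arange(20, 30), 2), np.full(10, 30), [-1]])
        tree = LineageTree(
            parent=parent,
            leaf_ids=[f"c{i}" for i in range(20)],
            edge_mutation_count=rng.integers(1, 4, size=31).astype(float),
        )
        regions = {f"c{i}": rng.choice(["R1", "R2"]) for i in range(20)}
        r = compute_rrs(tree, regions, n_boot=400, seed=2)
        assert r.ci[0] <= 1.0 <= r.ci[1]

    def test_permutation_null_band(self):
        rng = np.random.default_rng(3)
        parent = np.concatenate([np.repeat(np.arange(20, 30), 2), np.full(10, 30), [-1]])
        tree = LineageTree(
            parent=parent,
            leaf_ids=[f"c{i}" for i in range(20)],
            edge_mutation_count=rng.integers(1, 4, size=31).astype(float),
        )
        # exchangeable observed labels: a random permutation themselves
        labels = rng.permutation(np.array(["R1"] * 10 + ["R2"] * 10))
        obs = compute_rrs(tree, dict(zip(tree.leaf_ids, labels)), n_boot=50, seed=4).rrs
        perms = []
        for _ in range(100):
            perm = rng.permutation(labels)
            perms.append(
                compute_rrs(tree, dict(zip(tree.leaf_ids, perm)), n_boot=1, seed=5).rrs
            )
        lo, hi = np.quantile(perms, [0.025, 0.975])
        assert lo <= obs <= hi

    def test_single_region_clade_undefined(self):
        regions = {f"c{i}": "R1" for i in range(6)}
        r = compute_rrs(self._tree(), regions, n_boot=10, seed=0)
        assert not r.defined


class TestDispersionClusters:
    def test_orthogonal_profiles_recovered(self):
        X = pd.DataFrame(
            np.kron(np.eye(5), np.ones((5, 1))),
            index=[f"v{i}" for i in range(25)],
        )
        out = kmeans_dispersion(X, k=5, seed=0)
        from sklearn.metrics import adjusted_rand_score

        truth = np.repeat(np.arange(5), 5)
        assert adjusted_rand_score(truth, out.labels.values) == 1.0

    def test_k1_centroid_is_column_mean(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.uniform(size=(8, 3)))
        out = kmeans_dispersion(X, k=1, seed=0)
        np.testing.assert_allclose(out.centroids.values[0], X.mean(axis=0).values)

    def test_degenerate_all_zero(self):
        X = pd.DataFrame(np.zeros((6, 3)))
        out = kmeans_dispersion(X, k=2, seed=0)
        assert set(out.labels) <= {0, 1}

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            kmeans_dispersion(pd.DataFrame(np.zeros((3, 2))), k=5)
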