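"""Cell-type sharing statistics, minMF, clone clustering and composition."""

import numpy as np
import pandas as pd
import pytest

from clonetrace.celltype import (
    SharedVariantStat,
    clone_table,
    eb_composition,
    louvain_clones,
    minmf_bootstrap,
    shared_count_test,
    shared_variant_counts,
)


def tally(rows):
    return pd.DataFrame(
        rows, columns=["cell", "variant", "total_umis", "mut_umis", "cell_type", "region"]
    )


def two_by_two():
    rows = [
        ("a1", "v1", 3, 2, "A", "R"),
        ("a2", "v1", 3, 1, "A", "R"),
        ("b1", "v1", 3, 1, "B", "R"),
        ("b2", "v1", 3, 2, "B", "R"),
        ("a3", "v2", 3, 0, "A", "R"),
    ]
    return tally(rows)


class TestSharedCounts:
    def test_enumerated_example(self):
        stats = {(s.type_a, s.type_b): s for s in shared_variant_counts(two_by_two())}
        ab = stats[("A", "B")]
        assert ab.shared_count == 1
        assert ab.n_mutant_cell_pairs == 4
        assert ab.normalized == pytest.approx(0.25)

    def test_minimum_two_cells_per_type(self):
        rows = [
            ("a1", "v1", 3, 2, "A", "R"),
            ("a2", "v1", 3, 1, "A", "R"),
            ("b1", "v1", 3, 1, "B", "R"),
        ]
        stats = {(s.type_a, s.type_b): s for s in shared_variant_counts(tally(rows))}
        assert stats[("A", "B")].shared_count == 0
        assert stats[("A", "A")].shared_count == 1

    def test_empty_tally(self):
        assert shared_variant_counts(tally([])) == []

    def test_zero_umi_cells_non_informative(self):
        base = {
            (s.type_a, s.type_b): s.shared_count
            for s in shared_variant_counts(two_by_two())
        }
        extra = two_by_two()
        extra = pd.concat(
            [extra, tally([("z1", "v1", 0, 0, "B", "R")])], ignore_index=True
        )
        after = {
            (s.type_a, s.type_b): s.shared_count
            for s in shared_variant_counts(extra)
        }
        assert base == after


class TestSharedCountTest:
    def _stat(self, contributions, source):
        c = np.asarray(contributions, dtype=float)
        return SharedVariantStat("A", "B", len(c), 10, c.mean(), c, source)

    def test_identical_sources_near_half(self, rng):
        x = rng.uniform(0.1, 0.3, size=40)
        p = shared_count_test(self._stat(x, "observed"), self._stat(x, "expected"),
                              n_boot=4000, seed=1)
        assert 0.3 <= p <= 0.7

    def test_large_shift_detected(self, rng):
        x = rng.uniform(0.1, 0.2, size=40)
        p = shared_count_test(
            self._stat(x + 1.0, "observed"), self._stat(x, "expected"),
            n_boot=4000, seed=1,
        )
        assert p < 1e-3

    def test_calibration_at_five_percent(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for _ in range(reps):
            x = rng.exponential(0.2, size=25)
            y = rng.exponential(0.2, size=25)
            p = shared_count_test(
                self._stat(x, "observed"), self._stat(y, "expected"),
                n_boot=400, seed=int(rng.integers(2**31)),
            )
            rejections += p < 0.05
        rate = rejections / reps
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_small_bootstrap_warns(self):
        with pytest.warns(UserWarning, match="n_boot"):
            shared_count_test(
                self._stat([0.1, 0.2], "observed"),
                self._stat([0.1, 0.2], "expected"),
                n_boot=100,
                seed=0,
            )


class TestMinMF:
    def test_point_is_minimum(self):
        est = minmf_bootstrap([10, 4, 2], seed=0)
        assert est.minmf == 2.0
        assert est.ci[0] <= est.minmf

    def test_degenerate_constant(self):
        est = minmf_bootstrap([2, 2, 2], seed=0)
        assert est.ci == (2.0, 2.0)

    def test_bootstrap_matches_exhaustive_enumeration(self):
        # 27 equally likely triples of {1,2,3}: P(min=1)=19/27, P(2)=7/27,
        # P(3)=1/27
        est_draws = []
        rng = np.random.default_rng(3)
        mfs = np.array([1.0, 2.0, 3.0])
        n = 30_000
        mins = rng.choice(mfs, size=(n, 3), replace=True).min(axis=1)
        for val, expect in [(1.0, 19 / 27), (2.0, 7 / 27), (3.0, 1 / 27)]:
            frac = (mins == val).mean()
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(frac - expect) < 4 * se
        # and the packaged bootstrap reproduces the same law
        est = minmf_bootstrap(mfs, n_boot=30_000, seed=4)
        assert est.minmf == 1.0
        assert est.ci == (1.0, 2.0)  # 5% < P(min>=2)=8/27 < 95%
        del est_draws

    def test_too_few_shared_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            minmf_bootstrap([1, 2], seed=0)

    def test_anti_monotone_in_set_inclusion(self, rng):
        mfs = rng.uniform(1, 20, size=10)
        sub = mfs[:5]
        assert minmf_bootstrap(mfs, n_boot=10, seed=0).minmf <= minmf_bootstrap(
            sub, n_boot=10, seed=0
        ).minmf


class TestLouvainClones:
    def test_disjoint_groups_two_clones(self):
        rows = [(c, "vA", 2, 1, "A", "R") for c in ["x1", "x2", "x3"]]
        rows += [(c, "vB", 2, 1, "A", "R") for c in ["y1", "y2"]]
        clones = louvain_clones(tally(rows))
        assert clones.nunique() == 2
        assert clones["x1"] == clones["x2"] == clones["x3"]
        assert clones["y1"] == clones["y2"] != clones["x1"]

    def test_single_shared_variant_single_clone(self):
        rows = [(f"c{i}", "v1", 2, 1, "A", "R") for i in range(5)]
        clones = louvain_clones(tally(rows))
        assert clones.nunique() == 1

    def test_planted_partition_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(5)
        rows = []
        for g, cells in enumerate([range(30), range(30, 60)]):
            for v in range(8):
                for c in cells:
                    if rng.random() < 0.5:
                        rows.append((f"c{c}", f"g{g}v{v}", 2, 1, "A", "R"))
        # 5% cross-group shared noise variants
        for v in range(4):
            for c in rng.choice(60, size=3, replace=False):
                rows.append((f"c{c}", f"noise{v}", 2, 1, "A", "R"))
        clones = louvain_clones(tally(rows), seed=1)
        truth = [0 if int(c[1:]) < 30 else 1 for c in clones.index]
        assert adjusted_rand_score(truth, clones.values) >= 0.9

    def test_no_mutant_cells_rejected(self):
        with pytest.raises(ValueError):
            louvain_clones(tally([("c1", "v1", 2, 0, "A", "R")]))


class TestCloneTable:
    def test_counts_and_covariates(self):
        rows = [
            ("c1", "v1", 2, 1, "GluN_upper", "R"),
            ("c2", "v1", 2, 1, "CGE_GABN", "R"),
            ("c2", "v2", 2, 1, "CGE_GABN", "R"),
        ]
        clones = pd.Series({"c1": 0, "c2": 0})
        out = clone_table(
            tally(rows),
            clones,
            {"GluN": ["GluN_upper"], "GABN": ["CGE_GABN", "MGE_GABN"]},
        )
        assert out.loc[0, "N"] == 2
        assert out.loc[0, "GluN"] == 1
        assert out.loc[0, "GABN"] == 1
        assert out.loc[0, "n_variants"] == 2


class TestEBComposition:
    def _clone_counts(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        N = (2.0 ** rng.uniform(1, 10, size=n)).astype(int)
        return pd.DataFrame(
            {
                "clone": range(n),
                "N": N,
                "n_variants": rng.integers(1, 9, n),
                "GluN": rng.binomial(N, 0.5),
                "GABN": rng.binomial(N, 0.04),
            }
        )

    def test_shrinkage_between_prior_and_empirical(self):
        table, _ = eb_composition(self._clone_counts(), ["GluN"], seed=0, n_boot=20)
        for _, r in table.iterrows():
            emp = r.X / r.N
            lo, hi = sorted((r.mu0, emp))
            if abs(r.mu0 - emp) > 1e-9:
                assert lo - 1e-9 <= r.posterior <= hi + 1e-9

    def test_small_clones_excluded(self):
        cc = self._clone_counts()
        table, _ = eb_composition(cc, ["GluN"], min_clone_size=10, seed=0, n_boot=20)
        assert set(table["N"]) <= set(cc[cc["N"] >= 10]["N"])

    def test_prior_dominated_limit(self):
        # huge precision pins the posterior at the prior mean
        from clonetrace.celltype import _betabinom_regression

        s = 1e8
        mu0, X, N = 0.3, 50, 60
        post = (mu0 * s + X) / (s + N)
        assert post == pytest.approx(mu0, abs=1e-5)
        del _betabinom_regression

    def test_planted_composition_covered(self):
        table, agg = eb_composition(
            self._clone_counts(seed=2), ["GluN", "GABN"], seed=2, n_boot=120
        )
        g, b = agg["GluN"]["ci"], agg["GABN"]["ci"]
        assert g[0] <= 0.5 <= g[1]
        assert b[0] <= 0.04 <= b[1]

    def test_too_few_clones_rejected(self):
        cc = self._clone_counts().head(4)
        with pytest.raises(ValueError):
            eb_composition(cc, ["GluN"], min_clone_size=1)


def test_unmatched_minmfs_flat_across_pairs():
    # sample-unmatched (noise-only) variants: minMF should not depend on the
    # cell-type pair — the spread of pair minMFs stays inside bootstrap noise
    rng = np.random.default_rng(11)
    mf_pool = rng.uniform(1, 20, size=200)
    pair_est = []
    for pair in range(6):
        shared = rng.choice(mf_pool, size=12, replace=False)
        pair_est.append(minmf_bootstrap(shared, n_boot=2000, seed=pair))
    points = np.array([e.minmf for e in pair_est])
    widths = np.array([e.ci[1] - e.ci[0] for e in pair_est])
    assert points.max() - points.min() <= 3 * max(widths.max(), 1e-9)
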