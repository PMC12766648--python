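"""Ground-truth generator: growth, mutations, regions, readout layers."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from clonetrace import SimConfig, simulate_population
from clonetrace.simulate import (
    simulate_amplicons,
    simulate_bulk_wgs,
    simulate_single_cell_readouts,
)


def make_uniform_mf_pop(n_cells=50, n_carriers=2, n_mutations=4000, seed=0):
    """Population whose mutations all share one carrier set — gives many
    independent readout draws at a single known mosaic fraction."""
    from clonetrace.simulate import TruePopulation
    from clonetrace.trees import LineageTree

    cfg = SimConfig(n_regions=1, region_restriction_times={"BA17": 8}, seed=seed)
    parent = np.concatenate([np.full(n_cells, n_cells), [-1]])
    tree = LineageTree(parent=parent, leaf_ids=[f"c{i:05d}" for i in range(n_cells)])
    carriers = {
        f"m{k:05d}": np.arange(n_carriers) for k in range(n_mutations)
    }
    muts = pd.DataFrame(
        {
            "mutation_id": list(carriers),
            "origin_generation": 5,
            "origin_node": 0,
            "true_mf": n_carriers / n_cells,
        }
    )
    cells = pd.DataFrame(
        {
            "cell_id": tree.leaf_ids,
            "region": "BA17",
            "cell_type": "GluN_upper",
            "clade": "clade0",
            "dorsal": False,
        }
    )
    return TruePopulation(
        cells=cells,
        mutations=muts,
        carriers=carriers,
        tree=tree,
        n_generations=26,
        final_size=2**26,
        population_mutations_per_generation=np.zeros(26, dtype=int),
        config=cfg,
    )


class TestConfig:
    def test_defaults_are_study_conditions(self):
        cfg = SimConfig()
        assert cfg.n_generations == 26  # ~6e7 cells after doubling
        assert cfg.mutations_per_generation == 7.0
        assert cfg.dorsal_glun_gabn_ratio == 12.0
        assert cfg.amplicon_depth == 10_000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"panel_ado_rate": 1.5},
            {"celltype_proportions": {"GluN_upper": 0.5, "CGE_GABN": 0.4}},
            {"final_population_size": -1},
            {"wgs_depth": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestPopulation:
    def test_no_mutation_case(self):
        pop = simulate_population(
            SimConfig(mutations_per_generation=0, tracked_lineages=50, seed=0)
        )
        assert len(pop.mutations) == 0
        assert pop.population_mutations_per_generation.sum() == 0
        assert all(len(s) == 0 for s in pop.mutation_sets())

    def test_single_region_degenerate(self):
        pop = simulate_population(
            SimConfig(
                n_regions=1, region_restriction_times={"BA17": 8},
                tracked_lineages=60, seed=2,
            )
        )
        mf = pop.regional_mf()
        assert list(mf.columns) == ["BA17"]
        assert (pop.cells["region"] == "BA17").all()

    def test_population_mutation_rate(self):
        # mean new population-level mutations per generation ~ Poisson(7)
        pop = simulate_population(SimConfig(tracked_lineages=1000, seed=3))
        tally = pop.population_mutations_per_generation[:20]
        se = np.sqrt(7.0 / tally.size)
        assert abs(tally.mean() - 7.0) < 3 * se

    def test_infinite_sites_carriers_are_clades(self, small_pop):
        tree = small_pop.tree
        for mut, origin in zip(
            small_pop.mutations["mutation_id"], small_pop.mutations["origin_node"]
        ):
            np.testing.assert_array_equal(
                small_pop.carriers[mut], tree.leaves_under(int(origin))
            )

    def test_mf_non_increasing_down_lineage(self, small_pop):
        # a mutation on a descendant branch has carriers nested inside (and
        # never exceeding) its ancestors' carrier sets
        mf = small_pop.mutations.set_index("mutation_id")
        node_of = dict(zip(mf.index, mf["origin_node"]))
        parent = small_pop.tree.parent
        anc_cache = {}

        def ancestors(v):
            if v not in anc_cache:
                chain = set()
                u = parent[v]
                while u >= 0:
                    chain.add(int(u))
                    u = parent[u]
                anc_cache[v] = chain
            return anc_cache[v]

        for m1, v1 in node_of.items():
            for m2, v2 in node_of.items():
                if v2 in ancestors(int(v1)):
                    assert mf.loc[m1, "true_mf"] <= mf.loc[m2, "true_mf"]

    def test_regional_mf_conservation(self, small_pop):
        mf = small_pop.regional_mf()
        sizes = small_pop.cells["region"].value_counts()
        weights = sizes.reindex(mf.columns).values / sizes.sum()
        global_mf = small_pop.mutations.set_index("mutation_id")["true_mf"]
        np.testing.assert_allclose(
            (mf.values * weights).sum(axis=1),
            global_mf.reindex(mf.index).values,
            atol=1e-12,
        )

    def test_seed_reproducibility(self):
        cfg = SimConfig(tracked_lineages=80, seed=11)
        p1, p2 = simulate_population(cfg), simulate_population(cfg)
        pdt.assert_frame_equal(p1.cells, p2.cells)
        pdt.assert_frame_equal(p1.mutations, p2.mutations)
        pdt.assert_frame_equal(simulate_bulk_wgs(p1), simulate_bulk_wgs(p2))
        pdt.assert_frame_equal(simulate_amplicons(p1), simulate_amplicons(p2))

    def test_cap_exceeding_population_rejected(self):
        with pytest.raises(ValueError):
            simulate_population(
                SimConfig(final_population_size=64, tracked_lineages=100)
            )


class TestBulkWGS:
    def test_zero_mf_zero_alt_and_fixation(self):
        pop = make_uniform_mf_pop(n_carriers=0, n_mutations=50)
        wgs = simulate_bulk_wgs(pop)
        assert (wgs["alt_reads"] == 0).all()
        full = make_uniform_mf_pop(n_carriers=50, n_mutations=400)
        wgs = simulate_bulk_wgs(full)
        assert abs(wgs["aaf"].mean() - 0.5) < 3 * wgs["aaf"].std() / np.sqrt(len(wgs))

    def test_binomial_moments_at_4pct_mf(self):
        pop = make_uniform_mf_pop(n_cells=50, n_carriers=2, n_mutations=4000)
        wgs = simulate_bulk_wgs(pop)
        frac = wgs["alt_reads"] / wgs["depth"]
        se = np.sqrt(0.02 * 0.98 / 210 / len(wgs))
        assert abs(frac.mean() - 0.02) < 3 * se


class TestAmplicons:
    def test_zero_error_zero_flank_and_zero_mf(self):
        pop = make_uniform_mf_pop(n_carriers=0, n_mutations=30)
        object.__setattr__(pop.config, "amplicon_error_rate", 0.0)
        amp = simulate_amplicons(pop)
        assert (amp["flank_error"] == 0).all()
        assert (amp["alt_reads"] == 0).all()

    def test_binomial_moments_at_2pct_mf(self):
        pop = make_uniform_mf_pop(n_cells=50, n_carriers=1, n_mutations=500)
        amp = simulate_amplicons(pop)
        frac = amp["alt_reads"] / amp["depth"]
        se = np.sqrt(0.01 * 0.99 / 10_000 / len(amp))
        assert abs(frac.mean() - 0.01) < 3 * se
        assert (amp["depth"] >= 10_000).all()
        assert amp["primer"].nunique() <= 3


class TestSingleCell:
    def test_full_ado_silences_panel(self):
        cfg = SimConfig(
            tracked_lineages=60, seed=4, panel_ado_rate=1.0, seq_error_rate=0.0
        )
        pop = simulate_population(cfg)
        panel = list(pop.mutations["mutation_id"][:5])
        if not panel:
            pytest.skip("no mutations drawn")
        reads, _ = simulate_single_cell_readouts(pop, panel=panel, n_cells=60)
        assert (reads["alt_reads"] == 0).all()

    def test_noncarrier_zero_mutant_umis(self):
        cfg = SimConfig(tracked_lineages=60, seed=4, seq_error_rate=0.0)
        pop = simulate_population(cfg)
        panel = list(pop.mutations["mutation_id"][:8])
        _, tally = simulate_single_cell_readouts(pop, panel=panel, n_cells=60)
        cells_idx = {c: i for i, c in enumerate(pop.cells["cell_id"])}
        for mut in panel:
            carr = set(pop.carriers[mut])
            sub = tally[tally["variant"] == mut]
            noncarr = sub[~sub["cell"].map(cells_idx).isin(carr)]
            assert (noncarr["mut_umis"] == 0).all()

    def test_poisson_thinning_closed_form(self):
        # P(carrier shows >=1 mutant UMI) = 1 - exp(-rate * 0.5)
        pop = make_uniform_mf_pop(n_cells=400, n_carriers=400, n_mutations=25)
        object.__setattr__(pop.config, "snrna_umi_rate", 2.0)
        _, tally = simulate_single_cell_readouts(pop, n_cells=400)
        seen = (tally["mut_umis"] >= 1).mean()
        p = 1.0 - np.exp(-2.0 * 0.5)
        se = np.sqrt(p * (1 - p) / len(tally))
        assert abs(seen - p) < 3 * se

    def test_unknown_panel_id_rejected(self, small_pop):
        with pytest.raises(KeyError):
            simulate_single_cell_readouts(small_pop, panel=["nope"], n_cells=10)
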