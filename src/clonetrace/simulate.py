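"""Synthetic developmental lineage with regional and cell-type structure.

The generator emulates a founding cell population growing by synchronous
binary division to ~6x10^7 cells over human cortical neurogenesis, accruing
neutral somatic SNVs (infinite sites, no recurrence), allocating clones to
cortical regions (restricted vs dispersed modes) and to cell types
(glutamatergic / GABAergic neurons and glia), and emits the four
observational layers the analysis consumes:

* bulk WGS variant tables (~210x, per region),
* ultra-deep amplicon readouts (>=10,000 reads, replicate primers,
  flanking-error tallies),
* a single-cell amplification panel with allelic dropout, and
* sparse single-nucleus UMI tallies with cell-type labels.

Only a capped number of lineages is materialised; the genealogy of those
tracked cells is simulated exactly (backward, under synchronous doubling),
and the untracked population mass enters analytically through the
deterministic growth law.  Tracked cells are an exchangeable sample of the
final population, so mutation carrier fractions over tracked cells are the
ground-truth mosaic fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trees import LineageTree

__all__ = [
    "SimConfig",
    "TruePopulation",
    "simulate_population",
    "simulate_bulk_wgs",
    "simulate_amplicons",
    "simulate_single_cell_readouts",
    "planted_regional_excess",
]

#: Broad cortical cell-type groups and their default proportions among all
#: profiled nuclei.  Neurons ~2/3 (GluN:GABN roughly 5:1 overall), glia ~1/3.
DEFAULT_CELLTYPE_PROPORTIONS: dict[str, float] = {
    "GluN_upper": 0.25,
    "GluN_other": 0.30,
    "CGE_GABN": 0.06,
    "MGE_GABN": 0.06,
    "astrocyte": 0.15,
    "oligodendrocyte": 0.14,
    "microglia": 0.04,
}

GLUN_TYPES = ("GluN_upper", "GluN_other")
GABN_TYPES = ("CGE_GABN", "MGE_GABN")

#: Generation at which clones founded in each region become region-confined.
#: On a 26-generation tree spanning 16 weeks these sit at ~post-MRCA weeks
#: 5-7, the window in which regional restriction is first observed.
DEFAULT_RESTRICTION_TIMES: dict[str, int] = {"BA9": 8, "BA17": 10, "BA18": 12}


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth conditions for the synthetic lineage.

    Defaults are the fitted values the study reports (final population
    ~6e7 cells, ~7 population-level mutations per generation, 16-week
    neurogenesis span, 12:1 dorsal GluN:GABN ratio) re-used here as
    simulation truth; readout parameters match the assay designs (210x WGS,
    >=10,000-read amplicons).
    """

    final_population_size: float = 6.0e7
    mutations_per_generation: float = 7.0
    neurogenesis_span_weeks: float = 16.0
    n_regions: int = 3
    region_restriction_times: dict[str, int] | None = None
    celltype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELLTYPE_PROPORTIONS)
    )
    dorsal_glun_gabn_ratio: float = 12.0
    wgs_depth: float = 210.0
    amplicon_depth: int = 10_000
    amplicon_error_rate: float = 5e-4
    panel_ado_rate: float = 0.2
    panel_mean_depth: float = 50.0
    snrna_umi_rate: float = 2.0
    seq_error_rate: float = 1e-3
    amplification_beta_shape: float = 5.0
    tracked_lineages: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "panel_ado_rate",
            "amplicon_error_rate",
            "seq_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        props = self.celltype_proportions
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("celltype_proportions must sum to 1")
        if any(p < 0 or p > 1 for p in props.values()):
            raise ValueError("celltype_proportions must be fractions in [0, 1]")
        for name in (
            "final_population_size",
            "wgs_depth",
            "amplicon_depth",
            "tracked_lineages",
            "n_regions",
            "panel_mean_depth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mutations_per_generation < 0:
            raise ValueError("mutations_per_generation must be >= 0")
        if self.region_restriction_times is None:
            object.__setattr__(
                self, "region_restriction_times", self._default_restriction()
            )
        if len(self.region_restriction_times) != self.n_regions:
            raise ValueError(
                "region_restriction_times must name exactly n_regions regions"
            )

    def _default_restriction(self) -> dict[str, int]:
        if self.n_regions == 3:
            return dict(DEFAULT_RESTRICTION_TIMES)
        base = sorted(DEFAULT_RESTRICTION_TIMES.values())
        return {
            f"R{i + 1}": base[i % len(base)] + 2 * (i // len(base))
            for i in range(self.n_regions)
        }

    @property
    def regions(self) -> list[str]:
        return list(self.region_restriction_times)

    @property
    def n_generations(self) -> int:
        """Doublings from one founder to the (power-of-two) final size."""
        return int(round(math.log2(self.final_population_size)))


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *key]))


@dataclass
class TruePopulation:
    """Ground truth: genealogy, mutations, regions and cell types.

    ``cells`` has one row per tracked cell (cell_id, region, cell_type,
    clade, dorsal); ``mutations`` one row per mutation that hit a lineage
    ancestral to the tracked cells (mutation_id, origin_generation,
    origin_node, true_mf).  ``carriers[mutation_id]`` gives tracked-cell
    indices carrying the mutation — exactly the descendants of its origin
    branch (infinite sites).  ``population_mutations_per_generation`` tallies
    *all* new population-level mutations, including those on untracked mass.
    """

    cells: pd.DataFrame
    mutations: pd.DataFrame
    carriers: dict[str, np.ndarray]
    tree: LineageTree
    n_generations: int
    final_size: int
    population_mutations_per_generation: np.ndarray
    config: SimConfig

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def mutation_sets(self) -> pd.Series:
        """Per-cell frozenset of carried mutation ids."""
        sets: list[set[str]] = [set() for _ in range(self.n_cells)]
        for mut, idx in self.carriers.items():
            for i in idx:
                sets[i].add(mut)
        return pd.Series([frozenset(s) for s in sets], index=self.cells["cell_id"])

    def regional_mf(self) -> pd.DataFrame:
        """True mosaic fraction (carrier fraction) per mutation x region."""
        regions = self.config.regions
        region_idx = {r: np.flatnonzero(self.cells["region"].values == r) for r in regions}
        rows = {}
        for mut, idx in self.carriers.items():
            carr = np.zeros(self.n_cells, dtype=bool)
            carr[idx] = True
            rows[mut] = [
                carr[region_idx[r]].mean() if region_idx[r].size else 0.0
                for r in regions
            ]
        return pd.DataFrame.from_dict(rows, orient="index", columns=regions).sort_index()

    def lineage_tree(self) -> LineageTree:
        """The true genealogy with mutations attached to their branches."""
        return self.tree


def _sample_distinct(rng: np.random.Generator, high: int, k: int) -> np.ndarray:
    """k distinct integers uniform in [0, high) without materialising range(high)."""
    if k > high:
        raise ValueError("cannot sample more positions than cells")
    if high <= 4 * k:
        return rng.choice(high, size=k, replace=False)
    out = rng.integers(0, high, size=k)
    while True:
        uniq, counts = np.unique(out, return_counts=True)
        if uniq.size == k:
            return out
        dup_mask = np.isin(out, uniq[counts > 1])
        # keep first occurrence of each duplicate, redraw the rest
        seen: set[int] = set()
        for i in np.flatnonzero(dup_mask):
            if out[i] in seen:
                out[i] = rng.integers(0, high)
            else:
                seen.add(int(out[i]))


def simulate_population(config: SimConfig) -> TruePopulation:
    """Grow the lineage and place mutations, regions and cell types.

    The genealogy of ``config.tracked_lineages`` cells sampled from the final
    population is simulated exactly backward under synchronous binary
    division (population 2^t at generation t, capped at the final size).
    Each generation, Poisson(mutations_per_generation) new mutations arise
    uniformly over the whole population; those landing on lineages ancestral
    to the tracked cells are recorded with their carrier clades.
    """
    G = config.n_generations
    N = 2**G
    n = int(config.tracked_lineages)
    if n > N:
        raise ValueError(
            f"tracked_lineages={n} exceeds the final population size 2^{G}"
        )
    rng = _rng(config.seed, 1)

    # ---- backward genealogy under synchronous doubling -------------------
    parent = [-1] * n
    times = [float(G)] * n
    active = list(range(n))
    for t in range(G, 0, -1):
        k = len(active)
        if k == 1:
            break
        pos = _sample_distinct(rng, 2**t, k)
        slots = pos // 2
        order = np.argsort(slots, kind="stable")
        new_active: list[int] = []
        i = 0
        while i < k:
            j = i + 1
            if j < k and slots[order[j]] == slots[order[i]]:
                a, b = active[order[i]], active[order[j]]
                node = len(parent)
                parent.append(-1)
                times.append(float(t - 1))
                parent[a] = node
                parent[b] = node
                new_active.append(node)
                i += 2
            else:
                new_active.append(active[order[i]])
                i += 1
        active = new_active
    if len(active) > 1:  # population size 1 at generation 0: forced MRCA
        node = len(parent)
        parent.append(-1)
        times.append(0.0)
        for a in active:
            parent[a] = node
        active = [node]

    parent_arr = np.asarray(parent)
    times_arr = np.asarray(times)
    n_nodes = parent_arr.size

    # ---- mutations: population-level Poisson, thinned onto the tree ------
    mu = config.mutations_per_generation
    # edge above node v spans generations (times[parent[v]], times[v]]
    has_par = parent_arr >= 0
    lo = np.where(has_par, times_arr[parent_arr], -1.0)
    hi = times_arr
    totals = np.zeros(G, dtype=int)
    mut_edge: list[int] = []
    mut_gen: list[int] = []
    for g in range(1, G + 1):
        m_total = int(rng.poisson(mu))
        totals[g - 1] = m_total
        if m_total == 0:
            continue
        crossing = np.flatnonzero(has_par & (lo < g) & (g <= hi))
        A = crossing.size
        P = 2**g
        hits = int(rng.binomial(m_total, min(1.0, A / P))) if A else 0
        if hits:
            chosen = rng.choice(crossing, size=hits, replace=True)
            mut_edge.extend(int(c) for c in chosen)
            mut_gen.extend([g] * hits)

    tree = LineageTree(
        parent=parent_arr,
        leaf_ids=[f"c{i:05d}" for i in range(n)],
        edge_variants=[[] for _ in range(n_nodes)],
        times=times_arr,
    )
    order = np.argsort(mut_gen, kind="stable")
    carriers: dict[str, np.ndarray] = {}
    rows = []
    for rank, oi in enumerate(order):
        mid = f"m{rank:04d}"
        node = mut_edge[oi]
        leaves = tree.leaves_under(node)
        carriers[mid] = leaves
        tree.edge_variants[node].append(mid)
        rows.append((mid, int(mut_gen[oi]), node, leaves.size / n))
    tree.edge_mutation_count = np.array(
        [len(v) for v in tree.edge_variants], dtype=float
    )
    mutations = pd.DataFrame(
        rows, columns=["mutation_id", "origin_generation", "origin_node", "true_mf"]
    )

    # ---- regions: restricted vs dispersed clades -------------------------
    regions = config.regions
    rtimes = config.region_restriction_times
    g_min = min(rtimes.values())
    region_of = np.empty(n, dtype=object)
    clade_of = np.empty(n, dtype=object)
    dorsal = np.zeros(n, dtype=bool)
    # maximal clades whose root crosses the earliest restriction time
    cross = [
        v
        for v in range(n_nodes)
        if times_arr[v] >= g_min and (parent_arr[v] < 0 or times_arr[parent_arr[v]] < g_min)
    ]
    for ci, v in enumerate(cross):
        leaves = tree.leaves_under(v)
        clade_of[leaves] = f"clade{ci:03d}"
        r = regions[int(rng.integers(len(regions)))]
        if times_arr[v] >= rtimes[r]:
            region_of[leaves] = r  # restricted (dorsal) clone
            dorsal[leaves] = True
        else:  # dispersed clone: members mix across all regions
            region_of[leaves] = [regions[i] for i in rng.integers(len(regions), size=leaves.size)]

    # ---- cell types ------------------------------------------------------
    props = config.celltype_proportions
    type_names = list(props)
    base_p = np.array([props[t] for t in type_names])
    dorsal_p = base_p.copy()
    glun = np.array([t in GLUN_TYPES for t in type_names])
    gabn = np.array([t in GABN_TYPES for t in type_names])
    neuron_mass = base_p[glun].sum() + base_p[gabn].sum()
    if neuron_mass > 0 and base_p[gabn].sum() > 0:
        r = config.dorsal_glun_gabn_ratio
        glun_target = neuron_mass * r / (r + 1.0)
        gabn_target = neuron_mass / (r + 1.0)
        dorsal_p[glun] = base_p[glun] / base_p[glun].sum() * glun_target
        dorsal_p[gabn] = base_p[gabn] / base_p[gabn].sum() * gabn_target
    cell_type = np.empty(n, dtype=object)
    for i in range(n):
        p = dorsal_p if dorsal[i] else base_p
        cell_type[i] = type_names[int(rng.choice(len(type_names), p=p))]

    cells = pd.DataFrame(
        {
            "cell_id": tree.leaf_ids,
            "region": region_of,
            "cell_type": cell_type,
            "clade": clade_of,
            "dorsal": dorsal,
        }
    )
    return TruePopulation(
        cells=cells,
        mutations=mutations,
        carriers=carriers,
        tree=tree,
        n_generations=G,
        final_size=N,
        population_mutations_per_generation=totals,
        config=config,
    )


# --------------------------------------------------------------------------
# Readout layer 1: bulk WGS
# --------------------------------------------------------------------------
def simulate_bulk_wgs(
    pop: TruePopulation, config: SimConfig | None = None, drop_undetected: bool = False
) -> pd.DataFrame:
    """Bulk WGS variant table: per region x mutation, Poisson depth at the
    configured coverage and binomial alt reads at the regional AAF (= MF/2).
    """
    config = config or pop.config
    rng = _rng(config.seed, 2)
    mf = pop.regional_mf()
    rows = []
    for mut, mf_row in mf.iterrows():
        for region in mf.columns:
            depth = int(rng.poisson(config.wgs_depth))
            aaf_true = mf_row[region] / 2.0
            alt = int(rng.binomial(depth, aaf_true)) if depth else 0
            rows.append((mut, region, depth, alt))
    out = pd.DataFrame(rows, columns=["variant", "region", "depth", "alt_reads"])
    out["aaf"] = np.where(out["depth"] > 0, out["alt_reads"] / out["depth"], 0.0)
    out["donor"] = f"sim{config.seed}"
    if drop_undetected:
        out = out[out["alt_reads"] > 0].reset_index(drop=True)
    return out


# --------------------------------------------------------------------------
# Readout layer 2: deep amplicons (MIPP-seq-like)
# --------------------------------------------------------------------------
def simulate_amplicons(
    pop: TruePopulation,
    config: SimConfig | None = None,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Deep-amplicon readouts: 1-3 replicate primers per variant/region,
    >=amplicon_depth reads each, binomial alt reads at the true regional AAF
    and 100 flanking positions sequenced at the platform error rate.

    Columns: variant, region, primer, depth, alt_reads, flank_error (mean
    flanking AAF over the 100 positions).
    """
    config = config or pop.config
    rng = _rng(config.seed, 3)
    mf = pop.regional_mf()
    if variants is not None:
        wanted = pd.unique(variants["variant"])
        mf = mf.loc[[v for v in mf.index if v in set(wanted)]]
    rows = []
    for mut, mf_row in mf.iterrows():
        for region in mf.columns:
            aaf_true = mf_row[region] / 2.0
            for primer in range(1, int(rng.integers(1, 4)) + 1):
                depth = int(config.amplicon_depth + rng.poisson(0.1 * config.amplicon_depth))
                alt = int(rng.binomial(depth, aaf_true))
                flank = rng.binomial(depth, config.amplicon_error_rate, size=100)
                rows.append(
                    (mut, region, f"p{primer}", depth, alt, float(flank.mean() / depth))
                )
    return pd.DataFrame(
        rows, columns=["variant", "region", "primer", "depth", "alt_reads", "flank_error"]
    )


# --------------------------------------------------------------------------
# Readout layers 3+4: single-cell panel and snRNA UMI tallies
# --------------------------------------------------------------------------
def simulate_single_cell_readouts(
    pop: TruePopulation,
    config: SimConfig | None = None,
    panel: list[str] | None = None,
    n_cells: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample cells (stratified by region) and emit the two single-cell layers.

    Panel layer: per cell x site read counts from whole-genome-amplified
    DNA, with allelic dropout at ``panel_ado_rate`` and Beta-distributed
    amplification imbalance of the mutant-read fraction around 0.5.
    snRNA layer: per cell x site UMIs ~ Poisson(snrna_umi_rate); mutant UMIs
    binomial at 0.5 in carriers and at the sequencing error rate otherwise.
    """
    config = config or pop.config
    rng = _rng(config.seed, 4)
    if panel is None:
        panel = list(pop.mutations["mutation_id"])
    known = set(pop.mutations["mutation_id"])
    unknown = [m for m in panel if m not in known]
    if unknown:
        raise KeyError(f"panel references unknown mutation ids: {unknown[:5]}")
    n_cells = n_cells or pop.n_cells
    if n_cells > pop.n_cells:
        raise ValueError(
            f"n_cells={n_cells} exceeds the {pop.n_cells} tracked cells; "
            "raise SimConfig.tracked_lineages"
        )

    # stratified (proportional) sample over regions
    cells = pop.cells
    take: list[int] = []
    groups = [np.flatnonzero(cells["region"].values == r) for r in config.regions]
    sizes = np.array([g.size for g in groups])
    alloc = np.floor(sizes / sizes.sum() * n_cells).astype(int)
    while alloc.sum() < n_cells:
        alloc[int(np.argmax(sizes - alloc))] += 1
    for g, a in zip(groups, alloc):
        take.extend(rng.choice(g, size=min(a, g.size), replace=False))
    take = sorted(take)

    carrier = np.zeros((len(take), len(panel)), dtype=bool)
    for j, mut in enumerate(panel):
        carrier[:, j] = np.isin(take, pop.carriers[mut])

    shape = config.amplification_beta_shape
    err = config.seq_error_rate
    panel_rows = []
    tally_rows = []
    for i, ci in enumerate(take):
        cid = cells["cell_id"].iloc[ci]
        ctype = cells["cell_type"].iloc[ci]
        region = cells["region"].iloc[ci]
        depths = rng.poisson(config.panel_mean_depth, size=len(panel))
        umis = rng.poisson(config.snrna_umi_rate, size=len(panel))
        for j, mut in enumerate(panel):
            d = int(depths[j])
            if carrier[i, j]:
                if rng.random() < config.panel_ado_rate:
                    alt = int(rng.binomial(d, err)) if d else 0
                else:
                    p_alt = float(rng.beta(shape, shape))
                    alt = int(rng.binomial(d, p_alt)) if d else 0
            else:
                alt = int(rng.binomial(d, err)) if d else 0
            panel_rows.append((cid, mut, d, alt))
            u = int(umis[j])
            p_mut = 0.5 if carrier[i, j] else err
            mu_u = int(rng.binomial(u, p_mut)) if u else 0
            tally_rows.append((cid, mut, u, mu_u, ctype, region))
    panel_df = pd.DataFrame(panel_rows, columns=["cell", "site", "total_reads", "alt_reads"])
    tally_df = pd.DataFrame(
        tally_rows,
        columns=["cell", "variant", "total_umis", "mut_umis", "cell_type", "region"],
    )
    return panel_df, tally_df


# --------------------------------------------------------------------------
# Construction helper for regional-ratio experiments
# --------------------------------------------------------------------------
def planted_regional_excess(
    n_shared: int,
    n_excess: int,
    region_a: str = "BA17",
    region_b: str = "BA18",
    mf_band: tuple[float, float] = (0.02, 0.04),
    depth: int = 210,
    seed: int = 0,
) -> pd.DataFrame:
    """Variant table with a planted regional excess in an MF band.

    ``n_shared`` variants appear in both regions at the same AAF; region_a
    additionally carries ``n_excess`` exclusive variants, so the true count
    ratio in the band is (n_shared + n_excess) / n_shared.  AAFs are drawn
    uniformly over the band (MF scale; AAF = MF/2).
    """
    rng = _rng(seed, 5)
    lo, hi = mf_band[0] / 2.0, mf_band[1] / 2.0
    rows = []
    for i in range(n_shared):
        aaf = float(rng.uniform(lo, hi))
        rows.append((f"s{i:04d}", region_a, aaf, depth))
        rows.append((f"s{i:04d}", region_b, aaf, depth))
    for i in range(n_excess):
        aaf = float(rng.uniform(lo, hi))
        rows.append((f"x{i:04d}", region_a, aaf, depth))
        rows.append((f"x{i:04d}", region_b, 0.0, depth))
    return pd.DataFrame(rows, columns=["variant", "region", "aaf", "depth"])
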