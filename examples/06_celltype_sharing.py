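"""Cell-type sharing from snRNA UMI tallies: minMF, clones, composition.

Simulates sparse single-nucleus UMI tallies, counts shared sSNVs per
cell-type pair, estimates the minimum shared mosaic fraction (minMF),
clusters cells into clones on the shared-variant graph, and estimates
GluN/GABN clone composition by empirical Bayes.
"""

import pandas as pd

from clonetrace import SimConfig, simulate_population
from clonetrace.celltype import (
    clone_table,
    eb_composition,
    louvain_clones,
    minmf_bootstrap,
    shared_variant_counts,
)
from clonetrace.simulate import GABN_TYPES, GLUN_TYPES, simulate_single_cell_readouts

cfg = SimConfig(tracked_lineages=800, seed=2, snrna_umi_rate=2.0)
pop = simulate_population(cfg)
mm = pop.mutations
# clone structure lives in the low-mosaic variants; near-fixed mutations
# connect every cell and carry no clonal signal
panel = list(mm[mm["true_mf"] < 0.12]["mutation_id"])
_, tally = simulate_single_cell_readouts(pop, panel=panel, n_cells=800)

stats = shared_variant_counts(tally, min_cells_per_type=2)
top = sorted(stats, key=lambda s: -s.normalized)[:5]
print("top cell-type pairs by normalized shared sSNV count:")
for s in top:
    print(f"  {s.type_a} x {s.type_b}: {s.shared_count} shared sSNVs / "
          f"{s.n_mutant_cell_pairs} mutant cell pairs = {s.normalized:.4f}")

# minMF between GluN and GABN groups, on the percent-MF scale
mf_pct = pop.mutations.set_index("mutation_id")["true_mf"] * 100
mut = tally[tally["mut_umis"] > 0]
glun_cells = mut[mut["cell_type"].isin(GLUN_TYPES)]
gabn_cells = mut[mut["cell_type"].isin(GABN_TYPES)]
shared = sorted(
    v for v in set(glun_cells["variant"]) & set(gabn_cells["variant"])
    if glun_cells[glun_cells.variant == v]["cell"].nunique() >= 2
    and gabn_cells[gabn_cells.variant == v]["cell"].nunique() >= 2
)
if len(shared) >= 3:
    est = minmf_bootstrap(mf_pct[shared].values, n_boot=5000, seed=0)
    print(f"\nGluN/GABN minMF: {est.minmf:.2f}% "
          f"(90% CI {est.ci[0]:.2f}-{est.ci[1]:.2f}%, {est.n_shared} shared sSNVs)")

clones = louvain_clones(tally, seed=0)
print(f"\nLouvain clones: {clones.nunique()} over {len(clones)} mutant-bearing cells")

groups = {"GluN": list(GLUN_TYPES), "GABN": list(GABN_TYPES)}
counts = clone_table(tally, clones, groups)
big = counts[counts["N"] >= 10]
if len(big) >= 5:
    _, agg = eb_composition(counts, ["GluN", "GABN"], min_clone_size=10, seed=0)
    for t in ("GluN", "GABN"):
        p, ci = agg[t]["proportion"], agg[t]["ci"]
        print(f"  {t} composition: {100 * p:.1f}% "
              f"(95% CI {100 * ci[0]:.1f}-{100 * ci[1]:.1f}%)")
else:
    print("  (not enough clones of >=10 cells for the composition regression)")
# The minMF of the last variant shared by two cell types proxies the mosaic
# fraction of their most recent common progenitor; the composition estimate
# shrinks small clones toward the regression prior before aggregating.
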