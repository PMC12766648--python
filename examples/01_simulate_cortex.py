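"""Simulate a developing cortex and emit all four observational layers.

Grows a ~6.7e7-cell population (2000 tracked lineages) accruing neutral
somatic SNVs at ~7 per generation, assigns cortical regions and cell
types, and writes the bulk-WGS, amplicon and single-cell tables to
scratch files.
"""

from pathlib import Path

from clonetrace import SimConfig, io, simulate_population
from clonetrace.simulate import (
    simulate_amplicons,
    simulate_bulk_wgs,
    simulate_single_cell_readouts,
)

out = Path("scratch/example01")
out.mkdir(parents=True, exist_ok=True)

cfg = SimConfig(tracked_lineages=2000, seed=1)
pop = simulate_population(cfg)
print(f"population: {pop.final_size:.3g} cells over {pop.n_generations} generations")
print(f"tracked cells: {pop.n_cells}; mutations on the sample tree: {len(pop.mutations)}")
print(pop.cells["region"].value_counts().to_string())
print(pop.cells["cell_type"].value_counts().to_string())

wgs = simulate_bulk_wgs(pop)
amp = simulate_amplicons(pop)
panel = list(pop.mutations["mutation_id"][:40])
panel_reads, tally = simulate_single_cell_readouts(pop, panel=panel, n_cells=500)

for name, df in [
    ("wgs.tsv", wgs), ("amplicons.tsv", amp),
    ("panel_reads.tsv", panel_reads), ("umi_tally.tsv", tally),
    ("cells.tsv", pop.cells),
]:
    io.write_table(df, out / name)
io.write_config(cfg, out / "config.yaml")

print(f"\nbulk WGS rows: {len(wgs)} (mean depth {wgs['depth'].mean():.0f}x)")
print(f"amplicon rows: {len(amp)} (min depth {amp['depth'].min()})")
print(f"single-cell panel rows: {len(panel_reads)}; UMI tally rows: {len(tally)}")
print(f"tables written under {out}/")
# Each table is one observational layer of the same ground-truth lineage:
# deep WGS sees regional allele fractions, amplicons re-genotype them
# ultra-deeply, and the single-cell layers carry lineage + cell-type signal.
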