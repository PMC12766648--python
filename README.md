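# clonetrace

Statistical tools for mapping the clonal architecture of the human cortex
from somatic single-nucleotide variants (sSNVs). During fetal
neurogenesis, each cell division leaves behind a handful of somatic
mutations; a variant present in a fraction *m* of cells (its mosaic
fraction, MF = 2 × AAF for a heterozygous site) marks the clone descended
from the cell in which it arose. Reading those marks across cortical
regions, sequencing assays and single cells reconstructs where and when
cortical clones formed, how far they dispersed, and which cell types they
produced.

The package is aimed at researchers analysing somatic mosaicism in bulk
and single-cell sequencing of brain (or other) tissue, and implements the
full statistical chain as an importable library:

- **`clonetrace.simulate`** — a ground-truth developmental-lineage
  generator: synchronous doubling of one founder to N = 2²⁶ ≈ 6.7×10⁷
  cells; Poisson(μ = 7) neutral mutations per generation
  (infinite sites); regionally restricted vs dispersed clones; cell-type
  assignment with a 12:1 dorsal GluN:GABN ratio; and the four
  observational layers every stage consumes (210× bulk WGS, ≥10,000-read
  amplicons with flanking-error tallies, a single-cell panel with allelic
  dropout, sparse snRNA UMI tallies).
- **`clonetrace.regional_ratio`** — sensitivity-corrected ratio of
  detectable sSNV counts between regions within AAF bins, with a
  "uniformly mixed" Monte-Carlo null and empirical p-values.
- **`clonetrace.artifact_filter`** — position-weight-matrix likelihood
  -ratio filtering of platform T>G/A>C artifacts with empirical p-values.
- **`clonetrace.mipp`** — deep-amplicon (MIPP-seq-style) MF estimation
  with background error, the ≥10,000-read / ≥0.1%-MF detection rule,
  mosaicism categories, Tukey outlier fences, and the Poisson/BH regional
  restriction test against a simulated mixing null.
- **`clonetrace.genotyping`** — binomial-mixture posterior genotyping of
  panel sSNVs in whole-genome-amplified single cells, with pooled-AAF
  priors and cross-batch consensus.
- **`clonetrace.lineage`** — perfect-phylogeny imputation (exact for ≤12
  sites, coordinate-descent heuristic above), direct tree construction,
  a coalescent model over a doubling population giving posterior times of
  origin in generations and post-MRCA weeks (PMW), the regional
  restriction statistic (RRS), and k-means dispersion modes.
- **`clonetrace.celltype`** — normalized shared-sSNV counts per cell-type
  pair with a bootstrap difference test, the minimum shared mosaic
  fraction (minMF) with bootstrap CIs, Louvain clone clustering on the
  shared-variant graph, and empirical-Bayes (beta-binomial) clone
  composition estimates.

The models and their assumptions are documented in
[`docs/methods.md`](docs/methods.md); [`examples/`](examples/) holds one
short runnable script per capability.

## Core quantities

- MF = 2 × AAF; detection floor 0.1% MF at ≥10,000 reads.
- Projected regional count = Σ retained variants / sensitivity(AAF), with
  per-bin thresholds min(Binomial(250, AAF)) over bin members.
- Genotype posterior: π·B(a; d, p_mut) / [π·B(a; d, p_mut) + (1−π)·B(a; d, e)].
- Branch mutation count ~ Poisson(μ·(2^−t_parent − 2^−t_child)) under
  doubling growth P(t) = 2^t; node-time prior = exact synchronous
  Wright–Fisher pairing probability.
- RRS = mean cross-region patristic distance / mean within-region distance
  (RRS > 1 ⇒ regional restriction).
- Clone composition posterior = (α₀ + X)/(α₀ + β₀ + N), α₀ = μ₀σ₀,
  β₀ = (1−μ₀)σ₀ from a beta-binomial regression.

## Worked example

Estimate the ratio of detectable variants between two regions when one
carries a planted 1.5× excess of 2–4% MF variants:

```python
from clonetrace.regional_ratio import SensitivityCurve, estimate_ratio_ci
from clonetrace.simulate import planted_regional_excess

variants = planted_regional_excess(n_shared=60, n_excess=30,
                                   mf_band=(0.02, 0.04), seed=3)
est = estimate_ratio_ci(variants, "BA17", "BA18",
                        SensitivityCurve.default(), n_iter=1000, seed=1)
print(est.observed, est.observed_ci, est.expected_ci, est.p_value)
```

Running `python examples/02_regional_ratio.py` prints:

```
observed ratio BA17/BA18: 1.62 (95% CI 1.60-1.62)
expected under uniform mixing: 1.00 (95% CI 0.98-1.00)
empirical p = 0.0020; significant: True
```

The observed interval sits near the planted excess (the point exceeds 1.5
because half of the excess variants' null mass is shared back to BA18),
while the uniformly-mixed null hugs 1; the small empirical p declares the
regional difference real.

`python examples/05_single_cell_lineage.py` runs the single-cell chain
(genotype → impute → tree → coalescent → RRS) on 120 simulated cells and
prints, among other lines:

```
posterior mu (mutations/generation): median 5.5, 90% CI 3.9-7.4
root-clade RRS: 0.98 (95% CI 0.94-1.05)
```

— the mutation-rate interval covers the generating rate of 7 per
generation, and the root clade (which mixes all regions by construction)
shows no regional restriction.

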