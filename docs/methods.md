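# Methods

`clonetrace` reimplements, as a tested library, the statistical machinery
needed to map the clonal architecture of a human cortex from somatic
single-nucleotide variants (sSNVs): regional variant-count ratios from bulk
WGS, a position-weight-matrix artifact filter, deep-amplicon mosaic-fraction
statistics with a uniform-mixing null, single-cell posterior genotyping,
perfect-phylogeny lineage trees with coalescent times of origin, regional
restriction statistics, and cell-type variant-sharing and clone-composition
analyses. Because the underlying human data are controlled-access, every
stage is exercised against a synthetic developmental-lineage generator whose
defaults are the study conditions themselves.

Throughout, the mosaic fraction (MF) of a heterozygous sSNV is defined as
twice its alternate allele fraction (AAF): a read samples alleles, a cell
carries two, so a variant in a fraction m of cells occupies m/2 of reads.

## Synthetic lineage generator (`clonetrace.simulate`)

**Growth model.** One founder cell divides synchronously (the population
doubles each generation) until it reaches N = 2^G cells; the requested final
size (default 6.0e7, giving G = 26, N ≈ 6.7e7) is rounded to the nearest
power of two. Only `tracked_lineages` cells (default 2000) are materialised:
their genealogy is simulated *exactly* by the backward coalescent of the
doubling population (lineages occupy distinct cells among 2^t at generation
t and merge when they share a parent), which is equivalent to forward growth
with the untracked mass carried analytically. Tracked cells are an
exchangeable sample of the final population, so a mutation's true MF is its
carrier fraction over tracked cells; regional MFs weighted by region sizes
recover the global MF exactly (a unit-tested conservation law).

**Mutations.** Each generation, Poisson(`mutations_per_generation`, default
7) new mutations arise uniformly over the whole population (infinite sites,
no recurrence). A mutation is recorded when it lands on a lineage ancestral
to the tracked cells (probability A(t)/2^t, with A(t) the number of
ancestral lineages); its carriers are exactly the tracked descendants of
that branch. Population-level totals per generation are tallied regardless,
so the rate itself is testable.

**Regions.** Each maximal clade whose root crosses the earliest
restriction generation draws a target region uniformly; if the clade was
founded after that region's restriction time (defaults BA9: 8, BA17: 10,
BA18: 12 generations, ≈ post-MRCA weeks 5–7 on a 26-generation/16-week
tree) the whole clade is confined there ("restricted"/dorsal mode),
otherwise its cells scatter uniformly over regions ("dispersed" mode). The
staggering of restriction times is what produces a mixture of both modes.

**Cell types.** Types are drawn i.i.d. per cell from
`celltype_proportions` (defaults: upper-layer GluN 0.25, other-layer GluN
0.30, CGE-GABN 0.06, MGE-GABN 0.06, astrocyte 0.15, oligodendrocyte 0.14,
microglia 0.04 — neurons ≈ 2/3 of nuclei with an overall GluN:GABN ratio
near 5:1). Inside restricted (dorsal) clades the neuronal mass is re-split
to the configured `dorsal_glun_gabn_ratio` (default 12:1), leaving glia
untouched.

**Readout layers.** (1) Bulk WGS: per region × mutation, depth ~
Poisson(210) and alt reads ~ Binomial(depth, regional MF/2). (2) Deep
amplicons: 1–3 replicate primers per variant/region, ≥10,000 reads each,
binomial alt reads, and 100 flanking positions sequenced at the platform
error rate (default 5e-4/base) whose mean AAF is the background error. (3)
Single-cell panel: per cell × site depth ~ Poisson(50); in carriers the
mutant-read fraction is Beta(5,5)-distributed around 0.5 (amplification
imbalance) and the mutant allele drops out entirely with probability
`panel_ado_rate` (default 0.2); non-carriers see alt reads at the
sequencing error rate 1e-3. (4) snRNA: UMIs ~ Poisson(2) per cell × site,
mutant UMIs binomial at 0.5 in carriers (so the fraction of carriers with
≥1 mutant UMI follows the closed form 1 − exp(−rate/2)) and at the error
rate otherwise.

**What the generator does not emulate:** selection, region- or
type-specific death rates, migration trajectories, doublets/ambient RNA,
locus dropout correlated across sites, mapping artifacts, or germline
variation. Passing tests therefore demonstrate correctness of the
*statistics* under neutral, independent-noise conditions, not robustness to
every failure mode of real sequencing data.

All randomness derives from `SimConfig.seed` through per-layer child
streams, so a fixed seed fixes every emitted table byte-for-byte.

## Regional sSNV-count ratio (`clonetrace.regional_ratio`)

Variant discovery sensitivity falls steeply at low AAF, so raw per-region
counts are not comparable. For each of seven AAF bins (1–2, 2–3, 3–4, 4–5,
5–10, 10–20, 20–50%) a detection threshold is simulated as the minimum of
Binomial(250, AAF) draws over the bin's member variants; each variant-region
is then re-simulated at its regional AAF, retained when the draw reaches its
bin's threshold, and contributes 1/sensitivity(AAF) to the region's
projected count. The ratio of projected counts, re-simulated over
`n_iter` iterations (thresholds recomputed every iteration), gives a
median point estimate and percentile CI (the CI level is a parameter —
95% by default, 99% available). The null replaces each variant's regional
AAFs with its cross-region mean ("uniformly mixed") before simulating; the
empirical p-value is the two-sided tail probability of the observed point
under the null ratio distribution with a +1 finite-sample correction.

Numerical choices: variants are binned by the mean of their *positive*
AAFs (the AAF at which they were actually found), while the null mean runs
over all tested regions including zeros; a variant with AAF 0 in a region
contributes nothing there regardless of simulated reads; iterations with a
zero projected denominator are dropped and counted. The packaged default
sensitivity curve is a logistic in log10(AAF) with midpoint 2% AAF,
saturating near 1 above 10% — a stand-in *shape*, not the published
caller-specific values, which should be supplied via
`SensitivityCurve(aaf, sensitivity)` (isotonic regression then a monotone
PCHIP spline) for canonical analyses.

## PWM artifact filter (`clonetrace.artifact_filter`)

Platform-specific T>G/A>C artifacts concentrate in characteristic sequence
contexts (e.g. TTCC/GA repeats). Per substitution class — records are
reverse-complemented into the pyrimidine frame so complementary classes
pool — a 41-base position weight matrix is built from a suspect ("test")
callset and a clean ("control") callset with pseudocount 0.5 per base
(masked/non-ACGT positions excluded column-wise). Each call is scored by
the joint multinomial log likelihood ratio of the 9 bases centered on the
substitution; the empirical p of a test call is
(1 + #{control LR ≥ observed}) / (n_control + 1), and calls with p < 0.05
are removed.

When scoring, each record's own window is left out of the PWM it
contributed to. Without this leave-one-out correction the test set's
records score systematically inflated ratios under their own PWM and the
filter removes far more than α of exchangeable data at modest callset
sizes; with it, the removal rate is calibrated and the p-values are
super-uniform (both are tested).

## Deep-amplicon statistics (`clonetrace.mipp`)

MF per variant/region is 2 × the mean per-primer AAF; background error is
the mean flanking AAF (reported both as an AAF fraction and on the
percent-MF scale). Detection requires ≥10,000 reads (below: inconclusive),
the expected alternate allele, and MF ≥ 0.1%; otherwise the site is called
absent. Mosaicism categories: germline when the average AAF ≥ 45%, else
ultra-low (MF ≤ 2%), low (2–10%], higher (10–90%], boundaries closed on the
lower category.

The uniform-mixing null asks how many regions a variant at its cortex-wide
average MF would be detected in: per replicate and region, mutant reads ~
Binomial(10,000, MF/2) and error reads ~ Binomial(10,000, error/2); a
region is detected when mutant reads exceed error reads and the mutant-read
fraction clears the 0.1%-MF floor. The printed floor is ambiguous between
the MF and AAF scales; it is interpreted on the MF scale (mutant reads >
0.05% of reads, i.e. >5 of 10,000), with `floor_scale="aaf"` available.
Error reads are drawn independently per region. Observed region counts are
scored with a lower-tail Poisson p (rate = mean simulated count; p = 1 when
both are zero) and Benjamini–Hochberg q-values across the variant family
(one-sided: fewer regions than expected). Outlier fences use
linear-interpolation quartiles and strict Tukey inequalities (mild beyond
1.5×IQR, extreme beyond 3×IQR).

## Single-cell genotyping (`clonetrace.genotyping`)

Each cell × site is a two-component binomial mixture: carrier alt reads at
p_mut (≈0.5; lower under amplification imbalance) versus error reads at the
per-read error rate, both estimated by pooling panel heterozygous SNPs and
off-target reference-homozygous sites. The prior that a cell carries the
variant is the pooled mutant-read fraction mapped to a cell fraction
(2 × pooled AAF) and clamped to (1e-3, 1−1e-3); the posterior is the usual
two-hypothesis Bayes ratio, computed in log space. Zero-depth entries
return the prior. Batches are combined by summing log likelihood ratios
under a shared mosaic-fraction prior; cells where two batches individually
exceed 0.99 posterior on opposite sides are flagged discordant and their
hard call (default threshold 0.9) withheld. A site with MF exactly 0
forces posterior 0. The model closes analytically, so no sampler is used.

## Lineage reconstruction and coalescent TOO (`clonetrace.lineage`)

**Imputation.** Infinite sites means no site pair may show all of the
patterns {10, 01, 11}. Flipping an entry to value v costs
|posterior − v|. For ≤12 sites the minimum-cost compatible matrix is found
exactly by uniform-cost (best-first) search over single-entry flips of the
first conflicting pair — complete because any compatible matrix must change
at least one such entry, optimal because costs are non-negative. Above 12
sites: cells are clustered hierarchically (average linkage, L1 on
posteriors) and each site starts on its min-cost clade; coordinate-descent
sweeps then replace each site's carrier set by the *exact* min-cost set
compatible with the laminar family of the other sites (inside some node of
the family's forest, any union of whole child blocks plus free cells;
optimum takes the parts with negative flip weight). The joint cost never
increases and the family stays laminar. Per-site carrier fractions are
kept within `mf_tolerance` (default 0.25) of the supplied site MFs where
possible.

**Tree building.** On a compatible matrix the perfect phylogeny is built
directly by nested containment of carrier sets: identical sets share an
edge, nesting gives ancestry, ties break by site order, zero-carrier sites
stay unplaced, and the parsimony score equals the number of placed sites.
No heuristic tree search is needed because imputation guarantees
compatibility; on noiseless generator output the result matches the true
genealogy with zero-mutation edges contracted (Robinson–Foulds 0, tested).

**Coalescent model.** The population doubles from one founder to
N = 2^G; sampled cells live at generation G. Mutations arise at a
population rate μ per generation, uniformly over the 2^t cells alive, so a
branch spanning generations (t_p, t_c] carries Poisson(μ·(2^-t_p − 2^-t_c))
observable mutations (the geometric sum over crossed generations). Node
times are *integer* generations; their prior is the exact probability of
the genealogy's merge pattern under synchronous doubling — for each
backward step from t to t−1, a specific pairing with p merges among k
lineages has probability (2^{t-1})_{k-p}·2^{k-p}/(2^t)_k (falling
factorials), which sums to one over pairings. An earlier continuous-time
embedding (pair rate 1/P(t)) was measurably misspecified against the
generational simulator — node times ran ~0.5–1 generation late and μ
intervals missed the generating rate — and was replaced by this discrete
form, under which parameter recovery calibrates (tested).

Sampling: conjugate-gamma Gibbs for μ (weak Gamma(0.5, 0.1) prior),
uniform-bracket Metropolis for each node time, and a mixed
independence/±1 move for G with times held fixed (the conditional of times
given G is nearly G-independent), G uniform on the grid implied by
log10 N ∈ [5, 9.5]. Defaults: 4 chains, 2000 draws after 1000 warmup;
split-R̂ on log N and log μ must stay below 1.01 or the fit raises.
Polytomies are binarized randomly (seeded) with zero-mutation edges before
fitting. A variant's time of origin is reported as the posterior of its
origin *generation* — drawn per posterior sample from the branch's
generations weighted by the per-generation intensity 2^-g — rather than
the branch midpoint; this is the exact within-branch posterior the model
implies and makes credible-interval coverage of the true origin generation
well-defined. Generations convert to post-MRCA weeks by monotone
interpolation of week against log2(population); the default growth table
is exponential from one cell at PMW 0 to 2^26 cells at week 16 (so
generation 13 ↦ week 8). N is only weakly identified from samples of tens
of cells (coalescences finish long before generation G); its posterior is
honestly wide rather than pinned.

**RRS.** For a clade, RRS = mean cross-region patristic distance / mean
within-region patristic distance over the clade's cell pairs, so RRS > 1
means same-region clade-mates are more closely related (regional
restriction). The ratio-of-means form is used because a single pair is
either within- or cross-region, so a mean of per-pair ratios does not
exist; the opposite orientation is available via a flag. CIs bootstrap
cells within the clade (resampled self-pairs excluded). Clades entirely in
one region, or with no within/cross pairs, are reported undefined.

**Dispersion modes.** Variants' per-region cell-fraction profiles are
clustered with standard k-means (k = 5 by default, 10 restarts, seeded);
centroids are member means.

## Cell-type sharing and clone composition (`clonetrace.celltype`)

Cells with zero UMIs at a variant are non-informative throughout. A
variant counts as shared by a cell-type pair when ≥2 distinct cells of each
type (≥2 cells total for self-pairs) carry a mutant UMI; the normalized
count divides by the number of cross-type cell pairs sharing ≥1 mutant
allele. Observed (sample-matched) versus expected (sample-unmatched,
noise-only) normalized counts are compared by a pooled bootstrap: the null
difference distribution resamples both means from the pooled per-variant
contributions (10,000 pairs by default), and the p-value is the upper tail
of the actual difference — pooling is what makes the test calibrated under
exchangeability (tested at α = 0.05).

minMF: with ≥3 shared variants, the minimum of their MFs estimates the MF
of the last variant in the two types' common progenitor; the 90% CI is the
percentile interval of minima over bootstrap resamples of the shared
variant set (variants only; cells are not resampled).

Clones: Louvain communities (resolution 1.0, seeded) on the graph whose
edge weights count variants shared by cell pairs; cells sharing nothing are
singleton clones. Composition: per cell type, a beta-binomial regression
of (X, N−X) on the number of variants in the clone and log10 clone size is
fit by direct maximum likelihood (logit mean link, shared precision σ0 with
a weak lognormal penalty that keeps σ0 finite on exactly-binomial data;
intercept-only fallback on non-convergence — no installed package provides
a beta-binomial GLM). Each clone's posterior proportion is
(α0 + X)/(α0 + β0 + N) with α0 = μ0σ0, β0 = (1−μ0)σ0, i.e. σ0 acts as the
prior weight; only clones with ≥10 cells enter. The size-weighted
aggregate proportion takes its CI from a bootstrap over clones that refits
the regression and draws each clone's proportion from its beta posterior —
plain empirical-Bayes intervals ignore hyperparameter and within-clone
binomial uncertainty and under-cover planted truths (observed during
development; the bootstrap restores coverage).

## Problem sizes and tolerances used in the test suite

Simulation-backed checks run at deliberately reduced scale chosen for tight
feedback: 200–500 tracked cells for genotyping/imputation, 20–50 panel
sites, 40 cells per coalescent fit with 2 chains × 600 draws (R̂ threshold
relaxed to 1.2 at these chain lengths), 20 replicates for
coverage/recovery claims, and 200 replicates for calibration claims with a
3-standard-error Monte-Carlo allowance. Moment checks use 3–4 standard
errors. Exact-imputation oracles enumerate all 2^12 flip sets on 4×3
matrices.

## Known limitations

- The coalescent fit assumes the tree's mutation counts are correct;
  genotyping and imputation errors propagate into μ and the TOOs (visible
  as mild μ attenuation when fitting imputed rather than true matrices).
- N is weakly identified from small cell samples; treat its CI as a bound.
- The greedy imputation is a heuristic: it is exact only per coordinate
  given the other sites, and its initialisation tree can absorb correlated
  errors.
- The sensitivity curve default is a plausible shape, not measured caller
  sensitivity; regional-ratio results on real data require the user's own
  curve.
- Beta-binomial regression covariates are the raw variant count and log10
  size; no interaction or offset structure is modelled.
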