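"""Posterior genotyping of panel sSNVs in amplified single cells.

Whole-genome amplification (MDA) of single cells produces noisy, unbalanced
read counts.  Each cell x site is genotyped with a two-component binomial
model: a carrier cell yields alternate reads at probability ``p_mut``
(ideally 0.5, lower under amplification imbalance), a non-carrier at the
per-read error rate.  Both parameters are estimated from built-in controls
(heterozygous germline SNPs and reference-homozygous off-target sites); the
prior that a cell carries the variant comes from the pooled mutant-read
fraction across all cells (2 x pooled AAF, i.e. the apparent cell
fraction).  Batches sequenced separately are combined into a consensus
matrix by multiplying their likelihood ratios under a shared mosaic-
fraction prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypingParams",
    "GenotypeMatrix",
    "fit_params",
    "posterior_genotype",
    "genotype_batch",
    "consensus_matrix",
]

_PRIOR_CLAMP = 1e-3  # keep site priors away from 0/1


@dataclass(frozen=True)
class GenotypingParams:
    """Carrier read fraction and per-read error rate, with binomial SEs."""

    p_mut: float
    error_rate: float
    p_mut_se: float = 0.0
    error_rate_se: float = 0.0
    n_het_reads: int = 0
    n_refhom_reads: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < self.p_mut <= 1.0:
            raise ValueError(
                f"need 0 < error_rate < p_mut <= 1, got "
                f"error_rate={self.error_rate}, p_mut={self.p_mut}"
            )


def fit_params(
    het_snp_reads: pd.DataFrame, ref_hom_reads: pd.DataFrame
) -> GenotypingParams:
    """Estimate (p_mut, error_rate) from control sites.

    ``het_snp_reads`` / ``ref_hom_reads`` need columns alt_reads and
    total_reads; heterozygous SNPs in carrier cells give the pooled
    alternate fraction, reference-homozygous sites the pooled non-reference
    fraction.
    """
    for name, df in (("het_snp", het_snp_reads), ("ref_hom", ref_hom_reads)):
        if len(df) < 10:
            raise ValueError(f"need >=10 {name} control observations, got {len(df)}")
        if df["total_reads"].sum() == 0:
            raise ValueError(f"{name} controls have zero total depth")
    het_alt = int(het_snp_reads["alt_reads"].sum())
    het_tot = int(het_snp_reads["total_reads"].sum())
    hom_alt = int(ref_hom_reads["alt_reads"].sum())
    hom_tot = int(ref_hom_reads["total_reads"].sum())
    p_mut = het_alt / het_tot
    err = max(hom_alt / hom_tot, 0.5 / hom_tot)  # never exactly zero
    return GenotypingParams(
        p_mut=p_mut,
        error_rate=err,
        p_mut_se=float(np.sqrt(p_mut * (1 - p_mut) / het_tot)),
        error_rate_se=float(np.sqrt(err * (1 - err) / hom_tot)),
        n_het_reads=het_tot,
        n_refhom_reads=hom_tot,
    )


def posterior_genotype(
    alt_reads,
    total_reads,
    params: GenotypingParams,
    site_prior,
) -> np.ndarray:
    """Posterior probability that the cell carries the variant.

    posterior = pi * B(a; d, p_mut) / [pi * B(a; d, p_mut) + (1-pi) * B(a; d, e)]
    with pi the site prior.  Zero-depth observations return the prior
    unchanged (no data).  Vectorised over cells/sites.
    """
    a = np.asarray(alt_reads, dtype=int)
    d = np.asarray(total_reads, dtype=int)
    pi = np.asarray(site_prior, dtype=float)
    if np.any(a > d):
        raise ValueError("alt_reads cannot exceed total_reads")
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValueError("site_prior must lie strictly inside (0, 1)")
    with np.errstate(divide="ignore"):
        log_lr = stats.binom.logpmf(a, d, params.p_mut) - stats.binom.logpmf(
            a, d, params.error_rate
        )
    log_odds = np.log(pi) - np.log1p(-pi) + log_lr
    post = 1.0 / (1.0 + np.exp(-log_odds))
    return np.where(d == 0, pi, post)


def _site_prior_from_reads(reads: pd.DataFrame) -> pd.Series:
    """Prior carrier probability per site: pooled AAF mapped to a cell
    fraction (2 x AAF), clamped away from 0 and 1."""
    pooled = reads.groupby("site").apply(
        lambda g: g["alt_reads"].sum() / max(g["total_reads"].sum(), 1),
        include_groups=False,
    )
    return (2.0 * pooled).clip(_PRIOR_CLAMP, 1.0 - _PRIOR_CLAMP)


@dataclass
class GenotypeMatrix:
    """Cells x sites posterior genotypes with the evidence behind them."""

    posterior: pd.DataFrame  # cells x sites, P(carrier)
    alt_reads: pd.DataFrame
    total_reads: pd.DataFrame
    site_prior: pd.Series
    batch: str = "consensus"
    call_threshold: float = 0.9
    discordant: pd.DataFrame | None = None  # bool mask where call withheld

    @property
    def calls(self) -> pd.DataFrame:
        """Hard calls at the threshold (pandas nullable boolean; discordant
        entries are <NA>)."""
        calls = (self.posterior >= self.call_threshold).astype("boolean")
        if self.discordant is not None:
            calls = calls.mask(self.discordant)
        return calls

    @property
    def cells(self) -> list[str]:
        return list(self.posterior.index)

    @property
    def sites(self) -> list[str]:
        return list(self.posterior.columns)

    def genotyping_rate(self) -> float:
        """Fraction of cell x site entries with any read support."""
        return float((self.total_reads.values > 0).mean())


def genotype_batch(
    reads: pd.DataFrame,
    params: GenotypingParams,
    site_prior: pd.Series | None = None,
    batch: str = "batch",
    call_threshold: float = 0.9,
) -> GenotypeMatrix:
    """Genotype one sequencing batch from a long read table.

    ``reads`` needs columns cell, site, alt_reads, total_reads.  When no
    prior is given it is derived from the pooled mutant-read fraction of
    this batch (2 x pooled AAF, clamped).
    """
    alt = reads.pivot_table(
        index="cell", columns="site", values="alt_reads", aggfunc="sum", fill_value=0
    )
    tot = reads.pivot_table(
        index="cell", columns="site", values="total_reads", aggfunc="sum", fill_value=0
    )
    if site_prior is None:
        site_prior = _site_prior_from_reads(reads)
    site_prior = site_prior.reindex(alt.columns).fillna(_PRIOR_CLAMP)
    post = posterior_genotype(
        alt.values, tot.values, params, site_prior.values[None, :]
    )
    return GenotypeMatrix(
        posterior=pd.DataFrame(post, index=alt.index, columns=alt.columns),
        alt_reads=alt,
        total_reads=tot,
        site_prior=site_prior,
        batch=batch,
        call_threshold=call_threshold,
    )


def consensus_matrix(
    batch_matrices: list[GenotypeMatrix],
    site_mfs: pd.Series | dict,
    params: GenotypingParams | list[GenotypingParams] | None = None,
    batch_params: list[GenotypingParams] | None = None,
    call_threshold: float = 0.9,
    discord_posterior: float = 0.99,
) -> GenotypeMatrix:
    """Cross-batch consensus genotypes under a mosaic-fraction prior.

    The prior that a cell carries the variant is the variant's estimated
    mosaic (cell) fraction; each batch contributes its binomial likelihood
    ratio, multiplied across batches.  Cells where two batches disagree
    with individual posteriors above ``discord_posterior`` on opposite
    sides are flagged discordant and their call withheld.
    """
    if not batch_matrices:
        raise ValueError("need at least one batch")
    if batch_params is None:
        if params is None:
            raise ValueError("supply per-batch params via `params` or `batch_params`")
        batch_params = (
            list(params) if isinstance(params, (list, tuple)) else [params] * len(batch_matrices)
        )
    cells = batch_matrices[0].cells
    sites = batch_matrices[0].sites
    for m in batch_matrices[1:]:
        if m.cells != cells or m.sites != sites:
            raise ValueError("batches must share cell and site identifiers")
    mf = pd.Series(site_mfs, dtype=float).reindex(sites)
    if mf.isna().any():
        raise KeyError(f"missing MF for sites {list(mf.index[mf.isna()])[:5]}")
    pi = mf.clip(_PRIOR_CLAMP, 1.0 - _PRIOR_CLAMP).values[None, :]
    pi = np.broadcast_to(pi, (len(cells), len(sites)))

    log_odds = np.log(pi) - np.log1p(-pi)
    batch_posts = []
    any_reads = np.zeros((len(cells), len(sites)), dtype=bool)
    for m, pr in zip(batch_matrices, batch_params):
        a, d = m.alt_reads.values, m.total_reads.values
        log_lr = stats.binom.logpmf(a, d, pr.p_mut) - stats.binom.logpmf(
            a, d, pr.error_rate
        )
        log_lr = np.where(d > 0, log_lr, 0.0)
        log_odds = log_odds + log_lr
        any_reads |= d > 0
        batch_posts.append(posterior_genotype(a, d, pr, pi))
    post = 1.0 / (1.0 + np.exp(-log_odds))
    post = np.where(any_reads, post, pi)
    # MF exactly 0 forces posterior 0 regardless of reads
    zero_mf = (mf.values <= 0.0)[None, :]
    post = np.where(zero_mf, 0.0, post)

    discordant = np.zeros_like(post, dtype=bool)
    for i in range(len(batch_posts)):
        for j in range(i + 1, len(batch_posts)):
            discordant |= (batch_posts[i] > discord_posterior) & (
                batch_posts[j] < 1 - discord_posterior
            )
            discordant |= (batch_posts[j] > discord_posterior) & (
                batch_posts[i] < 1 - discord_posterior
            )
    alt = sum(m.alt_reads for m in batch_matrices)
    tot = sum(m.total_reads for m in batch_matrices)
    return GenotypeMatrix(
        posterior=pd.DataFrame(post, index=cells, columns=sites),
        alt_reads=alt,
        total_reads=tot,
        site_prior=pd.Series(np.asarray(pi)[0], index=sites),
        batch="consensus",
        call_threshold=call_threshold,
        discordant=pd.DataFrame(discordant, index=cells, columns=sites),
    )
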