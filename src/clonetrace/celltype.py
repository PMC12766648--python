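"""Cell-type variant sharing, minMF, clone clustering and composition.

Single-nucleus RNA data covers pre-specified somatic variants sparsely
(1-4 UMIs per site per cell), but across tens of thousands of nuclei the
sharing of mutant alleles between cell types carries lineage information:

* normalized shared sSNV counts per cell-type pair (shared count divided by
  the number of mutant cell pairs), compared between sample-matched
  ("observed") and sample-unmatched ("expected", pure-noise) variant sets
  by a bootstrap difference test;
* the minimum mosaic fraction (minMF) among variants shared by two cell
  types — a proxy for the MF of the last variant in their common ancestor
  — with a bootstrap confidence interval;
* Louvain clustering of cells on the shared-variant graph into clones; and
* empirical-Bayes (beta-binomial) estimates of each clone's cell-type
  composition that shrink small-clone proportions toward a regression
  prior, with clone-size-weighted aggregates.

Cells with zero UMIs at a variant are non-informative throughout (never
counted as non-carriers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement
from warnings import warn

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "SharedVariantStat",
    "MinMFEstimate",
    "CloneComposition",
    "shared_variant_counts",
    "shared_count_test",
    "minmf_bootstrap",
    "louvain_clones",
    "clone_table",
    "eb_composition",
]


@dataclass
class SharedVariantStat:
    type_a: str
    type_b: str
    shared_count: int
    n_mutant_cell_pairs: int
    normalized: float
    contributions: np.ndarray  # per qualifying sSNV: 1/denominator
    source: str = "observed"


def _mutant_cells(tally: pd.DataFrame) -> pd.DataFrame:
    m = tally[tally["mut_umis"] > 0]
    return m[["cell", "variant", "cell_type"]]


def shared_variant_counts(
    tally: pd.DataFrame,
    min_cells_per_type: int = 2,
    source: str = "observed",
) -> list[SharedVariantStat]:
    """Normalized shared-sSNV counts for every unordered cell-type pair.

    A variant counts for pair (A, B) when at least ``min_cells_per_type``
    distinct cells of each type carry the mutant allele (for self-pairs: at
    least that many distinct cells of the type).  The denominator is the
    number of cross-type cell pairs sharing at least one mutant allele.
    """
    if tally.empty:
        return []
    mut = _mutant_cells(tally)
    types = sorted(tally["cell_type"].dropna().unique())
    # per variant: mutant cells per type
    by_var: dict[str, dict[str, set[str]]] = {}
    for (variant, ctype), grp in mut.groupby(["variant", "cell_type"]):
        by_var.setdefault(variant, {})[ctype] = set(grp["cell"])
    out = []
    for a, b in combinations_with_replacement(types, 2):
        qualifying = []
        pair_cells: set[tuple[str, str]] = set()
        for variant, per_type in by_var.items():
            ca = per_type.get(a, set())
            cb = per_type.get(b, set())
            if a == b:
                ok = len(ca) >= min_cells_per_type
                pairs = set(combinations(sorted(ca), 2))
            else:
                ok = len(ca) >= min_cells_per_type and len(cb) >= min_cells_per_type
                pairs = {(x, y) for x in ca for y in cb if x != y}
            pair_cells |= pairs
            if ok:
                qualifying.append(variant)
        denom = len(pair_cells)
        count = len(qualifying)
        if count > 0:
            assert denom > 0, "qualifying sSNV implies at least one mutant cell pair"
        norm = count / denom if denom else 0.0
        out.append(
            SharedVariantStat(
                type_a=a,
                type_b=b,
                shared_count=count,
                n_mutant_cell_pairs=denom,
                normalized=norm,
                contributions=(
                    np.full(count, 1.0 / denom) if denom else np.zeros(0)
                ),
                source=source,
            )
        )
    return out


def shared_count_test(
    observed: SharedVariantStat,
    expected: SharedVariantStat,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> float:
    """Upper-tail bootstrap p for observed > expected normalized sharing.

    Per-sSNV normalized contributions from the two sources are pooled;
    ``n_boot`` pairs of bootstrap samples from the pool give a null
    distribution of mean differences, and the p-value is the upper-tail
    probability of the actual difference in means.
    """
    if n_boot < 1000:
        warn(f"n_boot={n_boot} is small; p-value resolution will be coarse")
    rng = np.random.default_rng(seed)
    x = np.asarray(observed.contributions, dtype=float)
    y = np.asarray(expected.contributions, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both sources need at least one qualifying sSNV")
    diff = x.mean() - y.mean()
    pool = np.concatenate([x, y])
    bx = rng.choice(pool, size=(n_boot, x.size), replace=True).mean(axis=1)
    by = rng.choice(pool, size=(n_boot, y.size), replace=True).mean(axis=1)
    null = bx - by
    return float((1 + np.sum(null >= diff)) / (n_boot + 1))


@dataclass
class MinMFEstimate:
    type_a: str
    type_b: str
    minmf: float  # percent
    ci: tuple[float, float]  # 90% bootstrap CI
    n_shared: int


def minmf_bootstrap(
    shared_mfs,
    n_boot: int = 10_000,
    seed: int | None = None,
    ci_level: float = 0.90,
    type_a: str = "",
    type_b: str = "",
) -> MinMFEstimate:
    """Minimum MF among shared variants, with a bootstrap CI.

    Requires at least three shared sSNVs.  The bootstrap resamples the
    shared variants with replacement and takes the minimum each time.
    """
    mfs = np.asarray(shared_mfs, dtype=float)
    if mfs.size < 3:
        raise ValueError(
            f"need at least 3 shared sSNVs to estimate a minMF, got {mfs.size}"
        )
    rng = np.random.default_rng(seed)
    mins = rng.choice(mfs, size=(n_boot, mfs.size), replace=True).min(axis=1)
    q = (1.0 - ci_level) / 2.0
    return MinMFEstimate(
        type_a=type_a,
        type_b=type_b,
        minmf=float(mfs.min()),
        ci=(float(np.quantile(mins, q)), float(np.quantile(mins, 1 - q))),
        n_shared=int(mfs.size),
    )


def louvain_clones(
    tally: pd.DataFrame, resolution: float = 1.0, seed: int = 0
) -> pd.Series:
    """Louvain communities on the shared-variant cell graph.

    Nodes are cells with at least one mutant UMI; edge weight between two
    cells is the number of variants both carry.  Cells sharing nothing form
    singleton clones.
    """
    mut = _mutant_cells(tally)
    if mut.empty:
        raise ValueError("no cell carries a mutant UMI")
    g = nx.Graph()
    g.add_nodes_from(mut["cell"].unique())
    for _, grp in mut.groupby("variant"):
        for u, v in combinations(sorted(grp["cell"].unique()), 2):
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    assign = {}
    for cid, comm in enumerate(sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))):
        for cell in comm:
            assign[cell] = cid
    return pd.Series(assign, name="clone").sort_index()


def clone_table(
    tally: pd.DataFrame, clones: pd.Series, celltype_groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-clone size, per-group cell counts and variant count covariate."""
    mut = _mutant_cells(tally)
    cell_type = tally.drop_duplicates("cell").set_index("cell")["cell_type"]
    rows = []
    for clone, cells in clones.groupby(clones):
        members = list(cells.index)
        n = len(members)
        nvar = mut[mut["cell"].isin(members)]["variant"].nunique()
        row = {"clone": clone, "N": n, "n_variants": int(nvar)}
        for gname, members_types in celltype_groups.items():
            row[gname] = int(cell_type.reindex(members).isin(members_types).sum())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CloneComposition:
    clone: object
    cell_type: str
    N: int
    X: int
    mu0: float
    sigma0: float
    posterior: float
    ci: tuple[float, float]


def _betabinom_regression(
    X: np.ndarray, N: np.ndarray, covars: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """MLE of a beta-binomial regression: logit(mu) = covars @ beta, shared
    precision s (prior weight alpha0+beta0).  A weak lognormal penalty on s
    keeps the precision finite when the data are exactly binomial; falls
    back to intercept-only when the full model fails to converge."""

    def nll(theta, C):
        beta, log_s = theta[:-1], theta[-1]
        s = math.exp(min(log_s, 25.0))
        mu = special.expit(C @ beta)
        a = np.clip(mu * s, 1e-6, 1e8)
        b = np.clip((1 - mu) * s, 1e-6, 1e8)
        penalty = (log_s - math.log(10.0)) ** 2 / (2.0 * 3.0**2)
        return -float(stats.betabinom.logpmf(X, N, a, b).sum()) + penalty

    def fit(C):
        p0 = np.zeros(C.shape[1] + 1)
        frac = (X.sum() + 0.5) / (N.sum() + 1.0)
        p0[0] = special.logit(frac)
        p0[-1] = math.log(10.0)
        return optimize.minimize(nll, p0, args=(C,), method="L-BFGS-B")

    res = fit(covars)
    if res.success and np.isfinite(res.fun):
        return res.x[:-1], math.exp(min(res.x[-1], 25.0)), True
    warn("beta-binomial regression did not converge; using intercept-only prior")
    res = fit(covars[:, :1])
    beta = np.zeros(covars.shape[1])
    beta[0] = res.x[0]
    return beta, math.exp(min(res.x[-1], 25.0)), False


def eb_composition(
    clone_counts: pd.DataFrame,
    cell_types: list[str] | None = None,
    min_clone_size: int = 10,
    ci_level: float = 0.95,
    n_boot: int = 200,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Empirical-Bayes clone composition per cell type.

    ``clone_counts`` (from :func:`clone_table`) has one row per clone with
    columns clone, N, n_variants and one count column per cell type.  Per
    type, a beta-binomial regression of (X, N-X) on the number of variants
    in the clone and log10 clone size yields a prior mean mu0 per clone and
    a shared precision sigma0 (prior weight alpha0 + beta0); the posterior
    proportion is (alpha0 + X) / (alpha0 + beta0 + N) with a beta posterior
    CI.  Only clones with N >= min_clone_size are analysed.  Returns the
    per-clone table and clone-size-weighted aggregate proportions whose CI
    comes from ``n_boot`` bootstrap resamples of the clones (refitting the
    regression and drawing each clone's proportion from its beta
    posterior, so hyperparameter and within-clone binomial uncertainty
    both enter the interval).
    """
    df = clone_counts[clone_counts["N"] >= min_clone_size].reset_index(drop=True)
    if len(df) < 5:
        raise ValueError(
            f"need >=5 clones of size >= {min_clone_size} for the regression, got {len(df)}"
        )
    if cell_types is None:
        cell_types = [
            c for c in df.columns if c not in ("clone", "N", "n_variants")
        ]
    rng = np.random.default_rng(seed)
    N = df["N"].values.astype(int)
    covars = np.column_stack(
        [np.ones(len(df)), df["n_variants"].values, np.log10(N)]
    )
    q = (1.0 - ci_level) / 2.0
    rows = []
    aggregates: dict[str, dict] = {}
    for ctype in cell_types:
        X = df[ctype].values.astype(int)
        beta, s, converged = _betabinom_regression(X, N, covars)
        mu0 = special.expit(covars @ beta)
        a0 = mu0 * s
        b0 = (1 - mu0) * s
        post = (a0 + X) / (s + N)
        lo = stats.beta.ppf(q, a0 + X, b0 + N - X)
        hi = stats.beta.ppf(1 - q, a0 + X, b0 + N - X)
        for i in range(len(df)):
            rows.append(
                CloneComposition(
                    clone=df["clone"].iloc[i],
                    cell_type=ctype,
                    N=int(N[i]),
                    X=int(X[i]),
                    mu0=float(mu0[i]),
                    sigma0=float(s),
                    posterior=float(post[i]),
                    ci=(float(lo[i]), float(hi[i])),
                )
            )
        # aggregate CI: bootstrap over clones, refitting the regression on
        # each resample and recomputing the size-weighted posterior mean
        w = N / N.sum()
        agg = []
        for _ in range(n_boot):
            idx = rng.integers(len(df), size=len(df))
            Xb, Nb, Cb = X[idx], N[idx], covars[idx]
            if Xb.sum() == 0 or (Nb - Xb).sum() == 0:
                continue
            bb, sb, _conv = _betabinom_regression(Xb, Nb, Cb)
            mub = special.expit(Cb @ bb)
            # draw each clone's proportion from its beta posterior so the
            # aggregate interval carries within-clone binomial uncertainty
            postb = rng.beta(
                np.clip(mub * sb, 1e-6, None) + Xb,
                np.clip((1 - mub) * sb, 1e-6, None) + (Nb - Xb),
            )
            wb = Nb / Nb.sum()
            agg.append(float(np.sum(wb * postb)))
        agg = np.asarray(agg)
        aggregates[ctype] = {
            "proportion": float(np.sum(w * post)),
            "ci": (float(np.quantile(agg, q)), float(np.quantile(agg, 1 - q))),
            "converged": converged,
        }
    table = pd.DataFrame([r.__dict__ for r in rows])
    return table, aggregates
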