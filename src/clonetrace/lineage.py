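"""Lineage reconstruction and coalescent times of origin.

From consensus single-cell genotypes: enforce an infinite-sites (perfect
phylogeny) structure by minimum-cost imputation, build the lineage tree by
nested containment of carrier sets, fit a coalescent model to convert
per-branch mutation counts into posterior times of origin (TOO) in
generations and post-MRCA weeks (PMW), quantify regional restriction of
clades (RRS), and cluster variants' regional mosaic-fraction profiles into
spatial dispersion modes.

The coalescent model
--------------------
The population grows by synchronous binary doubling from one founder to
N = 2^G cells, so P(t) = 2^t at generation t and sampled cells live at
generation G.  Mutations arise at a population-level rate of mu per
generation, placed uniformly among the P(t) cells alive; a mutation is
seen on the sample tree when it lands on a lineage ancestral to the
sample, so the mutation count on a branch spanning generations
(t_parent, t_child] is Poisson(mu * (2^-t_parent - 2^-t_child)) — the
geometric sum over the generations the branch crosses.  Internal-node
times are integer generations whose prior is the exact probability of the
genealogy's merge pattern under synchronous doubling (lineages at
generation t occupy distinct cells among 2^t; two lineages merge when they
share a parent).  The posterior over (G, mu, node times) is sampled by
Markov chain Monte Carlo: conjugate-gamma Gibbs updates for mu,
uniform-bracket Metropolis updates for node times, and mixed
independence/local moves for G.  A variant's time of origin is the
posterior distribution of its origin generation on its branch (weighted by
the per-generation intensity), converted to post-MRCA weeks through the
growth table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genotyping import GenotypeMatrix
from .trees import LineageTree

__all__ = [
    "ImputedMatrix",
    "MCMCSettings",
    "CoalescentFit",
    "RRSResult",
    "DispersionClusters",
    "is_compatible",
    "impute_perfect_phylogeny",
    "build_tree",
    "default_growth_table",
    "generations_to_pmw",
    "fit_coalescent_too",
    "compute_rrs",
    "kmeans_dispersion",
]

LN2 = math.log(2.0)


# ==========================================================================
# Perfect-phylogeny compatibility and imputation
# ==========================================================================
def _conflicting_pair(M: np.ndarray) -> tuple[int, int] | None:
    """First site pair showing all of {10, 01, 11} (rooted three-pattern)."""
    n_sites = M.shape[1]
    for i in range(n_sites):
        ci = M[:, i].astype(bool)
        for j in range(i + 1, n_sites):
            cj = M[:, j].astype(bool)
            if (ci & cj).any() and (ci & ~cj).any() and (~ci & cj).any():
                return i, j
    return None


def is_compatible(matrix) -> bool:
    """True when every site pair nests or is disjoint (four-gamete test,
    rooted at the all-zero ancestral state)."""
    M = np.asarray(matrix, dtype=int)
    return _conflicting_pair(M) is None


def _flip_cost(posterior: np.ndarray, M: np.ndarray) -> float:
    """Total posterior-weighted cost of the entries where M deviates from
    the hard call: cost of an entry set to v is |posterior - v|."""
    call = (posterior >= 0.5).astype(int)
    dev = M != call
    return float(np.abs(posterior - M)[dev].sum())


def _mf_ok(M: np.ndarray, site_mf: np.ndarray | None, tol: float) -> bool:
    if site_mf is None:
        return True
    frac = M.mean(axis=0)
    return bool(np.all(np.abs(frac - site_mf) <= tol))


def _exact_impute(
    posterior: np.ndarray, site_mf: np.ndarray | None, tol: float
) -> np.ndarray | None:
    """Exact minimum-cost imputation by best-first (uniform-cost) search.

    States are candidate matrices; the first compatible state popped is
    optimal because costs are non-negative and any compatible matrix must
    change at least one of the expanded entries of the first conflicting
    pair (so the expansion is complete).
    """
    import heapq

    call = (posterior >= 0.5).astype(int)
    start = call.copy()
    counter = itertools.count()
    frontier = [(0.0, next(counter), start)]
    seen = {start.tobytes()}

    def push(M2: np.ndarray) -> None:
        key = M2.tobytes()
        if key not in seen:
            seen.add(key)
            heapq.heappush(frontier, (_flip_cost(posterior, M2), next(counter), M2))

    while frontier:
        cost, _, M = heapq.heappop(frontier)
        pair = _conflicting_pair(M)
        if pair is None:
            if _mf_ok(M, site_mf, tol):
                return M
            # compatible but a site fraction is off its MF: nudge the
            # offending sites entry by entry
            frac = M.mean(axis=0)
            for s in np.flatnonzero(np.abs(frac - site_mf) > tol):
                for cell in range(M.shape[0]):
                    M2 = M.copy()
                    M2[cell, s] = 1 - M2[cell, s]
                    push(M2)
            continue
        i, j = pair
        ci, cj = M[:, i].astype(bool), M[:, j].astype(bool)
        cells = np.flatnonzero((ci & cj) | (ci & ~cj) | (~ci & cj))
        for cell in cells:
            for site in (i, j):
                M2 = M.copy()
                M2[cell, site] = 1 - M2[cell, site]
                push(M2)
    return None


def _linkage_projection(posterior: np.ndarray) -> list[frozenset[int]]:
    """Initial carrier sets: cluster cells hierarchically on their posterior
    profiles (average linkage, L1) and give every site its min-cost clade
    (or the empty set).  All sets are clades of one tree, so the result is
    compatible."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import pdist

    n, m = posterior.shape
    Z = linkage(pdist(posterior, metric="cityblock"), method="average")
    members: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    for a, b in Z[:, :2].astype(int):
        members.append(members[a] | members[b])
    chosen = []
    for j in range(m):
        w = 1.0 - 2.0 * posterior[:, j]
        wsum = [float(w[i]) for i in range(n)]
        for a, b in Z[:, :2].astype(int):
            wsum.append(wsum[a] + wsum[b])
        k = int(np.argmin(wsum))
        chosen.append(members[k] if wsum[k] < 0 else frozenset())
    return chosen


def _optimal_compatible_set(
    w: np.ndarray,
    others: list[frozenset[int]],
    n: int,
    mf_j: float | None,
    tol: float,
) -> frozenset[int]:
    """Exact min-cost carrier set compatible with a laminar family.

    A set compatible with every member of a laminar family must be, inside
    some node of the family's forest, a union of whole child blocks plus
    free cells; the optimum per anchor node takes the blocks/cells with
    negative flip weight w = 1 - 2*posterior.  The cheapest candidate whose
    carrier fraction lies within ``tol`` of the site's mosaic fraction is
    preferred when one exists.
    """
    universe = frozenset(range(n))
    uniq = sorted({s for s in others if s}, key=lambda s: (-len(s), sorted(s)))
    nodes = [universe] + [s for s in uniq if s != universe]
    children: list[list[int]] = [[] for _ in nodes]
    for i in range(1, len(nodes)):
        containers = [
            k for k in range(len(nodes)) if k != i and nodes[i] < nodes[k]
        ]
        children[min(containers, key=lambda k: len(nodes[k]))].append(i)
    wsum = [float(sum(w[c] for c in s)) for s in nodes]
    candidates: list[tuple[float, frozenset[int]]] = [(0.0, frozenset())]
    for i, s in enumerate(nodes):
        covered: set[int] = set()
        cost = 0.0
        out: set[int] = set()
        for ch in children[i]:
            covered |= nodes[ch]
            if wsum[ch] < 0:
                cost += wsum[ch]
                out |= nodes[ch]
        for c in s - covered:
            if w[c] < 0:
                cost += float(w[c])
                out.add(c)
        candidates.append((cost, frozenset(out)))
    candidates.sort(key=lambda t: (t[0], len(t[1])))
    if mf_j is not None:
        for cost, s in candidates:
            if abs(len(s) / n - mf_j) <= tol:
                return s
    return candidates[0][1]


def _greedy_impute(
    posterior: np.ndarray, site_mf: np.ndarray | None, tol: float, sweeps: int = 6
) -> np.ndarray | None:
    """Heuristic for matrices too large for exact search.

    Initialise every site on a clade of a hierarchical clustering of the
    cells, then run coordinate descent: sweep over sites (most confident
    first), replacing each carrier set by the exact min-cost set compatible
    with all the others (:func:`_optimal_compatible_set`), until no set
    changes.  The joint flip cost never increases and the family stays
    laminar throughout.
    """
    n, m = posterior.shape
    if n < 3:
        M = (posterior >= 0.5).astype(int)
        return M if is_compatible(M) else None
    w_all = 1.0 - 2.0 * posterior
    chosen = _linkage_projection(posterior)
    order = np.argsort(-np.abs(w_all).sum(axis=0), kind="stable")
    for _ in range(sweeps):
        changed = False
        for j in order:
            others = [chosen[k] for k in range(m) if k != j]
            s = _optimal_compatible_set(
                w_all[:, j],
                others,
                n,
                None if site_mf is None else float(site_mf[j]),
                tol,
            )
            if s != chosen[j]:
                chosen[j] = s
                changed = True
        if not changed:
            break
    M = np.zeros((n, m), dtype=int)
    for j in range(m):
        M[sorted(chosen[j]), j] = 1
    return M


@dataclass
class ImputedMatrix:
    """Perfect-phylogeny-compatible binary genotypes with change tracking."""

    genotypes: pd.DataFrame  # cells x sites, 0/1
    changed: pd.DataFrame  # True where the hard call was overridden
    cost: float
    site_mf: pd.Series | None = None
    exact: bool = True

    @property
    def n_changed(self) -> int:
        return int(self.changed.values.sum())


def impute_perfect_phylogeny(
    matrix: GenotypeMatrix | pd.DataFrame,
    site_mf: pd.Series | dict | None = None,
    mf_tolerance: float = 0.25,
    max_exact_sites: int = 12,
) -> ImputedMatrix:
    """Minimum-cost imputation of an infinite-sites-compatible matrix.

    Starts from hard calls on the posteriors; flipping an entry to value v
    costs |posterior - v|.  Site pairs exhibiting all of {01, 10, 11} are
    resolved by flipping entries, minimising total cost exactly (branch and
    bound) for up to ``max_exact_sites`` sites and greedily per conflicting
    pair above that.  Per-site carrier fractions are kept within
    ``mf_tolerance`` of the site's mosaic fraction when one is supplied.
    """
    if isinstance(matrix, GenotypeMatrix):
        post = matrix.posterior
    else:
        post = matrix
    posterior = post.values.astype(float)
    mf_arr = None
    mf_series = None
    if site_mf is not None:
        mf_series = pd.Series(site_mf, dtype=float).reindex(post.columns)
        mf_arr = mf_series.values
    n_sites = posterior.shape[1]
    exact = n_sites <= max_exact_sites
    M = (
        _exact_impute(posterior, mf_arr, mf_tolerance)
        if exact
        else _greedy_impute(posterior, mf_arr, mf_tolerance)
    )
    if M is None:
        raise ValueError(
            "no compatible genotype matrix within the mosaic-fraction tolerance"
        )
    call = (posterior >= 0.5).astype(int)
    return ImputedMatrix(
        genotypes=pd.DataFrame(M, index=post.index, columns=post.columns),
        changed=pd.DataFrame(M != call, index=post.index, columns=post.columns),
        cost=_flip_cost(posterior, M),
        site_mf=mf_series,
        exact=exact,
    )


# ==========================================================================
# Tree building (perfect phylogeny construction)
# ==========================================================================
def build_tree(imputed: ImputedMatrix | pd.DataFrame) -> LineageTree:
    """Build the (unique) perfect phylogeny by nested containment.

    Each site's carrier set is a clade; identical carrier sets share an
    edge, nested sets nest as ancestor/descendant, and the parsimony score
    equals the number of placed sites (every site mutates exactly once).
    Sites with no carriers are left unplaced.  Ties in nesting are broken
    by site order.
    """
    if isinstance(imputed, ImputedMatrix):
        G = imputed.genotypes
    else:
        G = imputed
    M = G.values.astype(int)
    if not is_compatible(M):
        raise ValueError("matrix is not perfect-phylogeny compatible; impute first")
    n_cells, _ = M.shape
    cell_ids = [str(c) for c in G.index]
    site_ids = [str(s) for s in G.columns]

    # group sites by identical carrier set, order by decreasing size
    clades: dict[frozenset[int], list[str]] = {}
    for j, site in enumerate(site_ids):
        carr = frozenset(np.flatnonzero(M[:, j]))
        if not carr:
            continue
        clades.setdefault(carr, []).append(site)
    order = sorted(clades, key=lambda c: (-len(c), clades[c][0]))

    parent = list(range(n_cells))  # placeholder; root appended below
    root = n_cells + len(order)
    parent = [-2] * (n_cells + len(order)) + [-1]
    variants: list[list[str]] = [[] for _ in range(n_cells + len(order) + 1)]
    clade_nodes: list[tuple[frozenset[int], int]] = []
    for k, carr in enumerate(order):
        node = n_cells + k
        variants[node] = list(clades[carr])
        # parent = smallest strictly-containing clade already placed
        par = root
        for c2, n2 in clade_nodes:
            if carr < c2:
                par = n2  # clade_nodes is in decreasing size order; keep last
        parent[node] = par
        clade_nodes.append((carr, node))
    for i in range(n_cells):
        par = root
        for c2, n2 in clade_nodes:
            if i in c2:
                par = n2
        parent[i] = par
    return LineageTree(parent=np.asarray(parent), leaf_ids=cell_ids, edge_variants=variants)


# ==========================================================================
# Generation -> post-MRCA week conversion
# ==========================================================================
def default_growth_table(
    span_weeks: float = 16.0, final_size: float = 2**26
) -> pd.DataFrame:
    """Exponential growth from one cell at PMW 0 to the final size at the
    end of the span (log2-linear between the two anchors)."""
    return pd.DataFrame({"week": [0.0, span_weeks], "population": [1.0, final_size]})


def generations_to_pmw(g, growth_table: pd.DataFrame | None = None):
    """Post-MRCA week at which cumulative doublings reach ``g``.

    Interpolates week against log2(population) monotonically; values beyond
    the table are clamped with a warning.
    """
    table = default_growth_table() if growth_table is None else growth_table
    weeks = np.asarray(table["week"], dtype=float)
    log2pop = np.log2(np.asarray(table["population"], dtype=float))
    if np.any(np.diff(weeks) <= 0) or np.any(np.diff(log2pop) <= 0):
        raise ValueError("growth table must be strictly increasing in both columns")
    g_arr = np.asarray(g, dtype=float)
    if np.any(g_arr > log2pop[-1] + 1e-9) or np.any(g_arr < log2pop[0] - 1e-9):
        warn("generation outside the growth table range; clamping")
    out = np.interp(g_arr, log2pop, weeks)
    return float(out) if np.isscalar(g) else out


# ==========================================================================
# Coalescent MCMC
# ==========================================================================
@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 4
    draws: int = 2000
    warmup: int = 1000
    log10_n_range: tuple[float, float] = (5.0, 9.5)
    rhat_threshold: float = 1.01
    check_convergence: bool = True
    thin: int = 1


@dataclass
class CoalescentFit:
    """Posterior summaries of the coalescent fit."""

    params: pd.DataFrame  # per-draw: chain, draw, N, mu, G
    too: pd.DataFrame  # per-variant TOO summaries (generations and PMW)
    node_times: pd.DataFrame  # per-node posterior summaries
    rhat: dict[str, float]
    growth_table: pd.DataFrame
    settings: MCMCSettings

    def summary(self) -> pd.Series:
        q = self.params[["N", "mu"]].quantile([0.05, 0.5, 0.95])
        return pd.Series(
            {
                "N_median": q.loc[0.5, "N"],
                "N_ci90": (q.loc[0.05, "N"], q.loc[0.95, "N"]),
                "mu_median": q.loc[0.5, "mu"],
                "mu_ci90": (q.loc[0.05, "mu"], q.loc[0.95, "mu"]),
            }
        )


def _falling_log_table(g_max: int, n: int) -> np.ndarray:
    """L[t, j] = sum_{i<j} log(2^t - i), with -inf where 2^t < j."""
    L = np.full((g_max + 1, n + 1), -np.inf)
    i = np.arange(n)
    for t in range(g_max + 1):
        terms = np.exp2(t) - i
        ok = terms > 0
        c = np.concatenate(([0.0], np.cumsum(np.log(np.maximum(terms, 1e-300)))))
        L[t, : int(ok.sum()) + 1] = c[: int(ok.sum()) + 1]
    return L


def _wf_log_prior(tau: np.ndarray, G: int, n_leaves: int, L: np.ndarray) -> float:
    """Exact log probability of the genealogy's merge times under synchronous
    binary doubling (population 2^t at generation t, one founder at 0).

    For each backward step from generation t to t-1: k_t lineages occupy
    distinct cells among 2^t; a specific pairing with p_t merges has
    probability (2^(t-1))_(k_t - p_t) * 2^(k_t - p_t) / (2^t)_(k_t), with
    (x)_j the falling factorial.  These step probabilities multiply over t.
    """
    counts = np.bincount(tau, minlength=G)[:G]  # merges at time g, g=0..G-1
    suffix = np.concatenate((np.cumsum(counts[::-1])[::-1], [0]))  # tau >= g
    ts = np.arange(1, G + 1)
    k = n_leaves - suffix[ts]
    p = counts[ts - 1]
    rem = k - p  # parent slots used = surviving lineages
    if np.any(rem > np.exp2(ts - 1)):
        return -math.inf
    logq = L[ts - 1, rem] + rem * LN2 - L[ts, k]
    return float(logq.sum())


def _branch_intensity(t: np.ndarray, parent: np.ndarray) -> np.ndarray:
    """Per-branch mutation intensity / mu: geometric sum over generations
    the branch crosses, 2^-t_parent - 2^-t_child (0 for the root)."""
    root_mask = parent < 0
    tp = np.where(root_mask, t, t[np.where(root_mask, 0, parent)])
    return np.where(root_mask, 0.0, np.exp2(-tp) - np.exp2(-t))


def _log_posterior(
    t: np.ndarray,
    G: int,
    mu: float,
    parent: np.ndarray,
    mcount: np.ndarray,
    n_leaves: int,
    L: np.ndarray,
) -> float:
    delta = _branch_intensity(t, parent)
    has_par = parent >= 0
    loglik = float(
        np.sum(
            mcount[has_par] * np.log(np.maximum(mu * delta[has_par], 1e-300))
            - mu * delta[has_par]
        )
    )
    return loglik + _wf_log_prior(t[n_leaves:].astype(int), G, n_leaves, L)


def _sample_origin_generation(
    lo: np.ndarray, hi: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Sample the origin generation on a branch covering [lo, hi] (integers),
    weighted by the per-generation intensity 2^-g (truncated geometric)."""
    m = hi - lo + 1
    j = np.floor(-np.log2(1.0 - u * (1.0 - np.exp2(-m.astype(float)))))
    return lo + np.clip(j.astype(int), 0, m - 1)


def fit_coalescent_too(
    tree: LineageTree,
    growth_table: pd.DataFrame | None = None,
    mcmc: MCMCSettings | None = None,
    seed: int | None = None,
    mu_prior: tuple[float, float] = (0.5, 0.1),
    ci_level: float = 0.90,
) -> CoalescentFit:
    """Posterior over (N, mu, node times) and per-variant times of origin.

    See the module docstring for the model.  Node times are integer
    generations; the founder population doubles every generation to
    N = 2^G.  ``mu_prior`` is the (shape, rate) of the conjugate gamma
    prior on the population-level mutation rate.  A variant's TOO is the
    posterior distribution of its origin generation (position on its
    branch weighted by the per-generation intensity), reported with
    credible intervals in generations and post-MRCA weeks.  Raises on
    non-mixing chains (split R-hat above the configured threshold) unless
    convergence checking is disabled.
    """
    mcmc = mcmc or MCMCSettings()
    rng = np.random.default_rng(seed)
    btree = tree.binarized(rng)
    parent = btree.parent
    mcount = np.asarray(btree.edge_mutation_count, dtype=float)
    n_nodes, n_leaves = btree.n_nodes, btree.n_leaves
    internal = np.arange(n_leaves, n_nodes)
    children = btree.children()
    a0, b0 = mu_prior
    total_m = float(mcount[parent >= 0].sum())

    # depth (edges from root) bounds the minimal G
    depth = np.zeros(n_nodes, dtype=int)
    for v in btree.postorder()[::-1]:
        p = parent[v]
        depth[v] = 0 if p < 0 else depth[p] + 1
    g_lo = max(int(math.ceil(mcmc.log10_n_range[0] * math.log2(10.0))), int(depth.max()))
    g_hi = int(math.floor(mcmc.log10_n_range[1] * math.log2(10.0)))
    if g_lo > g_hi:
        raise ValueError(
            f"tree depth {int(depth.max())} exceeds the maximum generations "
            f"{g_hi} allowed by log10_n_range; widen the prior range"
        )
    L = _falling_log_table(g_hi, n_leaves)

    n_keep = mcmc.draws // mcmc.thin
    all_params = []
    node_time_draws = []
    var_edges = btree.variant_edges()

    for chain in range(mcmc.chains):
        crng = np.random.default_rng(rng.integers(2**31))
        G = int(crng.integers(g_lo, g_hi + 1))
        t = np.where(np.arange(n_nodes) < n_leaves, G, depth)
        # push internal times down so parents stay strictly above children
        for v in sorted(internal, key=lambda x: -depth[x]):
            hib = min(t[c] for c in children[v]) - 1
            t[v] = min(max(t[v], 0), hib)
        mu = max(total_m / max(G, 1), 0.5)
        lp = _log_posterior(t, G, mu, parent, mcount, n_leaves, L)
        keep_params = np.zeros((n_keep, 2))
        keep_times = np.zeros((n_keep, internal.size), dtype=int)
        kept = 0
        for it in range(mcmc.warmup + mcmc.draws):
            # -- Gibbs: mu | times (Poisson likelihood, conjugate gamma)
            delta_tot = float(_branch_intensity(t, parent).sum())
            mu = float(crng.gamma(a0 + total_m, 1.0 / (b0 + delta_tot)))
            lp = _log_posterior(t, G, mu, parent, mcount, n_leaves, L)
            # -- node times: uniform integer proposal inside the bracket
            for v in crng.permutation(internal):
                lob = t[parent[v]] + 1 if parent[v] >= 0 else 0
                hib = min(t[c] for c in children[v]) - 1
                if hib < lob:
                    continue
                prop_t = int(crng.integers(lob, hib + 1))
                if prop_t == t[v]:
                    continue
                old = t[v]
                t[v] = prop_t
                lp_new = _log_posterior(t, G, mu, parent, mcount, n_leaves, L)
                if math.log(crng.random() + 1e-300) < lp_new - lp:
                    lp = lp_new
                else:
                    t[v] = old
            # -- G: independence + local mixture (times fixed)
            G_new = (
                int(crng.integers(g_lo, g_hi + 1))
                if crng.random() < 0.5
                else G + int(crng.choice([-1, 1]))
            )
            t_max = int(t[internal].max()) if internal.size else 0
            if g_lo <= G_new <= g_hi and G_new > t_max:
                prop = t.copy()
                prop[:n_leaves] = G_new
                lp_new = _log_posterior(prop, G_new, mu, parent, mcount, n_leaves, L)
                if math.log(crng.random() + 1e-300) < lp_new - lp:
                    t, G, lp = prop, G_new, lp_new
            if it >= mcmc.warmup and (it - mcmc.warmup) % mcmc.thin == 0 and kept < n_keep:
                keep_params[kept] = (G, mu)
                keep_times[kept] = t[internal]
                kept += 1
        df = pd.DataFrame(keep_params[:kept], columns=["G", "mu"])
        df["chain"] = chain
        df["draw"] = np.arange(kept)
        df["N"] = np.exp2(df["G"])
        all_params.append(df)
        node_time_draws.append(keep_times[:kept])

    params = pd.concat(all_params, ignore_index=True)
    times = np.concatenate(node_time_draws, axis=0)  # (draws_total, n_internal)

    # convergence: split R-hat on log N and log mu
    import arviz as az

    def _stacked(col):
        return np.stack(
            [params.loc[params["chain"] == c, col].values for c in range(mcmc.chains)]
        )

    rhat = {
        "log_N": float(az.rhat(np.log(_stacked("N")))),
        "log_mu": float(az.rhat(np.log(np.maximum(_stacked("mu"), 1e-12)))),
    }
    if mcmc.check_convergence:
        bad = {k: v for k, v in rhat.items() if v > mcmc.rhat_threshold}
        if bad:
            raise RuntimeError(
                f"MCMC chains did not mix: split R-hat {bad} exceeds "
                f"{mcmc.rhat_threshold}; increase draws/warmup"
            )

    # per-variant TOO: posterior of the origin generation on the branch
    q = (1.0 - ci_level) / 2.0
    growth = default_growth_table() if growth_table is None else growth_table
    log2_final = float(np.log2(growth["population"].iloc[-1]))
    idx_of = {int(v): i for i, v in enumerate(internal)}
    G_draws = params["G"].values.astype(int)
    too_rng = np.random.default_rng(rng.integers(2**31))
    too_rows = []
    for variant, node in sorted(var_edges.items()):
        t_child = (
            G_draws if node < n_leaves else times[:, idx_of[node]]
        )
        p = int(parent[node])
        t_par = times[:, idx_of[p]] if p >= n_leaves else np.zeros_like(t_child)
        gen = _sample_origin_generation(
            t_par + 1, np.maximum(t_child, t_par + 1), too_rng.random(times.shape[0])
        )
        pmw = generations_to_pmw(np.clip(gen, 0, log2_final), growth)
        too_rows.append(
            {
                "variant": variant,
                "too_median": float(np.median(gen)),
                "too_lo": float(np.quantile(gen, q)),
                "too_hi": float(np.quantile(gen, 1 - q)),
                "pmw_median": float(np.median(pmw)),
                "pmw_lo": float(np.quantile(pmw, q)),
                "pmw_hi": float(np.quantile(pmw, 1 - q)),
            }
        )
    too = pd.DataFrame(too_rows)

    node_times = pd.DataFrame(
        {
            "node": internal,
            "time_median": np.median(times, axis=0),
            "time_lo": np.quantile(times, q, axis=0),
            "time_hi": np.quantile(times, 1 - q, axis=0),
        }
    )
    return CoalescentFit(
        params=params[["chain", "draw", "N", "mu", "G"]],
        too=too,
        node_times=node_times,
        rhat=rhat,
        growth_table=growth,
        settings=mcmc,
    )


# ==========================================================================
# Regional restriction statistic
# ==========================================================================
@dataclass
class RRSResult:
    clade: object
    rrs: float
    ci: tuple[float, float]
    n_within_pairs: int
    n_cross_pairs: int
    defined: bool = True


def compute_rrs(
    tree: LineageTree,
    regions: dict[str, str] | pd.Series,
    clade: int | list[str] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
    lengths: str = "mutations",
    orientation: str = "cross_over_within",
) -> RRSResult:
    """Regional restriction statistic of a clade with bootstrap CI.

    RRS = (mean patristic distance between clade cells in different
    regions) / (mean distance between clade cells in the same region), so
    RRS > 1 means clade-mates in the same region are more closely related
    (regional restriction).  ``orientation='within_over_cross'`` flips the
    ratio.  The CI bootstraps cells within the clade.
    """
    rng = np.random.default_rng(seed)
    regions = pd.Series(regions)
    if clade is None:
        leaf_idx = np.arange(tree.n_leaves)
    elif isinstance(clade, (int, np.integer)):
        leaf_idx = tree.leaves_under(int(clade))
    else:
        wanted = set(clade)
        leaf_idx = np.array(
            [i for i, lid in enumerate(tree.leaf_ids) if lid in wanted], dtype=int
        )
    labels = regions.reindex([tree.leaf_ids[i] for i in leaf_idx]).values
    dist = tree.patristic_matrix(lengths)[np.ix_(leaf_idx, leaf_idx)]
    k = leaf_idx.size

    def ratio(idx: np.ndarray) -> tuple[float, int, int]:
        same = labels[idx][:, None] == labels[idx][None, :]
        iu = np.triu_indices(idx.size, 1)
        keep = idx[:, None] != idx[None, :]  # drop self-pairs under resampling
        d = dist[np.ix_(idx, idx)]
        w_mask = same[iu] & keep[iu]
        c_mask = (~same[iu]) & keep[iu]
        nw, nc = int(w_mask.sum()), int(c_mask.sum())
        if nw == 0 or nc == 0:
            return math.nan, nw, nc
        within = d[iu][w_mask].mean()
        cross = d[iu][c_mask].mean()
        if within == 0:
            return math.inf if cross > 0 else math.nan, nw, nc
        r = cross / within
        return (r if orientation == "cross_over_within" else 1.0 / r), nw, nc

    point, nw, nc = ratio(np.arange(k))
    if not math.isfinite(point):
        return RRSResult(clade, math.nan, (math.nan, math.nan), nw, nc, defined=False)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(k, size=k)
        r, _, _ = ratio(idx)
        if math.isfinite(r):
            boots.append(r)
    qq = (1.0 - ci_level) / 2.0
    ci = (
        (float(np.quantile(boots, qq)), float(np.quantile(boots, 1 - qq)))
        if boots
        else (math.nan, math.nan)
    )
    return RRSResult(clade, float(point), ci, nw, nc)


# ==========================================================================
# Dispersion-mode clustering
# ==========================================================================
@dataclass
class DispersionClusters:
    labels: pd.Series  # variant -> cluster id
    centroids: pd.DataFrame  # cluster x region
    k: int
    inertia: float


def kmeans_dispersion(
    variant_region_mf: pd.DataFrame,
    k: int = 5,
    seed: int | None = None,
    n_init: int = 10,
) -> DispersionClusters:
    """k-means over variants' per-region mosaic-fraction profiles.

    Rows are variants, columns regions, entries the MF (fraction of cells)
    in that region.  Five clusters recover the canonical spatial dispersion
    modes on cortical data.
    """
    X = variant_region_mf.values.astype(float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} variants available")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    lab = km.fit_predict(X)
    return DispersionClusters(
        labels=pd.Series(lab, index=variant_region_mf.index, name="cluster"),
        centroids=pd.DataFrame(
            km.cluster_centers_, columns=variant_region_mf.columns
        ),
        k=k,
        inertia=float(km.inertia_),
    )
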