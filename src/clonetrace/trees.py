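"""Rooted lineage trees over single cells.

A :class:`LineageTree` is a rooted tree whose leaves are sampled cells and
whose edges carry somatic variants.  Edge "length" is either the number of
mutations assigned to the edge (the natural unit straight after perfect-
phylogeny reconstruction) or a duration in cell generations (after the
coalescent fit calibrates node times).  The class is a thin array-based
container; newick serialisation goes through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["LineageTree"]


@dataclass
class LineageTree:
    """Rooted tree over cells with variants assigned to edges.

    Nodes are integers ``0..n_nodes-1``; leaves are ``0..n_leaves-1`` and map
    one-to-one onto ``leaf_ids``.  ``parent[root] == -1``.  ``edge_variants[i]``
    lists the variant ids on the edge above node ``i`` (empty for the root) and
    ``edge_mutation_count[i] == len(edge_variants[i])`` unless counts were set
    directly.  ``times`` holds node times in generations when known
    (leaves latest), else None.
    """

    parent: np.ndarray
    leaf_ids: list[str]
    edge_variants: list[list[str]] = field(default_factory=list)
    edge_mutation_count: np.ndarray | None = None
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        n = self.parent.size
        if not self.edge_variants:
            self.edge_variants = [[] for _ in range(n)]
        if self.edge_mutation_count is None:
            self.edge_mutation_count = np.array(
                [len(v) for v in self.edge_variants], dtype=float
            )
        else:
            self.edge_mutation_count = np.asarray(self.edge_mutation_count, dtype=float)
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        self._root = int(roots[0])

    # ---- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def root(self) -> int:
        return self._root

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def postorder(self) -> list[int]:
        ch = self.children()
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(ch[v])
        order.reverse()
        return order

    def leaves_under(self, node: int) -> np.ndarray:
        """Leaf indices in the clade rooted at ``node``."""
        ch = self.children()
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            stack.extend(ch[v])
        return np.sort(np.asarray(out, dtype=int))

    def variant_edges(self) -> dict[str, int]:
        """Map variant id -> node below its edge."""
        out: dict[str, int] = {}
        for i, vs in enumerate(self.edge_variants):
            for v in vs:
                out[v] = i
        return out

    # ---- distances -------------------------------------------------------
    def edge_lengths(self, lengths: str = "mutations") -> np.ndarray:
        if lengths == "mutations":
            return np.asarray(self.edge_mutation_count, dtype=float)
        if lengths == "generations":
            if self.times is None:
                raise ValueError("node times not set; run the coalescent fit first")
            ln = np.zeros(self.n_nodes)
            has_parent = self.parent >= 0
            ln[has_parent] = (
                self.times[has_parent] - self.times[self.parent[has_parent]]
            )
            return ln
        raise ValueError(f"unknown length unit {lengths!r}")

    def patristic_matrix(self, lengths: str = "mutations") -> np.ndarray:
        """Pairwise leaf-to-leaf path lengths, ordered as ``leaf_ids``."""
        ln = self.edge_lengths(lengths)
        depth = np.zeros(self.n_nodes)
        for v in self.postorder()[::-1]:  # preorder
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + ln[v]
        # ancestor chains per leaf
        chains = []
        for leaf in range(self.n_leaves):
            chain = []
            v = leaf
            while v >= 0:
                chain.append(v)
                v = self.parent[v]
            chains.append(set(chain))
        nl = self.n_leaves
        dist = np.zeros((nl, nl))
        for i in range(nl):
            vi = chains[i]
            for j in range(i + 1, nl):
                # deepest common ancestor = max depth over shared chain nodes
                common = vi & chains[j]
                dlca = max(depth[v] for v in common)
                dist[i, j] = dist[j, i] = depth[i] + depth[j] - 2.0 * dlca
        return dist

    # ---- edits -----------------------------------------------------------
    def collapse_unsupported(self) -> "LineageTree":
        """Contract internal edges carrying zero mutations.

        The result is the topology recoverable from genotypes alone (edges
        with no mutation leave no genotype signal).  Leaf edges are kept.
        """
        keep = np.ones(self.n_nodes, dtype=bool)
        newparent = self.parent.copy()
        for v in range(self.n_leaves, self.n_nodes):
            if v == self.root:
                continue
            if self.edge_mutation_count[v] == 0:
                keep[v] = False
        # reroute children of dropped nodes to nearest kept ancestor
        def kept_anc(v: int) -> int:
            p = self.parent[v]
            while p >= 0 and not keep[p]:
                p = self.parent[p]
            return p

        for v in range(self.n_nodes):
            if keep[v] and self.parent[v] >= 0:
                newparent[v] = kept_anc(v)
        idx = np.flatnonzero(keep)
        remap = {old: new for new, old in enumerate(idx)}
        parent = np.array(
            [remap[newparent[v]] if newparent[v] >= 0 else -1 for v in idx]
        )
        return LineageTree(
            parent=parent,
            leaf_ids=list(self.leaf_ids),
            edge_variants=[list(self.edge_variants[v]) for v in idx],
            edge_mutation_count=self.edge_mutation_count[idx],
            times=self.times[idx] if self.times is not None else None,
        )

    def binarized(self, rng: np.random.Generator | None = None) -> "LineageTree":
        """Resolve polytomies into random caterpillars (zero-mutation edges)."""
        rng = rng or np.random.default_rng(0)
        ch = self.children()
        parent = list(self.parent)
        variants = [list(v) for v in self.edge_variants]
        counts = list(np.asarray(self.edge_mutation_count, dtype=float))
        times = list(self.times) if self.times is not None else None
        for v in range(self.n_nodes):
            kids = ch[v]
            while len(kids) > 2:
                i, j = sorted(rng.choice(len(kids), size=2, replace=False))
                a, b = kids[j], kids[i]
                new = len(parent)
                parent.append(v)
                variants.append([])
                counts.append(0.0)
                if times is not None:
                    times.append(times[v])
                parent[a] = new
                parent[b] = new
                kids = [k for k in kids if k not in (a, b)] + [new]
        return LineageTree(
            parent=np.asarray(parent),
            leaf_ids=list(self.leaf_ids),
            edge_variants=variants,
            edge_mutation_count=np.asarray(counts),
            times=np.asarray(times) if times is not None else None,
        )

    # ---- I/O -------------------------------------------------------------
    def to_dendropy(self, lengths: str = "mutations") -> dendropy.Tree:
        ln = self.edge_lengths(lengths)
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_leaves):
            nodes[i].taxon = taxa.new_taxon(self.leaf_ids[i])
        for v in range(self.n_nodes):
            nodes[v].edge.length = float(ln[v])
            if self.edge_variants[v]:
                nodes[v].annotations.add_new("variants", ",".join(self.edge_variants[v]))
            p = self.parent[v]
            if p >= 0:
                nodes[p].add_child(nodes[v])
        tree.seed_node = nodes[self.root]
        return tree

    def write_newick(self, path, lengths: str = "mutations") -> None:
        self.to_dendropy(lengths).write(
            path=str(path), schema="newick", suppress_annotations=False
        )

    def rf_distance(self, other: "LineageTree", lengths: str = "mutations") -> int:
        """Robinson-Foulds (symmetric difference) distance on shared leaves."""
        taxa = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(
            data=self.to_dendropy(lengths).as_string(schema="newick"),
            schema="newick",
            taxon_namespace=taxa,
        )
        t2 = dendropy.Tree.get(
            data=other.to_dendropy(lengths).as_string(schema="newick"),
            schema="newick",
            taxon_namespace=taxa,
        )
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))
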