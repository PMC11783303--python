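"""Phylogeny container used by the likelihood engine and the simulator.

A thin array-oriented wrapper around a dendropy tree: tips are indexed
0..n_tips-1 in the order of ``taxon_names``; internal nodes follow. The
pruning engine only needs, for each internal node in postorder, its
children and the lengths of the branches leading to them. Branch lengths
are in expected substitutions per codon site.
"""

from __future__ import annotations

import io

import dendropy


class Phylogeny:
    """Unrooted (or arbitrarily rooted) gene tree with codon-scale branch
    lengths. Reversible models make the rooting irrelevant for likelihood
    computation, so the dendropy seed node is used as the pruning root."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._index()

    # ---------------------------------------------------------- construction
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    # --------------------------------------------------------------- indexing
    def _index(self) -> None:
        tips = [lf for lf in self._tree.leaf_node_iter()]
        self.taxon_names = [lf.taxon.label for lf in tips]
        if len(set(self.taxon_names)) != len(self.taxon_names):
            raise ValueError("duplicate tip labels in tree")
        node_id = {}
        for i, lf in enumerate(tips):
            node_id[id(lf)] = i
        nxt = len(tips)
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                continue
            node_id[id(nd)] = nxt
            nxt += 1
        self.n_tips = len(tips)
        self.n_nodes = nxt
        self.root_index = node_id[id(self._tree.seed_node)]
        # children[k] for internal node k (offset by n_tips): list of
        # (child_node_index, branch_length)
        self.children: list[list[tuple[int, float]]] = [
            [] for _ in range(self.n_nodes - self.n_tips)
        ]
        self.postorder: list[int] = []
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                continue
            k = node_id[id(nd)]
            self.postorder.append(k)
            for ch in nd.child_nodes():
                bl = ch.edge.length if ch.edge.length is not None else 0.0
                if bl < 0:
                    raise ValueError("negative branch length")
                self.children[k - self.n_tips].append((node_id[id(ch)], bl))

    # ------------------------------------------------------------- operations
    def branch_lengths(self) -> list[float]:
        return [
            bl for kids in self.children for (_, bl) in kids
        ]

    def total_length(self) -> float:
        return sum(self.branch_lengths())

    def prune_to(self, taxa) -> "Phylogeny":
        """Restrict the tree to the given taxa (dropping others)."""
        keep = set(taxa)
        missing = keep - set(self.taxon_names)
        if missing:
            raise ValueError(f"taxa not in tree: {sorted(missing)}")
        tree = self._tree.clone(depth=1)
        tree.retain_taxa_with_labels(sorted(keep))
        return Phylogeny(
            dendropy.Tree.get(
                data=tree.as_string(schema="newick"),
                schema="newick",
                preserve_underscores=True,
            )
        )

    def rerooted_at_tip_edge(self, tip_label: str) -> "Phylogeny":
        """Reroot along the edge leading to a tip (used to check likelihood
        invariance to root placement under reversible models)."""
        tree = dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )
        nd = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == tip_label
        )
        half = (nd.edge.length or 0.0) / 2.0
        tree.reroot_at_edge(nd.edge, length1=half, length2=half)
        return Phylogeny(tree)

    def scaled(self, factor: float) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )
        for e in tree.edges():
            if e.length is not None:
                e.length = e.length * factor
        return Phylogeny(tree)

    def mean_root_to_tip(self) -> float:
        tree = self._tree
        depths = []

        def walk(nd, d):
            for ch in nd.child_nodes():
                bl = ch.edge.length or 0.0
                if ch.is_leaf():
                    depths.append(d + bl)
                else:
                    walk(ch, d + bl)

        walk(tree.seed_node, 0.0)
        return sum(depths) / len(depths)
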