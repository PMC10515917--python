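"""Phylogenetic tree container and the ape lineage chain.

The tree is stored in flat arrays (parent pointers, branch lengths,
postorder) which is what the pruning algorithm wants; dendropy handles
newick parsing.  Branch lengths are expected substitutions per site.

The *lineage chain* is the ordered root-to-tip node path

    Catarrhine -> Ape -> GreatApe -> AfricanGreatApe -> Hominin -> Human

whose five consecutive transitions define the five named lineages a
single-event change can be assigned to.  The catarrhine ancestor is the
sixth reference state: without it a change on the branch leading to the
ape ancestor (the "Ape lineage") could not be polarized, which is why old
world monkeys (sister group) and new world monkeys (outgroup) are in the
alignment at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

#: Chain node labels, deepest (catarrhine ancestor) to shallowest (human tip).
CHAIN_NODES: tuple[str, ...] = (
    "Catarrhine",
    "Ape",
    "GreatApe",
    "AfricanGreatApe",
    "Hominin",
    "Human",
)

#: Lineage label of the transition CHAIN_NODES[i] -> CHAIN_NODES[i+1].
LINEAGES: tuple[str, ...] = ("Ape", "GreatApe", "AfricanGreatApe", "Hominin", "Human")

#: Lineage branch lengths in million years (lower-bound divergence estimates).
BRANCH_MY: dict[str, float] = {
    "Human": 6.0,
    "Hominin": 2.0,
    "AfricanGreatApe": 8.0,
    "GreatApe": 4.0,
    "Ape": 13.0,
}


class TreeError(ValueError):
    """Raised for malformed trees or chain configurations."""


@dataclass
class PhyloTree:
    """Rooted tree in flat-array form.

    Attributes
    ----------
    names : list of str
        Node labels; tips carry taxon names, internal nodes may be ''.
    parent : ndarray of int
        Parent index per node; -1 at the root.
    lengths : ndarray of float
        Length of the branch above each node (0 at the root).
    children : list of list of int
        Child indices per node, in stable input order.
    """

    names: list[str]
    parent: np.ndarray
    lengths: np.ndarray
    children: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise TreeError("negative branch length")
        n = len(self.names)
        if not self.children:
            self.children = [[] for _ in range(n)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    self.children[p].append(i)

    # -- basic queries ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return int(np.where(self.parent < 0)[0][0])

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    @property
    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_tip(i)]

    @property
    def tip_names(self) -> list[str]:
        return [self.names[i] for i in self.tip_indices]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise TreeError(f"node {name!r} not in tree") from None

    def postorder(self) -> list[int]:
        """Node indices, every child before its parent."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def subtree(self, i: int) -> list[int]:
        """All nodes at or below node i (preorder)."""
        out = []
        stack = [i]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        return PhyloTree(list(self.names), self.parent.copy(),
                         np.asarray(lengths, dtype=float).copy(),
                         [list(c) for c in self.children])

    def scaled(self, factor: float) -> "PhyloTree":
        return self.with_lengths(self.lengths * factor)

    # -- newick ----------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
        names: list[str] = []
        parent: list[int] = []
        lengths: list[float] = []
        idx: dict[int, int] = {}
        for nd in tree.preorder_node_iter():
            i = len(names)
            idx[id(nd)] = i
            if nd.taxon is not None:
                names.append(nd.taxon.label)
            else:
                names.append(nd.label or "")
            parent.append(idx[id(nd.parent_node)] if nd.parent_node else -1)
            lengths.append(float(nd.edge.length or 0.0))
        return cls(names, np.array(parent), np.array(lengths))

    def to_newick(self) -> str:
        """Deterministic newick string (children in stored order)."""

        def fmt(i: int) -> str:
            label = self.names[i]
            if self.children[i]:
                inner = ",".join(fmt(c) for c in self.children[i])
                label = f"({inner}){label}"
            if self.parent[i] < 0:
                return label
            return f"{label}:{self.lengths[i]:.10g}"

        return fmt(self.root) + ";"


@dataclass(frozen=True)
class LineageChain:
    """The ordered ancestor-to-human node path and its lineage labels.

    ``nodes[i] -> nodes[i+1]`` is the branch named ``lineages[i]``.  The
    default six-node chain supports five lineages; ``five_node()`` yields
    the restricted chain (no catarrhine ancestor, four lineages) for
    sensitivity analyses.
    """

    nodes: tuple[str, ...] = CHAIN_NODES
    lineages: tuple[str, ...] = LINEAGES

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.lineages) + 1:
            raise TreeError("chain must have one more node than lineages")
        if len(set(self.lineages)) != len(self.lineages):
            raise TreeError("lineage labels must be unique")

    @classmethod
    def five_node(cls) -> "LineageChain":
        return cls(nodes=CHAIN_NODES[1:], lineages=LINEAGES[1:])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def branch_my(self) -> dict[str, float]:
        return {lin: BRANCH_MY[lin] for lin in self.lineages}

    def validate_on(self, tree: PhyloTree) -> None:
        """Check the chain nodes lie on a single root-to-tip path in `tree`."""
        idx = [tree.index(n) for n in self.nodes]
        for deeper, shallower in zip(idx, idx[1:]):
            v = shallower
            while v >= 0 and v != deeper:
                v = int(tree.parent[v])
            if v != deeper:
                raise TreeError(
                    f"{tree.names[deeper]} is not an ancestor of "
                    f"{tree.names[shallower]}")
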