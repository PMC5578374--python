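"""Dollo parsimony on a rooted species tree.

Under Dollo parsimony a character (here: presence of a homolog) is gained at
most once on the tree and may be lost any number of times.  The minimum-loss
reconstruction places the single gain at the most recent common ancestor of
all presence leaves and keeps a node present exactly when its subtree still
contains a presence leaf.  The distance between two proteins compares the
per-branch state changes of their reconstructions: branches where one protein
was gained or lost and the other was not each contribute one unit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np

from .measures import MeasureMatrix
from .profiles import BinaryProfile

__all__ = ["RootedTree", "DolloStates", "parse_newick",
           "dollo_reconstruct", "dollo_distance", "dollo_distance_matrix"]


class RootedTree:
    """A rooted (possibly multifurcating) species tree with indexed nodes.

    Nodes are numbered in preorder (root = 0), so every node's parent has a
    smaller index and the branch set is ``{(parent[v], v) : v > 0}``.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        if tree.is_rooted is False:
            raise ValueError(
                "tree is explicitly unrooted ([&U]); Dollo reconstruction "
                "requires a rooted tree — midpoint-root it or supply an "
                "outgroup first"
            )
        self._tree = tree
        self.nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.parent = np.full(len(self.nodes), -1, dtype=int)
        for i, nd in enumerate(self.nodes):
            if nd.parent_node is not None:
                self.parent[i] = index[id(nd.parent_node)]
        self.leaf_index: dict[str, int] = {}
        for i, nd in enumerate(self.nodes):
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon else nd.label
                if label is None:
                    raise ValueError("unlabelled leaf in tree")
                if label in self.leaf_index:
                    raise ValueError(f"duplicate leaf label {label!r}")
                self.leaf_index[label] = i

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(self.leaf_index)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()


def parse_newick(text: str) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    Multifurcations are kept as read.  Trees are treated as rooted at the
    Newick root unless explicitly tagged ``[&U]``.  Branch lengths are parsed
    but unused by Dollo reconstruction.
    """
    try:
        tree = dendropy.Tree.get(
            file=io.StringIO(text), schema="newick",
            rooting="default-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from None
    return RootedTree(tree)


@dataclass
class DolloStates:
    """Minimum-loss single-gain state assignment for one protein.

    ``state[v]`` is the presence state of node ``v`` (preorder index);
    ``gain_node`` is the index of the unique branch-top node on which the
    character appears, or None when the protein is absent everywhere.
    """

    tree: RootedTree
    state: np.ndarray
    gain_node: int | None

    def n_losses(self) -> int:
        """Number of branches on which the character is lost (1 -> 0)."""
        par = self.tree.parent
        child = np.arange(1, self.tree.n_nodes)
        return int(np.sum((self.state[par[child]] == 1)
                          & (self.state[child] == 0)))

    def branch_changes(self) -> np.ndarray:
        """Per-branch anc - desc differences, ordered by child preorder index."""
        par = self.tree.parent
        child = np.arange(1, self.tree.n_nodes)
        return (self.state[par[child]] - self.state[child]).astype(int)


def dollo_reconstruct(tree: RootedTree, leaf_states: dict[str, int]) -> DolloStates:
    """Minimum-loss Dollo reconstruction of one presence/absence character.

    The gain is placed at the MRCA of all presence leaves; a node is present
    iff it descends from (or is) the gain node and its subtree contains at
    least one presence leaf.  Every leaf of the tree must appear in
    ``leaf_states``.
    """
    missing = set(tree.leaf_index) - set(leaf_states)
    if missing:
        raise ValueError(f"missing leaf state(s): {sorted(missing)[:5]}")
    n = tree.n_nodes
    # has_presence[v]: subtree of v contains a presence leaf (postorder sweep)
    has_presence = np.zeros(n, dtype=bool)
    for label, idx in tree.leaf_index.items():
        if leaf_states[label]:
            has_presence[idx] = True
    for v in range(n - 1, 0, -1):
        if has_presence[v]:
            has_presence[tree.parent[v]] = True
    if not has_presence[0]:
        return DolloStates(tree, np.zeros(n, dtype=np.int8), None)
    # count presence leaves per subtree; the nodes whose subtree holds ALL of
    # them form the root->MRCA chain, so the deepest (largest preorder index)
    # such node is the MRCA = gain node
    n_pres = np.zeros(n, dtype=int)
    for label, idx in tree.leaf_index.items():
        if leaf_states[label]:
            n_pres[idx] = 1
    for v in range(n - 1, 0, -1):
        n_pres[tree.parent[v]] += n_pres[v]
    total = n_pres[0]
    gain = int(np.max(np.nonzero(n_pres == total)[0]))
    state = np.zeros(n, dtype=np.int8)
    # present iff in gain's subtree and subtree has a presence leaf
    in_subtree = np.zeros(n, dtype=bool)
    in_subtree[gain] = True
    for v in range(1, n):
        if in_subtree[tree.parent[v]]:
            in_subtree[v] = True
    state[in_subtree & has_presence] = 1
    return DolloStates(tree, state, gain)


def dollo_distance(sx: DolloStates, sy: DolloStates,
                   tree: RootedTree | None = None) -> int:
    """Dollo parsimony distance: per-branch L1 difference of state changes.

    Sums |(anc(x)-desc(x)) - (anc(y)-desc(y))| over all branches, where anc
    and desc are the parent and child states of the branch under each
    protein's reconstruction.  Identical reconstructions give 0.
    """
    if tree is None:
        tree = sx.tree
    if sx.tree is not sy.tree and sx.tree.n_nodes != sy.tree.n_nodes:
        raise ValueError("state maps cover different trees")
    return int(np.abs(sx.branch_changes() - sy.branch_changes()).sum())


def dollo_distance_matrix(profile: BinaryProfile, tree: RootedTree,
                          on_missing_species: str = "restrict") -> MeasureMatrix:
    """All-against-all Dollo distances for a binary profile on a tree.

    Profile species absent from the tree's leaf set are dropped (with their
    count reported via a ValueError when ``on_missing_species="error"``).
    Tree leaves absent from the profile are treated as absence for every
    protein.
    """
    leafset = set(tree.leaf_index)
    missing = [s for s in profile.species if s not in leafset]
    if missing and on_missing_species == "error":
        raise ValueError(
            f"{len(missing)} profile species not on the tree: {missing[:5]}"
        )
    cols = {s: j for j, s in enumerate(profile.species) if s in leafset}
    changes = np.empty((len(profile.proteins), tree.n_nodes - 1), dtype=int)
    for i, prot in enumerate(profile.proteins):
        row = profile.values[i]
        leaf_states = {s: int(row[cols[s]]) if s in cols else 0
                       for s in tree.leaf_index}
        changes[i] = dollo_reconstruct(tree, leaf_states).branch_changes()
    n = len(profile.proteins)
    dist = np.abs(changes[:, None, :] - changes[None, :, :]).sum(axis=2) \
        if n <= 512 else _blockwise_l1(changes)
    return MeasureMatrix(profile.proteins, dist.astype(float),
                         "dollo", "distance")


def _blockwise_l1(changes: np.ndarray, block: int = 128) -> np.ndarray:
    n = changes.shape[0]
    out = np.empty((n, n), dtype=int)
    for s in range(0, n, block):
        b = changes[s:s + block]
        out[s:s + b.shape[0]] = np.abs(b[:, None, :] - changes[None, :, :]).sum(axis=2)
    return out
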