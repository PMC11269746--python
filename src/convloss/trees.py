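"""Rooted phylogeny container shared by every analysis stage.

The tree is stored as flat arrays (parent pointers, branch lengths, names)
which makes likelihood passes and simulations easy to vectorise.  Newick text
is parsed through dendropy; serialisation back to Newick is plain recursion
over the stored topology.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import TreeError

__all__ = ["Phylogeny"]


class Phylogeny:
    """A rooted tree with uniquely named nodes and non-negative branch lengths.

    Parameters
    ----------
    names:
        One name per node; all names must be unique and non-empty.
    parent:
        Parent index per node, ``-1`` for the root (exactly one).
    blen:
        Branch length above each node in time units; the root's entry is 0.
    """

    def __init__(self, names: Sequence[str], parent: Sequence[int], blen: Sequence[float]):
        self.names: list[str] = [str(n) for n in names]
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        m = len(self.names)
        if not (len(self.parent) == len(self.blen) == m):
            raise TreeError("names, parent and blen must have equal length")
        if len(set(self.names)) != m or any(not n for n in self.names):
            raise TreeError("node names must be unique and non-empty")
        roots = np.flatnonzero(self.parent == -1)
        if roots.size != 1:
            raise TreeError(f"expected exactly one root, found {roots.size}")
        self.root = int(roots[0])
        if np.any(np.isnan(self.blen)) or np.any(self.blen[np.arange(m) != self.root] < 0):
            raise TreeError("branch lengths must be non-negative and finite")
        self.blen[self.root] = 0.0
        self.children: list[list[int]] = [[] for _ in range(m)]
        for v in range(m):
            p = int(self.parent[v])
            if p >= 0:
                if p == v:
                    raise TreeError("self-parenting node")
                self.children[p].append(v)
        self._index = {n: i for i, n in enumerate(self.names)}
        self._postorder = self._compute_postorder()
        if len(self._postorder) != m:
            raise TreeError("tree contains a cycle or disconnected nodes")

    # ----------------------------------------------------------------- basics
    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices())

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"node {name!r} not in tree") from None

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    def tip_indices(self) -> list[int]:
        return [v for v in range(len(self.names)) if self.is_tip(v)]

    @property
    def tip_names(self) -> list[str]:
        return [self.names[v] for v in self.tip_indices()]

    def _compute_postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        seen = set()
        while stack:
            v = stack.pop()
            if v in seen:
                raise TreeError("cycle detected")
            seen.add(v)
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()  # children precede parents
        return order

    def postorder(self) -> list[int]:
        """Node indices with every child before its parent."""
        return list(self._postorder)

    def preorder(self) -> list[int]:
        return list(reversed(self._postorder))

    # ------------------------------------------------------------- geometry
    def node_depths(self) -> np.ndarray:
        """Distance from the root to each node."""
        depth = np.zeros(len(self.names))
        for v in self.preorder():
            p = int(self.parent[v])
            if p >= 0:
                depth[v] = depth[p] + self.blen[v]
        return depth

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = self.node_depths()[self.tip_indices()]
        span = depths.max() - depths.min()
        return bool(span <= rel_tol * max(depths.max(), 1e-300))

    def total_length(self) -> float:
        return float(self.blen.sum())

    # ------------------------------------------------------------- topology
    def ancestors(self, name: str) -> list[str]:
        """Names of ancestors from the node's parent up to the root."""
        v = self.index(name)
        out = []
        while self.parent[v] >= 0:
            v = int(self.parent[v])
            out.append(self.names[v])
        return out

    def mrca(self, names: Iterable[str]) -> str:
        idxs = [self.index(n) for n in names]
        if not idxs:
            raise TreeError("mrca of empty set")
        paths = []
        for v in idxs:
            chain = [v]
            while self.parent[chain[-1]] >= 0:
                chain.append(int(self.parent[chain[-1]]))
            paths.append(list(reversed(chain)))
        anc = paths[0]
        for p in paths[1:]:
            k = 0
            while k < min(len(anc), len(p)) and anc[k] == p[k]:
                k += 1
            anc = anc[:k]
        if not anc:
            raise TreeError("nodes share no common ancestor")
        return self.names[anc[-1]]

    def subtree_tips(self, name: str) -> set[str]:
        """Tip names descending from (and including, if a tip) the node."""
        v = self.index(name)
        out: set[str] = set()
        stack = [v]
        while stack:
            u = stack.pop()
            if self.is_tip(u):
                out.add(self.names[u])
            stack.extend(self.children[u])
        return out

    def subtree_nodes(self, name: str) -> set[str]:
        v = self.index(name)
        out: set[str] = set()
        stack = [v]
        while stack:
            u = stack.pop()
            out.add(self.names[u])
            stack.extend(self.children[u])
        return out

    def path_branches(self, ancestor: str, descendant: str) -> list[tuple[str, str]]:
        """Ordered (parent, child) branches from `ancestor` down to `descendant`."""
        a, d = self.index(ancestor), self.index(descendant)
        chain = [d]
        while chain[-1] != a:
            p = int(self.parent[chain[-1]])
            if p < 0:
                raise TreeError(f"{ancestor!r} is not an ancestor of {descendant!r}")
            chain.append(p)
        chain.reverse()
        return [(self.names[chain[i]], self.names[chain[i + 1]]) for i in range(len(chain) - 1)]

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, text: str, autoname_internals: bool = True) -> "Phylogeny":
        """Parse a rooted Newick string (dendropy backend).

        Unnamed internal nodes are given deterministic preorder names
        ``IN1, IN2, ...`` when `autoname_internals` is true.
        """
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=False,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"could not parse Newick input: {exc}") from exc
        names: list[str] = []
        parent: list[int] = []
        blen: list[float] = []
        idx_of: dict[int, int] = {}
        counter = 0
        for node in dt.preorder_node_iter():
            label = None
            if node.taxon is not None and node.taxon.label:
                label = node.taxon.label
            elif node.label:
                label = node.label
            if label is None:
                if node.is_leaf() or not autoname_internals:
                    raise TreeError("unnamed tip (or autoname_internals disabled)")
                counter += 1
                label = f"IN{counter}"
                while label in names:
                    counter += 1
                    label = f"IN{counter}"
            names.append(label)
            idx_of[id(node)] = len(names) - 1
            if node.parent_node is None:
                parent.append(-1)
                blen.append(0.0)
            else:
                parent.append(idx_of[id(node.parent_node)])
                blen.append(float(node.edge.length or 0.0))
        return cls(names, parent, blen)

    def to_newick(self) -> str:
        """Serialise with all node names and branch lengths."""

        def fmt(v: int) -> str:
            name = self.names[v]
            if self.children[v]:
                inner = ",".join(fmt(c) for c in self.children[v])
                body = f"({inner}){name}"
            else:
                body = name
            if v == self.root:
                return body
            return f"{body}:{self.blen[v]:.12g}"

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def read(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())
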