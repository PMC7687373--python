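"""Phylogenetic tree container used across the pipeline.

A light rooted representation: unrooted trees carry a basal trifurcation.
Branch lengths are in expected substitutions/site; internal nodes may carry
bootstrap support in percent. Newick parsing is delegated to dendropy and
converted at the boundary; writing is direct.
"""

from __future__ import annotations

import itertools

import dendropy

__all__ = ["Node", "Tree"]


class Node:
    __slots__ = ("children", "parent", "length", "name", "support")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 support: float | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.name = name
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    def __repr__(self):  # pragma: no cover
        return f"<Node {self.name or 'internal'} len={self.length:.4g}>"


class Tree:
    """Rooted tree over named tips; a 3-child root encodes an unrooted tree."""

    def __init__(self, root: Node):
        self.root = root
        names = [t.name for t in self.tips()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tip labels")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))
        return out

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def internal_edges(self) -> list[Node]:
        """Child nodes of internal (non-tip, non-root) edges, deterministic
        postorder."""
        return [n for n in self.postorder()
                if not n.is_leaf and n.parent is not None]

    def n_tips(self) -> int:
        return len(self.tips())

    # -- construction / copying -------------------------------------------

    def copy(self) -> "Tree":
        def _clone(n: Node) -> Node:
            c = Node(n.name, n.length, n.support)
            for ch in n.children:
                c.add(_clone(ch))
            return c

        return Tree(_clone(self.root))

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            dt = dendropy.Tree.get(data=text, schema="newick",
                                   preserve_underscores=True,
                                   suppress_internal_node_taxa=True)
        except Exception as exc:
            raise ValueError(f"bad newick: {exc}") from exc

        def _convert(dn) -> Node:
            label = dn.taxon.label if dn.taxon is not None else None
            support = None
            if dn.label is not None and not dn.is_leaf():
                try:
                    support = float(dn.label)
                except ValueError:
                    support = None
            n = Node(name=label,
                     length=dn.edge.length if dn.edge.length is not None else 0.0,
                     support=support)
            for ch in dn.child_nodes():
                n.add(_convert(ch))
            return n

        return cls(_convert(dt.seed_node))

    @classmethod
    def read(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, lengths: bool = True, supports: bool = True) -> str:
        def _fmt(n: Node) -> str:
            if n.is_leaf:
                body = n.name or ""
            else:
                body = "(" + ",".join(_fmt(c) for c in n.children) + ")"
                if supports and n.support is not None:
                    body += f"{n.support:g}"
            if lengths and n.parent is not None:
                body += f":{n.length:.10g}"
            return body

        return _fmt(self.root) + ";"

    def write(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")

    # -- topology ----------------------------------------------------------

    def _clade_sets(self) -> dict:
        below: dict[int, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.name])
            else:
                below[id(n)] = frozenset(
                    itertools.chain.from_iterable(below[id(c)] for c in n.children))
        return below

    def bipartitions(self, min_support: float = 0.0,
                     include_trivial: bool = False) -> set[frozenset]:
        """Tip-set splits induced by edges, canonicalized as the smaller side
        (ties: lexicographically smaller). Edges whose support is below
        ``min_support`` are dropped; an absent support passes only at 0."""
        all_tips = frozenset(self.tip_names())
        below = self._clade_sets()
        out: set[frozenset] = set()
        for n in self.postorder():
            if n.parent is None:
                continue
            side = below[id(n)]
            if not include_trivial and (len(side) < 2 or len(side) > len(all_tips) - 2):
                continue
            if min_support > 0:
                if n.support is None or n.support < min_support:
                    continue
            other = all_tips - side
            canon = min(side, other, key=lambda s: (len(s), sorted(s)))
            out.add(canon)
        return out

    def reroot_on(self, outgroup: str) -> "Tree":
        """Return a copy rooted on the edge above the named tip.

        Edge supports travel with their bipartition: the support stored on a
        node refers to the edge above it, and flipping an edge's direction
        moves that value to the other endpoint.
        """
        t = self.copy()
        tip = next((n for n in t.tips() if n.name == outgroup), None)
        if tip is None:
            raise KeyError(f"no tip named {outgroup!r}")
        if tip.parent is t.root and len(t.root.children) == 2:
            t.root.children.sort(key=lambda c: c is not tip)
            return t
        new_root = Node()
        half = tip.length / 2.0
        node = tip.parent
        tip.detach()
        new_root.add(tip)
        tip.length = half
        carry_len, carry_sup = half, tip.support
        tip.support = None
        prev = new_root
        while node is not None:
            parent = node.parent
            next_len, next_sup = node.length, node.support
            node.detach()
            prev.add(node)
            node.length, node.support = carry_len, carry_sup
            carry_len, carry_sup = next_len, next_sup
            prev = node
            node = parent
        t2 = Tree(new_root)
        t2.suppress_unifurcations()
        return t2

    def suppress_unifurcations(self) -> None:
        changed = True
        while changed:
            changed = False
            for n in self.postorder():
                if n.parent is not None and not n.is_leaf and len(n.children) == 1:
                    child = n.children[0]
                    child.length += n.length
                    parent = n.parent
                    idx = parent.children.index(n)
                    n.detach()
                    child.parent = parent
                    parent.children.insert(idx, child)
                    changed = True
                    break
            if self.root is not None and len(self.root.children) == 1 \
                    and not self.root.children[0].is_leaf:
                new_root = self.root.children[0]
                new_root.parent = None
                new_root.length = 0.0
                self.root = new_root
                changed = True

    def unroot(self) -> "Tree":
        """Return a copy with a basal trifurcation (standard unrooted form)."""
        t = self.copy()
        while len(t.root.children) == 2:
            a, b = t.root.children
            absorb = b if not b.is_leaf else a
            keep = a if absorb is b else b
            if absorb.is_leaf:
                break  # 2-tip tree; nothing to unroot
            keep.length += absorb.length
            absorb.detach()
            for ch in list(absorb.children):
                ch.detach()
                t.root.add(ch)
        return t

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    def rf_distance(self, other: "Tree") -> int:
        """Robinson–Foulds distance (size of the symmetric difference of the
        nontrivial bipartition sets)."""
        if set(self.tip_names()) != set(other.tip_names()):
            raise ValueError("tip sets differ")
        return len(self.bipartitions() ^ other.bipartitions())
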