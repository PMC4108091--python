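"""Unrooted binary tree machinery for parsimony over areas.

Working trees are plain adjacency maps over integer node ids: leaves occupy
ids ``0..n_leaves-1`` (the hypothetical all-absent outgroup is always the
last leaf id) and internal nodes, all of degree 3, use ids ``>= n_leaves``.
Fitch state sets are packed into Python integers — one bit per character per
state — which keeps scoring allocation-free on the modest tree sizes PAE
deals with and lets exhaustive enumeration run millions of length
evaluations in pure Python.

:class:`AreaTree` is the immutable, label-carrying snapshot handed to users.
"""

from __future__ import annotations

import re

__all__ = [
    "AreaTree",
    "edges",
    "fitch_total",
    "insert_leaf",
    "remove_inserted_leaf",
    "enumerate_topologies",
    "tbr_neighbors",
    "clade_masks",
    "topology_key",
    "renumber",
    "quote_label",
]


def edges(adj):
    """Sorted list of undirected edges ``(u, v)`` with ``u < v``."""
    return sorted({(u, v) if u < v else (v, u) for u, vs in adj.items() for v in vs})


def _orient(adj, root):
    """Preorder node list and parent map for the tree rooted at ``root``."""
    parent = {root: -1}
    order = [root]
    i = 0
    while i < len(order):
        u = order[i]
        i += 1
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
    return order, parent


def fitch_total(adj, root, codes, full):
    """Total Fitch parsimony length over all packed binary characters.

    Parameters
    ----------
    adj
        Adjacency map of an unrooted binary tree.
    root
        A leaf id to root the pass at (the outgroup, conventionally; the
        result is rooting-invariant).
    codes
        Maps each leaf id to ``(absent_bits, present_bits)`` — bit ``i`` of
        the first int is set when character ``i`` has state 0 at that leaf.
    full
        Int with one bit set per character.
    """
    order, parent = _orient(adj, root)
    state = {}
    total = 0
    for u in reversed(order):
        kids = [v for v in adj[u] if v != parent[u]]
        if u == root:
            a0, a1 = state[kids[0]]
            c0, c1 = codes[u]
            conflict = full & ~((a0 & c0) | (a1 & c1))
            total += conflict.bit_count()
        elif not kids:
            state[u] = codes[u]
        else:
            a0, a1 = state[kids[0]]
            b0, b1 = state[kids[1]]
            i0 = a0 & b0
            i1 = a1 & b1
            conflict = full & ~(i0 | i1)
            total += conflict.bit_count()
            state[u] = (
                i0 | (conflict & (a0 | b0)),
                i1 | (conflict & (a1 | b1)),
            )
    return total


def insert_leaf(adj, leaf, edge, new_internal):
    """Attach ``leaf`` on ``edge`` via a fresh internal node (in place)."""
    u, v = edge
    adj[u].remove(v)
    adj[v].remove(u)
    adj[u].append(new_internal)
    adj[v].append(new_internal)
    adj[new_internal] = [u, v, leaf]
    adj[leaf] = [new_internal]


def remove_inserted_leaf(adj, leaf, new_internal, u, v):
    """Undo :func:`insert_leaf` (restores the edge ``(u, v)``)."""
    del adj[leaf]
    del adj[new_internal]
    adj[u].remove(new_internal)
    adj[v].remove(new_internal)
    adj[u].append(v)
    adj[v].append(u)


def enumerate_topologies(n_leaves, visit):
    """Visit every distinct unrooted binary topology on leaves ``0..n-1``.

    ``visit`` receives the (mutable, reused) adjacency map and must copy it
    if it keeps a reference.  Returns the number of topologies visited,
    ``(2n - 5)!!``.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    hub = n_leaves
    adj = {0: [hub], 1: [hub], 2: [hub], hub: [0, 1, 2]}
    if n_leaves == 3:
        visit(adj)
        return 1
    count = 0

    def rec(k, nid):
        nonlocal count
        if k == n_leaves:
            visit(adj)
            count += 1
            return
        for u, v in edges(adj):
            insert_leaf(adj, k, (u, v), nid)
            rec(k + 1, nid + 1)
            remove_inserted_leaf(adj, k, nid, u, v)

    rec(3, n_leaves + 1)
    return count


def _component(adj, start):
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def tbr_neighbors(adj, n_leaves):
    """Yield adjacency maps for all tree-bisection-reconnection moves.

    Every edge (internal and pendant) is bisected; the two fragments are
    reconnected across every pair of their edges, a detached single leaf
    reattaching directly.  Enumeration order is deterministic.  The original
    topology itself reappears among the rearrangements; callers relying on
    strict-improvement acceptance are unaffected.
    """
    for u, v in edges(adj):
        base = {a: list(bs) for a, bs in adj.items()}
        base[u].remove(v)
        base[v].remove(u)
        sides = []
        for w in (u, v):
            nb = base[w]
            if not nb:  # fragment is the single leaf w
                sides.append(("leaf", w, None))
            else:  # suppress the now degree-2 node w
                x, y = nb
                base[x].remove(w)
                base[x].append(y)
                base[y].remove(w)
                base[y].append(x)
                del base[w]
                comp = _component(base, x)
                es = [e for e in edges(base) if e[0] in comp]
                sides.append(("tree", None, es))
        nid0 = max(base) + 1
        ka, la, ea = sides[0]
        kb, lb, eb = sides[1]
        a_choices = [("leaf", la)] if ka == "leaf" else [("edge", e) for e in ea]
        b_choices = [("leaf", lb)] if kb == "leaf" else [("edge", e) for e in eb]
        for ca in a_choices:
            for cb in b_choices:
                new = {a: list(bs) for a, bs in base.items()}
                nid = nid0
                pts = []
                for kind, val in (ca, cb):
                    if kind == "leaf":
                        pts.append(val)
                    else:
                        x, y = val
                        p = nid
                        nid += 1
                        new[x].remove(y)
                        new[x].append(p)
                        new[y].remove(x)
                        new[y].append(p)
                        new[p] = [x, y]
                        pts.append(p)
                pa, pb = pts
                new[pa].append(pb)
                new[pb].append(pa)
                yield new


def clade_masks(adj, n_leaves):
    """Leaf bitmasks below each internal node, rooted at the outgroup leaf.

    The outgroup is leaf ``n_leaves - 1``; returned masks never contain its
    bit.  Includes the trivial full-ingroup mask at the outgroup's neighbour.
    """
    root = n_leaves - 1
    order, parent = _orient(adj, root)
    mask = {}
    out = []
    for u in reversed(order):
        if u < n_leaves:
            mask[u] = 1 << u
        else:
            m = 0
            for v in adj[u]:
                if v != parent[u]:
                    m |= mask[v]
            mask[u] = m
            out.append(m)
    return out


def topology_key(adj, n_leaves):
    """Canonical hashable key: the set of nontrivial ingroup clade masks."""
    hi = n_leaves - 2  # ingroup size minus one
    return frozenset(
        m for m in clade_masks(adj, n_leaves) if 2 <= m.bit_count() <= hi
    )


def renumber(adj, n_leaves):
    """Equivalent adjacency map with internal ids ``n_leaves..2n-3``.

    Internal ids are assigned in preorder from the outgroup leaf, giving a
    deterministic normal form independent of construction history.
    """
    order, _ = _orient(adj, n_leaves - 1)
    mapping = {}
    nid = n_leaves
    for u in order:
        if u < n_leaves:
            mapping[u] = u
        else:
            mapping[u] = nid
            nid += 1
    return {mapping[u]: [mapping[v] for v in adj[u]] for u in order}


_PLAIN_LABEL = re.compile(r"^[A-Za-z0-9_.\-]+$")


def quote_label(label: str) -> str:
    """Quote a Newick label when it contains spaces or punctuation."""
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


class AreaTree:
    """Unrooted binary tree whose leaves are areas plus the all-absent outgroup.

    Leaf ``i`` carries ``labels[i]``; the outgroup is the last label.  The
    rooted view used to read clades is obtained by rooting at the outgroup
    leaf.
    """

    __slots__ = ("labels", "adj", "_key")

    def __init__(self, labels, adj):
        labels = tuple(str(lab) for lab in labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        n = len(labels)
        if n < 4:
            raise ValueError("need at least 3 areas plus the outgroup")
        adjn = {int(u): sorted(int(v) for v in vs) for u, vs in adj.items()}
        if len(adjn) != 2 * n - 2:
            raise ValueError(
                f"tree on {n} leaves must have {2 * n - 2} nodes, got {len(adjn)}"
            )
        for u, vs in adjn.items():
            want = 1 if u < n else 3
            if len(vs) != want:
                raise ValueError(f"node {u} has degree {len(vs)}, expected {want}")
            for v in vs:
                if u not in adjn.get(v, ()):
                    raise ValueError(f"asymmetric edge {u}-{v}")
        self.labels = labels
        self.adj = {u: tuple(vs) for u, vs in adjn.items()}
        self._key = None

    # -- structure ---------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def n_areas(self) -> int:
        return len(self.labels) - 1

    @property
    def outgroup(self) -> int:
        return len(self.labels) - 1

    @property
    def outgroup_label(self) -> str:
        return self.labels[-1]

    @property
    def area_labels(self) -> tuple:
        return self.labels[:-1]

    def mutable_adj(self):
        return {u: list(vs) for u, vs in self.adj.items()}

    def topology_key(self):
        if self._key is None:
            self._key = topology_key(self.mutable_adj(), self.n_leaves)
        return self._key

    def clades(self):
        """Nontrivial ingroup clades as frozensets of area labels."""
        out = set()
        for m in self.topology_key():
            out.add(frozenset(self.labels[i] for i in range(self.n_areas)
                              if m >> i & 1))
        return frozenset(out)

    # -- output ------------------------------------------------------------
    def newick(self) -> str:
        """Newick string with a basal trifurcation at the outgroup's neighbour.

        Child order is normalised (smallest leaf id first) so equal
        topologies serialise identically; the outgroup appears last.
        """
        adj = self.adj
        og = self.outgroup

        def min_leaf(u, parent):
            if u < self.n_leaves:
                return u
            return min(min_leaf(v, u) for v in adj[u] if v != parent)

        def sub(u, parent):
            if u < self.n_leaves:
                return quote_label(self.labels[u])
            kids = sorted((v for v in adj[u] if v != parent),
                          key=lambda v: min_leaf(v, u))
            return "(" + ",".join(sub(v, u) for v in kids) + ")"

        r = adj[og][0]
        kids = sorted((v for v in adj[r] if v != og), key=lambda v: min_leaf(v, r))
        parts = [sub(v, r) for v in kids] + [quote_label(self.outgroup_label)]
        return "(" + ",".join(parts) + ");"

    def __eq__(self, other):
        if not isinstance(other, AreaTree):
            return NotImplemented
        return (frozenset(self.labels) == frozenset(other.labels)
                and self.clades() == other.clades())

    def __hash__(self):
        return hash((frozenset(self.labels), self.clades()))

    def __repr__(self):
        return f"<AreaTree {self.n_areas} areas + outgroup>"
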