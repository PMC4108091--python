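"""Parsimony Analysis of Endemicity: scoring, tree search, consensus.

PAE treats areas as taxa and species presences as unordered binary
characters.  A hypothetical area in which every species is absent roots the
trees and polarises presence as the derived state, so nested clades of areas
can be read as areas of endemism.  The search protocol mirrors standard
parsimony practice: random-addition-sequence starting trees refined by
tree-bisection-reconnection (TBR) hill climbing, equally parsimonious trees
pooled across replicates, and the result summarised as a majority-rule
consensus.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np

from .incidence import OUTGROUP_LABEL, IncidenceMatrix
from .trees import (
    AreaTree,
    edges,
    enumerate_topologies,
    fitch_total,
    insert_leaf,
    quote_label,
    remove_inserted_leaf,
    renumber,
    tbr_neighbors,
    topology_key,
)

__all__ = [
    "fitch_length",
    "stepwise_addition",
    "tbr_search",
    "heuristic_search",
    "exhaustive_search",
    "majority_rule_consensus",
    "write_newick",
    "SearchResult",
    "ConsensusTree",
    "ParsimonyEndemicity",
    "PAEResults",
    "EXHAUSTIVE_MAX_AREAS",
]

#: Largest ingroup for exhaustive enumeration: 9 areas + outgroup = 10 leaves,
#: (2*10-5)!! = 2,027,025 unrooted topologies.
EXHAUSTIVE_MAX_AREAS = 9


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _pack_codes(matrix: IncidenceMatrix):
    """Per-leaf packed Fitch state sets; leaf j = area column j, outgroup last."""
    full = (1 << matrix.n_species) - 1
    codes = {}
    for j in range(matrix.n_areas):
        c1 = 0
        for s in np.flatnonzero(matrix.presence[:, j]):
            c1 |= 1 << int(s)
        codes[j] = (full & ~c1, c1)
    codes[matrix.n_areas] = (full, 0)  # all-absent outgroup
    return codes, full


def _check_labels(tree: AreaTree, matrix: IncidenceMatrix):
    t = set(tree.area_labels)
    m = set(matrix.area_ids)
    if t != m:
        diff = sorted(t.symmetric_difference(m))
        raise ValueError(f"tree/matrix area labels differ: {diff}")


def fitch_length(tree: AreaTree, matrix: IncidenceMatrix) -> int:
    """Minimum total number of 0↔1 changes the matrix requires on ``tree``.

    One Fitch pass per species (all species scored simultaneously via bit
    packing); the result is independent of the arbitrary rooting.
    """
    _check_labels(tree, matrix)
    codes, full = _pack_codes(matrix)
    col = {a: j for j, a in enumerate(matrix.area_ids)}
    leaf_codes = {i: codes[col[tree.labels[i]]] for i in range(tree.n_areas)}
    leaf_codes[tree.outgroup] = codes[matrix.n_areas]
    return fitch_total(tree.mutable_adj(), tree.outgroup, leaf_codes, full)


# ---------------------------------------------------------------------------
# search results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchResult:
    """Outcome of a parsimony tree search.

    ``trees`` are topologically distinct and sorted by (score, discovery
    order); ``scores`` gives each tree's length.  For heuristic searches the
    pool may contain replicate-best trees that are worse than the global
    ``best_score``; :attr:`optimal_trees` filters to the global optimum.
    """

    best_score: int
    trees: tuple
    scores: tuple
    replicates_run: int
    seed: int | None = None
    n_examined: int | None = None
    replicate_scores: tuple = ()

    def __post_init__(self):
        if self.trees and min(self.scores) < self.best_score:
            raise ValueError("stored tree beats best_score")

    @property
    def optimal_trees(self) -> tuple:
        return tuple(t for t, s in zip(self.trees, self.scores)
                     if s == self.best_score)


# ---------------------------------------------------------------------------
# stepwise addition
# ---------------------------------------------------------------------------

def _stepwise(n_areas, codes, full, order, rng):
    og = n_areas
    a, b, c = (int(order[0]), int(order[1]), int(order[2]))
    cands = []
    for x, y, z in ((a, b, c), (a, c, b), (b, c, a)):
        p, q = n_areas + 1, n_areas + 2
        adj = {x: [p], y: [p], z: [q], og: [q], p: [x, y, q], q: [z, og, p]}
        cands.append((fitch_total(adj, og, codes, full), adj))
    m = min(s for s, _ in cands)
    ties = [t for s, t in cands if s == m]
    adj = ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0]
    nid = n_areas + 3
    for k in order[3:]:
        k = int(k)
        best = None
        ties = []
        for e in edges(adj):
            insert_leaf(adj, k, e, nid)
            s = fitch_total(adj, og, codes, full)
            remove_inserted_leaf(adj, k, nid, *e)
            if best is None or s < best:
                best, ties = s, [e]
            elif s == best:
                ties.append(e)
        e = ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0]
        insert_leaf(adj, k, e, nid)
        nid += 1
    return adj


def stepwise_addition(matrix: IncidenceMatrix, order=None, seed=None,
                      outgroup_label: str = OUTGROUP_LABEL) -> AreaTree:
    """Greedy random-addition-sequence starting tree.

    Areas are attached one at a time (after the best-scoring starting
    quartet with the outgroup) at the insertion edge minimising Fitch
    length; ties are broken by the seeded RNG.  ``order`` may be a
    permutation of area labels or of column indices; by default a seeded
    random permutation is drawn.
    """
    if matrix.n_areas < 3:
        raise ValueError("stepwise addition needs at least 3 areas")
    if outgroup_label in matrix.area_ids:
        raise ValueError(f"outgroup label {outgroup_label!r} collides with an area")
    rng = np.random.default_rng(seed)
    if order is None:
        order = rng.permutation(matrix.n_areas)
    else:
        order = list(order)
        if order and isinstance(order[0], str):
            col = {a: j for j, a in enumerate(matrix.area_ids)}
            order = [col[a] for a in order]
        if sorted(order) != list(range(matrix.n_areas)):
            raise ValueError("order must be a permutation of the areas")
    codes, full = _pack_codes(matrix)
    adj = _stepwise(matrix.n_areas, codes, full, list(order), rng)
    labels = matrix.area_ids + (outgroup_label,)
    return AreaTree(labels, renumber(adj, matrix.n_areas + 1))


# ---------------------------------------------------------------------------
# TBR hill climbing
# ---------------------------------------------------------------------------

def _tbr(adj0, n_leaves, codes, full, keep):
    """Swap on all best trees; return (best_score, pool of best adjacencies)."""
    root = n_leaves - 1
    best = fitch_total(adj0, root, codes, full)
    adj0 = renumber(adj0, n_leaves)
    pool = {topology_key(adj0, n_leaves): adj0}
    queue = deque([adj0])
    while queue:
        cur = queue.popleft()
        improved = False
        for nb in tbr_neighbors(cur, n_leaves):
            s = fitch_total(nb, root, codes, full)
            if s < best:
                best = s
                nb = renumber(nb, n_leaves)
                pool = {topology_key(nb, n_leaves): nb}
                queue = deque([nb])
                improved = True
                break
            if s == best and len(pool) < keep:
                k = topology_key(nb, n_leaves)
                if k not in pool:
                    nb = renumber(nb, n_leaves)
                    pool[k] = nb
                    queue.append(nb)
        if improved:
            continue
    return best, pool


def tbr_search(start: AreaTree, matrix: IncidenceMatrix, keep: int = 100) -> SearchResult:
    """Hill-climb from ``start`` over TBR neighbourhoods.

    Strict improvements are accepted immediately; when no neighbour improves,
    swapping continues on every equally parsimonious tree found, retaining up
    to ``keep`` distinct best-scoring topologies (discovery order).
    """
    if keep < 1:
        raise ValueError("keep must be >= 1")
    _check_labels(start, matrix)
    codes, full = _pack_codes(matrix)
    col = {a: j for j, a in enumerate(matrix.area_ids)}
    # work in matrix column order so pool keys are comparable across starts
    if tuple(start.area_labels) != matrix.area_ids:
        remap = {i: col[start.labels[i]] for i in range(start.n_areas)}
        remap[start.outgroup] = start.outgroup
        n = start.n_leaves
        adj = {}
        for u, vs in start.adj.items():
            adj[remap.get(u, u)] = [remap.get(v, v) for v in vs]
    else:
        adj = start.mutable_adj()
    n_leaves = matrix.n_areas + 1
    best, pool = _tbr(adj, n_leaves, codes, full, keep)
    labels = matrix.area_ids + (start.outgroup_label,)
    trees = tuple(AreaTree(labels, a) for a in pool.values())
    return SearchResult(best_score=best, trees=trees,
                        scores=(best,) * len(trees), replicates_run=1)


def heuristic_search(matrix: IncidenceMatrix, replicates: int = 1000,
                     keep: int = 100, seed=None,
                     outgroup_label: str = OUTGROUP_LABEL) -> SearchResult:
    """Random-addition-sequence + TBR search, pooled across replicates.

    Runs ``replicates`` independent seeded rounds of
    :func:`stepwise_addition` followed by TBR swapping, each retaining up to
    ``keep`` equally parsimonious trees; retained trees are pooled with
    topological deduplication.  All randomness derives from ``seed``; reruns
    with the same arguments reproduce the result exactly.
    """
    if matrix.n_areas < 3:
        raise ValueError("search needs at least 3 areas")
    if outgroup_label in matrix.area_ids:
        raise ValueError(f"outgroup label {outgroup_label!r} collides with an area")
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    seed = int(seed)
    codes, full = _pack_codes(matrix)
    n_leaves = matrix.n_areas + 1
    labels = matrix.area_ids + (outgroup_label,)
    global_pool = {}
    best = None
    rep_scores = []
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        order = list(rng.permutation(matrix.n_areas))
        adj = _stepwise(matrix.n_areas, codes, full, order, rng)
        b, pool = _tbr(adj, n_leaves, codes, full, keep)
        rep_scores.append(b)
        if best is None or b < best:
            best = b
        for k, a in pool.items():
            if k not in global_pool:
                global_pool[k] = (b, len(global_pool), a)
    items = sorted(global_pool.values(), key=lambda t: (t[0], t[1]))
    trees = tuple(AreaTree(labels, a) for _, _, a in items)
    scores = tuple(s for s, _, _ in items)
    return SearchResult(best_score=best, trees=trees, scores=scores,
                        replicates_run=replicates, seed=seed,
                        replicate_scores=tuple(rep_scores))


def exhaustive_search(matrix: IncidenceMatrix,
                      outgroup_label: str = OUTGROUP_LABEL) -> SearchResult:
    """Enumerate every unrooted topology; exact minimum and all optima.

    Refuses ingroups larger than :data:`EXHAUSTIVE_MAX_AREAS` areas (10
    leaves with the outgroup, 2,027,025 topologies).
    """
    if matrix.n_areas > EXHAUSTIVE_MAX_AREAS:
        raise ValueError(
            f"exhaustive search limited to {EXHAUSTIVE_MAX_AREAS} areas "
            f"({matrix.n_areas} requested; 10 leaves = 2,027,025 topologies)"
        )
    if matrix.n_areas < 3:
        raise ValueError("search needs at least 3 areas")
    if outgroup_label in matrix.area_ids:
        raise ValueError(f"outgroup label {outgroup_label!r} collides with an area")
    codes, full = _pack_codes(matrix)
    n_leaves = matrix.n_areas + 1
    root = n_leaves - 1
    state = {"best": None, "opts": []}

    def visit(adj):
        s = fitch_total(adj, root, codes, full)
        if state["best"] is None or s < state["best"]:
            state["best"] = s
            state["opts"] = [renumber(adj, n_leaves)]
        elif s == state["best"]:
            state["opts"].append(renumber(adj, n_leaves))

    n = enumerate_topologies(n_leaves, visit)
    labels = matrix.area_ids + (outgroup_label,)
    trees = tuple(AreaTree(labels, a) for a in state["opts"])
    return SearchResult(best_score=state["best"], trees=trees,
                        scores=(state["best"],) * len(trees),
                        replicates_run=1, n_examined=n)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

class _CNode:
    __slots__ = ("label", "support", "children", "mask")

    def __init__(self, mask, label=None, support=None):
        self.mask = mask
        self.label = label
        self.support = support
        self.children = []


class ConsensusTree:
    """Majority-rule consensus over the outgroup-rooted view of area trees.

    Internal nodes carry their clade's frequency among the input trees as a
    percentage in (50, 100], rounded to one decimal; nodes unresolved at the
    cutoff collapse into polytomies.
    """

    def __init__(self, root, area_labels, n_trees, cutoff):
        self.root = root
        self.area_labels = tuple(area_labels)
        self.n_trees = n_trees
        self.cutoff = cutoff

    def clades(self) -> dict:
        """Nontrivial retained clades mapped to their percent support."""
        out = {}

        def rec(node):
            for ch in node.children:
                if ch.children:
                    out[frozenset(self.area_labels[i]
                                  for i in range(len(self.area_labels))
                                  if ch.mask >> i & 1)] = ch.support
                    rec(ch)

        rec(self.root)
        return out

    def newick(self) -> str:
        def fmt(s):
            txt = f"{s:.1f}"
            return txt[:-2] if txt.endswith(".0") else txt

        def rec(node):
            if not node.children:
                return quote_label(node.label)
            inner = ",".join(rec(ch) for ch in node.children)
            sup = fmt(node.support) if node.support is not None else ""
            return f"({inner}){sup}"

        return rec(self.root) + ";"

    def __repr__(self):
        return (f"<ConsensusTree {len(self.area_labels)} areas, "
                f"{len(self.clades())} clades from {self.n_trees} trees>")


def majority_rule_consensus(trees, cutoff: float = 0.5) -> ConsensusTree:
    """Clades occurring in more than ``cutoff`` of ``trees``, with support.

    All trees must share one leaf-label set (outgroup included).  For
    ``cutoff >= 0.5`` the retained clades are mutually compatible, so they
    assemble into a unique (possibly polytomous) rooted tree.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("no trees to summarise")
    if not 0.5 <= cutoff < 1.0:
        raise ValueError("cutoff must be in [0.5, 1)")
    ref = trees[0]
    labels = ref.labels
    counts = Counter()
    for t in trees:
        if set(t.labels) != set(labels) or t.outgroup_label != ref.outgroup_label:
            diff = sorted(set(t.labels).symmetric_difference(labels))
            raise ValueError(f"mismatched leaf sets in consensus input: {diff}")
        if t.labels == labels:
            counts.update(t.topology_key())
        else:
            pos = {lab: i for i, lab in enumerate(labels)}
            for m in t.topology_key():
                rm = 0
                for i in range(t.n_areas):
                    if m >> i & 1:
                        rm |= 1 << pos[t.labels[i]]
                counts[rm] += 1
    n = len(trees)
    retained = {m: 100.0 * c / n for m, c in counts.items() if c / n > cutoff}
    masks = sorted(retained, key=lambda m: (-m.bit_count(), m))
    for i, a in enumerate(masks):  # guaranteed for cutoff >= 0.5; cheap check
        for b in masks[i + 1:]:
            x = a & b
            if x and x != a and x != b:
                raise AssertionError("incompatible majority clades")
    n_areas = len(labels) - 1
    root = _CNode((1 << n_areas) - 1)
    placed = [root]
    for m in masks:
        parents = [p for p in placed if p.mask & m == m]
        parent = min(parents, key=lambda p: p.mask.bit_count())
        node = _CNode(m, support=round(retained[m], 1))
        parent.children.append(node)
        placed.append(node)
    for i in range(n_areas):
        bit = 1 << i
        parents = [p for p in placed if p.mask & bit]
        parent = min(parents, key=lambda p: p.mask.bit_count())
        parent.children.append(_CNode(bit, label=labels[i]))

    def sort_rec(node):
        for ch in node.children:
            sort_rec(ch)
        node.children.sort(key=lambda ch: (ch.mask & -ch.mask).bit_length())

    sort_rec(root)
    return ConsensusTree(root, labels[:-1], n, cutoff)


def write_newick(tree) -> str:
    """Serialise an :class:`AreaTree` or :class:`ConsensusTree` to Newick."""
    return tree.newick()


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

class ParsimonyEndemicity:
    """Parsimony-analysis-of-endemicity model over an incidence matrix.

    Parameters
    ----------
    matrix
        Species × area incidence matrix.
    drop_uninformative
        Remove species present in fewer than two areas before searching.
        They cannot affect which topology is optimal, only the reported
        length, so the default keeps them.
    """

    def __init__(self, matrix: IncidenceMatrix, drop_uninformative: bool = False,
                 outgroup_label: str = OUTGROUP_LABEL):
        from .incidence import drop_uninformative as _drop

        self.matrix = matrix
        self.removed_species = ()
        if drop_uninformative:
            self.matrix, self.removed_species = _drop(matrix)
        self.outgroup_label = outgroup_label

    def fit(self, replicates: int = 1000, keep: int = 100, seed=None,
            method: str = "heuristic", consensus_over: str = "best-only",
            cutoff: float = 0.5) -> "PAEResults":
        """Search tree space and summarise the result.

        ``consensus_over`` selects the consensus input: ``"best-only"``
        (trees at the global best score; the default) or ``"pooled"``
        (every retained tree, including replicate-best trees that are
        globally suboptimal).
        """
        if method == "heuristic":
            search = heuristic_search(self.matrix, replicates=replicates,
                                      keep=keep, seed=seed,
                                      outgroup_label=self.outgroup_label)
        elif method == "exhaustive":
            search = exhaustive_search(self.matrix,
                                       outgroup_label=self.outgroup_label)
        else:
            raise ValueError(f"unknown method {method!r}")
        if consensus_over == "best-only":
            pool = search.optimal_trees
        elif consensus_over == "pooled":
            pool = search.trees
        else:
            raise ValueError(f"unknown consensus_over {consensus_over!r}")
        consensus = majority_rule_consensus(pool, cutoff=cutoff)
        return PAEResults(self, search, consensus, consensus_over)


class PAEResults:
    """Fitted PAE search: best trees, their length, and the consensus."""

    def __init__(self, model, search: SearchResult, consensus: ConsensusTree,
                 consensus_over: str):
        self.model = model
        self.search = search
        self.consensus = consensus
        self.consensus_over = consensus_over

    @property
    def best_score(self) -> int:
        return self.search.best_score

    def clade_table(self):
        import pandas as pd

        rows = [
            {"clade": "; ".join(sorted(c)), "n_areas": len(c), "support": s}
            for c, s in sorted(self.consensus.clades().items(),
                               key=lambda kv: (-len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows, columns=["clade", "n_areas", "support"])

    def summary(self) -> str:
        m = self.model.matrix
        s = self.search
        lines = [
            "Parsimony Analysis of Endemicity",
            "=" * 40,
            f"areas:                {m.n_areas}",
            f"species (characters): {m.n_species}",
            f"replicates run:       {s.replicates_run}",
            f"best tree length:     {s.best_score}",
            f"trees retained:       {len(s.trees)} "
            f"({len(s.optimal_trees)} at best score)",
            f"consensus over:       {self.consensus_over}",
            "",
            "majority-rule clades (support %):",
        ]
        tab = self.clade_table()
        if tab.empty:
            lines.append("  (none above cutoff — star consensus)")
        else:
            for _, row in tab.iterrows():
                lines.append(f"  {row.support:6.1f}  {row.clade}")
        return "\n".join(lines)
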