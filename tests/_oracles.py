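"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own scoring/consensus code paths:
Fitch lengths are recomputed by enumerating every internal state assignment,
and Newick/NEXUS round trips and consensus trees go through dendropy.
"""

import itertools

import dendropy

from endemicity.trees import edges as _edges


def brute_force_length(adj, n_leaves, leaf_states):
    """Minimum-change length of one binary character by full enumeration.

    ``leaf_states`` maps each leaf id to 0/1.  Every assignment of states to
    internal nodes is scored as the number of edges whose endpoints differ.
    """
    internal = sorted(u for u in adj if u >= n_leaves)
    es = _edges(adj)
    best = None
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(leaf_states)
        cost = sum(st[u] != st[v] for u, v in es)
        if best is None or cost < best:
            best = cost
    return best


def brute_force_matrix_length(tree, matrix):
    """Sum of brute-force per-character lengths, outgroup scored absent."""
    adj = tree.mutable_adj()
    col = {a: i for i, a in enumerate(matrix.area_ids)}
    total = 0
    for s in range(matrix.n_species):
        leaf_states = {
            i: int(matrix.presence[s, col[tree.labels[i]]])
            for i in range(tree.n_areas)
        }
        leaf_states[tree.outgroup] = 0
        total += brute_force_length(adj, tree.n_leaves, leaf_states)
    return total


def newick_clades(newick, outgroup_label):
    """Nontrivial unrooted splits of a Newick string, via dendropy.

    Each split is reported as the frozenset of ingroup leaf labels on the
    side not containing the outgroup.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ingroup = labels - {outgroup_label}
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if outgroup_label in below:
            below = labels - below
        if 2 <= len(below) <= len(ingroup) - 1:
            out.add(frozenset(below))
    return frozenset(out)


def dendropy_majority_clades(newicks, outgroup_label, min_freq=0.5):
    """Majority-rule consensus clade set computed by dendropy."""
    trees = dendropy.TreeList.get(data="\n".join(newicks), schema="newick",
                                  preserve_underscores=True)
    cons = trees.consensus(min_freq=min_freq)
    return newick_clades(cons.as_string(schema="newick").strip(),
                         outgroup_label)


def nexus_matrix_rows(nexus_text):
    """Parse a standard-data NEXUS block with dendropy; taxon -> 0/1 string."""
    data = dendropy.StandardCharacterMatrix.get(data=nexus_text,
                                                schema="nexus",
                                                preserve_underscores=True)
    return {taxon.label: "".join(str(ch) for ch in seq.symbols_as_list())
            for taxon, seq in data.items()}
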