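"""Independent brute-force duplication-loss oracle used only by the tests.

Works on plain nested tuples and adjacency dictionaries rather than the
package's tree classes: leaves are label strings, internal nodes are tuples
of subtrees.  LCA queries walk full ancestor paths, rooting enumerates edges
from an adjacency map — deliberately naive so the oracle shares no logic
with the implementation it checks.
"""

from __future__ import annotations

SEP = "|"


def to_tuples(node):
    """Convert a symscreen TreeNode into nested tuples / leaf-label strings."""
    if not node.children:
        return node.name
    return tuple(to_tuples(c) for c in node.children)


# ---------------------------------------------------------------------------
# rooted DL cost on nested tuples
# ---------------------------------------------------------------------------


def _index_species(stree, parent=None, table=None):
    """Assign an id to every species subtree; record parents and leaf ids."""
    if table is None:
        table = {"parent": {}, "leaf": {}, "n": 0}
    nid = table["n"]
    table["n"] += 1
    table["parent"][nid] = parent
    if isinstance(stree, str):
        table["leaf"][stree] = nid
    else:
        for child in stree:
            _index_species(child, parent=nid, table=table)
    return table


def _ancestors(table, nid):
    path = [nid]
    while table["parent"][path[-1]] is not None:
        path.append(table["parent"][path[-1]])
    return path


def _lca(table, a, b):
    ancestors_a = _ancestors(table, a)
    set_a = set(ancestors_a)
    for nid in _ancestors(table, b):
        if nid in set_a:
            return nid
    raise AssertionError("no common ancestor")


def _depth(table, nid):
    return len(_ancestors(table, nid)) - 1


def oracle_dl_cost(gene_tuple, species_tuple):
    """(dup, loss) of a rooted binary gene tree vs a rooted species tree.

    Gene leaves are 'Species|gene' strings.
    """
    table = _index_species(species_tuple)

    # nested tuples may share identical sub-structure; rebuild as lists so
    # id() keys stay unique and stable during the walk
    def listify(node):
        if isinstance(node, str):
            return [node]
        return [listify(c) for c in node]

    mapping = {}
    events = {}
    dup = 0
    groot = listify(gene_tuple)

    def is_leaf(gnode):
        return isinstance(gnode[0], str)

    def walk2(gnode):
        nonlocal dup
        if is_leaf(gnode):
            species = gnode[0].split(SEP, 1)[0]
            mapping[id(gnode)] = table["leaf"][species]
            return
        for c in gnode:
            walk2(c)
        image = mapping[id(gnode[0])]
        for c in gnode[1:]:
            image = _lca(table, image, mapping[id(c)])
        mapping[id(gnode)] = image
        is_dup = any(mapping[id(c)] == image for c in gnode)
        events[id(gnode)] = "dup" if is_dup else "spec"
        if is_dup:
            dup += 1

    walk2(groot)

    loss = 0

    def count_losses(gnode):
        nonlocal loss
        if is_leaf(gnode):
            return
        for c in gnode:
            d = _depth(table, mapping[id(c)]) - _depth(table, mapping[id(gnode)])
            loss += d if events[id(gnode)] == "dup" else d - 1
            count_losses(c)

    count_losses(groot)
    return dup, loss


# ---------------------------------------------------------------------------
# exhaustive rooting on an adjacency map
# ---------------------------------------------------------------------------


def _adjacency(node, adj, labels, counter):
    nid = counter[0]
    counter[0] += 1
    adj.setdefault(nid, [])
    if not node.children:
        labels[nid] = node.name
    for child in node.children:
        cid = _adjacency(child, adj, labels, counter)
        adj[nid].append(cid)
        adj[cid].append(nid)
    return nid


def _side_leaves(adj, labels, start, banned):
    out = []
    stack = [start]
    seen = {banned, start}
    while stack:
        nid = stack.pop()
        if nid in labels:
            out.append(labels[nid])
        for nb in adj[nid]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return out


def _orient_tuple(adj, labels, nid, came_from):
    kids = [nb for nb in adj[nid] if nb != came_from]
    if not kids:
        return labels[nid]
    return tuple(_orient_tuple(adj, labels, k, nid) for k in kids)


def oracle_root_costs(unrooted_root, species_tuple):
    """Edge-key -> (dup, loss) table for every rooting of an unrooted tree.

    Edge keys are the sorted leaf labels of the smaller bipartition side
    (ties between equal sizes broken lexicographically), matching the
    package's reporting convention.
    """
    adj: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    _adjacency(unrooted_root, adj, labels, [0])
    all_leaves = sorted(labels.values())
    edges = {tuple(sorted((a, b))) for a, nbs in adj.items() for b in nbs}
    table = {}
    for a, b in edges:
        side = sorted(_side_leaves(adj, labels, b, a))
        other = sorted(set(all_leaves) - set(side))
        key = tuple(side if (len(side), side) <= (len(other), other) else other)
        rooted = (
            _orient_tuple(adj, labels, a, b),
            _orient_tuple(adj, labels, b, a),
        )
        table[key] = oracle_dl_cost(rooted, species_tuple)
    return table
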