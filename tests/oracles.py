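"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own fast paths: the Feret oracle is
the O(n^2) pairwise maximum, and the likelihood/marginal oracles enumerate
every joint assignment of internal-node states.
"""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np

from molmorph.ancestral import CTMCParams, transition_matrix


def brute_force_diameter(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _edge_length(nd) -> float:
    return nd.edge.length if nd.edge.length is not None else 1.0


def enum_likelihood(tree: dendropy.Tree, traits: dict, params: CTMCParams):
    """Joint enumeration: returns (log-likelihood, per-internal-node marginals
    keyed by tip bipartition)."""
    nodes = list(tree.postorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    pi = [params.pi0, params.pi1]
    P = {id(nd): transition_matrix(params, _edge_length(nd)) for nd in nodes}
    clade = {}
    for nd in nodes:
        if nd.is_leaf():
            clade[id(nd)] = frozenset([nd.taxon.label])
        else:
            clade[id(nd)] = frozenset().union(*(clade[id(c)] for c in nd.child_nodes()))
    total = 0.0
    marg = {id(nd): np.zeros(2) for nd in internal}
    for assign in itertools.product([0, 1], repeat=len(internal)):
        amap = dict(zip([id(n) for n in internal], assign))
        p = pi[amap[id(tree.seed_node)]]
        for nd in nodes:
            if nd is tree.seed_node:
                continue
            if nd.is_leaf():
                s = traits[nd.taxon.label]
                if s == "?":
                    continue  # sum over both states = row sum = 1 after parent
            else:
                s = amap[id(nd)]
            sp = amap[id(nd.parent_node)]
            p *= P[id(nd)][sp, s]
        total += p
        for nd in internal:
            marg[id(nd)][amap[id(nd)]] += p
    marginals = {clade[i]: m / total for i, m in marg.items()}
    return math.log(total), marginals


def random_small_tree(rng: np.random.Generator, n_tips: int) -> dendropy.Tree:
    """Random topology (by sequential attachment) with random branch lengths."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaves = [tree.seed_node.new_child(), tree.seed_node.new_child()]
    while len(leaves) < n_tips:
        target = leaves[int(rng.integers(len(leaves)))]
        leaves.remove(target)
        leaves.extend([target.new_child(), target.new_child()])
    for i, lf in enumerate(leaves):
        lf.taxon = taxa.new_taxon(label=f"T{i}")
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = float(rng.uniform(0.05, 2.0))
    tree.is_rooted = True
    return tree
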