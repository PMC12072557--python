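"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's own algorithms: likelihoods are
computed by exhaustive enumeration over internal-node state assignments,
and local alignment scores by recursive enumeration of alignment paths.
"""

import itertools
import math
from functools import lru_cache

import numpy as np


def exhaustive_loglik(tree, aln, model):
    """Sum over all internal-node state assignments (flat root prior)."""
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    enc = aln.encode()
    row_of = {rid: i for i, rid in enumerate(aln.ids)}
    P_of = {n: model.transition_matrix(n.edge.length or 0.0) for n in nodes}
    ll = 0.0
    for s in range(aln.n_sites):
        site = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            amap = dict(zip(internals, assign))
            prob = 0.25
            for n in nodes:
                if n is tree.seed_node:
                    continue
                ps = amap[n.parent_node]
                if n.is_leaf():
                    code = enc[row_of[n.taxon.label], s]
                    prob *= 1.0 if code == -1 else P_of[n][ps, code]
                else:
                    prob *= P_of[n][ps, amap[n]]
            site += prob
        ll += math.log(site)
    return ll


def exhaustive_posterior(tree, aln, model, target_node, site):
    """Exact marginal posterior over ACGT at one internal node and site."""
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    enc = aln.encode()
    row_of = {rid: i for i, rid in enumerate(aln.ids)}
    P_of = {n: model.transition_matrix(n.edge.length or 0.0) for n in nodes}
    joint = np.zeros(4)
    for assign in itertools.product(range(4), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        prob = 0.25
        for n in nodes:
            if n is tree.seed_node:
                continue
            ps = amap[n.parent_node]
            if n.is_leaf():
                code = enc[row_of[n.taxon.label], site]
                prob *= 1.0 if code == -1 else P_of[n][ps, code]
            else:
                prob *= P_of[n][ps, amap[n]]
        joint[amap[target_node]] += prob
    return joint / joint.sum()


def brute_local_score(a, b, scoring):
    """Best local alignment score by recursive enumeration of paths.

    States: 0 = free (can stop/start), 1 = in gap consuming a, 2 = in gap
    consuming b. Enumerates every start pair and every path; exponential,
    only for short sequences.
    """

    @lru_cache(maxsize=None)
    def best_from(i, j, state):
        # best score of an alignment continuing at a[i:], b[j:], given the
        # previous column's state; alignment may stop here (score 0)
        options = [0.0]
        if i < len(a) and j < len(b):
            options.append(scoring.score(a[i], b[j]) + best_from(i + 1, j + 1, 0))
        if i < len(a):
            cost = scoring.gap_extend if state == 1 else scoring.gap_open
            options.append(cost + best_from(i + 1, j, 1))
        if j < len(b):
            cost = scoring.gap_extend if state == 2 else scoring.gap_open
            options.append(cost + best_from(i, j + 1, 2))
        return max(options)

    best = 0.0
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            best = max(best, best_from(i, j, 0))
    return best


def random_additive_tree(n_taxa, rng):
    """Random binary topology with branch lengths in [0.5, 2] and its
    exact additive distance matrix (path lengths)."""
    import dendropy
    import pandas as pd

    labels = [f"T{i}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        u = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            u.add_child(child)
            child.edge.length = float(rng.uniform(0.5, 2.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [u]
    root = dendropy.Node()
    for child in nodes:
        root.add_child(child)
        child.edge.length = float(rng.uniform(0.5, 2.0))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False

    # path-length distances by accumulating depths from each leaf
    pdm = tree.phylogenetic_distance_matrix()
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    for t1 in taxa:
        for t2 in taxa:
            if t1 is not t2:
                D.loc[t1.label, t2.label] = pdm.patristic_distance(t1, t2)
    return tree, D
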