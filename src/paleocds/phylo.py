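"""Distance-based phylogenetics under the Kimura 2-parameter model.

The K2P (K80) model assumes equal base frequencies (1/4 each) and two rate
classes: transitions (A<->G, C<->T) at rate ratio kappa relative to
transversions. Branch lengths are in expected substitutions per site.

Provided here: pairwise K2P distances, neighbor-joining tree construction
with nonparametric bootstrap support, the pruning (Felsenstein) algorithm
for the K2P log-likelihood of an alignment on a tree, marginal maximum
likelihood reconstruction of ancestral sequences on a rooted tree, and a
1-D maximum likelihood estimate of kappa.

Trees are ``dendropy.Tree`` objects; leaves are matched to alignment rows
by taxon label.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# transition partner of each base (A<->G, C<->T)
_TS_PARTNER = {0: 2, 1: 3, 2: 0, 3: 1}

KAPPA_BOUNDS = (0.05, 50.0)


class SaturationError(ValueError):
    """Observed divergence too high for a finite K2P distance."""


class RootingError(ValueError):
    """Operation requires a rooted (bifurcating-root) tree."""


@dataclass(frozen=True)
class K2PModel:
    """Kimura 2-parameter substitution model (equal base frequencies)."""

    kappa: float = 2.0

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t): 4x4 substitution probabilities over a branch of length t,
        base order ACGT, rows summing to 1. Rates are normalized so that t
        is the expected number of substitutions per site."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        kappa = self.kappa
        beta = 1.0 / (kappa + 2.0)
        alpha = kappa * beta
        e4 = math.exp(-4.0 * beta * t)
        e2 = math.exp(-2.0 * (alpha + beta) * t)
        p_same = 0.25 + 0.25 * e4 + 0.5 * e2
        p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
        p_tv = 0.25 - 0.25 * e4
        P = np.full((4, 4), p_tv)
        for i in range(4):
            P[i, i] = p_same
            P[i, _TS_PARTNER[i]] = p_ts
        return P


@dataclass(frozen=True)
class SiteAlignment:
    """Equal-length rows of {A,C,G,T,N} keyed by sequence id."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - set("ACGTN")
            if bad:
                raise ValueError(f"row {rid!r}: invalid characters {sorted(bad)}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")

    @classmethod
    def from_sequences(cls, seqs) -> "SiteAlignment":
        """Build from CodingSequence objects or an id -> sequence mapping."""
        if isinstance(seqs, dict):
            items = list(seqs.items())
        else:
            items = [(s.id, s.seq) for s in seqs]
        return cls(ids=tuple(i for i, _ in items), rows=tuple(s for _, s in items))

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def encode(self) -> np.ndarray:
        """(n_rows, n_sites) int array; ACGT -> 0..3, N -> -1."""
        lut = np.full(128, -1, dtype=np.int8)
        for b, i in _BASE_INDEX.items():
            lut[ord(b)] = i
        return np.vstack(
            [lut[np.frombuffer(r.encode(), dtype=np.uint8)] for r in self.rows]
        )

    def resample_columns(self, rng: np.random.Generator) -> "SiteAlignment":
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return SiteAlignment(ids=self.ids, rows=rows)


# --- distances -----------------------------------------------------------


def k2p_distance(a: str, b: str) -> float:
    """K2P distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).

    P and Q are the transition and transversion proportions over sites
    where both sequences have an unambiguous base; N sites are excluded
    pairwise. Raises :class:`SaturationError` when a log argument is <= 0.
    """
    if len(a) != len(b):
        raise ValueError(f"lengths differ ({len(a)} vs {len(b)})")
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            continue
        n += 1
        if x != y:
            if _BASE_INDEX[y] == _TS_PARTNER[_BASE_INDEX[x]]:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites (all masked)")
    P, Q = ts / n, tv / n
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError(
            f"saturated divergence (P={P:.3f}, Q={Q:.3f}); distance undefined"
        )
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def distance_matrix(aln: SiteAlignment) -> pd.DataFrame:
    """Symmetric K2P distance matrix over all alignment rows."""
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(aln.rows[i], aln.rows[j])
    return pd.DataFrame(d, index=aln.ids, columns=aln.ids)


# --- neighbor joining ----------------------------------------------------


def nj_tree(dist: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Returns an unrooted tree (trifurcating seed node). Negative estimated
    branch lengths are clamped to zero. Ties in the Q criterion are broken
    by (row, column) index for determinism.
    """
    labels = list(dist.index)
    D = np.asarray(dist, dtype=float)
    if D.shape[0] != D.shape[1] or list(dist.columns) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must have zero diagonal")
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    D = D.copy()
    active = list(range(len(labels)))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        di = 0.5 * sub[i_, j_] + (r[i_] - r[j_]) / (2.0 * (m - 2))
        dj = sub[i_, j_] - di
        u = dendropy.Node()
        for child, length in ((nodes[active[i_]], di), (nodes[active[j_]], dj)):
            u.add_child(child)
            child.edge.length = max(0.0, length)
        new_d = 0.5 * (sub[i_, :] + sub[j_, :] - sub[i_, j_])
        # grow D with the new node's distances
        D = np.pad(D, ((0, 1), (0, 1)))
        new_idx = D.shape[0] - 1
        for k_pos, k in enumerate(active):
            D[new_idx, k] = D[k, new_idx] = new_d[k_pos]
        nodes.append(u)
        removed = {active[i_], active[j_]}
        active = [k for k in active if k not in removed] + [new_idx]

    # join the last three nodes at an unrooted center
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    center = dendropy.Node()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(0.0, length)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of leaf labels.

    Each internal edge splits the leaves in two; the side not containing
    the alphabetically first label is the canonical representation, making
    the set comparable across differently rooted copies of a topology.
    """
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    anchor = min(leaves)
    bips = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = leaves - below if anchor in below else below
        if 1 < len(side) < len(leaves) - 1:
            bips.add(frozenset(side))
    return bips


@dataclass
class BootstrapResult:
    """NJ tree with bootstrap supports on its internal bipartitions."""

    tree: dendropy.Tree
    supports: dict[frozenset, float]
    n_reps: int
    degenerate: bool = False


def bootstrap_support(
    aln: SiteAlignment, n_reps: int, seed: int
) -> BootstrapResult:
    """Nonparametric bootstrap over alignment columns.

    Rebuilds the K2P/NJ tree for each column resample (replicate r uses
    seed + r) and reports, for each internal bipartition of the full-data
    tree, the percentage of replicates containing it. Supports are written
    onto the tree's internal node labels. An alignment with no variable
    site yields an arbitrary topology and is flagged degenerate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base_tree = nj_tree(distance_matrix(aln))
    base_bips = tree_bipartitions(base_tree)
    counts = {bip: 0 for bip in base_bips}
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        rep = aln.resample_columns(rng)
        rep_bips = tree_bipartitions(nj_tree(distance_matrix(rep)))
        for bip in base_bips:
            if bip in rep_bips:
                counts[bip] += 1
    supports = {bip: 100.0 * c / n_reps for bip, c in counts.items()}

    leaves = {leaf.taxon.label for leaf in base_tree.leaf_node_iter()}
    anchor = min(leaves)
    for node in base_tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = frozenset(leaves - below) if anchor in below else below
        if side in supports:
            node.label = f"{supports[side]:g}"
    degenerate = all(a == b for a in aln.rows for b in aln.rows)
    return BootstrapResult(
        tree=base_tree, supports=supports, n_reps=n_reps, degenerate=degenerate
    )


# --- likelihood and ancestral reconstruction -----------------------------


def _leaf_partials(aln: SiteAlignment) -> dict[str, np.ndarray]:
    """Per-leaf (n_sites, 4) indicator partials; N -> all-ones (missing)."""
    enc = aln.encode()
    partials = {}
    for rid, codes in zip(aln.ids, enc):
        p = np.zeros((len(codes), 4))
        known = codes >= 0
        p[known, codes[known]] = 1.0
        p[~known, :] = 1.0
        partials[rid] = p
    return partials


def _check_tree_alignment(tree: dendropy.Tree, aln: SiteAlignment) -> None:
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    if leaf_labels != set(aln.ids):
        raise ValueError(
            f"tree leaves {sorted(leaf_labels)} != alignment rows {sorted(aln.ids)}"
        )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")


def _edge_len(node: dendropy.Node) -> float:
    return node.edge.length or 0.0


def _down_partials(
    tree: dendropy.Tree, aln: SiteAlignment, model: K2PModel
) -> dict[dendropy.Node, np.ndarray]:
    """Post-order conditional likelihoods: D[v][site, x] = P(data below v | v=x)."""
    leaf_p = _leaf_partials(aln)
    down: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            down[node] = leaf_p[node.taxon.label]
        else:
            prod = None
            for child in node.child_nodes():
                P = model.transition_matrix(_edge_len(child))
                contrib = down[child] @ P.T
                prod = contrib if prod is None else prod * contrib
            down[node] = prod
    return down


def pruning_loglik(
    tree: dendropy.Tree, aln: SiteAlignment, model: K2PModel
) -> float:
    """Log-likelihood of the alignment on the tree via the pruning algorithm.

    N is treated as fully missing data. Works for rooted and unrooted
    (trifurcating-seed) trees; by reversibility the result is independent
    of the root position.
    """
    _check_tree_alignment(tree, aln)
    down = _down_partials(tree, aln, model)
    site_lik = down[tree.seed_node] @ np.full(4, 0.25)
    if np.any(site_lik <= 0):  # pragma: no cover - defensive
        return -math.inf
    return float(np.log(site_lik).sum())


@dataclass
class AncestralReconstruction:
    """Marginal ML ancestral states for the internal nodes of a rooted tree.

    ``sequences`` maps internal-node label -> argmax sequence; ``posteriors``
    maps label -> (n_sites, 4) posterior over ACGT; ``ties`` maps label ->
    boolean array flagging sites where the argmax was tied (broken
    alphabetically).
    """

    sequences: dict[str, str]
    posteriors: dict[str, np.ndarray]
    ties: dict[str, np.ndarray]


def label_internal_nodes(tree: dendropy.Tree) -> None:
    """Assign labels node0, node1, ... (preorder) to unlabeled internal nodes."""
    i = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            node.label = f"node{i}"
        i += not node.is_leaf()


def ancestral_states(
    tree: dendropy.Tree, aln: SiteAlignment, model: K2PModel
) -> AncestralReconstruction:
    """Marginal ML reconstruction at every internal node of a rooted tree.

    Per site and node the posterior over {A,C,G,T} combines the partial
    likelihoods below the node (post-order pass) with those from the rest
    of the tree (pre-order pass). The reported state is the argmax; exact
    ties are broken alphabetically and flagged.
    """
    if len(tree.seed_node.child_nodes()) != 2:
        raise RootingError(
            "tree must be rooted (bifurcating seed node); use root_at_outgroup"
        )
    _check_tree_alignment(tree, aln)
    label_internal_nodes(tree)
    down = _down_partials(tree, aln, model)
    n_sites = aln.n_sites
    pi = np.full(4, 0.25)

    # pre-order pass: up[v][site, x] = P(data outside subtree(v) | v=x) * pi-part
    up: dict[dendropy.Node, np.ndarray] = {tree.seed_node: np.tile(pi, (n_sites, 1))}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            outer = up[node].copy()
            for sib in node.child_nodes():
                if sib is child:
                    continue
                P = model.transition_matrix(_edge_len(sib))
                outer *= down[sib] @ P.T
            P = model.transition_matrix(_edge_len(child))
            up[child] = outer @ P
    sequences, posteriors, ties = {}, {}, {}
    base_arr = np.array(list(BASES))
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        joint = up[node] * down[node]
        post = joint / joint.sum(axis=1, keepdims=True)
        argmax = post.argmax(axis=1)  # first (alphabetical) index on ties
        tie = (post == post.max(axis=1, keepdims=True)).sum(axis=1) > 1
        sequences[node.label] = "".join(base_arr[argmax])
        posteriors[node.label] = post
        ties[node.label] = tie
    return AncestralReconstruction(sequences=sequences, posteriors=posteriors, ties=ties)


def root_at_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root the tree at the midpoint of the outgroup's terminal edge."""
    leaf = None
    for l in tree.leaf_node_iter():
        if l.taxon.label == outgroup_label:
            leaf = l
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup_label!r} not among leaves")
    length = _edge_len(leaf)
    tree.reroot_at_edge(leaf.edge, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    return tree


def estimate_kappa(aln: SiteAlignment, tree: dendropy.Tree) -> float:
    """ML estimate of kappa by bounded 1-D search over the pruning likelihood.

    A degenerate alignment (no variable site) returns the default kappa of
    2.0 with a warning; an estimate at the upper search bound (e.g. no
    observed transversions) is flagged with a warning.
    """
    if all(r == aln.rows[0] for r in aln.rows):
        warnings.warn("alignment has no variation; returning default kappa 2.0")
        return 2.0
    res = minimize_scalar(
        lambda k: -pruning_loglik(tree, aln, K2PModel(kappa=k)),
        bounds=KAPPA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-4},
    )
    est = float(res.x)
    if est > KAPPA_BOUNDS[1] * 0.98:
        warnings.warn(
            f"kappa estimate {est:.2f} at upper search bound "
            f"{KAPPA_BOUNDS[1]} (no transversions observed?)"
        )
    return est


# --- newick I/O ----------------------------------------------------------


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True
    )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
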