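"""Tree-based generative model of single-axon brain-region targeting.

A single long-range axon innervates a *subset* of the regions its source
population projects to; that subset is its projection type (p-type).  The
model places all regions (both hemispheres) at the leaves of a tree whose
edges carry direction-specific crossing probabilities.  An axon starts at
its source leaf and percolates outward: each directed edge reached is
crossed independently with its probability, and an edge not crossed stays
closed forever.  Leaves reached are innervated.

With edge length defined as -log10(probability), first-order innervation
probabilities are 10^-L(S,T) along the unique path, and the conditional
increase in innervation probability of one target given another is
10^L(S,m), where m is the node at which the paths from the source to the
two targets diverge (the lowest common ancestor of the target pair whenever
the source lies outside their common subtree).  The increase is always >= 1:
co-innervation can only be positively correlated under this model.

The tree topology is derived from the matrix of normalized connection
densities via community detection at successively coarser resolution; edge
lengths are then fitted leaf-to-root from the matrix of -log10 predicted
innervation probabilities in local sibling/parent motifs, by least squares.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import networkx as nx
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom, ks_2samp

from ._rng import keyed_rng, keyed_seed

__all__ = [
    "EPSILON",
    "K_CLASS",
    "PTypeTree",
    "innervation_probability",
    "build_tree_topology",
    "fit_edge_probabilities",
    "path_probability",
    "conditional_increase",
    "sample_innervation_profiles",
    "sample_naive_profiles",
    "test_pairwise_independence",
    "compare_hamming_distributions",
    "random_tree",
    "pathlength_matrix",
    "enumerate_profile_distribution",
    "num_possible_ptypes",
    "num_region_pairs",
]

EPSILON = 1e-6
MAX_LENGTH = -np.log10(EPSILON)  # 6.0

#: class-specific proportionality constants of P = k * sqrt(nps)
K_CLASS = {"L23": 0.5, "L6": 0.5, "L4": 0.33, "L5PT": 0.33, "L5IT": 0.22}


def num_possible_ptypes(n_targets: int) -> int:
    """Number of distinct innervation subsets of ``n_targets`` regions."""
    return 2 ** int(n_targets)


def num_region_pairs(n_regions: int) -> int:
    """Number of unordered target-region pairs."""
    n = int(n_regions)
    return n * (n - 1) // 2


# --------------------------------------------------------------------------
# tree container
# --------------------------------------------------------------------------

@dataclass
class PTypeTree:
    """Directed tree over region leaves with per-edge crossing probabilities.

    ``children`` maps each inner node to its children; each undirected link
    carries two directed lengths (child->parent and parent->child),
    ``lengths[(u, v)] = -log10 p(u -> v)``, clamped to [0, -log10 eps].
    """

    leaves: list
    children: dict
    root: object
    lengths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parent = {}
        for node, kids in self.children.items():
            for k in kids:
                if k in self.parent:
                    raise ValueError(f"node {k!r} has two parents")
                self.parent[k] = node
        # fill unset lengths with 0 (probability 1)
        for u, v in self.edges():
            self.lengths.setdefault((u, v), 0.0)
            self.lengths.setdefault((v, u), 0.0)
        self._check_connected()

    def _check_connected(self) -> None:
        seen = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n in seen:
                raise ValueError("cycle in tree")
            seen.add(n)
            stack.extend(self.children.get(n, []))
        missing = [l for l in self.leaves if l not in seen]
        if missing:
            raise ValueError(f"leaves not reachable from root: {missing}")

    def edges(self):
        """Undirected skeleton as (child, parent) pairs."""
        return [(k, p) for k, p in self.parent.items()]

    def nodes(self):
        out = [self.root]
        stack = [self.root]
        while stack:
            n = stack.pop()
            for k in self.children.get(n, []):
                out.append(k)
                stack.append(k)
        return out

    def set_probability(self, u, v, p: float) -> None:
        p = min(1.0, max(float(p), EPSILON))
        self.lengths[(u, v)] = -np.log10(p)

    def probability(self, u, v) -> float:
        return 10.0 ** (-self.lengths[(u, v)])

    def path_nodes(self, a, b) -> list:
        """Node sequence of the unique path from a to b."""
        up_a, node = [a], a
        while node in self.parent:
            node = self.parent[node]
            up_a.append(node)
        up_b, node = [b], b
        while node in self.parent:
            node = self.parent[node]
            up_b.append(node)
        set_a = {n: i for i, n in enumerate(up_a)}
        for j, n in enumerate(up_b):
            if n in set_a:
                return up_a[: set_a[n] + 1] + up_b[:j][::-1]
        raise ValueError("nodes are not connected")

    def lca(self, a, b):
        path = self.path_nodes(a, b)
        # the apex of the path is its highest node
        depth = self._depths()
        return min(path, key=lambda n: depth[n])

    def _depths(self) -> dict:
        depth = {self.root: 0}
        stack = [self.root]
        while stack:
            n = stack.pop()
            for k in self.children.get(n, []):
                depth[k] = depth[n] + 1
                stack.append(k)
        return depth

    def path_length(self, a, b) -> float:
        """Sum of directed edge lengths traveling from a to b."""
        path = self.path_nodes(a, b)
        return float(sum(self.lengths[(u, v)] for u, v in zip(path, path[1:])))

    def divergence_node(self, s, t1, t2):
        """Node at which the paths s->t1 and s->t2 part ways."""
        p1 = self.path_nodes(s, t1)
        p2 = self.path_nodes(s, t2)
        m = s
        for u, v in zip(p1, p2):
            if u != v:
                break
            m = u
        return m

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "leaves": [str(l) for l in self.leaves],
            "root": str(self.root),
            "children": {str(k): [str(c) for c in v]
                         for k, v in self.children.items()},
            "lengths": [[str(u), str(v), self.lengths[(u, v)]]
                        for u, v in self.lengths],
        })

    @classmethod
    def from_json(cls, text: str) -> "PTypeTree":
        d = json.loads(text)
        return cls(
            leaves=d["leaves"], root=d["root"],
            children={k: list(v) for k, v in d["children"].items()},
            lengths={(u, v): float(w) for u, v, w in d["lengths"]},
        )

    def to_newick(self) -> str:
        """Newick string; edge comments carry the two directed crossing
        probabilities [up=p(child->parent),down=p(parent->child)]."""

        def fmt(node):
            kids = self.children.get(node, [])
            label = str(node)
            if not kids:
                inner = label
            else:
                inner = "(" + ",".join(fmt(k) for k in kids) + ")" + label
            if node in self.parent:
                p = self.parent[node]
                up = self.probability(node, p)
                down = self.probability(p, node)
                return f"{inner}:{self.lengths[(node, p)]:.6g}[&&up={up:.6g},down={down:.6g}]"
            return inner

        return fmt(self.root) + ";"


# --------------------------------------------------------------------------
# first-order probabilities
# --------------------------------------------------------------------------

def innervation_probability(nps: float, projection_class: str) -> float:
    """Predicted single-axon innervation probability, min(1, k * sqrt(nps)).

    ``nps`` is the normalized projection strength (axon amount in the target
    over source-region volume); ``k`` depends on the projection class.
    """
    if nps < 0:
        raise ValueError("nps must be >= 0")
    try:
        k = K_CLASS[projection_class]
    except KeyError:
        raise ValueError(f"unknown projection class {projection_class!r}") from None
    return min(1.0, k * float(np.sqrt(nps)))


# --------------------------------------------------------------------------
# topology from community detection
# --------------------------------------------------------------------------

def build_tree_topology(
    ncd: pd.DataFrame,
    gamma_start: float = 6.0,
    gamma_step: float = 0.05,
    seed: int = 0,
) -> PTypeTree:
    """Derive the tree skeleton from normalized connection densities.

    The (symmetrized) density matrix is clustered with the Louvain
    heuristic while the resolution parameter gamma is lowered from
    ``gamma_start`` to 0; every region starts as its own leaf, and a pair of
    active communities is merged under a new inner node whenever a detected
    community contains more than half of the regions of each.  The root is
    placed when gamma reaches 0 and everything has merged.  Simultaneous
    merges are processed in lexicographic region order; community detection
    is seeded, so the result is deterministic.
    """
    if ncd.shape[0] == 0:
        raise ValueError("empty density matrix")
    regions = list(ncd.index)
    if list(ncd.columns) != regions:
        raise ValueError("matrix must be square with matching labels")
    sym = (ncd.values + ncd.values.T) / 2.0
    graph = nx.Graph()
    graph.add_nodes_from(range(len(regions)))
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            if sym[i, j] > 0:
                graph.add_edge(i, j, weight=float(sym[i, j]))

    active = {r: {i} for i, r in enumerate(regions)}  # node -> region indices
    children: dict = {}
    counter = 0

    def merge_pair(a, b):
        nonlocal counter
        counter += 1
        new = f"n{counter}"
        children[new] = [a, b]
        active[new] = active.pop(a) | active.pop(b)
        return new

    def sort_key(node):
        return min(str(regions[i]) for i in active[node])

    schedule = np.arange(gamma_start, -gamma_step / 2, -gamma_step)
    for gamma in schedule:
        if len(active) == 1:
            break
        comms = nx.community.louvain_communities(
            graph, weight="weight", resolution=float(max(gamma, 0.0)),
            seed=keyed_seed(seed, "louvain", round(float(gamma) * 1000)),
        )
        for comm in sorted(comms, key=lambda c: min(str(regions[i]) for i in c)):
            members = [
                node for node, regs in active.items()
                if len(regs & comm) * 2 > len(regs)
            ]
            if len(members) < 2:
                continue
            members.sort(key=sort_key)
            acc = members[0]
            for other in members[1:]:
                acc = merge_pair(acc, other)
    # gamma = 0 merges everything; guard in case the heuristic left stragglers
    remaining = sorted(active, key=sort_key)
    acc = remaining[0]
    for other in remaining[1:]:
        acc = merge_pair(acc, other)
    return PTypeTree(leaves=regions, children=children, root=acc)


# --------------------------------------------------------------------------
# edge-length fitting
# --------------------------------------------------------------------------

def fit_edge_probabilities(
    skeleton: PTypeTree,
    m_matrix: pd.DataFrame,
    epsilon: float = EPSILON,
) -> PTypeTree:
    """Fit directed edge lengths from -log10 innervation probabilities.

    Recursive leaf-to-root pass: for each sibling pair (T1, T2) with parent
    R the four directed motif lengths solve, in the least-squares sense,

        w1 - w2 = mean_x (D[T1, x] - D[T2, x])      (row differences)
        v1 - v2 = mean_x (D[x, T1] - D[x, T2])      (column differences)
        w1 + v2 = D[T1, T2]
        w2 + v1 = D[T2, T1]

    where D is the working distance matrix between active nodes (initially
    ``m_matrix`` over leaves) and x ranges over active nodes outside the
    motif.  The system is structurally rank deficient along the direction
    (1, 1, -1, -1); the residual-minimizing family is resolved by shifting
    the minimum-norm solution along that direction into the nonnegative
    orthant when feasible (the shift telescopes exactly through the
    inherited parent distances, so leaf-to-leaf path lengths are preserved).
    Remaining negative lengths are clamped to 0 and probabilities to
    [epsilon, 1].  Infinite / missing entries are replaced by
    -log10(epsilon) before fitting.
    """
    max_len = -np.log10(epsilon)
    leaves = skeleton.leaves
    m = m_matrix.reindex(index=leaves, columns=leaves).astype(float)
    vals = m.values.copy()
    vals[~np.isfinite(vals)] = max_len
    np.fill_diagonal(vals, 0.0)

    # working distances between active nodes
    dist: dict = {}
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            if a != b:
                dist[(a, b)] = vals[i, j]
    active = set(leaves)

    lengths: dict = {}
    order = _postorder_internal(skeleton)
    for node in order:
        kids = skeleton.children[node]
        if len(kids) != 2:
            raise ValueError("edge fitting requires a binary skeleton")
        t1, t2 = kids
        refs = [x for x in active if x not in (t1, t2)]
        rows = []
        rhs = []
        if refs:
            a = float(np.mean([dist[(t1, x)] - dist[(t2, x)] for x in refs]))
            b = float(np.mean([dist[(x, t1)] - dist[(x, t2)] for x in refs]))
            rows += [[1, -1, 0, 0], [0, 0, 1, -1]]
            rhs += [a, b]
        rows += [[1, 0, 0, 1], [0, 1, 1, 0]]
        rhs += [dist[(t1, t2)], dist[(t2, t1)]]
        sol, *_ = np.linalg.lstsq(np.asarray(rows, float), np.asarray(rhs, float),
                                  rcond=None)
        w1, w2, v1, v2 = _shift_nonnegative(sol)
        lengths[(t1, node)] = w1
        lengths[(t2, node)] = w2
        lengths[(node, t1)] = v1
        lengths[(node, t2)] = v2
        for x in refs:
            dist[(node, x)] = (dist[(t1, x)] - w1 + dist[(t2, x)] - w2) / 2.0
            dist[(x, node)] = (dist[(x, t1)] - v1 + dist[(x, t2)] - v2) / 2.0
        active -= {t1, t2}
        active.add(node)

    lengths = _gauge_repair(skeleton, lengths)
    clamped = {k: float(np.clip(v, 0.0, max_len)) for k, v in lengths.items()}
    return PTypeTree(leaves=leaves, children=dict(skeleton.children),
                     root=skeleton.root, lengths=clamped)


def _gauge_repair(skeleton: PTypeTree, lengths: dict) -> dict:
    """Redistribute length between parent and child edges to remove negative
    fitted lengths without changing any leaf-to-leaf path length.

    For every inner node X there is a gauge parameter s_X: adding s to the
    up-length of X's parent edge, subtracting it from the up-lengths of X's
    child edges, and doing the opposite for the down-lengths leaves all
    leaf-to-leaf sums invariant.  Nonnegativity of every directed length is
    a system of difference constraints ``-down(X,c) <= s_X - s_c <=
    up(c,X)`` (s fixed at 0 on leaves), solved by Bellman-Ford relaxation;
    it is feasible whenever the fitted distances are realizable with
    nonnegative lengths, in particular for input generated from a true
    tree.  If infeasible (inconsistent input), the best attained potentials
    are used and any remaining negatives are left to the final clamp.
    """
    if all(v >= 0 for v in lengths.values()):
        return lengths
    parent = {}
    for node, kids in skeleton.children.items():
        for k in kids:
            parent[k] = node
    nodes = list(skeleton.children) + list(skeleton.leaves) + ["__ref__"]
    # difference-constraint edges: x_a - x_b <= w  ->  edge (b, a, w)
    cons = []
    for c, x in parent.items():
        cons.append((c, x, lengths[(c, x)]))       # s_X - s_c <= up(c, X)
        cons.append((x, c, lengths[(x, c)]))       # s_c - s_X <= down(X, c)
    for leaf in skeleton.leaves:
        cons.append(("__ref__", leaf, 0.0))
        cons.append((leaf, "__ref__", 0.0))
    dist = {n: 0.0 for n in nodes}
    feasible = True
    for it in range(len(nodes) + 1):
        changed = False
        for b, a, w in cons:
            if dist[b] + w < dist[a] - 1e-12:
                dist[a] = dist[b] + w
                changed = True
        if not changed:
            break
    else:
        feasible = False
    if not feasible:
        warnings.warn("no nonnegative length assignment reproduces the fitted "
                      "distances exactly; residual negatives will be clamped")
    ref = dist["__ref__"]
    s = {n: dist[n] - ref for n in nodes}
    out = {}
    for c, x in parent.items():
        out[(c, x)] = lengths[(c, x)] + s[c] - s[x]
        out[(x, c)] = lengths[(x, c)] + s[x] - s[c]
    return out


def _postorder_internal(tree: PTypeTree) -> list:
    out = []

    def walk(node):
        for k in tree.children.get(node, []):
            walk(k)
        if node in tree.children:
            out.append(node)

    walk(tree.root)
    return out


def _shift_nonnegative(sol: np.ndarray) -> np.ndarray:
    """Shift along the null direction (1, 1, -1, -1)/2 toward nonnegativity.

    Leaves the least-squares residual unchanged; if full nonnegativity is
    infeasible the shift is clamped to the nearest end of the feasible
    interval.
    """
    w1, w2, v1, v2 = sol
    lo = max(-w1, -w2)
    hi = min(v1, v2)
    if lo > hi:
        # locally infeasible; the global gauge repair handles leftovers
        t = (lo + hi) / 2.0
    else:
        t = float(np.clip(0.0, lo, hi))
    return np.array([w1 + t, w2 + t, v1 - t, v2 - t])


# --------------------------------------------------------------------------
# closed-form predictions
# --------------------------------------------------------------------------

def path_probability(tree: PTypeTree, source, target) -> float:
    """First-order probability that an axon from ``source`` innervates
    ``target``: 10^-L along the unique path."""
    if source == target:
        raise ValueError("within-region innervation is local connectivity, "
                         "not covered by the p-type model")
    return 10.0 ** (-tree.path_length(source, target))


def conditional_increase(tree: PTypeTree, source, t1, t2) -> float:
    """Factor by which innervation of ``t1`` becomes more likely given that
    ``t2`` is innervated: 10^L(source -> divergence node).

    The divergence node equals lca(t1, t2) whenever the source lies outside
    the subtree below that ancestor.  Symmetric in (t1, t2); always >= 1
    for nonnegative lengths.
    """
    if len({source, t1, t2}) != 3:
        raise ValueError("source and both targets must be distinct")
    m = tree.divergence_node(source, t1, t2)
    return 10.0 ** tree.path_length(source, m)


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def _bfs_directed_edges(tree: PTypeTree, source) -> list:
    """Directed edges of the tree in breadth-first order away from source."""
    neighbors: dict = {}
    for child, par in tree.parent.items():
        neighbors.setdefault(child, []).append(par)
        neighbors.setdefault(par, []).append(child)
    seen = {source}
    frontier = [source]
    edges = []
    while frontier:
        nxt = []
        for u in frontier:
            for v in neighbors.get(u, []):
                if v not in seen:
                    seen.add(v)
                    edges.append((u, v))
                    nxt.append(v)
        frontier = nxt
    return edges


def sample_innervation_profiles(
    tree: PTypeTree, source, n: int, seed: int = 0
) -> pd.DataFrame:
    """Sample ``n`` binary innervation profiles by edge percolation.

    Starting at the source leaf, each directed edge reached is crossed with
    its associated probability (one independent Bernoulli draw per edge and
    axon); an edge not crossed stays closed.  Columns are all leaves in tree
    order; the source-region column is fixed at 0 (an axon trivially
    occupies its own region).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if source not in tree.leaves:
        raise ValueError(f"unknown source region {source!r}")
    rng = keyed_rng(seed, "ptype-sampling", source)
    edges = _bfs_directed_edges(tree, source)
    reached = {source: np.ones(n, dtype=bool)}
    for u, v in edges:
        p = tree.probability(u, v)
        crossed = rng.random(n) < p
        reached[v] = reached[u] & crossed
    data = {
        leaf: (reached.get(leaf, np.zeros(n, dtype=bool)).astype(np.int8)
               if leaf != source else np.zeros(n, dtype=np.int8))
        for leaf in tree.leaves
    }
    return pd.DataFrame(data, columns=list(tree.leaves))


def sample_naive_profiles(probabilities: pd.Series, n: int, seed: int = 0
                          ) -> pd.DataFrame:
    """Control model: independent Bernoulli draws at the first-order
    innervation probabilities, ignoring all interactions."""
    rng = keyed_rng(seed, "naive-sampling")
    p = probabilities.values.astype(float)
    draws = (rng.random((n, len(p))) < p).astype(np.int8)
    return pd.DataFrame(draws, columns=list(probabilities.index))


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def test_pairwise_independence(matrix: pd.DataFrame, region_a, region_b,
                               alpha: float = 0.05) -> dict:
    """Two-tailed hypergeometric test of independent innervation.

    Under independence the overlap between the ``n_a`` axons innervating a
    and the ``n_b`` innervating b follows the hypergeometric distribution
    with parameters (N, n_a, n_b).  The null is rejected when the observed
    overlap falls within the first or last alpha/2 tail.  The observed
    conditional increase is (overlap / n_b) / (n_a / N).
    """
    col_a = np.asarray(matrix[region_a], dtype=bool)
    col_b = np.asarray(matrix[region_b], dtype=bool)
    n_tot = len(col_a)
    if n_tot < 1:
        raise ValueError("need at least one axon")
    n_a, n_b = int(col_a.sum()), int(col_b.sum())
    overlap = int((col_a & col_b).sum())
    if n_a == 0 or n_b == 0:
        return {"p_value": 1.0, "increase": np.nan, "overlap": overlap,
                "reject": False, "flagged": True}
    dist = hypergeom(n_tot, n_a, n_b)
    p_low = float(dist.cdf(overlap))
    p_high = float(dist.sf(overlap - 1))
    p = min(1.0, 2.0 * min(p_low, p_high))
    increase = (overlap / n_b) / (n_a / n_tot)
    return {"p_value": p, "increase": float(increase), "overlap": overlap,
            "reject": bool(p < alpha), "flagged": False}


def compare_hamming_distributions(profiles_a: pd.DataFrame,
                                  profiles_b: pd.DataFrame) -> dict:
    """Pairwise Hamming distances within each profile set and a two-sample
    KS test between the two distance distributions."""
    if list(profiles_a.columns) != list(profiles_b.columns):
        raise ValueError("profile sets must cover the same regions")
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("need at least 2 profiles per set")
    n_regions = profiles_a.shape[1]
    d_a = pdist(profiles_a.values.astype(float), metric="hamming") * n_regions
    d_b = pdist(profiles_b.values.astype(float), metric="hamming") * n_regions
    stat, p = ks_2samp(d_a, d_b)
    return {"distances_a": d_a, "distances_b": d_b,
            "ks_statistic": float(stat), "p_value": float(p)}


# --------------------------------------------------------------------------
# fixtures and exact oracles
# --------------------------------------------------------------------------

def random_tree(n_leaves: int, seed: int = 0,
                p_range: tuple = (0.05, 0.95)) -> PTypeTree:
    """Random binary tree over leaves "R1".."Rn" with directed crossing
    probabilities drawn uniformly from ``p_range``."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = keyed_rng(seed, "random-tree")
    leaves = [f"R{i + 1}" for i in range(n_leaves)]
    nodes = list(leaves)
    children: dict = {}
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        counter += 1
        new = f"n{counter}"
        children[new] = [nodes[i], nodes[j]]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [new]
    tree = PTypeTree(leaves=leaves, children=children, root=nodes[0])
    lo, hi = p_range
    for u, v in list(tree.parent.items()):
        tree.set_probability(u, v, rng.uniform(lo, hi))
        tree.set_probability(v, u, rng.uniform(lo, hi))
    return tree


def pathlength_matrix(tree: PTypeTree) -> pd.DataFrame:
    """Directed leaf-to-leaf path-length matrix (the -log10 probability
    matrix the tree generates; diagonal 0)."""
    leaves = tree.leaves
    out = pd.DataFrame(0.0, index=leaves, columns=leaves)
    for a in leaves:
        for b in leaves:
            if a != b:
                out.loc[a, b] = tree.path_length(a, b)
    return out


def enumerate_profile_distribution(tree: PTypeTree, source) -> dict:
    """Exact distribution over innervation profiles by exhaustive
    enumeration of all 2^E edge-crossing outcomes.

    Intended as an independent oracle for the closed forms on small trees.
    Returns a map from a tuple of innervated leaves (source excluded) to
    probability.
    """
    edges = _bfs_directed_edges(tree, source)
    if len(edges) > 20:
        raise ValueError("enumeration oracle limited to 20 edges")
    probs = [tree.probability(u, v) for u, v in edges]
    dist: dict = {}
    for outcome in product([0, 1], repeat=len(edges)):
        weight = 1.0
        reached = {source}
        for (u, v), crossed, p in zip(edges, outcome, probs):
            weight *= p if crossed else (1.0 - p)
            if crossed and u in reached:
                reached.add(v)
        profile = tuple(l for l in tree.leaves if l != source and l in reached)
        dist[profile] = dist.get(profile, 0.0) + weight
    return dist
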