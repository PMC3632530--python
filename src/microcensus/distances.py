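"""Ecological distances over samples, including a native Fast UniFrac.

The UniFrac implementation precomputes, in a single post-order tree
traversal, each branch's length and per-sample descendant abundance
totals (:class:`BranchAbundance`); every pairwise distance then reuses
that table.  For two samples with per-branch descendant totals
``A_i, B_i``, grand totals ``A_T, B_T`` and root-to-tip depths ``d_j``:

  unweighted        sum of b_i over branches whose descendants occur in
                    exactly one sample, divided by the sum over branches
                    occupied by at least one sample
  weighted (raw)    sum_i b_i |A_i/A_T - B_i/B_T|
  weighted (norm.)  raw / sum_j d_j (A_j/A_T + B_j/B_T)

The general :func:`distance` dispatcher exposes a registry of 44 named
methods (quantitative indices, information-theoretic divergences, the
classic presence/absence incidence family, and the tree-based methods).
All methods are computed per sample pair by pure functions, so the set
of pairs may be partitioned across workers and merged with bitwise
identical results.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import hypergeom

from .core import AbundanceTable, Experiment, PhyloTree


class DistanceMatrix:
    """Symmetric non-negative pairwise dissimilarities with labels."""

    def __init__(self, values, labels: Sequence[str], method: str = ""):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(values, values.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(values < 0):
            raise ValueError("distance matrix has negative entries")
        self.values = values
        self.labels = [str(l) for l in labels]
        self.method = method

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform
        return squareform(self.values, checks=False)

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.values[i, j]

    def __repr__(self) -> str:
        return f"DistanceMatrix({len(self.labels)} x {len(self.labels)}, {self.method!r})"


# ---------------------------------------------------------------------------
# Fast UniFrac
# ---------------------------------------------------------------------------

@dataclass
class BranchAbundance:
    """Per-branch precomputation for Fast UniFrac.

    branch_lengths[i]        length b_i of branch i (every edge below the root)
    descendant_totals[i, s]  summed abundance, in sample s, of the tips below branch i
    sample_totals[s]         grand total of sample s
    tip_depths[t]            root-to-tip path length, aligned with taxon order
    taxon_ids / sample_ids   label orderings for the arrays above
    """

    branch_lengths: np.ndarray
    descendant_totals: np.ndarray
    sample_totals: np.ndarray
    tip_depths: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]


def branch_abundance(tree: PhyloTree, table: AbundanceTable) -> BranchAbundance:
    """Single post-order traversal filling per-branch descendant totals.

    Cost O(edges x samples).  The tree must be rooted; midpoint-root an
    unrooted tree first (see :meth:`PhyloTree.midpoint_rooted`).
    """
    if set(tree.tip_labels) != set(table.taxon_ids):
        raise ValueError("tree tips and abundance taxa differ")
    if tree.is_unrooted:
        raise ValueError("tree is unrooted; midpoint-root it first "
                         "(PhyloTree.midpoint_rooted)")
    tindex = {t: i for i, t in enumerate(table.taxon_ids)}
    x = table.values  # taxa x samples
    n_samples = table.n_samples

    lengths: list[float] = []
    desc: list[np.ndarray] = []
    totals: dict[int, np.ndarray] = {}
    depths = np.zeros(table.n_taxa)

    dtree = tree._tree
    # root-to-tip depths by preorder accumulation
    node_depth: dict[int, float] = {id(dtree.seed_node): 0.0}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        d = node_depth[id(node.parent_node)] + (node.edge.length or 0.0)
        node_depth[id(node)] = d
        if node.is_leaf():
            depths[tindex[node.taxon.label]] = d

    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            below = np.zeros(n_samples)
            below += x[tindex[node.taxon.label]]
        else:
            below = np.zeros(n_samples)
            for child in node.child_nodes():
                below += totals[id(child)]
        totals[id(node)] = below
        if node is not dtree.seed_node:
            lengths.append(float(node.edge.length or 0.0))
            desc.append(below)

    return BranchAbundance(
        branch_lengths=np.array(lengths),
        descendant_totals=np.array(desc),
        sample_totals=x.sum(axis=0),
        tip_depths=depths,
        taxon_ids=list(table.taxon_ids),
        sample_ids=list(table.sample_ids),
    )


def _unifrac_pair(ba: BranchAbundance, rel: np.ndarray, occ: np.ndarray,
                  tip_rel: np.ndarray, i: int, j: int,
                  weighted: bool, normalized: bool) -> float:
    b = ba.branch_lengths
    if not weighted:
        oi, oj = occ[:, i], occ[:, j]
        shared_or = b[oi | oj].sum()
        if shared_or == 0:
            return 0.0
        return float(b[oi ^ oj].sum() / shared_or)
    raw = float(np.sum(b * np.abs(rel[:, i] - rel[:, j])))
    if not normalized:
        return raw
    denom = float(np.sum(ba.tip_depths * (tip_rel[:, i] + tip_rel[:, j])))
    return raw / denom if denom > 0 else 0.0


def unifrac(exp: Experiment, weighted: bool = False, normalized: bool = True,
            workers: int = 1) -> DistanceMatrix:
    """UniFrac distances between all sample pairs.

    ``weighted=False`` gives the unweighted (presence/absence) variant;
    ``weighted=True`` the abundance-weighted variant, divided by its
    maximum attainable value when ``normalized``.  Normalized values lie
    in [0, 1].  Unrooted trees are midpoint-rooted deterministically.
    """
    if exp.tree is None:
        raise ValueError("unifrac requires a tree")
    tree = exp.tree.midpoint_rooted() if exp.tree.is_unrooted else exp.tree
    table = exp.abundance
    totals = table.sample_sums()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"zero-total sample(s): "
                         f"{[exp.sample_ids[i] for i in zero[:10]]}")
    ba = branch_abundance(tree, table)
    rel = ba.descendant_totals / ba.sample_totals
    occ = ba.descendant_totals > 0
    tidx = [ba.taxon_ids.index(t) for t in table.taxon_ids]
    tip_rel = table.values / totals

    name = ("wunifrac" if normalized else "wunifrac_raw") if weighted else "unifrac"
    pairfunc = lambda i, j: _unifrac_pair(ba, rel, occ, tip_rel, i, j,
                                          weighted, normalized)
    values = _pairwise(pairfunc, table.n_samples, workers)
    return DistanceMatrix(values, exp.sample_ids, method=name)


def _pairwise(pairfunc: Callable[[int, int], float], n: int,
              workers: int = 1) -> np.ndarray:
    """Evaluate a pure per-pair function over all pairs.

    With several workers the pair list is partitioned round-robin; because
    each pair is computed independently by the same function, the merged
    matrix is bitwise identical to serial evaluation.
    """
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    out = np.zeros((n, n))

    def run(chunk):
        return [(i, j, pairfunc(i, j)) for i, j in chunk]

    if workers <= 1:
        results = run(pairs)
    else:
        chunks = [pairs[k::workers] for k in range(workers)]
        results = []
        with ThreadPoolExecutor(max_workers=workers) as pool:
            for part in pool.map(run, chunks):
                results.extend(part)
    for i, j, v in results:
        out[i, j] = out[j, i] = v
    return out


# ---------------------------------------------------------------------------
# General registry
# ---------------------------------------------------------------------------

def _abc(x, y):
    px, py = x > 0, y > 0
    a = int(np.sum(px & py))
    b = int(np.sum(px & ~py))  # unique to the first-indexed sample
    c = int(np.sum(~px & py))
    return a, b, c


def _d_manhattan(x, y, ctx):
    return float(np.abs(x - y).sum())


def _d_euclidean(x, y, ctx):
    return float(np.sqrt(((x - y) ** 2).sum()))


def _d_canberra(x, y, ctx):
    nz = (x > 0) | (y > 0)
    if not nz.any():
        return 0.0
    return float((np.abs(x - y)[nz] / (x + y)[nz]).sum() / nz.sum())


def _d_bray(x, y, ctx):
    s = (x + y).sum()
    return float(np.abs(x - y).sum() / s) if s else 0.0


def _d_kulczynski(x, y, ctx):
    j = np.minimum(x, y).sum()
    return float(1 - 0.5 * (j / x.sum() + j / y.sum()))


def _d_jaccard(x, y, ctx):
    b = _d_bray(x, y, ctx)
    return 2 * b / (1 + b)


def _d_gower(x, y, ctx):
    rng = ctx["col_range"]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(rng > 0, np.abs(x - y) / rng, 0.0)
    return float(terms.sum() / len(x))


def _d_altgower(x, y, ctx):
    nz = (x > 0) | (y > 0)
    return float(np.abs(x - y)[nz].sum() / nz.sum()) if nz.any() else 0.0


def _d_morisita(x, y, ctx):
    if not ctx["integer"]:
        raise ValueError("morisita requires integer counts (use horn for "
                         "transformed abundances)")
    nx, ny = x.sum(), y.sum()
    lx = (x * (x - 1)).sum() / (nx * (nx - 1))
    ly = (y * (y - 1)).sum() / (ny * (ny - 1))
    # the Morisita similarity may exceed 1 for under-dispersed counts;
    # clamp the dissimilarity at 0 to keep the distance-matrix contract
    return max(0.0, float(1 - 2 * (x * y).sum() / ((lx + ly) * nx * ny)))


def _d_horn(x, y, ctx):
    nx, ny = x.sum(), y.sum()
    lx = (x ** 2).sum() / nx ** 2
    ly = (y ** 2).sum() / ny ** 2
    return float(1 - 2 * (x * y).sum() / ((lx + ly) * nx * ny))


def _d_mountford(x, y, ctx):
    a, b, c = _abc(x, y)
    A, B, j = a + b, a + c, a
    if j == 0:
        return math.log(2)
    if j == min(A, B):
        return 0.0
    f = lambda th: math.exp(th * A) + math.exp(th * B) - 1 - math.exp(th * (A + B - j))
    hi = 1.0
    while f(hi) > 0:
        hi *= 2
    theta = brentq(f, 1e-12, hi, xtol=1e-14)
    return max(0.0, math.log(2) - theta)


def _d_raup(x, y, ctx):
    a, b, c = _abc(x, y)
    A, B, j = a + b, a + c, a
    pool = ctx["n_species_pool"]
    # P(shared >= j) drawing B species from a pool containing A marked ones
    return float(hypergeom.sf(j - 1, pool, A, B))


def _d_binomial(x, y, ctx):
    nz = (x > 0) | (y > 0)
    x, y = x[nz], y[nz]
    n = x + y
    with np.errstate(divide="ignore", invalid="ignore"):
        tx = np.where(x > 0, x * np.log(np.where(x > 0, x, 1) / n), 0.0)
        ty = np.where(y > 0, y * np.log(np.where(y > 0, y, 1) / n), 0.0)
    return float(((tx + ty + n * math.log(2)) / n).sum())


def _d_chao(x, y, ctx):
    shared = (x > 0) & (y > 0)
    if not shared.any():
        return 1.0
    n, m = x.sum(), y.sum()
    a1 = int(np.sum(shared & (y == 1)))
    a2 = max(1, int(np.sum(shared & (y == 2))))
    b1 = int(np.sum(shared & (x == 1)))
    b2 = max(1, int(np.sum(shared & (x == 2))))
    U = x[shared].sum() / n + (m - 1) / m * a1 / (2 * a2) * x[shared & (y == 1)].sum() / n
    V = y[shared].sum() / m + (n - 1) / n * b1 / (2 * b2) * y[shared & (x == 1)].sum() / m
    U, V = min(U, 1.0), min(V, 1.0)
    if U == 0 or V == 0:
        return 1.0
    return float(1 - U * V / (U + V - U * V))


def _d_cao(x, y, ctx):
    nz = (x > 0) | (y > 0)
    x = np.where(x[nz] > 0, x[nz], 0.1)
    y = np.where(y[nz] > 0, y[nz], 0.1)
    n = x + y
    t = (n * np.log(n / 2) - (x * np.log(y) + y * np.log(x))) / n
    return float(t.sum() / nz.sum())


def _d_chisq(x, y, ctx):
    px, py = x / x.sum(), y / y.sum()
    w = ctx["col_sums"] / ctx["grand_total"]
    ok = w > 0
    return float(np.sqrt((((px - py) ** 2)[ok] / w[ok]).sum()))


def _d_jsd(x, y, ctx):
    p, q = x / x.sum(), y / y.sum()
    m = 0.5 * (p + q)

    def kl(a, b):
        nz = a > 0
        return float((a[nz] * np.log(a[nz] / b[nz])).sum())

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def _beta(expr):
    def f(x, y, ctx):
        a, b, c = _abc(x, y)
        return float(expr(a, b, c))
    return f


def _beta_I(a, b, c):
    n = 2 * a + b + c
    return (math.log(n) - 2 * a * math.log(2) / n
            - ((a + b) * math.log(a + b) + (a + c) * math.log(a + c)) / n)


_BETADIVER = {
    # Presence/absence incidence indices; a = shared species, b/c = species
    # unique to the first/second sample of the pair.
    "w": lambda a, b, c: (b + c) / (2 * a + b + c),
    "-1": lambda a, b, c: (b + c) / (2 * a + b + c),
    "c": lambda a, b, c: (b + c) / 2,
    "wb": lambda a, b, c: b + c,
    "r": lambda a, b, c: 2 * b * c / ((a + b + c) ** 2 - 2 * b * c),
    "I": _beta_I,
    "e": lambda a, b, c: math.exp(_beta_I(a, b, c)) - 1,
    "t": lambda a, b, c: (b + c) / (2 * a + b + c),
    "me": lambda a, b, c: (b + c) / (2 * a + b + c),
    "j": lambda a, b, c: a / (a + b + c),
    "sor": lambda a, b, c: 2 * a / (2 * a + b + c),
    "m": lambda a, b, c: (2 * a + b + c) * (b + c) / (a + b + c),
    "-2": lambda a, b, c: min(b, c) / (max(b, c) + a),
    "co": lambda a, b, c: (a * c + a * b + 2 * b * c) / (2 * (a + b) * (a + c)),
    "cc": lambda a, b, c: (b + c) / (a + b + c),
    "g": lambda a, b, c: (b + c) / (a + b + c),
    "-3": lambda a, b, c: min(b, c) / (a + b + c),
    "l": lambda a, b, c: (b + c) / 2,
    "19": lambda a, b, c: 2 * (b * c + 1) / ((a + b + c) ** 2 - (a + b + c)),
    "hk": lambda a, b, c: (b + c) / (2 * a + b + c),
    "rlb": lambda a, b, c: a / (a + b),
    "sim": lambda a, b, c: min(b, c) / (min(b, c) + a),
    "gl": lambda a, b, c: 2 * abs(b - c) / (2 * a + b + c),
    "z": lambda a, b, c: (math.log(2) - math.log(2 * a + b + c)
                          + math.log(a + b + c)) / math.log(2),
}

_QUANT = {
    "manhattan": _d_manhattan,
    "euclidean": _d_euclidean,
    "canberra": _d_canberra,
    "bray": _d_bray,
    "kulczynski": _d_kulczynski,
    "jaccard": _d_jaccard,
    "gower": _d_gower,
    "altGower": _d_altgower,
    "morisita": _d_morisita,
    "horn": _d_horn,
    "mountford": _d_mountford,
    "raup": _d_raup,
    "binomial": _d_binomial,
    "chao": _d_chao,
    "cao": _d_cao,
    "chisq": _d_chisq,
    "jsd": _d_jsd,
}

TREE_METHODS = ("unifrac", "wunifrac", "dpcoa")

_REGISTRY: dict[str, Callable | None] = {}
_REGISTRY.update(_QUANT)
for _name in TREE_METHODS:
    _REGISTRY[_name] = None  # dispatched specially (need the tree)
for _name, _expr in _BETADIVER.items():
    _REGISTRY[_name] = _beta(_expr)

_BINARY_ONLY = set(_BETADIVER) | {"mountford", "raup"}


def list_distance_methods() -> list[str]:
    """All supported method names in stable registry order (> 40)."""
    return list(_REGISTRY)


def rao_sq(exp: Experiment) -> np.ndarray:
    """Squared Rao phylogenetic dissimilarities between samples.

    Taxa are taken as points whose squared Euclidean separation equals
    their patristic distance; each sample sits at the abundance-weighted
    centroid of its taxa, and this returns the squared centroid
    separations (the squared sample distances of DPCoA's full space).
    """
    if exp.tree is None:
        raise ValueError("rao_sq requires a tree")
    labels, pat = exp.tree.patristic_matrix()
    order = [labels.index(t) for t in exp.taxon_ids]
    delta2 = pat[np.ix_(order, order)]
    totals = exp.abundance.sample_sums()
    if np.any(totals == 0):
        raise ValueError("zero-total sample")
    P = exp.abundance.values / totals  # taxa x samples, columns sum to 1
    M = P.T @ delta2 @ P
    d2 = M - 0.5 * np.diag(M)[:, None] - 0.5 * np.diag(M)[None, :]
    return np.maximum(d2, 0.0)


def distance(exp: Experiment, method: str, binary: bool = False,
             workers: int = 1) -> DistanceMatrix:
    """Pairwise sample dissimilarity by any registered method.

    ``binary`` reduces counts to presence/absence first (the incidence
    family and mountford/raup do this regardless).  Tree-dependent methods
    (unifrac, wunifrac, dpcoa) require a tree.
    """
    if method not in _REGISTRY:
        raise ValueError(f"unknown distance method {method!r}; choose from: "
                         f"{', '.join(list_distance_methods())}")
    if method == "unifrac":
        return unifrac(exp, weighted=False, workers=workers)
    if method == "wunifrac":
        return unifrac(exp, weighted=True, normalized=True, workers=workers)
    if method == "dpcoa":
        vals = np.sqrt(rao_sq(exp))
        np.fill_diagonal(vals, 0.0)
        vals = 0.5 * (vals + vals.T)
        return DistanceMatrix(vals, exp.sample_ids, method="dpcoa")

    x = exp.abundance.values.T.astype(float)  # samples x taxa
    totals = x.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"zero-total sample(s): "
                         f"{[exp.sample_ids[i] for i in zero[:10]]}")
    if binary or method in _BINARY_ONLY:
        x = (x > 0).astype(float)
    ctx = {
        "col_range": x.max(axis=0) - x.min(axis=0),
        "col_sums": x.sum(axis=0),
        "grand_total": x.sum(),
        "n_species_pool": int(np.sum(x.sum(axis=0) > 0)),
        "integer": bool(np.allclose(x, np.round(x))),
    }
    func = _REGISTRY[method]
    values = _pairwise(lambda i, j: func(x[i], x[j], ctx), x.shape[0], workers)
    return DistanceMatrix(values, exp.sample_ids, method=method)


def taxa_distance(exp: Experiment, method: str, binary: bool = False) -> DistanceMatrix:
    """Same registry applied over taxa (rows) instead of samples."""
    from .core import AbundanceTable, Experiment as _E
    flipped = AbundanceTable(exp.abundance.values.T, exp.sample_ids, exp.taxon_ids)
    return distance(_E(flipped), method, binary=binary)
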