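"""Ordination engines and the single `ordinate` dispatcher.

Supported methods: CA (correspondence analysis), CCA and RDA (constrained),
PCA, DPCoA, PCoA/MDS on any registered distance, and NMDS (Kruskal
stress-1 with monotone regression).  Results are returned uniformly as
:class:`OrdinationResult` with labeled coordinates, eigenvalues (or
stress for NMDS) and axis labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import Experiment, logger
from .distances import DistanceMatrix, distance as _distance, rao_sq

SUPPORTED = ("CA", "CCA", "RDA", "PCA", "DPCoA", "MDS", "PCoA", "NMDS")


@dataclass
class OrdinationResult:
    """Coordinates and metadata from one ordination.

    ``eigenvalues`` is non-increasing where present; ``stress`` is present
    only for NMDS.  ``extras`` carries method-specific scalars (total
    inertia, constrained inertia, distance provenance, ...).
    """

    method: str
    sample_coords: pd.DataFrame
    taxa_coords: pd.DataFrame | None = None
    eigenvalues: np.ndarray | None = None
    stress: float | None = None
    axis_labels: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.eigenvalues is not None:
            ev = np.asarray(self.eigenvalues, dtype=float)
            if np.any(np.diff(ev) > 1e-9):
                raise ValueError("eigenvalues must be non-increasing")
            self.eigenvalues = ev
        if (self.stress is not None) != (self.method.upper() == "NMDS"):
            raise ValueError("stress present iff method is NMDS")

    def proportions(self) -> np.ndarray:
        """Proportion of total (positive) variability per axis."""
        ev = np.clip(self.eigenvalues, 0, None)
        return ev / ev.sum() if ev.sum() > 0 else ev


def _axis_frame(coords: np.ndarray, labels, prefix: str) -> pd.DataFrame:
    cols = [f"{prefix}{k + 1}" for k in range(coords.shape[1])]
    return pd.DataFrame(coords, index=list(labels), columns=cols)


# ---------------------------------------------------------------------------
# Correspondence analysis
# ---------------------------------------------------------------------------

def ca(table, n_axes: int | None = None) -> OrdinationResult:
    """Correspondence analysis of a taxa x samples abundance table.

    Decomposes the standardized residuals of the correspondence matrix;
    eigenvalues are squared singular values and their sum (total inertia)
    equals the table's chi-square statistic over its grand total.  Scores
    are reported in symmetric scaling (both sides scaled by the square
    root of the singular values).
    """
    from .core import AbundanceTable
    if isinstance(table, Experiment):
        table = table.abundance
    X = table.values if isinstance(table, AbundanceTable) else np.asarray(table, float)
    taxa = table.taxon_ids if isinstance(table, AbundanceTable) else [
        f"row{i}" for i in range(X.shape[0])]
    samples = table.sample_ids if isinstance(table, AbundanceTable) else [
        f"col{j}" for j in range(X.shape[1])]

    rs, cs = X.sum(axis=1), X.sum(axis=0)
    if np.any(rs == 0):
        raise ValueError(f"zero row sum for {taxa[int(np.argmax(rs == 0))]!r}")
    if np.any(cs == 0):
        raise ValueError(f"zero column sum for {samples[int(np.argmax(cs == 0))]!r}")
    N = X.sum()
    P = X / N
    r, c = rs / N, cs / N
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    rank = min(X.shape) - 1
    U, sv, Vt = U[:, :rank], sv[:rank], Vt[:rank]
    if n_axes is not None:
        U, sv, Vt = U[:, :n_axes], sv[:n_axes], Vt[:n_axes]

    # symmetric scaling: standard coordinates times sqrt(singular value)
    row_coords = (U / np.sqrt(r)[:, None]) * np.sqrt(sv)
    col_coords = (Vt.T / np.sqrt(c)[:, None]) * np.sqrt(sv)
    ev = sv ** 2
    return OrdinationResult(
        method="CA",
        sample_coords=_axis_frame(col_coords, samples, "CA"),
        taxa_coords=_axis_frame(row_coords, taxa, "CA"),
        eigenvalues=ev,
        axis_labels=[f"CA{k + 1}" for k in range(len(ev))],
        extras={"total_inertia": float(ev.sum()), "scaling": "symmetric"},
    )


# ---------------------------------------------------------------------------
# Principal coordinates
# ---------------------------------------------------------------------------

def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical metric multidimensional scaling of a distance matrix.

    Double-centers -d^2/2 and eigendecomposes.  Negative eigenvalues (a
    non-Euclidean input) are retained and reported with a logged warning;
    coordinates are returned for positive-eigenvalue axes only.
    """
    D2 = d.values ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    ev, vec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(ev)[::-1]
    ev, vec = ev[order], vec[:, order]
    tol = 1e-9 * max(1.0, abs(ev[0]))
    if ev[-1] < -tol:
        logger.warning("pcoa: %d negative eigenvalue(s); most negative %.3g "
                       "(non-Euclidean distance)", int(np.sum(ev < -tol)), ev[-1])
    pos = ev > tol
    coords = vec[:, pos] * np.sqrt(ev[pos])
    return OrdinationResult(
        method="PCoA",
        sample_coords=_axis_frame(coords, d.labels, "Axis"),
        eigenvalues=ev,
        axis_labels=[f"Axis{k + 1}" for k in range(int(pos.sum()))],
        extras={"distance": d.method},
    )


# ---------------------------------------------------------------------------
# Non-metric multidimensional scaling
# ---------------------------------------------------------------------------

def _isotonic(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: best monotone non-decreasing fit to y."""
    from scipy.optimize import isotonic_regression
    return isotonic_regression(y).x


def _stress1(delta: np.ndarray, dhat: np.ndarray) -> float:
    denom = (delta ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - delta) ** 2).sum() / denom))


def _nmds_single(dvec: np.ndarray, n: int, k: int, init: np.ndarray,
                 max_iter: int, tol: float) -> tuple[np.ndarray, float, list[float]]:
    order = np.argsort(dvec, kind="stable")
    X = init.copy()
    X_best = X.copy()
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        delta = pdist(X)
        dhat = np.empty_like(delta)
        dhat[order] = _isotonic(delta[order])
        stress = _stress1(delta, dhat)
        if stress >= prev - 1e-15:  # monotone guard: keep the best config
            break
        trace.append(stress)
        prev = stress
        X_best = X.copy()
        if stress <= tol:
            break
        # Guttman transform with unit weights
        ratio = np.divide(dhat, delta, out=np.zeros_like(dhat), where=delta > 0)
        Bmat = -squareform(ratio, checks=False)
        np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
        X = (Bmat @ X) / n
        X -= X.mean(axis=0)
    if not trace:  # initial configuration was already (locally) optimal
        delta = pdist(X_best)
        dhat = np.empty_like(delta)
        dhat[order] = _isotonic(delta[order])
        trace.append(_stress1(delta, dhat))
    return X_best, trace[-1], trace


def nmds(d: DistanceMatrix, k: int = 2, n_starts: int = 20, max_iter: int = 200,
         tol: float = 1e-7, seed: int | None = None) -> OrdinationResult:
    """Kruskal non-metric MDS minimizing stress-1.

    stress-1 = sqrt( sum (dhat_ij - delta_ij)^2 / sum delta_ij^2 ) where
    delta are configuration distances and dhat the isotonic (monotone in
    the input dissimilarities) fit to them.  Runs one PCoA-initialized
    start plus ``n_starts`` random starts (seeded) and keeps the best;
    the returned configuration is centered and principal-axis rotated.
    """
    n = len(d.labels)
    if k >= n:
        raise ValueError("k must be smaller than the number of objects")
    dvec = d.condensed()
    if np.all(dvec == 0):
        raise ValueError("degenerate input: all distances are zero")
    rng = np.random.default_rng(seed)

    inits = []
    p = pcoa(d)
    pc = p.sample_coords.values
    if pc.shape[1] >= k:
        inits.append(pc[:, :k].copy())
    else:  # pad a rank-deficient metric start
        pad = np.zeros((n, k))
        pad[:, :pc.shape[1]] = pc
        inits.append(pad)
    scale = dvec.mean() if dvec.mean() > 0 else 1.0
    for _ in range(n_starts):
        inits.append(rng.normal(scale=scale, size=(n, k)))

    best: tuple[np.ndarray, float, list[float]] | None = None
    for init in inits:
        X, stress, trace = _nmds_single(dvec, n, k, init, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, trace)
    X, stress, trace = best

    if stress < 1e-3 and n > 2 * k + 1:
        logger.warning(
            "nmds: stress %.2g is (nearly) zero; the configuration may be "
            "degenerate (points collapsed into few clusters) or the data "
            "insufficient — inspect the configuration before interpreting",
            stress)
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T  # principal-axis rotation
    # fix sign for determinism: largest-magnitude loading positive
    for a in range(X.shape[1]):
        i = int(np.argmax(np.abs(X[:, a])))
        if X[i, a] < 0:
            X[:, a] = -X[:, a]
    return OrdinationResult(
        method="NMDS",
        sample_coords=_axis_frame(X, d.labels, "NMDS"),
        stress=stress,
        axis_labels=[f"NMDS{a + 1}" for a in range(k)],
        extras={"distance": d.method, "stress_trace": trace,
                "n_starts": n_starts},
    )


# ---------------------------------------------------------------------------
# PCA and constrained ordination
# ---------------------------------------------------------------------------

def pca(table, center: bool = True, scale: bool = False,
        sample_ids=None, taxa_ids=None) -> OrdinationResult:
    """PCA of a samples x variables matrix (rows = samples).

    Eigenvalues are the variances of the scores (n-1 denominator).
    """
    X = np.asarray(table, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance column with scale=True")
        X = X / sd
    U, sv, Vt = np.linalg.svd(X, full_matrices=False)
    ev = sv ** 2 / (n - 1)
    scores = U * sv
    loadings = Vt.T * sv / np.sqrt(n - 1)
    taxa_coords = None
    if taxa_ids is not None:
        taxa_coords = _axis_frame(loadings, taxa_ids, "PC")
    return OrdinationResult(
        method="PCA",
        sample_coords=_axis_frame(scores, ids, "PC"),
        taxa_coords=taxa_coords,
        eigenvalues=ev,
        axis_labels=[f"PC{k + 1}" for k in range(len(ev))],
        extras={"total_variance": float(ev.sum())},
    )


def _constraint_matrix(exp: Experiment, variables: list[str]) -> np.ndarray:
    if exp.samples is None:
        raise ValueError("constrained ordination needs a sample table")
    cols = []
    for v in variables:
        if v not in exp.samples.columns:
            raise ValueError(f"unknown sample variable {v!r}; "
                             f"available: {list(exp.samples.columns)}")
        s = exp.samples[v]
        if pd.api.types.is_numeric_dtype(s):
            vals = s.astype(float).values
            if np.any(np.isnan(vals)):
                raise ValueError(f"missing values in constraint {v!r}")
            cols.append(vals[:, None])
        else:  # categorical -> indicator columns
            dummies = pd.get_dummies(s.astype(str)).values.astype(float)
            cols.append(dummies)
    return np.hstack(cols)


def constrained_ordination(exp: Experiment, method: str,
                           formula: list[str]) -> OrdinationResult:
    """RDA / CCA constrained by named sample variables.

    RDA: least-squares projection of the centered abundance (samples x
    taxa) onto the constraint span, then PCA of the fitted values; the
    constrained eigenvalue sum never exceeds the unconstrained total.
    CCA: the same scheme under correspondence-analysis chi-square
    weighting (row-weighted regression of the standardized residuals).
    """
    method = method.upper()
    if method not in ("RDA", "CCA"):
        raise ValueError("method must be RDA or CCA")
    Y = exp.abundance.values.T.astype(float)  # samples x taxa
    n = Y.shape[0]
    Z = _constraint_matrix(exp, formula)
    Zc = Z - Z.mean(axis=0)
    if np.linalg.matrix_rank(Zc) == 0:
        raise ValueError("constraint matrix has rank 0 (intercept only?)")

    if method == "RDA":
        Yc = Y - Y.mean(axis=0)
        total = float((Yc ** 2).sum()) / (n - 1)
        Q, _ = np.linalg.qr(Zc)
        r = np.linalg.matrix_rank(Zc)
        Q = Q[:, :r]
        fitted = Q @ (Q.T @ Yc)
        resid = Yc - fitted
        U, sv, Vt = np.linalg.svd(fitted, full_matrices=False)
        ev = sv ** 2 / (n - 1)
        keep = ev > 1e-12 * max(1.0, ev[0] if len(ev) else 1.0)
        ev = ev[keep]
        scores = (U * sv)[:, keep]
        taxa_scores = (Vt.T)[:, keep] * np.sqrt(ev)
        extras = {
            "total_inertia": total,
            "constrained_inertia": float(ev.sum()),
            "residual_inertia": float((resid ** 2).sum()) / (n - 1),
        }
        prefix = "RDA"
    else:
        X = Y.T  # taxa x samples; CA weighting over the contingency table
        N = X.sum()
        P = X / N
        r_m, c_m = P.sum(axis=1), P.sum(axis=0)
        if np.any(r_m == 0) or np.any(c_m == 0):
            raise ValueError("zero row/column sum in abundance table")
        S = (P - np.outer(r_m, c_m)) / np.sqrt(np.outer(r_m, c_m))
        total = float((S ** 2).sum())
        # weighted regression of sample profiles (columns of S) on constraints
        W = np.sqrt(c_m)[:, None]  # column (sample) masses
        Zw = Zc * W
        Qw, _ = np.linalg.qr(Zw)
        rk = np.linalg.matrix_rank(Zw)
        Qw = Qw[:, :rk]
        fitted = (Qw @ (Qw.T @ S.T)).T  # project sample dimension
        U, sv, Vt = np.linalg.svd(fitted, full_matrices=False)
        ev = sv ** 2
        keep = ev > 1e-12 * max(1.0, ev[0] if len(ev) else 1.0)
        ev = ev[keep]
        col_coords = (Vt.T / W)[:, keep] * np.sqrt(ev)
        row_coords = (U / np.sqrt(r_m)[:, None])[:, keep] * np.sqrt(ev)
        scores = col_coords
        taxa_scores = row_coords
        extras = {
            "total_inertia": total,
            "constrained_inertia": float(ev.sum()),
            "residual_inertia": total - float(ev.sum()),
        }
        prefix = "CCA"

    return OrdinationResult(
        method=method,
        sample_coords=_axis_frame(scores, exp.sample_ids, prefix),
        taxa_coords=_axis_frame(taxa_scores, exp.taxon_ids, prefix),
        eigenvalues=np.sort(ev)[::-1],
        axis_labels=[f"{prefix}{k + 1}" for k in range(len(ev))],
        extras=extras,
    )


# ---------------------------------------------------------------------------
# Double principal coordinates analysis
# ---------------------------------------------------------------------------

def dpcoa(exp: Experiment) -> OrdinationResult:
    """Double principal coordinates analysis.

    Taxa are embedded by PCoA of the square-root patristic distances (so
    squared taxon separations equal patristic path lengths); each sample
    is placed at the abundance-weighted centroid of its taxa; a weighted
    PCA of the sample points (weights = sample relative totals) gives the
    displayed axes.  Squared sample distances in the full space equal the
    Rao dissimilarities computed directly from abundances and patristic
    distances.
    """
    if exp.tree is None:
        raise ValueError("dpcoa requires a tree")
    labels, pat = exp.tree.patristic_matrix()
    order = [labels.index(t) for t in exp.taxon_ids]
    pat = pat[np.ix_(order, order)]

    dtax = DistanceMatrix(np.sqrt(pat), exp.taxon_ids, method="sqrt-patristic")
    tax_ord = pcoa(dtax)
    ev = tax_ord.eigenvalues
    tol = 1e-8 * max(1.0, abs(ev[0]))
    if ev[-1] < -tol:
        raise ValueError("square-root patristic distances are not Euclidean-"
                         "embeddable; check the tree for inconsistent lengths")
    Ztax = tax_ord.sample_coords.values  # taxa x axes embedding

    totals = exp.abundance.sample_sums()
    if np.any(totals == 0):
        raise ValueError("zero-total sample")
    P = (exp.abundance.values / totals).T  # samples x taxa
    centroids = P @ Ztax

    w = totals / totals.sum()
    mean = w @ centroids
    Xc = centroids - mean
    C = (Xc * w[:, None]).T @ Xc  # weighted covariance of sample points
    evals, evecs = np.linalg.eigh(C)
    order2 = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order2], 0, None), evecs[:, order2]
    keep = evals > 1e-12 * max(1.0, evals[0] if len(evals) else 1.0)
    evals, evecs = evals[keep], evecs[:, keep]

    sample_coords = Xc @ evecs
    taxa_coords = (Ztax - mean) @ evecs
    return OrdinationResult(
        method="DPCoA",
        sample_coords=_axis_frame(sample_coords, exp.sample_ids, "DPCoA"),
        taxa_coords=_axis_frame(taxa_coords, exp.taxon_ids, "DPCoA"),
        eigenvalues=evals,
        axis_labels=[f"DPCoA{k + 1}" for k in range(len(evals))],
        extras={"rao_sq": rao_sq(exp)},
    )


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def ordinate(exp: Experiment, method: str,
             distance_method: str | DistanceMatrix | None = None,
             formula: list[str] | None = None,
             seed: int | None = None, **kwargs) -> OrdinationResult:
    """Single entry point dispatching to the ordination engines.

    MDS/PCoA and NMDS require a pre-calculated :class:`DistanceMatrix` or
    the name of a registered distance method.  CCA/RDA take ``formula``,
    a list of sample-variable names.  DCA is intentionally not
    implemented.
    """
    m = method.upper()
    if m == "DCA":
        raise NotImplementedError(
            "DCA (detrended correspondence analysis) is not implemented; its "
            "detrending-by-segments step is delegated to specialist software. "
            "Use CA or NMDS instead.")
    if m not in {s.upper() for s in SUPPORTED}:
        raise ValueError(f"unsupported ordination {method!r}; supported: "
                         f"{', '.join(SUPPORTED)} (DCA deliberately excluded)")

    if m in ("MDS", "PCOA", "NMDS"):
        if distance_method is None:
            raise ValueError(f"{method} requires a distance matrix or a "
                             "distance method name")
        d = (distance_method if isinstance(distance_method, DistanceMatrix)
             else _distance(exp, distance_method))
        if m == "NMDS":
            res = nmds(d, seed=seed, **kwargs)
        else:
            res = pcoa(d)
            res.method = "PCoA"
        res.extras.setdefault("distance", d.method)
        return res
    if m == "CA":
        return ca(exp.abundance, **kwargs)
    if m == "PCA":
        return pca(exp.abundance.values.T, sample_ids=exp.sample_ids,
                   taxa_ids=exp.taxon_ids, **kwargs)
    if m in ("CCA", "RDA"):
        if not formula:
            raise ValueError(f"{m} requires a formula (list of sample variables)")
        return constrained_ordination(exp, m, formula)
    if m == "DPCOA":
        return dpcoa(exp)
    raise AssertionError("unreachable")
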