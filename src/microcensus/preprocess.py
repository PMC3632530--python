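"""Filtering, transformation, subsampling and agglomeration of abundances.

These are the standardization steps applied between import and analysis:
per-sample relative abundance or even-depth scaling, log and rank
transforms, rarefaction-style random subsampling (seeded, no hidden
global state), prevalence (k-over-a) and coefficient-of-variation taxon
filters, and agglomeration of taxa by taxonomy rank or tree proximity.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import AbundanceTable, Experiment, MISSING, logger, merge_taxa, prune_samples, prune_taxa

TRANSFORMS = ("relative", "log1p_base", "rank", "even_depth_scale")


def _replace_values(exp: Experiment, values: np.ndarray) -> Experiment:
    ab = AbundanceTable(values, exp.taxon_ids, exp.sample_ids,
                        taxa_are_rows=exp.abundance.taxa_are_rows)
    return Experiment(ab, exp.samples, exp.taxonomy, exp.tree, exp.refseq)


def transform_counts(exp: Experiment, kind: str, param: float | None = None) -> Experiment:
    """Per-sample abundance transformation.

    kind:
      relative          x -> x / column sum
      log1p_base b      x -> log(1 + x) / log(b)
      rank              per-sample ranks of the taxa (average ties)
      even_depth_scale  column rescaled to sum to ``param`` (real-valued;
                        use :func:`rarefy_even_depth` for true subsampling)
    """
    x = exp.abundance.values
    if x.size == 0:
        raise ValueError("abundance table is empty")
    if kind in ("relative", "even_depth_scale"):
        sums = x.sum(axis=0)
        zero = np.flatnonzero(sums == 0)
        if zero.size:
            raise ValueError(f"zero-sum sample(s): "
                             f"{[exp.sample_ids[i] for i in zero[:10]]}")
        if kind == "relative":
            out = x / sums
        else:
            if param is None or param <= 0:
                raise ValueError("even_depth_scale requires a positive target depth")
            out = x * (float(param) / sums)
    elif kind == "log1p_base":
        if param is None or param <= 1:
            raise ValueError("log1p_base requires a base > 1")
        out = np.log1p(x) / np.log(param)
    elif kind == "rank":
        from scipy.stats import rankdata
        out = np.apply_along_axis(rankdata, 0, x)
    else:
        raise ValueError(f"unknown transform {kind!r}; choose from {TRANSFORMS}")
    return _replace_values(exp, out)


def rarefy_even_depth(exp: Experiment, depth: int, seed: int,
                      replace: bool = False) -> Experiment:
    """Randomly subsample each sample to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning; taxa left with all-zero rows are removed.  Deterministic given
    ``seed`` (which is required — reproducibility is part of the contract).
    """
    depth = int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    x = exp.abundance.values
    if not np.allclose(x, np.round(x)):
        raise ValueError("rarefaction requires integer counts")
    x = np.round(x).astype(np.int64)
    sums = x.sum(axis=0)
    keep = sums >= depth
    if not keep.any():
        raise ValueError(f"no sample reaches depth {depth} (max total {sums.max()})")
    dropped = [s for s, k in zip(exp.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy_even_depth: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped[:10])

    rng = np.random.default_rng(seed)
    out = np.zeros((exp.n_taxa, int(keep.sum())), dtype=np.int64)
    for j_out, j in enumerate(np.flatnonzero(keep)):
        col = x[:, j]
        if replace:
            out[:, j_out] = rng.multinomial(depth, col / col.sum())
        else:
            pool = np.repeat(np.arange(exp.n_taxa), col)
            chosen = rng.choice(pool, size=depth, replace=False)
            out[:, j_out] = np.bincount(chosen, minlength=exp.n_taxa)

    kept_samples = [s for s, k in zip(exp.sample_ids, keep) if k]
    sub = prune_samples(kept_samples, exp)
    sub = _replace_values(sub, out.astype(float))
    nonzero = [t for t, row in zip(sub.taxon_ids, out) if row.sum() > 0]
    if len(nonzero) < sub.n_taxa:
        sub = prune_taxa(nonzero, sub)
    return sub


def filter_taxa_k_over_a(exp: Experiment, k_fraction: float, a: float) -> Experiment:
    """Keep taxa whose count exceeds ``a`` in at least
    ``ceil(k_fraction * n_samples)`` samples (genefilter-style kOverA).

    "Observed at least 3 times in 20% of samples" is ``k_fraction=0.2,
    a=2`` (count > 2 means count >= 3 for integer data).
    """
    if not (0 < k_fraction <= 1):
        raise ValueError("k_fraction must be in (0, 1]")
    need = int(np.ceil(k_fraction * exp.n_samples))
    hits = (exp.abundance.values > a).sum(axis=1)
    keep = [t for t, h in zip(exp.taxon_ids, hits) if h >= need]
    if not keep:
        raise ValueError(f"k-over-a filter (k={k_fraction}, a={a}) removed every taxon")
    return prune_taxa(keep, exp) if len(keep) < exp.n_taxa else exp


def filter_taxa_cv(exp: Experiment, cv_min: float) -> Experiment:
    """Keep taxa whose coefficient of variation (sd with n-1 denominator
    over mean) across samples exceeds ``cv_min``; all-zero taxa are always
    removed."""
    if exp.n_samples < 2:
        raise ValueError("CV filter needs at least 2 samples")
    x = exp.abundance.values
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    keep = [t for t, c, m in zip(exp.taxon_ids, cv, mean) if m > 0 and c > cv_min]
    if not keep:
        raise ValueError(f"CV filter (cv_min={cv_min}) removed every taxon")
    return prune_taxa(keep, exp) if len(keep) < exp.n_taxa else exp


def _archetype(exp: Experiment, members: list[str]) -> str:
    """Most abundant member; ties broken by lexicographically smallest ID."""
    totals = exp.abundance.to_frame().loc[members].sum(axis=1)
    best = totals.max()
    return sorted(t for t in members if totals[t] == best)[0]


def tax_glom(exp: Experiment, rank: str, na_rm: bool = True) -> Experiment:
    """Merge taxa sharing identical taxonomy from the first rank through
    ``rank``.  Taxa unassigned at ``rank`` are dropped when ``na_rm`` else
    grouped by their exact shared prefix.  Per-sample totals of retained
    groups are conserved."""
    if exp.taxonomy is None:
        raise ValueError("tax_glom requires a taxonomy table")
    if rank not in exp.ranks:
        raise ValueError(f"unknown rank {rank!r}; available: {exp.ranks}")
    upto = exp.ranks[: exp.ranks.index(rank) + 1]
    tax = exp.taxonomy[upto]

    if na_rm:
        assigned = [t for t in exp.taxon_ids if tax.loc[t, rank] != MISSING]
        if not assigned:
            raise ValueError(f"no taxon has an assignment at rank {rank!r}")
        if len(assigned) < exp.n_taxa:
            exp = prune_taxa(assigned, exp)
            tax = exp.taxonomy[upto]

    groups: dict[tuple, list[str]] = {}
    for t in exp.taxon_ids:
        groups.setdefault(tuple(tax.loc[t]), []).append(t)
    for members in groups.values():
        if len(members) > 1:
            exp = merge_taxa(exp, members, _archetype(exp, members))
    return exp


def tip_glom(exp: Experiment, h: float) -> Experiment:
    """Merge taxa by complete-linkage clustering of patristic (cophenetic)
    distances, cut at height ``h``; every pair within a merged cluster is
    within ``h`` on the tree."""
    if exp.tree is None:
        raise ValueError("tip_glom requires a tree")
    if h <= 0:
        raise ValueError("h must be > 0")
    labels, pmat = exp.tree.patristic_matrix()
    if len(labels) < 2:
        return exp
    z = linkage(squareform(pmat, checks=False), method="complete")
    assign = fcluster(z, t=h, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for lab, c in zip(labels, assign):
        clusters.setdefault(int(c), []).append(lab)
    for members in clusters.values():
        if len(members) > 1:
            exp = merge_taxa(exp, members, _archetype(exp, members))
    return exp
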