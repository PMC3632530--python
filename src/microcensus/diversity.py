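"""Alpha diversity estimators and permutation-based multiple testing.

Richness estimators (Observed, Chao1, ACE with standard errors; Shannon,
Simpson) per sample; a Westfall-Young step-down minP procedure for
family-wise error control when testing every taxon against a sample
classification; and the upper-tail hypergeometric (Fisher) enrichment
test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import Experiment, logger

MEASURES = ("Observed", "Chao1", "ACE", "Shannon", "Simpson")


@dataclass
class FrequencyCounts:
    """Abundance-frequency summary of one sample."""

    S_obs: int   # observed taxa
    F1: int      # singletons
    F2: int      # doubletons
    N: int       # total individuals

    def __post_init__(self):
        if min(self.S_obs, self.F1, self.F2, self.N) < 0:
            raise ValueError("frequency counts must be non-negative")
        if self.F1 + self.F2 > self.S_obs:
            raise ValueError("F1 + F2 cannot exceed S_obs")


def frequency_counts(counts: np.ndarray) -> FrequencyCounts:
    counts = np.asarray(counts)
    return FrequencyCounts(
        S_obs=int(np.sum(counts > 0)),
        F1=int(np.sum(counts == 1)),
        F2=int(np.sum(counts == 2)),
        N=int(counts.sum()),
    )


def chao1(fc: FrequencyCounts) -> tuple[float, float]:
    """Bias-corrected Chao1 estimate and its standard error.

    S_chao1 = S_obs + F1(F1-1) / (2(F2+1)); defined at F2 = 0, and never
    below S_obs.
    """
    f1, f2 = fc.F1, fc.F2
    est = fc.S_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    # variance of the bias-corrected estimator (classic partial-derivative form)
    if f1 > 0:
        var = (f1 * (f1 - 1) / (2 * (f2 + 1))
               + f1 * (2 * f1 - 1) ** 2 / (4 * (f2 + 1) ** 2)
               + f1 ** 2 * f2 * (f1 - 1) ** 2 / (4 * (f2 + 1) ** 4))
    else:
        var = 0.0
    return float(est), float(math.sqrt(max(var, 0.0)))


def ace(counts: np.ndarray, rare_cutoff: int = 10) -> tuple[float, float]:
    """Abundance-based coverage estimator with the standard rare/abundant
    split at ``rare_cutoff`` and a coverage-based correction."""
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    rare = counts[counts <= rare_cutoff]
    s_abund = int(np.sum(counts > rare_cutoff))
    s_rare = len(rare)
    n_rare = int(rare.sum())
    f1 = int(np.sum(rare == 1))
    if n_rare == 0:
        return float(s_abund), 0.0
    if f1 == n_rare:  # all rare taxa are singletons: coverage undefined
        est, se = chao1(frequency_counts(counts))
        return est, se
    c_ace = 1 - f1 / n_rare
    ks = np.arange(1, rare_cutoff + 1)
    fk = np.array([np.sum(rare == k) for k in ks])
    gamma = max(
        s_rare / c_ace * np.sum(ks * (ks - 1) * fk) / (n_rare * (n_rare - 1)) - 1,
        0.0,
    ) if n_rare > 1 else 0.0
    est = s_abund + s_rare / c_ace + f1 / c_ace * gamma
    # jackknife-flavored rough standard error on the rare-taxon part
    se = math.sqrt(max(s_rare * (1 - c_ace) + f1 * gamma, 0.0))
    return float(est), float(se)


def shannon(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def simpson(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    return float(1 - (p ** 2).sum())


def estimate_richness(exp: Experiment, measures=MEASURES) -> pd.DataFrame:
    """Per-sample table of richness/diversity estimates.

    Chao1 and ACE require integer counts and come with standard-error
    columns (``se.chao1``, ``se.ACE``).
    """
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures {sorted(unknown)}; supported: {MEASURES}")
    x = exp.abundance.values
    needs_int = {"Chao1", "ACE"} & set(measures)
    if needs_int and not np.allclose(x, np.round(x)):
        raise ValueError(f"{sorted(needs_int)} require integer counts")
    out: dict[str, list[float]] = {m: [] for m in measures}
    ses: dict[str, list[float]] = {}
    if "Chao1" in measures:
        ses["se.chao1"] = []
    if "ACE" in measures:
        ses["se.ACE"] = []
    for j in range(exp.n_samples):
        col = x[:, j]
        for m in measures:
            if m == "Observed":
                out[m].append(float(np.sum(col > 0)))
            elif m == "Chao1":
                est, se = chao1(frequency_counts(col))
                out[m].append(est)
                ses["se.chao1"].append(se)
            elif m == "ACE":
                est, se = ace(col)
                out[m].append(est)
                ses["se.ACE"].append(se)
            elif m == "Shannon":
                out[m].append(shannon(col))
            elif m == "Simpson":
                out[m].append(simpson(col))
    frame = pd.DataFrame({**out, **ses}, index=exp.sample_ids)
    cols = []
    for m in measures:
        cols.append(m)
        if m == "Chao1":
            cols.append("se.chao1")
        if m == "ACE":
            cols.append("se.ACE")
    return frame[cols]


# ---------------------------------------------------------------------------
# Group-comparison statistics
# ---------------------------------------------------------------------------

def _f_statistics(x: np.ndarray, groups: np.ndarray, n_levels: int) -> np.ndarray:
    """One-way ANOVA F per row of ``x`` (taxa x samples), vectorized.

    ``groups`` may be a 1-D label vector or a 2-D (samples x B) matrix of
    permuted label vectors; the result is then (taxa,) or (taxa, B).
    Rows with zero within-group variance get statistic 0 (handled as p=1
    downstream).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[1]
    squeeze = groups.ndim == 1
    G = groups.reshape(n, -1) if squeeze else groups
    B = G.shape[1]
    total = x.sum(axis=1, keepdims=True)            # taxa x 1
    total_ss = (x ** 2).sum(axis=1, keepdims=True) - total ** 2 / n
    between = np.zeros((x.shape[0], B))
    counts = np.zeros((n_levels, B))
    for lev in range(n_levels):
        ind = (G == lev).astype(float)              # samples x B
        cnt = ind.sum(axis=0)                       # B
        counts[lev] = cnt
        gsums = x @ ind                             # taxa x B
        with np.errstate(invalid="ignore", divide="ignore"):
            between += np.where(cnt > 0, gsums ** 2 / cnt, 0.0)
    between -= total ** 2 / n
    within = total_ss - between
    dfb, dfw = n_levels - 1, n - n_levels
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (between / dfb) / (within / dfw)
    f = np.where(~np.isfinite(f) | (within <= 1e-12 * np.maximum(total_ss, 1e-300)),
                 np.where(between > 1e-12, np.inf, 0.0), f)
    f = np.where((total_ss <= 0), 0.0, f)  # constant rows: statistic 0
    return f[:, 0] if squeeze else f


def _t_statistics(x: np.ndarray, groups: np.ndarray, welch: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = x.shape[1]
    squeeze = groups.ndim == 1
    G = groups.reshape(n, -1) if squeeze else groups
    out = []
    for b in range(G.shape[1]):
        g = G[:, b]
        a, c = x[:, g == 0], x[:, g == 1]
        ma, mc = a.mean(axis=1), c.mean(axis=1)
        va, vc = a.var(axis=1, ddof=1), c.var(axis=1, ddof=1)
        na, nc = a.shape[1], c.shape[1]
        if welch:
            denom = np.sqrt(va / na + vc / nc)
        else:
            sp = ((na - 1) * va + (nc - 1) * vc) / (na + nc - 2)
            denom = np.sqrt(sp * (1 / na + 1 / nc))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (ma - mc) / denom
        t = np.where(denom == 0, 0.0, t)
        out.append(t)
    res = np.stack(out, axis=1)
    return res[:, 0] if squeeze else res


def _all_label_permutations(labels: np.ndarray) -> np.ndarray:
    """All distinct orderings of the label vector (samples x B)."""
    perms = sorted(set(itertools.permutations(labels.tolist())))
    return np.array(perms).T


def mt_minp(exp: Experiment, class_var: str, stat: str = "f", B: int = 9999,
            seed: int | None = None, exhaustive: bool = False) -> pd.DataFrame:
    """Permutation multiple testing with Westfall-Young step-down minP.

    Tests every taxon against the categorical sample variable
    ``class_var`` using a one-way ANOVA F (``stat="f"``) or a two-sample
    t / Welch t.  Raw p-values use the (1 + count)/(B + 1) convention over
    ``B`` seeded label permutations (so p > 0 and the smallest value is
    1/(B+1)); adjusted p-values control the FWER via step-down minP over
    the joint permutation null, with monotonicity enforced.  Rows are
    sorted by raw p then statistic descending.  With ``exhaustive=True``
    all distinct label permutations are enumerated instead (small n).
    """
    if exp.samples is None or class_var not in (exp.samples.columns if exp.samples is not None else []):
        raise ValueError(f"sample variable {class_var!r} not found")
    labels_raw = exp.samples[class_var]
    keep = labels_raw.notna()
    if not keep.all():
        logger.info("mt_minp: ignoring %d sample(s) with missing %r",
                    int((~keep).sum()), class_var)
    sub_exp_ids = [s for s, k in zip(exp.sample_ids, keep) if k]
    x = exp.abundance.to_frame()[sub_exp_ids].values
    levels, groups = np.unique(labels_raw[keep].astype(str).values, return_inverse=True)
    n = len(groups)
    if len(levels) < 2:
        raise ValueError(f"{class_var!r} has a single level")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if stat not in ("f", "t", "welch_t"):
        raise ValueError("stat must be one of f, t, welch_t")
    if stat != "f" and len(levels) != 2:
        raise ValueError("t statistics require exactly 2 levels")
    if not exhaustive and B < 99:
        logger.warning("mt_minp: B=%d gives a coarse p-value resolution of %.3g",
                       B, 1 / (B + 1))

    def statfunc(g):
        if stat == "f":
            return _f_statistics(x, g, len(levels))
        return _t_statistics(x, g, welch=(stat == "welch_t"))

    t0 = np.abs(statfunc(groups))

    if exhaustive:
        P = _all_label_permutations(groups)
        tb = np.abs(statfunc(P))
        B_eff = P.shape[1]
        raw = (tb >= t0[:, None] - 1e-12).sum(axis=1) / B_eff
    else:
        if seed is None:
            raise ValueError("seed is required for permutation testing")
        rng = np.random.default_rng(seed)
        P = np.stack([rng.permutation(groups) for _ in range(B)], axis=1)
        tb = np.abs(statfunc(P))
        B_eff = B
        raw = (1 + (tb >= t0[:, None] - 1e-12).sum(axis=1)) / (B_eff + 1)

    # per-taxon permutation p-value of each permuted statistic: its rank
    # among the pooled B+1 values (observed + permutations), exactly the
    # convention used for raw_p — without pooling, the permutation minima
    # would be stochastically larger than the observed minimum under the
    # null and the step-down adjustment would be anticonservative
    m = x.shape[0]
    pmat = np.empty_like(tb)
    for i in range(m):
        sorted_vals = np.sort(tb[i])
        geq = B_eff - np.searchsorted(sorted_vals, tb[i] - 1e-12, side="left")
        if exhaustive:  # the identity relabeling is already one of the B_eff
            pmat[i] = geq / B_eff
        else:
            pmat[i] = (geq + (t0[i] >= tb[i] - 1e-12)) / (B_eff + 1)

    # step-down ordering: most significant first
    step = np.lexsort((-t0, raw))
    q = np.empty((m, B_eff))
    q[m - 1] = pmat[step[-1]]
    for k in range(m - 2, -1, -1):
        q[k] = np.minimum(q[k + 1], pmat[step[k]])
    raw_thresh = raw[step]
    adj_sorted = np.empty(m)
    for k in range(m):
        adj_sorted[k] = (1 + np.sum(q[k] <= raw_thresh[k] + 1e-12)) / (B_eff + 1)
    adj_sorted = np.maximum.accumulate(adj_sorted)           # step-down monotone
    adj_sorted = np.maximum(adj_sorted, raw_thresh)          # adj >= raw
    adj_sorted = np.minimum(adj_sorted, 1.0)

    taxa = [exp.taxon_ids[i] for i in step]
    table = pd.DataFrame({
        "index": step + 1,                                   # 1-based row position
        "statistic": [float(t0[i]) for i in step],
        "raw_p": raw_thresh,
        "adj_p": adj_sorted,
    }, index=taxa)
    # constant taxa (statistic 0) carry no evidence: p = 1 by construction
    return table


def hypergeom_enrichment(universe_size: int, category_in_universe: int,
                         selected: int, category_in_selected: int) -> float:
    """Upper-tail hypergeometric (Fisher) enrichment p-value.

    P[X >= category_in_selected] when drawing ``selected`` items from a
    universe of ``universe_size`` containing ``category_in_universe``
    category members.
    """
    M, K, n, k = universe_size, category_in_universe, selected, category_in_selected
    if not (0 <= K <= M and 0 <= n <= M and 0 <= k <= min(n, K)):
        raise ValueError("inconsistent counts for hypergeometric test")
    return float(hypergeom.sf(k - 1, M, K, n))
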