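"""Deterministic data/layout computations behind the standard microbiome
plots: ordination scatter (samples / taxa / biplot / split), angle-ordered
heatmaps, threshold co-occurrence networks, annotated trees, stacked bars,
and richness panels.  Rendering is the caller's concern; every function
here returns plain labeled tables (or a networkx graph) that are pure
functions of (experiment, parameters, seed).
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .core import Experiment, logger
from .distances import DistanceMatrix, distance as _distance, taxa_distance
from .diversity import estimate_richness
from .ordination import OrdinationResult, ordinate

DISPLAYS = ("samples", "taxa", "biplot", "split")


def ordination_plot_data(exp: Experiment, ord: OrdinationResult,
                         display: str = "samples", axes: tuple[int, int] = (1, 2)):
    """Coordinate table(s) for plotting an ordination.

    samples/taxa: one table joined with sample variables / taxonomy ranks.
    biplot: both concatenated with a ``type`` column; split: a (samples,
    taxa) pair.  Also attaches scree proportions (positive eigenvalues)
    in ``DataFrame.attrs['scree']``.
    """
    if display not in DISPLAYS:
        raise ValueError(f"display must be one of {DISPLAYS}")
    a1, a2 = axes
    ncol = ord.sample_coords.shape[1]
    if not (1 <= a1 <= ncol and 1 <= a2 <= ncol):
        raise ValueError(f"requested axes {axes} but ordination has {ncol}")

    def pick(coords: pd.DataFrame) -> pd.DataFrame:
        out = coords.iloc[:, [a1 - 1, a2 - 1]].copy()
        out.columns = [coords.columns[a1 - 1], coords.columns[a2 - 1]]
        return out

    scree = None
    if ord.eigenvalues is not None:
        ev = np.clip(ord.eigenvalues, 0, None)
        scree = ev / ev.sum() if ev.sum() > 0 else ev

    samples_tab = pick(ord.sample_coords)
    if exp.samples is not None:
        samples_tab = samples_tab.join(exp.samples)
    samples_tab.attrs["scree"] = scree

    if display == "samples":
        return samples_tab

    if ord.taxa_coords is None:
        raise ValueError(
            f"display {display!r} needs taxon scores, but this "
            f"{ord.method} ordination is distance-based and has none; use a "
            "table-based method (CA, DPCoA, CCA/RDA) for biplots")
    taxa_tab = pick(ord.taxa_coords)
    if exp.taxonomy is not None:
        taxa_tab = taxa_tab.join(exp.taxonomy)
    taxa_tab.attrs["scree"] = scree

    if display == "taxa":
        return taxa_tab
    if display == "split":
        return samples_tab, taxa_tab
    samples_tab = samples_tab.assign(type="sample")
    taxa_tab = taxa_tab.assign(type="taxon")
    samples_tab.attrs = {}
    taxa_tab.attrs = {}  # ndarray attrs confuse pandas concat
    biplot = pd.concat([samples_tab, taxa_tab])
    biplot.attrs["scree"] = scree
    return biplot


def _angle_order(coords: pd.DataFrame) -> list[str]:
    """IDs sorted by atan2 angle in the first two axes, ascending in
    (-pi, pi]; ties broken by ID (determinism)."""
    xy = coords.iloc[:, :2].values
    theta = np.arctan2(xy[:, 1], xy[:, 0])
    keyed = sorted(zip(theta, coords.index.tolist()), key=lambda p: (p[0], p[1]))
    return [i for _, i in keyed]


def heatmap_order(exp: Experiment, ord_method: str = "NMDS",
                  distance_method: str = "bray", order_taxa: bool = True,
                  seed: int | None = None) -> tuple[list[str], list[str]]:
    """Sample (and taxa) orderings by radial ordination angle.

    Both orderings come from the first two axes of the requested
    ordination: samples from an ordination of sample distances, taxa from
    the same method applied over taxa.
    """
    if exp.n_samples < 3:
        raise ValueError("heatmap ordering needs at least 3 samples")
    sample_ord = ordinate(exp, ord_method, distance_method=distance_method,
                          seed=seed)
    sample_order = _angle_order(sample_ord.sample_coords)
    taxa_order = list(exp.taxon_ids)
    if order_taxa:
        if sample_ord.taxa_coords is not None:
            taxa_order = _angle_order(sample_ord.taxa_coords)
        else:
            from .ordination import nmds, pcoa
            dt = taxa_distance(exp, distance_method)
            tax_ord = (nmds(dt, seed=seed) if ord_method.upper() == "NMDS"
                       else pcoa(dt))
            taxa_order = _angle_order(tax_ord.sample_coords)
    return sample_order, taxa_order


# rendering hint recorded with heatmap output: log(1 + x) / log(4)
HEATMAP_TRANSFORM = ("log1p_base", 4)


def make_network(exp: Experiment, unit: str = "samples",
                 distance_method: str = "jaccard",
                 max_dist: float = 0.4) -> nx.Graph:
    """Threshold graph: two units are connected iff their distance is
    strictly below ``max_dist``.  Isolated nodes are kept; node attributes
    come from the sample table (or taxonomy)."""
    if unit not in ("samples", "taxa"):
        raise ValueError("unit must be 'samples' or 'taxa'")
    if unit == "samples":
        d = _distance(exp, distance_method)
        meta = exp.samples
    else:
        d = taxa_distance(exp, distance_method)
        meta = exp.taxonomy
    if len(d.labels) < 2:
        raise ValueError("need at least 2 units to build a network")
    g = nx.Graph(distance_method=distance_method, max_dist=max_dist, unit=unit)
    for lab in d.labels:
        attrs = {}
        if meta is not None and lab in meta.index:
            attrs = {k: v for k, v in meta.loc[lab].items() if pd.notna(v)}
        g.add_node(lab, **attrs)
    n = len(d.labels)
    for i in range(n):
        for j in range(i + 1, n):
            if d.values[i, j] < max_dist:
                g.add_edge(d.labels[i], d.labels[j], distance=float(d.values[i, j]))
    return g


def network_layout(g: nx.Graph, seed: int) -> pd.DataFrame:
    """Deterministic force-directed (spring) coordinates, centered at the
    origin."""
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["x", "y"])
    pos = nx.spring_layout(g, seed=seed, center=(0, 0))
    frame = pd.DataFrame(pos).T
    frame.columns = ["x", "y"]
    frame -= frame.mean(axis=0)
    return frame.loc[list(g.nodes)]


def tree_plot_data(exp: Experiment, color_var: str | None = None,
                   shape_var: str | None = None):
    """Segments and tip-marker tables for an annotated tree plot.

    Tips get integer vertical positions in tree (post-order) order;
    internal nodes sit at the mean of their children; horizontal position
    is the cumulative branch length.  One marker is emitted per (tip,
    sample with a positive count), offset in successive columns beside the
    tip and carrying the abundance plus any mapped sample variables.
    """
    if exp.tree is None:
        raise ValueError("tree_plot_data requires a tree")
    if exp.tree.n_tips > 200:
        logger.warning("tree has %d tips; plots beyond ~200 tips are rarely "
                       "readable — consider agglomerating or subsetting",
                       exp.tree.n_tips)
    for var in (color_var, shape_var):
        if var is not None and (exp.samples is None or var not in exp.samples.columns):
            raise ValueError(f"unknown sample variable {var!r}")

    dtree = exp.tree._tree
    ypos: dict[int, float] = {}
    xpos: dict[int, float] = {}
    tip_y: dict[str, float] = {}
    next_y = 0
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            ypos[id(node)] = next_y
            tip_y[node.taxon.label] = next_y
            next_y += 1
        else:
            ypos[id(node)] = float(np.mean([ypos[id(c)] for c in node.child_nodes()]))
    xpos[id(dtree.seed_node)] = 0.0
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        xpos[id(node)] = xpos[id(node.parent_node)] + (node.edge.length or 0.0)

    segments = []
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        p = node.parent_node
        # elbow: vertical connector at the parent, then horizontal branch
        segments.append({
            "x0": xpos[id(p)], "y0": ypos[id(p)],
            "x1": xpos[id(p)], "y1": ypos[id(node)], "kind": "vertical"})
        segments.append({
            "x0": xpos[id(p)], "y0": ypos[id(node)],
            "x1": xpos[id(node)], "y1": ypos[id(node)], "kind": "branch"})
    seg_frame = pd.DataFrame(segments)

    xmax = max(xpos.values()) if xpos else 1.0
    offset = 0.02 * (xmax if xmax > 0 else 1.0)
    markers = []
    frame = exp.abundance.to_frame()
    for tip in exp.taxon_ids:
        if tip not in tip_y:
            continue
        slot = 0
        for s in exp.sample_ids:
            count = frame.loc[tip, s]
            if count > 0:
                rec = {
                    "taxon": tip, "sample": s, "abundance": float(count),
                    "x": xmax + offset * (slot + 1), "y": tip_y[tip],
                }
                if color_var is not None:
                    rec["color"] = exp.samples.loc[s, color_var]
                if shape_var is not None:
                    rec["shape"] = exp.samples.loc[s, shape_var]
                markers.append(rec)
                slot += 1
    marker_frame = pd.DataFrame(
        markers, columns=["taxon", "sample", "abundance", "x", "y"]
        + (["color"] if color_var else []) + (["shape"] if shape_var else []))
    return seg_frame, marker_frame


def bar_plot_data(exp: Experiment, x: str = "Sample",
                  fill: str | None = None,
                  facet: str | None = None) -> pd.DataFrame:
    """Stacked-bar segments: per x group, fill segments sorted descending
    by abundance and cumulatively stacked, so the top of the last segment
    equals the group total."""
    frame = exp.abundance.to_frame()        # taxa x samples
    long = frame.stack().rename("abundance").reset_index()
    long.columns = ["taxon", "sample", "abundance"]

    def sample_group(col):
        if col == "Sample":
            return long["sample"]
        if exp.samples is not None and col in exp.samples.columns:
            return long["sample"].map(exp.samples[col])
        raise ValueError(f"unknown sample variable {col!r}")

    def taxon_group(col):
        if exp.taxonomy is not None and col in exp.taxonomy.columns:
            return long["taxon"].map(exp.taxonomy[col])
        raise ValueError(f"unknown taxonomy rank {col!r}")

    long["x"] = sample_group(x)
    long["fill"] = taxon_group(fill) if fill is not None else long["taxon"]
    if facet is not None:
        if exp.taxonomy is not None and facet in exp.taxonomy.columns:
            long["facet"] = taxon_group(facet)
        else:
            long["facet"] = sample_group(facet)

    keys = (["facet"] if facet else []) + ["x", "fill"]
    agg = long.groupby(keys, dropna=False)["abundance"].sum().reset_index()
    out = []
    group_keys = (["facet"] if facet else []) + ["x"]
    for _, sub in agg.groupby(group_keys, dropna=False, sort=True):
        sub = sub.sort_values(["abundance", "fill"], ascending=[False, True])
        bottom = 0.0
        for _, row in sub.iterrows():
            rec = dict(row)
            rec["bottom"] = bottom
            rec["top"] = bottom + row["abundance"]
            bottom = rec["top"]
            out.append(rec)
    cols = group_keys + ["fill", "abundance", "bottom", "top"]
    return pd.DataFrame(out)[cols]


def richness_plot_data(exp: Experiment, x: str, color: str | None = None,
                       measures=("Observed", "Shannon")) -> pd.DataFrame:
    """Long table (sample, x, [color], measure, estimate, se) delegating
    the estimates to :func:`estimate_richness`."""
    if exp.samples is None or x not in exp.samples.columns:
        raise ValueError(f"unknown sample variable {x!r}")
    if color is not None and color not in exp.samples.columns:
        raise ValueError(f"unknown sample variable {color!r}")
    rich = estimate_richness(exp, measures=measures)
    rows = []
    for s in exp.sample_ids:
        for m in measures:
            se_col = {"Chao1": "se.chao1", "ACE": "se.ACE"}.get(m)
            rec = {
                "sample": s,
                "x": exp.samples.loc[s, x],
                "measure": m,
                "estimate": rich.loc[s, m],
                "se": rich.loc[s, se_col] if se_col else np.nan,
            }
            if color is not None:
                rec["color"] = exp.samples.loc[s, color]
            rows.append(rec)
    cols = ["sample", "x"] + (["color"] if color else []) + ["measure", "estimate", "se"]
    return pd.DataFrame(rows)[cols]
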