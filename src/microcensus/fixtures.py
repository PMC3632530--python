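"""Synthetic experiment generation.

Everything downstream is testable without external data: random
coalescent-style trees with exponential branch lengths, and
group-structured multinomial count tables with a Dirichlet community
profile.  ``effect_size=1`` makes the group label independent of the
counts (an exchangeable null, used for error-rate calibration);
``effect_size>1`` multiplies the proportions of ``effect_taxa`` taxa in
alternating groups before renormalizing.  Counts are multinomial at a
fixed depth, so every sample total is exactly ``depth``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    AbundanceTable,
    DEFAULT_RANKS,
    Experiment,
    PhyloTree,
    build_experiment,
    make_sample_table,
    make_taxonomy_table,
)


def random_tree(n_tips: int, seed: int) -> PhyloTree:
    """Random coalescent-style topology with exponential branch lengths.

    Tips are labeled OTU1..OTUn; deterministic given ``seed``.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    # coalesce random lineage pairs at exponential waiting times
    frags = [f"OTU{i + 1}" for i in range(n_tips)]
    heights = [0.0] * n_tips
    t = 0.0
    while len(frags) > 1:
        k = len(frags)
        t += float(rng.exponential(scale=1.0 / (k * (k - 1) / 2)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        bi, bj = t - heights[i], t - heights[j]
        merged = f"({frags[i]}:{bi:.10g},{frags[j]}:{bj:.10g})"
        frags = [f for idx, f in enumerate(frags) if idx not in (i, j)] + [merged]
        heights = [h for idx, h in enumerate(heights) if idx not in (i, j)] + [t]
    return PhyloTree.from_newick(frags[0] + ";")


def _hierarchical_taxonomy(taxon_ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Consistent ranked taxonomy: nested random groupings, coarser ranks
    having fewer groups."""
    n = len(taxon_ids)
    paths = ["Bacteria"] * n
    assignments: dict[str, list[str]] = {"Kingdom": list(paths)}
    for rank in DEFAULT_RANKS[1:]:
        by_parent: dict[str, list[int]] = {}
        for idx, p in enumerate(paths):
            by_parent.setdefault(p, []).append(idx)
        new_paths = [""] * n
        for p, members in by_parent.items():
            k = int(rng.integers(1, 3))  # each group splits into 1 or 2
            split = rng.integers(0, k, size=len(members))
            for pos, idx in enumerate(members):
                new_paths[idx] = f"{p}.{rank[0].lower()}{split[pos]}"
        paths = new_paths
        assignments[rank] = list(paths)
    frame = pd.DataFrame(assignments, index=taxon_ids)
    return make_taxonomy_table(frame, DEFAULT_RANKS)


def simulate_experiment(n_taxa: int = 50, n_samples: int = 20, n_groups: int = 2,
                        effect_taxa: int = 0, effect_size: float = 1.0,
                        depth: int = 1000, seed: int = 0,
                        with_tree: bool = True,
                        with_taxonomy: bool = True) -> Experiment:
    """Group-structured multinomial count experiment.

    Per-sample counts are multinomial(depth, p_g); the group-g proportions
    p_g are one shared Dirichlet(1) draw with the first ``effect_taxa``
    components multiplied by ``effect_size`` in alternating (odd) groups,
    then renormalized.  ``effect_size=1`` gives exchangeable groups.
    Samples are assigned to groups round-robin; a random tree, nested
    taxonomy and a group-label sample table are attached.
    """
    if effect_taxa > n_taxa:
        raise ValueError("effect_taxa cannot exceed n_taxa")
    if n_groups > n_samples:
        raise ValueError("n_groups cannot exceed n_samples")
    if n_taxa < 2 or n_samples < 1 or depth < 1 or n_groups < 1:
        raise ValueError("invalid sizes")
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.ones(n_taxa))
    props = []
    for g in range(n_groups):
        p = base.copy()
        if g % 2 == 1 and effect_taxa > 0:
            p[:effect_taxa] *= effect_size
            p /= p.sum()
        props.append(p)

    taxon_ids = [f"OTU{i + 1}" for i in range(n_taxa)]
    sample_ids = [f"S{j + 1}" for j in range(n_samples)]
    groups = [j % n_groups for j in range(n_samples)]
    counts = np.zeros((n_taxa, n_samples))
    for j, g in enumerate(groups):
        counts[:, j] = rng.multinomial(depth, props[g])

    ab = AbundanceTable(counts, taxon_ids, sample_ids)
    samples = make_sample_table(pd.DataFrame(
        {"Group": [f"G{g + 1}" for g in groups],
         "Depth": [float(depth)] * n_samples},
        index=sample_ids))
    tree = random_tree(n_taxa, seed=int(rng.integers(0, 2 ** 31 - 1))) if with_tree else None
    taxonomy = _hierarchical_taxonomy(taxon_ids, rng) if with_taxonomy else None
    return build_experiment(ab, samples=samples, taxonomy=taxonomy, tree=tree)


PRESETS = {
    "small": dict(n_taxa=12, n_samples=6, n_groups=2, effect_taxa=0,
                  effect_size=1.0, depth=200),
    "null": dict(n_taxa=50, n_samples=20, n_groups=2, effect_taxa=0,
                 effect_size=1.0, depth=1000),
    "signal": dict(n_taxa=50, n_samples=20, n_groups=2, effect_taxa=5,
                   effect_size=8.0, depth=1000),
}


def preset_experiment(name: str, seed: int) -> Experiment:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return simulate_experiment(seed=seed, **PRESETS[name])
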