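"""Experiment container for microbiome census data.

The central object is :class:`Experiment`: an abundance table of taxa
(OTUs) by samples, optionally integrated with per-sample variables, a
taxonomy table, a phylogenetic tree over the taxa, and reference
sequences.  All components share one canonical taxon ordering and one
canonical sample ordering, so subsetting one component propagates to all
of them.  Validity checks are consolidated in :func:`build_experiment`;
downstream functions may assume a valid instance.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("microcensus")

MISSING = ""  # canonical missing marker in taxonomy tables

DEFAULT_RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species")


class ConstructionError(ValueError):
    """Raised when components cannot be assembled into a valid Experiment."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ConstructionError(f"duplicate {what} IDs: {sorted(set(dups))[:10]}")
    return ids


class AbundanceTable:
    """Non-negative taxa x samples matrix of counts or transformed abundances.

    The matrix is stored canonically with taxa as rows regardless of the
    orientation of the source file; ``taxa_are_rows`` records the source
    orientation for faithful re-export only.
    """

    def __init__(self, values, taxon_ids, sample_ids, taxa_are_rows: bool = True):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ConstructionError("abundance matrix must be 2-dimensional")
        if not taxa_are_rows:
            values = values.T
        self.taxon_ids = _check_unique(taxon_ids, "taxon")
        self.sample_ids = _check_unique(sample_ids, "sample")
        if values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ConstructionError(
                f"abundance shape {values.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if np.any(values < 0):
            raise ConstructionError("abundance matrix has negative entries")
        if np.any(~np.isfinite(values)):
            raise ConstructionError("abundance matrix has non-finite entries")
        self.values = values
        self.taxa_are_rows = bool(taxa_are_rows)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def taxon_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.sample_ids)

    def select(self, taxa: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "AbundanceTable":
        ti = [self.taxon_ids.index(t) for t in taxa] if taxa is not None else slice(None)
        si = [self.sample_ids.index(s) for s in samples] if samples is not None else slice(None)
        vals = self.values[ti][:, si] if taxa is not None or samples is not None else self.values
        return AbundanceTable(
            vals,
            list(taxa) if taxa is not None else list(self.taxon_ids),
            list(samples) if samples is not None else list(self.sample_ids),
            taxa_are_rows=self.taxa_are_rows,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AbundanceTable)
            and self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"AbundanceTable({self.n_taxa} taxa x {self.n_samples} samples)"


def make_sample_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample variable table (rows = samples)."""
    _check_unique(list(frame.index), "sample")
    frame = frame.copy()
    frame.index = [str(i) for i in frame.index]
    return frame


def make_taxonomy_table(frame: pd.DataFrame,
                        ranks: Sequence[str] | None = None) -> pd.DataFrame:
    """Validate a taxon x rank assignment table; missing entries normalized.

    Both NaN and empty strings are accepted as missing and normalized to
    one canonical representation.
    """
    _check_unique(list(frame.index), "taxon")
    frame = frame.copy()
    frame.index = [str(i) for i in frame.index]
    if ranks is not None:
        frame = frame.reindex(columns=list(ranks))
    out = frame.astype("object").where(frame.notna(), MISSING)
    return out.map(lambda v: MISSING if str(v).strip() == "" else str(v).strip())


class PhyloTree:
    """Rooted (or flagged-unrooted) phylogenetic tree over the taxa.

    Thin wrapper around a dendropy tree.  Branch lengths missing in the
    source are resolved to 0 so that every edge has a non-negative length.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        for edge in tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
            elif edge.length < 0:
                raise ConstructionError("negative branch length in tree")
        _check_unique(self.tip_labels, "tree tip")

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"newick parse error: {exc}") from exc
        return cls(tree)

    # -- basic properties ----------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def is_unrooted(self) -> bool:
        """True when the basal node is a trifurcation (classic unrooted form)."""
        return len(self._tree.seed_node.child_nodes()) > 2

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- operations -----------------------------------------------------
    def prune_to(self, keep: Iterable[str]) -> "PhyloTree":
        """Prune to the given tips; degree-2 nodes left behind are contracted
        with branch-length addition so patristic distances among kept tips
        are unchanged."""
        keep = set(keep)
        unknown = keep - set(self.tip_labels)
        if unknown:
            raise KeyError(f"tips not in tree: {sorted(unknown)[:10]}")
        tree = self._tree.clone(depth=1)
        taxa = [t for t in tree.taxon_namespace if t.label in keep]
        tree.retain_taxa(taxa, suppress_unifurcations=True)
        # dendropy may leave a unifurcate seed node; fold its edge away
        seed = tree.seed_node
        while len(seed.child_nodes()) == 1 and not seed.is_leaf():
            child = seed.child_nodes()[0]
            tree.seed_node = child
            child.parent_node = None
            seed = child
        return PhyloTree(tree)

    def midpoint_rooted(self) -> "PhyloTree":
        tree = self._tree.clone(depth=1)
        tree.reroot_at_midpoint(update_bipartitions=False)
        return PhyloTree(tree)

    def patristic_matrix(self) -> tuple[list[str], np.ndarray]:
        """Tip labels and the symmetric matrix of tip-to-tip path lengths."""
        pdm = self._tree.phylogenetic_distance_matrix()
        labels = self.tip_labels
        taxa = {t.label: t for t in self._tree.taxon_namespace if t.label in set(labels)}
        n = len(labels)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                out[i, j] = out[j, i] = d
        return labels, out

    def __repr__(self) -> str:
        return f"PhyloTree({self.n_tips} tips{', unrooted' if self.is_unrooted else ''})"


IUPAC = set("ACGTURYSWKMBDHVN-.acgturyswkmbdhvn")


def make_refseq(seqs: Mapping[str, str]) -> dict[str, str]:
    """Validate a taxon -> nucleotide sequence mapping (IUPAC alphabet)."""
    out: dict[str, str] = {}
    for k, v in seqs.items():
        bad = set(v) - IUPAC
        if bad:
            raise ConstructionError(f"non-IUPAC characters in sequence {k!r}: {sorted(bad)}")
        out[str(k)] = str(v)
    _check_unique(list(out), "refseq")
    return out


@dataclass
class Experiment:
    """Integrated multi-component microbiome experiment.

    All component taxon/sample ID sets are identical and identically
    ordered (canonical order = abundance order).  Construct via
    :func:`build_experiment`, which intersects, reorders and validates.
    """

    abundance: AbundanceTable
    samples: pd.DataFrame | None = None
    taxonomy: pd.DataFrame | None = None
    tree: PhyloTree | None = None
    refseq: dict[str, str] | None = None

    @property
    def taxon_ids(self) -> list[str]:
        return self.abundance.taxon_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.abundance.sample_ids

    @property
    def n_taxa(self) -> int:
        return self.abundance.n_taxa

    @property
    def n_samples(self) -> int:
        return self.abundance.n_samples

    @property
    def ranks(self) -> list[str]:
        return [] if self.taxonomy is None else list(self.taxonomy.columns)

    def validate(self) -> None:
        taxa = self.taxon_ids
        if self.taxonomy is not None and list(self.taxonomy.index) != taxa:
            raise ConstructionError("taxonomy IDs do not match abundance order")
        if self.tree is not None and sorted(self.tree.tip_labels) != sorted(taxa):
            raise ConstructionError("tree tips do not match abundance taxa")
        if self.refseq is not None and list(self.refseq) != taxa:
            raise ConstructionError("refseq IDs do not match abundance order")
        if self.samples is not None and list(self.samples.index) != self.sample_ids:
            raise ConstructionError("sample table IDs do not match abundance order")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Experiment):
            return NotImplemented
        if self.abundance != other.abundance:
            return False
        for a, b in ((self.samples, other.samples), (self.taxonomy, other.taxonomy)):
            if (a is None) != (b is None):
                return False
            if a is not None and not a.equals(b):
                return False
        if (self.tree is None) != (other.tree is None):
            return False
        if self.tree is not None and self.tree.to_newick() != other.tree.to_newick():
            return False
        return (self.refseq or None) == (other.refseq or None)

    def __repr__(self) -> str:
        parts = [f"{self.n_taxa} taxa x {self.n_samples} samples"]
        for name in ("samples", "taxonomy", "tree", "refseq"):
            if getattr(self, name) is not None:
                parts.append(name)
        return f"Experiment({', '.join(parts)})"


def build_experiment(abundance: AbundanceTable,
                     samples: pd.DataFrame | None = None,
                     taxonomy: pd.DataFrame | None = None,
                     tree: PhyloTree | None = None,
                     refseq: Mapping[str, str] | None = None) -> Experiment:
    """Assemble components into a validated :class:`Experiment`.

    Component ID sets are intersected (logging how many IDs each component
    drops) and every component is reordered to the abundance's canonical
    order.  An empty taxon or sample intersection is an error naming the
    offending component pair.
    """
    if abundance is None:
        raise ConstructionError("an experiment without an abundance table is invalid")

    taxa = list(abundance.taxon_ids)
    for name, ids in (("taxonomy", None if taxonomy is None else list(taxonomy.index)),
                      ("tree", None if tree is None else tree.tip_labels),
                      ("refseq", None if refseq is None else list(refseq))):
        if ids is None:
            continue
        if len(ids) == 0:
            raise ConstructionError(f"supplied {name} component is empty")
        idset = set(_check_unique(ids, name))
        new = [t for t in taxa if t in idset]
        if not new:
            raise ConstructionError(
                f"empty taxon intersection between abundance and {name}")
        taxa = new

    samples_ids = list(abundance.sample_ids)
    if samples is not None:
        if len(samples.index) == 0:
            raise ConstructionError("supplied sample table is empty")
        sset = set(_check_unique(list(samples.index), "sample table"))
        samples_ids = [s for s in samples_ids if s in sset]
        if not samples_ids:
            raise ConstructionError(
                "empty sample intersection between abundance and sample table")

    dropped_taxa = abundance.n_taxa - len(taxa)
    dropped_samples = abundance.n_samples - len(samples_ids)
    if dropped_taxa or dropped_samples:
        logger.info("build_experiment: dropped %d taxa and %d samples during "
                    "component intersection", dropped_taxa, dropped_samples)

    ab = abundance.select(taxa, samples_ids)
    tx = None if taxonomy is None else make_taxonomy_table(taxonomy).loc[taxa]
    tr = None if tree is None else tree.prune_to(taxa)
    rs = None if refseq is None else {t: refseq[t] for t in taxa}
    sm = None if samples is None else make_sample_table(samples).loc[samples_ids]
    exp = Experiment(ab, sm, tx, tr, None if rs is None else make_refseq(rs))
    exp.validate()
    return exp


def prune_taxa(keep_ids: Iterable[str], exp: Experiment) -> Experiment:
    """Restrict every component to ``keep_ids`` (relative order preserved)."""
    keep = set(keep_ids)
    unknown = keep - set(exp.taxon_ids)
    if unknown:
        raise KeyError(f"unknown taxon IDs: {sorted(unknown)[:10]}")
    if not keep:
        raise ValueError("keep_ids is empty; refusing to build a taxonless experiment")
    taxa = [t for t in exp.taxon_ids if t in keep]
    return Experiment(
        exp.abundance.select(taxa=taxa),
        exp.samples,
        None if exp.taxonomy is None else exp.taxonomy.loc[taxa],
        None if exp.tree is None else exp.tree.prune_to(taxa),
        None if exp.refseq is None else {t: exp.refseq[t] for t in taxa},
    )


def prune_samples(keep_ids: Iterable[str], exp: Experiment) -> Experiment:
    """Restrict the abundance columns and sample table to ``keep_ids``."""
    keep = set(keep_ids)
    unknown = keep - set(exp.sample_ids)
    if unknown:
        raise KeyError(f"unknown sample IDs: {sorted(unknown)[:10]}")
    if not keep:
        raise ValueError("keep_ids is empty; refusing to build a sampleless experiment")
    samples = [s for s in exp.sample_ids if s in keep]
    return Experiment(
        exp.abundance.select(samples=samples),
        None if exp.samples is None else exp.samples.loc[samples],
        exp.taxonomy,
        exp.tree,
        exp.refseq,
    )


def merge_taxa(exp: Experiment, ids: Sequence[str], archetype: str) -> Experiment:
    """Sum the abundance rows of ``ids`` into ``archetype``; other components
    keep only the archetype's entry.  Per-sample totals are conserved."""
    ids = list(ids)
    if archetype not in ids:
        raise ValueError(f"archetype {archetype!r} not among ids to merge")
    unknown = set(ids) - set(exp.taxon_ids)
    if unknown:
        raise KeyError(f"unknown taxon IDs: {sorted(unknown)[:10]}")
    if len(ids) == 1:
        return exp
    frame = exp.abundance.to_frame()
    merged_row = frame.loc[ids].sum(axis=0)
    drop = [t for t in ids if t != archetype]
    taxa = [t for t in exp.taxon_ids if t not in drop]
    frame = frame.loc[taxa]
    frame.loc[archetype] = merged_row
    ab = AbundanceTable(frame.values, taxa, exp.sample_ids,
                        taxa_are_rows=exp.abundance.taxa_are_rows)
    return Experiment(
        ab,
        exp.samples,
        None if exp.taxonomy is None else exp.taxonomy.loc[taxa],
        None if exp.tree is None else exp.tree.prune_to(taxa),
        None if exp.refseq is None else {t: exp.refseq[t] for t in taxa},
    )
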