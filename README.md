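# microcensus

Integrated analysis of microbiome census data in Python: a
multi-component experiment container with consistent subsetting
semantics, importers for the common OTU-clustering output formats,
40+ ecological distances including a native Fast UniFrac, ordination
(CA, PCoA/MDS, NMDS, PCA, RDA/CCA, DPCoA), alpha-diversity estimation,
permutation-based multiple testing with family-wise error control, and
deterministic layout computations for the standard microbiome plots.

## Who this is for

After sequence decoding and OTU clustering (QIIME, mothur, or any
pipeline that emits a BIOM table), an investigator holds several
heterogeneous objects: an OTU-by-sample count table, per-sample
covariates, taxonomic assignments, a phylogenetic tree, and reference
sequences. `microcensus` binds them into one `Experiment` whose
components always share a single taxon ordering and a single sample
ordering, so that filtering, agglomeration or subsetting one component
propagates everywhere — the step of the analysis where bookkeeping
mistakes are otherwise easiest to make and hardest to notice.
Upstream sequence processing and OTU clustering are deliberately out of
scope, as are the aesthetics of rendering (the `viz` module computes plot
*data* — coordinates, orderings, stacked segments — and leaves styling to
the caller).

## The methods at the core

**Fast UniFrac.** One post-order traversal of the tree fills, for every
branch *i*, its length *b_i* and the per-sample abundance totals of the
tips below it (`BranchAbundance`); every pairwise distance then reuses
this table. For samples *A*, *B* with totals *A_T*, *B_T* and
root-to-tip depths *d_j*:

- unweighted: `sum(b_i over branches in exactly one sample) / sum(b_i over occupied branches)`
- weighted (raw): `sum_i b_i |A_i/A_T − B_i/B_T|`
- weighted (normalized): raw divided by `sum_j d_j (A_j/A_T + B_j/B_T)`

Distances are computed per sample pair by pure functions, so the pair set
can be partitioned across workers with bitwise-identical results
(`workers=` argument).

**Distance registry.** `list_distance_methods()` enumerates 44 named
dissimilarities: the quantitative ecological indices (Bray–Curtis,
Canberra, Kulczynski, Morisita, Horn–Morisita, Chao–Jaccard, chi-square,
Jensen–Shannon divergence, ...), the 24 classic presence/absence
incidence indices expressed in shared/unique species counts (a, b, c),
and the tree-based methods (unweighted/weighted UniFrac, DPCoA
distances). The quantitative and incidence formulas were cross-checked
value-by-value against the vegan R package; those frozen references live
in the test suite.

**minP multiple testing.** `mt_minp` tests every taxon against a sample
classification (one-way F or t statistics), with raw permutation
p-values `(1 + #{|T_b| ≥ |T_obs|}) / (B + 1)` and Westfall–Young
step-down minP adjusted p-values computed on the joint permutation null
— every permuted statistic is ranked within the same pooled set of B+1
values as the observed one, which is what makes the null minima
exchangeable with the observed minimum and the FWER control honest.

**Ordination.** `ordinate(exp, method, ...)` dispatches to
correspondence analysis (inertia = chi-square/N), principal coordinates
(negative eigenvalues reported, not hidden), Kruskal NMDS (stress-1 with
isotonic regression, best of seeded multiple starts), PCA, constrained
RDA/CCA (constrained + residual inertia = total), and DPCoA (taxa
embedded from square-root patristic distances, samples at
abundance-weighted centroids).

## Worked example

```python
import microcensus as mc

exp = mc.simulate_experiment(n_taxa=40, n_samples=20, n_groups=2,
                             effect_taxa=4, effect_size=6.0,
                             depth=2000, seed=7)
exp = mc.rarefy_even_depth(exp, depth=1500, seed=7)       # even depth
exp = mc.filter_taxa_k_over_a(exp, k_fraction=0.2, a=2)   # >2 in >=20%
print(exp)
# Experiment(37 taxa x 20 samples, samples, taxonomy, tree)

d = mc.unifrac(exp, weighted=True, normalized=True)
ordp = mc.ordinate(exp, "MDS", "wunifrac")
print(round(float(ordp.proportions()[:2].sum()), 3))
# 0.93        <- axes 1+2 carry 93% of the (positive) inertia

tab = mc.mt_minp(exp, "Group", stat="f", B=999, seed=1)
print(tab.head(4).round(4))
#       index  statistic  raw_p  adj_p
# OTU2      2  1798.8148  0.001  0.011
# OTU4      4  1202.1374  0.001  0.011
# OTU3      3   586.6460  0.001  0.011
# OTU1      1   561.1913  0.001  0.011
```

The four spiked taxa (OTU1–OTU4) head the table with family-wise
adjusted p ≈ 0.011; the `index` column is each taxon's row position in
the original table. Rarefaction and every other stochastic step demand
an explicit seed — rerunning any seeded pipeline is byte-identical.

The same pipeline is available from the shell over zip "experiment
bundles" (BIOM v1 + TSV + Newick + FASTA):

```sh
microcensus fixtures generate --preset signal --seed 7 --out e.zip
microcensus rarefy e.zip --depth 800 --seed 7 --out even.zip
microcensus distance even.zip --method wunifrac --out dist.tsv
microcensus mt even.zip --class Group --stat f -B 9999 --seed 11 --out tests.tsv
```

## Format support

BIOM v1 JSON (dense and sparse; BIOM v2/HDF5 is rejected with an
explanatory message), QIIME legacy OTU tables with `Consensus Lineage`
columns, mothur `.shared`/`.cons.taxonomy`, Newick, FASTA, TSV/CSV
sample tables. RDP-pipeline and Pyrotagger exports are not supported
(the CLI names them and suggests converting to BIOM); those formats are
effectively extinct and documented as out of scope.
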