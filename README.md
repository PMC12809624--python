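# microtempo

Tools for asking *how* microbial communities are assembled through time.
Given a marine (or any) microbial observatory time series — an ASV count
table, a rooted phylogeny, sample metadata and optionally a static
association network — `microtempo` quantifies the balance between
deterministic selection and stochastic processes, detects seasonal taxa,
classifies ASVs by their distribution across two sites, and tracks how
co-occurrence network architecture reorganises month by month. A
synthetic two-observatory generator (a seasonally forced "temperate"
site versus a near-constant "tropical" site) makes every stage testable
end to end without any sequencing data.

## The core model

For each pair of communities *(j, k)* within a dataset:

1. **Phylogenetic turnover.** The abundance-weighted β-mean nearest
   taxon distance,

   βMNTD(j,k) = ½ [ Σ_{i∈j} f_ij · min_{i′∈k} d(i,i′) + Σ_{i′∈k} f_i′k · min_{i∈j} d(i,i′) ],

   with *f* relative abundances and *d* the cophenetic distance, is
   compared against a null distribution obtained by shuffling taxa
   labels across the distance matrix (999 randomisations). The z-score
   is the β-nearest taxon index, **βNTI**.

2. **Taxonomic turnover.** For pairs not explained by selection, the
   **Raup–Crick** metric on Bray–Curtis dissimilarities (RC_bray)
   ranks the observed dissimilarity within a null ensemble that
   preserves each sample's richness and total count (taxa drawn by
   occurrence frequency, individuals by mean relative abundance),
   rescaled to [−1, 1].

3. **Classification** (temporal framework): βNTI > 2 → heterogeneous
   selection; βNTI < −2 → homogeneous selection; otherwise RC_bray >
   0.95 → historical contingency, RC_bray < −0.95 → non-selective low
   turnover, |RC_bray| ≤ 0.95 → ecological drift.

Around this core: Lomb–Scargle seasonality on unevenly sampled series
(peak normalised power PN > 0.2, permutation p < 0.01, period within
~1 year), IndVal.g indicator analysis (stat > 0.7, p < 0.01),
common/exclusive/background categories, PERMANOVA (adonis2-style
sequential R²), rarefaction, alpha diversity (Shannon, Pielou, richness,
Faith PD), CLR transformation, joint-detection edge filtering and
monthly temporal subnetworks with the standard global topology metrics.

## Worked example

```sh
python examples/03_assembly_processes.py
```

```
fraction of sample pairs per assembly process:
group                       temperate|small  tropical|small
heterogeneous selection               0.352           0.018
homogeneous selection                 0.000           0.000
historical contingency                0.141           0.867
non-selective low turnover            0.212           0.048
ecological drift                      0.294           0.067
```

The seasonally forced site is selection-dominated (35% of pairs show
higher phylogenetic turnover than the null expects: the environment
sweeps through the year and selects different taxa in different
months), while the unforced site's pairs fall almost entirely in the
stochastic classes (drift plus historical contingency ≈ 0.93). Each
`examples/*.py` script demonstrates one capability the same way; the
whole pipeline runs as `microtempo demo --seed 1` (or
`python examples/07_full_demo.py`), writing tidy TSVs, provenance
manifests and a `summary.json` contrasting the two sites.

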