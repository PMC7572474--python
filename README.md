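# nichescope

Fundamental and realized niche typing for microbial community time-series
from multi-omic data.

Mixed microbial communities — activated sludge, anaerobic digesters, natural
consortia — are shaped by which capabilities each population *encodes* (its
fundamental niche) and which it actually *expresses* under in-situ conditions
(its realized niche). `nichescope` implements a complete analysis pipeline
for resolving both from time-resolved metagenomic (MG), metatranscriptomic
(MT), metaproteomic (MP) and metabolomic measurements over a set of
representative metagenome-assembled genomes (rMAGs), together with a
synthetic multi-omic community generator that provides ground truth for every
stage.

## What it computes

**Fundamental niches.** Each rMAG's KEGG-ortholog (KO) repertoire is a binary
vector; pairwise binary Jaccard distances

&nbsp;&nbsp;&nbsp;&nbsp;d(a, b) = 1 − |a ∧ b| / |a ∨ b|

are embedded in two dimensions by classical MDS and clustered by k-means,
with the number of centroids k ∈ {1, …, 9} selected by the maximum-chord-
distance elbow rule on the total within-cluster sum of squares. The resulting
functional clusters (FunCs) are characterized by one-sided Fisher exact KO
enrichment (Benjamini–Hochberg adjusted over all KO × FunC pairs),
UpSet-style exact set-overlap partitions, completeness-adjusted pathway
prevalence, and Procrustes/PROTEST agreement with an independent genome-scale
ordination.

**Community dynamics.** Relative abundances from depth-of-coverage
(summed per-base depth / sequence length, contig-length-weighted per rMAG)
are compared through the correlation distance d = 1 − (ρ+1)/2, tested against
FunC membership with PERMANOVA (pseudo-F, R² = 1 − SS_within/SS_total,
permutation p) and a betadisper-style dispersion test. Temporal stability is
the invariability ratio mean/sd of each abundance series, with and without a
disturbance window. Bray–Curtis ordination plus least-squares vector fitting
links community structure to abiotic factors; gappy factor series are
completed by Stineman interpolation.

**Realized niches.** A KO is *active* for an rMAG at a time-point if any of
its genes has MT/MG depth ratio > 1 (MT depth > 1 when MG depth < 1), or ≥ 2
peptide spectral counts. Per time-point, rMAGs are clustered on binary
Jaccard distances over their activity vectors (classical MDS → HDBSCAN,
minimum five members, explicit noise label). MT/MG depth ratios summarize
transcriptional activity per rMAG, FunC and condition.

**Functional trends, metabolomics, taxonomy.** Gene-level MT depth and MP
counts are aggregated per FOAM L1 category, normalized by community totals,
min–max scaled and correlated. Metabolite runs are QC-filtered (blank rule:
mean blank intensity > 75 % of mean sample intensity; detection in all pools
and ≥ 25 % of samples), normalized against the mean of up to two preceding
and two following pool injections, and intracellular/extracellular ratios are
computed for metabolites detected in both fractions. Marker-gene taxonomies
are combined by probability-mass voting per rank (winners holding < 1/3 of
the mass become "low confidence assignment") and merged with genome-level
calls.

## Worked example

Generate a synthetic community (78 rMAGs, 4 planted functional types, 51
weekly time-points, one transient disturbance) and type its niches:

```bash
python analysis/01_simulate_community.py
python analysis/02_fundamental_niches.py
```

which prints (seed 20):

```
                  statistic    value
                    elbow_k   4.0000
       ari_vs_planted_types   1.0000
   variance_explained_axis1   0.3018
   variance_explained_axis2   0.2481
n_enriched_ko_cluster_pairs 387.0000
    kos_shared_by_all_funcs 215.0000
              procrustes_m2   0.0107
            procrustes_corr   0.9946
                  protest_p   0.0010
```

The elbow rule recovers the four planted types exactly (adjusted Rand index
1.0 against the ground truth), 387 KO × FunC pairs are significantly
enriched, and the gene-level embedding matches the full-repertoire embedding
almost perfectly (Procrustes correlation 0.995, PROTEST p = 0.001 at 999
permutations). The remaining drivers (`03` … `07`) run the dynamics,
expression, trend, metabolomics and taxonomy stages the same way, each
printing its headline statistics and writing tables under `results/`.

The same pipeline runs on user data from TSV inputs via the CLI:

```bash
nichescope simulate --seed 20 --out data/          # or bring your own TSVs
nichescope run-all --data data/ --out out/ --seed 20
```

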