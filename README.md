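# panicleheat

Time-course heat-stress transcriptome analysis for rice panicle.

Rice at the reproductive stage is acutely heat-sensitive, and the classic
desk analysis of a panicle heat-shock experiment follows one pipeline: a
single-channel microarray time course (untreated control plus 20 min,
60 min, 2 h, 4 h and 8 h at 40 °C, two biological replicates each) is
normalized and QC'd, heat-responsive genes are called by fold-change rules,
partitioned into temporal co-expression clusters, and the clusters'
promoters are mined for over-represented cis-regulatory elements and
element co-occurrence networks, with qRT-PCR validation of selected genes.
`panicleheat` implements that pipeline end to end as a tested, reusable
library plus CLI, together with seeded synthetic-data generators so every
stage can be validated against planted ground truth without microarray
data in hand.

## What it computes

**Expression pipeline** (`panicleheat.expression`). Quantile normalization
(each rank replaced by the cross-sample mean at that rank), per-probe
baseline-to-median centering, replicate QC by Pearson correlation and
complete-linkage trees on 1 − r, detection-flag filtering (probes with a
P call in ≥ 6 of 12 samples), and log2 fold changes
log2FC(p, t) = mean log2 x(p, t) − mean log2 x(p, CK). A probe is
*differential* at time t when |log2FC| > log2(3) (strict), *heat-responsive
(HR)* when differential in ≥ 2 of the 5 treatment time points, direction
need not be consistent.

**Clustering** (`panicleheat.clustering`). Euclidean k-means (k-means++,
10 seeded restarts, default k = 12) of temporal profiles, rule-based
pattern labels (early/late/continuous up/down, early-down-late-up, mixed)
from the centroid log2FC trajectory, and hypergeometric category
over-representation per cluster.

**Promoter motifs** (`panicleheat.motifs`). IUPAC consensus scanning of
−3000..−1 promoters on both strands, gene-level counting, and two
hypergeometric statistics against the whole-database background. For a
motif carried by m of M cluster genes and n of N database genes:

    ratio = (m/M) / (n/N),      p = Σ_{i≥m} C(n,i) C(N−n, M−i) / C(N, M)

Two distinct motifs *co-occur* in a promoter when any two matches start
within 250 bp, counted at most once per promoter; pair significance uses
the same upper tail with (t, T, k, K) in place of (m, M, n, N). Results
assemble into a Cytoscape-style network: node size = carrier count, color =
enrichment ratio, shape = significance (diamond p < 0.001, triangle
p < 0.05, circle otherwise), edges solid (p < 0.01) or dashed (p < 0.05).

**qPCR validation** (`panicleheat.qpcr`). 2^(−ΔΔCT) relative
quantification against a reference gene (actin-1) and calibrator condition
(CK), technical replicates averaged on the CT scale, and sign-concordance /
correlation of qPCR log2 RQ with array log2FC.

**Synthetic data** (`panicleheat.simulate`). Seeded generators for all of
the above with planted ground truth: expression matrices with 12 temporal
archetype profiles, P/A/M flags, promoter databases with motifs planted at
controlled per-cluster frequencies and pairs at fixed start-to-start
distances, and qPCR plates encoding known fold changes.

## Worked example

```python
from panicleheat import *

cfg = default_expression_config(seed=1, n_probes=2000, n_planted_per_cluster=30)
dataset, truth = generate_expression_dataset(cfg)
dataset.values = quantile_normalize(dataset.values)
qc = replicate_correlation(dataset.values, dataset.design)
print(f"replicate correlations: min r = {qc.replicate_pairs['r'].min():.4f}")
kept = flag_filter(dataset)
fct = fold_changes(dataset.subset(kept))
calls = differential_probes(fct, fold=3)
hr = heat_responsive(calls, dataset.probe_gene, min_timepoints=2)
print(f"heat-responsive: {len(hr.probes)} probes, {len(hr.genes)} genes")

promoters, library, ptruth = generate_promoter_set(default_promoter_config(seed=1))
occ = scan_motifs(promoters, library)
db = build_background(occ, promoters, window=250)
cluster1 = [g for g, c in ptruth.planted_cluster.items() if c == 1]
top = motif_enrichment(cluster1, db).sort_values("p").iloc[0]
print(f"top motif: {top.motif} ratio={top.ratio:.2f} p={top.p:.2e} [{top.node_class}]")
edge = pair_cooccurrence(cluster1, db).sort_values("p").iloc[0]
print(f"top pair: {edge.motif_a}--{edge.motif_b} p={edge.p:.2e} [{edge.edge_class}]")
```

prints

```
replicate correlations: min r = 0.9902
heat-responsive: 277 probes, 268 genes
top motif: HSE_like ratio=3.70 p=3.57e-24 [diamond]
top pair: CE3_like--GCC_box_like p=2.54e-15 [solid]
```

The replicates correlate above the 0.99 QC bar; 277 of 2,000 probes exceed
3-fold at ≥ 2 time points; the HSE-like element planted in 80% of cluster-1
promoters against a 10% background comes out most enriched (3.7× the
background frequency, diamond class), and the pair planted 100 bp apart in
60% of cluster promoters forms the strongest (solid) co-occurrence edge.

The same stages are available from the shell, e.g.

```sh
panicleheat simulate expression --seed 1 --out sim/
panicleheat hr --matrix sim/expression.tsv --flags sim/flags.tsv \
    --design sim/design.csv --annotation sim/probe_gene.tsv --out hr.tsv
panicleheat simulate promoters --seed 1 --out prom/
panicleheat network --promoters prom/promoters.fasta --motifs prom/motifs.tsv \
    --cluster prom/cluster1_genes.txt --out-prefix net/cluster1
```

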