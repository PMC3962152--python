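# hubnet

Hub-gene prioritization from confidence-weighted protein–protein interaction
(PPI) networks, with downstream gene-set enrichment and cross-dataset
differential-expression meta-analysis.

## The problem

Interaction databases such as STRING export a weighted network: proteins as
nodes, predicted functional associations as edges, each edge carrying a
combined confidence score in [0, 1]. A common systems-biology workflow —
used, for example, to study the interactome of a disease-relevant receptor in
leukemia — is:

1. **Filter** the network to high-confidence edges (score > 0.9).
2. **Characterize** its topology: degree distribution P(k) with a scale-free
   fit P(k) ∝ k^(−γ), average clustering coefficient C, characteristic path
   length L, and diameter D.
3. **Prioritize hubs**: rank nodes by degree and by betweenness centrality
   g(v) = Σ_{s≠t≠v} σ_st(v)/σ_st, take the top N = 50 under each, and keep
   the intersection (the "common hub" set).
4. **Cluster** the network by k-means on adjacency-matrix rows, with
   k = round(√(n/2)) clusters.
5. **Test enrichment** of gene lists against user-supplied categories with
   the hypergeometric upper tail and Benjamini–Hochberg adjustment.
6. **Meta-classify** hub genes across two independent two-group expression
   datasets: per gene a pooled two-sample Student's t, a signed log-scale
   fold change, a within-class "top X%" rank percentile; a gene counts as
   under- or over-expressed only if it is present in both datasets, its fold
   changes agree in sign, and its cumulative rank percentile (mean of the two
   per-dataset percentiles) reaches the top 36%.

`hubnet` implements this pipeline as a library of statsmodels-style
model/results objects plus a thin `hubnet` command-line interface, and ships
synthetic generators (scale-free networks by preferential attachment, paired
expression datasets with planted differential genes) so every stage can be
exercised and validated without any database access. Two small reference
tables from a published T-cell acute lymphoblastic leukemia (T-ALL) hub-gene
study are bundled: the 42 common hub symbols and their two-study expression
summary (27 genes with rank percentile, p-value, and fold change per study).

## Worked example

```python
import hubnet as hn
from hubnet.datasets import load_hub_genes, expression_summary_stats

# a synthetic 201-protein scale-free interactome
net = hn.make_network(hn.SyntheticNetworkSpec(n_nodes=201, attach_m=3, seed=1))

print(hn.NetworkTopology(net).fit().summary())

hubs = hn.HubModel(net, n_top=50).fit()
print(f"common hubs: {len(hubs.common_hubs)}")

print(hn.GraphKMeans(net, seed=0).fit().summary())

# meta-classification of the bundled two-study hub expression summary
a, b = expression_summary_stats()
meta = hn.ExpressionMeta(a, b, threshold_pct=36.0).fit()
print(meta.classify_hubs(load_hub_genes()).summary())
```

prints

```
Network topology summary
========================
nodes                    201
edges                    594
degree exponent (gamma)  1.647
fit R^2                  0.817
avg clustering coeff     0.104
  (excluding deg<2)      0.104
characteristic path len  2.851
diameter                 5

common hubs: 46

Graph k-means summary
=====================
k (clusters)    10
seed            0
inertia         936.4823
Lloyd sweeps    13
cluster sizes   1:8, 2:9, 3:1, 4:122, 5:3, 6:1, 7:28, 8:1, 9:1, 10:27

Hub expression report
=====================
underexpressed  16: APP, KAT2B, CREBBP, NFKB1, PSEN1, CDC42, CTNNA1, CDH1, APC, NOTCH2, SMAD3, VEGFA, EP300, RAC1, CCND1, AXIN1
overexpressed   11: LEF1, HDAC1, NOTCH1, SMAD2, NOTCH3, CDH2, SMAD4, AKT1, GSK3B, JUN, EGFR
discordant      0:
absent          0:
```

The topology block reads: the synthetic interactome's degree distribution
decays roughly as k^(−1.65) (log–log least squares, R² = 0.82), any two
proteins are on average 2.85 interactions apart, and no pair is farther than
5. The k-means block partitions the 201 nodes into k = round(√(201/2)) = 10
clusters. The final report classifies the bundled hub genes: 16 consistently
underexpressed and 11 consistently overexpressed in disease across both
expression studies.

The same stages are available from the shell: `hubnet network`, `hubnet
topology`, `hubnet hubs`, `hubnet cluster`, `hubnet enrich`, `hubnet meta`,
and `hubnet simulate` (see `hubnet --help`).

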