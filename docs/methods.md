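# Methods

## Network substrate

Networks are simple undirected graphs over protein symbols. Edges carry one
confidence score in [0, 1]; a STRING-style export with integer scores in
[0, 1000] is divided by 1000 on read. Cleaning is applied at parse time:
self-loops are dropped and duplicate unordered pairs collapse to the maximum
confidence — the most permissive choice, since confidence is only ever used
to *remove* edges downstream. The confidence filter keeps edges with score
strictly greater than the threshold (default 0.9, the conventional
"high confidence" level at which a predicted interaction has an estimated
precision above 75%); an inclusive variant is available
(`strict=False`). Nodes left isolated by filtering are dropped by default,
mirroring a displayed-interactors network in which only connected proteins
appear; `keep_isolated=True` retains them. All node orderings are
lexicographic, which makes every ranking, tie-break, and cluster assignment
deterministic.

Topology is computed on the unweighted graph; confidence can optionally
weight the centralities (`use_confidence_weights`), in which case degree
becomes node strength (sum of incident confidences) and shortest paths
minimise total distance 1/confidence. The default is unweighted because the
ranking conventions of the common hub-screening plugins are not published,
and the downstream use — top-N membership — is generally insensitive to it.

## Topology statistics

- **Degree distribution.** P(k) = (#nodes of degree k)/n over all observed
  degrees; isolated nodes contribute to n (and to P(0)) but k = 0 is
  excluded from the power-law fit support.
- **Power-law fit.** Ordinary least squares of log10 P(k) on log10 k over
  the raw, unbinned support, with γ = −slope and R² the coefficient of
  determination of that regression. This is the convention of the
  NetworkAnalyzer family of tools; it is a descriptive fit, not a maximum
  likelihood estimate, and can legitimately return γ < 1 (a pure power law
  with γ < 1 is not normalizable on infinite support, so such values should
  be read as "slowly decaying", not as parameters of a generative law).
  Logarithmic binning is available behind `log_binning=True` for sparse
  tails. The fit requires at least two distinct positive degrees.
- **Clustering coefficient.** Mean over all nodes of 2·t(v)/(deg(v)(deg(v)−1));
  nodes of degree < 2 contribute 0 by default, and the alternative
  convention (excluding them from the mean) is reported alongside, since
  published network summaries do not always state which was used.
- **Path metrics.** Characteristic path length (mean shortest-path distance
  over unordered connected pairs) and diameter are computed on the largest
  connected component, the standard choice when a network may carry minor
  satellite components; a single-node component returns (0, 0) with a
  warning. Ties between equal-sized components break toward the one
  containing the lexicographically smallest node.
- **Betweenness.** Unnormalized shortest-path betweenness via Brandes'
  accumulation algorithm (exact path counts, no sampling). Normalization by
  2/((n−1)(n−2)) is available but irrelevant to ranking.

## Hub selection

Nodes are ranked descending by degree and, separately, by betweenness; ties
break lexicographically by symbol so the top-N boundary is deterministic.
The hub set is the intersection of the two top-N lists (default N = 50),
reported sorted. The intersection is monotone non-decreasing in N.

## Graph k-means

Each node is represented by its adjacency-matrix row (binary by default,
confidence-weighted behind a flag) and partitioned by Lloyd's algorithm
under squared Euclidean distance. The cluster count defaults to the rule of
thumb k = round(√(n/2)). Initialization picks k distinct data rows uniformly
from a seeded generator; `n_init = 10` restarts are drawn from the same
stream and the lowest-inertia solution kept, so a fixed seed yields
bit-identical labels. If a cluster empties during a sweep, its centroid is
re-seeded at the point farthest from its assigned centroid — a standard
safeguard. The per-iteration inertia trace is retained on the result for
diagnostics; apart from the rare re-seed kick it is non-increasing.
Cluster *membership* depends on the feature embedding, so partitions
produced by other software on other embeddings are not expected to be
reproduced — only the procedure is.

## Enrichment

Over-representation of a query list in a category is tested with the exact
hypergeometric upper tail P(X ≥ overlap) for
X ~ Hypergeom(|background|, |category|, |query|). Categories overlapping
the query in fewer than `min_overlap` genes (default 2) are excluded
*before* Benjamini–Hochberg adjustment, matching the behaviour of the
common web toolkits; significance defaults to adjusted p ≤ α (α = 0.05),
with a flag to threshold raw p instead. The background defaults to the
union of the GMT's categories when not supplied. Genes outside the
background raise by default; `strict=False` drops them instead.

## Differential expression and meta-classification

Expression matrices are assumed log-scale and median-centered per array, as
cancer-microarray compendia provide them. Per gene, the two-sample pooled
Student's t (Welch behind a flag) gives a two-sided p-value; the fold change
is the difference of group means on the log scale, negative meaning
underexpressed in disease. Degenerate genes — zero within-group variance —
get t = 0, p = 1 when the means agree, and p pinned at the smallest positive
float with a warning flag when they differ.

Genes are split by fold-change sign into an under- and an over-expressed
class and ranked within class by ascending p (ties by symbol); the rank is
reported as the percentile ⌈100·rank/n_class⌉ in (0, 100], the "top X%"
convention of two-group microarray compendia. Genes with exactly zero fold
change belong to neither class and stay unranked.

The meta-filter over two datasets classifies each gene in the union:
**absent** if unranked in either dataset, **discordant** if the fold-change
signs disagree (or either is zero), otherwise **under**/**over** by the
shared sign. The cumulative rank percentile combines the two per-dataset
percentiles; the default rule is their **mean**, with **sum** and **max**
available. The mean was chosen because a two-study meta-rank naturally
reduces to it and, applied to the bundled 27-gene reference summary, it is
the rule that contradicts the fewest printed rows — exactly one, EGFR, whose
percentiles average 36.5 and therefore fall just outside the top-36%
band; that row is flagged rather than silently passed. `passes_filter`
requires presence in both datasets, a consistent direction, and cumulative
percentile ≤ the threshold (default 36). Classification by direction alone
(the 16-under/11-over split of the bundled summary) does not depend on the
cumulative rule.

## Synthetic data

The generators produce inputs with the statistical structure the pipeline
assumes, not facsimiles of any real database export.

- **Networks**: Barabási–Albert preferential attachment (each arriving node
  attaches to `attach_m = 3` existing nodes), chosen over a configuration
  model because the path metrics need one dominant connected component.
  Default size 201 nodes, comparable to a grown single-query interactome;
  confidences i.i.d. uniform on [0.4, 1), the span from the conventional
  low-confidence floor to certainty, or fixed.
- **Expression pairs**: Gaussian noise (σ = 1) on the log scale around 0;
  a planted 10% of genes is shifted in the disease group by
  `effect_size × σ` (default 2), with a random sign per gene shared across
  the pair; matrices are median-centered per sample. Defaults are 2000
  genes and 20 + 20 samples per dataset. Heteroskedasticity, probe-level
  artifacts, correlated genes and batch effects are deliberately out of
  scope — so passing tests demonstrate correctness of the statistics and
  the filter logic, not robustness to real microarray pathology.
- **Full-pipeline study** (`planted_hub_recovery`): a 300-node network whose
  20 highest-degree nodes receive planted shifts; recovery is the fraction
  of planted genes landing in the final under/over hub lists with the
  planted sign, using 30 + 30 samples per group. At effect size 2 the mean
  recovery across 10 seeded replicates is required to reach 90%; the main
  loss mechanism is a planted high-degree node missing the top-50
  betweenness list, not the expression statistics.

All generators take an integer seed and are bit-reproducible; replicate
studies derive per-replicate seeds from one `numpy` generator.

## Numerical conventions

- Probabilities of a degree distribution must sum to 1 within 1e-12.
- The hypergeometric tail is exact (scipy's implementation); tests pin it to
  direct rational-arithmetic tail sums at 1e-12.
- BH adjustment is the standard step-up with monotone enforcement, capped at
  1, input order preserved.
- All rankings break ties lexicographically by symbol.
- k-means inertia comparisons across restarts use strict `<`, so the first
  restart wins ties — another determinism guarantee.

## Limitations

- The power-law fit is a log–log regression, adequate for descriptive
  comparison but not for rigorous scale-free hypothesis testing
  (likelihood-based estimators are out of scope).
- Reference tables bundled with the package (the 42-symbol hub list and the
  27-gene expression summary) are published summary statistics; the
  underlying raw networks and microarray matrices are not redistributable,
  so stages upstream of those tables are validated against synthetic data
  and brute-force oracles rather than against the original sources.
- Enrichment requires a user-supplied GMT; no annotation database is bundled
  and no ontology graph structure (term ancestry) is modelled.
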