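# Methods

## Model and procedure

A property graph is an undirected simple graph with a vector of categorical
labels per vertex. The generator treats the joint label category (the whole
vector) as the unit of structure: it estimates the empirical category
distribution over vertices (`P_L`) and the empirical unordered category-pair
distribution over edges (`P_C`), then samples a target graph that reproduces
both. `P_C` is stored over unordered pairs because the graphs are
undirected; storage is sparse (only observed categories), since augmentation
makes the full joint space combinatorially large.

Sampling is deterministic-then-random:

1. **Vertex bag.** The target vertex count `n_t` is apportioned over
   categories by largest-remainder (Hamilton) rounding of `n_t · P_L`,
   ties broken by descending mass then key order. When every quota is an
   integer — in particular when `n_t` equals the source vertex count —
   the apportionment is exact, which is why equal-size surrogates preserve
   vertex category proportions with zero residual. Generated vertices get
   fresh ids (`g0001`, ...), so no source identifier leaks into output.
2. **Edge bag.** The target edge count `m_t` is apportioned over category
   pairs the same way. Each pair's allocation is realised by drawing
   distinct vertex pairs uniformly *without replacement* from the
   admissible set (endpoints of the required categories, no self-pairs).
   Distinct category pairs cannot produce the same vertex pair, so the
   output is simple by construction.
3. **Shortfall policy.** An allocation can exceed the number of admissible
   pairs (e.g. two edges requested within a two-vertex category). The
   excess is dropped and reported per pair — never converted into
   self-loops, duplicates, or edges of another pair. This keeps `P_C`
   unbiased at the cost of occasionally undershooting `m_t`; the
   evaluation module's edge residual equals the squared probability gap
   this creates.
4. **Resample loop.** The full pipeline augments the source once (labels
   are fixed thereafter; augmentation labels are not recomputed per
   iteration since the source does not change), then repeats steps 1–2
   with per-iteration sub-seeds while the error metric exceeds the
   tolerance, returning the best attempt. The default metric is
   degree-CCDF NRMSE. The default tolerance is 0 with `max_iterations=20`:
   ask for exact degree recovery and keep the best of twenty tries when it
   is unattainable. Sub-seeds are derived from the root seed by hashing
   `(seed, iteration)` through `numpy.random.SeedSequence`, so runs are
   reproducible and iterations independent.

## Augmentation

Structure the labels do not encode is not preserved, so structural
information is folded into the label space before estimation:

- **Degree bins.** Quantile mode cuts the degree distribution at the
  empirical `k/n_b` quantiles with right-closed bins and ties to the lower
  bin (the boundary convention is a package choice; inverted-CDF empirical
  quantiles keep boundaries at observed degrees). If `n_b` exceeds the
  number of distinct degrees the scheme collapses to one bin per distinct
  degree with a warning. Fixed-width mode assigns `floor(degree/width)`,
  the convention natural for large claims-derived graphs.
- **Communities.** `edge_betweenness` is Girvan–Newman splitting with the
  dendrogram cut at the modularity-maximal level (the initial partition
  into connected components is a candidate, so disconnected inputs are
  handled); `fast_greedy` is greedy modularity maximisation. Both are
  deterministic given the vertex order; community ids are ordered by
  descending size with ties broken by smallest member id. Both
  implementations agree with python-igraph's corresponding algorithms on
  the karate fixture (checked in the test suite).
- **Linchpin centrality.** The score used is
  `score(v) = #{u ∈ N(v) : no w ∈ N(u)\{v} shares v's value} / deg(v)`:
  the fraction of v's neighbours for whom v is their only contact of its
  kind. This is a documented stand-in capturing the "one-of-a-kind
  bridging" idea; the three-level binning is none (= 0), low (0, 0.2),
  high (≥ 0.2), with the upper cut inclusive.
- **Custom labels.** Any vertex → category map can be appended, so
  arbitrary metrics (closeness quartiles, k-cores, ...) can participate.

Augmentation never changes vertices or edges, only the schema and labels.

## Evaluation

- **NRMSE.** Curves are compared on the union support (integer-support
  CCDFs extended with zeros) and normalised by the range (max − min) of
  the *source* curve. For a degree CCDF the range is 1, so the choice is
  inert there; it matters for centrality curves, which is why the function
  is asymmetric and the source must be passed first. A constant source
  curve has no defined normalisation and raises.
- **Eigenvector centrality** is computed by power iteration on the
  adjacency matrix, L2-normalised, convergence tolerance 1e-10. On
  disconnected graphs the iteration converges to the principal component's
  eigenvector; other components score near zero. Centrality CCDFs are
  evaluated on 100 evenly spaced thresholds on [0, source max].
- **KS tests** are classical two-sample statistics with asymptotic
  p-values (scipy), applied to raw degree and centrality sequences. On
  heavily tied (discrete) data the test is conservative, as usual.
- **Vertex matching** pairs source and generated vertices one-to-one:
  candidates must agree exactly on every shared categorical label
  dimension (the generation labels, including the community label the
  surrogate was generated from; the per-graph *re-detected* community
  dimensions are excluded because their ids are graph-specific), and ties
  are resolved greedily by ascending Euclidean distance on (degree,
  eigenvector centrality). Exact-category matching plus a
  nearest-structural tie-break stands in for propensity matching; no
  propensity model is specified for this setting and the exact-match
  constraint is the binding one.
- **Community agreement** re-detects communities independently on both
  graphs with the same algorithm, aligns community ids by a
  maximum-overlap Hungarian assignment on the matched-vertex confusion
  matrix (resolving label switching), and reports the fraction of source
  vertices whose matched partner lies in the corresponding community.
  Unmatched source vertices count against the score.
- **Joint-probability residuals** project both graphs onto their shared
  label dimensions and sum squared differences of `P_L` (and `P_C`) over
  the union of supports.
- **Homophily regression.** Per vertex with at least one neighbour:
  outcome 1 iff its value lies in the target set, predictor the percentage
  (0–100) of neighbours sharing the vertex's own value. A binomial GLM
  with logit link (IRLS via statsmodels) yields exp(slope) as the odds
  ratio per percentage point, with a Wald 95% CI and the fit's AIC.
  One-sided outcomes, constant predictors and suspected separation raise
  a `DegenerateFitError` rather than returning a meaningless fit.
  Isolated vertices are excluded (their predictor is undefined).

## Synthetic data

Two generators define the study conditions used by the tests.

**Karate labels.** The karate club graph gets two stochastic attributes: a
3-level label sampled per degree-tercile stratum with weight rows
(0.80, 0.15, 0.05) / (0.15, 0.70, 0.15) / (0.05, 0.15, 0.80), and a 4-level
label over closeness quartiles with 0.70 on the diagonal and 0.10
elsewhere. The stratified weights fix the expected label–structure
association while leaving individual assignments noisy, so degree-bin
tuning results are reproducible in distribution but not digit-exactly
across label draws. The tuning sweep re-draws labels per replicate; its
community+degree column runs the full resample loop (that loop *is* the
algorithm), while the no-community columns are single-shot.

**Patient-sharing network.** A planted-partition graph with ten
communities of sizes (45, 40, 35, 32, 28, 25, 22, 20, 19, 18),
within-community density 0.60 and between-community density 0.0005, a
6-value specialty attribute concentrated at 0.8 on each community's home
specialty, and five bridge vertices appended after partition sampling with
a distinct "bridge" specialty and three edges into each of two of the four
largest communities. The scale is roughly half the motivating setting
(hundreds of physicians, thousands of edges) to keep test runtimes in
seconds. The density separation is deliberately strong: greedy modularity
has a known resolution limit and merge-order instability, and wiring
bridges into *small* communities makes it glue the bridged pair together
— which would measure the detector's pathology, not the generator's
fidelity. With these defaults fast-greedy recovers the ten planted blocks
essentially always, so community-preservation comparisons are attributable
to generation. What this fixture does not emulate: weighted patient-sharing
intensities, overlapping communities, degree heavy-tails within
communities, and the claims-thresholding pipeline that produces real
unipartite projections — conclusions about those features do not follow
from these tests.

**Homophily test-bed.** Recovery of a known homophily coefficient is
awkward because outcome and predictor derive from the same label: sharing
an edge forces equal target status. The test-bed therefore builds disjoint
three-vertex stars whose value assignments are mixed so that, marginally,
P(target | x) equals logistic(a + bx) exactly at the design points
x ∈ {0, 50, 100} (share-both, share-one and share-none star types in
proportions 0.2/0.4/0.4, with per-type target rates solved from the three
cell probabilities; infeasible (a, b) combinations raise). The default
slope is (logit 0.8 − logit 0.2)/100 ≈ 0.0277 (odds ratio 1.028 per
percentage point). Residual within-star outcome correlations are mostly
variance-deflating (deterministic or negatively correlated cells), so Wald
intervals hold their nominal coverage within sampling error — verified by
the coverage test. Steep slopes cannot be realised at these design points
because a shared-value pair pins the x = 100 cell away from 1; the
parameter-recovery tests therefore use moderate slopes.

## Numerical choices and degenerate inputs

- Largest-remainder rounding uses a 1e-9 floor guard against floating
  quotas like `2.9999999999`.
- Edge sampling materialises admissible-pair lists per category pair;
  category sizes after augmentation are small, keeping this linear in
  practice.
- Probability masses are exact ratios of integer counts; conservation
  (Σ mass = 1) holds to 1e-12 by construction.
- Empty graphs, edgeless graphs, constant CCDFs, missing dimensions,
  all-isolated regressions: each raises a targeted error rather than
  returning NaN.

## Known limitations

- Exact degree-CCDF recovery is a lucky draw, not a guarantee: vertices
  sharing a joint category are exchangeable, so their incident edges split
  randomly. The resample loop makes exact recovery likely on small graphs
  when labels nearly individualise vertices; on large graphs the NRMSE
  plateaus at a small positive value.
- Greedy-modularity community detection is itself unstable on weakly
  separated structure; comparisons of detected community counts inherit
  that instability regardless of generation quality.
- The homophily odds ratio on surrogate graphs is consistent only insofar
  as the labels used for generation carry the association; attributes
  correlated with unmodelled structure bias it, and the regression treats
  vertices as independent observations.
- Edge weights, directed edges, multigraphs, bipartite claim graphs and
  overlapping communities are out of scope.
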