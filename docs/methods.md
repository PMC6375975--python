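# Methods

## The null model

A node of degree *k* and strength *s* is modelled as distributing its
strength over its links by a Pólya urn: the urn starts with one red ball
(the focal link) and *k* − 1 black balls (the other links), every draw
returns the drawn ball together with *a* extra balls of the same colour, and
the weight *w* on the focal link is the number of red draws in *s* attempts.
The null distribution of *w* is Beta-Binomial,

    P(w | k, s, a) = C(s, w) · B(1/a + w, (k−1)/a + s − w) / B(1/a, (k−1)/a),

and the p-value of an observed weight is the survival probability
P(X ≥ w).  The reinforcement parameter *a* ≥ 0 tunes the null's tolerance
to heterogeneity: *a* = 0 recovers the Binomial(s, 1/k) of uniformly random
allocation, while *a* → ∞ makes the first draw decisive and the p-value of
any positive weight tends to 1/k.  Each link is tested from the viewpoint of
both endpoints (out-urn of the source and in-urn of the target for directed
networks), giving a family of L = 2 × links tests; a link enters the
backbone when at least one of its p-values beats the corrected threshold
(Bonferroni α_u/L with strict inequality by default; Benjamini–Hochberg and
uncorrected thresholds are options).  A degree-1 viewpoint is a degenerate
urn with no black balls: its p-value is 1, so such viewpoints never validate
a link and links between two degree-1 nodes are never retained.

## Numerical choices

* All binomial/beta factors are sums of log-gamma terms; strengths of order
  10⁶ neither overflow nor underflow.
* Survival sums accumulate the tail with fewer terms via `logsumexp` and
  complement only when the result is O(1), so p-values of 10⁻⁸⁰ retain full
  relative precision.
* For 0 < a with a·s ≤ 10⁻¹⁰ the binomial limit is evaluated directly: there
  the Beta-Binomial is numerically indistinguishable from it while the
  log-beta difference loses all precision.  The practically supported range
  of the exact routine is a ∈ {0} ∪ [10⁻⁴, ∞); between 10⁻¹⁰ and 10⁻⁴ the
  absolute error grows to at worst ~10⁻³ in the pmf.
* "auto" mode uses exact summation for integer weights with per-observation
  s ≤ 10⁵ and the large-strength approximation otherwise.  The crossover is
  this package's choice.
* The large-strength approximation
  π ≈ (1 − w/s)^{(k−1)/a} (wk/(sa))^{1/a−1} / Γ(1/a) and its r-only
  reduction π ≈ e^{−r/a}(r/a)^{1/a−1}/Γ(1/a) are not normalized
  probabilities and are clipped to [0, 1].  At a = 1 the former reduces
  bit-for-bit to the disparity filter's (1 − w/s)^{k−1}.  The expansion is
  accurate in the upper tail (where filtering decisions are made) and
  degrades below the null mean r < 1, where the raw expression can exceed 1;
  measured against exact summation at k = 10, s = 10⁴ the error is ~2·10⁻⁴
  across the support at a = 1 and ~8·10⁻⁴ deep in the tail at a = 2.
* Real-valued weights cannot be scored by a count distribution; they are
  routed through the large-strength form, which assigns a p-value to the
  interaction rate w/s.  a = 0 with real weights is undefined and raises.

## Monotone shrinkage and its boundary

Backbones shrink monotonically in *a* at fixed significance in the regime
the filter is meant for: corrected thresholds well below 1/k.  For loose
thresholds at or above 1/k the property can fail, because the p-value of a
sub-mean link approaches its a → ∞ limit 1/k non-monotonically and can
cross a loose threshold from above.  The nestedness tests therefore run
under Bonferroni, where retained links always sit deep in the upper tail.
`sweep_a` — which binary-searches a 0.01-decade log grid of *a* for a target
retained fraction — likewise assumes the Bonferroni-regime monotonicity.

## Likelihood calibration

The composite log-likelihood is Σ log P(w | k, s, a) over every
(link, viewpoint) test, one urn per viewpoint node; degree-1 viewpoints
contribute zero.  This is the definition `log_likelihood` implements, and it
is also what the worked toy example evaluates.

For *fitting*, the default is a refinement.  On an observed network a link
exists precisely because its weight is positive, and the event "this cell of
the allocation is non-zero" is informative about *a*: strongly reinforced
urns starve many cells to zero.  Maximizing the plain composite likelihood
on networks whose absent links are genuinely zero-weight cells
underestimates *a* badly (measured on synthetic allocations with k = 10,
s = 1000: −23% at a = 2, −53% at a = 5).  The default estimator therefore
scores each viewpoint node's weight vector under the symmetric
Dirichlet-multinomial allocation with concentration 1/a — whose one-cell
marginal is exactly the Beta-Binomial null — *conditioned on every observed
cell being ≥ 1*.  The truncation constant P(all cells ≥ 1) is an
inclusion–exclusion sum over forced-zero cells, evaluated in log space and
cached per (k, s).  This estimator recovers a to ~1% median relative error
at a ∈ {0.5, 1, 2, 5} on the synthetic allocations.  The composite variant
remains available (`likelihood="composite"`).

Optimization is bounded scalar maximization on log a over the bracket
(10⁻⁴, 10³) with ~10⁻³ relative tolerance; profiles are smooth on the log
scale.  A maximum hugging a bracket edge sets a flag and warns — perfectly
homogeneous networks legitimately drive a_ML to the lower edge.  Networks
with real-valued weights are fitted with the Beta(1/a, (k−1)/a) density of
the rate w/s (the large-strength law of the weight fraction), flagged
`pseudo=True`: summing log p-values would not be a likelihood.

## Salience and the O1/O2 criteria

Salience is the fraction of per-node weighted shortest-path trees containing
a link, with the standard proximity-to-distance conversion length = 1/w.
Distances come from Dijkstra on the sparse graph; the predecessor of each
node is chosen deterministically as the smallest-index neighbour (in
first-appearance order) attaining the shortest distance within a 10⁻⁹
relative tolerance, so tie configurations cannot make runs irreproducible.
Every node is a reference node; isolated nodes contribute empty trees.

The optimality criteria are O1 = J·⟨S⟩ and O2 = F_n·⟨S⟩, where ⟨S⟩ is the
mean parent-network salience of retained links, F_n the fraction of nodes
retained, and J the Jaccard similarity between the parent's and backbone's
weight assignments.  Because backbone weights are a subset of the parent's,
the weighted Jaccard equals the retained-strength fraction, which is how it
is computed.  Empty backbones score ⟨S⟩ = O1 = O2 = 0.

## The synthetic generator

Each viewpoint node allocates an integer strength s over k potential links
by a symmetric Dirichlet-multinomial with concentration 1/a (equal-probability
multinomial at a = 0), so the marginal weight on any single potential link
is exactly the Beta-Binomial null — the property every downstream test
relies on.  Zero cells are emitted as absent links, consistent with the
convention that zero weight means no link; consequently the realized degree
of a node can fall below k when a is large, while emitted weights still sum
exactly to s.  Planted signal links overwrite the drawn weight and the
remaining strength is reallocated over the remaining cells, preserving
totals.  Supported topologies are directed out-stubs (each source has its
own targets, which have in-degree 1) and undirected star unions (leaves
have degree 1): all statistical structure sits in the allocating viewpoints,
which is the situation the null actually describes.  A joint undirected
generative model consistent from both endpoints of every link is not defined
by the null, and none is invented — recovery tests would otherwise be
contaminated by an arbitrary modelling choice.

What the generator does **not** emulate: degree/strength correlations,
reciprocity, clustering, community structure, or weight distributions of
real traffic/trade networks.  Passing tests demonstrate correctness of the
statistical machinery under its own null and power against planted
departures, not performance claims on any empirical network.

## Problem sizes used in the test suite

Synthetic fixtures are sized so the full suite runs in about a minute:
recovery uses 20 networks per a_true value with 500 sources of degree 10 and
strength 1000 (≥ 3000 viewpoint tests each), nestedness uses 50 networks of
25 sources, the disparity correspondence uses 400 sources with strength 10⁴,
and Monte-Carlo moment checks use 10⁵ draws.  These sizes were chosen to
keep Monte-Carlo standard errors well inside the asserted tolerances.

## Known limitations

* The Bonferroni family is always the whole network (L = 2 × links), also
  for directed networks; per-direction families are not offered.
* The directed convention tests each link from the source's out-urn and the
  target's in-urn.  Other conventions (out-views only) exist; backbones of
  directed networks depend on this choice.
* Duplicate links in input are an error, never aggregated.
* p-values for real-valued weights test interaction rates, not counts, and
  therefore embody a slightly different null than the exact test.
* `sweep_a` returns a grid value (backbone size is a step function of a),
  and assumes the monotone regime discussed above.
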