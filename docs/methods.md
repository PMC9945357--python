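# Methods

This note documents the statistical procedures implemented in `symptomnet`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that affect results.

## Scoring

Instruments are defined in editable YAML (items with response ranges,
subscale membership, reverse-coded items, node granularity).  The bundled
definitions follow the standard published assignments: HADS, 14 items
scored 0–3, seven anxiety and seven depression items, each item one network
node; DERS, 36 items scored 1–5 partitioned into six subscales
(Nonacceptance, Goals, Impulse, Awareness, Strategies, Clarity), each
subscale summed into one node.  Reverse correction maps a response `r` to
`(min + max) − r` before any use; it is an involution and is applied to the
bundled reverse lists (HADS positively worded items 2, 4, 6, 7, 12, 14;
the standard 11-item DERS reverse list).  Whether a given study reverse-
corrected before summation is often unstated in the literature; here it is
a property of the definition file, and an empty reverse list is valid.

Participants with any missing item response are dropped (listwise) and
counted; missing demographics are retained.  Descriptives report
(group, measure, N, mean, SD) with the n−1 denominator; a single-member
group gets SD = NaN, never 0.

## Network estimation

Node scores are modelled as a Gaussian graphical model.  The precision
matrix is estimated from the Pearson correlation matrix (Spearman available
as a switch) by the graphical lasso with the L1 penalty on off-diagonal
entries only, so the λ → λ_max limit is exactly diagonal with
`k_ii = 1/s_ii` and no shrinkage is wasted on variances.  Edge weights are
the regularized partial correlations `w_ij = −k_ij/√(k_ii k_jj)`.  The
network is *not* refit without penalty after selection: the reported
weights are the regularized coefficients.

The penalty path has 100 log-spaced values from `λ_max = max_{i≠j} |s_ij|`
down to `0.01·λ_max`; models are scored by
`EBIC = −2ℓ(K) + E log n + 4 E γ log p` with `ℓ(K) = (n/2)(log det K −
tr(SK))` and γ = 0.5, the conservative community default.  Ties go to the
larger penalty (sparser model), which makes selection deterministic.

Solver: proximal-gradient iterations (gradient step on the smooth part,
soft-thresholding of off-diagonals, Barzilai–Borwein trial step with
backtracking that preserves positive definiteness), warm-started along the
path and stopped when the maximum KKT violation of the penalized objective
falls below 1e−5 (cap 5000 iterations, then a hard error with diagnostics).
A proximal scheme was preferred over coordinate-wise updates because it
vectorizes cleanly at p = 20 and reaches the same optimum of the same
convex objective; tests verify KKT residuals and agreement (1e−3
entry-wise) with an independent split-variable L-BFGS-B optimizer.

Caveat: with weak signals and moderate n, EBIC with γ = 0.5 can select the
empty network.  That is correct behaviour of the criterion, not a failure
mode of the solver, but downstream stability analysis is then undefined
(all centralities constant).

## Centrality and bridge centrality

Path-based indices use edge length `1/|w_ij|` — the convention of the
psychometric-network software tradition — rather than −log|w|.  Strength is
`Σ_j |w_ij|`, expected influence `Σ_j w_ij`, closeness the reciprocal of
the summed shortest-path distance to reachable peers (0 for an isolated
node, with a disconnectedness warning), betweenness the fractional-credit
count of shortest paths through the node (Brandes-style accumulation;
ties in path length detected with relative tolerance 1e−10).

Bridge variants restrict each index to the node's connections *outside* its
community: bridge strength sums |w| over cross-community edges (magnitudes,
consistent with strength; the signed version is bridge expected influence),
bridge closeness is the reciprocal of the summed distance to all
other-community nodes (0 with a warning if any is unreachable), and bridge
betweenness counts shortest paths between pairs of nodes from two different
communities.  Bridge closeness uses reciprocal-of-sum rather than of-mean;
either is coherent, the sum matches the closeness convention above.  All
indices are reported raw and scaled by the maximum absolute value per
index; tables are ordered by scaled expected influence.

Node and bridge indices share one Dijkstra + path-count routine; both are
tested against exhaustive path enumeration on small graphs
(`bridge_strength + within-community strength = strength` is asserted as a
conservation law).

## Stability

Case-dropping (not resampling) bootstrap: for each drop proportion q on the
grid (default 0.05–0.75 in steps of 0.05) and each of B replicates,
`⌈(1−q)·n⌉` participants are retained without replacement, the full
network + centrality procedure re-run, and each index vector correlated
(Pearson) with the full-sample vector.  A constant vector makes the
correlation undefined; undefined values are recorded, counted and excluded
from the certainty denominator.  The CS coefficient is the largest q such
that at q *and every smaller grid proportion* at least 95 % of defined
correlations are ≥ 0.7 — the monotone-prefix reading, which keeps CS unique
when qualification is non-monotone.  Identical data, grid, B and seed give
bit-identical results.

## Layouts

*Grouped circle*: community centers equally spaced on a unit master circle
starting at 90°, each community's nodes equally spaced (from 0°) on a
0.45-radius sub-circle, in given node order; fully deterministic.

*MDS*: dissimilarities `δ_ij = max_{kl}|w_kl| − |w_ij|` (bounded; absent
edges get the maximum — chosen over reciprocal weights to keep zero-weight
pairs finite), embedded in 2-D by non-metric SMACOF: isotonic regression of
configuration distances on the dissimilarity order (primary tie approach —
tied dissimilarities may keep distinct disparities, with ties re-broken by
current distances each iteration), disparities rescaled to the distance
norm to prevent collapse, Guttman transform, best of 10 seeded random
starts, Kruskal stress-1 reported with its per-iteration trace.  Two
consequences of ordinal scaling worth knowing: a perfectly tied
dissimilarity matrix (e.g. three equally weighted nodes) has stress 0 for
*any* configuration under primary ties, so no particular geometry is
implied; and a planted configuration is recovered up to a monotone
transform of distances (ranks exactly, metric shape only approximately).
Metric (ratio) scaling and custom dissimilarity matrices (e.g. zero-order
correlations) are switches.

## Synthetic data

The generator plants a ground-truth network over 20 nodes in communities of
7 (anxiety-like), 7 (depression-like) and 6 (emotion-regulation
components), mirroring the instrument structure above.  Edges appear
independently with probability 0.3 within and 0.03 between communities;
four designated bridge edges are always present (Rlx–Chr, Wrr–Slw, STR–Wrr,
STR–Chr in the default labelling), so bridge-recovery can be scored.
Weights are uniform in magnitude on [0.2, 0.45] with a 25 % chance of a
negative sign.  Truth is parameterized directly in partial-correlation
space: with unit-diagonal precision, `k_ij = −w_ij`; off-diagonals are
shrunk proportionally until the smallest eigenvalue reaches 0.05, and the
*shrunk* partials are recorded as the truth, so the estimand and the truth
live on the same scale.

Participant scores are multivariate-normal draws from the implied
correlation matrix; HADS-like nodes are discretized to 4 levels by
equal-probability normal quantiles, DER nodes stay continuous (sums of 5–8
Likert items are effectively continuous).  Default n = 209.  An item-level
mode emits raw item responses (DERS items as subscale factor + noise with
loading 0.7, reverse items stored un-corrected, plausible demographics with
~3 % missingness) in exactly the CSV schema the scoring front-end reads, to
exercise loading and scoring end to end.

Default magnitudes: with |w| ∈ [0.15, 0.35] at n = 209 on Likert data,
EBIC (γ = 0.5) selects the empty model — the per-edge likelihood gain
(~n·w²) sits below the ~11.3 per-edge penalty.  Since empirical
anxiety/depression/DER networks at this scale are clearly non-empty, the
default range is [0.2, 0.45]; the continuous recovery benchmark
(`benchmark_config`: n = 2000, |w| ∈ [0.15, 0.35], γ = 0.5) keeps the
weaker weights and is the configuration on which sensitivity ≥ 0.7,
specificity ≥ 0.9, weight correlation ≥ 0.8 and strength-rank recovery
≥ 0.8 are asserted.

What the generator does *not* emulate: item-level floor/ceiling effects of
clinical samples (skewed thresholds are available but not default),
non-normal copula dependence, demographic composition, measurement error
structure beyond the single-factor item mode.  Passing recovery tests
therefore shows the pipeline recovers the model class it assumes — not that
any particular empirical dataset satisfies those assumptions.

## Pipeline and reproducibility

`run_pipeline` expands one master seed into per-stage seeds
(SeedSequence-derived, recorded in the manifest), runs data → scoring →
estimation → centrality → layouts → stability, and writes CSV/GraphML/JSON
artifacts plus a manifest (settings, seeds, package version, input hash).
Identical config + seed reproduces every output byte (the manifest's
timestamp aside); this replay property is asserted in the test suite.
Problem sizes in the validation suite — n = 2000 for the recovery
benchmark, B = 100 over a 5-point grid for the bootstrapped CS check,
100 random small graphs for the path-enumeration oracle — were chosen as
the smallest sizes at which the checked properties are comfortably
identified.

## Known limitations

* Pearson (or Spearman) input correlations only: no polychoric option, so
  partial correlations from few-level Likert nodes are attenuated.
* EBIC-glasso inherits the known conservatism of γ = 0.5 at small n.
* No edge-weight accuracy bootstrap or node-difference tests; stability is
  centrality-only, as is the CS coefficient.
* The community partition is an input, never inferred.
* Bridge closeness/betweenness depend on the 1/|w| length convention;
  alternative conventions change rankings and are not implemented.
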