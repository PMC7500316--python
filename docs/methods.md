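# Methods

`scovnet` analyzes group-level *structural covariance networks*: graphs whose
nodes are atlas regions and whose edges are between-subject Pearson
correlations of a regional morphometric measure (typically gray-matter
volume). This note records the model, the conventions, and the design choices
behind the implementation, and what the synthetic validation does and does
not demonstrate.

## Pipeline model

For each group, the subject × region value matrix is first residualized by
ordinary least squares on an intercept plus three nuisance covariates — age
(years), sex (0/1), and total intracranial volume (ml) — fitted **within the
group**. Pearson correlations of the residuals across subjects give a
symmetric N × N matrix `r` (diagonal set to 0 for network purposes; at least
3 subjects are required, and zero-variance regions are an error).

The matrix is binarized on a **density grid** (default 0.10 to 0.50 in steps
of 0.02). At density `d` the K = round(d·N(N−1)/2) top-ranked node pairs
become edges. Ranking is by **signed r** by default — structural covariance
edges are conventionally positive co-variation — with `edge_rank="abs"`
available; ties break by descending |r| then lexicographic pair order, so
edge sets are nested along the grid and every run is bit-reproducible. A
grid-validation report flags densities at which either group's network is
disconnected and warns when the grid extends to 0.5 or beyond, where
covariance networks approach random graphs.

## Graph measures

All measures operate on binary undirected adjacencies:

- **Cp** — mean Watts–Strogatz clustering; nodes of degree < 2 contribute 0.
- **Lp** — mean shortest-path length over *connected* pairs. Permuted or
  sparse networks may disconnect; rather than returning infinities, the mean
  is taken over reachable pairs and a `disconnected` flag is propagated.
- **E_glob** — mean of 1/d(i,j) over pairs, with 1/∞ = 0.
- **E_loc** — mean over nodes of the global efficiency of each node's
  neighbour subgraph (the node itself excluded); degree < 2 contributes 0.
- **Betweenness** — Brandes shortest-path betweenness with fractional
  crediting across equally short paths (networkx implementation, verified
  against an independent walk-count oracle). Nodal values are normalized by
  the network-mean betweenness, so the normalized values average to 1; on
  graphs where no shortest path passes through any node (e.g. complete
  graphs) the normalized vector is all zeros with a `degenerate` flag.

Shortest-path computations use compiled kernels (distance-1/2 resolution by
edge and bitset common-neighbour tests, BFS fallback for farther pairs),
validated to 1e−12 against brute-force enumeration on every non-isomorphic
graph with up to 7 nodes.

**Null normalization.** γ = Cp/Cp_rand, λ = Lp/Lp_rand, σ = γ/λ, against an
ensemble of degree-preserving randomizations (default 20). Each null applies
10·E *attempted* Maslov–Sneppen double-edge swaps; proposals creating
self-loops or multi-edges are rejected, so the degree sequence is preserved
exactly. Connectivity of nulls is deliberately not enforced (standard
Maslov–Sneppen). Ensemble statistics are arithmetic means. A warning fires
when the swap acceptance ratio drops below 10% (near-regular or saturated
graphs barely randomize). Note that σ of any *single* sparse graph is a
noisy quantity — the clustering of a 90-node, degree-6 random graph is a
small number with large relative spread — so σ for one network should be
read against the ensemble spread, not as a precise value.

## Resilience

Relative giant-connected-component (GCC) size is tracked as nodes are
removed, normalized by the GCC of the intact network (even if it is
disconnected). Curves start at 1, end at 0, and are non-increasing.

- **Random failure** averages over `n_orders` (default 100) seeded random
  removal orders; a single pass is noise-dominated, and `n_orders=1` remains
  available for literal single-realization replication. For small graphs
  `exact_random_failure_curve` computes the exact expectation by subset
  enumeration (the surviving set after k uniform removals is a uniform
  (N−k)-subset).
- **Targeted attack** removes nodes by decreasing betweenness or degree,
  computed once on the intact network by default (`recompute=True`
  re-ranks after every removal); ties break by ascending node index.

Curves are computed with a reverse union-find sweep (removals replayed
backwards as insertions), costing O(N + E) per order.

## Permutation inference

Two groups are compared by subject-label permutation: subjects are pooled
and reassigned without replacement to pseudo-groups of the original sizes,
covariates travelling with their subjects, and the **entire** pipeline —
residualization re-fitted within each pseudo-group, correlation,
thresholding, metrics, and fresh null ensembles whenever σ is requested —
is re-run per permutation (default 1000). The observed statistics flow
through exactly the same code path as permutation zero would.

Differences (A − B) are evaluated per density, as trapezoidal areas under
the metric-vs-density curve (AUC; less sensitive to any single threshold),
per region (normalized-betweenness AUC), and per removal count for
resilience curves at a reference density (default: the smallest grid
density at which both observed networks are connected, recorded in the
output metadata).

**Calibration.** Results are reported with the tail in the observed
direction. Because that direction is chosen after seeing the data, a naive
one-tailed tail probability at the 95th percentile would reject truly
exchangeable groups at twice the nominal rate (the selected tail is the
smaller of two, each with its own 5%). The p-value therefore uses the
standard equal-tail doubling, p = min(1, 2(b+1)/(n_perm+1)), and the
critical value sits at the (1 − α/2) permutation quantile on the observed
side, holding the type-I probability at α. This calibration is verified
empirically on exchangeable synthetic cohorts. A zero observed difference
has no direction and is assigned p = 1. Per-density and per-region tests
are **not** corrected for multiple comparisons by default (a
Benjamini–Hochberg helper is provided but off by default); the AUC summary
is the primary guard against threshold-selection sensitivity.

## Synthetic cohorts

No public morphometry dataset accompanies this problem, so validation rests
on a generator with known ground truth. Regional values are drawn from a
multivariate normal whose correlation matrix is `I + c·A` for a ground-truth
graph `A` (Watts–Strogatz, Erdős–Rényi, ring lattice, hub-and-spoke,
modular-bridge, or custom) and edge correlation `c`, repaired to the nearest
valid correlation matrix by eigenvalue clipping and diagonal rescaling; the
repaired matrix is the closed-form oracle for downstream checks. Linear
covariate effects and i.i.d. Gaussian noise are added on top, so the
residual-scale correlation is the repaired matrix attenuated by
1/(1 + noise_sd²).

Defaults, chosen once to mirror a mid-sized morphometry study: 90 regions,
31 subjects per group, edge correlation 0.5, noise SD 0.2 (signal has unit
SD), age ~ U(40, 67) years, sex ~ Bernoulli(0.5), TIV ~ N(1450, 130) ml,
covariate slopes (−0.01/year, 0.15, 0.003/ml), baseline volume 10 arbitrary
units. The topology carries its own seed, separate from the data seed, so
two groups can share a generating graph while drawing independent subjects.

Documented two-group presets (`preset_pair`): `null` (identical generating
models — the exchangeability scenario), `reduced_clustering` (group B
rewires every lattice edge, destroying triangles at equal density),
`hub_spoke` (group B collapses under targeted attack), and `bridge` (group
B funnels cross-module paths through one region). Effect presets use edge
correlation 0.6.

**A transitivity caveat discovered during validation:** in a multivariate
normal, two regions connected only *through* a bridge region are themselves
correlated (≈ the product of the edge correlations). Once the threshold
density exceeds the generating graph's density, these indirect correlations
enter as edges that bypass the bridge, and the bridge's betweenness
signature disappears — at any sample size. Regional bridge effects are
therefore only recoverable below the generating density; the bridge
scenario is evaluated on a 0.03–0.06 grid with 60 subjects per group.

**What the synthetic cohorts do not emulate:** spatial autocorrelation and
smoothing-induced neighbourhood correlation, non-Gaussian volume
distributions, site or scanner effects, hemispheric symmetry, and any
realistic anatomical covariance backbone. Passing tests demonstrate that
the pipeline recovers known statistical structure and holds its nominal
error rates — not that any particular clinical finding would replicate.

## Numerical and scale choices

Validation studies are sized to run on a single CPU: the type-I study uses
100 replicate null cohort pairs at 200 permutations on a 5-point density
grid with σ omitted (its null ensembles dominate runtime and σ is checked
separately); the power study uses 50 replicates of the reduced-clustering
preset under the same configuration, where the Cp AUC test has empirical
power ≈ 0.9 at n = 31 + 31. Small-world detection uses Watts–Strogatz
(N = 90, k = 6, p = 0.05) against 20-null ensembles; degree-randomized
versions of the same graphs centre on σ = 1 with SD ≈ 0.22 (see the σ
noisiness note above), so self-consistency is asserted on the ensemble
mean. All randomness flows from named integer seeds through
`numpy.random.Generator`; identical configurations reproduce results
byte-for-byte.

## Known limitations

- Binary undirected networks only; no weighted or directed variants, no
  individual-subject networks, no hub classification or modularity.
- Group-level covariance networks cannot be computed per subject, so
  inference is purely permutation-based; no parametric alternatives.
- The resilience reference density is a single density; results at other
  densities may differ.
- Betweenness in thresholded covariance networks is sensitive to the
  density regime (see the transitivity caveat): regional conclusions should
  be checked across grids.
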