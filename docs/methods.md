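# Methods

`netnorm` studies one question: when brain networks are built for subjects
whose network *scale* differs (because their brains differ in size and a
fixed parcel-area threshold therefore yields different node counts), how
much does normalizing global network metrics improve subject-level
prediction of a cognitive outcome?  Everything in the package — the
synthetic cohorts, the connectivity pipeline, the five global metrics, the
conserving null model, the out-of-bag forest — serves that comparison.

## The analysis pipeline

**Node definition (mesh pathway).**  Cortical-surface parcels are split
until every parcel's area falls below a threshold (600, 350 or 150 mm²,
yielding roughly 420, 705 or 1620 nodes on a full cortex).  A parcel's area
is vertex-weighted: each triangle contributes its area in proportion to how
many of its three corners carry the parcel's label, so parcel areas sum
exactly to the mesh area.  A parcel larger than the threshold is split at
the median of the vertex projections onto the vector joining its two most
distant vertices, with distance measured along the surface.  Two
documented approximations: along-surface distance is the shortest path on
the mesh edge graph with Euclidean edge lengths (exact polyhedral geodesics
would change split orientations negligibly), and "equal size" means equal
vertex counts (median split; ties go to the lower side, with an index-parity
fallback when all projections coincide).  Splitting a non-convex parcel can
disconnect one side; connected components are promoted to parcels of their
own and re-checked.  Each split strictly reduces the maximum parcel vertex
count, so the procedure terminates.

**Edge definition.**  The first 5 volumes are dropped; each node series is
high-pass filtered by least-squares removal of the discrete-cosine basis
functions with period longer than 100 s (plus the mean); the edge weight is
the absolute Pearson correlation; correlations failing a Bonferroni-corrected
two-sided t test (family = the N(N−1)/2 node pairs of that subject, alpha
0.05) are set to zero.  The t transform is exact (T−2 degrees of freedom),
and thresholding p at alpha/m is implemented as thresholding |r| at the
equivalent critical value — identical decisions, one inverse-t evaluation.

**Global metrics.**  Five weighted-graph summaries:

| metric | formulation |
|---|---|
| clustering coefficient | node mean of Onnela's geometric-mean triangle intensity, weights normalized by the graph maximum; degree < 2 contributes 0 |
| transitivity | total triangle intensity over total connected triples (one network-level ratio) |
| modularity | Newman weighted Q, maximized by Louvain (igraph) with seeded restarts; node order is permuted per restart (igraph's sweep order is index-driven, so relabeling is what diversifies restarts); small graphs (≤ 256 nodes) get greedy single-node-move and community-merge refinement, and very small graphs (≤ 24 nodes) additional seeded basin hopping from random partitions — Louvain's aggregation alone misses the global optimum on a few percent of dense 8-node graphs |
| characteristic path length | mean shortest-path distance (edge length 1/w, Dijkstra) over reachable ordered pairs; the unreachable fraction is reported rather than penalized, keeping L finite on Bonferroni-sparsified graphs |
| global efficiency | mean of 1/d over ordered pairs with 1/∞ = 0 |

Weighted clustering and transitivity are scale-free (max-normalization);
under w → c·w path length scales by 1/c and efficiency by c.

**Null model.**  Surrogates conserve node count, edge count, the exact
degree sequence and the exact edge-weight multiset: Maslov–Sneppen double
edge swaps on the binary topology (default 10 accepted swaps per edge;
swap validity is checked against a dense boolean adjacency in a compiled
loop), then the original weight multiset is re-placed by iterative rank
matching — the largest remaining weight goes to the free edge whose
endpoints have the largest remaining strength deficit, with incremental
score updates.  Strength is therefore conserved only approximately; the
per-node strength correlation between observed and surrogate networks is
computed on every null and reported (typically ≥ 0.95; the acceptance
bound is 0.9).  Normalized metrics are ratios observed / null-ensemble
mean.  Defaults: 20 nulls, 10 swaps per edge; the scaled-down experiment
runs use a single null per subject, which also mirrors the literal
"a random network" reading.

**Prediction.**  Bagged regression trees (default 500) with explicit
bootstrap bookkeeping: each subject's prediction averages only trees whose
bootstrap sample omitted it, so out-of-bag purity is verifiable from the
stored in-bag masks.  The score is fractional variation explained,
fve = 1 − MSE_oob/Var(outcome); the constant predictor scores exactly 0,
negative values are reported as-is and floored at 0 only for display.
Permutation importance is the OOB MSE increase when one feature column is
permuted (default 50 permutations); the magnitude of the most negative
importance defines the noise floor and features above it are flagged.
Confidence limits for fve come from subject-bootstrap percentile intervals
(default 1000 resamples, refitting per resample).  The control model runs
the identical machinery on covariates only (age, gender, cortical volume,
node count, motion).

## The synthetic cohort generator

No real imaging data ship with the package; the generator defines the
study conditions.  Defaults: 26 subjects, 300 volumes at TR 2 s (295
usable), node counts 420 ± 35, 705 ± 65 or 1620 ± 144 by scale, outcome
intercept 89 (an IQ-like scale).

**Planted topology.**  Each subject's network is a weighted Watts–Strogatz
graph at the subject's own node count: ring lattice of mean degree 6,
each edge rewired with probability β drawn uniformly from (0.15, 0.45),
edge weights from a per-subject power-skewed uniform on (0.2, 1.0).  The
outcome depends on β only:

    outcome = 89 + 60 · (clustering_proxy(β) − path_proxy(β)) + ε,
    clustering_proxy = (1 − β)³,  path_proxy = exp(−β / 0.06),
    ε ~ N(0, 6²),

which over the default β range is monotone, spans roughly ±10 outcome
points, and yields a planted R² ≈ 0.5 (recorded per cohort in the
metadata; the acceptance floor is 0.3).

**BOLD model.**  Signals are a Gaussian graph moving-average process:
node i observes α·z_i + Σ_j B_ij z_j + γ·u + noise, with
B_ij = sqrt(g²·w_ij/s_i), α² + g² = 1 (g² = 0.5), a shared global
fluctuation u of per-subject amplitude γ, and white noise.  The implied
covariance (αI+B)(αI+B)ᵀ + γ²J + σ²I is positive definite by construction,
every node has unit signal variance, and a connected pair's correlation
grows with its edge weight (direct term ≈ 2αg·sqrt(w/s) plus
shared-neighbor terms), which puts planted edges comfortably above the
Bonferroni threshold at T = 295.  An earlier formulation with the
covariance equal to the diagonally loaded adjacency was implemented and
rejected: positive-definiteness caps its edge correlations at
0.95·w/|λ_min(A)| ≈ 0.3, at the detection threshold, so measured graphs
came out nearly empty.

**Confound structure** (what makes the comparison meaningful).  The
outcome never depends on node count, but node count correlates with age
(confound strength 0.5, echoing the cortical-volume–age association), and
several *outcome-neutral* heterogeneity axes contaminate the raw metrics
in ways the conserving nulls can absorb:

* per-subject observation noise grows with node count
  (σ_i = 0.4·max(0.75, (N_i/N̄)²); the floor keeps the quietest subjects
  away from a density run-away right at the significance threshold),
  coupling the measured edge-weight scale — hence raw path length and
  efficiency — to network size;
* a per-subject residual global signal (amplitude uniform on 0.2–0.5)
  shifts all correlations, moving measured density, modularity, path
  length and efficiency — and because parcel averaging preserves this
  spatially uniform component while shrinking neural signal, its
  contamination is *relatively stronger at coarse scales*;
* hub-biased rewiring targets (preference exponent uniform on 0–3) skew
  the degree sequence — variance that degree-conserving nulls capture;
* triadic-closure re-targeting (rate uniform on 0–0.35) moves local
  clustering independently of β;
* the per-subject weight-law skew (power uniform on 0.5–2.5) varies the
  weight distribution, which the weight-multiset-conserving nulls absorb.

Under these conditions the raw metrics' correlation with the planted β
degrades sharply while the normalized ratios stay comparatively clean,
and raw path length correlates positively with node count within a
cohort — the scale confound the comparison is about.  (Through the
size/SNR coupling alone that correlation is ≈ 0.5; the heterogeneity
contamination below, required so raw prediction fails at coarse scales,
dilutes it to ≈ 0.2 at the default scale.)

**Node heterogeneity and scale ordering.**  Prediction accuracy should
*increase* with node count.  The generator implements the standard
explanation — large parcels average functionally distinct regions, so
their mean time course represents none of them — as random-partner
mixing: at node scale S each node's series is blended with a randomly
paired node's with fraction 0.35·(1 − S/1620)^2.2 (≈ 0.18 at 420 nodes,
0.10 at 705, 0 at 1620), preserving per-node variance.  This attenuates
true edges, adds spurious ones, and amplifies the relative weight of the
global component at coarse scales.  Two alternatives were tried and
rejected: parcel-mean aggregation of a single micro-resolution network
(under any unit-variance signal model the cross-parcel correlation mass
dilutes quadratically with parcel size, so coarse graphs lose nearly all
significant edges) and ring-neighbor mixing (a local smoothing of the
correlation matrix that leaves all global metrics nearly unchanged).

**What the generator does not emulate.**  Hemodynamics, physiological
noise spectra, motion, image-space registration; the standard-space
condition is operationalized as a shared node count per subject (networks
regenerated from the subject's own β) plus a small extra observation noise
(default 0.25) standing in for node-placement error.  Passing tests show
the pipeline recovers planted structure under this idealized observation
model, not that real denoised rs-fMRI satisfies it.

## Problem sizes and numerical choices

The replicated comparison runs 20 cohorts × 3 scales with a single null
per subject, 2 Louvain restarts and 300 trees — sizes chosen so the whole
experiment replays in minutes while the compared means are stable (the
paired per-replicate design removes cohort-sampling variance from the
condition contrast).  Mean fve for normalized metrics rises from roughly
0.1 at 420 nodes to ≈ 0.2 at 705 and ≈ 0.3 at 1620, beating the raw
metrics at every scale — the qualitative structure of the source
comparison, at a synthetic effect size.  Degenerate inputs are defined: empty graphs raise for modularity
and path length; a null ensemble whose mean clustering is zero (possible
on very sparse graphs) raises rather than returning an infinite ratio;
single-feature models have no noise floor (reported 0 with a warning);
all generators are pure functions of their seed, and nested stages derive
child seeds from one master seed.

## Known limitations

* The Fig-1-style "flag exactly the planted metrics above the
  most-negative-importance noise floor" criterion is not reproducible as
  an exact-set statement on metrics measured from a common graph: if the
  non-planted metrics are given no variance the noise floor degenerates to
  zero (every ε-positive importance is "above" it), and any variance
  source they share with a planted metric — transitivity shares triangles
  with clustering, efficiency shares the weight scale with path length —
  gives them genuine denoising value to the forest and hence positive
  importance.  Measured exact-set rates plateau near 50% across probe
  designs.  The robust form of the result does hold and is tested: both
  planted metrics are flagged and their importances dominate all others
  several-fold in ≈ 95% of replicates.
* The strength conservation of the null model is approximate by design
  (exact joint conservation of degrees, strengths and weights is a hard
  combinatorial problem); its quality is measured and reported instead of
  assumed.
* Louvain with restarts and refinement is a heuristic; global optimality
  is verified exhaustively only up to 8 nodes.
* The three conditions share cohorts but not graph noise; standard-space
  networks are fresh realizations at the shared node count, as real
  re-parcellation would produce.
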