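# Methods

`cytotemplates` implements a template-based analysis stack for flow
cytometry cohorts. This note records the models, the tunable parameters
and their defaults, the numerical choices, what the synthetic cohorts do
and do not emulate, and the known limitations.

## Measurement model and preprocessing

**Spectral unmixing.** Observed detector signals are modeled as
`o = M s + e` with a column-stochastic p x p spillover matrix `M`
(`M[i, j]` = fraction of fluorochrome j's emission captured by detector
i; columns sum to one). `compensate` recovers `s` by solving the linear
system exactly, ignoring the noise term — the simplest standard scheme.
Spillover matrices with condition number above 1e8 are rejected rather
than inverted.

**Boundary events.** Cells whose total signal over the fluorescence
channels falls outside a `[low, high]` window are removed: very dim
events are likely debris, very bright ones doublets or instrument noise.
Thresholds are user-supplied (chosen once per cohort in practice);
removing every cell is an error.

**Variance stabilization.** Each fluorescence channel z is transformed
by `asinh(z / c)` with a single cofactor c shared by all samples. Because
raw fluorescence variance grows with mean intensity, bright populations
are wider than dim ones; the cofactor is chosen to equalize
within-population variances. For each candidate c on a grid (default 30
log-spaced points in [1, 1e5], covering published cytometry cofactors),
the channel is transformed in every sample, one-dimensional density-peak
clusters are found per sample, and all peak variances are pooled into
Bartlett's homogeneity-of-variances statistic
`chi2 = [(N - m) ln s2_p - sum (n_i - 1) ln s2_i] / C` (pooled variance
`s2_p`, the usual correction `C`). The argmin cofactor wins; grid ties
break toward the smaller cofactor so the choice is deterministic. Peaks
are modes of a Silverman-bandwidth Gaussian KDE evaluated on a 512-point
grid, kept when they exceed 5% of the global density maximum in height
and prominence (the method itself fixes no peak-finding parameters;
these suppress noise modes and are overridable). Inputs with fewer than
50 cells, or constant inputs, yield a single all-spanning peak;
zero-variance peaks are dropped from the Bartlett pool (their
log-variance is undefined) with a warning.

## Cell population identification

Samples are partitioned by k-means (10 restarts, seeded, best
within-cluster sum of squares kept). The number of populations is chosen
by consensus of five cluster-validity indices — average silhouette
width, Calinski-Harabasz and Dunn (maximized), S_Dbw and Davies-Bouldin
(minimized). Each index votes for its optimal k over the scanned range;
the consensus is the majority vote with ties broken toward smaller k
(the conservative direction). The O(n^2) indices (silhouette, Dunn,
S_Dbw) run on a seeded subsample of at most 5,000 cells. Points in
singleton clusters are given silhouette 0 by convention.

Each population is reduced to a Gaussian summary (mean, ML covariance,
cell count). Covariances get a relative ridge `1e-6 * trace/p` (floored
at 1e-12) so pooled covariances stay invertible even for tiny clusters.

## Cluster dissimilarity and mixed edge cover

Two Gaussian summaries `c1(mu1, S1, n1)` and `c2(mu2, S2, n2)` are
compared by default with the Mahalanobis distance under the pooled
covariance

    d = sqrt( (mu1-mu2)' Sp^-1 (mu1-mu2) / 2 ),
    Sp = ((n1-1) S1 + (n2-1) S2) / (n1+n2-2).

The printed form of this distance is typographically ambiguous between
the square-root form above and the squared form `(1/2) d' Sp^-1 d`; the
matched-only-if-average-squared-deviation-below-one reading of the
lambda = p default fits the squared form. Both are available
(`MatchConfig(squared=True)`); the square-root form is the package
default and all defaults are internally consistent with it. Symmetrized
Kullback-Leibler divergence (closed Gaussian form) and the Euclidean
distance between centers are the two alternatives. Mahalanobis and
symmetrized KL are invariant under invertible affine maps of feature
space; the Euclidean center distance is not, which is why center-based
matching misgroups samples whose populations differ mainly in shape.

Populations of two samples are registered by a **minimum-cost mixed edge
cover**: every cluster is matched to zero, one, or more clusters on the
other side; an unmatched cluster pays a fixed penalty lambda (default:
the dimensionality p). The cover cost — matched-pair dissimilarities
plus penalties — is minimized exactly, and the optimum defines the
sample dissimilarity D(A, B).

*Solver.* An optimal cover decomposes into stars: every vertex is either
matched once within an ordinary matching, left unmatched at cost lambda,
or attached to its cheapest partner (multi-covering it) at cost
min over partners of d. The problem therefore reduces exactly to a
square assignment problem of size k_a + k_b with per-vertex slack priced
at `min(lambda, cheapest incident edge)`, solved by the Hungarian
algorithm in O(k^3) — exact at any k arising in practice (k < 50).
Correctness is established in the test suite against exhaustive
enumeration of all covers on small instances, not against any particular
published reduction. Ties between optimal covers resolve to whatever the
assignment solver returns; the cost (not the edge set) is the
contractual output. A consequence of optimality is that every covered
cluster's average distance to its matched set is at most 2 lambda.

## Template trees (hierarchical matching-and-merging)

A cohort is organized into a binary tree: one orphan node per sample,
then repeatedly match and merge the two least-dissimilar orphans until
one remains. Pairwise dissimilarities are cached and only the new node's
row is recomputed after each merge (O(N^2) D evaluations). Argmin ties
break toward the lexicographically smallest node-id pair, so rebuilding
from the same inputs yields an identical tree.

Merging forms **meta-clusters** from the connected components of the MEC
edge set — chains such as (a1-b1, a2-b1) collapse into one component,
the unique closure of pairwise matching — plus singleton components for
unmatched clusters, which become self-contained meta-clusters.
Meta-cluster parameters are the maximum-likelihood single-Gaussian fit
to the pooled member cells, computed in closed form from member moments:

    n = sum n_i,   mu = sum n_i mu_i / n,
    S = sum n_i (S_i + mu_i mu_i') / n - mu mu'.

This is exact (to rounding) whenever member covariances are themselves
ML fits, and it conserves the total cell count from leaves to root. Each
meta-cluster keeps provenance records (sample id, cluster index) so the
fraction of samples participating in it can be reported.

Merge heights are the dissimilarity at merge time; the algorithm does
not force monotone heights, so small inversions can occur (they are
logged, and Newick export clamps the affected branch to length zero).

**Cutting templates.** Class templates are roots of well-separated
branches. Three cut rules are provided: `by_labels` (lowest nodes
covering exactly one class, given cohort metadata), `by_height`, and the
default `by_gap`, which cuts at the largest relative gap between
successive sorted merge heights — "well-separated" has no quantitative
definition in the method itself, and the relative-gap rule is the
standard dendrogram heuristic; it is overridable.

**Dynamic insertion.** A new sample is compared against the current
templates; if the smallest D is within a threshold it is matched-and-
merged into that template (parameters update by the same ML merge),
otherwise it seeds a new singleton template. When inserting into a
single tree the default threshold is the root height (no threshold is
inherent to the method; this default is documented, not canonical). The
tree is not rebalanced on insertion.

## Template-based classification and disease scoring

Nearest-template classification assigns a sample to the template with
the smallest D; an optional reject threshold returns "unassigned" (a
candidate new class). Exact ties resolve to the smallest template index.

For a disease that perturbs only a subset of populations, templates
T+ (disease) and T- (healthy) are first registered against each other by
a MEC on their meta-cluster lists; T+ meta-clusters left unmatched form
the disease-specific set M+. A sample X with k clusters is scored by two
independent MECs (X vs T+, X vs T-). With d the average Mahalanobis
distance from a cluster to its matched set and `s = 2 lambda - d >= 0`:

    f+(c) =  s        if c matches an M+ meta-cluster,
            -s / k    if c matches only non-specific T+ meta-clusters,
             0        if c is unmatched in T+;
    f-(c) = -s / k    if c matches some T- meta-cluster,
             lambda   if c is unmatched in T-;
    f(X)  = sum_c (|c| / |X|) * (f+(c) + f-(c)) / 2.

A positive f(X) predicts the disease class; an exact zero is classified
negative (the false-negative aversion lives in the score's asymmetry —
positive contributions are not divided by k — not in the tie rule). The
two per-template covers are computed independently, not as a joint
three-way problem. Panel scores from several marker panels are combined
by a plain mean over a user-selected panel subset. Evaluation uses
precision, recall, specificity and F-value; a metric with a zero
denominator is reported as undefined, never as zero. Empirical p-values
against a null score distribution (e.g. an isotype-control panel) use
the add-one rule `p = (1 + #{null >= s}) / (1 + #null)`.

**Decision boundary of the score.** The piecewise definition implies a
structural abundance threshold for a single disease-specific population:
with near-perfect matches (s ~ 2 lambda) the score changes sign near
fractional abundance `4 / (3k + 4)` — about 25% when k = 4. Samples
whose disease population is planted at 20-24% abundance therefore score
(correctly per the formula, undesirably for the clinician) slightly
negative; the sign dichotomy is guaranteed from roughly 30% abundance
upward under the default geometry. This mirrors the behavior on the real
cohort that motivated the score, where the one training sample below the
diagnostic blast-fraction threshold was the one misclassification.

## Synthetic cohorts

The generator produces finite mixtures of well-separated multivariate
Gaussians — exactly the model class the Gaussian summaries assume — with
ground-truth labels at the population, sample and class level.

*Healthy-donor cohort* (default 65 samples): 5 subjects sampled on
(4, 3, 2, 2, 2) days with 5 technical replicates each, four lymphocyte
populations (helper T, cytotoxic T, B, NK) in five channels, unit
covariance, pairwise mean separation >= 10 sigma, expected fractions
(0.35, 0.25, 0.20, 0.20). Per-population mean shifts are drawn
independently at each hierarchy level with standard deviations
subject 2.0 >> day 0.5 >> replicate 0.1 (per dimension), so biological
between-subject variation dominates, making subject identity
recoverable from the template tree.

*Disease cohort* (default 200 negatives + 30 positives, stratified 50/50
train/test split): three shared populations; every positive additionally
carries a blast-like population at uniform 20-60% abundance (the
clinical confirmation threshold for the motivating disease is 20%
blasts), placed >= 5 sigma from all shared populations. Positive samples
receive per-sample mean shifts with twice the standard deviation of
negatives (0.6 vs 0.3), making the disease class the more heterogeneous
one, as observed in real cohorts.

Abundances are Dirichlet-jittered around expected fractions
(concentration 200, sd ~ 3%); population presence is Bernoulli per
sample; an optional t-distribution flag provides heavy-tailed
contamination for robustness probes. Samples default to 1,000 cells —
enough for stable Gaussian summaries of populations above a few percent
abundance while keeping a 230-sample end-to-end run in tens of seconds.

**What the generator does not emulate:** spectral spillover and
autofluorescence (compensation is exercised on separately constructed
linear mixtures), doublets and dead cells, non-Gaussian population
shapes (skewed or curved gates), rare populations below ~1% abundance,
and real marker panels. Passing tests therefore demonstrate correctness
of the algorithms under their own model assumptions, not performance on
raw instrument data.

## Numerical and design choices

- Covariance ridge 1e-6 relative to mean variance: large enough to make
  singleton-cluster covariances invertible, small enough not to move
  Mahalanobis distances at data scale.
- Bartlett with fewer than two usable clusters returns 0 with a warning
  (homoscedasticity is trivially satisfied).
- lambda defaults to p and is overridable; all 2-lambda-bound reasoning
  holds for any positive lambda.
- k-means restarts (10) and the 5,000-cell index subsample are seeded;
  every public entry point with randomness takes a seed, and cohort
  generation flows through a single `numpy` Generator per cohort.
- FCS reading supports versions 3.0/3.1, single-dataset list mode,
  float32/float64/uniform-integer data, either byte order; everything
  else is rejected with an explicit message. The core pipeline consumes
  CSV and JSON, so FCS support is an input adapter only; FCS writing is
  out of scope.

## Limitations

- k-means with Gaussian summaries assumes roughly elliptical
  populations; strongly non-convex populations would be split across
  clusters (and then typically re-joined by the multi-matching of the
  edge cover, but with inflated covariances).
- The gap cut assumes one dominant scale separation in the dendrogram;
  cohorts with a continuum of merge heights need `by_labels` or
  `by_height`.
- Dynamic insertion updates template parameters but never revisits the
  tree topology; long insertion sequences can drift from the batch tree
  when classes are not well separated.
- The disease score's abundance boundary (~`4/(3k+4)`) is a property of
  the published piecewise definition, not of this implementation;
  samples with disease populations near the clinical threshold sit near
  the decision boundary by construction.
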