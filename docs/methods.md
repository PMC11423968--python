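# Methods

## Activation model

Receptor activation follows the mass-action law `f/(1-f) = K·c`, giving
`f = s/(1+s)` with drive `s = K_r·c` for a mixture with concentration vector
`c ≥ 0`. Affinities `K` have units of inverse concentration; the threshold
concentration of a receptor–odorant pair is `1/K`. A receptor counts as
*active* when `f > θ` strictly; the boundary value is inactive. This makes
the zero-concentration case unambiguous and matches the "higher than half
maximum" convention. θ defaults to 1/2 and is configurable, but no primacy
computation consults it: the first p receptors to cross any common θ along a
fixed mixture direction are the p receptors of largest projection `K_r·q`,
which is how `primacy_set` computes them.

Under the low-rank factorization `K = R·Q` (receptors as points `R_r` in a
D-dimensional property space, odorants as columns of `Q`), activation is
`f/(1-f) = R_r·(Qc)`, and all geometric constructions transfer to the rows
of `R`. Activation calls require fully observed affinity rows; masked
(DoOR-style) data enters only the primacy-matrix analyses, where missing
entries are excluded from ranking rather than imputed.

Ties at the p-th projection rank are resolved toward the lowest receptor
index and flagged on the result. For continuous affinities this is a
measure-zero event; the deterministic rule keeps outputs reproducible.

## Primacy hulls

`build_hull` sweeps Monte-Carlo directions: i.i.d. standard normal vectors
normalized to the unit sphere (uniform by symmetry), folded by absolute
value into the nonnegative orthant when the sweep cone is restricted.
The orthant cone is the default when points are raw affinities, because
mixture directions are normalized concentration vectors and hence
nonnegative; the full sphere is available for property-space points whose
loadings may carry signs. Each direction contributes one primacy set;
simplices are deduplicated with a support count (the number of directions
that produced them), which later serves as a sampling weight and as a
convergence diagnostic (`discovery_rate`: the fraction of support carried by
singleton simplices — near zero at convergence). With nested direction
samples the hull grows monotonically.

For D = 2 an exact construction is available: the projection ranking changes
only at directions orthogonal to a pairwise difference vector, so
enumerating the O(N²) critical angles and evaluating one direction per
angular interval visits every primacy set. This is quadratic and specific to
the plane; higher dimensions use sampling plus the diagnostic. The exact
sweep doubles as the oracle for the sampled sweep in the tests.

Hull membership partitions receptors into hull vertices and receptors
belonging to no primacy set; the latter are the model's
predicted-pseudogenized receptors. No topological summaries beyond face
enumeration are computed.

## Connectivity analysis

Connectivity is binarized at a configurable synapse-count threshold
(default ≥ 1; the threshold is logged, and empty rows/columns are dropped
with a logged warning). Glomerulus–glomerulus similarity is the Pearson
correlation of binary columns over KCs. Cross-animal agreement is the
Pearson r of the strictly-upper-triangle entries after intersecting
glomerulus labels, with a two-sided Mantel-style permutation p-value
(joint row/column label permutation of one matrix, +1 pseudocount).

The null model everywhere is the degree-preserving shuffle: a Markov chain
of checkerboard swaps (`[[1,0],[0,1]] ↔ [[0,1],[1,0]]`) that preserves every
row and column sum exactly, with chain length 10× the number of ones by
default. Margins are asserted after every shuffle. The inner loop is
numba-jitted with an identical pure-Python fallback.

PCA treats similarity rows as glomerulus feature vectors (the package
follows the similarity-matrix formulation; running PCA directly on the
binary matrix is a caller's choice). Isomap uses the same row geometry:
Euclidean distances between similarity rows, a symmetrized k-NN graph
(default k = smallest value that connects the graph, reported in the result
metadata and in the error message when a requested k disconnects), geodesics
by shortest path, and classical MDS of the geodesic Gram matrix; variance
explained per dimension is the positive-eigenvalue fraction. In the
complete-graph limit this reduces to PCA up to an orthogonal map, which the
tests exploit.

Embeddings from different animals are aligned by orthogonal Procrustes —
centroid translation plus rotation/reflection, *no scaling*, since a scale
factor would hide genuine disagreement between animals and reflections are
needed because embedding sign is arbitrary. The reported RMSD is over shared
glomeruli; significance against a shuffle ensemble uses a two-sample t-test
on per-glomerulus residuals (the test variant is a package choice). Variance
significance per dimension is empirical: `p = (1 + #{null ≥ observed}) /
(n_shuffles + 1)`.

## Affinity–connectivity enrichment

Per odorant, the primacy matrix marks the p largest observed responses;
odorants with fewer than `max(p, 8)` observations are dropped and
enumerated in the result. The default sweep covers p = 1–8. OR–OR primacy
similarity reuses the Pearson kernel; ORs that are never or always primary
are dropped with a warning. Comparisons against connectivity are restricted
to glomeruli with a single cognate OR, supplied as a two-column
glomerulus→OR table.

The overlap matrix is the boolean matrix product of connectivity and
primacy matrices: entry (KC, odorant) counts the intersection of the KC's
claw set with the odorant's primacy set. For a given k (k = 1 is the single
"grandmother" KC per odorant), the k largest overlaps per odorant are
histogrammed by degree 0..p; the same histograms on degree-preserving
shuffles of the connectivity give the null. Cell-level significance is a
two-sided empirical p-value around the null mean with a +1 pseudocount
(the test statistic behind the FDR boxes is a package choice), and
Benjamini–Hochberg q-values are computed across the full (p × degree) grid
per k, reusing the same shuffle realizations across p so the grid is
internally consistent. Top-k selection takes exactly k values with
deterministic tie order; because only overlap *degrees* are histogrammed,
tie resolution cannot change the statistic.

## Surrogate worlds

The generator plants one geometry behind all three datasets. Receptor
points are folded standard normals in the positive orthant (a hard shift
cannot guarantee positivity, so the reflection is used). Odorant property
columns are unit vectors drawn from the same cone as the hull sweep, so
every planted primacy set is a hull simplex by construction (the odorant
directions are appended to the sweep). Responses are
`clip(R·Q + N(0,σ²), 0)` rescaled to [0, 1]; the noise-free matrix has rank
≤ D. Missingness is i.i.d. Bernoulli by default, or copied from a template
mask; a template value histogram can be imposed by rank mapping. KCs pick a
hull simplex with probability proportional to sweep support, then a uniform
n-subset of its vertices as claws; each claw rewires to a uniform random
glomerulus with the claw-noise probability, with duplicate collisions
redrawn so claw counts stay exact. A second animal resamples KCs from the
same hull with a fresh seed; the null world replaces connectivity by its
degree-preserving shuffle.

Defaults are fly-scale: 51 glomeruli, D = 6, p = 5, 156 odorants, 1800 KCs,
5 claws, 20% claw noise, 30% missingness, σ = 0.05, 20 000 sweep
directions. D = 6 and the noise/missingness levels are the package's
choices of a realistic regime (missingness in community response datasets is
substantial; claw counts in the fly are 5–6). The `validation` preset scales
to 30 receptors, D = 4, 60 odorants, 300 KCs — the problem size at which the
planted-recovery and negative-control replicate studies run, chosen so the
full replicate suite completes quickly while keeping ≥ 250 KC–odorant
top-10 draws per world.

What the generator does *not* emulate: synapse counts and their
binarization ambiguity, multi-OR glomeruli, odorant-dependent primacy
numbers, receptor antagonism or nonlinear mixture interactions, and any
temporal (latency-based) notion of primacy. Passing tests therefore show
that the statistics detect the planted structure under the model's own
assumptions, not that real data satisfies those assumptions.

## Numerical choices and limitations

- All randomness flows from explicit seeds; pipeline stages derive
  per-stage seeds from one global seed via `SeedSequence`, recorded in run
  metadata, so identical config + seed give byte-identical outputs.
- Exact float equality is used to *flag* projection/response ties (they are
  measure-zero for continuous data); tie resolution itself is
  deterministic.
- Sweep density: the 2D construction is exact; in higher dimensions hull
  completeness is only asymptotic in the number of directions, with the
  singleton-support discovery rate as the practical convergence check.
- Degenerate inputs fail loudly: identical receptor points (every direction
  ties), thresholds exceeding all weights, disconnected neighbor graphs
  (the error names the smallest connecting k), fewer than three shared
  labels for matrix correlation or Procrustes alignment.
- Enrichment power depends on scale: at fly scale the single-gKC readout
  (k = 1) shows no enrichment on planted worlds while population readouts
  (k = 10–50) do, consistent with a population-coding readout of subprime
  faces.
- Fitting the property-space dimension D from data is out of scope, as is
  any evolutionary dynamics beyond flagging hull non-membership.
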