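# Methods

This note records the models, conventions and numerical choices behind
`synconn`, in the spirit of a package methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Synthetic functional cohort

### Generative model

Node time series are sampled i.i.d. over T time points (default T = 120)
from a zero-mean unit-variance factor model. Node i's series is a weighted
sum of latent standard-normal factors plus white residual noise whose
variance is set to 1 minus the node's squared loadings, so the population
correlation between two nodes is exactly the inner product of their loading
vectors. The loading architecture, drawn once per cohort and shared by the
two groups:

- **Module sub-factors.** Nodes are partitioned into M planted modules
  (default 4, near-equal sizes). Each module is represented by *two*
  sub-factors, and a node loads equally (1/√2 each) on both of its
  module's sub-factors with total loading α·b_i, where b_i ~
  N(1, cv²) clipped to [0.75, 1.35] (`loading_cv`, default 0.15). Two
  sub-factors leave population correlations identical to a single factor
  but halve the variance of a node's *sampled* alignment with its module
  signal — the dominant failure mode by which a sampled-weak node would
  otherwise lose all of its thresholded edges at once.
- **Anti-correlation subspace.** Module m loads with strength γ·g_i on the
  m-th unit vector of a regular M-simplex embedded in an (M−1)-dimensional
  factor subspace (g_i ~ N(1, 0.1²) clipped to [0.8, 1.1]). Simplex
  directions have pairwise inner products −1/(M−1), so *every*
  between-module pair is equally, mildly anticorrelated — emulating the
  segregation of task-positive and default-mode systems without coupling
  any particular module pair more than another (which would bias Louvain
  toward merging them).
- **Connector (bridge) nodes.** A fraction (default 0.3) of nodes carry a
  positive cross-loading β on one other module's sub-factors, with
  secondary modules dealt round-robin over the module pairs so every pair
  is bridged by several connectors. These create the realistic tail of
  positive between-module edges that keeps thresholded graphs connected
  across the anticorrelated blocks.
- **Anchor triples.** Every node shares one dedicated factor of strength
  0.45 (`anchor_strength`) with two module mates; two further
  fixed-strength (0.4) cross-module anchor pairs exist per module pair.
  These play the role of the very strong short-range couplings of real
  parcellations: each guarantees edges several noise standard deviations
  above any thresholding cutoff in the 15–32% sparsity range, so graphs
  stay connected at the grid's lower end — the same property the original
  grid was chosen to satisfy. Anchor groups are disjoint pairs/triples and
  add no triangles beyond their own, so their effect on clustering and
  modularity is marginal. Rows whose total squared loadings would exceed
  0.93 are rescaled into the unit-variance budget.

### Calibration

Per group, the two scale parameters (α for module loadings, γ for the
simplex subspace) are solved numerically (`scipy.optimize.root`) so that
the *population* mean Fisher-z over within-module pairs and over
between-module pairs equal the configured targets — defaults z_within =
0.26 (TD-like) / 0.16 (ASD-like) and z_between = −0.03 / −0.015. The
defaults plant the group effects in the reported direction: the TD-like
group has stronger positive within-module connectivity and stronger
negative between-module connectivity. Realized cohort means land within
about ±0.01 of the targets at n ≥ 12 per group (the residual bias is the
convexity of arctanh over sampling noise); the test suite asserts ±0.03.

Between-subject variance enters through a scalar latent δ_s ~
N(0, `subject_sd`) multiplying each subject's α — the "latent network
factor" that severity scores are planted against. Between-edge variance
enters through the loading jitters plus correlation sampling noise
(SD ≈ 1/√(T−3) ≈ 0.092 in z units at T = 120); both sources are exposed
as parameters rather than fixed to a particular split, since only their
combination is identified by cohort-level summaries.

## 2. Synthetic structural cohort

Fiber counts are negative-binomial (gamma–Poisson, dispersion k = 8),
symmetric, with subject-level log-rate

    log mu_ij = intercept − d_ij / 10 mm + 3.0·[same spatial module]
                + jitter_ij + group offset + c·(z_ij − mean z)

where d is Euclidean inter-node distance, spatial modules are k-means
clusters of the node coordinates (default 9 — Louvain on the average count
matrix recovers 8–11, mostly 9, spatially local communities), jitter ~
N(0, 0.8) is an edge-level architecture term giving realistically
heavy-tailed counts, and z is the subject's functional matrix. Three
structural guarantees are engineered explicitly:

- edges of the Euclidean minimum spanning tree are boosted to near the top
  of the rate distribution (u-fiber-like short-range web), so binarized
  graphs stay connected at 5% sparsity;
- a small fraction (2%) of distant pairs is boosted likewise (homotopic /
  association tracts), so the network does not fragment into spatial
  clumps;
- log-rates are capped 2.4 log-units above their 97th percentile so no
  single edge dominates the count variance (which would cap the attainable
  structure–function correlation).

Two scalars are calibrated per cohort: the intercept (by root-finding) so
the expected fraction of nonzero edges matches `fiber_density`, and the
coupling coefficient c (by scan + bisection against simulated cohorts from
a dedicated seed stream) so the mean per-subject Pearson r between counts
and functional z over mask-eligible edges (cohort-average count ≥ 5)
matches `structure_function_coupling` (default 0.32). Across seeds the
realized cohort-mean r lands within ±0.03 of the target. `fiber_density`
defaults to 0.10 rather than the emulated mean unthresholded sparsity of
8.5%: with the mean at exactly 8.5%, half the subjects would fall short of
the 8.5% sparsity quota and the thresholding operation (correctly) errors;
0.10 lets every subject cover the full structural grid. FA is drawn around
0.45 with a weak distance decline and clipped to [0.05, 0.95]; MD around
8×10⁻⁴ mm²/s; both get small group offsets in the reported directions
(ASD-like: more fibers, lower FA, higher MD).

## 3. Phenotypes

Ages are uniform on 9–18 years; mean relative head motion is normal
(0.10 ± 0.06 mm, floored at 0.03) with maximum motion a 4–9× multiple.
Severity subscales (ADOS social/communication, ADI social/communication)
exist only for ASD-like subjects, are generated on the instruments' printed
ranges, and are planted to correlate (default r = −0.4) with the
standardized subject latent δ — more severe scores for subjects with weaker
planted connectivity. Scores are rounded and clipped to scale ranges, which
attenuates the realized correlation slightly; recovery tests therefore
average over replicate cohorts. No claim of clinical realism is made.

## 4. Thresholding and graph metrics

- **Sparsity thresholding.** Exactly round(s·N(N−1)/2) edges are kept
  (round-half-up): the largest strictly positive weights; negative and zero
  weights never become edges. Ties at the cutoff break by (weight
  descending, row, column), making thresholding deterministic. Thresholded
  edge sets are nested across any grid, so connectivity at the smallest
  sparsity implies it everywhere above.
- **Connectivity is a hard requirement.** Metric curves error (listing the
  failing levels) rather than falling back to the largest component,
  because the sparsity grids are defined by the requirement that every
  subject's graph be fully connected.
- **Metrics.** Binary CC (nodes of degree < 2 contribute 0 and stay in the
  mean), CPL as the mean breadth-first distance over unordered pairs,
  unnormalized betweenness, participation coefficient 1 − Σ(k_is/k_i)²
  against a caller-supplied reference partition (degree-0 nodes score 0),
  and Q averaged over repeated Louvain runs (module assignment is
  stochastic). Implementations ride on igraph/scipy and are tested for
  exact agreement with brute-force enumeration on all-random small graphs.
- **Null normalization.** lambda = CC / mean null CC and gamma = CPL /
  mean null CPL over an ensemble of degree-preserving *connected* rewired
  graphs (default 100): random double edge swaps applied in batches with a
  connectivity check after each batch and rollback of batches that
  disconnect the graph, targeting 10 swap attempts per edge. The batched
  check gives the same invariants as per-swap validation (exact degree
  sequence, connectedness, seed reproducibility) at a fraction of the
  cost. Graphs admitting no degree-preserving alternative (triangles,
  complete graphs) return an identical copy with a warning.
- **Grid summaries.** Arithmetic mean over levels, and the trapezoidal
  integral divided by the grid span (so a constant curve integrates to its
  constant). The integrated variant exists because grid averaging and
  integration may in principle diverge on irregular grids; on the default
  grids the two are nearly collinear across subjects.

## 5. Community detection

Louvain (igraph's two-phase multilevel implementation, resolution 1) on
non-negative weights; functional matrices have negative weights removed
first. The representative partition over n runs keeps the runs whose module
count equals the modal count (ties toward fewer modules) and returns the
kept run with the highest mean NMI to the other kept runs — a deterministic
stand-in for choosing one modal-count run at random, with the module-count
histogram and mean pairwise NMI reported as diagnostics. NMI uses the
arithmetic normalization 2·I/(H₁+H₂) (other normalizations of the same
mutual information differ only in the denominator; the arithmetic form is
what sklearn's default computes, and the two are cross-checked in tests).
Two identical trivial partitions score 1; against a single-module partition
NMI is 0 by the H = 0 convention.

## 6. Group statistics

Two-sample Student t-tests with pooled variance (Welch by flag), two-tailed
throughout. Edges with no variance in either group report t = 0, p = 1 and
are flagged degenerate. Edge classes cross within/between module (from the
reference partition) with the sign of the pooled mean over *all* subjects
(exact zero counts as positive); a significant difference at a
negative-mean edge is attributed as stronger-negative connectivity to the
group with the more negative mean. Benjamini–Hochberg FDR (statsmodels,
verified against a hand-rolled step-up) is applied within each family: the
6 global metrics, the N nodal tests per metric, the tested PCA component
associations. Structure–function correlations are Fisher-z transformed
before the group test; |r| = 1 is capped at 1 − 10⁻⁶ with a warning.

## 7. Multimodal PCA

Unrotated PCA of the correlation matrix of the standardized subjects × 12
metric panel (eigendecomposition; deterministic up to sign, fixed by making
each component's largest-magnitude loading positive). Scores are the
standardized panel projected on the unit-norm eigenvectors. Associations:
diagnosis by two-sample t-test on motion-residualized scores (a group
regression coefficient is reported alongside), age by Pearson correlation
of motion-residualized scores, severity by Pearson correlation of motion-
and age-residualized scores within the ASD-like group only, each family
FDR-corrected; the first 4 components are examined by default (count
configurable). Residualization is ordinary least squares with an intercept;
rank-deficient covariates are an error.

## 8. Problem sizes

The generator's structural defaults are a 264-node parcellation with 35
subjects per group. Tests and the acceptance script run the same model at
reduced sizes chosen so each check completes in seconds to a few minutes on
one CPU: 48–128 nodes, 8–20 subjects per group, 10–20 rewired nulls and
10–20 Louvain iterations per level instead of 100. The properties asserted
(calibration, connectivity over the grids, planted-structure recovery,
small-worldness, statistical calibration) hold at these sizes and are the
same quantities the full-size configuration computes.

## 9. Known limitations

- Time points are i.i.d.: no autocorrelation, hemodynamics, scanner drift
  or motion artifacts; "motion" is a phenotype covariate only, uncorrelated
  with the planted network structure by default.
- Functional modules are index-based, not spatial, so functional edge
  distance effects are null by construction (distance stratification of
  functional differences is exercised, but its expected signal is flat);
  structural communities are spatial by construction.
- Synthetic structural connectomes are generated as count matrices
  directly; the streamline-level construction path (endpoint assignment,
  per-streamline FA/MD averaging) is exercised through its own unit tests
  rather than by the generator.
- Severity planting is a single-latent linear mechanism on printed scale
  ranges; it supports recovery and calibration tests, not clinical
  inference.
- The anchor/bridge/MST devices guarantee grid-wide connectivity by
  construction. Real cohorts earn this property from richer topology;
  conclusions about *why* real networks are connected at a given sparsity
  cannot be read off the generator.
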