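# Methods

This note documents the models, parameter choices and numerical decisions
behind `fcscaffold`, in the spirit of a statistical software appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Pipeline model

The unit of analysis is a cohort of per-subject ROI time-series matrices
(T time points × N regions). Each subject contributes a Pearson correlation
matrix; the group matrix is the Fisher average — tanh of the across-subject
mean of atanh r — which is the variance-stabilised way to average
correlations. All structural analysis operates on the pointwise square
w = r²: the sign of a resting-state correlation carries phase information
that the undirected analyses here do not use, and squaring preserves the
ranking of magnitudes. The diagonal of w is zeroed; self-links never enter
percolation or spanning construction. |r| is clipped at 1 − 1e−12 before
atanh to keep finite arithmetic.

Inter-subject variability diagnostics use the *plain arithmetic* mean and
the ddof = 1 SD across subjects (the Fisher average is the analysis input;
the arithmetic mean is the descriptive map). The coefficient of variation
sd/|mean| is only meaningful where the edge is reliably nonzero, so it is
masked by a per-edge one-sample t-test of the Fisher-z values against 0
with Benjamini–Hochberg FDR control over all N(N−1)/2 edges at q = 0.05
(both the statistic and q are configurable; they affect only this
diagnostic, not the pipeline).

## Percolation and plateau statistics

Edges are ranked increasingly, ties broken lexicographically by (i, j) —
with continuous weights ties have measure zero, and the component counts
after a tie block are invariant to the order within it. After each single
removal the component count is recorded (isolated nodes count). Exact zero
weights are treated as absent links, so an identity correlation matrix is
an edgeless graph. The implementation runs the process backwards — adding
edges from the heaviest down with a union-find structure — which yields all
counts in near-linear time; tests compare every count against a networkx
flood-fill recomputation.

A plateau is the weight increment between consecutive component births.
The first birth has no predecessor; its plateau is anchored at the global
minimum edge weight so that lengths telescope to
(last birth weight − min weight). This convention is reported as such in
the plateau tables.

**Threshold selection.** A real plateau is *significant* when its length
exceeds mean + k·SD (default k = 4) of the null ensemble's plateau lengths
*at the same component-count transition*. The per-transition comparison is
deliberate: plateau lengths pooled across a whole curve are heavily
right-skewed (most births are consecutive removals in the dense bulk of the
weight distribution), so a pooled mean + 4 SD cut sits low enough that the
longest plateau of nearly any curve — including the null curves themselves
— exceeds it, destroying the specificity of the rule. Matching by
transition compares each plateau against the band the ensemble defines at
that point of the curve, which is exactly what mean ± k·SD confidence bands
on a percolation figure display. The pooled statistics (mean, SD, the
1/2/3/4-SD bands, and the pooled selection count) are still computed and
included in the run report for comparison. Selected thresholds are
start-of-plateau weights, reported on both the w scale and the √w
(correlation) scale.

## Spectrum-preserving null model

A valid benchmark for a correlation matrix must stay symmetric,
unit-diagonal and positive semidefinite; naive entry shuffles are not.
The ensemble fixes the eigenvalue spectrum of the observed matrix:
A₀ = Q diag(λ) Qᵀ with Q drawn from the Haar measure (Gaussian matrix, QR
factorisation, column signs fixed by R's diagonal), followed by Givens
rotations. While the diagonal is not all ones, the trace condition
(Σλ = N) guarantees indices i, j with a_ii < 1 < a_jj; the rotation angle
in the (i, j) plane solving t²(a_jj − 1) + 2t·a_ij + (a_ii − 1) = 0 (the
smaller-|t| root, for stability) sets a_ii to exactly 1 while preserving
the spectrum. Each rotation fixes one diagonal entry permanently, so at
most N − 1 rotations are needed; non-convergence raises, as it would
indicate a bug rather than a data condition. Deterministic first-low /
first-high index scanning keeps runs reproducible. Member i of an ensemble
uses seed master_seed·10000 + i.

Eigenvalues of the empirical group matrix negative within 1e−8 are clipped
to zero and the spectrum rescaled to trace N before randomization; anything
more negative is an upstream error. `scipy.stats.random_correlation`
implements the same construction and serves as an independent cross-check
in the test suite (distribution of off-diagonal entries), never as the
implementation.

## Spanning forest and tree

The MSF keeps arc i → argmax_j w_ij for every node (ties to the smallest
index, warned when a whole row ties). Its undirected support is a forest:
each weakly-connected component of m nodes carries m arcs but exactly one
mutually-strongest (reciprocated) pair, hence m − 1 distinct edges and no
cycle. The equivalent from-scratch construction — scan links decreasingly,
add one whenever an endpoint still has degree zero — is asserted equal on
distinct-weight matrices. Completion to the MST adds the remaining links in
*decreasing* weight order under union-find, merging components until one
remains; decreasing order is what makes the result the maximum-weight
spanning tree, and tests enforce optimality against networkx's Kruskal and,
for N ≤ 7, exhaustive enumeration over all spanning trees. The tree has the
standard undirected count of N − 1 edges (2(N−1) is the double-counted
directed reading).

Degree profiles report MSF in-degree over *all* nodes (in-degree 0 is
possible and counted — every node has out-degree 1, not in-degree 1) and
plain degree for the MST. The `chain_score` of a structure is the fraction
of nodes with undirected degree ≤ 2: 1.0 for paths, (m−1)/m for an m-star.

## Synthetic cohort generator

The generator emulates the study design this pipeline targets: 40
subjects, T = 240 volumes, N = 116 regions. Defaults plant 8 chain modules
of sizes [26, 18, 14, 12, 12, 12, 12, 10] (a parcellation-scale network
with one long cerebellum-like chain and several shorter ones; the sizes are
this package's choice), with:

- `r_within = 0.6` — adjacent-pair correlation inside a module; strong but
  sub-unity functional coupling.
- `r_between = 0.1` — background correlation between modules, the weak
  global coupling typical of parcel-averaged BOLD.
- `subject_noise_sd = 0.1` — SD of i.i.d. perturbations applied to the
  planted matrix on the Fisher-z scale per subject, matching the
  across-subject spread of mid-range correlations; the z scale keeps
  perturbed values in (−1, 1) and mirrors the group-averaging transform.

Within a module, non-adjacent pairs at topology-graph distance d get
r_within^d floored at r_between — the correlation profile of a Gaussian
Markov chain, which interpolates toward the background and is PSD-friendly.
Supported topologies: chain, star (first member is the hub), pair, clique.
The assembled matrix is repaired to PSD by eigenvalue clipping at zero plus
diagonal renormalisation; if the repair moves any entry by more than 0.05
the design is rejected with the offending module named. Across the valid
parameter domain the construction stays PSD and the guard is defensive
(property-tested), which is why requested levels are honoured essentially
exactly.

Sampling is zero-mean multivariate normal via the eigendecomposition square
root — Pearson correlation is the only statistic consumed downstream, so
heavier-tailed or autocorrelated BOLD features are deliberately not
modelled. Subject i draws from seed master_seed·1000 + i, making cohorts
bitwise reproducible and subject noise independent across subjects.

**What the generator does not emulate** — hemodynamic response, temporal
autocorrelation, physiological confounds, motion artefacts, negative
correlations (downstream analysis squares weights, so only magnitudes
matter), and spatial autocorrelation between neighbouring parcels. Passing
recovery tests therefore certify the *pipeline* (given data whose
correlation structure contains chains and modules, the stages recover
them), not the preprocessing of real BOLD data.

**Arc recovery** is defined as the fraction of the N MSF arcs whose target
is a topology-neighbour of the source in the planted module graph. With
uniform within-chain correlation the two neighbours of an interior node tie
in the population, so "fraction of planted path edges present in the MSF
support" would hover near 3/4 by symmetry regardless of estimation quality;
the per-arc criterion measures exactly what the generator plants.

## Problem sizes and determinism

The test suite and acceptance script run the recovery experiment at the
full study scale (N = 116, 40 subjects, T = 240) with 20 repetitions and
20-member null ensembles per repetition — ample for the qualitative
contrasts being asserted, which are far from their decision boundaries
(measured plateau contrasts are ~4×, in-degree contrasts ~3×). Oracle
checks use 100–500 random matrices at N ≤ 20. Every random draw flows from
an explicit seed; reruns are bitwise identical, and the pipeline logs the
spectrum hash of the group matrix so null ensembles are provably matched to
their source.

## Known limitations

- The percolation curve records one component count per removal; for very
  large N the O(E α(N)) reverse sweep is fast, but the curve table itself
  is O(E).
- Plateau significance assumes the null ensemble's per-transition length
  distribution is summarised adequately by mean + k·SD; with fewer than ~10
  null curves the SD estimate is unstable (the pipeline warns).
- The FDR family for the CV mask treats edges as independent tests, which
  is standard but approximate for correlated connectivity matrices.
- Negative group correlations are handled (squared), but the generator
  only plants nonnegative targets.
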