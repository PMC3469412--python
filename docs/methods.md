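# Methods

## Model

Cluster-mean log2 fold-change expression is modeled as a coupled linear ODE
system dc/dt = A·c.  Off-diagonal A entries are signed regulatory
influences between clusters (per hour, per unit log2FC); each diagonal
entry absorbs the cluster's own expression decay, A_ii = w_ii − 1/τ_i with
τ_i in hours.  The model is *closed*: given only the state at the first
observation time, the full trajectory follows as c(t) = exp(A·(t−t₀))·c(t₀),
evaluated with the matrix exponential (exact for a linear system; verified
against an adaptive integrator to < 1e−8 relative error).  Internally the
effective matrix A is stored directly rather than (w, τ) pairs: the
randomisation nulls must be able to represent matrices whose diagonal
implies a non-positive decay constant.

Assumptions worth stating explicitly:

* Regulator–target relationships are linear and fixed over the 96 h
  horizon; nonlinear regulator combinations are deliberately excluded so
  the system stays a linear ODE.
* External perturbations during the course (such as an injurious stimulus
  at 72 h) are not modeled as inputs; calibration absorbs their effect into
  the matrix.
* All observation noise is additive Gaussian on log2FC values.

## Fitness metric

Simulations are scored by the gene-count-weighted mean of per-cluster
Pearson correlations across all observation times, the anchored initial
point included.  Correlation, not RMSD, is primary: the goal is the pattern
of expression rather than its magnitude.  Conventions: a constant vector
(simulated or observed) contributes r = 0; a simulation that overflows to
non-finite values (possible for strongly unstable null matrices)
contributes r = 0 for the affected cluster — a divergent trajectory carries
no usable pattern, and a neutral zero keeps every null score defined.  A
normalised-RMSD alternative (per-cluster RMSD divided by the observed
range, averaged; zero-range clusters excluded with a warning) is provided
for comparison only.

## Module discovery

Genes are clustered by Ward's minimum-variance linkage; the distance is
Euclidean on log2FC rows (the standard companion to Ward linkage).  All
candidate divisions are cuts of the *same* tree, so partitions at different
K are nested.  Functional coherence of a division counts genes annotated
with at least one term whose one-sided hypergeometric tail (cluster versus
all other clustered genes) falls below a threshold; only terms with at
least one member gene in the cluster are tested, no multiple-testing
correction is applied inside the score (thresholds are swept instead), and
ties in the best division resolve to the smallest K.  A normalised variant
(coherence ÷ annotated genes) is reported alongside the raw count.

Scale dependence, demonstrated in the test suite: with perfectly
cluster-private ("purity-1") annotations, any union of true clusters is
itself significantly enriched once term sizes reach roughly five genes
(all g term genes inside a union is a tail of order C(n−g, k−g)/C(n, k)),
so the coherence curve saturates for every division at or below the true K
and the smallest-K tie-break wins.  Coherence-based selection therefore
discriminates at desk scale (few genes per term, as in the bundled
generator's small configurations) or on real annotations, which are
overlapping and impure; the planted-K recovery checks use the small-scale
regime where the mathematics genuinely distinguishes the divisions.

## Steady-state inference

Each sampled time point is treated as an independent steady-state
observation.  For each target cluster, an L1-penalised linear regression on
all other clusters' profiles (self excluded — the diagonal is reserved for
decay) is fitted per leave-one-treatment-out fold, data centred, no
intercept.  The penalty is chosen per target from the grid
(0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1, 3, 10) by an inner
leave-one-treatment-out mean-squared-error loop; the grid spans near-OLS to
full shrinkage for data on the log2FC scale.  Fold coefficients are
averaged; influences seen in fewer than 3 of 5 folds or with |mean| < 0.1
are dropped.  Held-out performance is the weighted correlation between
predicted and observed cluster values on the left-out treatment.

A structural caveat the tests document honestly: per-target symmetric
regression on observational ensembles recovers each cluster's *conditional
dependence neighbourhood* (regulators, targets and co-regulators all
predict it), not the directed support of A.  On data generated by the
planted ODE model — trajectory ensembles or exact equilibria alike — the
consensus support therefore overlaps the true support only partially
(precision ≈ 0.2–0.4 at desk scale), and the corresponding recovery check
is expected to fail; the inferred matrix is a *starting point* whose value
the calibration and randomisation stages then establish, which mirrors how
the method is used.

## Calibration

Two-stage simulated annealing, defaults: 25 runs × 5000 steps (stage one,
initial deleterious-acceptance probability 0.80), champion reseeds
25 runs × 25000 steps (stage two, 0.10).  One move per step: with
probability 0.001 a zero off-diagonal cell gains a weight drawn from
U(−0.6, 0.6); with probability 0.01 a nonzero off-diagonal influence is
removed; otherwise a nonzero cell (diagonal included — the decay terms are
tuned but never deleted) is rescaled y → y·(1+f), f ~ U(−0.6, 0.6).
Improving moves are always accepted; deleterious ones with probability
p₀·(1−0.002)^step.  The cooling is geometric because a multiplicative
"cooling factor" read subtractively would extinguish acceptance by step 400
of 5000; acceptance is a bare probability independent of the loss
magnitude (no Metropolis ratio).  Runs are embarrassingly parallel and
fully reproducible: every run seed derives from the configuration seed.

## Randomisation nulls

`resample` permutes nonzero values among nonzero positions (structure
kept); `uniform` redraws nonzero values from U(−2, 2) (structure kept);
`scramble` permutes all entries (structure destroyed, value multiset
kept).  The diagonal participates in all three — the randomisations probe
the matrix as a whole.  Nulls are simulated under the observed course's
initial state and times; the empirical p uses add-one smoothing
(1 + #{null ≥ observed})/(n+1) so finite replicates never yield p = 0, and
a one-sided normal tail on the null moments is reported alongside (it is
the only route to p-values far below 1/n_reps, and is flagged as undefined
when the null is degenerate).

## External validation

Interaction edges whose endpoints are both clustered are counted between
ordered cluster pairs (undirected sets count both directions, twice on the
diagonal for within-cluster edges).  The null permutes clustered-gene
identities across the edge list — same genes, same edges, randomised
labels — preserving topology and degree sequence; 1000 replicates by
default.  Cluster pairs are labelled TP (model edge, significant count),
FN (model edge, non-significant), TN (no edge, non-significant), FP (no
edge, significant); the naming follows the validation protocol literally
even though a conventional confusion matrix would call the model-edge/
non-significant case differently.  Accuracy is (TP+TN)/(TP+TN+FP+FN) per
dataset, plus an "any" accuracy counting a pair correct if TP or TN under
at least one dataset.  Within-cluster (diagonal) counts are a separate
diagnostic and never enter accuracy.

## Consensus

Ensemble summaries count edge presence and combine weights by mean and
median with absent edges contributing zero.  Group consensus keeps an edge
present in ≥ ceil(fraction × members) member models (default one half) and
averages its weight over the members that contain it — contributing models
only, since averaging in zeros would shrink every group weight by its
absence rate.  Edges averaging to exactly zero are treated as absent.
Cross-group comparison classifies edges as conserved (both groups, same
sign), differential (exactly one group) or opposite (both, opposite sign).

## Synthetic data

The generator plants K clusters (default 10, 20–100 genes each) with
independent off-diagonal edges at density ρ (default 0.1), weight
magnitudes U(0.1, 1.0) with random sign, and decay constants τ ~ U(5, 50) h.
Off-diagonals are shrunk geometrically until the spectral abscissa is at
most −0.005/h — a margin that keeps 96 h trajectories bounded while still
allowing transient rises.  Five treatments × five time points
(3, 24, 72, 75, 96 h) emulate the preconditioning study design; per
treatment, the initial state is N(0, 1) per cluster, cluster observations
add N(0, σ_obs²) (default 0.1), and member-gene values add N(0, σ_gene²)
(default 0.3) around their cluster value.  Annotations give each cluster a
private term carried by its genes with probability π (default 0.9);
interaction sets place ~10·κ gene pairs per true edge (default κ = 0.9)
plus random background pairs totalling ~10·(1−κ) per true edge.

Beyond the trajectory mode, an equilibrium mode generates each sample as
the steady state c* = −A⁻¹u under a sample-specific constant input
u ~ N(0, 1) — the data-generating process the steady-state regression
stage actually assumes — which the tests use to characterise the inference
stage separately from the dynamics.

What the generator does *not* emulate: probe-level measurement artefacts,
batch effects, overlapping annotation ontologies, and mid-course external
perturbations.  Passing recovery tests on this generator therefore show
the algorithms are correct under the model's own assumptions, not that
real tissue data satisfies those assumptions.

## Problem sizes in the checks

The bundled checks run at desk scale, chosen to exercise every code path
with comfortable margins: the planted study uses K = 10 clusters and
5 × 5 samples; annealing recovery uses 5 runs × 2000 then 5 × 5000 steps;
nulls use 100 replicates (50 repetitions for the uniformity check);
label-permutation validation uses 200–400 replicates over 20 seeds; the
coherence toy uses 3 clusters × 5 genes where the hypergeometric
mathematics cleanly separates the divisions.  The defaults embedded in the
code (25 SA runs, 25000 steps, 1000 permutations) are the full protocol.

## Known limitations

* Steady-state regression cannot orient edges (see above); the consensus
  matrix is a calibration starting point, not a validated network.
* With five time points per course the models are underdetermined;
  ensembles and group consensus mitigate but do not remove this.
* The weighted-correlation fitness is scale-blind per cluster; applications
  needing magnitude fidelity should consult the RMSD diagnostic.
* Divisions of the coherence curve are cuts of a single tree; a different
  clustering of the same data is outside the search space.
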