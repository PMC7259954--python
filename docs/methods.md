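# Methods

## The model

The pipeline treats a motor's P-loop as a system hopping between a small
number of metastable conformational states. Trajectory frames are reduced
to a 36-dimensional feature vector — the Euclidean distances between every
backbone amide nitrogen and every backbone carbonyl oxygen of the
6-residue GESGAG loop, all 36 ordered pairs, in nm. These internal
distances are invariant to global rotation and translation, so no frame
alignment is needed before clustering or PCA.

A Markov state model is estimated in two stages. Microstates come from
k-hybrid clustering: a deterministic k-centers pass (first center = frame
0, then repeatedly promote the farthest frame) adds centers until every
frame lies within the cluster radius, followed by rounds of k-medoids
refinement in which one random in-cluster swap per cluster per round is
accepted when the total within-cluster distance drops. Transition counts
at an integer lag (stride) use a sliding window and never cross trajectory
boundaries. Fitting adds a uniform pseudocount of 1/n (n = number of
states of the model being fitted) to every cell of the count matrix and
row-normalizes. The pseudocount acts as a uniform prior over the state
space; it also makes the chain irreducible, so no ergodic trimming is
performed, and no detailed-balance symmetrization is applied — the
estimator is exactly count + pseudocount + row-normalize. The equilibrium
distribution π is the leading left eigenvector (imaginary parts asserted
below 1e-9, negatives clipped at −1e-12, renormalized); a power-iteration
cross-check (a row of T^1000) is part of the test suite. Lag times are
chosen by the user from the implied-timescales table
t_i = −τ/ln λ_{i+1}(τ): on Markovian data the t_i are flat in τ.

The coarse P-loop model has five states, A–E. The microstate
representatives (the medoid frames' 36-D feature vectors) are reduced by
PCA — mean-centered full SVD, no whitening, component signs fixed by
making each component's largest-magnitude loading positive — and the first
four PCs are clustered by Ward-linkage agglomeration (Euclidean metric)
into five groups. Conformations of other systems are assigned to these
states by majority vote of their k = 5 nearest labeled points in the same
PCA space, with ties broken by the nearest member among tied labels;
results are insensitive for k in 3..15 on well-separated states. The
coarse transition matrix is re-estimated at the frame level from the
macrostate-mapped assignments with the same pseudocount rule (n = 5);
projecting the microstate matrix through the equilibrium-weighted mapping
is available behind a flag. The macrostate equilibrium is additionally
computed by summing microstate probabilities per macrostate, and the two
routes are required to agree within three jackknife standard errors.

Two scalars summarize each motor: ΔG_AB = −ln(π_A/π_B) in kT, negative
when the nucleotide-favorable A state is preferred (the duty-ratio proxy,
thresholded at 0 kT for a high/low call), and P(A→B) = T₅[A,B], the
one-lag probability of leaving A for B (the ADP-release proxy). Because
absolute in-silico transition probabilities are not comparable to in-vitro
rates, panel evaluation against ADP release rates is rank-based within
condition groups (measurements are only mutually comparable under one
experimental condition); uncertainties on both predictors come from
leave-one-trajectory-out jackknife resampling.

The free-energy surface is a weighted 2-D histogram of the microstate
projections in the PC1/PC3 plane — one point per microstate, weighted by
π, 50 bins per axis spanning the data range — converted to F = −ln p in
kT and smoothed with a Gaussian kernel of variance 0.3 in grid-cell units
(σ = √0.3 ≈ 0.55 cells), then summarized by six evenly spaced level-set
boundaries between the minimum and the maximum finite F. By default the
convolution is applied to the free-energy field after the logarithm,
following the construction order of histogram → −ln → convolve, with
empty-cell infinities capped at (max finite F + 1) first; a
`smooth_space="probability"` flag instead smooths the histogram before the
logarithm, which conserves probability mass exactly (reflective boundary,
normalized kernel) and is what the conservation test exercises. An
alternative reading of "variance 0.3" as σ = 0.3 can be had by passing
`variance=0.09`.

Crystal-ensemble comparison classifies a structure as nucleotide-bound if
any ligand residue name is on the recognized 14-entry list (ADP, ATP, ANP,
MNQ, MNT, ONP, PNQ, DAE, DAQ, NMQ, AGS, AD9, AOV, FLC), partitions
structures by backbone RMSD to a reference conformation ("within" means
≤ 0.6 Å; the superposition set is the same P-loop backbone whose RMSD is
reported, which keeps the quantity self-contained), and cross-tabulates.
The contingency table puts the outlier (beyond / low-duty) row first, so
the sample odds ratio (a·d)/(b·c) directly measures depletion of the
positive label among outliers — for the packaged printed counts
([[1, 8], [84, 21]]) it is 0.03125, printed as 0.03. The Fisher exact test
is implemented in-package with hypergeometric terms in log space
(log-gamma factorials); the two-sided p sums the probabilities of all
fixed-margin tables at most as probable as the observed one
(probability-mass rule), which for the unliganded duty table
[[8, 12], [0, 9]] gives p = 0.0332 (the one-sided value is 0.0293). An
exact rational-arithmetic enumeration oracle and scipy's implementation
cross-check it in the tests. Bootstrap 95% intervals on the per-row
positive fractions use 1000 record resamples by default.

## Superposition and surface areas

RMSD minimization over rigid transforms uses the standard rotation-matrix
(Kabsch) solution via `scipy`'s rotational alignment after centering; a
brute-force SO(3) grid search with successive refinement serves as the
test oracle at 1e-3 Å. Side-chain solvent-accessible surface areas use the
sphere-point sampling construction (via `biotite`) with a fixed Bondi-type
element radius table and a 1.4 Å probe; backbone atoms occlude but are
excluded from the per-residue sums, and unknown elements require an
explicit user-supplied radius. A single isolated sphere reproduces
4π(r + probe)² within 2% at 960 points.

## The synthetic-data generator

Real inputs to this kind of analysis are millisecond-scale molecular
dynamics ensembles, which are not reproducible at desk scale. The
generator instead emulates the statistical structure the estimators
assume: a hidden 5-state Markov chain (default diagonal 0.95, off-diagonal
mass decaying with state-index distance, so basins are metastable and the
slow timescales well-resolved) with isotropic Gaussian emissions
(sd 0.1 nm) around state-specific centers drawn uniformly in
[0.4, 1.2] nm per coordinate — the range a short loop's N/O distances
actually span; in 36 dimensions this puts centers roughly 2 nm apart, an
order of magnitude beyond the emission width. The frame interval is
0.1 ns so nanosecond lag times are integer strides. Trajectory starts are
drawn from the stationary distribution. Toy 6-residue structures (N, CA,
C, O per residue, optional CB pseudo-atoms) realize the A/B distinction as
a ~150° swing of the third residue's carbonyl — a pure 180° mirror would
leave every N/O distance unchanged, so the swing is deliberately
asymmetric — and a bent "far" template provides outlier conformations
(~1.5 Å backbone RMSD from A).

Motor panels prescribe each motor's π_A/π_B and T[A→B] exactly by building
reversible chains (Metropolis-style off-diagonals around a prescribed
stationary distribution, with π_A + π_B = 0.8 of the mass). Ground-truth
ΔG_AB values are spread evenly over [−2, +2] kT, matching the spread a
real motor panel exhibits, and P(A→B) is coupled log-linearly to ΔG
(p = 0.05·e^{0.6ΔG}): motors that favor A also leave it more slowly, which
is both the physical expectation and what keeps the reverse rate feasible.
Observed duty ratios are a logistic-decreasing function of ΔG (noise
sd 0.03) and ADP release rates a log-linear increasing function of P(A→B)
(scale 1500 s⁻¹, log-noise sd 0.15), keeping both observables in their
physical ranges. Crystal-set generators allocate exactly round(p·n) bound
records per group (which ones is a seeded shuffle), so requested fractions
are met deterministically.

What the generator does *not* emulate: force-field physics, non-Markovian
memory, anisotropic or state-dependent emission noise, slow drift within
states, and the sequence-specific side-chain interactions that produce the
state shifts in real motors. Passing recovery tests therefore demonstrates
that the estimators are correct and well-calibrated for data with the
assumed structure, not that real trajectories satisfy those assumptions.

## Problem sizes and numerical choices

Default study conditions for the recovery suites: MSM parameter recovery
uses 100 trajectories × 10⁴ frames (maximum absolute transition-matrix
error < 0.02 and equilibrium error < 0.01 are comfortably met; measured
errors are a few 10⁻³); the end-to-end panel uses 8 motors × 20
trajectories × 2000 frames with k-hybrid run on a 1-in-5 frame subsample
of the reference motor (radius 1.0 nm, between the intra-state spread of
~0.6 nm and the ~2 nm center separation). These sizes were chosen once as
realistic desk-scale analogues of the study design. Coarse models on
synthetic panels are fitted at a one-frame lag because the generated
chains are exactly Markov at one step and the ground-truth P(A→B) is a
one-step probability; for real trajectory data the documented coarse lag
default is 37.5 ns. For parameter recovery, Ward macrostate indices are
aligned to the generating labels by dominant overlap (a greedy fallback
handles non-bijective overlaps); on real data the A–E naming is the
analyst's choice.

Ties and degeneracies: Ward labels are renumbered by first appearance so
results are deterministic for a given input order; k-centers seeding is
frame 0 (deterministic); medoid-swap proposals are seeded; eigenvector
sign and PCA component signs are fixed deterministically; equal-probability
tables in the Fisher sum are kept using a 1e-9 relative log-tolerance.
All generators and the pipeline are bit-reproducible for a fixed seed, and
every artifact embeds the seed that produced it.

## Limitations

The five-state coarse-graining assumes the reference motor visits all five
states well enough to define them; motors whose ensembles concentrate in
one basin yield noisy P(A→B) estimates (their rare escapes are the very
reason rank-based comparison is restricted to low-duty motors in the
motivating analysis). The Fisher test is exact but the bootstrap intervals
are percentile intervals, slightly anti-conservative at small n. The
free-energy surface is a 2-D projection; basins separated only in
discarded dimensions can merge. The package asserts nothing about real
myosins: the packaged motor-panel table ships as input data for
user-supplied models.
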