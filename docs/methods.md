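# Methods

`advpes` implements uncertainty-driven adversarial sampling for
committee-learned potential energy surfaces (PES), together with the active
learning (AL) loop that retrains the committee on the sampled points, and a
benchmark on an analytic two-dimensional double well.

## Model

A surrogate potential is a smooth parametric map h_theta(X) from a
configuration X to a scalar energy.  Configurations are either bare
d-dimensional vectors (toy surfaces) or molecules (Z, R) with fixed atomic
numbers Z and Cartesian coordinates R in angstrom; every operation in the
package perturbs coordinates only, never composition.  Predicted forces are
the negative coordinate gradient of the surrogate energy, obtained
analytically from the network (softplus activations keep the energy twice
differentiable, which the attack gradients require).

Epistemic uncertainty comes from a committee of M >= 2 independently
initialized members.  For member predictions E_m and force arrays F_m:

- mean energy  Ebar = (1/M) sum_m E_m, and likewise for forces;
- energy variance  sigma_E^2 = (1/(M-1)) sum_m (E_m - Ebar)^2;
- force variance   sigma_F^2 = (1/(M-1)) sum_m [ (1/D) sum_k (F_mk - Fbar_k)^2 ],

with D the number of scalar force components (3n for a molecule, d for a
vector).  sigma_F^2 is a single scalar per configuration.  Variances use the
unbiased 1/(M-1) form.

An in-domain classifier declares a configuration inside the training domain
when its committee variance lies strictly below a threshold t; t is
calibrated as a percentile (default the 80th) of the variance over the
current training set.  The boundary value sigma^2 = t is classified
out-of-domain.  The force variance is the default statistic because it
tracks extrapolation error more sharply than the energy variance; the energy
variance is selectable.

## Adversarial objective

Candidates are proposed by maximizing, over a perturbation delta,

    L_adv(X_delta) = p(X_delta) * sigma_F^2(X_delta),
    p(X_delta)     = exp(-Ebar(X_delta) / kT) / Q,
    Q              = sum_{(X,E,F) in D} exp(-E / kT),

where D is the current labeled dataset and kT a sampling temperature in the
dataset's energy units.  Q is computed once per generation in log space
(log-sum-exp with max shift) and frozen during the attacks; p is evaluated
as exp(-Ebar/kT - log Q), which equals the textbook ratio in exact
arithmetic but stays finite for large |E|/kT.  The likelihood factor uses
the committee mean energy (the bar notation is taken literally).

The ascent iterates delta <- delta + alpha_delta * dL_adv/ddelta with an
adaptive-moment (Adam) update by default; plain gradient ascent is
selectable.  delta is initialized from N(0, sigma_delta^2 I); sigma_delta=0
gives exact zeros and a fully deterministic attack.  The iteration budget is
fixed (no early stopping).  The gradient is exact, not finite-differenced:

    d sigma_F^2 / dx = 2/((M-1) D) * sum_m H_m (g_m - gbar),
    d p / dx         = -(p / kT) * gbar,

with g_m the member energy gradients and H_m (g_m - gbar) computed as
Hessian-vector products by a reverse-over-forward pass through each member
network.  Cartesian attacks act on all coordinates (X_delta = (Z, R+delta));
collective-variable attacks act on torsion angles through the backmap below,
with the chain rule closed by the backmap's forward-mode Jacobian.

Batched attacks derive each seed's random stream from the attack seed plus a
content hash of the seed configuration, so results are independent of batch
partitioning and permuting the seeds permutes the results.  Non-finite
losses abort a single attack (or flag it inside a batch) with the last valid
iterate preserved.

## Collective variables

A torsion CV is four atom indices (a, b, c, d) plus the molecular bond
graph.  The measured angle is the standard signed atan2 torsion (cis = 0,
trans = pi).  The rotating set is the connected component containing atom d
after deleting the b-c edge; bonds through rings are rejected at
construction.  A CV displacement rotates that set rigidly about the b->c
axis (Rodrigues rotation), which shifts the measured torsion by exactly the
requested angle and preserves all intra-fragment distances.  The backmap
applies the declared CVs sequentially; its forward-mode Jacobian propagates
tangents exactly, including the motion of later rotation axes caused by
earlier rotations, so nested rotating sets are differentiated correctly.

## Selection pipeline

Attack candidates pass, in order: (1) deduplication — agglomerative
clustering (average linkage by default) of the pairwise RMSD matrix, cut at
a distance threshold, keeping the most force-uncertain member per cluster;
(2) the uncertainty filter — only candidates classified out-of-domain
survive; (3) oracle labeling; (4) an optional energy cap that drops
extremely high-energy samples.  RMSD is the root of the coordinate-wise
mean squared difference, so for a d-vector it is the Euclidean distance
divided by sqrt(d); optimal rigid superposition (Kabsch) is available for
molecules and off by default, since attack displacements are small and
vector-kind configurations have no rigid-motion ambiguity.

## Ground-truth oracles

Two analytic oracles replace the expensive reference calculations of a real
campaign:

- the 2D double well E(x, y) = 10x^4 - 10x^2 + 2x + 4y^2, whose linear tilt
  makes the left basin the global minimum (E = -3.96 at (-0.75, 0)); an
  energy filter E < -2 on uniform samples over [-1.5, 1.5]^2 retains left
  basin points only (about 7.4% of draws);
- a smooth 2pi-periodic two-torsion surface (truncated cosine series plus a
  von-Mises-style bump at the origin) evaluated on a six-atom chain molecule
  through its two backbone torsions, with forces from the analytic torsion
  gradient.  It emulates a flexible molecule whose PES is governed by
  rotatable bonds; it deliberately omits bond-stretch and angle terms, so
  forces on non-torsional degrees of freedom are zero and CV attacks are
  exactly the right sampling move.

## Double-well benchmark protocol

Study conditions (fixed in the presets):

- initial data: up to 800 uniform points on [-1.5, 1.5]^2, keep E < -2
  (about 59 survivors);
- committee: 5 feedforward members, 4 softplus hidden layers, energy-only
  loss, Adam, batch 35, 60:20:20 splits shared across members, different
  initial weights;
- attacks: kT = 5 (dimensionless energy units), Adam, learning rate 0.003,
  600 iterations, 20 seed points per generation drawn from the current
  dataset, delta init sigma = 0.01;
- selection: dedup threshold 0.02, 80th-percentile force-variance filter;
- random baseline: delta ~ U(-1, 1) per coordinate from 20 training points,
  the same selection pipeline, then at most 20 random picks;
- evaluation: RMSE of the committee mean energy against the oracle on a
  100 x 100 grid over [-1.5, 1.5]^2.

Desk-scale adaptations, chosen once and applied identically to both
sampling strategies:

- members use 64 units per hidden layer (not 1024).  Narrow members need a
  stronger optimization schedule to reach the same converged fit as wide
  ones, so training runs up to 3000 Adam steps at learning rate 1e-2 with
  exponential decay to 1e-3, energy targets standardized during training
  (undone exactly on the linear output layer), and remainder minibatches
  smaller than half the batch size dropped.  With these settings every
  member fits the initial basin data to a train RMSE below 0.1.
- a member that ends more than 3x above the committee's median train RMSE
  is retrained from a fresh deterministic initialization (at most twice).
  Such members are optimization failures, not epistemic signal, and a
  single one corrupts every downstream variance.
- labeled candidates with E > 200 (40 kT) are discarded before augmenting
  the training set, for both strategies.  Points this extreme lie far
  outside the evaluation region and visibly destabilize retraining by
  inflating the target scale.
- candidates within the deduplication threshold of an existing training
  point are rejected: the purpose of deduplication is never to evaluate the
  same configuration twice.
- the generation count is fixed at 8, enough for the sampled frontier to
  cross the barrier and approach the high-energy rim of the evaluation box
  at 20 seeds per generation.
- the comparative study uses 10 paired replicates (same initial data and
  seed streams for both strategies within a replicate).

A caveat on what narrow members change: with 64-unit members the grid RMSE
over the full box is dominated by the outer high-energy band (roughly a
third of the grid), where extrapolation differs between retrains by a few
energy units regardless of sampling strategy.  The interior — both basins
and the barrier — trains to a grid RMSE of 1-2 under either strategy.  The
sampled-energy contrast between adversarial and random proposals is robust
at this scale; relative grid-RMSE contrasts between the two strategies are
noisy, and wider members are needed to resolve them.

## Numerical choices

- All randomness flows from explicit integer seeds through numpy
  SeedSequence spawning; two runs with the same master seed are
  bit-identical, including whole AL loops.
- Committee training of shared-split, energy-only presets runs all members
  in one stacked tensor pass with a shared batch order (member diversity
  comes from the initial weights); the general path (force matching,
  per-member splits) trains members sequentially.
- Hierarchical clustering and percentiles come from scipy; linkage choice
  (average) and the cluster-representative rule (max force variance) are
  recorded in the selection configuration.
- Degenerate inputs: empty datasets, all-equal calibration variances, rings
  through a torsion bond, collinear torsion atoms, and non-finite attack
  losses all raise or warn explicitly rather than propagating silently.

## What the synthetic setup does and does not show

The double well probes the core claims — epistemic-uncertainty contrast
between sampled and unsampled basins, likelihood-bounded attack energies,
and the data-efficiency gap against random distortion — in a setting where
the oracle is exact and every quantity is computable.  It does not emulate
quantum-chemical label noise, many-body force fields, conformational
entropy, or the cost asymmetry of real oracles; passing the benchmark says
the machinery behaves as designed, not that a particular molecular system
will train to a given accuracy.  The torsional molecule exercises the CV
machinery end to end but its energy depends on two angles only, so it
cannot probe couplings between CV and non-CV degrees of freedom.

## Known limitations

- Committee members are plain feedforward networks on flat coordinates;
  message-passing architectures satisfy the same interface (energy plus
  input gradients and Hessian-vector products) but none ships with the
  package.
- Grid-search verification of attack maxima is exhaustive only in 2D.
- The energy-variance attack objective is available but not the default,
  and the package has no conformal or Bayesian uncertainty layer beyond the
  percentile threshold.
- Narrow members extrapolate more roughly than the wide committees the
  protocol was designed around; at desk scale the uncertainty landscape has
  more local maxima, which the fixed-budget multi-start attacks only partly
  compensate.
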