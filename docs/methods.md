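# Methods

## Overview

`chimerabrain` implements a synchronization framework for studying
cognitive integration and segregation across the lifespan with
personalized brain-network models.  The pipeline has five stages:

1. **Structural connectome** — a weighted, undirected network of brain
   regions; weights are streamline counts divided by the summed
   volumes of the two endpoint regions.  Each region belongs to one of
   nine cognitive systems: attention (Att), auditory (Aud),
   fronto-parietal (FP), cingulo-opercular (CO), motor-sensory (MS),
   default mode (DM), visual (V), ventral-temporal (VT) and
   subcortical (SC).
2. **Critical-coupling calibration** — the excitatory global coupling
   C_E of the Wilson-Cowan network is bisected to the boundary between
   the quiescent fixed point and spontaneous network oscillation, so
   every connectome operates in the same dynamical regime relative to
   its own criticality.
3. **Single-region stimulation** — each selected region in turn
   receives a constant stimulus P = 1.15 while the delay-coupled
   stochastic dynamics is integrated; the post-transient window is the
   steady state analysed downstream.
4. **Synchrony and classification** — per-region phases feed pairwise
   Kuramoto order parameters for all cognitive-system pairs; the
   time-averaged 9 x 9 synchrony matrix is thresholded at R >= 0.65,
   partitioned with Louvain community detection, and mapped to a
   binary synchronization pattern whose class is synchronous (all
   systems in one multi-member community), asynchronous (all
   singletons) or chimera (any mixture).
5. **Aging statistics** — class proportions, prevalence tiers, pattern
   similarity and strength stratification over age bins.

## The neural-mass model

Each region k carries excitatory and inhibitory population activities
E_k(t), I_k(t):

    tau dE_k/dt = -E_k + (S_Emax - r_E E_k) *
        S_E(C_EE E_k - C_EI I_k + C_E sum_j A_jk E_j(t - tau^d_jk) + P_k)
        + sigma-noise
    tau dI_k/dt = -I_k + (S_Imax - r_I I_k) *
        S_I(C_IE E_k - C_II I_k + C_I sum_j A_jk I_j(t - tau^d_jk))
        + sigma-noise

with the shifted logistic S(x) = 1/(1+exp(-a(x-theta))) -
1/(1+exp(a theta)), which vanishes at 0 so the origin is an exact
fixed point of the unstimulated noise-free network.  C_I = C_E / 4 is
enforced (about four in five cortical neurons are excitatory).
Conduction delays are Euclidean distances between region centroids
over a 10 m/s conduction velocity, giving ~1-17 ms for human-brain
geometry.

Local parameters default to the classical oscillation-capable
Wilson-Cowan set: C_EE = 16, C_EI = 12, C_IE = 15, C_II = 3,
a_E = 1.3, theta_E = 4, a_I = 2, theta_I = 3.7, tau = 8 ms,
r_E = r_I = 1.  With these values an isolated region crosses a Hopf
bifurcation under constant drive: at P = 1.15 it sustains a limit
cycle of roughly 55 ms period, while P = 0 leaves it quiescent.  All
parameters are overridable; the downstream analyses are properties of
the regime (quiescent baseline, single-region oscillation under
stimulus), not of one parameter set.

### Numerical scheme

Euler-Maruyama at dt = 1e-3 ms.  Design choices that matter:

- **Noise.**  The noise magnitude sigma = 1e-5 is interpreted as the
  variance intensity of the driving white noise; the per-step
  increment is (1/tau) sqrt(sigma dt) N(0,1), independently for E and
  I.  Increments are aggregated over blocks of `noise_block` steps
  (default 16): the summed increment over a block is Gaussian with the
  summed variance, so this is the same discretization on a coarser
  noise grid.  At this amplitude the noise only provides spontaneous
  background activity.
- **Delay history.**  Delayed states are read from a per-region ring
  buffer stored every `delay_quantum` steps.  The default quantum of 1
  reproduces each edge's delay exactly (verified by signal-front
  tests); the desk-scale configurations use 16, i.e. at most 0.016 ms
  jitter on delays of 1-17 ms, which keeps the buffer cache-resident
  and roughly triples throughput.  The buffer holds 32-bit values;
  state and integration are 64-bit.  Delays have a floor of one
  quantum — a region never reads a neighbour's same-step state.
- **History initialization.**  For t < 0 the delayed history is the
  initial value (default 0.1).
- **Blow-up.**  Non-finite states abort with the step and region; the
  bounded sigmoid makes this unreachable in practice for sane
  parameters.

### Criticality calibration

`tune_global_coupling` bisects C_E between quiescent and active
behaviour of the *unstimulated, noise-free* network started at 0.1.
A run counts as "beyond critical" when the region-mean excitatory
activity fluctuates (std > 1e-4 over the analysis window) **or**
settles at an elevated level (mean > 0.01).  The second clause
matters: far above criticality the network saturates at a high fixed
point with vanishing variance, and a variance-only test would let the
upward bracketing search escape through that regime.  Just above the
boundary the departure is oscillatory, so the returned bracket's
upper endpoint classifies as active under the variance test alone.

The default tolerance is 1e-6 on the bracket width.  The tuned C_E
depends (weakly but systematically) on the transient and window used
by the tuning runs, so a cohort must be tuned under one fixed
protocol; the pipeline enforces a single tuning configuration per run
and warm-starts each individual's bracket from the previous one,
roughly halving the bisection count.

## Synchrony and classification

Phases are phi_k(t) = atan2(I_k, E_k) on the raw steady-state series
(mean-centering is available but off by default).  For systems s_j,
s_k the Kuramoto order parameter over the union of their regions is
averaged over the steady window to give R_{s_j,s_k}; the diagonal
uses the single-system order parameter (the pair formula would
double-count the members and cap the diagonal at 0.5).  Quiescent
samples with E = I = 0 exactly have no defined angle; they are set to
phase 0 with a logged warning.

Classification thresholds at R >= 0.65 (inclusive), removes
self-loops, and runs networkx Louvain with 20 seeded restarts at
resolution 1, keeping the modularity-best partition.  Every system in
a community of size >= 2 joins the synchronous group — also in the
rare runs with several multi-member communities — and the three-way
class follows.  An exhaustive Bell(9) = 21147-partition search serves
as the oracle for the 9-node graphs in the tests.  For an edgeless
binary graph modularity is undefined; both implementations return
all-singletons.

## Synthetic cohorts

Real lifespan connectome databases cannot ship with the package, so
cohorts are synthetic, generated by a seeded stochastic block model
over the cognitive systems:

- **Block structure.**  Within-system blocks: density 0.8, unit weight
  scale.  Between-system blocks: density and weight scale follow age
  trajectories (below).  Edge weights are log-normal (sigma_log =
  0.45), giving the heavy-tailed, right-skewed strength distributions
  seen in volume-normalized tractography networks.
- **Rich-club core.**  One hub region per system (nine by default) is
  completely interconnected with 2.5-fold up-weighted edges — a
  backbone of hubs that is denser than expected from strength alone
  and gives every cognitive system a path into the core.
- **Geometry.**  Regions are placed in two mirrored hemispheric slabs
  sized so inter-region distances span ~10-170 mm (delays ~1-17 ms at
  10 m/s); volumes are log-normal.  The parcellation (128 regions
  full-scale, with VT = 10 and 3 auditory regions per hemisphere;
  27 regions at demo scale) is deterministic given the region plan.
- **Age trajectories.**  Each block parameter follows a configurable
  trajectory over age 5-90: constant, linear, power-law, linear
  decline, or inverse-U.  The default cohort raises between-system
  *density* (0.08 -> 0.20) and *weight scale* (0.10 -> 0.30) with a
  convex power-law profile (gamma = 1.7, most of the change after
  midlife).  Age acts on the between-system blocks rather than on a
  global gain because the per-connectome criticality calibration
  absorbs any uniform rescaling of the weights: what survives the
  calibration is the *ratio* of between- to within-system coupling
  and the number of between-system routes.  Simulations of the
  stimulation protocol across this parameter range show the
  synchronous-class proportion rising with the between-system
  parameters up to a saturation near a weight ratio of ~0.36; the
  default trajectories stay below that saturation, and the convex
  profile spreads the response across the middle and old bins instead
  of exhausting it by midlife.
- **Paired bins (common random numbers).**  By default, individual i
  of every age bin shares one random stream, so the bins contain
  matched network skeletons that differ only through the age
  trajectories, and the pipeline reuses the same stimulated-region
  choice and stimulation noise for paired individuals.  The
  one-per-system stimulation policy is likewise a stratified
  rotation — individual i stimulates within-system position
  (i + system index) mod n — so every individual covers hub and
  non-hub positions equally often and no cohort is skewed by a lucky
  draw of hubs.  At the demo
  scale (4 individuals per bin) this paired design is what lets the
  planted age trend rise above sampling noise; with
  `paired_across_bins=False` individuals are fully independent, as in
  a real cross-sectional cohort, and correspondingly larger cohorts
  are needed to recover trends.

What the generator does *not* emulate: multi-site scanner effects,
age-binned anonymization, head-size covariates, hemispheric
asymmetries of real anatomy, and any direct structure-function
coupling beyond the block model.  Passing tests on synthetic cohorts
show the pipeline recovers structure the generator planted; they say
nothing about effect sizes in real populations.

## Problem sizes of the shipped configurations

The full protocol (1000 ms transient, 500 ms window, all 128 regions,
1e-6 tuning tolerance) is cluster-scale: ~2000 individuals x 128
stimulations x 1.5e6 steps.  The package's desk-scale demo
(`demo_config`) uses 12 individuals (4 per coarse age bin), 27
regions (3 per system), one stimulated region per system, an 80 ms
transient with a 200 ms synchrony window (3-4 oscillation periods),
100 + 100 ms tuning runs at 1e-3 tolerance, and delay quantum 16.
One cohort completes in under two minutes on one CPU; the acceptance
checks run ten master seeds.  The analysis windows were chosen as the
smallest that keep classification stable: halving dt changes the
oscillation period by < 2%, and widening the window beyond 300 ms
changes class proportions only at the level of single borderline
runs.

## Known limitations

- The three-way class of a run near the R = 0.65 threshold can flip
  under tiny numerical perturbations; aggregate proportions are the
  meaningful output, not single-run classes.
- The tuned C_E is protocol-dependent (window lengths, activity
  threshold); comparisons are valid within one protocol only.
- Louvain is a heuristic; on 9-node graphs it attains the exhaustive
  optimum's class in >= 98% of random instances (tested), not always.
- The hop-count distance to the rich club uses the binary graph of
  nonzero edges; an inverse-weight variant is available but the two
  are not comparable numerically.
- Pattern-similarity decompositions follow the convention that
  *individual similarity* compares individuals at a fixed stimulated
  region and *region similarity* compares a system's regions within
  an individual.
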