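# Methods

## Model

Each subject's parcellated BOLD recording is an `n_regions × n_timepoints`
matrix Y (the package convention keeps regions as rows on disk and in
memory; the fitting code works on its transpose). The cohort is modelled
by one shared K-state hidden Markov model: a latent first-order Markov
chain z₁…z_T per subject with initial distribution π and row-stochastic
transition matrix A, and Gaussian emissions

  yₜ | zₜ = k  ~  N(μₖ, Σₖ),

so each state is a whole-brain configuration of mean activity (μₖ) and
region-by-region covariance (Σₖ). Subjects are treated as independent
sequences sharing one set of parameters (a group-level fit): states must
be common across subjects for any between-group comparison of their
dynamics to be meaningful. The number of free parameters is
(K−1) + K(K−1) + Kd + Kd(d+1)/2 for d regions.

Assumptions worth stating plainly: state durations are geometric (no
explicit dwell-time model); emissions are conditionally independent given
the state (no autoregressive structure); all subjects share μₖ, Σₖ, A and
π, with between-subject variability entering only through each subject's
realized state sequence.

## Estimation

Parameters are estimated by maximum-likelihood EM (Baum–Welch). This is a
deliberate design choice: the variational-Bayes free-energy machinery
used by several HMM toolboxes for this kind of data adds priors and a
model-evidence bound that are not needed to define the estimator, whereas
ML-EM is fully specified by the model above. The consequences of the
choice are documented below (order selection, empty states).

- **E step.** Per-subject forward–backward with per-timepoint rescaling:
  emission densities are divided by their row maximum and forward
  variables renormalized at every step, with the log evidence recovered
  from the accumulated scaling constants. This is algebraically exact and
  stable for T = 220, d = 116; the implementation is checked to 1e-8
  against exhaustive path enumeration on small instances (K ≤ 3, T ≤ 8).
- **M step.** Closed-form updates; covariances get a ridge of
  1e-6 × mean(diag) at every update to keep Cholesky factorizations
  well-posed. Gaussian log-densities use Cholesky solves throughout.
- **Initialization.** Means from k-means on the pooled timepoints
  (centers sorted lexicographically so restarts are reproducible), a
  shared pooled covariance, sticky transitions (diagonal 0.8), uniform π.
  Default 10 restarts; the restart with the best final log-likelihood
  wins. Every random element derives from the single fit seed.
- **Convergence.** Relative log-likelihood improvement < tol
  (default 1e-6) or max_iter (default 500). The winning restart's
  log-likelihood history is retained in `fit_meta` and is non-decreasing
  (asserted in tests to 1e-8 relative tolerance).
- **State starvation.** A state whose total responsibility drops below
  d + 1 frames is re-seeded from the worst-explained frames with the
  pooled covariance, and the event is logged.
- **Decoding.** Default is the argmax of the per-timepoint marginal
  posterior γ (it underlies fractional occupancy naturally); the Viterbi
  path is always computed alongside and can be made the decoder by
  config. All ties break toward the lower state index.

## Order selection

For each candidate K the model is fitted and scored by
BIC = −2·logL + p·ln(N_total). The report also counts "near-empty"
states — median decoded fractional occupancy across subjects below
1/(10K) — and the chosen K is the smallest candidate within one BIC
standard error of the minimum that has none; the BIC standard error is
taken as 2 × sd(per-subject log-likelihoods) × √n_subjects of the
minimum-BIC fit, subjects being the independent unit of the pooled
likelihood. On simulated 3-state data the procedure selects K = 3 over
{2…6}.

A known property of this ML-EM scheme: because k-means initialization
places every state on occupied data and maximum likelihood retains any
state that explains even a modest data region, overfitted fits (K well
above the true order) typically show surplus states with *low* (~3–6%)
but not *near-zero* occupancy. Genuine state pruning — states driven to
emptiness — is characteristic of variational-Bayes inference with
shrinkage priors, not of ML-EM, so the near-empty counter should be read
as a degeneracy guard rather than an expected signature of overfitting.
The full per-K table is always emitted so users can override the choice.

## Dynamics metrics

From each subject's decoded path (states labelled 1…K):

- **Fractional occupancy**: fraction of timepoints in each state; sums
  to 1. A posterior-weighted ("soft") variant is emitted alongside.
- **Lifetime (s)**: mean duration of maximal constant runs (visits); a
  visit spanning samples a…b lasts (b − a + 1)·TR, mapping each sample to
  one TR of dwell time. NaN for states never visited.
- **Interval time (s)**: mean number of timepoints strictly between
  consecutive visits to a state, times TR. Requires two visits (NaN
  otherwise); the censored stretches before the first and after the last
  visit are excluded, since they are not bounded by two visits.
- **Switching rate (Hz)**: (# adjacent differing pairs) / ((T−1)·TR).
  With this denominator the identity
  switching_rate = (T−1−trace(transition_counts)) / ((T−1)·TR) holds
  exactly; a single per-subject scalar is primary (a per-state variant is
  derivable from the transition counts).
- **Transition matrix**: counts of adjacent pairs (self-transitions
  included) with row-normalized probabilities; rows of unvisited states
  are NaN. An off-diagonal view (diagonal zeroed, rows renormalized) is
  derived for analyses of between-state switching only. Group tests
  default to the including-diagonal matrix.

NaN metric values are excluded pairwise from group tests with recorded
per-state sample sizes.

## Group statistics

- **t tests**: two-tailed two-sample tests per state for fractional
  occupancy, lifetime and interval time, plus one global test for
  switching rate. Student's pooled-variance variant is the default, Welch
  by flag. BH-FDR is applied within each metric family (4 families) by
  default; a single pooled family is available by config and is what the
  no-effect calibration uses, because with four separate families the
  probability of at least one false FDR discovery under the global null
  is ≈ 1 − 0.95⁴ ≈ 0.19 rather than ≈ 0.05.
- **Permutation tests on transitions**: the statistic per directed pair
  is the difference of group means (a Welch-t variant by flag); each of
  the n permutations (default 5000) shuffles group labels once jointly
  for all K² entries, preserving the matrix's dependence structure in the
  null. Two-sided p with add-one smoothing,
  p = (1 + #{|null| ≥ |obs|})/(n + 1), so p is never exactly 0. Raw p is
  the primary output (multiplicity-corrected q is appended as an
  advisory column).
- **Partial Spearman correlation**: ranks of x and y residualized on the
  covariates (intercept included; continuous covariates rank-transformed
  by default, sex as a 0/1 indicator), Pearson correlation of residuals,
  p from a t approximation at df = n − 2 − #covariates. Verified
  numerically against an independent implementation on random data.
- **Cognitive grouping**: MoCA < 26 defines impairment; scores exactly 26
  go to the unimpaired group and their count is logged, the cutoff being
  ambiguous at the boundary.

## Synthetic-data generator

The generator is the model's exact generative counterpart plus two layers
of realism: per-subject transition matrices (base matrix → multiplicative
group effects on targeted entries with row renormalization → iid Gaussian
jitter on each row's log-probabilities, renormalized; default jitter sd
0.2), and demographics (age ~ N(44, 10) truncated to [18, 80], education
~ N(12, 3) truncated at 0, MoCA per group ~ N(24.5, 2.5) patients /
N(27.4, 2.5) controls, clipped to [0, 30]; optionally coupled linearly to
one true transition entry for correlation studies). Each subject draws
from a substream keyed by (seed, group, subject index), so per-subject
data are invariant to cohort ordering. Demographics are scenery for the
statistical interfaces, not inference targets.

The default study-like specification has 12 states, 116 regions, 220
timepoints at TR = 2 s and 71 patients / 57 controls, all scaled by a
single factor (clamped at 8 regions and 5 subjects per group). Transitions
are sticky (diagonal 0.85). Two structural choices support validation and
were fixed by pilot runs of the power harness, not by any fit to data:
the designated transition 7→1 carries most of row 7's off-diagonal mass
(0.14) and every other state feeds state 7 with probability 0.09, giving
state 7 a stationary occupancy of ≈ 0.37 so that per-subject estimates of
that entry rest on enough transition counts at T = 220 for planted
multiplicative effects to be detectable in scaled-down cohorts. The
default patient effect multiplies every transition into state 3 by 0.6,
suppressing that state's occupancy in patients. State means are sparse
random ±1 patterns over ~d/3 regions; covariances are identity plus a
rank-one component (condition number ≈ 3).

What the generator does *not* emulate: hemodynamic convolution and its
autocorrelation, scanner drift and motion artifacts, spatial smoothness,
site effects, and emission heterogeneity across subjects. Passing tests
therefore demonstrate correctness of the estimator and calibration of the
inference under the model's own assumptions — not robustness to the ways
real fMRI violates them.

## Validation harness sizes

Chosen as the package's desk-scale defaults: oracle equivalence on 100
random instances (K ≤ 3, T ≤ 8); parameter recovery over 10 seeds of a
3-state, 8-region, 20-subject design (transition entries within 0.05
absolute, state means within 10% relative L2 after Hungarian matching);
order selection on the same design over K ∈ {2…6}; t-test type-I error
over 500 null replicates of two 1000-subject groups (rate pooled over
states, whose Monte-Carlo standard error ~0.005 supports the [0.04, 0.06]
band; single-state rates at 500 replicates have SE ~0.01 and are reported
but not individually banded); permutation calibration over 200 null
cohorts at 999 permutations (rate pooled over the 16 matrix entries, same
reasoning); 20 end-to-end no-effect pipeline runs (4 states, 10 regions,
12+12 subjects, pooled FDR family); and 50 power replicates of the 1.6×
planted effect at generator scale 0.3 with dynamics computed from the
true simulated paths, so that the power of the statistical layer is
measured separately from decoding fidelity.

## Numerical and degenerate-input conventions

Zero-probability transitions are handled in linear space (no log(0)
pathologies); all tie-breaks go to the lower state index; standardization
requires nonzero per-region variance and errors otherwise, naming the
region; band-pass filtering uses a zero-phase order-4 Butterworth design
(no phase distortion of state timing) and refuses bands at or above
Nyquist; empty ROIs in volume extraction yield NaN rows with a warning;
permutation p values are floored at 1/(n+1); loaders reject non-finite
cells, naming the file and position. Matrix round-trips are bit-identical
(17 significant digits on write, round-trip float parsing on read).

## Known limitations

Geometric dwell times and shared emission parameters are model
assumptions, not findings; ML-EM provides no model-evidence bound, so
order selection rests on BIC's asymptotics; the permutation test's
add-one smoothing makes its minimum attainable p equal to 1/(n+1); the
generator's group effects act only on transitions (not on emission
parameters); and network-level summaries require a user-supplied
region-to-network lookup, since no atlas mapping ships with the package.
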