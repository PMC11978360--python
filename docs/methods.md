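# Methods

`midpipe` implements a pipeline for asking whether the spiking activity of a
recorded neural population during delay (inter-trial) periods carries
information about a binary behavioral variable — e.g. whether the animal's
previous maze run turned left or right — and, when it does, *which neurons*
and *which moments in time* carry it. The pipeline was designed for
hippocampal tetrode recordings with few trials (8–20), long delays
(20–60 s) and low firing rates, where the informative signal is expected to
be sparse in both neurons and time.

## Population vectors

Spikes of the N simultaneously recorded units are counted in bins of width
L (default 0.1 s) restricted to the delay windows; each bin inherits its
trial's label l_t ∈ {−1 (left), +1 (right)}. Units with no delay-period
spikes are removed. Counts are z-scored per unit over all delay bins of the
session (population 1/T variance convention), yielding standardized
population vectors x_t ∈ R^N.

Choices the data do not dictate:

* the bin grid is anchored at each delay-window start and a trailing
  partial bin is discarded, keeping within-trial bin indices comparable
  across trials;
* spikes on a bin edge belong to the later bin (half-open intervals);
* standardization statistics are computed over delay bins only, and
  constant columns (undefined z-score) are dropped with a warning.

## Decoding

The classifier is a bias-free linear two-node softmax network
O = σ(W x), W ∈ R^{2×N}, trained by full-batch gradient descent on the
cross-entropy loss (default 1000 epochs, learning rate 0.001, small uniform
seeded initialization, no regularization, no early stopping). Because the
two rows of the cross-entropy gradient are exact negatives, these dynamics
reduce analytically to logistic regression on the row difference
u = W_1 − W_0 with doubled learning rate; the implementation exploits this
to train all (split × shuffle) classifiers of a cross-validation run in a
single batched loop. The reduction is exact, not an approximation.

Performance is the correct classification rate (CCR): the mean test-set
accuracy over 100 stratified random half/half splits (class ratio preserved
to within one pattern; odd counts favor the training half). The per-bin
prediction score (PS) is the fraction of splits in which that bin, while
held out, was classified correctly; bins never sampled into a test fold
have undefined (NaN) PS rather than zero.

Significance comes from a label-permutation null: labels are shuffled
uniformly (default 1000 times, at the bin level; a trial-blocked variant is
available because bins within a trial share a label and are
autocorrelated), the full cross-validated CCR is recomputed per shuffle,
and p is the fraction of null CCRs ≥ the observed CCR. The add-one
convention (r+1)/(n+1) is reported alongside the raw percentile.

## Boundary sampling by adversarial attacks

To expose which directions in pattern space the classifier actually uses,
its decision boundary is sampled with the fast gradient sign method (FGSM):
a pattern is perturbed along the elementwise sign of the input gradient of
the loss, with the smallest step ε* that flips the predicted class (found
on a geometric grid over [1e−3, 10] in standardized units, refined by
bisection to 1e−4; already-misclassified patterns keep ε* = 0). Applying
the attack a second time — now escaping the class the first attack reached,
with a tenfold finer refinement — re-crosses the boundary, so the doubly
attacked vector a_t = A(A(x_t)) lies within one (finer) refinement step of
it. The tighter second refinement guarantees the double attack ends closer
to the boundary than the single one.

One classifier's boundary would overfit the sample, so the attack set is
rebuilt over 100 stratified half-subsamples, each with its own retrained
classifier (per-subsample derived seeds). Attack vectors whose softmax
output deviates from 0.5 by more than 0.05 are dropped and logged; all
members of each subsample are attacked.

## Most informative directions

At each attack vector the local boundary normal is estimated from the
difference vectors d_k to neighboring attack points of the same subsample:
the unit vector n minimizing Σ_k (n·d_k)², i.e. the eigenvector of
Σ_k d_k d_kᵀ with the smallest eigenvalue. Neighbors are taken from a
ring (0.02–0.35 of the anchor's maximum distance to other points,
Euclidean). Two robustness refinements matter in practice:

* neighborhoods are formed over *distinct* attack-vector positions —
  sparse integer counts produce many duplicated patterns, hence duplicated
  attack vectors, which add no geometric information but would leave the
  neighbor scatter rank-deficient;
* when the ring holds fewer distinct points than needed to span the local
  tangent space (pairwise distances concentrate in high dimension once
  class separation is weak), the neighborhood grows with the nearest
  distinct points beyond the inner radius until the scatter's
  second-smallest eigenvalue separates from zero. Without this the
  estimator returns arbitrary vectors from the scatter's null space.

Normals are oriented to point into the +1 hemispace, operationalized
classifier-consistently: n is flipped unless the softmax probability of
class +1 increases along +n. This also merges antipodal duplicates before
clustering. Flipping all labels therefore flips every normal exactly.

Normals are clustered per subsample with DBSCAN (Euclidean, eps = 0.25,
min_samples = 3% of the subsample's normals, floored at 2); each cluster
contributes a representative (renormalized member mean), the fraction of
the subsample's normals it absorbed, and a bias vector (centroid of the
member attack vectors). A second DBSCAN with the same parameters over all
per-subsample representatives matches clusters across subsamples; isolated
representatives are retained as singleton candidates rather than discarded,
so weakly separated data still yields a ranked list. Each final cluster —a
most informative direction (MID) — carries an *amount* α(c) (mean over all
subsamples of the fraction of normals assigned to it; absent subsamples
contribute zero, so Σ_c α(c) ≤ 1) and a *consistency* χ(c) (fraction of
subsamples in which it was found). The bias b(c) is kept per cluster (one
centroid), not per time bin; a per-bin variant was considered and rejected
because a single cluster centroid is what the overlap correction needs.

## Relevant time bins

The bias-corrected overlap of a bin with a MID is q_t(c) = n(c)·(x_t −
b(c)). Its null distribution comes from shuffling the neuron indices of
x_t — each bin draws its own fresh set of uniform permutations (default
1000) — which preserves the bin's value multiset and therefore asks
specifically whether the *identity* of the active neurons matters. Bins
with q above the 97.5th (below the 2.5th) percentile (linear interpolation)
are flagged as predictive of right (left). No multiple-testing correction
is applied across bins; the 5% two-sided rate is the calibrated null
property the tests verify. Downstream statistics compare firing rates
(counts/L in Hz, from raw counts), fractions of active cells, and
prediction scores between relevant and non-relevant bins (Mann–Whitney U;
Wilcoxon signed rank of PS − 0.5), and histogram the relevant bins across
the delay period with a chi-squared uniformity test.

## Session-level statistics

Groups of sessions are compared by their fractions of significant
permutation tests: a Pearson chi-squared homogeneity test on the 2×2
significant/total table *without* continuity correction (required to
reproduce the reference values 1.723, 0.326 and 2.571 from the printed
4/18 vs 1/16, 6/28 vs 4/26 and 6/18 vs 2/18 fractions), and an exact
one-sided binomial test of each group's count against the nominal 5% rate.

## LFP band power and the PS screen

Band power (theta 6–11, slow gamma 30–50, mid gamma 55–90, fast gamma
95–140, ripple 150–250 Hz) is the mean squared Hilbert amplitude per bin of
the zero-phase (forward–backward) Hamming-window FIR bandpass output, in dB
re 1. The filter length is set from a transition width of one third of the
lower band edge, with the −6 dB cutoffs pushed half a transition width
outside the nominal band; this keeps passband ripple under 1 dB across the
band and stopband attenuation above 40 dB by 1.5× the edges. (An order
proportional to fs/lower-edge alone leaves the transition wider than the
theta band and cannot meet both constraints.) Zero-power bins are floored
at −120 dB and flagged. The screen is an OLS fit of the z-scored PS on the
five band powers plus optional speed and label regressors, with the overall
F-test and per-coefficient t-tests from statsmodels; rank-deficient designs
raise instead of silently pseudo-inverting.

## Synthetic validation data

Two generators define the study conditions every claim is tested under:

* **Linear task** — x_t = l_t (d/2) w + ξ, ξ ~ N(0, I_n), with w a unit
  vector with round(s·n) equal nonzero entries (s defaults to 1/n, one
  active dimension); labels exactly balanced, odd T favoring +1. d ranges
  0–10, n 2–100 in the validated regimes.
* **Spiking task** — counts Poisson(λ) per neuron per unit-width bin
  (λ 0.05–0.2), balanced random labels; a binary weight vector with
  round(s·n) ones (s 10–30%) added to a uniformly chosen subset of
  round((1−p_fail)·T⁺) positive-label bins, indices recorded as ground
  truth.
* **Sessions** — full spike-time sessions (trials, non-overlapping delay
  windows, balanced labels, optional sinusoid-plus-noise LFP) whose
  per-bin counts follow the spiking model; spike times are placed uniformly
  inside their bin (keeping 1% of the bin width clear of the edges so
  binning and microsecond-precision file round trips are exact inverses).

What the generators deliberately do not emulate: refractoriness, bursting,
theta modulation, place/time fields, rate drift across trials, or
correlated noise between neurons. Passing tests therefore demonstrate that
the machinery recovers planted structure under Poisson/Gaussian
assumptions, not that real hippocampal sessions contain such structure.

## Problem sizes and numerical choices in the validation suite

The validation suite scales the published defaults down to the sizes at
which the tested properties are already stable; these are the package's
chosen study conditions for its own regression tests:

* null calibration: 50 datasets (n=20, T=1000, d=0), 100 shuffles × 20
  splits, 50 training epochs — for chance-level data the permutation
  p value is uniform under any fixed training length, so a short schedule
  suffices;
* ground-truth recovery: n=50, T=400, 20 subsamples, 300 epochs, 20 seeds
  per separation d ∈ {0.5, 1, 2, 4, 6, 8};
* planted-bin recovery: n=30, T=1000, s=0.2, p_fail=0.5, 20 subsamples,
  600 epochs, 200 relevance shuffles, 20 seeds per λ ∈ {0.05, 0.1, 0.2};
* eigen-estimator optimality: 50 random instances vs 10⁶ random unit
  directions each.

Degenerate inputs are refused loudly: empty sessions, all-inactive units,
single-class training sets, constant columns, empty attack clouds, fewer
than 3 neurons for the shuffle null, bands at or above Nyquist,
rank-deficient regression designs. Ties in the softmax decision (z = 0)
predict +1; DBSCAN noise points simply do not join any MID; an all-noise
clustering returns an empty MID set rather than an error.

## Known limitations

* The local-normal estimator assumes the attack cloud samples a smooth
  hypersurface; with a purely linear classifier per subsample the
  "non-linearity" the MID set can express lives entirely in the variation
  across subsamples.
* Bin-level label shuffling ignores within-trial autocorrelation; the
  trial-blocked option is more conservative and is the right default when
  bins per trial are many and trials few, but bin-level is kept as the
  default for comparability.
* The amount/consistency scores depend on the DBSCAN radius (0.25 on unit
  vectors ≈ 14° half-angle); very diffuse boundaries fragment into many
  low-α singletons, which is informative in itself but makes "the top MID"
  a noisy notion there.
* Percentile flags are not corrected for multiple comparisons across bins
  or clusters; interpret flag *rates* against the calibrated 5% null.
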