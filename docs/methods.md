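# Methods

This note documents the models, estimators, default parameters and design
choices behind `cemarker`, and what the synthetic validation does and does
not establish about real EEG.

## Cohort selection (extreme-group design)

Input is a table of four already-scored stress items per participant:
neuroticism (five-factor personality model), worries and tension (Perceived
Stress Questionnaire), and STAI trait anxiety. Rows with any missing item
are dropped (and counted). For each item the two-sided confidence interval
of the cohort mean is `mean ± t_{(1+level)/2, n−1}·sd/√n` with `level=0.95`
by default; this is a *parametric bound on the mean*, not a percentile of
the score distribution, so each single bound is exceeded by a large
fraction of the cohort — selectivity comes from requiring exceedance on
**all four items simultaneously**, and strictly. Zero-variance items yield
a degenerate interval that is flagged rather than silently used.

Group balancing reduces the larger extreme group to the size of the smaller
one. Its 4-item vectors are z-scored per item using that group's own
mean/sd (the items live on different scales), all-pair Euclidean distances
are computed, and the size-`k` subset minimizing the within-subset summed
pairwise distance is selected. "Smallest mutual distances" is ambiguous
between sum, max and distance-to-centroid objectives; the sum is the
default and the other two are config options. The search is exhaustive
whenever `C(n,k) ≤ 10^6` (exact optimum); larger instances use greedy
best-first growth from the medoid. Candidate subsets are scanned in
participant-id order so ties resolve deterministically. Demographic
exclusions are expressed through a generic metadata row filter, not
hard-coded.

## Conditional-entropy profiles

All information quantities are computed through the decomposition
`H(X|Y) = H(X) − I(X;Y)`; joint or conditional densities are never
estimated. Defaults:

- **Entropy**: Kozachenko–Leonenko k-NN estimator, `k=4`.
- **Mutual information**: Kraskov–Stögbauer–Grassberger estimator
  (algorithm 1), `k=4`, computed on per-variable standardized copies so the
  Chebyshev ball treats both coordinates comparably (the estimator is
  asymptotically invariant to monotone per-variable rescaling, so this is a
  numerical, not statistical, choice). Small negative estimates under
  independence are legitimate estimator noise and are returned as-is.
- **Tie breaking**: quantized inputs (integer ADC codes, heavily filtered
  data) can contain exact duplicates, which k-NN estimators cannot handle;
  a deterministic jitter of `1e-10 × sd` is added, seeded from the byte
  content of the array itself so that `I(x,y) == I(y,x)` exactly and
  repeated calls are reproducible.
- **Units**: nats by default; bits divide by `ln 2`.
- **Gaussian alternative**: `method="gaussian"` switches every estimate to
  the closed forms `H = ½ ln(2πe σ̂²)`, `I = −½ ln(1−ρ̂²)`; these also serve
  as the oracles the non-parametric defaults are tested against (agreement
  within 0.05 nats for H and I, 0.07 for their difference, at n=5000 over
  ρ ∈ {0, .3, .6, .9} and σ ∈ {.5, 1, 2}).
- **Cost control**: recordings longer than `max_samples` (default 15 000)
  are evenly strided down with a seeded phase before estimation; each
  profile costs `C(C−1)/2` pairwise estimates at `O(n log n)` each.

The per-channel summary of an `N`-channel recording is
`CE(c_i) = mean_{j≠i} H(c_i|c_j)`. The divisor is the number of summed
terms (`N−1`), i.e. a true average. A constant-factor alternative (dividing
by `N`) rescales every profile by the same factor; both the Pearson-based
RSA and the KNN distance ranks are invariant to a common rescaling, so the
choice cannot affect any downstream result — the true mean is used because
the quantity is described as an average.

### Surrogate significance

The null for "channels X and Y share no information" is built by shuffling
Y's samples (marginals preserved, dependence destroyed), re-estimating MI,
and repeating `n_surrogates` times (default 100);
`p = (1 + #{I_surr ≥ I_obs}) / (n_surrogates + 1)` (add-one estimator, so p
is never zero; the smallest attainable value with 100 surrogates is 1/101).
Shuffling destroys serial correlation as well as cross-correlation, so for
strongly autocorrelated signals the test is anti-conservative for the
hypothesis "no dependence between the *processes*"; it is used here as the
standard toolbox check that a non-zero estimate is not a small-sample
artifact. Per-channel aggregate significance of a profile entry is the
median of that channel's pairwise p-values; non-significant pairwise terms
are *not* zeroed by default (a config switch exists). At profile scale each
pair would need `n_surrogates` full re-estimates, so the pipeline's default
estimator config disables surrogates; calibration (≈5% of independent pairs
below p = 0.05) is verified at pair scale in the test suite.

## RSA and classification

RSA represents each participant by their CE vector and uses the Pearson
correlation between vectors as similarity, with the exact t-transform
two-sided p-value (`df = C−2`, `C` the number of channels — so df follows
the montage, including reduced montages). Blocks are summarized by
mean/sd/median of r and of p for within-HIGH, within-LOW (off-diagonal
pairs) and between (all cross pairs); pairwise p-values are reported as-is,
without multiplicity correction.

Classification is k-nearest-neighbour (Euclidean, `k=3`) under
leave-one-out cross-validation; CE vectors are fed raw (no standardization)
by default, with a switch. `k=3` is the default because it is odd (no
neighbour-vote ties in a binary problem) and small relative to the 19
training points of a 20-participant cohort; `k=1` and `k=5` accuracies are
included in the run report as a sensitivity check.

Permutation importance shuffles one channel's column across participants
(training and test alike), re-runs the leave-one-out evaluation, and
records the accuracy drop; a channel's importance is the mean drop over
`n_repeats` seeded permutations. With ~20 participants a leave-one-out
evaluation moves in steps of 1/n = 0.05, and informative-but-redundant
channels reveal themselves only through occasional single-fold flips, so
the default repeat count is 30 — enough to stabilize the *sign* of small
importances at negligible cost. The across-channel mean importance and its
bootstrap 95% CI (percentile, 2000 resamples over channels) are attached.
Channel reduction keeps either the strictly-positive-importance channels or
the strictly-above-average ones (default), and RSA/KNN are re-run on the
reduced montage.

## Preprocessing

Automatable resting-state preprocessing only: polyphase anti-aliased
downsampling to 250 Hz, per-channel linear detrend, zero-phase 4th-order
Butterworth bandpass 1–45 Hz (`sosfiltfilt`; forward–backward application
gives an effective 8th-order magnitude response with zero phase
distortion), and a final detrend so channels are exactly zero-mean.
Detrending precedes the filter so slow drift does not excite edge
transients. Visual channel/interval screening and ICA-based
ocular/cardiac artifact removal require a human in the loop and are
deliberately represented by an explicit pass-through stage that logs the
omission; synthetic data contains no artifacts to remove. Multi-block
recordings are either concatenated in time after per-block detrending
(default — maximizes samples available to the k-NN estimators) or profiled
per block and averaged (`per-block-mean`).

## Synthetic data: what it emulates

**Questionnaires.** Background participants answer each item with a
truncated normal centred at mid-scale, rounded to integer Likert steps.
The background sd is 7.5% of the scale range (0.3 on a 1–5 scale): wide
enough that the CI bounds are interior to the scale (so strict extremes can
exist), narrow enough that the probability of a background responder
clearing the bound on all four items at once is negligible (~10⁻⁵ per
cohort), which is what makes exact planted-recovery a testable guarantee.
Planted extremes sit one Likert step beyond the background extremes,
clipped to the scale; generation fails explicitly if the scale is too
narrow for the plants to clear the confidence bounds.

**EEG.** Channels are linear mixtures of latent AR(2) sources (coefficients
(0.5, −0.3): stationary, broadband, with non-trivial autocorrelation like
filtered EEG) plus independent channel noise. In the default 16-channel
spec every channel loads 0.4 on one *global* source (the diffuse baseline
dependence volume conduction produces) and 1.2 on one *strong* source:
private to the channel for background channels and for the HIGH group's
discriminative channels, but one *common synchronizing source* for the LOW
group's discriminative channels (Fp2, F4, CPz, O2 — indices 0, 5, 10, 15).
Marginal composition is therefore identical across groups, and each channel
is normalized to unit variance, so amplitude carries no group information:
the planted contrast lives entirely in the shared-information structure
(LOW discriminative pairs: high MI, low CE). Inter-individual variability
comes from an entry-wise coupling jitter (relative sd 0.1) and a
participant-level gain on the non-global sources (relative sd 0.25) — weak
expressors are genuinely borderline cases, which keeps the classification
problem honest (accuracy is high but not structurally perfect, and
single-channel permutation can flip borderline folds, giving informative
channels their positive importance).

Default cohort/problem sizes: 100 background + 10 HIGH + 10 LOW
questionnaires; 16 channels, 20 s at 250 Hz (5000 samples) per participant
— enough for stable k-NN estimates (the estimator floor is 1000 samples)
while a full pipeline run stays under a minute on one CPU. A 53-channel
reference-montage mode exists for larger experiments.

**What passing tests do not show.** The generator produces stationary
Gaussian mixtures: no realistic EEG spectra (alpha peaks, 1/f), no
artifacts (blinks, heartbeat, movement), no volume-conduction head model,
no non-stationarity. Recovery of the planted structure validates the
*pipeline mechanics and estimators*, not the empirical claim that
conditional entropy separates stress groups in real recordings — that
claim can only be tested on real data, and the published analyses it would
rest on involve manual, visual-inspection preprocessing that this package
intentionally does not automate.

## Numerical and degenerate-input policy

- Constant signals are rejected (differential entropy diverges); constant
  questionnaire items give a flagged degenerate CI; zero-variance CE
  vectors abort RSA naming the participant.
- Even `k` in binary KNN triggers a warning; ties resolve to the class
  encountered first in training order.
- A constant channel's permutation importance is exactly zero (permutation
  is a no-op and is short-circuited).
- Balancing with equal group sizes returns both groups unchanged; the
  smaller group is never reduced.
- EDF writing picks the samples-per-record as the largest divisor of the
  sample count within the 61 440-byte record recommendation, so files
  round-trip without padding; amplitudes round-trip within the 16-bit
  quantization of each channel's range.
- All randomness (sources, noise, jitter, permutations, subsampling,
  bootstrap) derives from explicit integer seeds; identical configurations
  reproduce byte-identical outputs.

## Known limitations

- The KSG estimator treats samples as i.i.d.; autocorrelation (real EEG,
  filtered synthetic data) inflates effective dependence and the surrogate
  null ignores it. Block-preserving surrogates would be the next step.
- Only pairwise (bivariate) information quantities are computed; multivariate
  extensions (conditioning on the rest of the montage jointly) are out of
  scope.
- The importance-based channel reduction inherits the instability of
  permutation importance under feature redundancy: redundant informative
  channels can split or mask each other's importance. The 30-repeat default
  mitigates but does not remove this.
- No re-referencing, bad-channel interpolation, or artifact handling;
  inputs are assumed cleaned.
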