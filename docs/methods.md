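# Methods

This note documents the models, numerical choices and limitations behind
`corticode`: what the synthetic cortex simulates, how the LFP features are
computed, how the sparse decoder is trained, and how the study-level
experiments are assembled. Units are microvolts, seconds and Hz throughout;
grid indices are 0-based; time intervals are half-open `[start, end)`.

## The simulated preparation

**Cortical surface.** The site map is a 10 × 10 grid at 400 µm pitch
(4 × 4 mm) with the four corner sites inactive, giving 96 active sites.
The default layout partitions the grid into two core fields (A1, AAF),
four belt fields (PAF, VAF, SRAF, AVAF) and a non-auditory margin, with
region totals 44 / 37 / 15. Within each auditory field the characteristic
frequency (CF) runs log-linearly along the field's tonotopic axis over
1.6–64 kHz (A1 posterior-to-anterior, AAF reversed), with a per-site
Gaussian jitter of 0.1 octaves clipped to less than half the inter-site
octave step so the gradient stays monotone along the axis. Ground-truth
spike peak latencies are drawn per region — core 12 ± 2 ms, belt
22 ± 3 ms — reflecting the shorter latencies of primary fields;
non-auditory sites carry neither CF nor latency.

**Stimuli.** Two protocols are generated. The tone-burst protocol presents
25-ms pips (5 ms rise/fall + 20 ms plateau) over an 18-frequency
(1.6–64 kHz) × 7-level (20–80 dB SPL) grid, each condition repeated
(default 20×) in pseudorandom order at 600-ms onset spacing: 126
conditions, 2 520 events. The long-tone protocol presents 30-s pure tones
at 60 dB SPL in pseudorandom order, each followed by a 30-s silent block,
so a session is `n_events × 60 s` long.

**Spike trains.** Multi-unit activity is an inhomogeneous point process:
homogeneous baseline firing (4 Hz) everywhere, plus, for each tone-burst,
an evoked Poisson count with mean `gain · G(log2(f/CF); 0.5 oct) ·
level_scale · 50 ms` whose spike times start at the site's ground-truth
latency and decay exponentially (8 ms). Peak gain is 60 Hz at CF and
80 dB SPL; `level_scale` rises linearly from 0 at 20 dB to 1 at 80 dB, so
the recovered response threshold sits around 40 dB. Non-auditory sites fire
at baseline only.

**LFP.** The background is per-channel AR(1)-filtered Gaussian noise
(coefficient 0.95, stationary SD 40 µV), a simple 1/f-like process whose
windowed-SD distribution makes burst thresholding well posed. On top of it
the simulator plants the effects the analysis is meant to recover:

* *AEP*: a negative Gaussian-shaped deflection (peak 20 ms post onset,
  width 8 ms, amplitude 150 µV at CF and maximum level) added at
  CF-matched sites after every tone-burst onset. CF matching is a Gaussian
  weight with 0.5-octave SD, comparable to the inter-site CF spacing of
  the simulated gradient.
* *Sustained activity*: during each long tone (0.5–29.5 s post onset,
  with 100-ms cosine ramps) a shared 70-Hz source is added at CF-matched
  sites with amplitude 20 µV × the CF weight. Each coupled site receives a
  slowly varying phase jitter around the shared source (SD 0.4 rad), so
  the expected phase-locking value between two strongly coupled sites is
  approximately `exp(-0.4²) ≈ 0.85` while uncoupled pairs sit at the
  estimation floor.
* *Response variability*: the oscillation amplitude is modulated by a
  slowly varying log-normal gain process (SD 0.3, ~0.5 s correlation time,
  independent per site and event); AEP amplitudes get an analogous
  per-event log-normal gain. Real evoked responses vary strongly both
  across and within trials; without this term every window of a tone event
  shares one amplitude fingerprint, window-level cross-validation can key
  on it, and the frequency-range experiment saturates at ceiling for every
  set — i.e. the phenomenon it probes (confusability of close frequencies)
  would be unreproducible in principle.
* *Burst suppression*: multiplicative amplitude episodes (gain 6×) on a
  random subset of at least `min_sites` channels (default 80), with
  durations uniform on 150–1000 ms and exponential gaps tuned to a target
  occupancy. True episode intervals are kept in `burst_log` so detection
  can be validated against ground truth.

Setting the effect amplitudes to zero yields a null recording on which
every downstream discrimination sits at chance (tested). All randomness
flows through one seeded generator: identical seed and configuration give
bit-identical output.

What the generator does *not* emulate: volume conduction between
neighbouring sites, non-stationary anesthesia depth, 1/f spectra beyond
AR(1), evoked broadband transients in the sustained window, or any
biophysical (conductance-based) dynamics. Passing tests therefore
demonstrate that the pipeline recovers what it assumes — planted
band-limited, CF-organized effects — not that real cortical recordings
would decode at these accuracies.

## Feature extraction

**Burst rejection.** The per-recording threshold is `mean + 3 SD` of the
trailing 100-ms windowed SDs of all channels, pooled over a calibration
segment (default: the first 60 s; the recording start is an arbitrary but
fixed choice, configurable). A time point is *elevated* when more than 24
channels exceed the threshold. Because the trailing window smears a burst
forward by up to its own length, the elevated run is eroded by the window
(a sample belongs to the burst support only if every SD window starting at
it is supra-threshold) before the duration rule discards runs shorter than
150 ms. The duration rule consequently applies to the physical burst
duration; bursts within about one SD window of the 150-ms cutoff can fall
on either side of it (the support estimate loses ~10 ms at the edges).

**Analysis windows.** Sustained activity is read 1–29 s from tone onset
(label *sound*) or tone offset (*spontaneous*): 28 consecutive 1000-ms
periods per alignment, with the analysis window of 200/400/600/800/1000 ms
starting at each period's beginning. A period is discarded if any sample
overlaps the burst mask — the strictest reading of burst elimination.
When a fixed per-label sample count is requested, surviving windows are
subsampled without replacement with a seeded generator.

**Filtering, power, PLV.** Band-pass filtering is a 4th-order Butterworth
applied forward–backward (`sosfiltfilt`), so it is zero-phase — a
prerequisite for meaningful phase comparison. Band power is the RMS of the
filtered signal over the window. For PLV, filtering and the Hilbert
transform are applied to the window padded with 200 ms of contiguous
recording on each side and then cropped, which keeps filter and
analytic-signal edge transients out of the phase estimate; all 4 560 site
pairs of a window are computed at once as `|Z Zᴴ|/T` with
`Z = e^{iθ}`. The standalone `plv()` on bare windows has no context to pad
with and carries edge effects of order 10⁻² on a filtered pure sinusoid;
the pipeline path is the accurate one.

**AEP.** P1 is `|min|` of the single-trial LFP over the 50 ms after a
tone-burst onset (half-open `(onset, onset+50 ms]`); the spontaneous
reference is the matching pre-onset minimum.

## Site characterization

The evoked rate for one tone is the mean firing rate 5–55 ms post onset
minus the mean rate 1–600 ms (it may be negative); per-condition means are
clipped at zero and normalized by the grid maximum to form the frequency
response area. CF is the argmax frequency (lowest on ties) at the
threshold intensity — the lowest level whose maximal normalized response
reaches 0.3. Two guards reject pure-noise maps, for which normalization is
meaningless: a grid neighbour of the argmax cell must reach 0.15
(contiguity), and the raw peak evoked rate must exceed 15 Hz (with 20
repeats the baseline Poisson noise stays an order of magnitude below this
floor, while true responses at CF reach ~55 Hz). Peak latency is the
argmax bin of a 1-ms PSTH from maximum-level tones at CF.

Region labels: sites without a clear CF are non-auditory; the rest are
split into core (short latency) and belt at the latency threshold that
maximizes the between-class variance of the latency distribution, scanned
over midpoints of consecutive sorted values. The across-site *median* was
considered and rejected: with unequal group sizes it lands inside the
larger mode (e.g. 60 sites at 8 ms and 36 at 20 ms put the median at 8 ms)
and misclassifies systematically, whereas the variance-maximizing cut
separates well-separated modes exactly. The five belt subfields are
collapsed to one label; subfield geometry, when needed, comes from the
generator's layout. A tonotopic-gradient consistency score is not used.

## The sparse decoder

`SparseLogisticRegression` is a softmax classifier with one weight vector
per class and an independent zero-mean Gaussian prior per weight whose
precision α is re-estimated from the data (ARD). Training alternates:

1. **MAP step** — L-BFGS on the penalized multinomial log-likelihood over
   the currently active weights, warm-started, preconditioned by the
   estimated diagonal curvature (prior precision + the softmax curvature
   bound ¼Σφ²) so the spread of per-direction curvatures stays modest.
   Intermediate solves use a loose gradient tolerance; a tight polish runs
   once after the outer loop.
2. **ARD step** — from the Laplace approximation with the *full* posterior
   covariance: its diagonal is taken by direct inversion of the active
   Hessian when the active set is small, and otherwise through a
   sample-space push-through identity that only needs an (n·K)-sized
   solve. A diagonal-curvature approximation was tried first and retained
   an order of magnitude too many noise features. The default rule
   re-estimates retained precisions by effective degrees of freedom
   (α ← γ/w², γ = 1 − α·var) and removes weights by the per-weight
   evidence test: when the weight's optimum of the approximate marginal
   likelihood is an infinite precision (quality² ≤ sparsity, evaluated in
   a cancellation-free combined form), the precision is set to infinity
   and the prune threshold (10⁸) fires. Pruned weights are exactly zero
   and never return. The curvature weights p(1−p) are floored at
   p ∈ [0.01, 0.99] so near-separable fits keep a usable Laplace
   approximation.

Defaults: prune threshold 10⁸, at most 500 MAP/ARD alternations,
convergence when the largest weight change falls below 10⁻⁶. The initial
precision scales with the feature count, `α₀ = max(1, d/4)`: a fixed small
α₀ lets the initial ridge fit absorb the labels outright when d is large
(all 4 560 PLV features then fail the evidence test at the first iteration
and the model collapses to empty), whereas a deliberately strong prior
start approximates the empty-model start of constructive relevance
determination, so the first evidence test ranks features by marginal
signal. Features are z-scored with training-fold statistics
(`standardize=True`); reported coefficients are mapped back to the
original feature scale. The bias is never pruned and keeps a fixed mild
precision (10⁻²), which also conditions the otherwise likelihood-flat
softmax sum direction. Two pure alternative rules remain selectable:
`"evidence"` (precision set to its per-weight optimum; greedier, and once
the fit nears separation it can discard redundant informative features)
and `"variational"` (α ← 1/(w² + var); its precision growth for null
features is additive, so pruning effectively never completes — kept for
comparison only).

Two behaviors worth knowing. With pruning disabled and α fixed, the fit
matches an L2-penalized multinomial logistic regression — for binary
problems, sklearn's single-vector formulation with C = 2/α, since the
penalty splits across the two symmetric class vectors (tested to 10⁻⁴
against an independent optimizer). On label-permuted data the decoder
stays at chance, but the active set is small rather than empty
(~10–17 of 96 features at n ≈ 100–200): a noise-overfitting equilibrium in
which each survivor has spuriously positive conditional evidence is a
fixed point of every evidence-maximizing ARD variant, and no ad hoc
criterion is added to hide it.

Cross-validation is label-stratified (10-fold by default: with 100 samples
per label, each test fold holds 20 samples, 10 per label); accuracies are
percentages of correctly labelled test samples, and each fold records the
features that survived pruning.

## Experiments and statistics

The discrimination experiment decodes *sound* vs *spontaneous* windows per
test frequency for each (band, window length) cell and keeps per-fold
records. Accuracies aggregate folds first, then frequencies. *Informative
sites* are pooled from the most successful discriminations (default: top
20 folds per frequency, ranked by test accuracy with earlier folds winning
ties), irrespective of weight sign or magnitude; a PLV pair contributes
both member sites, and sites keep their multiplicity. CF histograms count
informative sites at the nearest of the 18 standard frequencies (log
scale), tallying CF-less sites separately; the peak is the modal CF. The
contribution rate of region r is `(remaining_r/total_r)` normalized across
the three regions — undefined (raised) when no site remains. Under uniform
random selection of 10 sites from the default map the exact per-region
expectations are 0.349 / 0.344 / 0.307 (core / belt / non-auditory,
enumerable over the hypergeometric support) — near, though not exactly,
the 1/3 reference, because the smallest region's proportion is the most
variable. The frequency-range experiment decodes the four tone frequencies
of each set (6-fold, 1000-ms high-gamma power by default) and tabulates
accuracy against octave span.

Rank statistics: replicate values are compared to chance with a one-sample
Wilcoxon signed-rank test (exact null below n = 20; zero differences
dropped, all-zero giving p = 1), two samples with Mann–Whitney U; the
Bonferroni-adjusted p is `min(1, m·p)` for m comparisons (m = 3 for the
three regional rates).

## Problem sizes used by the test suite

The default generator settings are the full study conditions (e.g. 7–12
long-tone repeats per frequency, 100 samples per label, 20 tone-burst
repeats). The test suite and the acceptance script run deliberately
scaled-down instances of the same pipeline — typically 1–2 long-tone
repeats per frequency, 25–30 samples per label, 4–6 folds, and 10 seeded
replicates for the qualitative trend checks — chosen so the whole suite
runs on a single desktop core in minutes while every planted effect
remains comfortably recoverable at those sizes.

## Known limitations

* The synthetic background is AR(1), not a measured anesthesia spectrum;
  absolute accuracies on synthetic data say nothing about accuracies on
  real recordings, where the paper-scale effects are far subtler.
* The burst-duration rule is applied to an eroded support estimate with
  ~10 ms edge bias (see above).
* ARD feature selection is not a causal localization: noise-overfit
  survivors occur (on permuted labels, and as a minority on real tasks),
  so informative-site summaries should be read as population histograms,
  not site-level claims.
* The evidence-test pruning keeps one representative of a set of strongly
  correlated informative sites rather than the whole set; pooled over
  folds and frequencies the histograms still localize correctly, but
  per-fold active counts are smaller than the number of truly responsive
  sites.
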