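# Methods

This note documents the model, the numerical choices, and what the
synthetic experiments do and do not establish.

## Signal model and feature representation

The package treats a biosignal as a sequence of locally stationary
regimes: within a regime the generating process (mean level, variance,
dominant frequency, waveform shape) is constant at the analysis timescale;
events of interest are the instants where it changes, or the starts of
repeating cycles. All analysis happens at a single user-chosen timescale
set by the window size `w` (in samples): `w` acts like a zoom — windows
much longer than a cycle expose regime structure, windows shorter than a
cycle expose the periodicity itself. The overlap fraction sets the frame
rate; `hop = max(1, round(w·(1 − overlap)))` samples (the product is
pre-rounded at 9 decimals so binary representation noise in the overlap
cannot flip the half-to-even rounding). Each frame is attributed to its
window-centre sample `start + w//2`.

Per window and channel, 22 registry features span four families:
location/scale (mean, median, std, variance, min, max, peak-to-peak, IQR,
RMS, absolute energy), temporal (mean absolute difference, zero crossings,
linear slope, lag-1 autocorrelation), distribution shape (skewness,
kurtosis, differential entropy), and spectral (centroid, spread, median
frequency, maximum-power frequency, spectral entropy, all from the
periodogram of the mean-removed window, in Hz). The registry is a plain
name → function mapping; callers may pass any subset or register their
own.

Two estimator choices matter on short windows and are deliberate:

* **Skewness and kurtosis are computed on the window winsorized at
  mean ± 3 σ.** Plain third/fourth moments on ~50 samples are dominated by
  single extreme samples; one outlier steps the moment rows of every
  window that contains it, which paints a spurious mini-block into the SSM
  and a false novelty peak. Winsorizing bounds the influence of any one
  sample while preserving the bulk shape (e.g. the platykurtic, bimodal
  distribution of an oscillation). Quantile-based shape estimators
  (Bowley/Moors) were considered and rejected: on coarsely sampled
  oscillations their order statistics are sensitive to sampling phase.
* **Entropy uses the Vasicek m-spacing estimator (m = √n) on the
  standardized window**, not a fixed-bin histogram. Histogram estimates
  jump whenever a sample crosses a bin edge — pure estimator noise that,
  again, becomes false SSM structure. The spacing estimator is continuous
  in the data; standardizing first makes it a pure shape descriptor
  (≈1.42 for Gaussian windows, lower for strongly bimodal ones).

Feature rows are z-normalized over the record (zero-variance rows become
all-zero with a warning), then frame columns are scaled to unit norm, so
`SSM = FMᵀ·FM` contains cosine similarities in `[−1, 1]`. Non-finite
feature values (e.g. spectral features of an exactly flat window) are
replaced by 0 with a warning to keep the product defined. All-zero frames
yield zero SSM rows/columns, including a zero diagonal entry — documented
rather than special-cased.

## Novelty function

The checkerboard kernel has half-size `L` (total `D = 2L+1`, centre row
and column zero) and taper `exp(−(a²+b²)/(2L²σ²))`; σ is dimensionless
relative to `L` (default 0.5) so the same value gives the same relative
weighting at any size, and the kernel is normalized by Σ|K| so curve
amplitudes are comparable across sizes. The default `L` scales with the
matrix (`D ≈ 0.2·m`) when not given.

The correlation of the kernel along the diagonal is computed with
zero-padding, so the curve is defined for all `m` frames; the exact
correlation values are kept (`raw`). For peak picking the curve is
post-processed:

1. **Smoothing** (centred moving average, default length `L//2`). A true
   block transition is smeared over `w/hop` frames by the window overlap
   and produces a peak roughly `2L` wide; residual estimator noise in the
   SSM produces much narrower bumps. Averaging at half the kernel
   half-size attenuates the narrow bumps with little effect on genuine
   peaks. (Smoothing the *feature rows* instead was tried and rejected:
   it widens noise excursions to kernel scale and makes them *more*
   peak-like.)
2. **Border exclusion.** Within `L (+ smoothing margin)` frames of either
   end the kernel overlaps the zero padding, which looks exactly like a
   block transition; those values are pinned to the interior minimum so
   border artifacts can never become peaks.
3. **Min-max normalization** to `[0, 1]` (an all-constant curve maps to
   zeros), so height thresholds are per-record fractions.

Candidate events are strict interior local maxima; the selection strategy
is a height threshold θ (default 0.3), a fixed count (`top_n` — the choice
when the number of events is known, e.g. a record with a known number of
cycles), or the top fraction of candidates. Peaks closer than
`min_separation` frames are thinned greedily, keeping the higher peak
(ties to the earlier frame). The pipeline default is
`min_separation = D`: two change points closer than the kernel width are
not resolvable at this timescale, and transition shoulders within one
kernel width of a genuine peak are duplicates by construction.

## Periodic search and similarity profiles

The similarity function is the raw column sum of the SSM (no division by
`m`); an optional centred moving average (default off; `w/hop` is a
sensible length when used) suppresses frame-rate ripple. Valley picking
negates and min-max normalizes the curve and reuses the peak machinery.

One structural caveat: most registry features are invariant under time
reversal, so for a *symmetric* waveform such as a sine the peak-centred
and trough-centred windows are equally unusual, and the similarity
function dips twice per cycle — valley spacing is half the period. For
asymmetric cycles (pulse- or spike-shaped, i.e. the ABP/ECG morphology
this search targets), the dip is unique and valley spacing recovers the
period exactly. The package's period-recovery experiment therefore uses
the spike-train fixture; the sine half-period behaviour is asserted in the
unit tests as a property, not a defect.

Frames ranked by ascending similarity-function value are exposed as an
anomaly ordering (`anomaly_ranking`) without any detection threshold
attached, as ranking-only output.

A segment's similarity profile is the mean over its SSM rows (rows and
columns are equivalent by symmetry). Profiles are compared un-normalized
by Euclidean distance (optional z-scoring behind a flag), and clustered
agglomeratively; average linkage (UPGMA) is the default, with complete and
single available. Flat labels come from a cluster count `k` or a distance
cut, renumbered by first appearance so they are deterministic.

## Evaluation

Matching is greedy in ground-truth order: each truth event takes the
nearest still-unassigned detection within `± tolerance` samples (distance
ties to the earlier detection); leftover detections are FPs, unmatched
truth events FNs. The greedy scheme equals exhaustive assignment whenever
tolerance zones do not overlap (property-tested); with overlapping zones
it is deterministic and documented. The default tolerance is `w` samples
on either side of the truth event — the window size is the spatial
resolution of the frame domain, and the zone half-width is exposed as a
flag. Precision, recall and F1 use the 0/0 → 0 convention; macro-F1 is
the unweighted mean of unrounded per-dataset F1 values, rounded only for
display.

## Synthetic fixtures: what they emulate, what they do not

`make_piecewise_signal` concatenates regimes of
`amplitude·sin(2πft) + N(mean, std²)` (sine phase continuous on the global
time axis); boundaries are the ground truth. The standard four-regime
scenario (`default_piecewise_regimes`) alternates rest
(`N(0, 0.5²)`), a strong 5 Hz oscillation, a 4σ level shift, and a 15 Hz
oscillation (frequency ratio 3) — activity-like transitions that move
location, scale, spectrum and distribution shape together, which is what
makes real activity switches conspicuous in feature space. Signals whose
regimes differ in a *single* property (e.g. only the mean) leave most
feature rows carrying pure estimator noise, the SSM correspondingly
noisier, and occasional genuine local excursions of the noise process
(e.g. a 50-sample stretch with skewed samples) are then flagged — the
detector is faithfully reporting a property change that the ground truth
does not list. Passing recovery tests on the standard fixture therefore
demonstrates correct mechanics and calibration under multi-feature
contrast, not performance on minimally contrasting regimes, on real
sensor artifacts, or on autocorrelated noise.

`make_periodic_signal` tiles an exact template (sine, Gaussian pulse,
spike train) with optional white noise; `add_noise_at_snr` rescales a
noise waveform (white, 0.3 Hz wander surrogate, or Hann-enveloped burst)
so the in-interval signal-to-noise power ratio equals the requested dB
exactly, and appends the episode boundaries to the ground truth. No
physiological waveform morphology (PQRS complexes, respiratory coupling)
is modelled.

All generators consume a single integer seed through one
`numpy.random.Generator`; identical arguments give bit-identical records.

## Problem sizes and defaults used in the shipped experiments

Segmentation recovery: 20 seeds × 2000 samples (4×500) at 100 Hz, `w=50`,
95 % overlap (hop 2, m=976), `L=20`, σ=0.5, θ=0.3, `min_sep=D=41`,
tolerance `w` — F1 = 1.0 on every seed. Period recovery: 10 seeds of 10 ×
100-sample spike-train cycles, `w=10`, 95 % overlap (hop 1), smoothing 10,
`top_n=10` — median valley spacing exactly the period. Clustering: ABA and
ABAB fixtures (400-sample regimes, `w=50`, 90 % overlap), `k` = number of
distinct regimes — exact grouping on all seeds. These sizes keep the whole
suite and the acceptance script around a minute each while leaving the
matrices large enough (≈10⁶ entries) to exercise the full pipeline.

## Known limitations

* O(m²) memory and time for the SSM: maximize overlap only when the
  record is short, or downsample via a lower overlap first.
* Single timescale per run; hierarchical multi-scale search is out of
  scope.
* Threshold choice remains per-record; the count-based strategy is the
  robust option when the number of events is known.
* The anomaly use of the similarity function is exposed as a ranking only
  and has not been validated here.
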