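# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic data can and cannot show.

## Synthetic EEG generator

**Block design.** Each session alternates SPN blocks with task blocks,
starting and ending with SPN: the defaults give 9 SPN + 8 MEC (session 1)
and 9 SPN + 8 MER (session 2), 30-s task blocks, 250 Hz sampling, 28
channels.  SPN duration is only constrained to be "about half" a task
block in the study design; the default is 15 s, configurable.  Transitions
are instantaneous and inter-block gaps default to 0 s: windows that would
straddle a boundary are discarded downstream, so modelling fade-outs would
not change any feature.

**Signal model.** The generator is power-spectrum-level, not
waveform-level.  Each channel in each block is the sum of

* 1/f^β Gaussian background (β = 1 by default, 10 µV rms, high-passed at
  0.5 Hz so the variance integral converges), and
* band-limited Gaussian oscillations — flat in-band spectrum — for theta
  (3–7 Hz) and alpha (8–12 Hz), baseline 4 µV rms, scaled per condition
  and scalp region by the *spectral signature*.

Fourier coefficients are drawn with variance proportional to the target
PSD rather than renormalising each realisation to an exact rms.  This
matters: exact-rms scaling ties per-Hz levels to the synthesis grid, so
blocks of different duration (SPN vs task) would differ systematically in
band power and every downstream two-sample test would be miscalibrated.
With analytic scaling, expected band power is duration-invariant; the
measured null false-alarm rate of the screening test is ≈ α.

**Default signature.** The study constrains only the workload contrast:
frontal alpha and frontal+parietal theta are elevated during the mental
tasks relative to navigation.  Separating MER from MEC additionally
requires the two tasks to differ; the defaults make calculation
theta-dominant and reading alpha-dominant over the same topography:

| condition | frontal | parietal | central |
|---|---|---|---|
| SPN | baseline | baseline | baseline |
| MEC | θ ×2.4, α ×1.7 | θ ×2.0, α ×1.5 | θ ×1.5 |
| MER | θ ×1.6, α ×2.4 | θ ×1.4, α ×2.0 | — |

(amplitude multipliers on the baseline oscillation; power scales with the
square).  `default_signature(effect_scale)` interpolates the elevation
above baseline; `null_signature()` removes all condition dependence.
These effects are deliberately large — they make the synthetic subject
close to perfectly decodable, which is the right regime for validating
the machinery (the informative tests are chance behaviour on null data,
band selection, and topography recovery, not the absolute accuracy).

**Artifacts.** Optional ocular (<6 Hz) and muscle (>20 Hz) sources are
added to chosen channels; with `condition_correlated=True` their
amplitude doubles during task blocks, which is the failure mode the
channel screen exists to catch.

**Randomness.** Every draw derives from one integer seed via
`SeedSequence([seed, session, block, channel, component])`; block
boundaries depend only on the design, never the seed.

## Channel screening

Per channel and band (low: ocular proxy, high: muscle proxy, defaults
0.5–6 Hz and 20–40 Hz), per-block mean log₁₀ band power of SPN blocks is
compared with MER+MEC blocks by Wilcoxon rank-sum at α = 0.05, without
multiplicity correction; a channel significant in either band is
discarded.  Two deliberate choices:

* **Equal-length segments.** Band power is estimated over the leading
  `min(block duration)` seconds of every block.  SPN blocks are half as
  long as task blocks; whole-block estimates would have
  condition-dependent variance and inflate the rank-sum false-alarm rate
  roughly four-fold under the null.
* **Pipeline band edges.** In the end-to-end pipeline the ocular band is
  narrowed to 0.5–2.5 Hz.  A 0.5–6 Hz screen overlaps the physiological
  theta band (3–7 Hz): with a genuine theta workload effect it flags the
  modulated channels as "artifacts", which contradicts how such screens
  behave in practice (studies retain almost all channels while still
  finding strong 3–7 Hz workload contrasts).  Blink energy concentrates
  well below 3 Hz, so the narrowed band keeps full sensitivity to
  workload-correlated ocular sources (measured: 8/8 injected artifacts
  detected, clean-channel flags at the α level).  The 2.5 Hz edge leaves
  one 1-Hz-resolution Welch bin of margin below the 3 Hz theta edge.

A variance pre-check (channel variance > 25× the median channel variance)
stands in for manual inspection of grossly broken channels.

## Features

Windows of 2 or 5 s advance every 200 ms (5 decisions/s) and never cross
block boundaries; a block of duration D yields ⌊(D−W)/0.2⌋+1 windows.
Per window and channel, PSD is estimated by Welch's method with 1-s
Hamming sub-windows at 50% overlap (1 Hz bins — stable at these window
lengths), restricted to the candidate band (bins with low ≤ f ≤ high) and
log₁₀-transformed.  Features are per-bin by default (channel-major); an
aggregate mean-band-power-per-channel option exists.  The `F#`-style
channel groups expand by label prefix over the 28-channel montage, with
`F#` excluding Fp1/Fp2 (the montage lists Fp separately and no `Fp#`
group exists); the four subsets expand to 16, 24, 26 and 18 channels.

The 64-point grid varies only the channel subset and band on top of
(window length × spatial filter), so the feature cache computes the
full-montage window PSD once per (window, filter) pair and grid
evaluation is a slice.

## Classifiers

* **LDA**: pooled covariance with Ledoit-Wolf shrinkage toward the
  diagonal (`lsqr` solver) — small inner folds can have window counts
  near the feature dimension.  Priors are uniform, not empirical: class
  window counts track block durations (scheme-2 training is ~2:1 HW:LW),
  and a decoder that exploits that imbalance would sit above 1/k on data
  with no signal.  With uniform priors chance is 1/k for any test
  composition.
* **RBF-SVM**: C = 0.6, γ = 1/(n_features · var) ("scale").  libsvm's
  decomposition is already one-against-one (k(k−1)/2 binary machines);
  the per-pair decision values are re-aggregated so that majority-vote
  ties break on the largest summed absolute margin, then on class order.
  Features are z-scored with training-fold statistics (RBF kernels are
  scale-sensitive); LDA sees raw log powers (affine-invariant).

Even with uniform priors, null-data scheme-2 accuracy sits slightly above
1/2 (≈0.55–0.58 in 20-seed runs): the majority class's mean is estimated
more precisely, so high-dimensional noise fits lean toward it.  This is a
property of the estimator, not leakage; it stays well inside the binomial
95% band over held-out blocks, which is how the calibration tests bound
it (blocks, not the heavily overlapping windows, are the independent
unit).

## Cross-validation

Both schemes split strictly by block.  Holdouts are seeded uniform draws
without replacement, stratified by class; scheme-1 repetitions take
successive elements of one seeded permutation per class, so the 7 default
repetitions have disjoint holdouts.  Inner selection maximises mean
window accuracy over folds; ties go to the first grid point in canonical
order (subset, filter, band, window).  The winner is refit on the entire
inner pool and scored on the holdout (accuracy, MCC, confusion matrix).

Scheme 2's stated fold structure (16 LW + 14 HW blocks, 11 folds, each
testing 2 LW + 2 HW) cannot tile the pool with disjoint test sets
(11 × 4 > 34), so folds are 11 seeded draws with coverage balancing:
blocks tested least often are drawn first, guaranteeing every pool block
is tested at least once.  The construction is recorded in the emitted
report.

`assert_no_window_leakage` re-checks at fit time that no training window
originates from a test or holdout block and raises `LeakageError`
otherwise.

## Workload contrasts

Per channel and band (theta 3–7 Hz — the methods-style definition, not
the 3–6 Hz variant — and alpha 8–12 Hz), each task block is paired with
the SPN block immediately preceding it in its session (16 pairs at the
default design), and the paired log-power differences enter a Wilcoxon
signed-rank test (α = 0.001; refused below 6 pairs).  The reported
statistic is the signed-rank sum T₊ − T₋, which carries the effect
direction; scipy's two-sided statistic min(T₊, T₋) does not.

## I/O

Recordings round-trip through CSV (rows = samples, header = labels, 17
significant digits — bit-exact for float64) with a JSON sidecar holding
sampling rate, labels and 0-based half-open block intervals.  Reports are
emitted as JSON (schema-versioned) plus TSV tables; a pipeline rerun with
the same config is byte-identical.

## Problem sizes

The test suite and acceptance script run the full block counts throughout
but shorten blocks to 10 s task / 5 s SPN with 2-s windows for
Monte-Carlo runs (20 seeds for null calibration and signal recovery), and
run the full-scale 30 s / 15 s subject with a 16-point sub-grid (both
candidate subsets and filters, all four bands, 5-s window) for the
headline decoding numbers.  These sizes keep a complete run on one CPU in
the minutes range while preserving every structural property of the
design (fold arithmetic, window overlap, class imbalance).

## Limitations

The generator reproduces spectra, not waveforms: no evoked transients, no
eye-movement or EMG biophysics, no nonstationarity within blocks, no
inter-subject variability, no volume-conduction correlation structure
between channels (channels are independent given the signature).
Passing tests therefore validate the pipeline's statistics and split
hygiene, not decoding performance on real EEG — real accuracies will be
far from the synthetic subject's near-perfect values.  The screening
test's band edges are a design choice with a documented trade-off; with
recordings whose artifact spectrum genuinely overlaps the decoding bands
the screen cannot separate artifact from physiology.
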