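# Methods

This note documents the models and procedures implemented in `hfovar`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open. No empirical claim here goes beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## Signal model and detection

The detector treats each channel as stationary background activity plus
rare, brief oscillatory events. After decimation to a common 5 kHz rate
(anti-aliased, integer factors only; recordings acquired at non-multiple
rates such as 4096 Hz are used as acquired) and a common average reference,
the per-channel pipeline is:

1. zero-phase FIR bandpass (80–500 Hz; fast-ripple variant 200–500 Hz),
   transition width 10 % of the lower band edge, applied by centered
   convolution with a symmetric kernel;
2. rectification and a sliding RMS envelope (`rms_window_ms = 3`);
3. threshold at background mean + 5 SD of the envelope
   (`threshold_sd = 5`), runs ≥ 6 ms kept (`min_duration_ms`), runs closer
   than 10 ms merged (`merge_gap_ms`);
4. a peak criterion: ≥ 6 local maxima of the rectified signal above
   background mean + 3 SD (`min_peaks`, `peak_threshold_sd`).

Background statistics are computed over the containing analysis window
(`background_window_s = 600`) and recomputed once with detected event
samples excluded, so dense events do not inflate their own threshold. All
thresholds live in `DetectorParams` and are recorded in the run manifest.

**Artifact redaction.** Three detectors produce redaction intervals:
*fast transients* — RMS power in a band above the HFO range (850 Hz to
Nyquist at 5 kHz) exceeding its own mean + 5 SD, padded by 100 ms to cover
bandpass ringing; skipped with a warning when the sampling rate cannot
support the band, in which case the other two rules carry the redaction;
*non-focal events* — times when candidate oscillations are active
simultaneously on more than half of all channels (physiological HFOs are
focal; a "detection" on most of the montage at once is an artifact);
*data-quality gaps* — NaN runs and flatlines ≥ 0.5 s. Candidates with any
positive-length overlap with an applicable interval are dropped;
channel-specific artifacts redact only their channel, non-focal ones all
channels. Artifact detection runs on the signal *as acquired* rather than
after re-referencing: a transient hitting all channels equally cancels
exactly under the common average reference and would otherwise be
invisible, while the oscillation detector still sees its per-channel
residue. The artifact rules are reconstructions of the published behaviour
(the detector family is described functionally, not as formulas) and are
flagged as such; their thresholds are exposed in `ArtifactParams`.

## Epoching and rates

Interictal time excludes a closed 30-minute margin around every seizure
("more than 30 min" is read strictly, so data at exactly the margin
boundary is excluded). NREM is stages 2–4; interruptions strictly shorter
than 60 s remain inside a bout with their time redacted, an interruption of
exactly 60 s splits. A sub-minute *gap in the hypnogram* is not treated as
a microarousal — only scored non-NREM time is. Each segment is tiled into
10-min epochs anchored at the segment start (not wall clock), the terminal
partial epoch is kept, and rates are normalized by the analyzed minutes
(epoch length minus redacted time). Events are attributed to epochs by
their start time. Two invariants are enforced by tests: total counted
events equal `Σ R·analyzed_min`, and a continuous two-hour block yields
exactly twelve 10-min epochs. No minimum analyzed time per epoch is
enforced (none is stated for the original analysis); fully redacted epochs
are dropped with a log entry.

For display, channels are grouped by SOZ/RV membership and then arranged
by optimal-leaf-ordered average-linkage clustering on the correlation
distance between rate profiles; the permutation never touches the values.

## Asymmetry

`A = (mean_in − mean_out) / (mean_in + mean_out)` over channel-mean rates.
A value is only computed when some channel in the tested scope exceeds
0.5 HFOs/min (strictly; lower rates are unlikely to be epileptic), and the
per-subject value averages epochs weighted by analyzed minutes, which makes
it the asymmetry of total events / total time when partial epochs exist
(whether the original per-subject average weighted epochs is not stated;
the weighted version is the unbiased rate estimate). Identities tested:
A = +1 / 0 / −1 for all-inside / equal / all-outside, exact antisymmetry
under mask complement, invariance under uniform rescaling, |A| ≤ 1.

## Source separation and categorization

NMF minimizes the Frobenius loss with multiplicative updates: uniform
random initialization scaled to the data magnitude, at most 500 iterations,
relative tolerance 1e-6 checked every 10 iterations. The inner loop is
numba-jitted (pure-numpy fallback) because the categorization performs
thousands of fits on small matrices; tests cross-check fit quality against
scikit-learn's independent NMF implementation and against the closed-form
rank-1 SVD solution. A single global scale is moved from W into H so the
mean summed effective rate per epoch equals the mean entry of `W × H`
(whether the original convention was global or per-source is ambiguous;
global is used and noted). Multiplicative updates drive H entries for
all-zero epochs to exact zero, but the zero-epoch rule still uses a 1e-12
absolute tolerance as a guard.

K-selection decrements from `min(channels, epochs, 12)` whenever any
factor pair exceeds Spearman 0.30 in time or space ("greater than 30 %" is
read as the signed correlation; every unordered pair is checked, one
exceedance triggers the decrement). Each decrement refits from a fresh
initialization with the seed offset by K, so local minima are not
inherited across K. A degenerate factor (constant or all-zero row/column)
makes the correlation undefined and is treated as redundancy — K is
reduced — since a null source means K was too large.

Category rules: **d** if every channel is below 0.5 HFOs/min in every
epoch (deterministic, NMF-free, short-circuits the vote); otherwise **c**
if K > 1; otherwise the consistency rule on H's single row — **a** iff
≥ 40 % of epochs are *strictly* above the row mean and ≤ 5 % of epochs are
zero, else **b**. The strict reading means a perfectly constant noiseless
row classifies as **b**; this edge case is documented and tested. Ten
repetitions vote; ties resolve toward complexity (c > b > a).

## Longitudinal and cohort analyses

Nightly analysis classifies each night's 01:00–03:00 window independently
(calendar night of the 1 AM timestamp; nights without analyzed time are
skipped) and reports the number of distinct labels. The stopping-time
analysis classifies all epochs starting before each grid hour (default:
every integer hour from first to last epoch), carrying the previous label
forward when no new epochs arrived; hours before the first epoch are
undefined. The cumulative rule uses *all* epochs up to the stopping hour,
not a recent window. `stabilization_summary` reports the hour of the last
label change (0 if none), and a cohort helper gives the median with a
bootstrap 95 % CI.

Cohort fractions treat per-category subject counts as Poisson (error
√count / total); multi-night subjects contribute 1/n_nights per night so
each subject's weight sums to one (applied at the cohort level only).
Binary comparisons use the one-df χ² on the 2×2 table without continuity
correction (the plain statistic; correction is switchable).

## Synthetic data: what it emulates and what it does not

The EEG generator produces white Gaussian background low-passed at 1 kHz
and rescaled to the stated SD (optional 1/f shaping, off by default),
Tukey-tapered sinusoid bursts for HFOs (the taper avoids edge clicks that
would themselves trigger the artifact detector), one-sample-rise
exponential-decay transients at 20× background SD (τ = 10 ms), and
synchronous common bursts. The detection benchmark injects 20 clean bursts
at 8× background SD (110–240 Hz, 8–12 cycles) plus 5 bursts coincident
with all-channel transients, on 8 channels over ~54 s. Real iEEG has
colored spectra, state-dependent nonstationarity, spikes and sharp waves,
and HFO amplitudes near the detection floor; passing these benchmarks
demonstrates the mechanics of detection and redaction, not clinical-grade
sensitivity. Amplitude and SNR defaults are calibration choices — the
source publication does not state real HFO amplitude distributions.

The rate generator draws Poisson counts about `10 min × Σ_k w_k h_k` per
epoch. Default category conditions (chosen once as a plausible overnight
record: 10 channels, 30 epochs ≈ 5 h analyzed NREM, source rates of a few
HFOs/min on 2–3 active channels with graded weights):

* **a** — one source, sinusoidally modulated envelope (mean 3 HFOs/min,
  ±40 %, floor 0.5), redrawn under its seed until > 40 % of epochs are
  above the mean;
* **b** — one source active in a contiguous 30 % block at 3–5 HFOs/min,
  zero elsewhere;
* **c** — two sources on disjoint channel triplets, active in
  complementary epoch blocks (pairwise envelope Spearman < 0.3 and
  disjoint dominant channels are asserted before emitting);
* **d** — low uniform rates (0.15 HFOs/min expectation) with counts
  truncated at 4 per epoch, so the realized matrix certifiably satisfies
  the < 0.5 HFOs/min definition — untruncated Poisson noise would
  stochastically break the ground-truth label.

Sources spanning a single channel, strongly unbalanced source durations,
or rates near the 0.5 HFOs/min boundary are harder for NMF and are *not*
part of the default conditions; one test probes the single-channel 3×3
case and documents that recovery there is majority-correct rather than
certain.

## Numerical choices and limitations

Seeds: every stochastic component takes an explicit seed; repetition r of
the vote uses `seed·1009 + r (mod 2³¹)` and K-fits offset by K. Detection
is fully deterministic. Problem sizes in tests and the acceptance script
(100 scenarios per category, 20-seed detection benchmark, 60 K-selection
fits) were chosen to give stable percentages at interactive runtimes.
Known limitations: the Hilbert-transform detector used as a third scheme
in the source study is out of scope; EDF export is not provided (signals
interchange as CSV + YAML sidecar; EDF is read via `mne` when installed);
sleep staging and seizure marking are consumed as annotations, never
inferred; and the artifact detectors are functional reconstructions, not
re-implementations of published formulas.
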