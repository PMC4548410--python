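# Methods

This note documents the models, estimators, parameter defaults, and
numerical choices behind each analysis stage, and what the synthetic data
do and do not emulate. Units throughout: currents in pA (outward
positive — inhibitory currents at depolarized holding potentials are
positive deflections), times in ms, potentials in mV, distances in µm.

## Recording model and containers

A recording is a trial × sample matrix of membrane current at 20 kHz with
a voltage-step protocol. The paired protocol steps the presynaptic cell
from V_h = −70 mV to +20 mV for 200 ms with the postsynaptic cell held at
+30 mV; the autaptic protocol steps a single cell from −70 to +60 mV for
2–4 ms and returns to −20 mV, at which the current is measured. Each
protocol carries an `artifact_blank_ms` window (default 1.0 ms) excluded
from peak searches after every step transition — longer than typical
capacitive transients, much shorter than the 12 ms latency bound. Sweeps
are stored one recording per HDF5 file (`/traces`, `/protocol`, `/meta`)
in their native float dtype, so the read/write round trip is bit-exact;
no filtering is applied on read or write.

## Connection detection

The classifier follows a three-part conjunction on the trial-averaged
trace, baselined on the 50 ms before stimulus onset (unbiased SD):

1. **Peak**: largest absolute deviation from the baseline mean within the
   artifact-blanked 30 ms post-onset window ≥ 2 baseline SD (a tie at
   exactly 2 counts as passing).
2. **Presence**: a per-trial deflection — ≥ 2 per-trial-baseline SDs from
   the per-trial baseline mean, in the polarity of the averaged peak,
   sustained ≥ 1 ms contiguously — in ≥ 80 % of trials.
3. **Kinetics**: Boltzmann-fit onset latency < 12 ms and 10–90 % rise
   time < 4 ms (both strict).

With unfiltered i.i.d. Gaussian noise the 30 ms window holds 600 samples,
so the maximum of a pure-noise averaged trace exceeds 2 SD with
probability near one: criterion 1 alone is a weak filter, and the
detector's specificity comes from the conjunction — a sustained 1 ms
excursion (20 consecutive supra-threshold samples) is astronomically
unlikely under independent noise, and noise peaks rarely present compliant
kinetics. On the benchmark of 100 planted compliant pairs (15 pA, 7 ms
latency, events in every trial) and 100 pure-noise pairs, the detector
measures sensitivity 1.00 and false-positive rate 0.00.

A post-hoc anomaly flag marks averaged baselines containing an excursion
beyond 5 SD, mirroring manual screening for large baseline deviations.

### Latency: Boltzmann tangent intersection

The rising phase is fit with I(t) = base + amp / (1 + exp((t½ − t)/k));
the latency is where the maximal-slope tangent meets the baseline, which
for this sigmoid is t½ − 2k (the tangent at t½ has slope amp/4k and
passes through base + amp/2). A sigmoid never intersects its own baseline
asymptote, so the tangent intersection is the natural operational reading
of "onset"; it is exact for sigmoid rises (t½ = 8 ms, k = 0.5 ms gives
7.000 ms) and the convention is documented rather than asserted as unique.

The fit window runs from the end of the artifact blank to the peak sample,
i.e. it includes the pre-event baseline, not only the rising samples.
Fitting the rising samples alone puts the sigmoid's foot systematically
before the true onset of concave rises such as a difference of
exponentials (measured bias −1.2 ms); anchoring with baseline samples
removes it (bias −0.02 ms, max |error| 0.09 ms over 100 noise seeds at
the benchmark SNR). Initialization: base 0, amp at the peak, t½ at the
half-maximum crossing, k = (t90 − t10)/4.4; bounded least squares
(`scipy.optimize.curve_fit`), xtol 10⁻⁸, max 500 evaluations. A fit
failure or negative latency invalidates criterion 3.

### Rise time

10 % and 90 % crossings of (peak − baseline) by linear interpolation. The
10 % crossing is the *last* sub-10 % sample before the peak (the rise's
own foot): taking the first post-onset crossing lets baseline noise cross
10 % of a small peak milliseconds early. The 90 % crossing is the first
after the foot. Dense-grid oracle for the default kinetics
(τ_r = 1 ms, τ_d = 20 ms): 1.571 ms.

### Amplitude readout

The criterion-1 peak is the raw windowed maximum and therefore rides the
noise crest (≈ +2 noise SDs, measured 16.3 pA for planted 15 pA events).
For amplitude *summaries* `peak_amplitude` applies a 0.5 ms boxcar before
the peak search (measured 15.2 pA); detection criteria never use the
smoothed readout.

### I–V reversal

Zero-current crossing of the piecewise-linear I–V interpolation; if the
currents never change sign, the least-squares line's zero is returned with
an `extrapolated` flag and a warning. The interpolation estimator carries
a small crossing-selection bias under noise (≈ 0.3 mV at 0.5 pA noise on a
0.2 pA/mV relation) — a property tests document against the unbiased
regression oracle.

## Autapse detection

The intrinsic depolarization-evoked transient is modeled as
offset + A₁e^(−t/τ₁) + A₂e^(−t/τ₂) from the return to −20 mV. Residual
criteria are evaluated on the first 30 ms after the return; three
numerical choices make the residual faithful to the synaptic event:

- **Non-negative amplitudes.** The transient is a decaying outward
  current. Unconstrained, the difference of two exponentials is exactly a
  synaptic-bump shape, and least squares will happily morph into
  intrinsic-plus-half-the-event, erasing the residual the classifier
  thresholds.
- **Sigma-clipped fitting.** Samples whose outward residual exceeds the
  2-SD threshold are excluded and the remainder refit (up to 6 passes,
  retaining ≥ 30 samples), so the model represents the intrinsic current
  rather than intrinsic + event. The residual is always recomputed on the
  full window against the final parameters.
- **Extended fit window.** The model is fit over up to 100 ms of the
  post-return decay although criteria use only the first 30 ms: a 20 ms
  decay event occupies most of a 30 ms window and is itself nearly a
  double exponential, so the short window cannot identify the slow
  intrinsic component once an event rides on it; the near-flat tail
  (where the invariant guarantees the transient has fallen below 5 % of
  its peak and any event has decayed) pins it.

Initialization is by log-linear peeling (tail → slow component, early
remainder → fast), with three randomized restarts; the optimizer sees
every 4th sample (the smooth exponential model does not need 20 kHz) while
residuals are full-resolution. A cell whose fit never converges, or whose
averaged post-return trace dips below −500 pA (calcium-like inward
saturation, as in very young tissue), is excluded with an anomaly flag.

Candidates (residual > 2 pre-stimulus-baseline SD) then pass the three
connection criteria on the residual trace, with latency referenced to the
start of the +60 mV step. For the per-trial presence test each trial's
segment is compared against the *one* intrinsic model fitted to the
averaged trace — the transient is trial-invariant, and refitting each
noisy trial would re-absorb the event's decay (measured: per-trial refits
recover only ~half the event and push presence fractions below 0.8 for
true autapses). Benchmark at study conditions (20 pA events, 2 pA noise):
100/100 planted cells detected, 0/100 false alarms.

Population summaries report per-genotype autapse frequency with binomial
SE = √(p̂(1−p̂)/n).

## Direction selectivity

Spikes are threshold crossings (default median + 5·MAD, scaled to Gaussian
SD) with 1 ms refractory enforcement. Histograms use 50 ms bins anchored
at stimulus onset, partial trailing bins dropped; rates are
counts/(bin · n_trials). ON and OFF epochs derive from bar geometry: a
300 µm receptive-field window centered on the soma, crossed by the leading
(ON) and trailing (OFF) edge of a 300 µm-wide, 1000 µm-long bar at
1000 µm/s — generators emit these markers so simulation and analysis share
one definition. Peak rates are the maximal bin rates inside each epoch.

DSI = |Σ r e^{iθ}| / Σ r (the standard normalization, bounded by 1), its
argument the preferred angle. The axis convention (ventral = 270° by
default) is stored in every spike-train set. Deviations and ON/OFF
differences are minimal circular differences in [0°, 180°]; the ventral
projection sums per-direction maximal ON and OFF rates into one vector and
projects its DSI onto the unit ventral vector. ON and OFF responses can be
pooled or treated as independent points; both modes are exposed (the
per-cell summary reports ON, OFF, and combined).

Note one measurement property the tests quantify: a peak rate is a max
over bins, which inflates low-rate directions more than high-rate ones, so
the measured DSI of a tuned cell sits below the DSI of the underlying
intensity profile. The recovery test therefore uses the expected-max
Poisson oracle, not the raw intensity profile, as its reference.

## Connectivity statistics

The unit of analysis is the directed test; bidirectionally tested pairs
contribute two. Distance bins are left-closed/right-open with the last bin
closed (default edges 35, 100, 175 µm: 100 µm falls in the far bin);
binomial SE on p̂ throughout.

The reciprocity null pools p̂ over all directed tests (distance-stratified
estimation is available via the table interface) and simulates each
bidirectionally tested pair as two independent Bernoulli(p̂) draws —
10⁵ simulations by default, chunked. The closed form
(n p², 2np(1−p), n(1−p)²) is kept as an independent oracle; simulated
means converge to it within 1 % at 10⁵ simulations.

Three p-value variants are reported for the observed
(bidirectional, unidirectional, unconnected) counts:

- `p_values` — two-sided percentile with add-one smoothing
  (r+1)/(n_sim+1): never zero, always valid, but conservative for a
  discrete count (stochastically larger than uniform under the null);
- `p_values_mid` — deterministic mid-p (half-weight on ties),
  approximately uniform;
- `p_values_randomized` — randomized-rank construction
  (#{sim < obs} + U·(#{sim = obs}+1))/(n_sim+1), folded two-sided:
  exactly uniform under exchangeability. Uses the same seeded RNG.

Plugging in the p̂ estimated from the same table couples null and
observation and adds conservatism of its own; `p_null` accepts an
externally estimated probability (e.g. pooled over a larger dataset) for
calibrated inference. Calibration is verified by simulation: with the
null parameter known, randomized p-values over 200 null replicates pass a
KS uniformity test at α = 0.01.

`combined_relative_strength` multiplies a genotype's connection frequency
relative to control by its relative mean amplitude — a population
connecting at 20 % of the control rate with 40 % of the control amplitude
carries 8 % of the control connection strength.

## Mosaic geometry

The density recovery profile counts neighbors in 10 µm annuli up to
150 µm around each *interior* reference cell (cells ≥ r_max from every
field boundary), dividing by n_ref × annulus area; the interior buffer is
unbiased without analytic edge correction. The effective radius is the
inner edge of the first annulus reaching the mosaic's mean density —
definitions vary across the literature, so the full profile is always
reported alongside. Dendritic overlap uses the exact circle-intersection
area (πR² at d = 0, 12 283.7 µm² at d = R = 100 µm, 0 at d ≥ 2R),
cross-checked against Monte-Carlo integration.

## Synthetic data: what it emulates, and what it does not

Defaults are the study conditions: postsynaptic currents as
peak-normalized differences of exponentials (amplitude 15 pA synaptic /
20 pA autaptic, latency 7 ms from step onset, τ_r 1 ms, τ_d 20 ms —
rise < 4 ms), 20 % amplitude CV and 10 % failure rate per trial
(unreported in the source data; chosen as realistic trial variability and
kept configurable), ~10 repetitions per pair, i.i.d. Gaussian noise of
SD 2 pA. The intrinsic transient defaults to 200 pA/5 ms + 50 pA/30 ms,
satisfying the <100 ms decay constraint. Direction tuning is a von-Mises
rate modulation (baseline + peak·exp(κ(cosΔ−1)), defaults κ = 2, peak
100 Hz, baseline 2 Hz) driving an inhomogeneous Poisson process — the
minimal circular unimodal choice; the measured system's tuning is an
empirical quantity, not a model commitment. Mosaics use random sequential
adsorption with a 10⁴-attempt cap per point. The default connection table
(juvenile near/far 0.60/0.25; adult 0.10/0.30 for controls, with proximal
connections retained in the knockout and ~5× lower frequency in the
single-isoform genotype; autapse probability 0.75 in the knockout, 0 in
controls) encodes the qualitative contrasts — near pairs over twice as
likely to be connected in juveniles, elimination of proximal connections
with maturation — with illustrative magnitudes, since exact probabilities
are not printed as numbers in the source.

Not emulated: low-pass filtering of the recording chain (noise here is
white; real contiguity statistics are easier under correlated noise, so
the presence criterion is tested under the harder condition),
conductance-based or multicompartment SAC biophysics, stimulus artifacts
beyond a blanking window, electrode drift, series-resistance errors, and
the SAC–SAC network mechanism underlying direction selectivity itself.
Passing benchmarks on these data therefore validates the estimators'
statistical behavior at realistic SNR, not the biophysics of real
recordings.

Every generator is a pure function of (parameters, seed); planted ground
truth is emitted in metadata.

## Pipeline

`run_pipeline` validates a YAML config (pydantic schema; errors name the
offending field), derives per-stage RNG streams from the config seed via
stable labels, isolates stage failures, and writes CSV/JSON artifacts, a
JSON-lines run log with the config hash, and a sorted-key `summary.json`
that is byte-identical across reruns of the same config.
`compare_groups` applies a stock Welch t-test to per-cell metrics between
cohorts and is flagged descriptive (no multiplicity correction). Group
comparisons in the package delegate to stock statistics routines
throughout; no test statistic is re-derived.

## Problem sizes in the shipped checks

The test suite and acceptance script run in minutes on one CPU:
200-pair detector benchmarks, 100 + 100-cell autapse benchmarks, 10⁵
reciprocity simulations, 10⁴-pair probability recovery, 500-replicate
coverage checks, and 200-replicate calibration checks. These sizes give
Monte-Carlo error comfortably inside each asserted tolerance; none of the
estimators is sensitive to them.

## Known limitations

- The Boltzmann tangent convention is one defensible reading of "onset";
  absolute latencies from other conventions (e.g. first threshold
  crossing) differ by fractions of a millisecond.
- The autapse residual underestimates event amplitude (~80 % recovery at
  study conditions) because intrinsic fit and event are not perfectly
  separable even with the extended window; verdicts and kinetics are
  unaffected, amplitude summaries from residuals are lower bounds.
- The plug-in reciprocity null is conservative; use `p_null` for
  calibrated inference when an external probability estimate exists.
- `estimate_reversal`'s interpolation has a small noise-dependent bias
  relative to the regression line's zero crossing.
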