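# Methods

`csdscope` analyzes one-hour, three-channel DC-coupled ECoG recordings of
awake, head-restrained mice during continuous occipital KCl application:
two electrodes over the left (ipsilateral) hemisphere — primary motor
cortex (M1) and primary sensory cortex (S1), 2 mm apart — and one over
right M1. Two phenomena are scored per animal: cortical spreading
depression (CSD), a slowly propagating depolarization wave visible as a
large, slow negative DC shift confined to the ipsilateral hemisphere, and
epileptiform activity, generalized low-frequency (0.5–4 Hz) spike
discharges. Because no recordings from such experiments are publicly
deposited, the package ships a synthetic generator with exact ground
truth; every detector and the statistical battery are validated against
it.

## Signal conditioning

All analysis runs at 300 Hz (polyphase FIR resampling for other input
rates). Two offline chains are applied to the raw trace independently:

* **DC chain** — 0.005 Hz high-pass + 100 Hz low-pass, for CSD analysis.
* **Spike chain** — 0.5 Hz high-pass + 100 Hz low-pass, for epileptiform
  analysis.

Both use 2nd-order Butterworth sections run forward-backward. The
forward-backward output is additionally averaged with its time-reversed
application, which makes filtering *exactly* symmetric under time
reversal: event onsets carry no direction-dependent edge bias, at twice
the filtering cost. Edge padding extends one period of the lowest cutoff
(odd extension), enough for the interior to be transient-free.

## CSD detection

1. Smooth the DC-chain trace with a centered 2 s moving average. CSD
   shifts evolve over tens of seconds, whereas superimposed epileptic
   spikes (which pass the DC chain) live at ~0.1 s; smoothing removes the
   spikes without touching the shift.
2. Estimate the background spread of the *unsmoothed* trace blockwise:
   MAD-based spread per 10 s block, lower quartile across blocks. Blocks
   containing CSDs or dense spiking have inflated spreads and fall above
   the quartile, so events cannot raise their own detection threshold.
3. Threshold: `max(8 × spread, 2 mV)` below baseline. Excursions are
   merged when closer than 60 s, must stay below threshold ≥ 10 s, and a
   trough within ~5 s of a trace edge is discarded (truncated wave or
   filter boundary transient).
4. Per event: trough = minimum; onset = last downward crossing of
   0.2 × trough depth before the trough (the start of the depolarization
   wave); duration = onset to the recovery crossing of the same level.

CSD frequency is the event count per hour on S1 left (the electrode
nearest the KCl site registers each wave first; the counting channel is
configurable). Propagation speed divides the 2 mm electrode separation by
the onset difference of the **first** CSD between S1 and M1, in mm/min;
per-event speeds are also exposed but the headline figure uses the first
pair only. Onset timing resolution is one sample (1/300 s), so
quantization contributes < 1% speed error at physiological speeds.

Published descriptions of CSD identification in this preparation are
qualitative (characteristic DC shifts, identified by inspection); all
numeric thresholds here are the package's own, live in
`CsdDetectParams`, and are recorded in every run's provenance block.

## Epileptiform analysis

Spikes are suprathreshold absolute deflections of the spike-chain trace:
threshold `5 × spread` (same blockwise background estimator), one
detection per 50 ms refractory window, and a multiphasic-merge rule — a
peak within 120 ms of a larger opposite-polarity peak is the same spike's
afterwave, not a second spike. Without the merge rule every large
interictal spike double-counts.

Bouts are maximal runs of ≥ 3 spikes with inter-spike gaps ≤ 2 s. The
**onset** of epileptiform activity is the first spike of the first bout:
activity begins in bouts, and an isolated suprathreshold crossing that
never organizes into a train is treated as noise (at the 5×MAD threshold,
background alone produces ~2 isolated crossings per hour, which would
otherwise fabricate onsets in animals without any activity). The
**terminal class** over the final 10 minutes is `continuous` when spiking
spans the window with no gap > 2 s (including the window edges), `bouts`
when organized activity exists but that fails, `none` when no bout ever
occurred.

**Severity** is the mean 0.5–4 Hz power density of the last 10 minutes
divided by the first 10 minutes, from Welch spectra (30 s Hann segments,
50% overlap). "Power at spike frequency" is read as the band mean rather
than a single dominant-frequency bin, which would be unstable. Severity
and onset are scored on M1 left (activity consistently appears there
first; configurable). Recordings shorter than one hour are allowed —
severity then uses the last available 10 minutes and the annotation is
flagged. Activity is **generalized** when the contralateral channel has
an onset within 60 s of the ipsilateral one.

## Cross-correlation timing

Channel-pair similarity uses the coefficient normalization: the raw
cross-correlation of the mean-removed traces scaled so each trace's
zero-lag autocorrelation is 1, evaluated on a ±2 s lag grid at sample
resolution over the terminal 10 minutes (the window with the strongest
activity; configurable). The reported peak is the extremum of largest
magnitude with its sign, so an inverted signal correlates at −1 rather
than being missed. Lag sign convention: positive = first-named channel
leads. Ties break toward the smallest |lag|, then the negative lag. A
flat channel raises an exclusion signal for the whole subject, so a dead electrode
excludes the animal, as bad channels exclude animals in practice.

## Group statistics

Per-subject summaries feed a fixed battery, all two-tailed at α = 0.05:

* Mann-Whitney U per group, wild type vs mutant, on CSD frequency and
  speed. Midrank ties; exact enumeration p when n₁+n₂ ≤ 25 without ties,
  otherwise the tie-corrected normal approximation with continuity
  correction. The reported statistic is the larger of the two U values,
  the convention under which complete separation prints U = n₁·n₂.
* Kruskal-Wallis (tie-corrected, df = k−1) across the four groups within
  each genotype, followed — only after a significant omnibus — by Dunn's
  pairwise z tests on mean-rank differences with tie-corrected pooled
  variance and Bonferroni correction (p × number of pairs, capped at 1).
* Epileptiform onset: Kruskal-Wallis over five groups — wild types pooled
  (few develop activity) plus the four mutant cells — then Dunn's tests
  (10 pairs). Subjects without activity have no onset and are excluded;
  the report states how many.
* OLS regressions over mutant subjects only: severity~frequency,
  onset~frequency, severity~onset, each reported as the slope t
  (t = slope/SE, df = n−2).
* Paired t-tests across subjects between the three channel pairs, for
  both the peak coefficient and the absolute lag.

A note on the originating analyses: published Dunn post-hoc statistics in
this design are often labeled "t" with software-specific scaling; this
package reports the standard mean-rank z, so only direction and
significance — not the magnitude of that statistic — are comparable
across implementations.

## The synthetic generator

What it emulates, per channel (values are defaults, all in `SimParams`):

* **CSD events**: a fixed template — brief positive deflection, steep
  descending limb (σ ≈ 2.7 s), deep trough (−10 mV) at 25% of the 60 s
  span, slow recovery with a mild after-depolarization — placed by a
  gamma renewal process (CV 0.2) at 6/hr (WT), 12/hr (mutant) or 8/hr
  (post-menopausal mutant females). KCl-driven CSDs recur near
  rhythmically, hence the low-CV renewal rather than a Poisson process;
  it also keeps events non-overlapping. Events appear on M1 and S1 left
  only, S1 delayed by exactly d/v (d = 2 mm; v = 3.5 WT / 5.0 mutant
  mm/min). Ground-truth onsets are defined on the template *after* the DC
  chain, at the 20%-of-trough crossing — the same operational definition
  the detector uses — so onset errors are meaningful; the S1−M1 lag is
  exactly d/v either way.
* **Spikes**: a sharp negative transient (σ = 22 ms) with a 25% positive
  afterwave, in bouts (4–12 s at 2 Hz, exponential gaps) from the onset
  time, optionally escalating to uninterrupted firing covering the final
  window. Amplitude 2.2 mV ramps linearly to `severity_growth` × by the
  end of the recording. All three channels spike; M1 left leads, S1 left
  by 10 ms, M1 right by 30 ms, plus 5 ms per-channel Gaussian jitter —
  which is exactly why the S1L–M1R pair, combining both jitter sources,
  is the least correlated — the expected ordering for activity
  spreading out from ipsilateral M1.
* **Noise**: independent 1/f Gaussian noise per channel, std 0.6 mV,
  chosen so the filtered CSD trough SNR is ≈ 20 and the spike SNR ≈ 6
  (detection reliable but not trivial).
* **Cohorts**: default cell sizes are 8, 8, 7, 7 wild types and
  9 per mutant cell. Per-subject parameters are drawn around the cell
  preset: speed ±8%, log-normal conduction-lag jitter, a terminal-class
  draw (wild types: 70% none / 30% bouts; mutants: 45% bouts / 55%
  continuous), and a latent susceptibility coupling earlier onset to
  faster severity growth, emulating the covariation of phenotype
  severity across animals. Only the *orderings* between cells are
  fixed by the modelled phenotypes; the magnitudes are physiological choices and are
  plain data in `simulate.py`.

Per-subject seeds derive from the master seed via
`SeedSequence(master, spawn_key=(index,))`; identical configurations
reproduce recordings and reports bit-for-bit.

What it does **not** emulate: 2-D wave geometry (propagation is a pure
delay), electrode drift and movement artifacts, the amplifier's hardware
filter shape, behavioral correlates, and any biophysics of the
depolarization itself. Passing recovery tests therefore show that the
algorithms measure what they claim on signals with the modelled morphology
and SNR — not that they are robust to every artifact of real recordings.

## Numerical choices and degenerate inputs

* Spread estimation: MAD scaled by 1.4826; blockwise lower quartile for
  detection thresholds; iteratively clipped global MAD for short traces.
* A flat trace or a DC-offset-dominated trace raises a quality error
  instead of producing events; zero-variance correlation inputs and
  zero-variance paired differences raise typed errors (a constant
  non-zero paired shift reports an infinite t with p = 0).
* `kruskal_wallis` returns H = 0, p = 1 when every value is identical.
* Welch band power of a zero trace is 0; severity with a silent first
  window raises an undefined-severity error.
* Problem sizes in the validation suite: detector recovery runs 20
  one-hour recordings at default SNR; severity and lag-recovery contracts
  use 20–25-minute recordings (the shortest spans their definitions
  allow); the cohort calibration runs the full 66-subject design at one
  hour for 20 master seeds (~0.55 s per subject).

## Known limitations

* Detection defaults are tuned to the modelled signal regime (trough
  SNR ~20, spike SNR ~6); far noisier data will need `CsdDetectParams` /
  `SpikeDetectParams` adjustments.
* The onset definition (first bout) deliberately ignores isolated
  spikes; in data where single interictal spikes are meaningful, lower
  `bout_min_spikes`.
* Speed uses two electrodes on one axis: it measures the apparent speed
  along M1→S1 and cannot resolve wave direction in 2-D.
* EDF export quantizes to 16 bits over each channel's range (~0.3 µV
  resolution for a ±10 mV span); the HDF5 container is lossless.
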